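"""AOI polygon geometry: pixel/degree conversion, layout descriptors, and
fixation-to-AOI assignment under the category overlap-priority rule.

When AOI polygons overlap, a fixation on the shared region is attributed to
the most actionable/diagnostic element: Website/CTA > Logo > Symbol >
Source/Authority > Text > Image/Visual. Points exactly on an edge count as
inside (AOIs are closed polygons). Equal-priority overlaps are broken by
smaller pixel area, then lexicographic AOI id, so specific elements beat
large backdrops deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from shapely.geometry import Point, Polygon

from gazeatlas.core import CATEGORY_PRIORITY, Category, ScreenGeometry, ValidationError

__all__ = [
    "AOIDefinition",
    "px_per_degree",
    "aoi_descriptors",
    "assign_fixation",
    "assign_fixations",
]


def px_per_degree(geometry: ScreenGeometry) -> float:
    """Pixels subtended by 1 degree of visual angle at the viewing distance.

    Uses the small-patch chord approximation 2 * d * tan(0.5 deg) for the
    physical extent of one degree, converted through horizontal px/cm. At
    60 cm one degree spans ~1.05 cm, i.e. ~38 px on a 1920 px / 53 cm panel.
    """
    if geometry.viewing_distance_cm <= 0:
        raise ValidationError("viewing distance must be positive")
    cm_per_degree = 2.0 * geometry.viewing_distance_cm * math.tan(math.radians(0.5))
    return cm_per_degree * geometry.width_px / geometry.width_cm


@dataclass
class AOIDefinition:
    """A polygonal area of interest on one stimulus.

    ``priority_rank`` is derived solely from the category (1 = highest).
    ``area_px2`` and ``eccentricity_px`` are layout covariates filled in by
    :func:`aoi_descriptors`.
    """

    ad_id: str
    aoi_id: str
    category: Category
    vertices: list[tuple[float, float]]
    priority_rank: int = field(init=False)
    area_px2: Optional[float] = None
    eccentricity_px: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValidationError(
                f"AOI {self.aoi_id!r} needs >= 3 vertices, got {len(self.vertices)}"
            )
        if not self.polygon.is_simple:
            raise ValidationError(f"AOI {self.aoi_id!r} polygon is self-intersecting")
        self.priority_rank = CATEGORY_PRIORITY[self.category]

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def contains(self, x: float, y: float) -> bool:
        """Closed containment: boundary points count as inside."""
        # shapely covers() = contains or touches the boundary
        return self.polygon.covers(Point(x, y))


def aoi_descriptors(
    aoi: AOIDefinition, geometry: ScreenGeometry
) -> tuple[float, float]:
    """Compute (area_px2, eccentricity_px) layout covariates for an AOI.

    Area is the absolute polygon area (shoelace); eccentricity is the
    Euclidean distance from the polygon centroid to the screen center.
    Results are also written back onto the AOI. Degenerate (zero-area)
    polygons are rejected.
    """
    poly = aoi.polygon
    area = poly.area
    if area <= 0:
        raise ValidationError(f"AOI {aoi.aoi_id!r} polygon is degenerate (zero area)")
    cx, cy = poly.centroid.x, poly.centroid.y
    sx, sy = geometry.center_px
    ecc = math.hypot(cx - sx, cy - sy)
    aoi.area_px2 = area
    aoi.eccentricity_px = ecc
    return area, ecc


def assign_fixation(
    point: tuple[float, float], aois: Sequence[AOIDefinition]
) -> Optional[str]:
    """Return the AOI id owning a point, or None if no polygon contains it.

    Among containing AOIs, the highest-priority category wins; equal
    priority falls back to smaller area, then lexicographic AOI id.
    """
    x, y = point
    hits = [a for a in aois if a.contains(x, y)]
    if not hits:
        return None
    best = min(hits, key=lambda a: (a.priority_rank, a.polygon.area, a.aoi_id))
    return best.aoi_id


def assign_fixations(fixations, aois: Sequence[AOIDefinition]):
    """Assign each fixation's centroid to an AOI in place; returns the list."""
    for fx in fixations:
        fx.aoi_id = assign_fixation((fx.cx_px, fx.cy_px), aois)
    return fixations
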