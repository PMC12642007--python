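"""Atlas rendering: normalized Gaussian attention heatmaps, dominance and
support heatmaps with low-support masking, top-AOI bars, early-vs-sticky
quadrant scatters, and subgroup delta heatmaps.

Every figure is written alongside the exact table it renders, so the plots
never carry numbers the analysis modules did not produce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from gazeatlas.core import FixationRecord, ScreenGeometry, ValidationError
from gazeatlas.dominance import DominanceRanking, PairwiseMatrix, apply_support_mask
from gazeatlas.geometry import px_per_degree

__all__ = ["HeatmapGrid", "AtlasPanelSpec", "attention_heatmap", "render_panel"]

_KNOWN_PLOTS = (
    "dominance_heatmap",
    "top5_bars",
    "category_heatmap",
    "quadrant_scatter",
    "delta_heatmaps",
)


@dataclass
class HeatmapGrid:
    """A [0, 1]-normalized attention intensity grid for one ad/subgroup."""

    ad_id: str
    subgroup: str
    values: np.ndarray
    sigma_deg: float
    downsample: int = 1

    def max(self) -> float:
        return float(self.values.max())


@dataclass
class AtlasPanelSpec:
    """What to draw for one ad's atlas panel and where to put it."""

    ad_id: str
    out_dir: Path
    plots: tuple[str, ...] = _KNOWN_PLOTS
    mask_threshold: int = 5

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not self.plots:
            raise ValidationError("atlas panel must select at least one plot")
        unknown = [p for p in self.plots if p not in _KNOWN_PLOTS]
        if unknown:
            raise ValidationError(f"unknown plot(s) {unknown}; options: {_KNOWN_PLOTS}")


def attention_heatmap(
    fixations: Sequence[FixationRecord],
    geometry: ScreenGeometry | None = None,
    sigma_deg: float = 1.0,
    weight: str = "duration",
    downsample: int = 4,
    ad_id: str = "",
    subgroup: str = "overall",
) -> HeatmapGrid:
    """Splat fixation centroids onto the screen grid, smooth with an
    isotropic Gaussian of the given width in degrees, and normalize to [0, 1].

    Weighting is by fixation duration (dwell-proportional) by default, or by
    count. The maximum is exactly 1 whenever any fixation is present; an
    empty input yields an all-zero grid.
    """
    geometry = geometry or ScreenGeometry()
    if sigma_deg <= 0:
        raise ValidationError("sigma_deg must be positive")
    if weight not in ("duration", "count"):
        raise ValidationError(f"unknown weight {weight!r}; use 'duration' or 'count'")
    ds = max(1, int(downsample))
    h = geometry.height_px // ds
    w = geometry.width_px // ds
    grid = np.zeros((h, w))
    for f in fixations:
        col = min(w - 1, max(0, int(f.cx_px // ds)))
        row = min(h - 1, max(0, int(f.cy_px // ds)))
        grid[row, col] += f.duration_ms if weight == "duration" else 1.0
    if grid.any():
        sigma_px = sigma_deg * px_per_degree(geometry) / ds
        grid = gaussian_filter(grid, sigma=sigma_px)
        grid /= grid.max()
    return HeatmapGrid(
        ad_id=ad_id, subgroup=subgroup, values=grid, sigma_deg=sigma_deg, downsample=ds
    )


def _save(fig, stem: Path) -> list[Path]:
    paths = [stem.with_suffix(".png"), stem.with_suffix(".svg")]
    for p in paths:
        fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    return paths


def _masked_matrix_figure(
    matrix: PairwiseMatrix, order: Sequence[str], title: str
) -> tuple:
    idx = [matrix.keys.index(k) for k in order]
    P = matrix.P[np.ix_(idx, idx)]
    mask = (
        matrix.mask[np.ix_(idx, idx)]
        if matrix.mask is not None
        else np.zeros_like(P, dtype=bool)
    )
    display = np.ma.masked_where(mask | np.isnan(P), P)
    fig, ax = plt.subplots(figsize=(1.0 + 0.5 * len(order), 1.0 + 0.5 * len(order)))
    cmap = plt.get_cmap("coolwarm").copy()
    cmap.set_bad("0.85")
    im = ax.imshow(display, vmin=0, vmax=1, cmap=cmap)
    for (i, j), m in np.ndenumerate(mask):
        if m:
            ax.text(j, i, "x", ha="center", va="center", fontsize=7, color="0.4")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8, label="P(row beats column)")
    return fig, P, mask


def render_panel(
    spec: AtlasPanelSpec,
    aoi_matrix: Optional[PairwiseMatrix] = None,
    ranking: Optional[DominanceRanking] = None,
    category_matrix: Optional[PairwiseMatrix] = None,
    first_hit_pct: Optional[Mapping[str, float]] = None,
    quadrants: Optional[Sequence] = None,
    delta_matrices: Optional[Sequence] = None,
) -> dict[str, list[Path]]:
    """Render the selected atlas plots for one ad, each with its companion
    CSV table.

    The dominance heatmap is reordered by descending dominance score and a
    companion support-N heatmap shows the evidence behind masked cells. The
    quadrant scatter draws the within-ad median first-hit reference (vertical)
    and the S = 0 reference (horizontal). Missing required inputs raise a
    labeled error naming the absent artifact.
    """
    spec.out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[Path]] = {}

    def need(name: str, obj) -> None:
        if obj is None:
            raise ValidationError(f"render_panel: missing required input {name!r}")

    if "dominance_heatmap" in spec.plots or "top5_bars" in spec.plots:
        need("aoi_matrix", aoi_matrix)
        need("ranking", ranking)

    if "dominance_heatmap" in spec.plots:
        m = apply_support_mask(aoi_matrix, spec.mask_threshold)
        order = ranking.ordered_keys() + [
            k for k in m.keys if k not in ranking.ranks
        ]
        fig, _, _ = _masked_matrix_figure(
            m, order, f"{spec.ad_id}: pairwise dwell dominance (by S)"
        )
        paths = _save(fig, spec.out_dir / f"{spec.ad_id}_dominance_heatmap")
        table = spec.out_dir / f"{spec.ad_id}_dominance_heatmap.csv"
        m.to_long_frame().to_csv(table, index=False)
        # companion support-N heatmap
        fig2, ax = plt.subplots(figsize=(1.0 + 0.5 * len(order), 1.0 + 0.5 * len(order)))
        idx = [m.keys.index(k) for k in order]
        im = ax.imshow(m.N[np.ix_(idx, idx)], cmap="Greys")
        ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
        ax.set_yticks(range(len(order)), order, fontsize=7)
        ax.set_title(f"{spec.ad_id}: pairwise support N", fontsize=9)
        fig2.colorbar(im, ax=ax, shrink=0.8, label="N joint observers")
        paths += _save(fig2, spec.out_dir / f"{spec.ad_id}_support_heatmap")
        written["dominance_heatmap"] = paths + [table]

    if "top5_bars" in spec.plots:
        top = ranking.ordered_keys()[:5]
        scores = [ranking.scores[k] for k in top]
        fig, ax = plt.subplots(figsize=(4, 2.5))
        ax.barh(range(len(top))[::-1], scores, color="#3b6fb6")
        ax.set_yticks(range(len(top))[::-1], top, fontsize=7)
        ax.axvline(0, color="0.4", lw=0.8)
        ax.set_xlabel("dominance score S")
        ax.set_title(f"{spec.ad_id}: top {len(top)} AOIs by dominance", fontsize=9)
        paths = _save(fig, spec.out_dir / f"{spec.ad_id}_top5_dominance")
        table = spec.out_dir / f"{spec.ad_id}_top5_dominance.csv"
        pd.DataFrame({"aoi_id": top, "S": scores}).to_csv(table, index=False)
        written["top5_bars"] = paths + [table]

    if "category_heatmap" in spec.plots:
        need("category_matrix", category_matrix)
        m = apply_support_mask(category_matrix, spec.mask_threshold)
        fig, _, _ = _masked_matrix_figure(
            m, m.keys, f"{spec.ad_id}: category dwell dominance"
        )
        paths = _save(fig, spec.out_dir / f"{spec.ad_id}_category_dominance")
        table = spec.out_dir / f"{spec.ad_id}_category_dominance.csv"
        m.to_long_frame().to_csv(table, index=False)
        written["category_heatmap"] = paths + [table]

    if "quadrant_scatter" in spec.plots:
        need("quadrants", quadrants)
        fig, ax = plt.subplots(figsize=(4.5, 4))
        xs = [q.first_hit_pct for q in quadrants]
        ys = [q.S for q in quadrants]
        ax.scatter(xs, ys, s=25, color="#b6452c", zorder=3)
        for q in quadrants:
            ax.annotate(q.aoi_id, (q.first_hit_pct, q.S), fontsize=6,
                        xytext=(2, 2), textcoords="offset points")
        ax.axvline(float(np.median(xs)), color="0.4", lw=0.8)
        ax.axhline(0.0, color="0.4", lw=0.8)
        ax.set_xlabel("first-hit %")
        ax.set_ylabel("dominance score S")
        ax.set_title(f"{spec.ad_id}: early vs sticky", fontsize=9)
        paths = _save(fig, spec.out_dir / f"{spec.ad_id}_early_vs_sticky")
        table = spec.out_dir / f"{spec.ad_id}_early_vs_sticky.csv"
        pd.DataFrame([vars(q) for q in quadrants]).to_csv(table, index=False)
        written["quadrant_scatter"] = paths + [table]

    if "delta_heatmaps" in spec.plots:
        need("delta_matrices", delta_matrices)
        paths: list[Path] = []
        for dm in delta_matrices:
            fig, ax = plt.subplots(
                figsize=(1.5 + 0.6 * len(dm.levels), 1.0 + 0.45 * len(dm.categories))
            )
            lim = max(1.0, float(np.abs(dm.values).max()))
            im = ax.imshow(dm.values, cmap="RdBu_r", vmin=-lim, vmax=lim)
            ax.set_xticks(range(len(dm.levels)), dm.levels, rotation=45,
                          ha="right", fontsize=7)
            ax.set_yticks(range(len(dm.categories)), dm.categories, fontsize=7)
            ax.set_title(
                f"{spec.ad_id}: first-hit delta by {dm.dimension} "
                f"({dm.sign_convention}, pp)",
                fontsize=8,
            )
            fig.colorbar(im, ax=ax, shrink=0.8, label="pp")
            stem = spec.out_dir / f"{spec.ad_id}_delta_{dm.dimension}"
            paths += _save(fig, stem)
            dm.to_frame().round(1).to_csv(stem.with_suffix(".csv"))
        written["delta_heatmaps"] = paths

    return written
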