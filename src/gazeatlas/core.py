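"""Domain types and long-form table I/O shared by every analysis stage.

The analysis unit throughout the package is the *attention record*: one row
per participant x ad x AOI holding time to first fixation (TTFF, ms,
right-censored at the exposure duration), fixation count (FC), total
fixation duration / dwell (FD, ms), and the participant's demographic
strata. A study is a collection of such records plus the screen geometry
under which it was recorded.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Category",
    "ScreenGeometry",
    "GazeSample",
    "FixationRecord",
    "AttentionRecord",
    "StudyTable",
    "ParseError",
    "ValidationError",
    "SchemaError",
    "parse_aoi_label",
    "normalize_category",
    "read_study_table",
    "write_study_table",
    "study_table_to_frame",
    "read_gaze_samples",
    "write_gaze_samples",
    "read_aoi_definitions",
    "write_aoi_definitions",
]


class ParseError(ValueError):
    """A malformed label or file fragment that cannot be interpreted."""


class ValidationError(ValueError):
    """A well-formed value outside the domain the model accepts."""


class SchemaError(ValueError):
    """An input table missing required structure (columns, keys)."""


class Category(str, enum.Enum):
    """The six semantic AOI classes used to group ad elements.

    Priority order for overlapping polygons (most actionable first):
    Website/CTA > Logo > Symbol > Source/Authority > Text > Image/Visual.
    """

    WEBSITE_CTA = "Website/CTA"
    LOGO = "Logo"
    SYMBOL = "Symbol"
    SOURCE_AUTHORITY = "Source/Authority"
    TEXT = "Text"
    IMAGE_VISUAL = "Image/Visual"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Overlap priority: lower rank wins when polygons overlap.
CATEGORY_PRIORITY: Mapping[Category, int] = {
    Category.WEBSITE_CTA: 1,
    Category.LOGO: 2,
    Category.SYMBOL: 3,
    Category.SOURCE_AUTHORITY: 4,
    Category.TEXT: 5,
    Category.IMAGE_VISUAL: 6,
}

_CATEGORY_SYNONYMS = {
    "website/cta": Category.WEBSITE_CTA,
    "website": Category.WEBSITE_CTA,
    "cta": Category.WEBSITE_CTA,
    "logo": Category.LOGO,
    "symbol": Category.SYMBOL,
    "source/authority": Category.SOURCE_AUTHORITY,
    "source": Category.SOURCE_AUTHORITY,
    "authority": Category.SOURCE_AUTHORITY,
    "text": Category.TEXT,
    "image/visual": Category.IMAGE_VISUAL,
    "image": Category.IMAGE_VISUAL,
    "visual": Category.IMAGE_VISUAL,
}


def normalize_category(raw: str | Category) -> Category:
    """Map a raw category label onto one of the six canonical classes.

    Matching is case-insensitive and tolerant of the common synonyms used
    in exported AOI tables ("Image" for "Image/Visual", "Website" for
    "Website/CTA", ...).

    Raises
    ------
    ValidationError
        If the label matches none of the canonical classes.
    """
    if isinstance(raw, Category):
        return raw
    key = str(raw).strip().lower()
    try:
        return _CATEGORY_SYNONYMS[key]
    except KeyError:
        options = ", ".join(c.value for c in Category)
        raise ValidationError(
            f"unknown AOI category {raw!r}; expected one of: {options}"
        ) from None


def parse_aoi_label(label: str) -> tuple[str, str]:
    """Split an ``Ad3_SmallText2``-style AOI label into (ad_id, aoi_name).

    The split is on the FIRST underscore only, so AOI names may themselves
    contain underscores.

    Raises
    ------
    ParseError
        If the label has no underscore or either side is empty.
    """
    if not label:
        raise ParseError("AOI label is empty")
    ad_id, sep, aoi_name = label.partition("_")
    if not sep or not ad_id or not aoi_name:
        raise ParseError(
            f"malformed AOI label {label!r}: expected '<ad>_<aoi>' with both parts non-empty"
        )
    return ad_id, aoi_name


def _require_positive(name: str, value: float) -> None:
    if not (value > 0):
        raise ValidationError(f"{name} must be strictly positive, got {value}")


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical and pixel geometry of the presentation screen.

    Defaults mirror a 24-inch 1920 x 1080 display (active area ~53 x 30 cm)
    viewed at 60 cm with a 60 Hz eye tracker.
    """

    width_px: int = 1920
    height_px: int = 1080
    width_cm: float = 53.0
    height_cm: float = 30.0
    viewing_distance_cm: float = 60.0
    sampling_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "width_px",
            "height_px",
            "width_cm",
            "height_cm",
            "viewing_distance_cm",
            "sampling_rate_hz",
        ):
            _require_positive(name, getattr(self, name))

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)


@dataclass(frozen=True)
class GazeSample:
    """One eye-tracker sample: screen position at a timestamp.

    Coordinates use the screen-capture convention: origin at the top-left,
    x rightward, y downward, units pixels. Invalid samples (blinks, track
    loss) may carry NaN coordinates.
    """

    participant_id: str
    ad_id: str
    t_ms: float
    x_px: float
    y_px: float
    valid: bool = True


@dataclass
class FixationRecord:
    """One fixation: a stable-gaze episode with a centroid, optionally
    assigned to an AOI by the geometry stage."""

    participant_id: str
    ad_id: str
    onset_ms: float
    duration_ms: float
    cx_px: float
    cy_px: float
    aoi_id: Optional[str] = None

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass(frozen=True)
class AttentionRecord:
    """One participant x ad x AOI row of the long-form study table.

    ``censored`` marks AOIs never fixated within the exposure: TTFF is set
    to the censor value and FC/FD are zeroed.
    """

    participant_id: str
    ad_id: str
    aoi_id: str
    category: Category
    ttff_ms: float
    censored: bool
    fc: int
    fd_ms: float
    age_band: str = ""
    household: str = ""
    education: str = ""

    def validate(self, censor_ms: float, exposure_ms: float) -> None:
        if self.ttff_ms < 0 or self.fc < 0 or self.fd_ms < 0:
            raise ValidationError(
                f"negative metric in record ({self.participant_id}, {self.ad_id}, {self.aoi_id})"
            )
        if self.ttff_ms > censor_ms:
            raise ValidationError(
                f"ttff_ms {self.ttff_ms} exceeds censor value {censor_ms} "
                f"({self.participant_id}, {self.ad_id}, {self.aoi_id})"
            )
        if self.censored and not (
            self.ttff_ms == censor_ms and self.fc == 0 and self.fd_ms == 0
        ):
            raise ValidationError(
                f"censored record must have ttff=={censor_ms}, fc==0, fd==0 "
                f"({self.participant_id}, {self.ad_id}, {self.aoi_id})"
            )
        if self.fd_ms > exposure_ms:
            raise ValidationError(
                f"fd_ms {self.fd_ms} exceeds exposure {exposure_ms} "
                f"({self.participant_id}, {self.ad_id}, {self.aoi_id})"
            )


@dataclass
class StudyTable:
    """A full long-form study: attention records plus recording geometry."""

    records: list[AttentionRecord]
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    exposure_ms: float = 10_000.0
    censor_ms: float = 10_000.0

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for rec in self.records:
            key = (rec.participant_id, rec.ad_id, rec.aoi_id)
            if key in seen:
                raise ValidationError(f"duplicate (participant, ad, aoi) key {key}")
            seen.add(key)
            rec.validate(self.censor_ms, self.exposure_ms)

    @property
    def ad_ids(self) -> list[str]:
        return sorted({r.ad_id for r in self.records})

    @property
    def participant_ids(self) -> list[str]:
        return sorted({r.participant_id for r in self.records})

    def for_ad(self, ad_id: str) -> list[AttentionRecord]:
        return [r for r in self.records if r.ad_id == ad_id]

    def strata_map(self, dimension: str) -> dict[str, str]:
        """Participant -> stratum level for 'age_band'|'household'|'education'."""
        if dimension not in ("age_band", "household", "education"):
            raise ValidationError(f"unknown stratum dimension {dimension!r}")
        return {r.participant_id: getattr(r, dimension) for r in self.records}


_STUDY_COLUMNS = [
    "participant_id",
    "ad_id",
    "aoi_id",
    "category",
    "ttff_ms",
    "censored",
    "fc",
    "fd_ms",
    "age_band",
    "household",
    "education",
]
_REQUIRED_COLUMNS = _STUDY_COLUMNS[:5] + _STUDY_COLUMNS[6:8]
_OPTIONAL_COLUMNS = ["censored", "age_band", "household", "education"]


def study_table_to_frame(table: StudyTable) -> pd.DataFrame:
    """Long-form pandas view of a study table (one row per record)."""
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "ad_id": r.ad_id,
                "aoi_id": r.aoi_id,
                "category": r.category.value,
                "ttff_ms": r.ttff_ms,
                "censored": r.censored,
                "fc": r.fc,
                "fd_ms": r.fd_ms,
                "age_band": r.age_band,
                "household": r.household,
                "education": r.education,
            }
            for r in table.records
        ],
        columns=_STUDY_COLUMNS,
    )


def write_study_table(table: StudyTable, path: str | Path) -> None:
    """Write a study table as comma-delimited UTF-8 text."""
    study_table_to_frame(table).to_csv(path, index=False)


def read_study_table(
    path: str | Path,
    geometry: ScreenGeometry | None = None,
    exposure_ms: float = 10_000.0,
    censor_ms: float = 10_000.0,
) -> StudyTable:
    """Read a long-form metrics CSV into a validated :class:`StudyTable`.

    A ``censored`` column is authoritative when present; otherwise the flag
    is inferred as ``ttff_ms == censor_ms and fc == 0``. Duplicate
    (participant, ad, aoi) keys, missing required columns, and negative
    metrics are rejected with labeled errors.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "ad_id": str, "aoi_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"study table {path} missing column(s): {', '.join(missing)}")

    has_censored = "censored" in df.columns
    records: list[AttentionRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        ttff = float(row.ttff_ms)
        fc = int(row.fc)
        fd = float(row.fd_ms)
        if ttff < 0 or fc < 0 or fd < 0:
            raise SchemaError(f"negative metric at row {i} of {path}")
        if has_censored:
            censored = _as_bool(row.censored)
        else:
            censored = ttff == censor_ms and fc == 0
        rec = AttentionRecord(
            participant_id=str(row.participant_id),
            ad_id=str(row.ad_id),
            aoi_id=str(row.aoi_id),
            category=normalize_category(row.category),
            ttff_ms=ttff,
            censored=censored,
            fc=fc,
            fd_ms=fd,
            age_band=_opt_str(getattr(row, "age_band", "")),
            household=_opt_str(getattr(row, "household", "")),
            education=_opt_str(getattr(row, "education", "")),
        )
        records.append(rec)
    return StudyTable(
        records=records,
        geometry=geometry or ScreenGeometry(),
        exposure_ms=exposure_ms,
        censor_ms=censor_ms,
    )


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise SchemaError(f"cannot interpret censored flag {value!r}")


def _opt_str(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return str(value)


# ---------------------------------------------------------------------------
# Gaze sample I/O


def write_gaze_samples(samples: Iterable[GazeSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "ad_id": s.ad_id,
                "t_ms": s.t_ms,
                "x_px": s.x_px,
                "y_px": s.y_px,
                "valid": s.valid,
            }
            for s in samples
        ],
        columns=["participant_id", "ad_id", "t_ms", "x_px", "y_px", "valid"],
    ).to_csv(path, index=False)


def read_gaze_samples(path: str | Path) -> list[GazeSample]:
    """Read a gaze-sample CSV (participant_id, ad_id, t_ms, x_px, y_px, valid)."""
    df = pd.read_csv(path, dtype={"participant_id": str, "ad_id": str})
    missing = [
        c for c in ("participant_id", "ad_id", "t_ms", "x_px", "y_px", "valid")
        if c not in df.columns
    ]
    if missing:
        raise SchemaError(f"gaze file {path} missing column(s): {', '.join(missing)}")
    return [
        GazeSample(
            participant_id=str(r.participant_id),
            ad_id=str(r.ad_id),
            t_ms=float(r.t_ms),
            x_px=float(r.x_px),
            y_px=float(r.y_px),
            valid=_as_bool(r.valid),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# AOI definition I/O (JSON); the geometry lives in gazeatlas.geometry, this
# is only the serialization contract.


def write_aoi_definitions(aois: Sequence, path: str | Path) -> None:
    import json

    payload = [
        {
            "ad_id": a.ad_id,
            "aoi_id": a.aoi_id,
            "category": a.category.value,
            "vertices": [[float(x), float(y)] for x, y in a.vertices],
        }
        for a in aois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_aoi_definitions(path: str | Path) -> list:
    """Read AOI polygon definitions from JSON into AOIDefinition objects."""
    import json

    from gazeatlas.geometry import AOIDefinition

    payload = json.loads(Path(path).read_text())
    return [
        AOIDefinition(
            ad_id=str(item["ad_id"]),
            aoi_id=str(item["aoi_id"]),
            category=normalize_category(item["category"]),
            vertices=[(float(x), float(y)) for x, y in item["vertices"]],
        )
        for item in payload
    ]
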