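import pytest

from gazeatlas.core import AttentionRecord, Category, ScreenGeometry, normalize_category


@pytest.fixture
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


def make_record(
    participant="P01",
    ad="Ad1",
    aoi="A",
    category="Image",
    ttff=500.0,
    censored=False,
    fc=2,
    fd=400.0,
    **strata,
) -> AttentionRecord:
    """Compact attention-record builder for tests."""
    if censored:
        ttff, fc, fd = 10_000.0, 0, 0.0
    return AttentionRecord(
        participant_id=participant,
        ad_id=ad,
        aoi_id=aoi,
        category=normalize_category(category),
        ttff_ms=ttff,
        censored=censored,
        fc=fc,
        fd_ms=fd,
        age_band=strata.get("age_band", ""),
        household=strata.get("household", ""),
        education=strata.get("education", ""),
    )


def dwell_records(ad: str, dwells: dict[str, dict[str, float | None]], categories=None):
    """Build one ad's records from participant -> {aoi: dwell or None (censored)}."""
    categories = categories or {}
    recs = []
    for pid, per in dwells.items():
        for aoi, fd in per.items():
            cat = categories.get(aoi, "Image")
            if fd is None:
                recs.append(make_record(pid, ad, aoi, cat, censored=True))
            else:
                recs.append(make_record(pid, ad, aoi, cat, ttff=300.0, fc=1, fd=fd))
    return recs
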