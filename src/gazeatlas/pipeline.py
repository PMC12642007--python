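"""End-to-end pipeline: simulate/read -> preprocess -> metrics -> dominance
-> audience -> diagnostics -> atlas rendering, with a machine-readable run
manifest. The command-line interface in :mod:`gazeatlas.cli` is a thin
wrapper over these functions.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from gazeatlas import __version__
from gazeatlas.audience import classify_quadrants, delta_matrix, stratified_first_hit
from gazeatlas.core import (
    ScreenGeometry,
    StudyTable,
    ValidationError,
    read_aoi_definitions,
    read_gaze_samples,
    read_study_table,
    write_aoi_definitions,
    write_gaze_samples,
    write_study_table,
)
from gazeatlas.dominance import (
    apply_support_mask,
    category_dominance,
    concordance,
    dominance_scores,
    pairwise_dwell_matrix,
    ttff_precedence_matrix,
    verify_axioms,
)
from gazeatlas.geometry import assign_fixations
from gazeatlas.metrics import (
    benchmark_frame,
    benchmark_table,
    compute_aoi_metrics,
    first_hit,
    first_hit_distribution,
)
from gazeatlas.preprocess import IVTParams, classify_fixations_ivt, merge_adjacent_fixations, qc_trial
from gazeatlas.simulate import default_study_config, generate_study
from gazeatlas.viz import AtlasPanelSpec, attention_heatmap, render_panel

__all__ = ["PipelineError", "run_pipeline", "analyze_ad", "preprocess_gaze"]

log = logging.getLogger("gazeatlas")


class PipelineError(RuntimeError):
    """A pipeline stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class AdAnalysis:
    """Per-ad analysis bundle consumed by export and rendering."""

    ad_id: str
    first_hits: list
    dist_aoi: dict[str, float]
    dist_category: dict[str, float]
    benchmark_aoi: list
    benchmark_category: list
    aoi_matrix: object
    ranking: object
    category_matrix: Optional[object]
    precedence_matrix: Optional[object]
    axioms: object
    concord: Optional[object]
    quadrants: list
    deltas: dict[str, object] = field(default_factory=dict)


def preprocess_gaze(samples, aois, params: IVTParams | None = None,
                    geometry: ScreenGeometry | None = None,
                    exposure_ms: float = 10_000.0, censor_ms: float = 10_000.0):
    """Raw route: QC each trial, classify + merge fixations, assign AOIs,
    and aggregate per-trial attention records.

    Returns (records, fixations, qc_reports). Trials failing QC are dropped
    from the records but reported.
    """
    params = params or IVTParams()
    geometry = geometry or ScreenGeometry()
    by_trial: dict[tuple[str, str], list] = {}
    for s in samples:
        by_trial.setdefault((s.participant_id, s.ad_id), []).append(s)
    aois_by_ad: dict[str, list] = {}
    for a in aois:
        aois_by_ad.setdefault(a.ad_id, []).append(a)

    records, fixations, reports = [], [], []
    for (pid, ad_id), trial in sorted(by_trial.items()):
        trial.sort(key=lambda s: s.t_ms)
        report = qc_trial(trial)
        reports.append(report)
        if report.excluded:
            continue
        if ad_id not in aois_by_ad:
            raise ValidationError(f"no AOI definitions for ad {ad_id!r}")
        fx = classify_fixations_ivt(trial, params, geometry)
        fx = merge_adjacent_fixations(fx, params, geometry)
        assign_fixations(fx, aois_by_ad[ad_id])
        fixations.extend(fx)
        if fx:
            records.extend(
                compute_aoi_metrics(fx, aois_by_ad[ad_id], exposure_ms, censor_ms)
            )
    return records, fixations, reports


def analyze_ad(table: StudyTable, ad_id: str, mask_threshold: int = 5) -> AdAnalysis:
    """Run the full analytic stack for one ad of a study table."""
    records = table.for_ad(ad_id)
    by_participant: dict[str, list] = {}
    for r in records:
        by_participant.setdefault(r.participant_id, []).append(r)
    hits = [first_hit(rs) for rs in by_participant.values()]
    dist_aoi = first_hit_distribution(hits, level="aoi")
    dist_cat = first_hit_distribution(hits, level="category")

    bench_aoi = [b for b in benchmark_table(table, level="aoi") if b.ad_id == ad_id]
    bench_cat = [b for b in benchmark_table(table, level="category") if b.ad_id == ad_id]

    matrix = apply_support_mask(
        pairwise_dwell_matrix(records, level="aoi"), mask_threshold
    )
    ranking = dominance_scores(matrix)
    axioms = verify_axioms(matrix)

    n_cats = len({r.category for r in records})
    cat_matrix = (
        apply_support_mask(category_dominance(records), mask_threshold)
        if n_cats >= 2
        else None
    )
    precedence = (
        apply_support_mask(
            ttff_precedence_matrix(records, level="category"), mask_threshold
        )
        if n_cats >= 2
        else None
    )

    scored = [k for k in ranking.keys if not math.isnan(ranking.scores[k])]
    concord = None
    if len(scored) >= 3:
        concord = concordance(ranking, bench_aoi)

    pct = {k: dist_aoi.get(k, 0.0) for k in scored}
    quadrants = classify_quadrants(pct, ranking)

    deltas = {}
    for dim in ("age_band", "household", "education"):
        strata = {p: rs[0].__getattribute__(dim) for p, rs in by_participant.items()}
        if any(v == "" for v in strata.values()):
            continue
        sub = stratified_first_hit(hits, strata, level="category")
        if sub:
            deltas[dim] = delta_matrix(sub, dist_cat, ad_id=ad_id, dimension=dim)

    return AdAnalysis(
        ad_id=ad_id,
        first_hits=hits,
        dist_aoi=dist_aoi,
        dist_category=dist_cat,
        benchmark_aoi=bench_aoi,
        benchmark_category=bench_cat,
        aoi_matrix=matrix,
        ranking=ranking,
        category_matrix=cat_matrix,
        precedence_matrix=precedence,
        axioms=axioms,
        concord=concord,
        quadrants=quadrants,
        deltas=deltas,
    )


def _export_tables(analysis: AdAnalysis, tables_dir: Path) -> None:
    ad = analysis.ad_id
    pd.DataFrame(
        [
            {"ad_id": ad, "level": "category", "key": k, "first_hit_pct": round(v, 1)}
            for k, v in analysis.dist_category.items()
        ]
        + [
            {"ad_id": ad, "level": "aoi", "key": k, "first_hit_pct": round(v, 1)}
            for k, v in analysis.dist_aoi.items()
        ]
    ).to_csv(tables_dir / f"{ad}_first_hit.csv", index=False)
    benchmark_frame(analysis.benchmark_aoi).to_csv(
        tables_dir / f"{ad}_benchmark_aoi.csv", index=False
    )
    benchmark_frame(analysis.benchmark_category).to_csv(
        tables_dir / f"{ad}_benchmark_category.csv", index=False
    )
    analysis.aoi_matrix.to_long_frame().to_csv(
        tables_dir / f"{ad}_dominance_matrix.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "ad_id": ad,
                "aoi_id": k,
                "S": analysis.ranking.scores[k],
                "rank": analysis.ranking.ranks.get(k),
            }
            for k in analysis.ranking.keys
        ]
    ).to_csv(tables_dir / f"{ad}_dominance_scores.csv", index=False)
    if analysis.category_matrix is not None:
        analysis.category_matrix.to_long_frame().to_csv(
            tables_dir / f"{ad}_category_dominance.csv", index=False
        )
    if analysis.precedence_matrix is not None:
        analysis.precedence_matrix.to_long_frame().to_csv(
            tables_dir / f"{ad}_ttff_precedence.csv", index=False
        )
    pd.DataFrame([vars(q) for q in analysis.quadrants]).to_csv(
        tables_dir / f"{ad}_quadrants.csv", index=False
    )
    for dim, dm in analysis.deltas.items():
        dm.to_frame().round(1).to_csv(tables_dir / f"{ad}_delta_{dim}.csv")


def run_pipeline(config_path: str | Path, seed: Optional[int] = None,
                 out_dir: Optional[str | Path] = None) -> dict:
    """Execute the full pipeline described by a YAML config.

    The config names either a ``synthetic`` block (seed, n_participants) or
    an ``inputs`` block (``study_table``, or ``gaze_samples`` + ``aois``),
    plus ``out_dir`` and optional ``mask_threshold``/``sigma_deg``. Returns
    the run manifest (also written to ``<out>/manifest.json``); any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    t0 = time.time()
    stage = "config"
    try:
        cfg = yaml.safe_load(Path(config_path).read_text()) or {}
        out = Path(out_dir or cfg.get("out_dir", "gazeatlas_out"))
        mask_threshold = int(cfg.get("mask_threshold", 5))
        sigma_deg = float(cfg.get("sigma_deg", 1.0))
        exposure_ms = float(cfg.get("exposure_ms", 10_000.0))
        censor_ms = float(cfg.get("censor_ms", 10_000.0))
        tables_dir = out / "tables"
        figures_dir = out / "figures"
        tables_dir.mkdir(parents=True, exist_ok=True)
        figures_dir.mkdir(parents=True, exist_ok=True)

        qc_excluded: list[dict] = []
        heat_fixations = None
        if "synthetic" in cfg:
            stage = "simulate"
            syn = cfg["synthetic"] or {}
            run_seed = int(seed if seed is not None else syn.get("seed", 0))
            study_config = default_study_config(seed=run_seed)
            if "n_participants" in syn:
                study_config.n_participants = int(syn["n_participants"])
            study = generate_study(study_config, emit_gaze=bool(syn.get("emit_gaze", False)))
            table = study.table
            heat_fixations = study.fixations
            write_study_table(table, tables_dir / "study_table.csv")
            if study.samples:
                write_gaze_samples(study.samples, tables_dir / "gaze_samples.csv")
            write_aoi_definitions(
                [a for ad in sorted(study_config.ads) for a in study_config.aoi_definitions(ad)],
                tables_dir / "aois.json",
            )
        elif "inputs" in cfg:
            inputs = cfg["inputs"] or {}
            run_seed = int(seed if seed is not None else cfg.get("seed", 0))
            if "study_table" in inputs:
                stage = "read"
                table = read_study_table(
                    inputs["study_table"], exposure_ms=exposure_ms, censor_ms=censor_ms
                )
            elif "gaze_samples" in inputs and "aois" in inputs:
                stage = "read"
                samples = read_gaze_samples(inputs["gaze_samples"])
                aois = read_aoi_definitions(inputs["aois"])
                stage = "preprocess"
                records, heat_fixations, reports = preprocess_gaze(
                    samples, aois, exposure_ms=exposure_ms, censor_ms=censor_ms
                )
                qc_excluded = [
                    vars(r) for r in reports if r.excluded
                ]
                pd.DataFrame([vars(r) for r in reports]).to_csv(
                    tables_dir / "qc_report.csv", index=False
                )
                table = StudyTable(
                    records=records, exposure_ms=exposure_ms, censor_ms=censor_ms
                )
            else:
                raise ValidationError(
                    "inputs must name 'study_table' or both 'gaze_samples' and 'aois'"
                )
        else:
            raise ValidationError("config needs a 'synthetic' or 'inputs' section")

        stage = "metrics"
        analyses = {ad: analyze_ad(table, ad, mask_threshold) for ad in table.ad_ids}
        stage = "export"
        for analysis in analyses.values():
            _export_tables(analysis, tables_dir)

        stage = "render"
        for ad, analysis in analyses.items():
            spec = AtlasPanelSpec(ad_id=ad, out_dir=figures_dir, mask_threshold=mask_threshold)
            render_panel(
                spec,
                aoi_matrix=analysis.aoi_matrix,
                ranking=analysis.ranking,
                category_matrix=analysis.category_matrix,
                first_hit_pct=analysis.dist_aoi,
                quadrants=analysis.quadrants,
                delta_matrices=list(analysis.deltas.values()),
            )
            if heat_fixations is not None:
                fx = [f for f in heat_fixations if f.ad_id == ad]
                grid = attention_heatmap(fx, table.geometry, sigma_deg=sigma_deg, ad_id=ad)
                import matplotlib.pyplot as plt

                fig, ax = plt.subplots(figsize=(5, 3))
                ax.imshow(grid.values, cmap="inferno", vmin=0, vmax=1)
                ax.set_title(f"{ad}: attention heatmap (sigma={sigma_deg} deg)", fontsize=9)
                ax.set_axis_off()
                fig.savefig(figures_dir / f"{ad}_heatmap.png", bbox_inches="tight", dpi=120)
                plt.close(fig)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": run_seed,
            "config": str(config_path),
            "out_dir": str(out),
            "mask_threshold": mask_threshold,
            "sigma_deg": sigma_deg,
            "exposure_ms": exposure_ms,
            "censor_ms": censor_ms,
            "delta_sign_convention": "subgroup - overall",
            "censored_ttff_in_latency_summaries": True,
            "ads": table.ad_ids,
            "n_participants": len(table.participant_ids),
            "qc_excluded": qc_excluded,
            "axiom_checks": {
                ad: {
                    "passed": analysis.axioms.passed,
                    "max_offdiag_deviation": analysis.axioms.max_offdiag_deviation,
                    "max_diag_deviation": analysis.axioms.max_diag_deviation,
                }
                for ad, analysis in analyses.items()
            },
            "elapsed_s": round(time.time() - t0, 2),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc
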