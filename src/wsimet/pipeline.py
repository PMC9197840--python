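"""End-to-end pipeline: synthesis -> tiling -> training -> aggregation ->
risk statistics -> survival, with seeded substreams and an output manifest.

All randomness flows from one master seed through named substreams (slide
synthesis, fold assignment, training, cohort sampling, survival), so a
rerun with the same config reproduces every deterministic output. Each
stage's outputs are written as they are produced; a failing stage aborts
with its name while earlier outputs remain on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregation, classifier, risk_stats, survival, synthetic_data, tiling

logger = logging.getLogger("wsimet")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_STAGE_NAMES = ("synth", "tile", "train", "aggregate", "riskstats", "survival")


@dataclass(frozen=True)
class PipelineConfig:
    """Single configuration object for a full pipeline run."""

    out_dir: str | None = None
    n_per_class: int = 20          # slides per cohort in the imaging stages
    texture_effect: float = 1.0
    slide_px: int = 4096           # square synthetic slides; 512-px tiles -> 8x8 grid
    tile_px: int = 512
    input_mode: str = "single"     # single | front-in | front-out | front-both | stack:n
    folds: int = 4
    depth: str = "tiny"
    epochs: int = 6
    window: int = 2
    vote: str = "mean"
    rfm_factors: tuple[str, ...] = ("clark5", "diam_ge30")
    n_cohort: tuple[int, int, int] = (59, 22, 0)  # non_met, rapid_met, slow_met
    imaging: bool = True           # False = fixtures/statistics stages only
    save_heatmaps: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    """Results bundle of one pipeline run."""

    config: PipelineConfig
    slide_auroc: float | None = None
    tile_auroc: float | None = None
    n_tiles: int | None = None
    confusion: dict[str, float] | None = None
    decisions: pd.DataFrame | None = None
    table2: pd.DataFrame | None = None
    fixture_confusion: dict[str, float] | None = None
    synthetic_rfm: object | None = None
    synthetic_rfm_auroc: float | None = None
    km_summary: pd.DataFrame | None = None
    manifest: dict | None = None


def _substream_seeds(master_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGE_NAMES))
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(_STAGE_NAMES, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _select_training_tiles(records, mode: str):
    tumor_valid = [t for t in records if t.is_valid and t.is_tumor]
    if mode in {"single", "all"} or mode.startswith("stack"):
        return tumor_valid
    side = {"front-in": "inside", "front-out": "outside",
            "front-both": "both"}.get(mode)
    if side is None:
        raise ValueError(f"unknown input mode {mode!r}")
    front = tiling.select_invasive_front(records, side=side)
    return [t for t in front if t.is_valid]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages and return the results bundle."""
    seeds = _substream_seeds(config.seed)
    out_dir = Path(config.out_dir) if config.out_dir else None
    outputs: list[Path] = []
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(config=config)
    t_start = time.time()

    stage = "synth"
    try:
        if config.imaging:
            result = _run_imaging(config, seeds, out_dir, outputs, result)
        stage = "riskstats"
        cohort = _run_riskstats(config, seeds, out_dir, outputs, result)
        stage = "survival"
        _run_survival(config, seeds, out_dir, outputs, result, cohort)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "seeds": seeds,
        "elapsed_s": round(time.time() - t_start, 2),
        "outputs": [
            {"path": str(p.relative_to(out_dir)), "sha256": _sha256(p)}
            for p in outputs
        ] if out_dir else [],
    }
    result.manifest = manifest
    if out_dir:
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
    return result


def _run_imaging(config, seeds, out_dir, outputs, result) -> PipelineResult:
    """Stages synth/tile/train/aggregate on synthetic slides."""
    rng = np.random.default_rng(seeds["synth"])
    mode = config.input_mode
    stack_n = int(mode.split(":")[1]) if mode.startswith("stack") else None

    manifest_rows, features, per_slide = [], [], {}
    labels_of_cohort = {"non_met": "non_met", "rapid_met": "met"}
    logger.info("synth+tile: %d slides/class at %d px, tile %d px",
                config.n_per_class, config.slide_px, config.tile_px)
    for cohort in ("non_met", "rapid_met"):
        for i in range(config.n_per_class):
            slide_id = f"{cohort}_{i:03d}"
            spec = synthetic_data.SyntheticSlideSpec(
                slide_id=slide_id, patient_id=f"P_{slide_id}", cohort=cohort,
                width_px=config.slide_px, height_px=config.slide_px,
                texture_effect=config.texture_effect,
                annotation_polygons=(synthetic_data.default_annotation_polygon(
                    config.slide_px, config.slide_px, rng),),
                seed=int(rng.integers(2**31)))
            image, mask = synthetic_data.generate_slide(spec)
            records, images = tiling.extract_tiles(
                image, mask, config.tile_px, slide_id=slide_id,
                patient_id=spec.patient_id, label=labels_of_cohort[cohort],
                images_for="valid" if mode.startswith("front") else "tumor")
            selected = _select_training_tiles(records, mode)
            per_slide[slide_id] = {"records": records, "selected": selected,
                                   "label": labels_of_cohort[cohort],
                                   "patient_id": spec.patient_id,
                                   "cohort": cohort}
            for t in selected:
                manifest_rows.append({
                    "slide_id": t.slide_id, "patient_id": t.patient_id,
                    "row": t.row, "col": t.col, "label": t.label})
                features.append(classifier.featurize_tile(images[(t.row, t.col)]))

    tile_manifest = pd.DataFrame(manifest_rows)
    X = np.asarray(features)
    if out_dir:
        p = out_dir / "tile_manifest.csv"
        tile_manifest.to_csv(p, index=False)
        outputs.append(p)

    patients = pd.DataFrame(
        [{"patient_id": d["patient_id"], "cohort": d["cohort"]}
         for d in per_slide.values()])
    folds = classifier.assign_folds(patients, config.folds, seed=seeds["train"])
    train_config = classifier.TrainConfig(
        depth=config.depth, epochs=config.epochs, seed=seeds["train"])
    stacks = None
    if stack_n is not None:
        all_selected = [t for d in per_slide.values() for t in d["selected"]]
        stacks = tiling.make_tile_stacks(all_selected, stack_n, seed=seeds["train"])
    logger.info("train: %d tiles, %d-fold CV, depth=%s",
                len(tile_manifest), config.folds, config.depth)
    cv = classifier.train_cv(tile_manifest, X, folds, train_config, stacks=stacks)

    oof = pd.Series(cv.oof, index=tile_manifest.index)
    scored = tile_manifest.assign(oof_prob=oof)
    if out_dir:
        p = out_dir / "oof_probabilities.csv"
        scored.to_csv(p, index=False)
        outputs.append(p)

    decisions, slide_scores, slide_labels = [], [], []
    tile_probs, tile_labels = [], []
    n_grid = config.slide_px // config.tile_px
    for slide_id, d in per_slide.items():
        rows = scored[scored["slide_id"] == slide_id]
        probs_at = {(r.row, r.col): r.oof_prob for r in rows.itertuples()}
        recs = d["records"]
        probs = [probs_at.get((t.row, t.col), np.nan) for t in recs]
        grid = aggregation.score_grid_from_tiles(
            slide_id, recs, probs, n_rows=n_grid, n_cols=n_grid)
        smoothed = aggregation.median_smooth(grid, window=config.window)
        decision = aggregation.slide_score(
            smoothed, true_label=d["label"], vote=config.vote)
        decisions.append(decision)
        slide_scores.append(decision.mean_score)
        slide_labels.append(d["label"] == "met")
        finite = [p for p in probs if np.isfinite(p)]
        tile_probs.extend(finite)
        tile_labels.extend([d["label"] == "met"] * len(finite))
        if config.save_heatmaps and out_dir:
            p = out_dir / f"heatmap_{slide_id}.png"
            aggregation.save_probability_map(smoothed, config.tile_px, str(p))
            outputs.append(p)

    _, _, _, slide_auroc = aggregation.roc_curve(slide_scores, slide_labels)
    _, _, _, tile_auroc = aggregation.roc_curve(tile_probs, tile_labels)
    result.slide_auroc = slide_auroc
    result.tile_auroc = tile_auroc
    result.n_tiles = int(len(tile_manifest))
    result.confusion = aggregation.confusion_summary(decisions)
    result.decisions = pd.DataFrame(
        [{"slide_id": d.slide_id, "mean_score": d.mean_score,
          "predicted_label": d.predicted_label, "true_label": d.true_label}
         for d in decisions])
    if out_dir:
        p = out_dir / "slide_decisions.csv"
        result.decisions.to_csv(p, index=False)
        outputs.append(p)
    logger.info("aggregate: slide AUROC %.3f, tile AUROC %.3f",
                slide_auroc, tile_auroc)
    return result


def _run_riskstats(config, seeds, out_dir, outputs, result) -> pd.DataFrame:
    """Published risk-table reproduction plus an RFM on the synthetic cohort."""
    fixtures = synthetic_data.load_paper_fixtures()
    report = risk_stats.table2_report(fixtures.tables)
    conf = fixtures.ai_confusion
    result.fixture_confusion = aggregation.confusion_summary(counts={
        "tp": conf["rapid_met"]["pred_met"], "fn": conf["rapid_met"]["pred_non_met"],
        "tn": conf["non_met"]["pred_non_met"], "fp": conf["non_met"]["pred_met"]})
    result.table2 = report
    if out_dir:
        p = out_dir / "risk_table.csv"
        report.to_csv(p, index=False)
        outputs.append(p)

    n_nm, n_rm, n_sm = config.n_cohort
    cohort = synthetic_data.generate_cohort(
        n_nm, n_rm, n_sm, seed=seeds["riskstats"])
    if n_rm > 0 and config.rfm_factors:
        profiles = risk_stats.profiles_from_cohort(cohort)
        counts = risk_stats.build_rfm(profiles, list(config.rfm_factors))
        result.synthetic_rfm = counts
        result.synthetic_rfm_auroc = risk_stats.ordinal_auc(
            counts.cases, counts.controls)
        if out_dir:
            p = out_dir / "synthetic_rfm.csv"
            counts.to_frame().to_csv(p, index=False)
            outputs.append(p)
    return cohort


def _run_survival(config, seeds, out_dir, outputs, result, cohort) -> None:
    """Survival stage on the synthetic cohort: KM per stratum and endpoint."""
    records = synthetic_data.generate_survival(cohort, seed=seeds["survival"])
    if out_dir:
        p = out_dir / "cohort.csv"
        cohort.to_csv(p, index=False)
        outputs.append(p)
        p = out_dir / "survival_records.csv"
        records.to_csv(p, index=False)
        outputs.append(p)
    rows = []
    for endpoint in ("OS", "DSS"):
        curves = survival.km_by_stratum(records, endpoint=endpoint)
        for stratum, curve in curves.items():
            med = survival.median_survival(curve)
            rows.append({
                "endpoint": endpoint, "stratum": stratum, "n": curve.n_total,
                "five_year_survival": survival.survival_at(
                    curve, survival.FOLLOW_UP_CAP_DAYS),
                "median_survival_years": (med / survival.DAYS_PER_YEAR
                                          if med is not None else np.nan),
            })
    result.km_summary = pd.DataFrame(rows)
    if out_dir:
        p = out_dir / "km_summary.csv"
        result.km_summary.to_csv(p, index=False)
        outputs.append(p)
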