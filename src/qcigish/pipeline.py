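"""Stage orchestration: simulate -> score -> calibrate -> classify -> evaluate.

Each stage function takes in-memory tables, writes its artifacts plus a
manifest into an output directory, and returns the artifact for the next
stage.  ``run_full`` chains them end to end; it is what the CLI's
``full`` subcommand and the synthetic acceptance run use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io
from .calibration import screen_genes
from .classify import build_panel_models, classify_samples
from .evaluate import evaluate, evaluation_report
from .scoring import score_table, zscore_matrix
from .simulate import CohortConfig, default_study_config, generate_cohort
from .stats import significance_screen

log = logging.getLogger("qcigish")


@dataclass
class RunConfig:
    """Paths and options for one pipeline invocation."""

    out_dir: Path
    counts: Path | None = None
    scores: Path | None = None
    labels: Path | None = None
    model: Path | None = None
    cohort_config: Path | None = None
    seed: int | None = None
    alpha: float = 0.01
    mode: str = "full"


def stage_simulate(config: CohortConfig, out_dir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    out_dir.mkdir(parents=True, exist_ok=True)
    counts, meta = generate_cohort(config)
    io.write_counts(counts, out_dir / "counts.csv")
    io.write_metadata(meta, out_dir / "labels.csv")
    io.write_manifest(
        out_dir / "manifest_simulate.json",
        stage="simulate",
        inputs={},
        outputs={"counts": "counts.csv", "labels": "labels.csv"},
        params=config.to_dict(),
        seed=config.seed,
    )
    log.info("simulate: %d count rows, %d samples", len(counts), len(meta))
    return counts, meta


def stage_score(counts: pd.DataFrame, meta: pd.DataFrame, out_dir: Path) -> pd.DataFrame:
    out_dir.mkdir(parents=True, exist_ok=True)
    scores = score_table(counts)
    io.write_scores(scores, out_dir / "scores.csv")
    matrix = zscore_matrix(scores, meta)
    io.write_zscores(matrix, out_dir / "zscores.tsv")
    io.write_manifest(
        out_dir / "manifest_score.json",
        stage="score",
        inputs={"counts": "counts.csv"},
        outputs={"scores": "scores.csv", "zscores": "zscores.tsv"},
        params={"rows_in": len(counts), "rows_out": len(scores)},
    )
    log.info("score: %d sample x gene scores", len(scores))
    return scores


def stage_calibrate(scores: pd.DataFrame, meta: pd.DataFrame, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = scores.merge(meta, on="sample_id")
    models, details = build_panel_models(cohort)
    io.write_models(models, out_dir / "model.json")
    io.write_manifest(
        out_dir / "manifest_calibrate.json",
        stage="calibrate",
        inputs={"scores": "scores.csv", "labels": "labels.csv"},
        outputs={"model": "model.json"},
        params={
            "mode": "per_cancer",
            "achieved": {
                f"{ct}/{g}": {
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "feasible": r.feasible,
                }
                for (ct, g), r in details.items()
            },
        },
    )
    infeasible = [k for k, r in details.items() if not r.feasible]
    if infeasible:
        log.warning("calibrate: constraints infeasible for %s", infeasible)
    log.info("calibrate: %d cancer-type models", len(models))
    return models


def stage_screen(scores: pd.DataFrame, meta: pd.DataFrame, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = scores.merge(meta, on="sample_id")
    genes = sorted(scores["gene"].unique())
    result = screen_genes(cohort, genes=genes)
    table = pd.DataFrame(
        [
            {
                "gene": g,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "te_min": r.thresholds.te_min,
                "bae_min": r.thresholds.bae_min,
                "mae_min": r.thresholds.mae_min,
                "decision": (
                    "retained"
                    if g in result.retained
                    else "dropped" if g in result.dropped else "review"
                ),
            }
            for g, r in result.results.items()
        ]
    )
    table.to_csv(out_dir / "screening.csv", index=False)
    io.write_manifest(
        out_dir / "manifest_screen.json",
        stage="screen",
        inputs={"scores": "scores.csv", "labels": "labels.csv"},
        outputs={"screening": "screening.csv"},
        params={"genes": genes, "retained": list(result.retained)},
    )
    log.info("screen: retained %s", result.retained)
    return result


def stage_classify(scores: pd.DataFrame, meta: pd.DataFrame, models, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    calls, predictions = classify_samples(scores, meta, models)
    calls.to_csv(out_dir / "calls.csv", index=False)
    predictions.to_csv(out_dir / "predictions.csv", index=False)
    io.write_manifest(
        out_dir / "manifest_classify.json",
        stage="classify",
        inputs={"scores": "scores.csv", "model": "model.json"},
        outputs={"calls": "calls.csv", "predictions": "predictions.csv"},
        params={"n_samples": int(predictions["sample_id"].nunique())},
    )
    log.info("classify: %d samples", len(predictions))
    return calls, predictions


def stage_evaluate(predictions: pd.DataFrame, meta: pd.DataFrame, out_dir: Path) -> pd.DataFrame:
    out_dir.mkdir(parents=True, exist_ok=True)
    merged = predictions.drop(columns=["cancer_type"], errors="ignore").merge(
        meta[["sample_id", "cancer_type", "class_label"]], on="sample_id"
    )
    merged = merged[merged["class_label"].isin(["benign", "malignant"])]
    per_cancer = {
        ct: evaluate(grp["prediction"].tolist(), grp["class_label"].tolist())
        for ct, grp in merged.groupby("cancer_type", sort=True)
    }
    report = evaluation_report(per_cancer)
    report.to_csv(out_dir / "report.csv", index=False)
    io.write_manifest(
        out_dir / "manifest_evaluate.json",
        stage="evaluate",
        inputs={"predictions": "predictions.csv", "labels": "labels.csv"},
        outputs={"report": "report.csv"},
        params={"n": int(len(merged))},
    )
    log.info("evaluate:\n%s", report.to_string(index=False))
    return report


def stage_stats(scores: pd.DataFrame, meta: pd.DataFrame, out_dir: Path, *, alpha: float = 0.01, seed: int | None = None) -> pd.DataFrame:
    out_dir.mkdir(parents=True, exist_ok=True)
    table = significance_screen(scores, meta, alpha=alpha, seed=seed)
    table.to_csv(out_dir / "pvals.csv", index=False)
    io.write_manifest(
        out_dir / "manifest_stats.json",
        stage="stats",
        inputs={"scores": "scores.csv", "labels": "labels.csv"},
        outputs={"pvals": "pvals.csv"},
        params={"alpha": alpha},
        seed=seed,
    )
    return table


def run_full(out_dir: Path, *, seed: int, config: CohortConfig | None = None) -> pd.DataFrame:
    """Seeded end-to-end run on a synthetic cohort; returns the report."""
    out_dir = Path(out_dir)
    if config is None:
        config = default_study_config(seed)
    counts, meta = stage_simulate(config, out_dir)
    scores = stage_score(counts, meta, out_dir)
    models = stage_calibrate(scores, meta, out_dir)
    _, predictions = stage_classify(scores, meta, models, out_dir)
    return stage_evaluate(predictions, meta, out_dir)
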