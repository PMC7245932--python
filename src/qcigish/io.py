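"""Reading and writing the pipeline's tabular and model artifacts.

All tables are comma-separated UTF-8 with a mandatory header row.
Percentages are written with four decimal places; integer rounding
happens only in the human-readable evaluation report.  Panel models
travel as JSON, cohort configs as YAML, and every pipeline stage writes
a JSON manifest recording its inputs, parameters and seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .classify import PanelModel
from .scoring import KNOWN_GENES

COUNT_COLUMNS = [
    "sample_id",
    "cancer_type",
    "class_label",
    "gene",
    "field_index",
    "n0",
    "n1",
    "n2",
    "n2plus",
]
SCORE_COLUMNS = ["sample_id", "gene", "te", "bae", "mae"]


class CountTableError(ValueError):
    """A count table failed validation; the message names the rows."""


def read_counts(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a long-format count CSV.

    Returns ``(counts, metadata)`` where metadata has one row per sample.
    Row numbers in error messages are 1-based file lines (header = 1).
    Unknown genes are allowed with a warning; negative counts, missing
    columns, duplicate (sample, gene, field) keys and inconsistent
    per-sample metadata are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"{path}: missing column(s) {missing}")

    def _lines(mask) -> list[int]:
        return [int(i) + 2 for i in df.index[mask][:20]]

    for col in ("n0", "n1", "n2", "n2plus", "field_index"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
        if col == "field_index":
            bad |= numeric < 1
        if bad.any():
            raise CountTableError(
                f"{path}: column {col!r} must hold non-negative integers; "
                f"offending line(s) {_lines(bad)}"
            )
        df[col] = numeric.astype(int)

    dup = df.duplicated(subset=["sample_id", "gene", "field_index"], keep=False)
    if dup.any():
        raise CountTableError(
            f"{path}: duplicate (sample_id, gene, field_index) rows at "
            f"line(s) {_lines(dup)}"
        )

    unknown = sorted(set(df["gene"]) - set(KNOWN_GENES))
    if unknown:
        warnings.warn(f"{path}: unknown gene(s) {unknown}", stacklevel=2)

    meta = df[["sample_id", "cancer_type", "class_label"]].drop_duplicates()
    clash = meta["sample_id"].duplicated(keep=False)
    if clash.any():
        raise CountTableError(
            f"{path}: inconsistent metadata for sample(s) "
            f"{sorted(meta.loc[clash, 'sample_id'].unique())}"
        )
    return df[COUNT_COLUMNS].copy(), meta.reset_index(drop=True)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts[COUNT_COLUMNS].to_csv(path, index=False)


def write_scores(scores: pd.DataFrame, path) -> None:
    out = scores.copy()
    for col in ("te", "bae", "mae"):
        out[col] = out[col].map(lambda v: f"{v:.4f}")
    cols = [c for c in SCORE_COLUMNS if c in out.columns] + [
        c for c in out.columns if c not in SCORE_COLUMNS
    ]
    out[cols].to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: score table missing column(s) {missing}")
    return df


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = ["sample_id", "cancer_type", "class_label"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing column(s) {missing}")
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def write_zscores(matrix: pd.DataFrame, path) -> None:
    """Z-score matrix as TSV with ``<gene>_<measure>`` row labels."""
    matrix.to_csv(path, sep="\t", index_label="row")


def write_models(models: Mapping[str, PanelModel], path) -> None:
    payload = {"models": [models[ct].to_dict() for ct in sorted(models)]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_models(path) -> dict[str, PanelModel]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    models = [PanelModel.from_dict(d) for d in payload["models"]]
    return {m.cancer_type: m for m in models}


def write_manifest(path, *, stage: str, inputs: Mapping[str, str], outputs: Mapping[str, str], params: Mapping, seed: int | None = None) -> None:
    """Record what a stage consumed and produced, for exact re-runs."""
    params_json = json.dumps(params, sort_keys=True, default=str)
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "inputs": dict(inputs),
        "outputs": dict(outputs),
        "params": json.loads(params_json),
        "params_hash": hashlib.sha256(params_json.encode()).hexdigest(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
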