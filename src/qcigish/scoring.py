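"""Per-nucleus signal counting model and allelic-expression scores.

In a chromogenic in situ hybridization assay against intronic nascent RNA,
every actively transcribing allele of an imprinted gene appears as one dot
in the nucleus.  Nuclei are tallied into four classes: no signal (``n0``),
one signal (``n1``, single allelic expression), two signals (``n2``,
biallelic expression) and more than two signals (``n2plus``, multiallelic
expression).  From the pooled tallies of the counted fields three scores
are computed per sample and gene:

    TE  = (N1 + N2 + N2plus) / (N0 + N1 + N2 + N2plus) x 100
    BAE = N2     / (N1 + N2 + N2plus) x 100
    MAE = N2plus / (N1 + N2 + N2plus) x 100

TE (total expression) is the fraction of nuclei with any signal; BAE and
MAE are the biallelic / multiallelic fractions among expressing nuclei.
In normal somatic tissue an imprinted gene is expressed from a single
allele, so BAE and MAE are near zero; loss of imprinting in benign and
malignant lesions raises all three.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The imprinted genes assayed in the original five-gene screening panel.
KNOWN_GENES = ("GNAS", "GRB10", "SNRPN", "IGF2", "IGF2R")

#: The three genes retained after screening, used by the diagnostic panel.
PANEL_GENES = ("GNAS", "GRB10", "SNRPN")

#: Score measures, in canonical order.
MEASURES = ("te", "bae", "mae")

#: Histologic classes, in order of increasing malignant potential.
CLASS_LABELS = ("normal", "benign", "malignant")

#: Default number of high-power microscope fields counted per gene/sample.
DEFAULT_FIELDS = 4


@dataclass(frozen=True)
class CellCounts:
    """Nucleus tallies for one sample x gene, for one field or pooled.

    ``field_index`` is the 1-based high-power-field number, or ``None``
    once fields have been pooled by :func:`aggregate_fields`.
    """

    sample_id: str
    gene: str
    n0: int
    n1: int
    n2: int
    n2plus: int
    field_index: int | None = None

    def __post_init__(self) -> None:
        for name in ("n0", "n1", "n2", "n2plus"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(
                    f"{name}={value!r} for {self.sample_id}/{self.gene}: "
                    "counts must be non-negative integers"
                )

    @property
    def expressing_nuclei(self) -> int:
        return self.n1 + self.n2 + self.n2plus

    @property
    def total_nuclei(self) -> int:
        return self.n0 + self.expressing_nuclei


@dataclass(frozen=True)
class ExpressionScores:
    """TE/BAE/MAE percentages for one sample x gene."""

    sample_id: str
    gene: str
    te: float
    bae: float
    mae: float
    expressing_nuclei: int
    total_nuclei: int


@dataclass(frozen=True)
class GroupSummary:
    """Median with interquartile range (Q1, Q3)."""

    median: float
    q1: float
    q3: float


def aggregate_fields(counts: Sequence[CellCounts]) -> CellCounts:
    """Pool nucleus tallies across the counted fields of one sample x gene.

    Fields are summed, not averaged: the scores are ratios of pooled
    nuclei, and summing keeps integer counts.  All records must share the
    same ``sample_id`` and ``gene``.
    """
    if not counts:
        raise ValueError("aggregate_fields requires at least one field")
    first = counts[0]
    for c in counts[1:]:
        if c.sample_id != first.sample_id or c.gene != first.gene:
            raise ValueError(
                "cannot pool fields across identities: "
                f"({first.sample_id}, {first.gene}) vs ({c.sample_id}, {c.gene})"
            )
    return CellCounts(
        sample_id=first.sample_id,
        gene=first.gene,
        n0=sum(c.n0 for c in counts),
        n1=sum(c.n1 for c in counts),
        n2=sum(c.n2 for c in counts),
        n2plus=sum(c.n2plus for c in counts),
        field_index=None,
    )


def compute_scores(counts: CellCounts) -> ExpressionScores:
    """Compute TE, BAE and MAE (percent) from pooled nucleus tallies.

    Degenerate denominators: a sample with no expressing nuclei has
    BAE = MAE = 0 (absence of expression is not evidence of malignancy,
    and the TE gate classifies such samples negative anyway); a sample
    with no nuclei at all additionally has TE = 0.
    """
    expressing = counts.expressing_nuclei
    total = counts.total_nuclei
    te = 100.0 * expressing / total if total else 0.0
    if expressing:
        bae = 100.0 * counts.n2 / expressing
        mae = 100.0 * counts.n2plus / expressing
    else:
        bae = mae = 0.0
    return ExpressionScores(
        sample_id=counts.sample_id,
        gene=counts.gene,
        te=te,
        bae=bae,
        mae=mae,
        expressing_nuclei=expressing,
        total_nuclei=total,
    )


def score_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Vectorised scoring of a long-format count table.

    Parameters
    ----------
    counts
        Columns ``sample_id, gene, field_index, n0, n1, n2, n2plus``
        (extra columns are ignored).  Fields are pooled per
        (sample_id, gene) before the score equations are applied.

    Returns
    -------
    DataFrame with columns ``sample_id, gene, te, bae, mae,
    expressing_nuclei, total_nuclei``, one row per sample x gene.
    """
    needed = ["sample_id", "gene", "n0", "n1", "n2", "n2plus"]
    missing = [c for c in needed if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if (counts[["n0", "n1", "n2", "n2plus"]] < 0).any().any():
        raise ValueError("count table contains negative counts")
    pooled = (
        counts.groupby(["sample_id", "gene"], sort=True, as_index=False)[
            ["n0", "n1", "n2", "n2plus"]
        ].sum()
    )
    expressing = pooled["n1"] + pooled["n2"] + pooled["n2plus"]
    total = pooled["n0"] + expressing
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(total > 0, 100.0 * expressing / total, 0.0)
        bae = np.where(expressing > 0, 100.0 * pooled["n2"] / expressing, 0.0)
        mae = np.where(expressing > 0, 100.0 * pooled["n2plus"] / expressing, 0.0)
    return pd.DataFrame(
        {
            "sample_id": pooled["sample_id"],
            "gene": pooled["gene"],
            "te": te,
            "bae": bae,
            "mae": mae,
            "expressing_nuclei": expressing.astype(int),
            "total_nuclei": total.astype(int),
        }
    )


def _gene_order(genes: Iterable[str]) -> list[str]:
    known = {g: i for i, g in enumerate(KNOWN_GENES)}
    return sorted(set(genes), key=lambda g: (known.get(g, len(known)), g))


def zscore_matrix(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    measures: Sequence[str] = MEASURES,
) -> pd.DataFrame:
    """Standardise each (gene, measure) row to z-scores within cancer type.

    Rows are labelled ``<gene>_<measure>``; columns are sample ids, grouped
    by cancer type.  Within each cancer type every row is centred and
    scaled to unit sample standard deviation (n-1 denominator), matching
    the per-cancer normalisation used for expression heat maps.  A row
    that is constant within a group maps to zeros with a warning.
    """
    meta = metadata[["sample_id", "cancer_type"]].drop_duplicates()
    merged = scores.merge(meta, on="sample_id", how="left")
    if merged["cancer_type"].isna().any():
        orphans = sorted(merged.loc[merged["cancer_type"].isna(), "sample_id"].unique())
        raise ValueError(f"samples missing cancer_type metadata: {orphans}")

    genes = _gene_order(merged["gene"])
    row_labels = [f"{g}_{m}" for g in genes for m in measures]
    columns: list[str] = []
    blocks: list[np.ndarray] = []
    for cancer_type, grp in merged.groupby("cancer_type", sort=True):
        wide = grp.pivot(index="sample_id", columns="gene", values=list(measures))
        sample_ids = sorted(wide.index)
        if len(sample_ids) < 2:
            raise ValueError(
                f"cancer type {cancer_type!r} has fewer than 2 samples; "
                "cannot z-score"
            )
        mat = np.empty((len(row_labels), len(sample_ids)))
        for r, (g, m) in enumerate((g, m) for g in genes for m in measures):
            vals = wide[(m, g)].reindex(sample_ids).to_numpy(dtype=float)
            sd = np.std(vals, ddof=1)
            if sd == 0 or np.isnan(sd):
                warnings.warn(
                    f"constant row {g}_{m} in cancer type {cancer_type!r}; "
                    "z-scores set to 0",
                    stacklevel=2,
                )
                mat[r] = 0.0
            else:
                mat[r] = (vals - vals.mean()) / sd
        columns.extend(sample_ids)
        blocks.append(mat)
    return pd.DataFrame(np.hstack(blocks), index=row_labels, columns=columns)


def group_summary(values: Sequence[float]) -> GroupSummary:
    """Median and interquartile range of a score group.

    Quartiles use the linear-interpolation convention between order
    statistics (numpy's default), so a single value yields a degenerate
    IQR equal to that value.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("group_summary requires at least one value")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
    return GroupSummary(median=float(med), q1=float(q1), q3=float(q3))
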