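"""Gene-level calls and the cancer-type-specific panel voting model.

A gene call is negative when TE sits below the gene's TE gate; otherwise
the sample is positive for that gene when BAE or MAE strictly exceeds
its cutoff.  Comparisons mirror the wording of the decision rule
literally: the gate fires on ``te < te_min`` (equality passes) and
positivity needs strict ``>``.

A sample is called malignant when at least ``min_positive`` of the
panel's genes are positive (default two of GNAS/GRB10/SNRPN) and every
gene in ``required_genes`` is positive.  The gastric model is pure
configuration: genes GNAS and GRB10, both required, SNRPN excluded —
SNRPN imprinting moves in the opposite direction in gastric cancer and
would vote the wrong way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, GeneThresholds, calibrate_gene
from .scoring import PANEL_GENES, ExpressionScores

#: Cancer types whose panel deviates from the default 2-of-3 vote:
#: mapping cancer_type -> genes that must ALL be positive.
DEFAULT_SPECIAL_RULES: Mapping[str, tuple[str, ...]] = {"gastric": ("GNAS", "GRB10")}


@dataclass(frozen=True)
class GeneCall:
    """Negative/positive call of one gene on one sample, with the reason."""

    sample_id: str
    gene: str
    call: str       # "negative" | "positive"
    reason: str     # "te_gate" | "bae" | "mae" | "below_threshold"

    @property
    def is_positive(self) -> bool:
        return self.call == "positive"


@dataclass(frozen=True)
class PanelModel:
    """Diagnostic model for one cancer type.

    ``required_genes`` non-empty turns the vote into an AND over those
    genes (on top of the ``min_positive`` count over ``genes``).
    """

    cancer_type: str
    genes: tuple[str, ...]
    thresholds: Mapping[str, GeneThresholds]
    min_positive: int = 2
    required_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        missing = [g for g in self.genes if g not in self.thresholds]
        if missing:
            raise ValueError(
                f"model for {self.cancer_type!r} lacks thresholds for gene(s) {missing}"
            )
        bad = [g for g in self.required_genes if g not in self.genes]
        if bad:
            raise ValueError(f"required_genes {bad} not in panel genes {self.genes}")

    def to_dict(self) -> dict:
        return {
            "cancer_type": self.cancer_type,
            "genes": list(self.genes),
            "thresholds": {
                g: {"te_min": t.te_min, "bae_min": t.bae_min, "mae_min": t.mae_min}
                for g, t in self.thresholds.items()
            },
            "min_positive": self.min_positive,
            "required_genes": list(self.required_genes),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelModel":
        thresholds = {
            g: GeneThresholds(gene=g, scope=d["cancer_type"], **cuts)
            for g, cuts in d["thresholds"].items()
        }
        return cls(
            cancer_type=d["cancer_type"],
            genes=tuple(d["genes"]),
            thresholds=thresholds,
            min_positive=int(d.get("min_positive", 2)),
            required_genes=tuple(d.get("required_genes", ())),
        )


def classify_gene(scores: ExpressionScores, thresholds: GeneThresholds) -> GeneCall:
    """Apply the TE gate and BAE/MAE OR-rule to one sample x gene."""
    if scores.gene != thresholds.gene:
        raise ValueError(
            f"gene mismatch: scores for {scores.gene!r}, thresholds for "
            f"{thresholds.gene!r}"
        )
    if scores.te < thresholds.te_min:
        return GeneCall(scores.sample_id, scores.gene, "negative", "te_gate")
    if scores.bae > thresholds.bae_min:
        return GeneCall(scores.sample_id, scores.gene, "positive", "bae")
    if scores.mae > thresholds.mae_min:
        return GeneCall(scores.sample_id, scores.gene, "positive", "mae")
    return GeneCall(scores.sample_id, scores.gene, "negative", "below_threshold")


def classify_panel(calls: Mapping[str, GeneCall], model: PanelModel) -> str:
    """Combine per-gene calls into a benign/malignant vote for one sample."""
    missing = [g for g in model.genes if g not in calls]
    if missing:
        raise ValueError(f"missing gene call(s) for {missing}")
    positives = sum(calls[g].is_positive for g in model.genes)
    verdict = positives >= model.min_positive
    if model.required_genes:
        verdict = verdict and all(calls[g].is_positive for g in model.required_genes)
    return "malignant" if verdict else "benign"


def _call_reasons(te, bae, mae, thr: GeneThresholds):
    """Vectorised version of :func:`classify_gene` over score arrays."""
    gated = te < thr.te_min
    by_bae = ~gated & (bae > thr.bae_min)
    by_mae = ~gated & ~by_bae & (mae > thr.mae_min)
    positive = by_bae | by_mae
    reason = np.where(
        gated, "te_gate", np.where(by_bae, "bae", np.where(by_mae, "mae", "below_threshold"))
    )
    return positive, reason


def classify_samples(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    models: Mapping[str, PanelModel],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every sample with its cancer type's panel model.

    Parameters
    ----------
    scores
        Long score table (``sample_id, gene, te, bae, mae``).
    metadata
        ``sample_id, cancer_type`` (extra columns pass through untouched).
    models
        Mapping cancer type -> :class:`PanelModel`.

    Returns
    -------
    (calls, predictions)
        ``calls``: one row per sample x panel gene with call and reason;
        ``predictions``: one row per sample with the benign/malignant vote.
    """
    meta = metadata[["sample_id", "cancer_type"]].drop_duplicates()
    merged = scores.merge(meta, on="sample_id", how="inner")
    missing_types = set(merged["cancer_type"]) - set(models)
    if missing_types:
        raise ValueError(f"no panel model for cancer type(s) {sorted(missing_types)}")

    call_frames = []
    pred_frames = []
    for cancer_type, grp in merged.groupby("cancer_type", sort=True):
        model = models[cancer_type]
        samples = np.sort(grp["sample_id"].unique())
        pos_votes = pd.DataFrame(index=samples)
        for gene in model.genes:
            rows = grp[grp["gene"] == gene].set_index("sample_id")
            absent = sorted(set(samples) - set(rows.index))
            if absent:
                raise ValueError(
                    f"samples missing scores for panel gene {gene!r}: {absent}"
                )
            rows = rows.reindex(samples)
            positive, reason = _call_reasons(
                rows["te"].to_numpy(float),
                rows["bae"].to_numpy(float),
                rows["mae"].to_numpy(float),
                model.thresholds[gene],
            )
            pos_votes[gene] = positive
            call_frames.append(
                pd.DataFrame(
                    {
                        "sample_id": samples,
                        "gene": gene,
                        "call": np.where(positive, "positive", "negative"),
                        "reason": reason,
                    }
                )
            )
        verdict = pos_votes[list(model.genes)].sum(axis=1) >= model.min_positive
        for g in model.required_genes:
            verdict &= pos_votes[g]
        pred_frames.append(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "cancer_type": cancer_type,
                    "prediction": np.where(verdict.to_numpy(), "malignant", "benign"),
                }
            )
        )
    calls = pd.concat(call_frames, ignore_index=True).sort_values(
        ["sample_id", "gene"], ignore_index=True
    )
    predictions = pd.concat(pred_frames, ignore_index=True).sort_values(
        "sample_id", ignore_index=True
    )
    return calls, predictions


def build_panel_models(
    cohort: pd.DataFrame,
    *,
    genes: Sequence[str] = PANEL_GENES,
    min_positive: int = 2,
    special_rules: Mapping[str, Sequence[str]] = DEFAULT_SPECIAL_RULES,
    spec_floor: float | None = None,
    sens_floor: float | None = None,
) -> tuple[dict[str, PanelModel], dict[tuple[str, str], CalibrationResult]]:
    """Calibrate per-cancer thresholds and assemble the panel models.

    Every cancer type present in ``cohort`` gets a model over ``genes``
    with the 2-of-3 vote, except types listed in ``special_rules`` whose
    panel is restricted to the listed genes with all of them required
    (the gastric GNAS+GRB10 AND-rule by default).  Returns the models and
    the underlying per-(cancer, gene) calibration results.
    """
    models: dict[str, PanelModel] = {}
    details: dict[tuple[str, str], CalibrationResult] = {}
    for cancer_type, grp in cohort.groupby("cancer_type", sort=True):
        if cancer_type in special_rules:
            panel_genes = tuple(special_rules[cancer_type])
            required = panel_genes
            needed = max(min_positive, len(panel_genes))
        else:
            panel_genes = tuple(genes)
            required = ()
            needed = min_positive
        thresholds = {}
        for gene in panel_genes:
            res = calibrate_gene(
                grp,
                gene,
                mode="per_cancer",
                spec_floor=spec_floor,
                sens_floor=sens_floor,
                exclusions=(),
            )
            details[(cancer_type, gene)] = res
            thresholds[gene] = res.thresholds
        models[cancer_type] = PanelModel(
            cancer_type=cancer_type,
            genes=panel_genes,
            thresholds=thresholds,
            min_positive=min(needed, len(panel_genes)),
            required_genes=required,
        )
    return models, details
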