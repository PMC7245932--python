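"""Per-gene threshold calibration and gene screening.

A gene classifies a sample through three cutoffs applied to its scores:
the TE gate (``te < te_min`` forces a negative call, guarding against
spurious BAE/MAE inflation when hardly any cell expresses), then
positivity when ``bae > bae_min`` or ``mae > mae_min``.

Calibration searches the exhaustive grid of candidate cutoff triples —
the midpoints between consecutive distinct observed values of each
measure, plus disabling sentinels — for the triple that maximises
sensitivity subject to a specificity floor:

* ``screening`` mode (all cancer types pooled): specificity >= 80%,
  used to decide which genes enter the diagnostic panel;
* ``per_cancer`` mode (one cancer type): sensitivity and specificity
  both strictly > 70%, used to build the cancer-specific models.

Ties are broken toward higher specificity, then the lowest TE gate, then
the lowest BAE and MAE cutoffs.  When no triple satisfies the floor the
constrained-best triple (maximal min(sensitivity, specificity), then
maximal sum) is returned flagged infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import KNOWN_GENES

NEGATIVE_LABELS = frozenset({"normal", "benign"})
POSITIVE_LABELS = frozenset({"malignant"})

#: (cancer_type, gene) pairs excluded from pooled statistics.  SNRPN
#: behaves in the opposite direction in gastric cancer (its scores fall
#: with malignancy), so gastric SNRPN observations are left out of the
#: pooled screening analysis.
DEFAULT_EXCLUSIONS = (("gastric", "SNRPN"),)


@dataclass(frozen=True)
class GeneThresholds:
    """Calibrated TE/BAE/MAE cutoffs for one gene.

    ``scope`` is ``"screening"`` for the pooled screening thresholds or a
    cancer-type name for model-building thresholds.
    """

    gene: str
    te_min: float
    bae_min: float
    mae_min: float
    scope: str = "screening"

    def __post_init__(self) -> None:
        for name in ("te_min", "bae_min", "mae_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")


@dataclass(frozen=True)
class CalibrationResult:
    """Thresholds plus the performance achieved on the calibration cohort."""

    thresholds: GeneThresholds
    sensitivity: float
    specificity: float
    feasible: bool
    n_negative: int
    n_positive: int
    mode: str


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of panel screening over candidate genes."""

    retained: tuple[str, ...]
    dropped: tuple[str, ...]
    review: tuple[str, ...]
    results: Mapping[str, CalibrationResult]


def candidate_cutoffs(values, *, include_zero: bool = True, include_top: bool = False) -> np.ndarray:
    """Midpoints between consecutive distinct values, plus sentinels.

    ``0`` disables the TE gate / makes BAE-MAE positivity require any
    non-zero score; ``100`` disables a strict ``>`` cutoff entirely.
    """
    uniq = np.unique(np.asarray(values, dtype=float))
    parts = [(uniq[:-1] + uniq[1:]) / 2.0]
    if include_zero:
        parts.append([0.0])
    if include_top:
        parts.append([100.0])
    return np.unique(np.concatenate(parts))


def _is_positive_label(labels: pd.Series) -> np.ndarray:
    unknown = set(labels.unique()) - NEGATIVE_LABELS - POSITIVE_LABELS
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    return labels.isin(POSITIVE_LABELS).to_numpy()


def _grid_search(
    te: np.ndarray,
    bae: np.ndarray,
    mae: np.ndarray,
    is_pos: np.ndarray,
    *,
    spec_floor: float,
    spec_strict: bool,
    sens_floor: float | None,
    sens_strict: bool,
) -> tuple[float, float, float, int, int, bool]:
    """Exhaustive search over (te_min, bae_min, mae_min) candidate triples.

    Returns ``(te_min, bae_min, mae_min, tp, tn, feasible)``.  The inner
    grid over (bae, mae) is evaluated for every TE gate at once via 2-D
    cumulative histograms, so the search is O(n^3) in counts but fully
    vectorised.
    """
    te_c = candidate_cutoffs(te, include_zero=True)
    bae_c = candidate_cutoffs(bae, include_zero=True, include_top=True)
    mae_c = candidate_cutoffs(mae, include_zero=True, include_top=True)
    n_pos = int(is_pos.sum())
    n_neg = int(len(is_pos) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("calibration requires both classes present")

    # bin index: smallest candidate >= value, i.e. the first cutoff at
    # which this sample is NOT strictly above it
    ib = np.searchsorted(bae_c, bae, side="left")
    im = np.searchsorted(mae_c, mae, side="left")

    def _counts(mask: np.ndarray) -> np.ndarray:
        """#samples in ``mask`` with bae <= bae_c[i] and mae <= mae_c[j]."""
        h = np.zeros((len(bae_c), len(mae_c)), dtype=np.int64)
        np.add.at(h, (ib[mask], im[mask]), 1)
        return h.cumsum(axis=0).cumsum(axis=1)

    def _pick(tp: np.ndarray, tn: np.ndarray, ok: np.ndarray):
        """Best (tp, tn, i, j) among grid cells flagged ok, or None."""
        if not ok.any():
            return None
        cand = np.flatnonzero(ok.ravel())
        tpf, tnf = tp.ravel()[cand], tn.ravel()[cand]
        cand = cand[tpf == tpf.max()]
        tnf = tn.ravel()[cand]
        cand = cand[tnf == tnf.max()]
        flat = cand.min()  # lowest (bae, mae) indices = lowest cutoffs
        i, j = divmod(flat, len(mae_c))
        return int(tp[i, j]), int(tn[i, j]), int(i), int(j)

    best: tuple | None = None       # (tp, tn) maximised, earliest t wins ties
    best_any: tuple | None = None   # infeasible fallback

    for t in te_c:
        gate = te >= t
        below_pos = _counts(gate & is_pos)
        below_neg = _counts(gate & ~is_pos)
        tp = int((gate & is_pos).sum()) - below_pos
        fp = int((gate & ~is_pos).sum()) - below_neg
        tn = n_neg - fp

        if spec_strict:
            spec_ok = tn * 100 > spec_floor * n_neg
        else:
            spec_ok = tn * 100 >= spec_floor * n_neg
        if sens_floor is None:
            ok = spec_ok
        elif sens_strict:
            ok = spec_ok & (tp * 100 > sens_floor * n_pos)
        else:
            ok = spec_ok & (tp * 100 >= sens_floor * n_pos)

        hit = _pick(tp, tn, ok)
        if hit is not None:
            tp_v, tn_v, i, j = hit
            if best is None or (tp_v, tn_v) > (best[0], best[1]):
                best = (tp_v, tn_v, float(t), float(bae_c[i]), float(mae_c[j]))

        if best is None:  # only track the fallback until something is feasible
            se = tp / n_pos
            sp = tn / n_neg
            score = np.minimum(se, sp) * 1e6 + (se + sp)
            hit = _pick(tp, tn, score >= score.max())
            if hit is not None:
                tp_v, tn_v, i, j = hit
                key = (min(tp_v / n_pos, tn_v / n_neg), tp_v / n_pos + tn_v / n_neg)
                if best_any is None or key > best_any[:2]:
                    best_any = (*key, tp_v, tn_v, float(t), float(bae_c[i]), float(mae_c[j]))

    if best is not None:
        tp_v, tn_v, t, b, m = best
        return t, b, m, tp_v, tn_v, True
    assert best_any is not None
    _, _, tp_v, tn_v, t, b, m = best_any
    return t, b, m, tp_v, tn_v, False


def calibrate_gene(
    cohort: pd.DataFrame,
    gene: str,
    mode: str = "screening",
    *,
    spec_floor: float | None = None,
    sens_floor: float | None = None,
    exclusions: Sequence[tuple[str, str]] = DEFAULT_EXCLUSIONS,
) -> CalibrationResult:
    """Calibrate TE/BAE/MAE cutoffs for one gene on a labelled cohort.

    Parameters
    ----------
    cohort
        Long-format scores joined with metadata; columns ``sample_id,
        gene, te, bae, mae, class_label`` and, when exclusions are to be
        honoured, ``cancer_type``.
    gene
        The gene to calibrate.
    mode
        ``"screening"`` (specificity >= 80%, pooled) or ``"per_cancer"``
        (sensitivity and specificity both > 70%).
    spec_floor, sens_floor
        Override the mode's default floors (percent).

    The per-measure ROC optima are members of the candidate grids, so the
    search starts from (and can only improve on) the single-measure
    Youden-optimal cutoffs.
    """
    if mode == "screening":
        spec_floor = 80.0 if spec_floor is None else spec_floor
        spec_strict, sens_strict = False, False
    elif mode == "per_cancer":
        spec_floor = 70.0 if spec_floor is None else spec_floor
        sens_floor = 70.0 if sens_floor is None else sens_floor
        spec_strict, sens_strict = True, True
    else:
        raise ValueError(f"unknown calibration mode {mode!r}")

    rows = cohort[cohort["gene"] == gene]
    excluded_types = {ct for ct, g in exclusions if g == gene}
    if excluded_types:
        if "cancer_type" in rows.columns:
            rows = rows[~rows["cancer_type"].isin(excluded_types)]
        all_samples = cohort.loc[
            ~cohort.get("cancer_type", pd.Series(index=cohort.index, dtype=object)).isin(
                excluded_types
            ),
            "sample_id",
        ]
    else:
        all_samples = cohort["sample_id"]
    missing = sorted(set(all_samples) - set(rows["sample_id"]))
    if missing:
        raise ValueError(f"samples missing scores for {gene}: {missing}")
    if rows.empty:
        raise ValueError(f"no scores for gene {gene!r}")

    is_pos = _is_positive_label(rows["class_label"])
    t, b, m, tp, tn, feasible = _grid_search(
        rows["te"].to_numpy(dtype=float),
        rows["bae"].to_numpy(dtype=float),
        rows["mae"].to_numpy(dtype=float),
        is_pos,
        spec_floor=spec_floor,
        spec_strict=spec_strict,
        sens_floor=sens_floor,
        sens_strict=sens_strict,
    )
    n_pos = int(is_pos.sum())
    n_neg = len(is_pos) - n_pos
    scope = "screening" if mode == "screening" else str(rows["cancer_type"].iloc[0]) if "cancer_type" in rows.columns and rows["cancer_type"].nunique() == 1 else mode
    return CalibrationResult(
        thresholds=GeneThresholds(gene=gene, te_min=t, bae_min=b, mae_min=m, scope=scope),
        sensitivity=100.0 * tp / n_pos,
        specificity=100.0 * tn / n_neg,
        feasible=feasible,
        n_negative=n_neg,
        n_positive=n_pos,
        mode=mode,
    )


def screen_genes(
    cohort: pd.DataFrame,
    genes: Sequence[str] = KNOWN_GENES,
    *,
    sens_keep: float = 80.0,
    sens_drop: float = 60.0,
    spec_floor: float = 80.0,
    exclusions: Sequence[tuple[str, str]] = DEFAULT_EXCLUSIONS,
) -> ScreeningResult:
    """Screen candidate genes on the pooled cohort at a specificity floor.

    Each gene is calibrated in screening mode (specificity >= ``spec_floor``)
    and judged on the sensitivity it then achieves: retained when above
    ``sens_keep``, dropped when below ``sens_drop``, flagged for manual
    review in between.
    """
    results: dict[str, CalibrationResult] = {}
    retained, dropped, review = [], [], []
    for gene in genes:
        res = calibrate_gene(
            cohort, gene, mode="screening", spec_floor=spec_floor, exclusions=exclusions
        )
        results[gene] = res
        if res.sensitivity > sens_keep:
            retained.append(gene)
        elif res.sensitivity < sens_drop:
            dropped.append(gene)
        else:
            review.append(gene)
    return ScreeningResult(
        retained=tuple(retained),
        dropped=tuple(dropped),
        review=tuple(review),
        results=results,
    )
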