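"""Robust rank-order (Fligner-Policello) test and significance screening.

The two-sample location comparisons here involve small groups whose
variances differ between histologic classes, so the Wilcoxon rank-sum
assumption of equal shapes is not safe.  The Fligner-Policello test is
the standard "robust rank-order" procedure for that setting: it is built
on placements — for each observation, the number of observations in the
other sample below it, ties counted half — and studentises the placement
sums by their empirical variability.

With placements ``P_i = #{y < x_i} + 0.5 #{y = x_i}`` and ``Q_j``
symmetrically, means ``Pbar, Qbar`` and squared deviations
``V_x = sum (P_i - Pbar)^2``, ``V_y = sum (Q_j - Qbar)^2``, the
standardised statistic is

    U = (sum P_i - sum Q_j) / (2 * sqrt(V_x + V_y + Pbar * Qbar))

oriented so that U > 0 when the first sample tends larger.  For groups
of at least 12 each, U is compared with the standard normal; smaller
groups use the permutation distribution of the placement sum —
exhaustive when the number of label assignments is at most
``max_exact``, otherwise Monte Carlo with an explicit seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calibration import DEFAULT_EXCLUSIONS
from .scoring import MEASURES

ALTERNATIVES = ("greater", "less", "two-sided")


@dataclass(frozen=True)
class RankOrderResult:
    """Outcome of the robust rank-order test.

    ``statistic`` is the standardised U (NaN when both groups are
    internally constant, in which case the permutation path decides);
    ``method`` records how the p-value was obtained.
    """

    statistic: float
    p_value: float
    method: str  # "normal_approximation" | "exact_permutation" | "monte_carlo_permutation"
    n_x: int
    n_y: int
    alternative: str


def _placements(x: np.ndarray, y_sorted: np.ndarray) -> np.ndarray:
    lo = np.searchsorted(y_sorted, x, side="left")
    hi = np.searchsorted(y_sorted, x, side="right")
    return lo + 0.5 * (hi - lo)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(U, placement sum of x).  U is NaN on a zero denominator."""
    p = _placements(x, np.sort(y))
    q = _placements(y, np.sort(x))
    vx = float(((p - p.mean()) ** 2).sum())
    vy = float(((q - q.mean()) ** 2).sum())
    denom = 2.0 * math.sqrt(vx + vy + p.mean() * q.mean()) if vx + vy + p.mean() * q.mean() > 0 else 0.0
    u = (p.sum() - q.sum()) / denom if denom else math.nan
    return u, float(p.sum())


def _perm_stats_exact(pooled_ranks: np.ndarray, n_x: int) -> np.ndarray:
    """Placement sums of every label assignment, via midranks.

    The placement sum of x against y equals ``sum(midranks of x) -
    n_x (n_x + 1) / 2``, so enumerating subsets of midranks enumerates
    the permutation distribution.
    """
    offset = n_x * (n_x + 1) / 2.0
    return np.array(
        [sum(c) - offset for c in itertools.combinations(pooled_ranks, n_x)]
    )


def robust_rank_order(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "greater",
    *,
    min_asymptotic: int = 12,
    max_exact: int = 20_000,
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> RankOrderResult:
    """Fligner-Policello test of location for two independent samples.

    ``alternative="greater"`` tests whether ``x`` tends larger than
    ``y``.  The normal approximation is used when both groups have at
    least ``min_asymptotic`` observations and the statistic is defined;
    otherwise p-values come from the permutation distribution of the
    placement sum (exact enumeration up to ``max_exact`` assignments,
    else Monte Carlo, which requires ``seed``).  Exact permutation
    p-values use the mid-p convention — half weight on assignments tying
    the observed statistic — so exchangeable samples yield p = 0.5.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = len(x), len(y)
    if n_x < 2 or n_y < 2:
        raise ValueError("each group needs at least 2 observations")

    u, t_obs = _u_statistic(x, y)

    if min(n_x, n_y) >= min_asymptotic and not math.isnan(u):
        if alternative == "greater":
            p = float(sps.norm.sf(u))
        elif alternative == "less":
            p = float(sps.norm.cdf(u))
        else:
            p = float(2.0 * sps.norm.sf(abs(u)))
        return RankOrderResult(u, min(p, 1.0), "normal_approximation", n_x, n_y, alternative)

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks handle ties
    n_comb = math.comb(n_x + n_y, n_x)
    if n_comb <= max_exact:
        ts = _perm_stats_exact(ranks, n_x)
        greater = float(
            (ts > t_obs + 1e-9).sum() + 0.5 * (np.abs(ts - t_obs) <= 1e-9).sum()
        ) / len(ts)
        less = float(
            (ts < t_obs - 1e-9).sum() + 0.5 * (np.abs(ts - t_obs) <= 1e-9).sum()
        ) / len(ts)
        method = "exact_permutation"
    else:
        if seed is None:
            raise ValueError("Monte Carlo permutation requires an explicit seed")
        rng = np.random.default_rng(seed)
        offset = n_x * (n_x + 1) / 2.0
        ts = np.array(
            [rng.permutation(ranks)[:n_x].sum() - offset for _ in range(n_resamples)]
        )
        # add-one rule: the observed assignment counts as one permutation
        greater = (1.0 + float((ts >= t_obs - 1e-9).sum())) / (n_resamples + 1)
        less = (1.0 + float((ts <= t_obs + 1e-9).sum())) / (n_resamples + 1)
        method = "monte_carlo_permutation"

    if alternative == "greater":
        p = greater
    elif alternative == "less":
        p = less
    else:
        p = min(1.0, 2.0 * min(greater, less))
    return RankOrderResult(u, min(p, 1.0), method, n_x, n_y, alternative)


def significance_screen(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    *,
    measures: Sequence[str] = MEASURES,
    comparisons: Sequence[tuple[str, str]] = (("normal", "benign"), ("benign", "malignant")),
    alpha: float = 0.01,
    exclusions: Sequence[tuple[str, str]] = DEFAULT_EXCLUSIONS,
    seed: int | None = None,
    adjust: str | None = None,
) -> pd.DataFrame:
    """One-tailed group comparisons for every gene x measure.

    Each comparison ``(lo, hi)`` tests whether the ``hi`` class scores
    higher than the ``lo`` class (malignant > benign > normal), pooling
    samples across cancer types except for excluded (cancer_type, gene)
    pairs.  No multiplicity adjustment is applied by default; pass
    ``adjust="bh"`` for Benjamini-Hochberg on the p column.

    Returns a table with columns ``gene, measure, comparison, n_x, n_y,
    statistic, p_value, method, significant``; untestable rows (a group
    with fewer than 2 samples) carry NaN p-values and ``method
    = "untestable"``.
    """
    meta_cols = ["sample_id", "class_label"]
    if "cancer_type" in metadata.columns:
        meta_cols.append("cancer_type")
    merged = scores.merge(metadata[meta_cols].drop_duplicates(), on="sample_id")

    rows = []
    for gene in sorted(merged["gene"].unique()):
        sub = merged[merged["gene"] == gene]
        excluded_types = {ct for ct, g in exclusions if g == gene}
        if excluded_types and "cancer_type" in sub.columns:
            sub = sub[~sub["cancer_type"].isin(excluded_types)]
        for measure in measures:
            for lo, hi in comparisons:
                hi_vals = sub.loc[sub["class_label"] == hi, measure].to_numpy(float)
                lo_vals = sub.loc[sub["class_label"] == lo, measure].to_numpy(float)
                row = {
                    "gene": gene,
                    "measure": measure,
                    "comparison": f"{hi}>{lo}",
                    "n_x": len(hi_vals),
                    "n_y": len(lo_vals),
                }
                if len(hi_vals) < 2 or len(lo_vals) < 2:
                    row.update(
                        statistic=math.nan, p_value=math.nan, method="untestable",
                        significant=False,
                    )
                else:
                    res = robust_rank_order(hi_vals, lo_vals, "greater", seed=seed)
                    row.update(
                        statistic=res.statistic,
                        p_value=res.p_value,
                        method=res.method,
                        significant=bool(res.p_value < alpha),
                    )
                rows.append(row)
    table = pd.DataFrame(rows)
    if adjust == "bh":
        testable = table["p_value"].notna()
        adjusted = np.full(len(table), np.nan)
        adjusted[testable.to_numpy()] = sps.false_discovery_control(
            table.loc[testable, "p_value"].to_numpy()
        )
        table["p_adjusted"] = adjusted
        table["significant"] = table["p_adjusted"] < alpha
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table
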