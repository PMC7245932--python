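"""Threshold calibration vs brute-force enumeration; gene screening."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qcigish.calibration import (
    calibrate_gene,
    candidate_cutoffs,
    screen_genes,
)
from qcigish.classify import classify_gene
from qcigish.scoring import ExpressionScores


def _cohort_frame(te, bae, mae, labels, gene="GNAS", cancer="lung"):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(te))],
            "gene": gene,
            "te": te,
            "bae": bae,
            "mae": mae,
            "class_label": labels,
            "cancer_type": cancer,
        }
    )


def brute_force_calibration(frame, gene, *, spec_floor, spec_strict, sens_floor, sens_strict):
    """Enumerate every candidate cutoff triple through the scalar classifier."""
    rows = frame[frame.gene == gene]
    te_c = candidate_cutoffs(rows.te, include_zero=True)
    bae_c = candidate_cutoffs(rows.bae, include_zero=True, include_top=True)
    mae_c = candidate_cutoffs(rows.mae, include_zero=True, include_top=True)
    is_pos = (rows.class_label == "malignant").to_numpy()
    n_pos, n_neg = is_pos.sum(), (~is_pos).sum()
    best = None
    for t, b, m in itertools.product(te_c, bae_c, mae_c):
        from qcigish.calibration import GeneThresholds

        thr = GeneThresholds(gene=gene, te_min=t, bae_min=b, mae_min=m)
        calls = [
            classify_gene(
                ExpressionScores(r.sample_id, gene, r.te, r.bae, r.mae, 1, 1), thr
            ).is_positive
            for r in rows.itertuples()
        ]
        calls = np.asarray(calls)
        tp = int((calls & is_pos).sum())
        tn = int((~calls & ~is_pos).sum())
        sens, spec = 100 * tp / n_pos, 100 * tn / n_neg
        ok = (spec > spec_floor) if spec_strict else (spec >= spec_floor)
        if sens_floor is not None:
            ok &= (sens > sens_floor) if sens_strict else (sens >= sens_floor)
        if not ok:
            continue
        key = (tp, tn, -t, -b, -m)
        if best is None or key > best[0]:
            best = (key, (t, b, m, sens, spec))
    return best[1] if best else None


@pytest.mark.parametrize("mode,floors", [
    ("screening", dict(spec_floor=80.0, spec_strict=False, sens_floor=None, sens_strict=False)),
    ("per_cancer", dict(spec_floor=70.0, spec_strict=True, sens_floor=70.0, sens_strict=True)),
])
def test_matches_brute_force_on_small_cohorts(rng, mode, floors):
    for trial in range(25):
        n = int(rng.integers(6, 13))
        labels = ["benign"] * (n // 2) + ["malignant"] * (n - n // 2)
        te = rng.integers(0, 60, n).astype(float)
        bae = rng.integers(0, 50, n).astype(float)
        mae = rng.integers(0, 30, n).astype(float)
        frame = _cohort_frame(te, bae, mae, labels)
        oracle = brute_force_calibration(frame, "GNAS", **floors)
        res = calibrate_gene(frame, "GNAS", mode=mode, exclusions=())
        if oracle is None:
            assert not res.feasible
        else:
            t, b, m, sens, spec = oracle
            assert res.feasible
            assert (res.thresholds.te_min, res.thresholds.bae_min, res.thresholds.mae_min) == (t, b, m)
            assert res.sensitivity == pytest.approx(sens)
            assert res.specificity == pytest.approx(spec)


def test_perfectly_separable_cohort_is_perfect():
    frame = _cohort_frame(
        te=[5, 6, 7, 8, 40, 45, 50, 55],
        bae=[2, 3, 2, 4, 30, 35, 32, 38],
        mae=[1, 1, 2, 1, 15, 18, 16, 20],
        labels=["benign"] * 4 + ["malignant"] * 4,
    )
    res = calibrate_gene(frame, "GNAS", mode="screening")
    assert res.sensitivity == 100.0 and res.specificity == 100.0 and res.feasible


def test_specificity_floor_is_hard_constraint(rng):
    # overlapping classes: best Youden sits below the 80% floor, the
    # returned thresholds must still satisfy it
    n = 40
    te = np.concatenate([rng.normal(30, 12, n), rng.normal(40, 12, n)]).clip(0, 100)
    bae = np.concatenate([rng.normal(20, 10, n), rng.normal(30, 10, n)]).clip(0, 100)
    mae = np.concatenate([rng.normal(5, 4, n), rng.normal(10, 4, n)]).clip(0, 100)
    frame = _cohort_frame(te, bae, mae, ["benign"] * n + ["malignant"] * n)
    res = calibrate_gene(frame, "GNAS", mode="screening")
    assert res.specificity >= 80.0


def test_infeasible_constraints_flagged():
    # identical score distributions in both classes: >70/>70 unreachable
    frame = _cohort_frame(
        te=[10.0, 20.0] * 4, bae=[5.0, 15.0] * 4, mae=[1.0, 3.0] * 4,
        labels=["benign", "benign", "malignant", "malignant"] * 2,
    )
    res = calibrate_gene(frame, "GNAS", mode="per_cancer")
    assert not res.feasible


def test_missing_gene_scores_listed():
    frame = _cohort_frame([10, 20], [5, 6], [1, 2], ["benign", "malignant"])
    extra = frame.copy()
    extra["gene"] = "GRB10"
    cohort = pd.concat([frame, extra.iloc[:1]], ignore_index=True)
    with pytest.raises(ValueError, match="s1"):
        calibrate_gene(cohort, "GRB10")


class TestScreening:
    def _screening_cohort(self, seed=5):
        from qcigish.scoring import score_table
        from qcigish.simulate import (
            DEFAULT_PROFILES,
            ClassProfile,
            CohortConfig,
            generate_cohort,
        )

        # GNAS keeps the informative defaults; IGF2 is exchangeable noise
        flat = {
            c: ClassProfile((0.75, 0.17, 0.06, 0.02), concentration=8.0)
            for c in ("normal", "benign", "malignant")
        }
        cfg = CohortConfig(
            samples={
                ct: {"normal": 3, "benign": 5, "malignant": 10}
                for ct in ("lung", "skin", "breast")
            },
            seed=seed,
            genes=("GNAS", "IGF2"),
            profiles={"GNAS": dict(DEFAULT_PROFILES), "IGF2": flat},
        )
        counts, meta = generate_cohort(cfg)
        return score_table(counts).merge(meta, on="sample_id")

    def test_informative_retained_noise_dropped(self):
        cohort = self._screening_cohort()
        result = screen_genes(cohort, genes=("GNAS", "IGF2"))
        assert "GNAS" in result.retained
        assert "IGF2" not in result.retained

    def test_all_separable_all_retained(self):
        frame = pd.concat(
            [
                _cohort_frame(
                    te=[5, 6, 7, 8, 40, 45, 50, 55],
                    bae=[2, 3, 2, 4, 30, 35, 32, 38],
                    mae=[1, 1, 2, 1, 15, 18, 16, 20],
                    labels=["benign"] * 4 + ["malignant"] * 4,
                    gene=g,
                )
                for g in ("GNAS", "GRB10")
            ],
            ignore_index=True,
        )
        result = screen_genes(frame, genes=("GNAS", "GRB10"))
        assert result.retained == ("GNAS", "GRB10")
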