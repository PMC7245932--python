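"""Scoring equations, field pooling, z-scores and group summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qcigish.scoring import (
    CellCounts,
    aggregate_fields,
    compute_scores,
    group_summary,
    score_table,
    zscore_matrix,
)

counts_st = st.tuples(*[st.integers(0, 500)] * 4)


def _cc(n0, n1, n2, n2plus, sample="s", gene="GNAS", field=None):
    return CellCounts(sample, gene, n0, n1, n2, n2plus, field_index=field)


class TestAggregateFields:
    @pytest.mark.parametrize(
        "fields, expected",
        [
            ([(10, 1, 0, 0), (10, 1, 0, 0)], (20, 2, 0, 0)),
            ([(5, 3, 2, 1)], (5, 3, 2, 1)),
            ([(0, 0, 0, 0)] * 4, (0, 0, 0, 0)),
        ],
    )
    def test_elementwise_sum(self, fields, expected):
        pooled = aggregate_fields([_cc(*f, field=i + 1) for i, f in enumerate(fields)])
        assert (pooled.n0, pooled.n1, pooled.n2, pooled.n2plus) == expected
        assert pooled.field_index is None

    def test_rejects_mixed_identity(self):
        with pytest.raises(ValueError, match="identit"):
            aggregate_fields([_cc(1, 1, 1, 1), _cc(1, 1, 1, 1, gene="SNRPN")])
        with pytest.raises(ValueError):
            aggregate_fields([])

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            _cc(-1, 0, 0, 0)


class TestComputeScores:
    @pytest.mark.parametrize(
        "counts, te, bae, mae",
        [
            ((90, 5, 3, 2), 10.0, 30.0, 20.0),
            ((100, 0, 0, 0), 0.0, 0.0, 0.0),
            ((0, 0, 0, 10), 100.0, 0.0, 100.0),
            ((0, 0, 0, 0), 0.0, 0.0, 0.0),
        ],
    )
    def test_worked_examples(self, counts, te, bae, mae):
        s = compute_scores(_cc(*counts))
        assert (s.te, s.bae, s.mae) == (te, bae, mae)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(counts_st)
    def test_ranges_and_complement(self, counts):
        s = compute_scores(_cc(*counts))
        for v in (s.te, s.bae, s.mae):
            assert 0.0 <= v <= 100.0
        assert s.bae + s.mae <= 100.0 + 1e-9
        assert (s.te == 0.0) == (s.expressing_nuclei == 0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(counts_st, st.integers(1, 9))
    def test_scale_invariance(self, counts, k):
        a = compute_scores(_cc(*counts))
        b = compute_scores(_cc(*(k * c for c in counts)))
        assert np.allclose([a.te, a.bae, a.mae], [b.te, b.bae, b.mae])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(counts_st, min_size=2, max_size=5), st.randoms(use_true_random=False))
    def test_field_permutation_invariance(self, fields, rnd):
        recs = [_cc(*f, field=i + 1) for i, f in enumerate(fields)]
        shuffled = list(recs)
        rnd.shuffle(shuffled)
        a = compute_scores(aggregate_fields(recs))
        b = compute_scores(aggregate_fields(shuffled))
        assert (a.te, a.bae, a.mae) == (b.te, b.bae, b.mae)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(counts_st, st.integers(1, 200))
    def test_adding_silent_nuclei_lowers_te_only(self, counts, extra):
        a = compute_scores(_cc(*counts))
        b = compute_scores(_cc(counts[0] + extra, *counts[1:]))
        if a.expressing_nuclei > 0:
            assert b.te < a.te
        assert (a.bae, a.mae) == (b.bae, b.mae)


class TestScoreTable:
    def test_matches_scalar_path(self, rng):
        from conftest import random_counts_frame

        frame = random_counts_frame(rng)
        table = score_table(frame)
        for _, row in table.iterrows():
            sub = frame[(frame.sample_id == row.sample_id) & (frame.gene == row.gene)]
            pooled = aggregate_fields(
                [
                    _cc(r.n0, r.n1, r.n2, r.n2plus, row.sample_id, row.gene, r.field_index)
                    for r in sub.itertuples()
                ]
            )
            expected = compute_scores(pooled)
            assert np.allclose(
                [row.te, row.bae, row.mae], [expected.te, expected.bae, expected.mae]
            )

    def test_rejects_negative(self):
        frame = pd.DataFrame(
            [{"sample_id": "s", "gene": "GNAS", "n0": 1, "n1": -1, "n2": 0, "n2plus": 0}]
        )
        with pytest.raises(ValueError, match="negative"):
            score_table(frame)


class TestZscoreMatrix:
    @staticmethod
    def _tables(values_by_sample, cancer="lung"):
        scores = pd.DataFrame(
            [
                {"sample_id": s, "gene": "GNAS", "te": v, "bae": v, "mae": v}
                for s, v in values_by_sample.items()
            ]
        )
        meta = pd.DataFrame(
            [{"sample_id": s, "cancer_type": cancer} for s in values_by_sample]
        )
        return scores, meta

    def test_simple_row(self):
        scores, meta = self._tables({"a": 1.0, "b": 2.0, "c": 3.0})
        z = zscore_matrix(scores, meta, measures=("te",))
        assert list(z.index) == ["GNAS_te"]
        assert np.allclose(z.loc["GNAS_te"].to_numpy(), [-1.0, 0.0, 1.0])

    def test_constant_row_warns_and_zeroes(self):
        scores, meta = self._tables({"a": 5.0, "b": 5.0, "c": 5.0})
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_matrix(scores, meta, measures=("te",))
        assert (z.to_numpy() == 0).all()

    def test_moments_within_each_group(self, rng):
        rows, meta_rows = [], []
        for ct in ("lung", "skin"):
            for i in range(7):
                s = f"{ct}{i}"
                meta_rows.append({"sample_id": s, "cancer_type": ct})
                for g in ("GNAS", "GRB10"):
                    rows.append(
                        {
                            "sample_id": s,
                            "gene": g,
                            "te": rng.uniform(0, 100),
                            "bae": rng.uniform(0, 100),
                            "mae": rng.uniform(0, 100),
                        }
                    )
        z = zscore_matrix(pd.DataFrame(rows), pd.DataFrame(meta_rows))
        for ct in ("lung", "skin"):
            block = z[[c for c in z.columns if c.startswith(ct)]].to_numpy()
            assert np.allclose(block.mean(axis=1), 0, atol=1e-12)
            assert np.allclose(block.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_single_sample_group_errors(self):
        scores, meta = self._tables({"a": 1.0})
        with pytest.raises(ValueError, match="fewer than 2"):
            zscore_matrix(scores, meta)


class TestGroupSummary:
    def test_worked_examples(self):
        s = group_summary([1, 2, 3, 4, 5])
        assert (s.median, s.q1, s.q3) == (3, 2, 4)
        s = group_summary([7])
        assert (s.median, s.q1, s.q3) == (7, 7, 7)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            group_summary([])

    def test_against_order_statistic_oracle(self, rng):
        def oracle_quantile(sorted_vals, q):
            # linear interpolation between order statistics
            h = (len(sorted_vals) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(sorted_vals) - 1)
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        for _ in range(50):
            vals = rng.uniform(0, 100, size=rng.integers(1, 30))
            srt = np.sort(vals).tolist()
            s = group_summary(vals)
            assert np.isclose(s.median, oracle_quantile(srt, 0.5))
            assert np.isclose(s.q1, oracle_quantile(srt, 0.25))
            assert np.isclose(s.q3, oracle_quantile(srt, 0.75))
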