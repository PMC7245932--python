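import numpy as np
import pandas as pd
import pytest

from qcigish.simulate import CohortConfig, generate_cohort
from qcigish.scoring import score_table


@pytest.fixture(scope="session")
def small_cohort():
    """Scored two-class cohort of one cancer type, 8 benign / 12 malignant."""
    cfg = CohortConfig(
        samples={"lung": {"benign": 8, "malignant": 12}}, seed=42, genes=("GNAS",)
    )
    counts, meta = generate_cohort(cfg)
    scores = score_table(counts)
    return scores.merge(meta, on="sample_id")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_counts_frame(rng, n_samples=6, genes=("GNAS", "GRB10"), fields=4):
    rows = []
    for s in range(n_samples):
        for g in genes:
            for f in range(1, fields + 1):
                n = rng.integers(0, 40, size=4)
                rows.append(
                    {
                        "sample_id": f"s{s}",
                        "gene": g,
                        "field_index": f,
                        "n0": int(n[0]),
                        "n1": int(n[1]),
                        "n2": int(n[2]),
                        "n2plus": int(n[3]),
                    }
                )
    return pd.DataFrame(rows)
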