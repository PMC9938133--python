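import numpy as np
import pandas as pd
import pytest

from tissuemr import SummaryStats


def make_table(rows, **meta) -> SummaryStats:
    """Build a SummaryStats from dict rows, filling common defaults."""
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "n": 100_000,
        "pvalue": 1e-10,
        "beta": 0.05,
        "se": 0.01,
    }
    recs = []
    for i, r in enumerate(rows):
        rec = {**defaults, "rsid": f"rs{i:03d}", "pos": 1000 + i * 1000}
        rec.update(r)
        recs.append(rec)
    return SummaryStats(df=pd.DataFrame(recs), **meta)


def make_pairs(rng, n, theta=0.5, intercept=0.0, noise=True) -> pd.DataFrame:
    """Random harmonised exposure/outcome pairs with known slope."""
    bx = rng.normal(0.1, 0.04, n)
    se_x = rng.uniform(0.005, 0.02, n)
    se_y = rng.uniform(0.01, 0.05, n)
    by = intercept + theta * bx
    if noise:
        by = by + rng.normal(0, se_y)
    return pd.DataFrame(
        {"beta_exp": bx, "se_exp": se_x, "beta_out": by, "se_out": se_y}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
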