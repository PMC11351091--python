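import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrmediate.sumstats import HarmonizedSet, SumstatsTable

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_pairs(beta_x, beta_y, se_x=0.05, se_y=0.05, n_x=10_000.0, n_y=10_000.0):
    """Bare harmonized-pair DataFrame for estimator-level tests."""
    beta_x = np.asarray(beta_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    j = len(beta_x)
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(j)],
            "beta_x": beta_x,
            "se_x": np.broadcast_to(np.asarray(se_x, dtype=float), j).copy(),
            "eaf_x": 0.3,
            "n_x": n_x,
            "beta_y": beta_y,
            "se_y": np.broadcast_to(np.asarray(se_y, dtype=float), j).copy(),
            "eaf_y": 0.3,
            "n_y": n_y,
        }
    )


def make_harmonized(beta_x, beta_y, se_x=0.05, se_y=0.05, n_x=10_000.0, n_y=10_000.0):
    df = make_pairs(beta_x, beta_y, se_x, se_y, n_x, n_y)
    return HarmonizedSet("exposure", "outcome", df)


def make_table(
    snp_ids,
    beta,
    se,
    pval=None,
    chrom="1",
    pos=None,
    ea="A",
    oa="G",
    eaf=0.3,
    n=10_000.0,
    trait_id="trait",
    trait_type="quantitative",
):
    """SumstatsTable from parallel arrays with broadcastable scalars."""
    snp_ids = list(snp_ids)
    j = len(snp_ids)
    beta = np.broadcast_to(np.asarray(beta, dtype=float), j)
    se = np.broadcast_to(np.asarray(se, dtype=float), j)
    if pval is None:
        from scipy import stats

        pval = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": np.broadcast_to(np.asarray(chrom, dtype=object), j),
            "pos_bp": pos if pos is not None else np.arange(1, j + 1) * 1000,
            "effect_allele": np.broadcast_to(np.asarray(ea, dtype=object), j),
            "other_allele": np.broadcast_to(np.asarray(oa, dtype=object), j),
            "eaf": np.broadcast_to(np.asarray(eaf, dtype=float), j),
            "beta": beta,
            "se": se,
            "pval": np.broadcast_to(np.asarray(pval, dtype=float), j),
            "n": np.broadcast_to(np.asarray(n, dtype=float), j),
        }
    )
    return SumstatsTable(trait_id, trait_type, df)


@pytest.fixture(scope="session")
def default_triplet():
    """One reference simulation shared by read-only tests."""
    from mrmediate.simulate import SimParams, simulate_triplet

    return simulate_triplet(SimParams(seed=1))
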