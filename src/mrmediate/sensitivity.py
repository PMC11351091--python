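"""Heterogeneity, pleiotropy, outlier, and influence diagnostics.

Cochran's Q over per-SNP Wald ratios, funnel-plot point tables, a
simulation-based residual test for horizontal pleiotropy with per-SNP
outlier detection and re-evaluation after removal (MR-PRESSO style), and
leave-one-out influence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import IVWEstimator, MrResult, ivw, wald_arrays
from .sumstats import HarmonizedSet


def cochran_q(h) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test over per-SNP Wald ratios.

    Returns ``(Q, df, pval)`` with ``Q = sum_j w_j (theta_j - theta_IVW)^2``,
    ``df = J - 1`` and an upper-tail chi-square p.  This is the same Q that
    drives the multiplicative random-effects inflation inside the IVW
    estimator (single source of truth).
    """
    est = IVWEstimator(effects_model="fixed").fit(h)
    if est.n_snps_ < 2:
        raise ValueError("Cochran's Q needs >= 2 SNPs")
    return est.q_, est.q_df_, est.q_pval_


def funnel_points(h) -> pd.DataFrame:
    """Per-SNP (Wald ratio, precision) pairs for funnel plotting; no inference."""
    df = h.df if isinstance(h, HarmonizedSet) else h
    if len(df) < 1:
        raise ValueError("funnel_points needs >= 1 SNP")
    theta, se_theta = wald_arrays(df)
    return pd.DataFrame(
        {"snp_id": df["snp_id"].to_numpy(), "theta": theta, "precision": 1.0 / se_theta}
    )


@dataclass
class PressoResult:
    """Outcome of the simulation-based pleiotropy (MR-PRESSO style) test."""

    global_rss_obs: float
    global_p: float
    outlier_pvals: dict[str, float]
    outliers: list[str]
    result_before: MrResult
    result_after: MrResult
    n_sim: int
    seed: int
    alpha: float = 0.05
    extra: dict = field(default_factory=dict)


def _loo_theta(bx, by, se_x, se_y):
    """Leave-one-out IVW Wald-ratio means, vectorized over SNPs.

    Supports 1-D observed arrays and 2-D (n_sim, J) simulated arrays.
    """
    theta = by / bx
    w = (bx / se_y) ** 2
    s_w = w.sum(axis=-1, keepdims=True)
    s_wt = (w * theta).sum(axis=-1, keepdims=True)
    return (s_wt - w * theta) / (s_w - w)


def mr_presso(
    h,
    n_sim: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    effects_model: str = "auto",
) -> PressoResult:
    """Residual-sum-of-squares test for horizontal pleiotropy with outlier removal.

    The observed statistic is ``RSS = sum_j (beta_yj - theta_(-j) beta_xj)^2``
    where ``theta_(-j)`` is the IVW estimate leaving SNP j out.  Its null
    distribution comes from ``n_sim`` parametric draws
    ``beta_x* ~ N(beta_x, se_x)``, ``beta_y* ~ N(theta_(-j) beta_xj, se_y)``,
    each evaluated with its own leave-one-out ratios.  Empirical p-values use
    the (1 + k)/(n_sim + 1) estimator, so ``global_p >= 1/(n_sim + 1)``.
    Per-SNP outlier p-values take the empirical tail of each SNP's squared
    residual and are Bonferroni-corrected across the J SNPs at ``alpha``.
    Re-evaluation refits IVW with the flagged outliers removed (identical to
    the pre-removal result when none are flagged).
    """
    df = h.df if isinstance(h, HarmonizedSet) else h
    j = len(df)
    if j < 4:
        raise ValueError("mr_presso needs >= 4 SNPs")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    bx = df["beta_x"].to_numpy(float)
    by = df["beta_y"].to_numpy(float)
    se_x = df["se_x"].to_numpy(float)
    se_y = df["se_y"].to_numpy(float)
    snp_ids = df["snp_id"].to_numpy()

    theta_loo = np.asarray(_loo_theta(bx, by, se_x, se_y)).reshape(-1)
    resid_obs = by - theta_loo * bx
    rss_obs = float(np.sum(resid_obs**2))

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, se_x, size=(n_sim, j))
    by_sim = rng.normal(theta_loo * bx, se_y, size=(n_sim, j))
    bx_sim[bx_sim == 0] = np.finfo(float).tiny
    theta_loo_sim = _loo_theta(bx_sim, by_sim, se_x, se_y)
    resid_sim = by_sim - theta_loo_sim * bx_sim
    rss_sim = np.sum(resid_sim**2, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    tail = np.sum(resid_sim**2 >= resid_obs**2, axis=0)
    p_snp = (1 + tail) / (n_sim + 1)
    outlier_pvals = {str(s): float(p) for s, p in zip(snp_ids, p_snp)}
    flagged = [str(s) for s, p in zip(snp_ids, p_snp) if p < alpha / j]

    result_before = ivw(h, effects_model=effects_model)
    if flagged and j - len(flagged) >= 1:
        result_after = ivw(h.drop(flagged) if isinstance(h, HarmonizedSet) else df.loc[~df["snp_id"].isin(flagged)], effects_model=effects_model)
    else:
        result_after = result_before
    return PressoResult(
        global_rss_obs=rss_obs,
        global_p=global_p,
        outlier_pvals=outlier_pvals,
        outliers=flagged,
        result_before=result_before,
        result_after=result_after,
        n_sim=n_sim,
        seed=seed,
        alpha=alpha,
    )


def leave_one_out(h, effects_model: str = "auto") -> pd.DataFrame:
    """IVW re-estimated J times, each excluding one SNP.

    Returns one row per excluded SNP with the resulting estimate; the row
    count always equals the number of SNPs.
    """
    df = h.df if isinstance(h, HarmonizedSet) else h
    if len(df) < 3:
        raise ValueError("leave_one_out needs >= 3 SNPs")
    rows = []
    for snp in df["snp_id"]:
        sub = df.loc[df["snp_id"] != snp]
        res = ivw(sub, effects_model=effects_model)
        rows.append(
            {
                "excluded_snp": snp,
                "method": res.method,
                "n_snps": res.n_snps,
                "beta": res.beta,
                "se": res.se,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "pval": res.pval,
            }
        )
    return pd.DataFrame(rows)
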