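"""Simulation experiments that characterize the estimators' operating behavior.

Each function runs a seeded Monte-Carlo experiment against the synthetic
generator's known truth and returns summary numbers (bias, coverage,
rejection and detection rates, recovered mediation proportion).  They back
both the statistical test suite and the reproduction script; problem sizes
are chosen so each experiment runs in seconds to a couple of minutes on one
core.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .estimators import EggerEstimator, MrResult, ivw, weighted_median
from .instruments import LdTable, filter_weak, ld_clump, select_by_pvalue, steiger_filter
from .sensitivity import mr_presso
from .simulate import SimParams, simulate_triplet, spike_outlier
from .sumstats import HarmonizedSet, SumstatsTable, harmonize


def harmonized_chain(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    ld: LdTable | None = None,
    p_threshold: float = 5e-5,
    f_min: float = 10.0,
    steiger: bool = True,
    window_kb: int = 10_000,
    r2_threshold: float = 0.001,
) -> HarmonizedSet | None:
    """Instrument selection + harmonization exactly as the screening pipeline runs it."""
    ld = ld if ld is not None else LdTable()
    sel = select_by_pvalue(exposure, p_threshold)
    if sel is None:
        return None
    clumped = ld_clump(sel, ld, window_kb, r2_threshold)
    strong = filter_weak(clumped, f_min)
    if strong is None:
        return None
    try:
        h = harmonize(strong, outcome)
    except ValueError:
        return None
    if steiger and len(h):
        h, _ = steiger_filter(h)
    return h if len(h) else None


def estimate_path(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    ld: LdTable | None = None,
    effects_model: str = "auto",
    presso_remove: bool = False,
    presso_sim: int = 1000,
    seed: int = 0,
    **chain_kwargs,
) -> MrResult | None:
    """IVW causal estimate through the full selection chain (None if no instruments).

    With ``presso_remove`` the simulation-based outlier test is run first and
    the estimate is the re-evaluation with flagged outliers excluded, as the
    full pipeline reports it.
    """
    h = harmonized_chain(exposure, outcome, ld, **chain_kwargs)
    if h is None:
        return None
    if presso_remove and len(h) >= 4:
        return mr_presso(
            h, n_sim=presso_sim, seed=seed, effects_model=effects_model
        ).result_after
    return ivw(h, effects_model=effects_model)


def ivw_recovery(n_reps: int = 200, seed: int = 0, params: SimParams | None = None) -> dict:
    """Bias and 95%-CI coverage of IVW under the no-pleiotropy generative model."""
    base = params if params is not None else SimParams()
    estimates, covered = [], 0
    used = 0
    for rep in range(n_reps):
        p = replace(base, seed=seed + rep)
        exposure, _, outcome, ld, truth = simulate_triplet(p)
        res = estimate_path(exposure, outcome, ld)
        if res is None:
            continue
        used += 1
        estimates.append(res.beta)
        if res.ci_low <= truth.c <= res.ci_high:
            covered += 1
    est = np.asarray(estimates)
    mc_se = float(est.std(ddof=1) / np.sqrt(len(est)))
    return {
        "true_c": base.c,
        "mean_estimate": float(est.mean()),
        "mc_se": mc_se,
        "abs_bias": float(abs(est.mean() - base.c)),
        "coverage_pct": 100.0 * covered / used,
        "n_reps": used,
    }


def egger_calibration(
    n_reps: int = 500,
    seed: int = 0,
    pleio_mean: float = 0.0,
    pleio_sd: float = 0.02,
    alpha: float = 0.05,
) -> dict:
    """Intercept-test rejection rate and intercept recovery under pleiotropy.

    With ``pleio_mean = 0`` (balanced pleiotropy) the rejection rate measures
    the intercept test's type-I error; with a nonzero mean it measures power
    and the intercept's bias against the known directional effect.

    Steiger filtering is deliberately left out of this chain: under
    horizontal pleiotropy it preferentially removes SNPs whose pleiotropic
    effect inflates the outcome association, which would distort the very
    intercept this experiment characterizes.
    """
    base = SimParams(
        pleio_frac=1.0, pleio_mean=pleio_mean, pleio_sd=pleio_sd,
        n_med_snps=0, n_out_snps=0,
    )
    rejected, intercepts = 0, []
    for rep in range(n_reps):
        p = replace(base, seed=seed + rep)
        exposure, _, outcome, ld, _ = simulate_triplet(p)
        h = harmonized_chain(exposure, outcome, ld, steiger=False)
        if h is None or len(h) < 3:
            continue
        est = EggerEstimator().fit(h)
        intercepts.append(est.intercept_)
        if est.intercept_pval_ < alpha:
            rejected += 1
    icpt = np.asarray(intercepts)
    return {
        "true_intercept": pleio_mean,
        "rejection_pct": 100.0 * rejected / len(icpt),
        "intercept_mean": float(icpt.mean()),
        "intercept_mc_se": float(icpt.std(ddof=1) / np.sqrt(len(icpt))),
        "n_reps": len(icpt),
    }


def contaminated_pairs(
    seed: int = 5,
    n_valid: int = 10,
    n_invalid: int = 4,
    theta_valid: float = 0.3,
    theta_invalid: float = 3.0,
    se_x: float = 0.05,
    se_y: float = 0.1,
) -> pd.DataFrame:
    """Harmonized-pair frame with a minority of pleiotropic instruments.

    Valid instruments follow ``beta_y = theta_valid * beta_x``; the invalid
    minority follows a far larger ratio, emulating unbalanced horizontal
    pleiotropy that the weighted median should resist and IVW should not.
    """
    rng = np.random.default_rng(seed)
    n = n_valid + n_invalid
    theta = np.r_[np.full(n_valid, theta_valid), np.full(n_invalid, theta_invalid)]
    bx = rng.normal(1.0, se_x, size=n)
    by = rng.normal(theta * bx, se_y)
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(n)],
            "beta_x": bx,
            "se_x": se_x,
            "beta_y": by,
            "se_y": se_y,
        }
    )


def weighted_median_breakdown(seed: int = 5, n_boot: int = 1000) -> dict:
    """Weighted median vs IVW on the minority-contaminated instrument set."""
    pairs = contaminated_pairs(seed=seed)
    wm = weighted_median(pairs, n_boot=n_boot, seed=seed)
    naive = ivw(pairs, effects_model="fixed")
    return {
        "true_theta": 0.3,
        "wm_estimate": wm.beta,
        "wm_se": wm.se,
        "wm_abs_error": abs(wm.beta - 0.3),
        "ivw_estimate": naive.beta,
        "ivw_abs_error": abs(naive.beta - 0.3),
    }


def presso_null(
    n_reps: int = 200, seed: int = 0, n_snps: int = 20, n_sim: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Global-test rejection rate when no SNP is pleiotropic."""
    base = SimParams(n_snps=n_snps, n_med_snps=0, n_out_snps=0)
    rejected, used = 0, 0
    for rep in range(n_reps):
        p = replace(base, seed=seed + rep)
        exposure, _, outcome, ld, _ = simulate_triplet(p)
        h = harmonized_chain(exposure, outcome, ld)
        if h is None or len(h) < 4:
            continue
        used += 1
        res = mr_presso(h, n_sim=n_sim, seed=seed + rep, alpha=alpha)
        if res.global_p < alpha:
            rejected += 1
    return {"rejection_pct": 100.0 * rejected / used, "n_reps": used}


def presso_spike(
    n_reps: int = 100, seed: int = 0, n_snps: int = 20, n_sim: int = 1000,
    shift_in_se: float = 10.0, alpha: float = 0.05,
) -> dict:
    """Detection rate for a single spiked-outlier SNP and the error reduction
    from refitting without the flagged outliers."""
    base = SimParams(n_snps=n_snps, n_med_snps=0, n_out_snps=0)
    detected, used = 0, 0
    err_before, err_after = [], []
    for rep in range(n_reps):
        p = replace(base, seed=seed + rep)
        exposure, _, outcome, ld, truth = simulate_triplet(p)
        per = truth.per_snp
        target = per.loc[per["gamma"].abs().idxmax(), "snp_id"]
        outcome = spike_outlier(outcome, target, shift_in_se)
        h = harmonized_chain(exposure, outcome, ld)
        if h is None or target not in set(h.df["snp_id"]):
            continue
        used += 1
        res = mr_presso(h, n_sim=n_sim, seed=seed + rep, alpha=alpha)
        if target in res.outliers:
            detected += 1
        err_before.append(abs(res.result_before.beta - truth.c))
        err_after.append(abs(res.result_after.beta - truth.c))
    return {
        "detection_pct": 100.0 * detected / used,
        "mean_abs_error_before": float(np.mean(err_before)),
        "mean_abs_error_after": float(np.mean(err_after)),
        "n_reps": used,
    }


def mediation_recovery(
    n_reps: int = 200, seed: int = 0, params: SimParams | None = None
) -> dict:
    """Recovered mediation percentage against the planted decomposition.

    Each path estimate is the pipeline's headline number: IVW after
    Steiger filtering and outlier re-evaluation.  The outlier step matters
    for the mediator->outcome leg, where instruments shared with the
    exposure act through the direct path and surface as pleiotropic
    outliers.
    """
    base = params if params is not None else SimParams()
    proportions = []
    for rep in range(n_reps):
        p = replace(base, seed=seed + rep)
        exposure, mediator, outcome, ld, truth = simulate_triplet(p)
        c_res = estimate_path(exposure, outcome, ld, presso_remove=True, seed=seed + rep)
        a_res = estimate_path(exposure, mediator, ld, presso_remove=True, seed=seed + rep)
        b_res = estimate_path(mediator, outcome, ld, presso_remove=True, seed=seed + rep)
        if c_res is None or a_res is None or b_res is None or c_res.beta == 0:
            continue
        proportions.append(100.0 * a_res.beta * b_res.beta / c_res.beta)
    prop = np.asarray(proportions)
    return {
        "true_proportion_pct": base.proportion_pct,
        "mean_proportion_pct": float(prop.mean()),
        "median_abs_proportion_pct": float(np.median(np.abs(prop))),
        "mc_se": float(prop.std(ddof=1) / np.sqrt(len(prop))),
        "n_reps": len(prop),
    }


def null_mediator_recovery(n_reps: int = 200, seed: int = 0) -> dict:
    """Estimated |proportion mediated| when the exposure does not move the mediator."""
    params = SimParams(a=0.0)
    out = mediation_recovery(n_reps=n_reps, seed=seed, params=params)
    out["true_proportion_pct"] = 0.0
    return out


def _clump_reference(df: pd.DataFrame, ld: LdTable, window_kb: int, r2_threshold: float):
    """Brute-force clumping reference: re-derives the survivor set from the
    definition by exhaustive scanning, independent of the production code."""
    window_bp = window_kb * 1000
    remaining = [
        (str(r.snp_id), str(r.chrom), int(r.pos_bp), float(r.pval))
        for r in df.itertuples(index=False)
    ]
    survivors = []
    while remaining:
        best = min(remaining, key=lambda r: (r[3], r[1], r[2], r[0]))
        survivors.append(best[0])
        pruned = []
        for r in remaining:
            if r[0] == best[0]:
                continue
            conflict = (
                r[1] == best[1]
                and abs(r[2] - best[2]) <= window_bp
                and ld.r2(r[0], best[0]) >= r2_threshold
            )
            if not conflict:
                pruned.append(r)
        remaining = pruned
    return sorted(survivors)


def random_clump_instance(rng) -> tuple[SumstatsTable, LdTable]:
    """A small random clumping problem: clustered positions, random LD."""
    n = int(rng.integers(2, 26))
    chrom = rng.choice(["1", "2"], size=n)
    pos = rng.integers(1, 30_000_000, size=n)
    pval = 10.0 ** (-rng.uniform(0.5, 8.0, size=n))
    snp_ids = np.array([f"s{i}" for i in range(n)])
    df = pd.DataFrame(
        {
            "snp_id": snp_ids, "chrom": chrom, "pos_bp": pos,
            "effect_allele": "A", "other_allele": "G",
            "eaf": 0.3, "beta": 0.1, "se": 0.01, "pval": pval, "n": 10_000.0,
        }
    )
    ld = LdTable()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                ld.add(snp_ids[i], snp_ids[j], float(rng.random()))
    return SumstatsTable("sim", "quantitative", df), ld


def clump_agreement(
    n_instances: int = 500, seed: int = 0, window_kb: int = 1000, r2_threshold: float = 0.1
) -> dict:
    """Fraction of random instances where greedy clumping matches brute force."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        table, ld = random_clump_instance(rng)
        got = sorted(ld_clump(table, ld, window_kb, r2_threshold).df["snp_id"])
        want = _clump_reference(table.df, ld, window_kb, r2_threshold)
        if got == want:
            agree += 1
    return {"agreement_pct": 100.0 * agree / n_instances, "n_instances": n_instances}


def steiger_direction_rate(seed: int = 7, n_snps: int = 50) -> dict:
    """Share of instruments labeled direction-TRUE when exposure drives outcome."""
    params = SimParams(n_snps=n_snps, n_med_snps=0, n_out_snps=0, seed=seed)
    exposure, _, outcome, ld, _ = simulate_triplet(params)
    h = harmonized_chain(exposure, outcome, ld, steiger=False)
    _, report = steiger_filter(h)
    rate = 100.0 * (report["direction"] == "TRUE").mean()
    return {"true_direction_pct": float(rate), "n_snps": len(report)}
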