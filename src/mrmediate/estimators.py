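"""Causal-effect estimators on harmonized summary statistics.

Each estimator is a scikit-learn-style class: construct with hyperparameters,
``fit`` on a :class:`~mrmediate.sumstats.HarmonizedSet` (or an equivalent
DataFrame of per-SNP exposure/outcome effect pairs), read fitted attributes
with a trailing underscore, or collect everything into an :class:`MrResult`.
Module-level functions :func:`ivw`, :func:`egger`, :func:`weighted_median`
are thin wrappers kept for pipeline and interactive use.

The per-SNP building block is the Wald ratio ``theta_j = beta_yj / beta_xj``
with first-order (delta-method) standard error ``se_yj / |beta_xj|``.  IVW is
the inverse-variance-weighted meta-analysis of the Wald ratios; MR-Egger is a
weighted regression of outcome on exposure effects with a free intercept (the
intercept estimating directional pleiotropy); the weighted median is
consistent when under half of the instrument weight comes from invalid
variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .sumstats import HarmonizedSet

Z975 = stats.norm.ppf(0.975)
P_FLOOR = 1e-300


@dataclass
class MrResult:
    """A causal estimate on the beta (log-odds / per-unit) and OR scales."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float
    or_low: float
    or_high: float
    n_snps: int
    exposure_id: str = ""
    outcome_id: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI does not bracket the estimate")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError("pval outside (0, 1]")


def _pairs_frame(h) -> pd.DataFrame:
    if isinstance(h, HarmonizedSet):
        return h.df
    if isinstance(h, pd.DataFrame):
        return h
    raise TypeError(f"expected HarmonizedSet or DataFrame, got {type(h).__name__}")


def _ids(h) -> tuple[str, str]:
    if isinstance(h, HarmonizedSet):
        return h.exposure_id, h.outcome_id
    return "", ""


def wald_arrays(h) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their first-order standard errors."""
    df = _pairs_frame(h)
    bx = df["beta_x"].to_numpy(float)
    if (bx == 0).any():
        raise ZeroDivisionError("beta_x = 0: Wald ratio undefined")
    by = df["beta_y"].to_numpy(float)
    se_y = df["se_y"].to_numpy(float)
    return by / bx, se_y / np.abs(bx)


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> tuple[float, float]:
    """Single-SNP causal estimate ``beta_y / beta_x`` with delta-method SE.

    ``se_x`` is accepted for interface symmetry; the first-order SE uses only
    the outcome-side uncertainty, ``se_y / |beta_x|``.
    """
    if beta_x == 0:
        raise ZeroDivisionError("beta_x = 0: Wald ratio undefined")
    return beta_y / beta_x, se_y / abs(beta_x)


def _two_sided_norm_p(z: float) -> float:
    return float(max(2.0 * stats.norm.sf(abs(z)), P_FLOOR))


def _finish(method, beta, se, pval, ci_low, ci_high, n_snps, h, extra) -> MrResult:
    exposure_id, outcome_id = _ids(h)
    or_, or_low, or_high = np.exp(beta), np.exp(ci_low), np.exp(ci_high)
    return MrResult(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        pval=float(pval),
        or_=float(or_),
        or_low=float(or_low),
        or_high=float(or_high),
        n_snps=int(n_snps),
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        extra=dict(extra),
    )


class _MrEstimator(BaseEstimator):
    """Shared fit plumbing for summary-data MR estimators."""

    _min_snps = 1

    def fit(self, X, y=None):
        """Fit on a HarmonizedSet / pair DataFrame. ``y`` is ignored."""
        df = _pairs_frame(X)
        if len(df) < self._min_snps:
            raise ValueError(
                f"{type(self).__name__} needs >= {self._min_snps} SNPs, got {len(df)}"
            )
        self.n_snps_ = len(df)
        self._fit(X, df)
        return self

    def predict(self, beta_x):
        """Predicted outcome-side effects for exposure effects ``beta_x``."""
        bx = np.asarray(beta_x, dtype=float)
        return getattr(self, "intercept_", 0.0) + self.beta_ * bx

    def to_result(self, h=None) -> MrResult:
        return _finish(
            self.method_,
            self.beta_,
            self.se_,
            self.pval_,
            self.ci_low_,
            self.ci_high_,
            self.n_snps_,
            h if h is not None else getattr(self, "_fitted_on", None),
            getattr(self, "extra_", {}),
        )


class IVWEstimator(_MrEstimator):
    """Inverse-variance-weighted meta-analysis of per-SNP Wald ratios.

    Parameters
    ----------
    effects_model : {"fixed", "random", "auto"}
        ``fixed`` uses SE = sqrt(1/sum w).  ``random`` is the multiplicative
        random-effects model: the fixed SE inflated by
        ``max(1, sqrt(Q/(J-1)))``.  ``auto`` (default) switches to random
        effects when Cochran's Q has p < 0.05.

    With a single SNP the estimate degenerates to the Wald ratio and the
    fitted ``method_`` is tagged ``"wald"``.
    """

    _min_snps = 1

    def __init__(self, effects_model: str = "auto"):
        self.effects_model = effects_model

    def _fit(self, h, df):
        if self.effects_model not in ("fixed", "random", "auto"):
            raise ValueError(f"unknown effects_model {self.effects_model!r}")
        self._fitted_on = h
        theta, se_theta = wald_arrays(df)
        j = len(theta)
        if j == 1:
            self.method_ = "wald"
            self.beta_ = float(theta[0])
            self.se_ = float(se_theta[0])
            self.q_, self.q_df_, self.q_pval_ = 0.0, 0, 1.0
            self.extra_ = {}
        else:
            w = 1.0 / se_theta**2
            beta = float(np.sum(w * theta) / np.sum(w))
            se_fixed = float(np.sqrt(1.0 / np.sum(w)))
            q = float(np.sum(w * (theta - beta) ** 2))
            q_df = j - 1
            q_pval = float(stats.chi2.sf(q, q_df))
            phi = max(1.0, np.sqrt(q / q_df))
            if self.effects_model == "fixed":
                se, method = se_fixed, "ivw_fe"
            elif self.effects_model == "random":
                se, method = se_fixed * phi, "ivw_re"
            else:
                if q_pval < 0.05:
                    se, method = se_fixed * phi, "ivw_re"
                else:
                    se, method = se_fixed, "ivw_fe"
            self.method_ = method
            self.beta_ = beta
            self.se_ = float(se)
            self.q_, self.q_df_, self.q_pval_ = q, q_df, q_pval
            self.extra_ = {"Q": q, "Q_df": q_df, "Q_pval": q_pval}
        self.pval_ = _two_sided_norm_p(self.beta_ / self.se_)
        self.ci_low_ = self.beta_ - Z975 * self.se_
        self.ci_high_ = self.beta_ + Z975 * self.se_


class EggerEstimator(_MrEstimator):
    """MR-Egger: weighted regression of beta_y on beta_x with a free intercept.

    Pairs are internally oriented so beta_x >= 0 (joint sign flip), the
    regression is weighted by 1/se_y^2, and inference for both slope (the
    causal estimate) and intercept (the directional-pleiotropy test) uses the
    t distribution with J - 2 degrees of freedom and the WLS-estimated
    residual scale.
    """

    _min_snps = 3

    def _fit(self, h, df):
        self._fitted_on = h
        sign = np.where(df["beta_x"].to_numpy(float) < 0, -1.0, 1.0)
        bx = sign * df["beta_x"].to_numpy(float)
        by = sign * df["beta_y"].to_numpy(float)
        w = 1.0 / df["se_y"].to_numpy(float) ** 2
        model = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
        j = len(bx)
        tcrit = stats.t.ppf(0.975, j - 2)
        self.method_ = "egger"
        self.beta_ = float(model.params[1])
        self.se_ = float(model.bse[1])
        self.pval_ = float(max(model.pvalues[1], P_FLOOR))
        self.ci_low_ = self.beta_ - tcrit * self.se_
        self.ci_high_ = self.beta_ + tcrit * self.se_
        self.intercept_ = float(model.params[0])
        self.intercept_se_ = float(model.bse[0])
        self.intercept_pval_ = float(max(model.pvalues[0], P_FLOOR))
        self.extra_ = {
            "intercept": self.intercept_,
            "intercept_se": self.intercept_se_,
            "intercept_pval": self.intercept_pval_,
            "df_resid": j - 2,
        }


class WeightedMedianEstimator(_MrEstimator):
    """Weighted median of per-SNP Wald ratios with parametric-bootstrap SE.

    The estimate interpolates the inverse-variance-weighted quantile function
    of the sorted ratios at probability 0.5; it is consistent when valid
    instruments carry more than half of the total weight.  The SE is the
    standard deviation of the estimate over ``n_boot`` parametric resamples
    (effects redrawn normal around their observed values with the observed
    SEs), driven by an explicit ``seed`` recorded in the result.
    """

    _min_snps = 3

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    @staticmethod
    def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
        order = np.argsort(theta, kind="stable")
        theta_s = theta[order]
        w_s = w[order] / w.sum()
        p = np.cumsum(w_s) - 0.5 * w_s
        return float(np.interp(0.5, p, theta_s))

    def _fit(self, h, df):
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        self._fitted_on = h
        theta, se_theta = wald_arrays(df)
        w = 1.0 / se_theta**2
        estimate = self._weighted_median(theta, w)

        bx = df["beta_x"].to_numpy(float)
        by = df["beta_y"].to_numpy(float)
        se_x = df["se_x"].to_numpy(float)
        se_y = df["se_y"].to_numpy(float)
        rng = np.random.default_rng(self.seed)
        bx_b = rng.normal(bx, se_x, size=(self.n_boot, len(bx)))
        by_b = rng.normal(by, se_y, size=(self.n_boot, len(bx)))
        bx_b[bx_b == 0] = np.finfo(float).tiny  # guard degenerate resamples
        theta_b = by_b / bx_b
        w_b = (bx_b / se_y) ** 2
        boots = np.empty(self.n_boot)
        for i in range(self.n_boot):
            boots[i] = self._weighted_median(theta_b[i], w_b[i])
        se = float(np.std(boots, ddof=1))

        self.method_ = "weighted_median"
        self.beta_ = estimate
        self.se_ = se
        self.pval_ = _two_sided_norm_p(estimate / se)
        self.ci_low_ = estimate - Z975 * se
        self.ci_high_ = estimate + Z975 * se
        self.extra_ = {"n_boot": self.n_boot, "bootstrap_seed": self.seed}


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float, float]:
    """Exponentiate a log-odds estimate: (OR, 95% low, 95% high, two-sided p)."""
    if se <= 0:
        raise ValueError("se must be > 0")
    or_ = float(np.exp(beta))
    or_low = float(np.exp(beta - Z975 * se))
    or_high = float(np.exp(beta + Z975 * se))
    return or_, or_low, or_high, _two_sided_norm_p(beta / se)


def ivw(h, effects_model: str = "auto") -> MrResult:
    """IVW causal estimate on a harmonized set (see :class:`IVWEstimator`)."""
    return IVWEstimator(effects_model=effects_model).fit(h).to_result(h)


def egger(h) -> MrResult:
    """MR-Egger slope + intercept test (see :class:`EggerEstimator`)."""
    return EggerEstimator().fit(h).to_result(h)


def weighted_median(h, n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Weighted-median estimate (see :class:`WeightedMedianEstimator`)."""
    return WeightedMedianEstimator(n_boot=n_boot, seed=seed).fit(h).to_result(h)
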