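"""Three-stage MR screen and mediation ledger orchestration.

Stage 1 screens every exposure against the outcome bidirectionally
(instrument selection -> LD clumping -> weak-instrument filter ->
harmonization -> Steiger filter -> pleiotropy/outlier audit with removal ->
estimation on the cleaned set -> heterogeneity diagnostics, then the same
chain with the roles swapped).  Stage 2 repeats the screen for
candidate mediators.  Stage 3 links significant exposures to significant
mediators, estimates the exposure->mediator path, applies the mediator
eligibility gate and emits the mediation ledger.

Failures (no surviving instruments, estimator preconditions not met) degrade
to flagged rows rather than aborting a batch screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .estimators import MrResult, egger, ivw, weighted_median
from .instruments import (
    LdTable,
    filter_weak,
    ld_clump,
    select_by_pvalue,
    steiger_filter,
)
from .mediation import two_step_mediation
from .sensitivity import funnel_points, leave_one_out, mr_presso
from .sumstats import SumstatsTable, harmonize, read_sumstats

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_NO_INSTRUMENTS = "no_instruments"
STATUS_ERROR = "error"


@dataclass
class DatasetSpec:
    """One summary-statistics input: path, trait type, identifier."""

    path: str
    trait_type: str = "quantitative"
    id: str | None = None
    column_map: dict | None = None

    def load(self, base: Path | None = None) -> SumstatsTable:
        p = Path(self.path)
        if base is not None and not p.is_absolute():
            p = base / p
        return read_sumstats(
            p, column_map=self.column_map, trait_type=self.trait_type, trait_id=self.id
        )


@dataclass
class ScreenConfig:
    """All thresholds and knobs of the screening pipeline.

    Defaults follow the reference analysis settings: instrument p-value
    threshold 5e-5, clumping window 10 000 kb at r^2 < 0.001, F >= 10,
    significance alpha 0.05, automatic fixed/random-effects IVW, and raw
    (uncorrected) screen p-values; ``fdr=True`` switches the screen to
    Benjamini-Hochberg-adjusted significance calls.
    """

    p_instrument: float = 5e-5
    clump_window_kb: int = 10_000
    clump_r2: float = 0.001
    f_min: float = 10.0
    alpha: float = 0.05
    effects_model: str = "auto"
    n_boot: int = 1000
    presso_sim: int = 5000
    seed: int = 0
    steiger: bool = True
    fdr: bool = False
    exposures: list[DatasetSpec] = field(default_factory=list)
    mediators: list[DatasetSpec] = field(default_factory=list)
    outcome: DatasetSpec | None = None
    ld: str | None = None
    base_dir: Path | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_instrument <= 1.0:
            raise ValueError("p_instrument must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.clump_window_kb < 0 or not 0.0 <= self.clump_r2 <= 1.0:
            raise ValueError("invalid clumping parameters")
        if self.f_min < 0:
            raise ValueError("f_min must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        for key in ("exposures", "mediators"):
            raw[key] = [DatasetSpec(**d) for d in raw.get(key, [])]
        if raw.get("outcome") is not None:
            raw["outcome"] = DatasetSpec(**raw["outcome"])
        cfg = cls(**raw)
        cfg.base_dir = path.parent
        return cfg

    def load_ld(self) -> LdTable:
        if self.ld is None:
            return LdTable()
        p = Path(self.ld)
        if self.base_dir is not None and not p.is_absolute():
            p = self.base_dir / p
        return LdTable.from_tsv(p)


_NA = float("nan")

ROW_FIELDS = [
    "exposure", "outcome", "direction", "status",
    "n_selected", "n_clumped", "n_strong", "n_pairs",
    "n_dropped_palindromic", "n_dropped_incompatible", "n_steiger_removed",
    "ivw_method", "ivw_beta", "ivw_se", "ivw_ci_low", "ivw_ci_high", "ivw_pval",
    "ivw_or", "ivw_or_low", "ivw_or_high",
    "egger_beta", "egger_se", "egger_pval",
    "egger_intercept", "egger_intercept_se", "egger_intercept_pval",
    "wm_beta", "wm_se", "wm_pval",
    "q", "q_df", "q_pval",
    "presso_global_p", "presso_outliers", "n_snps_after_presso",
    "significant",
]


def _blank_row(exposure_id, outcome_id, direction, status) -> dict:
    row = {k: _NA for k in ROW_FIELDS}
    row.update(
        exposure=exposure_id,
        outcome=outcome_id,
        direction=direction,
        status=status,
        significant=False,
        presso_outliers="",
    )
    return row


def _single_direction(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    ld: LdTable,
    cfg: ScreenConfig,
    direction: str,
):
    """Run the full estimation chain in one direction.

    Returns ``(row, artifacts)`` where ``row`` is a flat dict (one screen
    line) and ``artifacts`` carries the in-memory objects (harmonized set,
    MrResults) for downstream reuse.  Never raises for empty instrument
    sets; those come back flagged.
    """
    row = _blank_row(exposure.trait_id, outcome.trait_id, direction, STATUS_NO_INSTRUMENTS)
    artifacts: dict = {"harmonized": None, "ivw": None}

    sel = select_by_pvalue(exposure, cfg.p_instrument)
    if sel is None:
        return row, artifacts
    row["n_selected"] = len(sel)
    clumped = ld_clump(sel, ld, cfg.clump_window_kb, cfg.clump_r2)
    row["n_clumped"] = len(clumped)
    strong = filter_weak(clumped, cfg.f_min)
    if strong is None:
        return row, artifacts
    row["n_strong"] = len(strong)
    try:
        h = harmonize(strong, outcome)
    except ValueError:
        return row, artifacts
    row["n_dropped_palindromic"] = h.n_dropped_palindromic
    row["n_dropped_incompatible"] = h.n_dropped_incompatible
    if len(h) == 0:
        return row, artifacts
    if cfg.steiger:
        before = len(h)
        h, steiger_report = steiger_filter(h)
        row["n_steiger_removed"] = before - len(h)
        artifacts["steiger_report"] = steiger_report
    if len(h) == 0:
        return row, artifacts

    row["status"] = STATUS_OK
    row["n_pairs"] = len(h)

    # pleiotropy/outlier audit first: flagged SNPs are removed and every
    # reported estimate is the re-evaluation on the cleaned instrument set
    if len(h) >= 4:
        presso = mr_presso(
            h, n_sim=cfg.presso_sim, seed=cfg.seed, alpha=cfg.alpha,
            effects_model=cfg.effects_model,
        )
        artifacts["presso"] = presso
        row.update(
            presso_global_p=presso.global_p,
            presso_outliers=",".join(presso.outliers),
            n_snps_after_presso=presso.result_after.n_snps,
        )
        if presso.outliers and len(h) - len(presso.outliers) >= 1:
            h = h.drop(presso.outliers)
    artifacts["harmonized"] = h

    res = ivw(h, effects_model=cfg.effects_model)
    artifacts["ivw"] = res
    row.update(
        ivw_method=res.method, ivw_beta=res.beta, ivw_se=res.se,
        ivw_ci_low=res.ci_low, ivw_ci_high=res.ci_high, ivw_pval=res.pval,
        ivw_or=res.or_, ivw_or_low=res.or_low, ivw_or_high=res.or_high,
        significant=bool(res.pval < cfg.alpha),
    )
    if "Q" in res.extra:
        row.update(q=res.extra["Q"], q_df=res.extra["Q_df"], q_pval=res.extra["Q_pval"])
    if len(h) >= 3:
        eg = egger(h)
        artifacts["egger"] = eg
        row.update(
            egger_beta=eg.beta, egger_se=eg.se, egger_pval=eg.pval,
            egger_intercept=eg.extra["intercept"],
            egger_intercept_se=eg.extra["intercept_se"],
            egger_intercept_pval=eg.extra["intercept_pval"],
        )
        wm = weighted_median(h, n_boot=cfg.n_boot, seed=cfg.seed)
        artifacts["weighted_median"] = wm
        row.update(wm_beta=wm.beta, wm_se=wm.se, wm_pval=wm.pval)
    logger.info(
        "%s -> %s [%s]: selected=%s clumped=%s strong=%s pairs=%s status=%s",
        exposure.trait_id, outcome.trait_id, direction,
        row["n_selected"], row["n_clumped"], row["n_strong"], row["n_pairs"],
        row["status"],
    )
    return row, artifacts


def run_bidirectional(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    cfg: ScreenConfig,
    ld: LdTable | None = None,
):
    """Forward (exposure->outcome) and reverse (outcome->exposure) screen rows.

    The reverse direction re-selects instruments from the outcome trait.
    """
    ld = ld if ld is not None else LdTable()
    fwd, fwd_art = _single_direction(exposure, outcome, ld, cfg, "forward")
    rev, rev_art = _single_direction(outcome, exposure, ld, cfg, "reverse")
    return (fwd, rev), (fwd_art, rev_art)


def run_screen(
    exposures: list[SumstatsTable],
    outcome: SumstatsTable,
    cfg: ScreenConfig,
    ld: LdTable | None = None,
) -> pd.DataFrame:
    """One forward + one reverse row per exposure; failures become flagged rows."""
    if not exposures:
        raise ValueError("empty exposure list")
    rows = []
    for exposure in exposures:
        try:
            (fwd, rev), _ = run_bidirectional(exposure, outcome, cfg, ld)
            rows.extend([fwd, rev])
        except Exception:  # pragma: no cover - batch robustness
            logger.exception("screen failed for %s", exposure.trait_id)
            rows.append(
                _blank_row(exposure.trait_id, outcome.trait_id, "forward", STATUS_ERROR)
            )
            rows.append(
                _blank_row(outcome.trait_id, exposure.trait_id, "reverse", STATUS_ERROR)
            )
    out = pd.DataFrame(rows, columns=ROW_FIELDS)
    if cfg.fdr:
        from statsmodels.stats.multitest import multipletests

        fwd_mask = (out["direction"] == "forward") & (out["status"] == STATUS_OK)
        if fwd_mask.any():
            rej, *_ = multipletests(
                out.loc[fwd_mask, "ivw_pval"].to_numpy(), alpha=cfg.alpha, method="fdr_bh"
            )
            out.loc[fwd_mask, "significant"] = rej
    return out


LEDGER_FIELDS = [
    "exposure", "mediator", "outcome",
    "a", "a_p", "b", "b_p", "c", "c_p",
    "indirect", "c_prime", "proportion_pct",
    "eligible", "reason",
    "reverse_beta", "reverse_p",
    "scale",
]


def build_mediation_ledger(
    sig_exposures: list[SumstatsTable],
    candidate_mediators: list[SumstatsTable],
    outcome: SumstatsTable,
    cfg: ScreenConfig,
    ld: LdTable | None = None,
) -> pd.DataFrame:
    """Two-step mediation ledger over all (exposure, mediator) pairs.

    For each pair: ``a`` re-estimates exposure->mediator with the exposure's
    instruments, ``b`` (mediator->outcome) and ``c`` (exposure->outcome) are
    estimated once per trait with their own instruments, and the reverse MR
    mediator->exposure is run and reported alongside.  Eligibility is
    decided by the significance/sign-consistency gate; the proportion
    mediated is computed on the estimation scale (log-odds for a binary
    outcome), which is recorded in the ``scale`` column.
    """
    ld = ld if ld is not None else LdTable()
    scale = "log_odds" if outcome.trait_type == "binary" else "sd_units"

    c_results: dict[str, MrResult | None] = {}
    for exposure in sig_exposures:
        _, art = _single_direction(exposure, outcome, ld, cfg, "forward")
        c_results[exposure.trait_id] = art["ivw"]
    b_results: dict[str, MrResult | None] = {}
    for mediator in candidate_mediators:
        _, art = _single_direction(mediator, outcome, ld, cfg, "forward")
        b_results[mediator.trait_id] = art["ivw"]

    rows = []
    for exposure in sig_exposures:
        c_res = c_results[exposure.trait_id]
        for mediator in candidate_mediators:
            b_res = b_results[mediator.trait_id]
            _, a_art = _single_direction(exposure, mediator, ld, cfg, "forward")
            a_res = a_art["ivw"]
            rev_row, rev_art = _single_direction(mediator, exposure, ld, cfg, "reverse")
            rev = rev_art["ivw"]
            if a_res is None or b_res is None or c_res is None or c_res.beta == 0:
                rows.append(
                    {
                        "exposure": exposure.trait_id,
                        "mediator": mediator.trait_id,
                        "outcome": outcome.trait_id,
                        "a": a_res.beta if a_res else _NA,
                        "a_p": a_res.pval if a_res else _NA,
                        "b": b_res.beta if b_res else _NA,
                        "b_p": b_res.pval if b_res else _NA,
                        "c": c_res.beta if c_res else _NA,
                        "c_p": c_res.pval if c_res else _NA,
                        "indirect": _NA, "c_prime": _NA, "proportion_pct": _NA,
                        "eligible": False, "reason": "estimation failed",
                        "reverse_beta": rev.beta if rev else _NA,
                        "reverse_p": rev.pval if rev else _NA,
                        "scale": scale,
                    }
                )
                continue
            med = two_step_mediation(
                a_res, b_res, c_res, alpha=cfg.alpha,
                exposure_id=exposure.trait_id,
                mediator_id=mediator.trait_id,
                outcome_id=outcome.trait_id,
            )
            rows.append(
                {
                    "exposure": med.exposure_id,
                    "mediator": med.mediator_id,
                    "outcome": med.outcome_id,
                    "a": med.a, "a_p": med.a_pval,
                    "b": med.b, "b_p": med.b_pval,
                    "c": med.c, "c_p": med.c_pval,
                    "indirect": med.indirect,
                    "c_prime": med.c_prime,
                    "proportion_pct": med.proportion_pct,
                    "eligible": med.eligible,
                    "reason": med.reason,
                    "reverse_beta": rev.beta if rev else _NA,
                    "reverse_p": rev.pval if rev else _NA,
                    "scale": scale,
                }
            )
    return pd.DataFrame(rows, columns=LEDGER_FIELDS)


def report_tables(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    cfg: ScreenConfig,
    ld: LdTable | None = None,
) -> dict[str, pd.DataFrame]:
    """Funnel and leave-one-out point tables for one exposure/outcome pair."""
    ld = ld if ld is not None else LdTable()
    _, art = _single_direction(exposure, outcome, ld, cfg, "forward")
    h = art["harmonized"]
    if h is None:
        return {}
    out = {"funnel": funnel_points(h)}
    if len(h) >= 3:
        out["leave_one_out"] = leave_one_out(h, effects_model=cfg.effects_model)
    if "steiger_report" in art:
        out["steiger"] = art["steiger_report"]
    return out
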