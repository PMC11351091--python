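"""Two-step MR mediation: decomposition of a total causal effect.

The total exposure->outcome effect ``c`` is decomposed into the direct
effect ``c' = c - a*b`` and the mediator-carried indirect effect ``a*b``,
where ``a`` is the exposure->mediator and ``b`` the mediator->outcome causal
estimate (each from univariable two-sample MR with its own instruments).
The proportion mediated is ``100 * a*b / c``.  A mediator is only declared
eligible when all three paths are significant and the indirect effect has
the same sign as the total effect — a mediator pushing the outcome the
opposite way cannot explain the total effect it is meant to carry.
"""

from __future__ import annotations

from dataclasses import dataclass

from .estimators import MrResult

GATE_OK = "eligible"


@dataclass
class MediationResult:
    """Effect decomposition for one exposure -> mediator -> outcome triplet."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    a: float
    b: float
    c: float
    indirect: float
    c_prime: float
    proportion_pct: float
    eligible: bool
    reason: str
    a_pval: float = float("nan")
    b_pval: float = float("nan")
    c_pval: float = float("nan")


def mediator_gate(
    a_res: MrResult, b_res: MrResult, c_res: MrResult, alpha: float = 0.05
) -> tuple[bool, str]:
    """Significance and sign-consistency gate for mediator eligibility.

    Eligible iff all of exposure->mediator (a), mediator->outcome (b) and
    exposure->outcome (c) are significant at ``alpha`` and
    ``sign(a*b) == sign(c)``.  The reason names the first failed condition.
    """
    if not a_res.pval < alpha:
        return False, "exposure→mediator not significant"
    if not b_res.pval < alpha:
        return False, "mediator→outcome not significant"
    if not c_res.pval < alpha:
        return False, "exposure→outcome not significant"
    indirect = a_res.beta * b_res.beta
    if indirect * c_res.beta <= 0:
        return False, "indirect sign opposes total effect"
    return True, GATE_OK


def two_step_mediation(
    a_res: MrResult,
    b_res: MrResult,
    c_res: MrResult,
    alpha: float = 0.05,
    exposure_id: str = "",
    mediator_id: str = "",
    outcome_id: str = "",
) -> MediationResult:
    """Decompose the total effect and compute the mediation percentage.

    All three inputs should come from the same estimator family (IVW by
    default in the pipeline).  The direct effect is derived as
    ``c' = c - a*b`` rather than estimated separately, so the decomposition
    identity ``c = c' + a*b`` holds exactly by construction.

    Raises
    ------
    ValueError
        If ``c_res.beta == 0`` (proportion undefined).
    """
    if c_res.beta == 0:
        raise ValueError("total effect c = 0: proportion mediated undefined")
    a, b, c = a_res.beta, b_res.beta, c_res.beta
    indirect = a * b
    eligible, reason = mediator_gate(a_res, b_res, c_res, alpha=alpha)
    return MediationResult(
        exposure_id=exposure_id or a_res.exposure_id,
        mediator_id=mediator_id or a_res.outcome_id,
        outcome_id=outcome_id or c_res.outcome_id,
        a=a,
        b=b,
        c=c,
        indirect=indirect,
        c_prime=c - indirect,
        proportion_pct=100.0 * indirect / c,
        eligible=eligible,
        reason=reason,
        a_pval=a_res.pval,
        b_pval=b_res.pval,
        c_pval=c_res.pval,
    )
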