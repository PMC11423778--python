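"""Two-step mediation: effect decomposition, Delta-method inference,
mediated proportion, and the screening/robustness rule sets.

The decomposition follows the product-of-coefficients convention: with β1
the exposure→mediator effect, β2 the mediator→outcome effect and β3 the
total exposure→outcome effect (all on the log-odds scale for a binary
outcome), the indirect effect is β1·β2, its SE comes from the first-order
Delta method, the direct effect is β3 − β1·β2, and the mediated proportion
is (β1·β2)/β3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonization import harmonize
from .iv_selection import select_instruments
from .mr_estimators import MRResult, ivw

__all__ = [
    "MediationResult",
    "MediatorScreen",
    "delta_indirect",
    "mediated_proportion",
    "screen_mediator",
    "classify_causal",
    "two_step_pipeline",
]


@dataclass
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta3: float
    se3: float
    indirect: float
    indirect_se: float
    indirect_pval: float
    proportion: float
    direct: float
    consistent: bool = True
    incomplete: str | None = None


@dataclass
class MediatorScreen:
    """The four candidate-mediator inclusion criteria.

    1. the mediator is causally associated with the outcome (FDR-significant);
    2. that effect survives adjustment for the exposure (MVMR p < 0.05);
    3. the exposure causally affects the mediator but not vice versa;
    4. the two legs of the indirect path point the same way as the total effect.
    """

    mediator_on_outcome: bool | None = None
    independent_of_exposure: bool | None = None
    exposure_to_mediator_only: bool | None = None
    signs_consistent: bool | None = None
    reasons: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        crits = (self.mediator_on_outcome, self.independent_of_exposure,
                 self.exposure_to_mediator_only, self.signs_consistent)
        return all(c is True for c in crits)


def delta_indirect(beta1: float, se1: float, beta2: float, se2: float) -> tuple:
    """Indirect effect β1·β2 with first-order Delta-method SE and normal p.

    SE = √(β1²·se2² + β2²·se1²).
    """
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    indirect = beta1 * beta2
    se = np.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)
    if se == 0:
        p = 0.0 if indirect != 0 else 1.0
    else:
        p = float(2 * stats.norm.sf(abs(indirect / se)))
    return float(indirect), float(se), p


def mediated_proportion(indirect: float, total=None, total_or=None) -> float:
    """Proportion of the total effect running through the mediator.

    ``total`` is the total effect on the log-odds scale; alternatively pass
    ``total_or`` (an odds ratio), which is log-converted first. Raises when
    the total effect is zero; an indirect effect opposing the total effect
    ("inconsistent mediation") raises too, since a signed proportion has no
    interpretation as a contribution share.
    """
    if (total is None) == (total_or is None):
        raise ValueError("pass exactly one of total (log-odds) or total_or (odds ratio)")
    if total_or is not None:
        if total_or <= 0:
            raise ValueError("odds ratio must be positive")
        total = float(np.log(total_or))
    if total == 0:
        raise ZeroDivisionError("total effect is zero; proportion undefined")
    prop = indirect / total
    if prop < 0:
        raise ValueError("inconsistent mediation: indirect and total effects have opposite signs")
    return float(prop)


def screen_mediator(
    mediator_on_outcome: MRResult | None,
    mediator_on_outcome_adjusted: MRResult | None,
    exposure_on_mediator: MRResult | None,
    mediator_on_exposure: MRResult | None,
    total_effect: MRResult | None = None,
    alpha: float = 0.05,
    fdr_alpha: float = 0.05,
) -> MediatorScreen:
    """Evaluate the four mediator-inclusion criteria from a results bundle.

    Missing components mark their criterion "not evaluable" (None), which
    fails the overall screen.
    """
    s = MediatorScreen()
    if mediator_on_outcome is not None:
        q = mediator_on_outcome.fdr_q
        sig = (q is not None and q < fdr_alpha) or (
            q is None and mediator_on_outcome.pval < alpha)
        s.mediator_on_outcome = bool(sig)
        if q is None:
            s.reasons["criterion1"] = "no FDR q available; raw p used"
    else:
        s.reasons["criterion1"] = "not evaluable: mediator→outcome MR missing"
    if mediator_on_outcome_adjusted is not None:
        s.independent_of_exposure = bool(mediator_on_outcome_adjusted.pval < alpha)
    else:
        s.reasons["criterion2"] = "not evaluable: MVMR-adjusted result missing"
    if exposure_on_mediator is not None and mediator_on_exposure is not None:
        s.exposure_to_mediator_only = bool(
            exposure_on_mediator.pval < alpha and mediator_on_exposure.pval >= alpha
        )
    else:
        s.reasons["criterion3"] = "not evaluable: forward or reverse MR missing"
    if exposure_on_mediator is not None and mediator_on_outcome is not None:
        b1, b2 = exposure_on_mediator.beta, mediator_on_outcome.beta
        ok = np.sign(b1 * b2) != 0
        if total_effect is not None and np.isfinite(total_effect.beta):
            ok = ok and np.sign(b1 * b2) == np.sign(total_effect.beta)
        s.signs_consistent = bool(ok)
    else:
        s.reasons["criterion4"] = "not evaluable: component betas missing"
    return s


def classify_causal(battery: list, report, fdr_alpha: float = 0.05) -> dict:
    """The four robustness criteria for calling an exposure a causal candidate.

    (1) primary IVW significant after FDR; (2) all five methods agree in
    direction; (3) no heterogeneity or pleiotropy signal (Cochran Q,
    Egger intercept, PRESSO global all p ≥ 0.05); (4) no single influential
    instrument in leave-one-out.
    """
    by_method = {r.method: r for r in battery}
    ivw_res = by_method.get("ivw")
    c1 = None
    if ivw_res is not None:
        q = ivw_res.fdr_q if ivw_res.fdr_q is not None else ivw_res.pval
        c1 = bool(q < fdr_alpha)
    betas = [r.beta for r in battery if np.isfinite(r.beta)]
    c2 = bool(betas and (all(b > 0 for b in betas) or all(b < 0 for b in betas)))
    checks = [report.q_pval, report.intercept_pval, report.presso_global_pval]
    c3 = all(p is None or p >= 0.05 for p in checks) and any(p is not None for p in checks)
    c4 = len(report.loo_influential) == 0
    verdict = bool(c1 and c2 and c3 and c4)
    return {
        "fdr_significant": c1,
        "directions_agree": c2,
        "no_heterogeneity_or_pleiotropy": bool(c3),
        "no_influential_snp": bool(c4),
        "robust_causal_candidate": verdict,
    }


def two_step_pipeline(
    exposure,
    mediator,
    outcome,
    ld=None,
    blocklist=None,
    pval_threshold: float = 1e-5,
    **select_kwargs,
) -> MediationResult:
    """Full two-step mediation on three summary-statistic tables.

    β3 comes from exposure→outcome IVW on the exposure's instruments, β1 from
    exposure→mediator IVW on the same instruments, and β2 from
    mediator→outcome IVW on the mediator's own instruments — each leg runs
    instrument selection independently.
    """
    def _leg(exp_table, out_table):
        iv = select_instruments(exp_table, ld=ld, blocklist=blocklist,
                                pval_threshold=pval_threshold, **select_kwargs)
        if iv is None:
            return None
        hs = harmonize(iv, out_table)
        if hs.n_retained < 2:
            return None
        return ivw(hs)

    legs = {
        "exposure->outcome": _leg(exposure, outcome),
        "exposure->mediator": _leg(exposure, mediator),
        "mediator->outcome": _leg(mediator, outcome),
    }
    failed = [name for name, r in legs.items() if r is None]
    if failed:
        return MediationResult(
            exposure.trait_id, mediator.trait_id, outcome.trait_id,
            *[float("nan")] * 11, consistent=False,
            incomplete=f"unanalyzable leg(s): {', '.join(failed)}",
        )
    total = legs["exposure->outcome"]
    step1 = legs["exposure->mediator"]
    step2 = legs["mediator->outcome"]
    indirect, ise, ip = delta_indirect(step1.beta, step1.se, step2.beta, step2.se)
    try:
        prop = mediated_proportion(indirect, total=total.beta)
        consistent = True
    except (ValueError, ZeroDivisionError):
        prop = float("nan")
        consistent = False
    return MediationResult(
        exposure.trait_id, mediator.trait_id, outcome.trait_id,
        step1.beta, step1.se, step2.beta, step2.se, total.beta, total.se,
        indirect, ise, ip, prop, total.beta - indirect, consistent=consistent,
    )
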