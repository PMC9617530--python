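"""Primary-care triage stage.

Standard care refers every presenting patient to the clinic immediately.
Under the risk-test arm the test classifies patients as low or high risk
(sensitivity 0.98 / specificity 0.20 by default); GPs refer high-risk
results immediately, overrule a configurable fraction of low-risk
results, and the remaining low-risk patients either return with
persisting symptoms after six weeks (a delayed referral) or never enter
secondary care.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MIN_PER_DAY, PINPOINT, STANDARD_CARE, ConfigError, TriageConfig
from .population import Patient


def apply_test(has_cancer: np.ndarray, config: TriageConfig,
               rng: np.random.Generator) -> np.ndarray:
    """Risk-test result per patient: True = high risk.

    Cancer patients test high with probability ``sensitivity``;
    non-cancer patients test low with probability ``specificity``.
    Only meaningful under the test arm.
    """
    if config.arm != PINPOINT:
        raise ConfigError("apply_test called under standard care")
    config.validate()
    u = rng.random(len(has_cancer))
    return np.where(has_cancer, u < config.sensitivity, u >= config.specificity)


def decide_referral(high_risk: np.ndarray, has_cancer: np.ndarray,
                    config: TriageConfig, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Referral decision per patient.

    Returns ``(kind, delay_minutes)`` where kind is 0 = immediate,
    1 = delayed, 2 = none.  Standard care: everyone immediate.  Test arm:
    high risk → immediate; low risk → GP override (immediate) first, then
    the stratum's delayed-return draw, else no referral.
    """
    config.validate()
    n = len(has_cancer)
    kind = np.zeros(n, dtype=np.int8)
    delay = np.zeros(n, dtype=float)
    if config.arm == STANDARD_CARE:
        return kind, delay

    low = ~np.asarray(high_risk, dtype=bool)
    override = low & (rng.random(n) < config.gp_override_probability)
    remaining = low & ~override
    p_return = np.where(has_cancer,
                        config.delayed_return_probability_cancer,
                        config.delayed_return_probability_noncancer)
    returns = remaining & (rng.random(n) < p_return)
    kind[returns] = 1
    delay[returns] = config.delay_weeks * 7 * MIN_PER_DAY
    kind[remaining & ~returns] = 2
    return kind, delay


@dataclass(frozen=True)
class ReferralFractions:
    """Closed-form expected referral fractions (analytic oracle)."""

    overall_referred: float
    cancer_referred: float
    noncancer_referred: float
    cancer_delayed_among_referred: float
    noncancer_delayed_among_referred: float


def referral_fraction_closed_form(config: TriageConfig,
                                  prevalence: float) -> ReferralFractions:
    """Expected referral fractions implied by the triage parameters.

    With sensitivity *se*, specificity *sp*, override *ov* and
    delayed-return probabilities *d_c*, *d_nc*::

        cancer referred     = se + (1-se)·ov + (1-se)·(1-ov)·d_c
        non-cancer referred = (1-sp) + sp·ov + sp·(1-ov)·d_nc

    and the overall fraction is the prevalence-weighted mix.  Standard
    care refers everyone immediately.
    """
    config.validate()
    if not 0.0 <= prevalence <= 1.0:
        raise ConfigError(f"prevalence must lie in [0, 1], got {prevalence}")
    if config.arm == STANDARD_CARE:
        return ReferralFractions(1.0, 1.0, 1.0, 0.0, 0.0)
    se, sp = config.sensitivity, config.specificity
    ov = config.gp_override_probability
    d_c = config.delayed_return_probability_cancer
    d_nc = config.delayed_return_probability_noncancer
    c_imm = se + (1 - se) * ov
    c_del = (1 - se) * (1 - ov) * d_c
    nc_imm = (1 - sp) + sp * ov
    nc_del = sp * (1 - ov) * d_nc
    c_ref = c_imm + c_del
    nc_ref = nc_imm + nc_del
    return ReferralFractions(
        overall_referred=prevalence * c_ref + (1 - prevalence) * nc_ref,
        cancer_referred=c_ref,
        noncancer_referred=nc_ref,
        cancer_delayed_among_referred=c_del / c_ref if c_ref else 0.0,
        noncancer_delayed_among_referred=nc_del / nc_ref if nc_ref else 0.0,
    )


def triage_population(patients: list[Patient], config: TriageConfig,
                      rng: np.random.Generator) -> None:
    """Apply the triage stage in place to a sampled population.

    Sets risk_result, referral_kind and referral_time on every patient.
    Immediate referrals happen at presentation (plus test turnaround);
    delayed referrals exactly ``delay_weeks`` later; never-referred
    patients exit the pathway at presentation.
    """
    config.validate()
    n = len(patients)
    cancer = np.fromiter((p.has_cancer for p in patients), dtype=bool, count=n)
    if config.arm == PINPOINT:
        high = apply_test(cancer, config, rng)
    else:
        high = np.zeros(n, dtype=bool)
    kind, delay = decide_referral(high, cancer, config, rng)
    kinds = ("immediate", "delayed", "none")
    for i, p in enumerate(patients):
        p.risk_result = ("high" if high[i] else "low") if config.arm == PINPOINT \
            else "not_tested"
        p.referral_kind = kinds[kind[i]]
        if kind[i] == 2:
            p.referral_time = None
            p.exit_type = "no_referral"
            p.completion_time = p.gp_arrival_time
        else:
            p.referral_time = (p.gp_arrival_time + config.turnaround_minutes
                               + delay[i])
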