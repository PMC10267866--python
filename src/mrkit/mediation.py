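"""Two-step MR mediation decomposition.

The total causal effect β1 of an exposure on an outcome (log-odds scale) is
decomposed through a mediator using two auxiliary MR estimates: β2, the
effect of the exposure on the mediator, and β3, the effect of the mediator
on the outcome (each a univariable MR with its own instruments).  Then

* mediation (indirect) effect = β2·β3,
* direct effect = β1 − β2·β3,
* proportion mediated = β2·β3 / β1,

so that on the log scale direct + mediation = total holds exactly, and on
the OR scale OR_total = OR_direct · OR_mediation.  The mediator→outcome
leg is deliberately univariable (not exposure-adjusted): the decomposition
is the classic product-of-coefficients two-step form, valid when the
mediator does not cause the exposure.

``PUBLISHED_*`` tables hold the inverse-variance-weighted odds ratios
reported by the motivating genome-wide study of irritability and
cardiovascular-disease risk; they serve as worked-example inputs for the
decomposition arithmetic (the raw GWAS datasets behind them are not
bundled).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .errors import AnalysisError
from .instruments import SelectionConfig
from .pipeline import RunConfig, run_mr
from .summary_io import SummaryDataset

logger = logging.getLogger(__name__)

#: total-effect ORs (exposure = irritability) by outcome abbreviation
PUBLISHED_TOTAL_OR = {
    "CAD": 2.989,   # coronary artery disease
    "CA": 5.989,    # coronary angioplasty
    "NIC": 5.186,   # non-ischemic cardiomyopathy
    "HF": 2.253,    # heart failure
    "ISla": 14.326, # large-artery atherosclerosis ischemic stroke
    "HHD": 8.203,   # hypertensive heart disease
}

#: exposure→mediator IVW ORs
PUBLISHED_EXPOSURE_MEDIATOR_OR = {
    "smoking": 1.919,
    "insomnia": 4.324,
    "depressed_affect": 3.327,
}

#: mediator→outcome IVW ORs, keyed (mediator, outcome)
PUBLISHED_MEDIATOR_OUTCOME_OR = {
    ("smoking", "CAD"): 1.218,
    ("smoking", "CA"): 1.443,
    ("smoking", "NIC"): 1.164,
    ("smoking", "HF"): 1.197,
    ("smoking", "ISla"): 1.302,
    ("insomnia", "CAD"): 1.082,
    ("insomnia", "NIC"): 1.180,
    ("depressed_affect", "CAD"): 1.279,
    ("depressed_affect", "CA"): 1.480,
    ("depressed_affect", "HHD"): 1.950,
    ("depressed_affect", "HF"): 1.260,
}

#: the mediator–outcome paths with a nominally significant mediated route
PUBLISHED_MEDIATION_PATHS = tuple(PUBLISHED_MEDIATOR_OUTCOME_OR)


@dataclass(frozen=True)
class MediationResult:
    """Decomposition of a total effect through one mediator."""

    beta1: float
    beta2: float
    beta3: float
    exposure_label: str = ""
    mediator_label: str = ""
    outcome_label: str = ""

    @property
    def mediation_effect(self) -> float:
        return self.beta2 * self.beta3

    @property
    def direct_effect(self) -> float:
        return self.beta1 - self.mediation_effect

    @property
    def proportion_mediated(self) -> float:
        """β2·β3/β1; NaN when β1 = 0 (flagged at construction)."""
        if self.beta1 == 0:
            return float("nan")
        return self.mediation_effect / self.beta1

    @property
    def or_total(self) -> float:
        return math.exp(self.beta1)

    @property
    def or_direct(self) -> float:
        return math.exp(self.direct_effect)

    @property
    def or_mediation(self) -> float:
        return math.exp(self.mediation_effect)

    def formatted_proportion(self) -> str:
        """Integer-percent rendering used in report tables."""
        p = self.proportion_mediated
        if math.isnan(p):
            return "undefined"
        return f"{round(100 * p):d}%"


def two_step_mediation(beta1: float, beta2: float, beta3: float,
                       exposure_label: str = "",
                       mediator_label: str = "",
                       outcome_label: str = "") -> MediationResult:
    """Decompose a total log-odds effect via the product of coefficients.

    ``beta1`` is the total exposure→outcome effect, ``beta2`` the
    exposure→mediator effect, ``beta3`` the mediator→outcome effect, all
    on log scales.  When β1 = 0 the proportion mediated is undefined
    (NaN, with a warning); the remaining fields are still returned.
    Proportions outside [0, 1] (inconsistent mediation) are reported
    as-is with a warning rather than truncated.
    """
    for name, v in (("beta1", beta1), ("beta2", beta2), ("beta3", beta3)):
        if not math.isfinite(v):
            raise AnalysisError(f"{name} must be finite, got {v!r}")
    result = MediationResult(beta1=beta1, beta2=beta2, beta3=beta3,
                             exposure_label=exposure_label,
                             mediator_label=mediator_label,
                             outcome_label=outcome_label)
    if beta1 == 0:
        logger.warning("total effect is 0: proportion mediated undefined")
    else:
        p = result.proportion_mediated
        if not (0 <= p <= 1):
            logger.warning("proportion mediated %.3f outside [0, 1]: "
                           "inconsistent decomposition", p)
    return result


def decompose_from_ors(total_or: float, step1_or: float,
                       step2_or: float, **labels) -> MediationResult:
    """Decompose printed odds ratios: the log-scale form of the above."""
    if min(total_or, step1_or, step2_or) <= 0:
        raise AnalysisError("odds ratios must be positive")
    return two_step_mediation(math.log(total_or), math.log(step1_or),
                              math.log(step2_or), **labels)


def mediation_se_delta(beta2: float, se2: float,
                       beta3: float, se3: float) -> float:
    """First-order delta-method SE of the product β2·β3.

    √(β3²·se2² + β2²·se3²); exact to first order when the two leg
    estimates are independent (they come from non-overlapping samples in
    a two-sample design).
    """
    if se2 <= 0 or se3 <= 0:
        raise AnalysisError("leg standard errors must be > 0")
    return math.sqrt(beta3 ** 2 * se2 ** 2 + beta2 ** 2 * se3 ** 2)


def mediation_pipeline(exposure: SummaryDataset,
                       mediator: SummaryDataset,
                       outcome: SummaryDataset,
                       config: RunConfig | None = None) -> MediationResult:
    """Estimate all three legs from summary data and decompose.

    β1 comes from the full exposure→outcome pipeline, β2 from
    exposure→mediator, β3 from mediator→outcome, each with its own
    instrument selection and the heterogeneity-driven IVW model choice.

    Raises :class:`AnalysisError` naming the failing leg when one lacks
    instruments.
    """
    config = config or RunConfig()
    legs = {}
    for name, (exp, out) in {
        "total (exposure->outcome)": (exposure, outcome),
        "step1 (exposure->mediator)": (exposure, mediator),
        "step2 (mediator->outcome)": (mediator, outcome),
    }.items():
        try:
            legs[name] = run_mr(exp, out, config=config).primary
        except AnalysisError as exc:
            raise AnalysisError(f"mediation leg {name} failed: {exc}") from exc
    return two_step_mediation(
        beta1=legs["total (exposure->outcome)"].theta,
        beta2=legs["step1 (exposure->mediator)"].theta,
        beta3=legs["step2 (mediator->outcome)"].theta,
        exposure_label=exposure.trait_label,
        mediator_label=mediator.trait_label,
        outcome_label=outcome.trait_label,
    )


def published_decompositions() -> list[MediationResult]:
    """Decompose every published mediation path from its printed ORs."""
    results = []
    for (mediator, outcome) in PUBLISHED_MEDIATION_PATHS:
        results.append(decompose_from_ors(
            PUBLISHED_TOTAL_OR[outcome],
            PUBLISHED_EXPOSURE_MEDIATOR_OR[mediator],
            PUBLISHED_MEDIATOR_OUTCOME_OR[(mediator, outcome)],
            exposure_label="irritability",
            mediator_label=mediator,
            outcome_label=outcome,
        ))
    return results


__all__ = [
    "PUBLISHED_TOTAL_OR",
    "PUBLISHED_EXPOSURE_MEDIATOR_OR",
    "PUBLISHED_MEDIATOR_OUTCOME_OR",
    "PUBLISHED_MEDIATION_PATHS",
    "MediationResult",
    "two_step_mediation",
    "decompose_from_ors",
    "mediation_se_delta",
    "mediation_pipeline",
    "published_decompositions",
]
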