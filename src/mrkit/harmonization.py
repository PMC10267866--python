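"""Allele harmonization of exposure and outcome effect estimates.

Two GWAS report each variant relative to an arbitrary effect allele and an
arbitrary strand.  Before any causal estimator can combine per-variant
exposure effects (βx, σx) with outcome effects (βy, σy), the two must be
expressed on the same effect allele:

* same allele pair, same orientation — copy the outcome effect;
* same pair, swapped orientation — negate βy (and flip the outcome EAF);
* strand-complement pair (A/G vs T/C …) — complement, then as above;
* palindromic pair (A/T or C/G) — alleles alone cannot resolve the strand;
  orientation is inferred from effect-allele frequencies when both are far
  from 0.5 and concordant, otherwise the variant is dropped and counted;
* incompatible alleles — dropped and counted.

Standard errors are never altered by harmonization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

from .errors import AnalysisError
from .summary_io import SummaryDataset, VariantAssociation

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Half-width of the EAF band around 0.5 inside which a palindromic
#: variant's strand is considered unresolvable.
DEFAULT_EAF_AMBIGUITY_BAND = 0.08


@dataclass(frozen=True)
class HarmonizedPair:
    """Per-variant exposure and outcome effects on a shared effect allele."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    effect_allele: str
    flipped: bool = False
    palindromic: bool = False
    pvalue_exposure: float = 1.0


@dataclass
class HarmonizedDataset:
    """Harmonized pairs plus bookkeeping of what was dropped and why."""

    pairs: list[HarmonizedPair] = field(default_factory=list)
    n_input: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_incompatible: int = 0
    exposure_label: str = ""
    outcome_label: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def variant_ids(self) -> list[str]:
        return [p.variant_id for p in self.pairs]

    def subset(self, ids) -> "HarmonizedDataset":
        wanted = set(ids)
        return HarmonizedDataset(
            pairs=[p for p in self.pairs if p.variant_id in wanted],
            n_input=len(self.pairs),
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
        )

    def drop(self, ids) -> "HarmonizedDataset":
        unwanted = set(ids)
        return self.subset([v for v in self.variant_ids() if v not in unwanted])


def _is_palindromic_pair(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _eaf_resolves(eaf_exp: float | None, eaf_out: float | None,
                  band: float) -> tuple[bool, bool]:
    """(resolvable, needs_flip) for a palindromic variant.

    Resolvable only when both EAFs are present, both outside
    [0.5 - band, 0.5 + band], and on consistent sides; needs_flip is True
    when they sit on opposite sides of 0.5 (the outcome's effect allele is
    the exposure's on the other strand, read as the other allele).
    """
    if eaf_exp is None or eaf_out is None:
        return False, False
    if abs(eaf_exp - 0.5) <= band or abs(eaf_out - 0.5) <= band:
        return False, False
    return True, (eaf_exp - 0.5) * (eaf_out - 0.5) < 0


def harmonize(exposure: SummaryDataset,
              outcome: SummaryDataset,
              eaf_ambiguity_band: float = DEFAULT_EAF_AMBIGUITY_BAND,
              keep_palindromic: bool = True) -> HarmonizedDataset:
    """Align outcome effects to the exposure's effect alleles.

    Parameters
    ----------
    eaf_ambiguity_band
        Palindromic variants whose exposure or outcome EAF falls within
        0.5 ± band (or is missing) are dropped as strand-ambiguous.
    keep_palindromic
        When False, every palindromic variant is dropped regardless of EAF
        (the stricter behavior some workflows prefer).

    Raises
    ------
    AnalysisError
        If the exposure/outcome variant intersection is empty.
    """
    out_by_id = outcome.by_id()
    shared = [r for r in exposure.records if r.variant_id in out_by_id]
    if not shared:
        raise AnalysisError(
            f"no shared instruments between {exposure.trait_label!r} "
            f"and {outcome.trait_label!r}")

    pairs: list[HarmonizedPair] = []
    n_pal = 0
    n_bad = 0
    for exp in shared:
        out = out_by_id[exp.variant_id]
        e1, e2 = exp.effect_allele, exp.other_allele
        o1, o2 = out.effect_allele, out.other_allele
        palindromic = _is_palindromic_pair(e1, e2)

        if palindromic:
            if not keep_palindromic:
                n_pal += 1
                logger.info("dropping palindromic variant %s (policy)",
                            exp.variant_id)
                continue
            # Alleles match trivially on either strand; orientation must
            # come from EAF.  Same-allele orientation first, then swapped.
            if {o1, o2} != {e1, e2}:
                n_bad += 1
                continue
            resolvable, eaf_flip = _eaf_resolves(
                exp.eaf, out.eaf if o1 == e1 else
                (1 - out.eaf if out.eaf is not None else None),
                eaf_ambiguity_band)
            if not resolvable:
                n_pal += 1
                logger.info("dropping palindromic variant %s "
                            "(EAF ambiguous)", exp.variant_id)
                continue
            base_flip = o1 != e1  # reported on the swapped orientation
            flip = base_flip ^ eaf_flip
        else:
            if {o1, o2} == {e1, e2}:
                flip = o1 != e1
            else:
                c1, c2 = _COMPLEMENT[o1], _COMPLEMENT[o2]
                if {c1, c2} == {e1, e2}:
                    flip = c1 != e1
                    logger.info("strand-complement resolution for %s",
                                exp.variant_id)
                else:
                    n_bad += 1
                    logger.info("dropping %s: incompatible alleles "
                                "%s/%s vs %s/%s", exp.variant_id,
                                e1, e2, o1, o2)
                    continue

        pairs.append(HarmonizedPair(
            variant_id=exp.variant_id,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            beta_outcome=-out.beta if flip else out.beta,
            se_outcome=out.se,
            effect_allele=e1,
            flipped=flip,
            palindromic=palindromic,
            pvalue_exposure=exp.pvalue,
        ))

    # deterministic ordering for bootstrap seeding
    pairs.sort(key=lambda p: (p.pvalue_exposure, p.variant_id))
    return HarmonizedDataset(
        pairs=pairs,
        n_input=len(shared),
        n_dropped_palindromic=n_pal,
        n_dropped_incompatible=n_bad,
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
    )


def orient_to_exposure_increasing(
        dataset: HarmonizedDataset) -> HarmonizedDataset:
    """Re-express every pair with beta_exposure ≥ 0.

    Jointly negates (βx, βy) where βx < 0 — a relabelling of the effect
    allele that leaves every estimator invariant.  Pairs with βx exactly 0
    are dropped with a warning (their ratio is undefined).
    """
    oriented = []
    for p in dataset.pairs:
        if p.beta_exposure == 0:
            logger.warning("dropping %s: beta_exposure is exactly 0",
                           p.variant_id)
            continue
        if p.beta_exposure < 0:
            p = replace(p, beta_exposure=-p.beta_exposure,
                        beta_outcome=-p.beta_outcome,
                        flipped=not p.flipped)
        oriented.append(p)
    return HarmonizedDataset(
        pairs=oriented,
        n_input=dataset.n_input,
        n_dropped_palindromic=dataset.n_dropped_palindromic,
        n_dropped_incompatible=dataset.n_dropped_incompatible,
        exposure_label=dataset.exposure_label,
        outcome_label=dataset.outcome_label,
    )


__all__ = [
    "DEFAULT_EAF_AMBIGUITY_BAND",
    "HarmonizedPair",
    "HarmonizedDataset",
    "harmonize",
    "orient_to_exposure_increasing",
]
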