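"""Ground-truthed GWAS summary-statistics simulation.

Generates two-sample (and exposure–mediator–outcome) summary datasets with
a known causal effect, a chosen pleiotropy regime, and optionally planted
outlier instruments, so that every pipeline stage can be tested against its
generating truth.

The generative model per instrument j:

* true exposure effect βxj ~ N(0, instrument_effect_sd), with |βxj| floored
  at 6·σxj so the expected single-variant F-statistic exceeds 30 (the
  instruments emulate genome-wide-significant hits, not marginal ones);
* observed exposure stats βxj_obs ~ N(βxj, σxj) with σxj = c/√n_exposure;
* outcome means θ·βxj + αj (+ an additive shift on planted outliers),
  observed with σyj = c/√n_outcome;
* pleiotropy αj per regime: ``none`` (0), ``balanced`` (N(0, τ)),
  ``directional`` (N(μα, τ)), or ``inside_violating`` (αj loads on a
  latent confounder correlated with instrument strength |βxj|, breaking
  the InSIDE assumption that MR-Egger needs while leaving the weighted
  median and MR-PRESSO something to detect).  αj is defined as the direct
  effect of the exposure-increasing allele — allele orientation in the
  emitted files is arbitrary, so αj enters the outcome mean as
  sign(βxj)·αj and directionality survives re-orientation, exactly as it
  would for real variants reported on arbitrary strands.

Default sizes mirror case/control GWAS at the scales this kind of study
combines, expressed as effective sample sizes 4/(1/cases + 1/controls):
a biobank questionnaire exposure (~259k effective, e.g. 90k cases /
232k controls), a disease-registry outcome (~74k effective, e.g. 22k
cases / 117k controls), a mediator GWAS of modest size (~31k effective),
and 21 instruments.  Standard errors use the single scale constant
c/√n_eff rather than per-variant allele frequencies — sufficient for
estimator testing, since no estimator here consumes the EAF beyond
palindrome resolution.  Note the outcome SEs dominate the exposure SEs,
as they do when the outcome is a disease endpoint; this is what makes
the no-measurement-error weighting of the estimators appropriate.

P-values are exact two-sided normal tails of β/σ; allele pairs are random
non-palindromic pairs; variants are spaced >20 Mb apart so default LD
clumping keeps them all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .summary_io import SummaryDataset, VariantAssociation

#: non-palindromic allele pairs sampled for simulated variants
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))

#: |true βx| floor in units of σx: expected F = (βx/σx)² + 1 ≥ 37
_F_FLOOR_SD = 6.0

PLEIOTROPY_REGIMES = ("none", "balanced", "directional", "inside_violating")


@dataclass(frozen=True)
class SimulationSpec:
    """Generating parameters for a synthetic two-sample MR dataset.

    ``theta`` is the true causal effect (log-odds of outcome per unit of
    exposure liability).  ``n_exposure``/``n_outcome``/``n_mediator``
    control the standard errors through σ = se_scale/√n.
    ``pleiotropy_mean`` (μα) and ``pleiotropy_sd`` (τ) parameterize the
    direct-effect distribution; ``inside_rho`` is the correlation between
    the pleiotropic loading and instrument strength in the
    InSIDE-violating regime.  ``mediation``, when present, is the
    (beta2, beta3, direct) triple of a two-step mediation structure.
    """

    k: int = 21
    theta: float = 0.5
    n_exposure: int = 259_000
    n_outcome: int = 74_000
    n_mediator: int = 31_000
    instrument_effect_sd: float = 0.02
    se_scale: float = 1.0
    pleiotropy: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_rho: float = 0.5
    n_outliers: int = 0
    outlier_magnitude: float = 0.0
    k_mediator: int = 21
    mediation: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.k < 3:
            raise ConfigurationError("k must be >= 3")
        if self.pleiotropy not in PLEIOTROPY_REGIMES:
            raise ConfigurationError(
                f"pleiotropy must be one of {PLEIOTROPY_REGIMES}")
        for name in ("instrument_effect_sd", "pleiotropy_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_outliers < 0 or self.n_outliers > self.k:
            raise ConfigurationError("n_outliers must be in [0, k]")

    @property
    def sigma_exposure(self) -> float:
        return self.se_scale / math.sqrt(self.n_exposure)

    @property
    def sigma_outcome(self) -> float:
        return self.se_scale / math.sqrt(self.n_outcome)

    @property
    def sigma_mediator(self) -> float:
        return self.se_scale / math.sqrt(self.n_mediator)


@dataclass
class SyntheticTruth:
    """Simulation parameters plus the realized per-variant generating values."""

    spec: SimulationSpec
    variant_ids: list[str]
    beta_x_true: np.ndarray
    alpha: np.ndarray
    outlier_flags: np.ndarray
    true_total_effect: float | None = None
    mediator_variant_ids: list[str] = field(default_factory=list)
    beta_m_true: np.ndarray | None = None


def _draw_instrument_effects(rng: np.random.Generator, k: int,
                             sd: float, sigma: float) -> np.ndarray:
    beta = rng.normal(0.0, sd, size=k)
    floor = _F_FLOOR_SD * sigma
    sign = np.where(beta < 0, -1.0, 1.0)
    return sign * np.maximum(np.abs(beta), floor)


def _draw_alpha(rng: np.random.Generator, spec: SimulationSpec,
                beta_x: np.ndarray) -> np.ndarray:
    k = spec.k
    if spec.pleiotropy == "none":
        return np.zeros(k)
    if spec.pleiotropy == "balanced":
        return rng.normal(0.0, spec.pleiotropy_sd, size=k)
    if spec.pleiotropy == "directional":
        return rng.normal(spec.pleiotropy_mean, spec.pleiotropy_sd, size=k)
    # inside_violating: loading correlated with instrument strength |βx|
    rho = spec.inside_rho
    z = rng.normal(0.0, 1.0, size=k)
    strength = np.abs(beta_x) - np.abs(beta_x).mean()
    denom = strength.std() if strength.std() > 0 else 1.0
    loading = rho * strength / denom + math.sqrt(1 - rho ** 2) * z
    return spec.pleiotropy_mean + spec.pleiotropy_sd * loading


def _records(rng: np.random.Generator, ids: list[str],
             chroms: list[str], positions: list[int],
             beta_obs: np.ndarray, sigma: float,
             n_total: int) -> list[VariantAssociation]:
    records = []
    for i, vid in enumerate(ids):
        a1, a2 = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
        z = beta_obs[i] / sigma
        pvalue = float(min(1.0, max(2 * stats.norm.sf(abs(z)),
                                    np.nextafter(0, 1))))
        records.append(VariantAssociation(
            variant_id=vid,
            chrom=chroms[i],
            pos=positions[i],
            effect_allele=a1,
            other_allele=a2,
            beta=float(beta_obs[i]),
            se=sigma,
            pvalue=pvalue,
            eaf=float(rng.uniform(0.1, 0.9)),
            n_total=n_total,
        ))
    return records


def _layout(n: int, start: int = 0) -> tuple[list[str], list[str], list[int]]:
    """IDs, chromosomes, and positions spaced beyond any clump window."""
    ids = [f"rs{1000000 + start + j}" for j in range(n)]
    chroms = [str((start + j) % 22 + 1) for j in range(n)]
    positions = [20_000_000 * ((start + j) // 22 + 1) for j in range(n)]
    return ids, chroms, positions


def simulate_pair_arrays(spec: SimulationSpec,
                         rng: np.random.Generator | None = None):
    """Fast path: return raw arrays (bx_obs, sx, by_obs, sy, truth).

    Used by Monte-Carlo studies that do not need full dataset objects.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    sx = spec.sigma_exposure
    sy = spec.sigma_outcome
    beta_x = _draw_instrument_effects(rng, spec.k,
                                      spec.instrument_effect_sd, sx)
    alpha = _draw_alpha(rng, spec, beta_x)
    flags = np.zeros(spec.k, dtype=bool)
    if spec.n_outliers:
        flags[rng.choice(spec.k, size=spec.n_outliers, replace=False)] = True
    # direct effects are defined on the exposure-increasing orientation
    sign = np.where(beta_x < 0, -1.0, 1.0)
    mean_y = spec.theta * beta_x + sign * (
        alpha + np.where(flags, spec.outlier_magnitude, 0.0))
    bx_obs = rng.normal(beta_x, sx)
    by_obs = rng.normal(mean_y, sy)
    ids, _, _ = _layout(spec.k)
    truth = SyntheticTruth(spec=spec, variant_ids=ids,
                           beta_x_true=beta_x, alpha=alpha,
                           outlier_flags=flags)
    return (bx_obs, np.full(spec.k, sx), by_obs, np.full(spec.k, sy), truth)


def simulate_pair(spec: SimulationSpec
                  ) -> tuple[SummaryDataset, SummaryDataset, SyntheticTruth]:
    """Simulate an (exposure, outcome) summary-dataset pair with truth."""
    rng = np.random.default_rng(spec.seed)
    sx = spec.sigma_exposure
    sy = spec.sigma_outcome
    beta_x = _draw_instrument_effects(rng, spec.k,
                                      spec.instrument_effect_sd, sx)
    alpha = _draw_alpha(rng, spec, beta_x)
    flags = np.zeros(spec.k, dtype=bool)
    if spec.n_outliers:
        flags[rng.choice(spec.k, size=spec.n_outliers, replace=False)] = True
    # direct effects are defined on the exposure-increasing orientation
    sign = np.where(beta_x < 0, -1.0, 1.0)
    mean_y = spec.theta * beta_x + sign * (
        alpha + np.where(flags, spec.outlier_magnitude, 0.0))
    bx_obs = rng.normal(beta_x, sx)
    by_obs = rng.normal(mean_y, sy)
    ids, chroms, positions = _layout(spec.k)

    exp_records = _records(rng, ids, chroms, positions, bx_obs, sx,
                           spec.n_exposure)
    # outcome reports the same variants with its own allele orientation:
    # reuse the exposure's alleles so harmonization is exercised only by
    # real data; orientation tests build their own fixtures.
    out_records = [replace(r, beta=float(by_obs[i]), se=sy,
                           pvalue=float(min(1.0,
                                            2 * stats.norm.sf(
                                                abs(by_obs[i] / sy)))),
                           n_total=spec.n_outcome)
                   for i, r in enumerate(exp_records)]
    truth = SyntheticTruth(spec=spec, variant_ids=ids,
                           beta_x_true=beta_x, alpha=alpha,
                           outlier_flags=flags)
    exposure = SummaryDataset("sim_exposure", exp_records, "binary")
    outcome = SummaryDataset("sim_outcome", out_records, "binary")
    return exposure, outcome, truth


def simulate_mediation_triple(
        spec: SimulationSpec
) -> tuple[SummaryDataset, SummaryDataset, SummaryDataset, SyntheticTruth]:
    """Simulate (exposure, mediator, outcome) datasets with known mediation.

    The exposure's instruments act on the mediator through β2 and on the
    outcome through direct + β2·β3; the mediator's own (independent)
    instruments act on the outcome through β3 alone.  Every dataset
    reports the union of both instrument sets, so each leg's instrument
    selection works exactly as it would on real data.  The true total
    effect direct + β2·β3 is recorded in the returned truth.
    """
    if spec.mediation is None:
        raise ConfigurationError("spec.mediation must be set")
    beta2, beta3, direct = spec.mediation
    total = direct + beta2 * beta3
    rng = np.random.default_rng(spec.seed)
    sx = spec.sigma_exposure
    sm = spec.sigma_mediator
    sy = spec.sigma_outcome

    k_e, k_m = spec.k, spec.k_mediator
    beta_x = _draw_instrument_effects(rng, k_e,
                                      spec.instrument_effect_sd, sx)
    gamma = _draw_instrument_effects(rng, k_m,
                                     spec.instrument_effect_sd, sm)

    ids_e, chrom_e, pos_e = _layout(k_e)
    ids_m, chrom_m, pos_m = _layout(k_m, start=k_e)

    # per-GWAS observed effects for the union of variants
    exp_means = np.concatenate([beta_x, np.zeros(k_m)])
    med_means = np.concatenate([beta2 * beta_x, gamma])
    out_means = np.concatenate([total * beta_x, beta3 * gamma])

    exp_obs = rng.normal(exp_means, sx)
    med_obs = rng.normal(med_means, sm)
    out_obs = rng.normal(out_means, sy)

    ids = ids_e + ids_m
    chroms = chrom_e + chrom_m
    positions = pos_e + pos_m
    n_union = k_e + k_m

    exp_records = _records(rng, ids, chroms, positions, exp_obs, sx,
                           spec.n_exposure)
    med_records = [replace(r, beta=float(med_obs[i]), se=sm,
                           pvalue=float(min(1.0,
                                            2 * stats.norm.sf(
                                                abs(med_obs[i] / sm)))),
                           n_total=spec.n_mediator)
                   for i, r in enumerate(exp_records)]
    out_records = [replace(r, beta=float(out_obs[i]), se=sy,
                           pvalue=float(min(1.0,
                                            2 * stats.norm.sf(
                                                abs(out_obs[i] / sy)))),
                           n_total=spec.n_outcome)
                   for i, r in enumerate(exp_records)]

    truth = SyntheticTruth(
        spec=spec, variant_ids=ids,
        beta_x_true=np.concatenate([beta_x, np.zeros(k_m)]),
        alpha=np.zeros(n_union),
        outlier_flags=np.zeros(n_union, dtype=bool),
        true_total_effect=total,
        mediator_variant_ids=ids_m,
        beta_m_true=med_means,
    )
    return (SummaryDataset("sim_exposure", exp_records, "binary"),
            SummaryDataset("sim_mediator", med_records, "binary"),
            SummaryDataset("sim_outcome", out_records, "binary"),
            truth)


def write_truth_sidecar(truth: SyntheticTruth, path) -> None:
    """Write the per-variant generating values as a TSV sidecar."""
    from pathlib import Path
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("variant_id\tbeta_x_true\talpha\toutlier\n")
        for i, vid in enumerate(truth.variant_ids):
            fh.write(f"{vid}\t{truth.beta_x_true[i]!r}\t"
                     f"{truth.alpha[i]!r}\t"
                     f"{int(truth.outlier_flags[i])}\n")


__all__ = [
    "PLEIOTROPY_REGIMES",
    "SimulationSpec",
    "SyntheticTruth",
    "simulate_pair",
    "simulate_pair_arrays",
    "simulate_mediation_triple",
    "write_truth_sidecar",
]
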