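"""Full exposure→outcome analysis orchestration.

``run_mr`` chains the whole workflow — genome-wide significance filter, LD
clumping, instrument-strength (F) filter, confounder exclusion,
harmonization, the estimator suite, and MR-PRESSO — and applies the
heterogeneity decision rule: when Cochran's Q is significant at
``heterogeneity_alpha`` the primary estimate is the multiplicative
random-effects IVW, otherwise the fixed-effects IVW.

Reports carry full attrition bookkeeping (instruments in = instruments
used + dropped per stage) and provenance (config hash, seed, input
digests) so identical configured runs are byte-identical.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .errors import AnalysisError
from .estimators import (HeterogeneityResult, MREstimate, egger, ivw,
                         weighted_median)
from .harmonization import (DEFAULT_EAF_AMBIGUITY_BAND, HarmonizedDataset,
                            harmonize, orient_to_exposure_increasing)
from .instruments import (SelectionConfig, LDMatrix, clump,
                          confounder_exclude, significance_filter,
                          strength_filter)
from .presso import PressoResult, presso
from .summary_io import SummaryDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All settings of a configured run."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    eaf_ambiguity_band: float = DEFAULT_EAF_AMBIGUITY_BAND
    keep_palindromic: bool = True
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    heterogeneity_alpha: float = 0.05
    outlier_alpha: float = 0.05

    def __post_init__(self):
        if not (0 < self.heterogeneity_alpha < 1):
            raise AnalysisError("heterogeneity_alpha must lie in (0, 1)")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a flat key-value config file with sections per module."""
    parser = configparser.ConfigParser()
    parser.read(str(path))

    def get(section, key, cast, default):
        if parser.has_option(section, key):
            raw = parser.get(section, key)
            return cast(raw) if cast is not bool else raw.lower() in (
                "1", "true", "yes")
        return default

    sel = SelectionConfig(
        p_threshold=get("instruments", "p_threshold", float, 5e-8),
        clump_window_kb=get("instruments", "clump_window_kb", float, 10_000.0),
        clump_r2=get("instruments", "clump_r2", float, 0.001),
        f_min=get("instruments", "f_min", float, 10.0),
        confounder_p_threshold=get("instruments", "confounder_p_threshold",
                                   float, 5e-8),
    )
    return RunConfig(
        selection=sel,
        eaf_ambiguity_band=get("harmonization", "eaf_ambiguity_band", float,
                               DEFAULT_EAF_AMBIGUITY_BAND),
        keep_palindromic=get("harmonization", "keep_palindromic", bool, True),
        n_boot=get("estimators", "n_boot", int, 1000),
        n_sim=get("estimators", "n_sim", int, 1000),
        seed=get("estimators", "seed", int, 0),
        heterogeneity_alpha=get("pipeline", "heterogeneity_alpha", float, 0.05),
        outlier_alpha=get("pipeline", "outlier_alpha", float, 0.05),
    )


@dataclass
class AnalysisReport:
    """Everything a configured exposure→outcome run produced."""

    exposure_label: str
    outcome_label: str
    estimates: list[MREstimate]
    heterogeneity: HeterogeneityResult | None
    egger_diagnostics: HeterogeneityResult | None
    presso_result: PressoResult | None
    primary_method: str
    harmonized: HarmonizedDataset
    attrition: dict[str, int]
    provenance: dict[str, str]

    @property
    def primary(self) -> MREstimate:
        return next(e for e in self.estimates if e.method == self.primary_method)

    def results_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.estimates:
            orr, lo, hi = e.or_scale
            rows.append({
                "exposure": self.exposure_label,
                "outcome": self.outcome_label,
                "method": e.method,
                "n_snps": e.n_snps,
                "theta": e.theta, "se": e.se,
                "ci_low": e.ci_low, "ci_high": e.ci_high,
                "pvalue": e.pvalue,
                "OR": orr, "OR_low": lo, "OR_high": hi,
                "primary": e.method == self.primary_method,
            })
        return pd.DataFrame(rows)

    def diagnostics_frame(self) -> pd.DataFrame:
        row = {"exposure": self.exposure_label,
               "outcome": self.outcome_label,
               "n_snps": len(self.harmonized)}
        if self.heterogeneity is not None:
            row.update(Q=self.heterogeneity.Q, Q_df=self.heterogeneity.df,
                       Q_pvalue=self.heterogeneity.pvalue)
        if self.egger_diagnostics is not None:
            row.update(egger_intercept=self.egger_diagnostics.egger_intercept,
                       egger_intercept_se=self.egger_diagnostics.egger_intercept_se,
                       egger_intercept_p=self.egger_diagnostics.egger_intercept_p)
        if self.presso_result is not None:
            row.update(presso_global_rss=self.presso_result.global_rss,
                       presso_global_p=self.presso_result.global_p,
                       presso_outliers=",".join(self.presso_result.outlier_ids)
                       or "none")
        return pd.DataFrame([row])

    def write(self, results_path: str | Path,
              diagnostics_path: str | Path | None = None) -> None:
        self.results_frame().to_csv(results_path, sep="\t", index=False)
        if diagnostics_path is not None:
            self.diagnostics_frame().to_csv(diagnostics_path, sep="\t",
                                            index=False)


def _digest_dataset(dataset: SummaryDataset) -> str:
    h = hashlib.sha256()
    for r in dataset.records:
        h.update(f"{r.variant_id}\t{r.beta!r}\t{r.se!r}\t{r.pvalue!r}\n"
                 .encode())
    return h.hexdigest()[:16]


def select_instruments(exposure: SummaryDataset,
                       config: RunConfig,
                       ld: LDMatrix | None = None,
                       confounders: pd.DataFrame | None = None
                       ) -> tuple[SummaryDataset, dict[str, int]]:
    """Run the selection chain, returning instruments plus attrition."""
    sel = config.selection
    attrition = {"input": len(exposure)}
    sig = significance_filter(exposure, sel.p_threshold)
    attrition["dropped_not_significant"] = len(exposure) - len(sig)
    clumped = clump(sig, ld=ld, config=sel)
    attrition["dropped_clumped"] = len(sig) - len(clumped)
    strong = [ir.variant for ir in strength_filter(clumped, sel.f_min)]
    attrition["dropped_weak"] = len(clumped) - len(strong)
    instruments = SummaryDataset(exposure.trait_label, strong,
                                 exposure.trait_type)
    if confounders is not None:
        screened = confounder_exclude(instruments, confounders,
                                      sel.confounder_p_threshold)
        attrition["dropped_confounded"] = len(instruments) - len(screened)
        instruments = screened
    else:
        attrition["dropped_confounded"] = 0
    attrition["selected"] = len(instruments)
    return instruments, attrition


def run_mr(exposure: SummaryDataset,
           outcome: SummaryDataset,
           config: RunConfig | None = None,
           ld: LDMatrix | None = None,
           confounders: pd.DataFrame | None = None) -> AnalysisReport:
    """Full configured exposure→outcome MR analysis.

    Raises :class:`AnalysisError` with stage-by-stage attrition counts if
    fewer than 3 instruments survive selection and harmonization.
    """
    config = config or RunConfig()
    instruments, attrition = select_instruments(exposure, config, ld,
                                                confounders)
    if len(instruments) < 3:
        raise AnalysisError(
            f"fewer than 3 instruments after filtering: {attrition}")

    harmonized = harmonize(instruments, outcome,
                           eaf_ambiguity_band=config.eaf_ambiguity_band,
                           keep_palindromic=config.keep_palindromic)
    attrition["dropped_palindromic"] = harmonized.n_dropped_palindromic
    attrition["dropped_incompatible"] = harmonized.n_dropped_incompatible
    attrition["dropped_missing_in_outcome"] = (
        len(instruments) - harmonized.n_input)
    harmonized = orient_to_exposure_increasing(harmonized)
    attrition["used"] = len(harmonized)
    if len(harmonized) < 3:
        raise AnalysisError(
            f"fewer than 3 instruments after harmonization: {attrition}")

    est_fe, het = ivw(harmonized, model="fixed")
    est_mre, _ = ivw(harmonized, model="multiplicative_random")
    est_egger, egger_diag = egger(harmonized)
    est_wm = weighted_median(harmonized, n_boot=config.n_boot,
                             seed=config.seed)

    primary = ("ivw_mre" if het is not None
               and het.pvalue < config.heterogeneity_alpha else "ivw_fe")

    presso_result = None
    estimates = [est_fe, est_mre, est_egger, est_wm]
    if len(harmonized) >= 4:
        presso_result = presso(harmonized, n_sim=config.n_sim,
                               seed=config.seed,
                               outlier_alpha=config.outlier_alpha)
        raw = presso_result.raw_estimate
        estimates.append(MREstimate(
            method="presso_raw", theta=raw.theta, se=raw.se,
            ci_low=raw.ci_low, ci_high=raw.ci_high, pvalue=raw.pvalue,
            n_snps=raw.n_snps))
        if presso_result.corrected_estimate is not None:
            cor = presso_result.corrected_estimate
            estimates.append(MREstimate(
                method="presso_corrected", theta=cor.theta, se=cor.se,
                ci_low=cor.ci_low, ci_high=cor.ci_high, pvalue=cor.pvalue,
                n_snps=cor.n_snps))
    else:
        logger.info("MR-PRESSO skipped: fewer than 4 instruments")

    provenance = {
        "config": config.digest(),
        "seed": str(config.seed),
        "exposure_digest": _digest_dataset(exposure),
        "outcome_digest": _digest_dataset(outcome),
    }
    return AnalysisReport(
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        estimates=estimates,
        heterogeneity=het,
        egger_diagnostics=egger_diag,
        presso_result=presso_result,
        primary_method=primary,
        harmonized=harmonized,
        attrition=attrition,
        provenance=provenance,
    )


__all__ = ["RunConfig", "AnalysisReport", "load_config",
           "select_instruments", "run_mr"]
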