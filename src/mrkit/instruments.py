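"""Instrument (IV) selection from an exposure GWAS.

Selection follows the conventional two-sample MR recipe: keep genome-wide
significant variants (p < 5e-8), prune them to independence by LD clumping
(r² < 0.001 within a 10,000 kb window), drop weak instruments by the
single-variant F-statistic F = (β/σ)² (F > 10), and exclude variants with a
genome-wide-significant association to a known confounder.

Clumping accepts an optional user-supplied LD matrix; without one it falls
back to distance-only pruning (every other variant inside the window is
discarded), and logs the fallback, since no reference panel ships with the
package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .summary_io import SummaryDataset, VariantAssociation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for instrument selection.

    Defaults are the conventional genome-wide settings: significance
    p < 5e-8, clumping at r² < 0.001 within 10,000 kb, instrument strength
    F > 10, and confounder exclusion at p < 5e-8.
    """

    p_threshold: float = 5e-8
    clump_window_kb: float = 10_000.0
    clump_r2: float = 0.001
    f_min: float = 10.0
    confounder_p_threshold: float = 5e-8

    def __post_init__(self):
        for name in ("p_threshold", "clump_window_kb", "clump_r2", "f_min",
                     "confounder_p_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if not (0 < self.clump_r2 < 1):
            raise ConfigurationError("clump_r2 must lie in (0, 1)")


@dataclass(frozen=True)
class InstrumentRecord:
    """A selected instrument together with its strength statistic."""

    variant: VariantAssociation
    f_statistic: float


@dataclass
class LDMatrix:
    """Pairwise r² between variants: symmetric, unit diagonal."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ConfigurationError(
                f"LD matrix shape {self.r2.shape} does not match "
                f"{k} variant ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ConfigurationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ConfigurationError("LD matrix diagonal must equal 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ConfigurationError("LD r² values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise ConfigurationError(
                f"LD matrix does not cover variant {exc.args[0]!r}") from None


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square tab-separated r² matrix with a header of variant IDs."""
    df = pd.read_csv(path, sep="\t")
    ids = [str(c) for c in df.columns]
    return LDMatrix(variant_ids=ids, r2=df.to_numpy(dtype=float))


def significance_filter(dataset: SummaryDataset,
                        p_threshold: float = 5e-8) -> SummaryDataset:
    """Keep records with ``pvalue < p_threshold``; order preserved."""
    return SummaryDataset(
        trait_label=dataset.trait_label,
        records=[r for r in dataset.records if r.pvalue < p_threshold],
        trait_type=dataset.trait_type,
    )


def f_statistic(variant: VariantAssociation) -> float:
    """Single-instrument strength approximation F = (β/σ)²."""
    return (variant.beta / variant.se) ** 2


def strength_filter(dataset: SummaryDataset,
                    f_min: float = 10.0) -> list[InstrumentRecord]:
    """Drop weak instruments; returns records paired with their F."""
    kept = []
    for rec in dataset.records:
        f = f_statistic(rec)
        if f > f_min:
            kept.append(InstrumentRecord(variant=rec, f_statistic=f))
        else:
            logger.info("dropping weak instrument %s (F=%.2f <= %.1f)",
                        rec.variant_id, f, f_min)
    return kept


def clump(dataset: SummaryDataset,
          ld: LDMatrix | None = None,
          config: SelectionConfig | None = None) -> SummaryDataset:
    """Greedy LD clumping.

    Repeatedly take the lowest-p unselected variant (ties broken by
    lexicographic variant_id for determinism) and discard every other
    variant on the same chromosome within ``clump_window_kb`` whose r² with
    it exceeds ``clump_r2``.  Without an LD matrix every within-window
    variant is discarded unconditionally (distance-only pruning).  The
    result is ordered by p ascending.

    Variants lacking chromosome/position are treated as isolated (they can
    only be pruned through the LD matrix pathway, never by distance).
    """
    config = config or SelectionConfig()
    if ld is not None:
        covered = set(ld.variant_ids)
        absent = [r.variant_id for r in dataset.records
                  if r.variant_id not in covered]
        if absent:
            raise ConfigurationError(
                "LD matrix missing variant(s): " + ", ".join(absent))
    else:
        logger.info("no LD matrix supplied: distance-only clumping "
                    "(all within-window variants pruned)")

    window_bp = config.clump_window_kb * 1000.0
    order = sorted(dataset.records, key=lambda r: (r.pvalue, r.variant_id))
    selected: list[VariantAssociation] = []
    discarded: set[str] = set()
    for cand in order:
        if cand.variant_id in discarded:
            continue
        selected.append(cand)
        for other in order:
            if other.variant_id == cand.variant_id:
                continue
            if other.variant_id in discarded:
                continue
            in_window = (
                cand.chrom != "" and other.chrom == cand.chrom
                and cand.pos is not None and other.pos is not None
                and abs(other.pos - cand.pos) <= window_bp
            )
            if not in_window:
                continue
            if ld is None or ld.lookup(cand.variant_id,
                                       other.variant_id) > config.clump_r2:
                discarded.add(other.variant_id)
    return SummaryDataset(
        trait_label=dataset.trait_label,
        records=selected,
        trait_type=dataset.trait_type,
    )


def read_confounder_table(path: str | Path) -> pd.DataFrame:
    """Read a (variant_id, trait_label, pvalue) confounder-association table."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str,
                                            "trait_label": str})
    required = {"variant_id", "trait_label", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(
            "confounder table missing column(s): " + ", ".join(sorted(missing)))
    if not np.isfinite(df["pvalue"].to_numpy(dtype=float)).all():
        raise ValidationError("confounder table has non-finite p-values")
    return df


def confounder_exclude(instruments: SummaryDataset,
                       associations: pd.DataFrame,
                       p_threshold: float = 5e-8) -> SummaryDataset:
    """Remove instruments strongly associated with a listed confounder.

    ``associations`` has columns (variant_id, trait_label, pvalue); an
    instrument is excluded when any of its rows has pvalue < ``p_threshold``.
    Exclusions are logged with the offending trait(s).
    """
    if len(associations) == 0:
        return instruments
    hits = associations[associations["pvalue"].astype(float) < p_threshold]
    flagged: dict[str, list[str]] = {}
    for _, row in hits.iterrows():
        flagged.setdefault(str(row["variant_id"]), []).append(
            str(row["trait_label"]))
    for vid, traits in flagged.items():
        if vid in set(instruments.variant_ids()):
            logger.info("excluding instrument %s: confounder association "
                        "with %s", vid, ", ".join(sorted(set(traits))))
    return SummaryDataset(
        trait_label=instruments.trait_label,
        records=[r for r in instruments.records
                 if r.variant_id not in flagged],
        trait_type=instruments.trait_type,
    )


__all__ = [
    "SelectionConfig",
    "InstrumentRecord",
    "LDMatrix",
    "read_ld_matrix",
    "significance_filter",
    "f_statistic",
    "strength_filter",
    "clump",
    "read_confounder_table",
    "confounder_exclude",
]
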