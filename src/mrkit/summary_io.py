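"""Reading, validation, and writing of GWAS summary statistics.

The on-disk dialect is a UTF-8, tab-separated table with a header row and
``NA`` for missing values — the shape of a typical IEU OpenGWAS export.
Canonical column names are fixed (see :data:`CANONICAL_COLUMNS`); foreign
headers are adapted through an explicit ``column_map`` rather than guessed.

Each row is one variant's association with one trait: an effect size on the
log-odds scale for binary traits (SD units otherwise), its standard error,
p-value, effect-allele frequency, and sample sizes.  Rows violating the
per-variant invariants are rejected with their line numbers collected, never
silently coerced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import ConfigurationError, ValidationError

#: Canonical header, in writing order.
CANONICAL_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "eaf",
    "n_total",
    "n_cases",
)

#: Columns that must be resolvable on read.
REQUIRED_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
)

_VALID_ALLELES = frozenset("ACGT")

#: Number of significant digits preserved on write (round-trip contract).
_WRITE_PRECISION = 12


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's allele-oriented effect estimate from one GWAS.

    ``beta`` is a log odds ratio for binary traits and is always expressed
    per copy of ``effect_allele``.  ``eaf``, ``n_total`` and ``n_cases`` may
    be missing (``None``).
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str = ""
    pos: int | None = None
    eaf: float | None = None
    n_total: int | None = None
    n_cases: int | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if not self.variant_id:
            problems.append("empty variant_id")
        for name, allele in (("effect_allele", self.effect_allele),
                             ("other_allele", self.other_allele)):
            if len(allele) != 1 or allele not in _VALID_ALLELES:
                problems.append(
                    f"{name} {allele!r} is not a single A/C/G/T base")
        if self.effect_allele == self.other_allele:
            problems.append(
                f"effect_allele equals other_allele ({self.effect_allele!r})")
        if not math.isfinite(self.beta):
            problems.append(f"beta {self.beta!r} is not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            problems.append(f"se {self.se!r} is not > 0")
        if not (0 < self.pvalue <= 1):
            problems.append(f"pvalue {self.pvalue!r} outside (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            problems.append(f"eaf {self.eaf!r} outside (0, 1)")
        if self.pos is not None and self.pos < 1:
            problems.append(f"pos {self.pos!r} is not 1-based positive")
        return problems

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants (strand-ambiguous)."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class SummaryDataset:
    """An ordered collection of :class:`VariantAssociation` for one trait."""

    trait_label: str
    records: list[VariantAssociation] = field(default_factory=list)
    trait_type: str = "binary"  # "binary" | "continuous"

    def __post_init__(self):
        if self.trait_type not in ("binary", "continuous"):
            raise ConfigurationError(
                f"trait_type must be 'binary' or 'continuous', "
                f"got {self.trait_type!r}")
        seen: dict[str, int] = {}
        dups = []
        for rec in self.records:
            seen[rec.variant_id] = seen.get(rec.variant_id, 0) + 1
            if seen[rec.variant_id] == 2:
                dups.append(rec.variant_id)
        if dups:
            raise ValidationError(
                f"duplicate variant_id values in {self.trait_label!r}",
                [f"duplicate: {v}" for v in dups])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def by_id(self) -> dict[str, VariantAssociation]:
        return {r.variant_id: r for r in self.records}

    def subset(self, ids: Iterable[str]) -> "SummaryDataset":
        """Records whose variant_id is in ``ids``, original order kept."""
        wanted = set(ids)
        return SummaryDataset(
            trait_label=self.trait_label,
            records=[r for r in self.records if r.variant_id in wanted],
            trait_type=self.trait_type,
        )

    def to_frame(self) -> pd.DataFrame:
        """Canonical-column DataFrame view (``None`` → ``pd.NA``)."""
        rows = []
        for r in self.records:
            rows.append({
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "eaf": r.eaf,
                "n_total": r.n_total,
                "n_cases": r.n_cases,
            })
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _fmt(value, integer: bool = False) -> str:
    if value is None:
        return "NA"
    if integer:
        return str(int(value))
    if isinstance(value, str):
        return value
    return repr(float(value)) if _needs_repr(value) else f"{value:.{_WRITE_PRECISION}g}"


def _needs_repr(x: float) -> bool:
    # %.12g loses bits for some doubles; fall back to repr when it does.
    return float(f"{x:.{_WRITE_PRECISION}g}") != x


def _parse_float(text: str, line_no: int, col: str, problems: list[str],
                 allow_missing: bool = False) -> float | None:
    if text == "NA":
        if allow_missing:
            return None
        problems.append(f"line {line_no}: {col} is NA but required")
        return None
    try:
        return float(text)
    except ValueError:
        problems.append(f"line {line_no}: unparseable {col} value {text!r}")
        return None


def _parse_int(text: str, line_no: int, col: str,
               problems: list[str]) -> int | None:
    if text in ("NA", ""):
        return None
    try:
        return int(float(text))
    except ValueError:
        problems.append(f"line {line_no}: unparseable {col} value {text!r}")
        return None


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str | None = None,
    trait_type: str = "binary",
) -> SummaryDataset:
    """Read a tab-separated summary-statistics table.

    Parameters
    ----------
    path
        File with a header row; tab-separated, ``NA`` for missing.
    column_map
        Optional mapping ``{canonical_name: header_in_file}`` used to adapt
        foreign headers; unmapped canonical names fall back to themselves.
    trait_label, trait_type
        Metadata attached to the returned dataset; the label defaults to the
        file stem.

    Raises
    ------
    ConfigurationError
        If a required column cannot be resolved.
    ValidationError
        If any row is malformed; the error lists every offending line.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise ValidationError(f"{path}: empty file, header row required")
        header = header_line.split("\t")
        col_of = {}
        cmap = dict(column_map or {})
        for canonical in CANONICAL_COLUMNS:
            source = cmap.get(canonical, canonical)
            if source in header:
                col_of[canonical] = header.index(source)
        missing = [c for c in REQUIRED_COLUMNS if c not in col_of]
        if missing:
            raise ConfigurationError(
                f"{path}: required column(s) missing: {', '.join(missing)}")

        records: list[VariantAssociation] = []
        problems: list[str] = []
        for line_no, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) < len(header):
                problems.append(
                    f"line {line_no}: expected {len(header)} fields, "
                    f"got {len(fields)}")
                continue

            def get(col: str, default: str = "NA") -> str:
                idx = col_of.get(col)
                return fields[idx] if idx is not None else default

            beta = _parse_float(get("beta"), line_no, "beta", problems)
            se = _parse_float(get("se"), line_no, "se", problems)
            pvalue = _parse_float(get("pvalue"), line_no, "pvalue", problems)
            eaf = _parse_float(get("eaf"), line_no, "eaf", problems,
                               allow_missing=True)
            if None in (beta, se, pvalue):
                continue
            chrom = get("chrom", "")
            rec = VariantAssociation(
                variant_id=get("variant_id", ""),
                chrom="" if chrom == "NA" else chrom,
                pos=_parse_int(get("pos"), line_no, "pos", problems),
                effect_allele=get("effect_allele", "").upper(),
                other_allele=get("other_allele", "").upper(),
                beta=beta,
                se=se,
                pvalue=pvalue,
                eaf=eaf,
                n_total=_parse_int(get("n_total"), line_no, "n_total", problems),
                n_cases=_parse_int(get("n_cases"), line_no, "n_cases", problems),
            )
            row_problems = rec.validate()
            if row_problems:
                problems.extend(f"line {line_no}: {p}" for p in row_problems)
                continue
            records.append(rec)

    if problems:
        raise ValidationError(f"{path}: {len(problems)} malformed row value(s)",
                              problems)
    return SummaryDataset(
        trait_label=trait_label if trait_label is not None else path.stem,
        records=records,
        trait_type=trait_type,
    )


def write_summary_table(dataset: SummaryDataset, path: str | Path) -> Path:
    """Write ``dataset`` in the canonical tab-separated dialect.

    Numeric text is preserved to at least 12 significant digits so that
    ``read_summary_table(write_summary_table(d))`` reproduces ``d`` exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in dataset.records:
            fh.write("\t".join([
                r.variant_id,
                r.chrom if r.chrom else "NA",
                _fmt(r.pos, integer=True) if r.pos is not None else "NA",
                r.effect_allele,
                r.other_allele,
                _fmt(r.beta),
                _fmt(r.se),
                _fmt(r.pvalue),
                _fmt(r.eaf),
                _fmt(r.n_total, integer=True) if r.n_total is not None else "NA",
                _fmt(r.n_cases, integer=True) if r.n_cases is not None else "NA",
            ]) + "\n")
    return path


__all__ = [
    "CANONICAL_COLUMNS",
    "REQUIRED_COLUMNS",
    "VariantAssociation",
    "SummaryDataset",
    "read_summary_table",
    "write_summary_table",
    "replace",
]
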