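"""GWAS summary-statistic reading, validation, filtering and allele harmonization.

Summary statistics arrive as tab-delimited text with one row per variant
(chromosome, position, effect/other allele, beta, SE, p, effect-allele
frequency, imputation INFO).  Filtering removes multiallelic positions,
strand-ambiguous SNVs, poorly imputed variants (INFO) and rare variants
(MAF) before effects are aligned to the counted allele of a target cohort.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

VALID_ALLELES = frozenset("ACGT")

AUTOSOMES = frozenset(str(c) for c in range(1, 23))

#: Default header names; override via ``column_map`` in :func:`read_sumstats`.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "eaf": "eaf",
    "info": "info",
}

# Fixed attribution order for exclusion counting: a removed record is charged
# to the FIRST rule it fails, so counts are reproducible.
EXCLUSION_RULES = ("multiallelic", "ambiguous", "info", "maf")


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's GWAS result."""

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float
    info: float

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset((self.effect_allele, self.other_allele))


@dataclass(frozen=True)
class HarmonizedWeight:
    """A signed effect aligned to the target cohort's counted allele."""

    chrom: str
    pos: int
    counted_allele: str
    other_allele: str
    weight: float
    flipped: bool


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


class SumstatsError(ValueError):
    pass


def _normalize_chrom(raw: str) -> str:
    c = raw.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def _validate_record(rec: SummaryStatRecord) -> str | None:
    """Return an error message, or None if the record is well formed."""
    if rec.effect_allele not in VALID_ALLELES or rec.other_allele not in VALID_ALLELES:
        return f"non-SNV or invalid alleles {rec.effect_allele}/{rec.other_allele}"
    if rec.effect_allele == rec.other_allele:
        return "effect and other allele identical"
    if not rec.se > 0:
        return f"se must be > 0, got {rec.se}"
    if not (0 < rec.pvalue <= 1):
        return f"pvalue must be in (0, 1], got {rec.pvalue}"
    if not (0 < rec.eaf < 1):
        return f"eaf must be in (0, 1), got {rec.eaf}"
    if not (0 <= rec.info <= 1):
        return f"info must be in [0, 1], got {rec.info}"
    return None


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> tuple[list[SummaryStatRecord], list[RowError]]:
    """Parse a summary-statistics file into validated records.

    Parameters
    ----------
    path
        Tab-delimited text file (``.gz`` accepted) with a header row.
    column_map
        Maps canonical field names (keys of :data:`DEFAULT_COLUMNS`) to the
        header names actually present in the file.

    Returns
    -------
    records, errors
        One record per parseable row; malformed rows are reported with their
        1-based line number and skipped.

    Raises
    ------
    SumstatsError
        If a required column is missing from the header.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[SummaryStatRecord] = []
    errors: list[RowError] = []
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split(sep)
        idx: dict[str, int] = {}
        for field, colname in colmap.items():
            if colname not in header:
                raise SumstatsError(f"missing required column {colname!r} (field {field})")
            idx[field] = header.index(colname)

        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(sep)
            if len(parts) < len(header):
                errors.append(RowError(lineno, "too few fields"))
                continue
            try:
                rec = SummaryStatRecord(
                    chrom=_normalize_chrom(parts[idx["chrom"]]),
                    pos=int(parts[idx["pos"]]),
                    effect_allele=parts[idx["effect_allele"]].strip().upper(),
                    other_allele=parts[idx["other_allele"]].strip().upper(),
                    beta=float(parts[idx["beta"]]),
                    se=float(parts[idx["se"]]),
                    pvalue=float(parts[idx["pvalue"]]),
                    eaf=float(parts[idx["eaf"]]),
                    info=float(parts[idx["info"]]),
                )
            except ValueError as exc:
                errors.append(RowError(lineno, f"non-numeric field: {exc}"))
                continue
            msg = _validate_record(rec)
            if msg is not None:
                errors.append(RowError(lineno, msg))
                continue
            records.append(rec)
    return records, errors


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """True iff the allele pair is A/T or C/G (strand-undecidable)."""
    if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
        raise SumstatsError(f"alleles must be in {{A,C,G,T}}, got {a1}/{a2}")
    pair = frozenset((a1, a2))
    return pair == frozenset("AT") or pair == frozenset("CG")


def filter_sumstats(
    records: Sequence[SummaryStatRecord],
    info_min: float = 0.8,
    maf_min: float = 0.01,
) -> tuple[list[SummaryStatRecord], dict[str, int]]:
    """Apply the discovery-side variant filters.

    A record is kept iff ``info > info_min``, ``maf > maf_min`` (strict
    inequalities), the allele pair is not strand-ambiguous, and its
    (chrom, pos) appears exactly once among ``records``.  Excluded records
    are counted under the first failing rule in the fixed order
    multiallelic > ambiguous > info > maf.
    """
    pos_counts: dict[tuple[str, int], int] = {}
    for rec in records:
        pos_counts[rec.key] = pos_counts.get(rec.key, 0) + 1

    kept: list[SummaryStatRecord] = []
    counts = {rule: 0 for rule in EXCLUSION_RULES}
    for rec in records:
        if pos_counts[rec.key] > 1:
            counts["multiallelic"] += 1
        elif is_strand_ambiguous(rec.effect_allele, rec.other_allele):
            counts["ambiguous"] += 1
        elif not rec.info > info_min:
            counts["info"] += 1
        elif not rec.maf > maf_min:
            counts["maf"] += 1
        else:
            kept.append(rec)
    return kept, counts


def harmonize_weights(
    records: Sequence[SummaryStatRecord],
    target_variants: Iterable[tuple[str, int, str, str]],
) -> tuple[list[HarmonizedWeight], int]:
    """Align effect sizes to the target cohort's counted alleles.

    Parameters
    ----------
    records
        Filtered summary-statistic records.
    target_variants
        ``(chrom, pos, counted_allele, other_allele)`` tuples; biallelic and
        unique per position.

    Returns
    -------
    weights, n_mismatch
        One weight per record whose position and allele set match a target
        variant.  If the effect allele equals the counted allele the weight
        is ``beta``; if the alleles are swapped the weight is ``-beta`` with
        ``flipped=True``.  Allele-set mismatches are dropped and counted.

    Raises
    ------
    SumstatsError
        On a duplicate (chrom, pos) key among target variants.
    """
    target: dict[tuple[str, int], tuple[str, str]] = {}
    for chrom, pos, counted, other in target_variants:
        key = (str(chrom), int(pos))
        if key in target:
            raise SumstatsError(f"duplicate target variant at {key[0]}:{key[1]}")
        target[key] = (counted, other)

    weights: list[HarmonizedWeight] = []
    n_mismatch = 0
    for rec in records:
        alleles = target.get(rec.key)
        if alleles is None:
            continue
        counted, other = alleles
        if rec.effect_allele == counted and rec.other_allele == other:
            weights.append(
                HarmonizedWeight(rec.chrom, rec.pos, counted, other, rec.beta, False)
            )
        elif rec.effect_allele == other and rec.other_allele == counted:
            weights.append(
                HarmonizedWeight(rec.chrom, rec.pos, counted, other, -rec.beta, True)
            )
        else:
            n_mismatch += 1
    return weights, n_mismatch


def write_sumstats(records: Sequence[SummaryStatRecord], path: str | Path) -> None:
    """Write records as a canonical tab-delimited file."""
    cols = list(DEFAULT_COLUMNS)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    str(getattr(rec, c)) if c in ("chrom", "pos", "effect_allele", "other_allele")
                    else repr(getattr(rec, c))
                    for c in cols
                )
                + "\n"
            )


def write_qc_report(counts: Mapping[str, int], n_input: int, n_kept: int, path: str | Path) -> None:
    report = {
        "n_input": n_input,
        "n_kept": n_kept,
        "excluded": dict(counts),
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
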