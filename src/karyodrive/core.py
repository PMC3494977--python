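"""Karyotype records and arm arithmetic.

A mammalian karyotype is summarised here by four integers per sex — the
diploid chromosome number 2n and the fundamental (arm) number NF — plus the
fraction of autosomal complements that are acrocentric.  Chromosome shape
categories follow Levan's nomenclature collapsed to two arm classes:
metacentric and submetacentric chromosomes are *biarmed* (two arms each),
while subtelocentric, telocentric and acrocentric chromosomes are
*acrocentric* (one arm each).  Under that convention every chromosome
contributes one or two arms, so 2n <= NF <= 2*2n, and the acrocentric count
can be recovered from the pair (2n, NF) as 2*2n - NF.

The printed per-species acrocentric fraction is treated as the authoritative
analysis input; the (2n, NF) estimate is a diagnostic cross-check only,
because fundamental-number conventions differ between source papers (most
visibly in the genus Gazella, where NF was evidently scored with a different
arm convention).
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, asdict
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

SYSTEMS = ("X1X2Y", "XY1Y2", "simple")

#: Multiple-sex-chromosome systems that enter the comparative analysis.
ANALYSIS_SYSTEMS = ("X1X2Y", "XY1Y2")

TABLE_COLUMNS = (
    "order", "family", "genus", "species",
    "female_2n", "male_2n", "female_nf", "male_nf",
    "female_frac_acro", "male_frac_acro", "system", "source",
)

_INT_COLUMNS = ("female_2n", "male_2n", "female_nf", "male_nf")
_FRAC_COLUMNS = ("female_frac_acro", "male_frac_acro")

_SHAPE_TO_ARM_CLASS = {
    "metacentric": "biarmed",
    "submetacentric": "biarmed",
    "subtelocentric": "acrocentric",
    "telocentric": "acrocentric",
    "acrocentric": "acrocentric",
}


class KaryotypeError(ValueError):
    """Base class for karyotype-table errors."""


class SchemaError(KaryotypeError):
    """The input file does not match the documented column schema."""


class ValidationError(KaryotypeError):
    """One or more records violate a karyotype invariant."""


def species_key(genus: str, species: str) -> str:
    """Canonical tip label for a species: genus + epithet, non-alphanumeric
    runs collapsed to underscores (``("Aotus", "sp.")`` -> ``"Aotus_sp"``).

    The same rule names the tips of the packaged tree, so table rows and tree
    tips join on this key.
    """
    key = re.sub(r"[^A-Za-z0-9]+", "_", f"{genus} {species}")
    return key.strip("_")


@dataclass(frozen=True)
class KaryotypeRecord:
    """One species' cytogenetic summary."""

    order: str
    family: str
    genus: str
    species: str
    female_2n: int
    male_2n: int
    female_nf: int
    male_nf: int
    female_frac_acro: float
    male_frac_acro: float
    system: str
    source: str = ""

    @property
    def key(self) -> str:
        return species_key(self.genus, self.species)

    def frac_acro(self, sex: str = "female") -> float:
        if sex == "female":
            return self.female_frac_acro
        if sex == "male":
            return self.male_frac_acro
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")

    def validation_errors(self) -> list[str]:
        """Invariant violations for this record (empty list when valid)."""
        errs: list[str] = []
        for sex in ("female", "male"):
            two_n = getattr(self, f"{sex}_2n")
            nf = getattr(self, f"{sex}_nf")
            if two_n <= 0 or nf <= 0:
                errs.append(f"{self.key}: {sex} 2n and NF must be positive")
                continue
            if not (two_n <= nf <= 2 * two_n):
                errs.append(
                    f"{self.key}: {sex} arm-count bound violated: "
                    f"need 2n <= NF <= 2*2n, got 2n={two_n}, NF={nf}"
                )
            frac = getattr(self, f"{sex}_frac_acro")
            if not (0.0 <= frac <= 1.0):
                errs.append(f"{self.key}: {sex} acrocentric fraction {frac} outside [0, 1]")
        if self.system not in SYSTEMS:
            errs.append(f"{self.key}: unknown system {self.system!r}; expected one of {SYSTEMS}")
        return errs


def classify_shape(category: str) -> str:
    """Collapse a Levan shape category to its arm class.

    Metacentric and submetacentric chromosomes are biarmed; subtelocentric,
    telocentric and acrocentric chromosomes count as acrocentric.
    """
    arm_class = _SHAPE_TO_ARM_CLASS.get(str(category).strip().lower())
    if arm_class is None:
        raise ValueError(
            f"unrecognized chromosome shape {category!r}; accepted categories: "
            + ", ".join(sorted(_SHAPE_TO_ARM_CLASS))
        )
    return arm_class


def acrocentric_fraction_from_counts(n_acro: int, n_biarmed: int) -> float:
    """Fraction of acrocentric chromosomes from the two shape-class counts."""
    if n_acro < 0 or n_biarmed < 0:
        raise ValueError("chromosome counts must be non-negative")
    total = n_acro + n_biarmed
    if total == 0:
        raise ValueError("cannot compute a fraction from an empty karyotype (both counts zero)")
    return n_acro / total


def estimate_acrocentric_fraction(two_n: int, nf: int) -> float:
    """Estimate the acrocentric fraction from the diploid number and the
    fundamental number by arm accounting: acrocentrics = 2*2n - NF.
    """
    if two_n <= 0:
        raise ValueError("diploid number must be positive")
    if not (two_n <= nf <= 2 * two_n):
        raise ValueError(
            f"arm-count inequality 2n <= NF <= 2*2n violated: 2n={two_n}, NF={nf}"
        )
    return (2 * two_n - nf) / two_n


def printed_fraction_matches(printed: float, exact: float, tol: float = 0.005) -> bool:
    """Whether a 2-decimal printed fraction is consistent with an exact value.

    Accepts either round-half-up agreement within ``tol`` or truncation
    (floor at two decimals) — both conventions occur in published tables.
    """
    if abs(printed - exact) <= tol:
        return True
    truncated = float(Fraction(int(exact * 100), 100))
    return abs(printed - truncated) < 1e-9


@dataclass(frozen=True)
class AuditRow:
    """Consistency check between a record's printed fraction and its
    (2n, NF) arm-arithmetic estimate."""

    key: str
    printed_fraction: float
    estimated_fraction: float
    deviation: float
    flagged: bool


def audit_table(records: Sequence[KaryotypeRecord], threshold: float = 0.02) -> list[AuditRow]:
    """Cross-check every record's printed female fraction against the
    estimate from (female 2n, female NF); flag deviations above *threshold*.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    rows = []
    for rec in records:
        est = estimate_acrocentric_fraction(rec.female_2n, rec.female_nf)
        dev = abs(rec.female_frac_acro - est)
        rows.append(AuditRow(rec.key, rec.female_frac_acro, est, dev, dev > threshold))
    n_flagged = sum(r.flagged for r in rows)
    logger.info("audit: %d/%d records deviate from arm arithmetic by more than %.3f",
                n_flagged, len(rows), threshold)
    return rows


def load_karyotype_table(path: str | Path, strict: bool = True) -> list[KaryotypeRecord]:
    """Read a tab-separated karyotype table into records.

    The header must match the documented schema exactly.  In strict mode any
    invariant violation raises :class:`ValidationError` listing the offending
    rows; in permissive mode violations are logged and the rows kept.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = tuple(reader.fieldnames or ())
        missing = [c for c in TABLE_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        records: list[KaryotypeRecord] = []
        problems: list[str] = []
        seen: set[tuple[str, str, str]] = set()
        for lineno, row in enumerate(reader, start=2):
            kwargs = {c: (row[c] or "").strip() for c in TABLE_COLUMNS}
            try:
                for c in _INT_COLUMNS:
                    kwargs[c] = int(kwargs[c])
                for c in _FRAC_COLUMNS:
                    kwargs[c] = float(kwargs[c])
            except ValueError as exc:
                raise KaryotypeError(f"{path}: row {lineno}: non-numeric cell ({exc})") from None
            rec = KaryotypeRecord(**kwargs)
            ident = (rec.genus, rec.species, rec.system)
            if ident in seen:
                problems.append(f"row {lineno}: duplicate (genus, species, system) {ident}")
            seen.add(ident)
            problems.extend(f"row {lineno}: {msg}" for msg in rec.validation_errors())
            records.append(rec)
    if problems:
        if strict:
            raise ValidationError(f"{path}: " + "; ".join(problems))
        for msg in problems:
            logger.warning("%s: %s", path, msg)
    counts = system_counts(records)
    if not records:
        logger.warning("%s: table contains a header but no data rows", path)
    else:
        logger.info("loaded %d records from %s: %s", len(records), path,
                    ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
    return records


def system_counts(records: Iterable[KaryotypeRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.system] = counts.get(rec.system, 0) + 1
    return counts


def write_karyotype_table(records: Sequence[KaryotypeRecord], path: str | Path) -> None:
    """Write records back to the tab-separated schema (round-trip safe)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TABLE_COLUMNS)
        for rec in records:
            d = asdict(rec)
            writer.writerow([d[c] for c in TABLE_COLUMNS])


def write_audit_report(rows: Sequence[AuditRow], tsv_path: str | Path | None = None,
                       json_path: str | Path | None = None) -> None:
    if tsv_path is not None:
        with Path(tsv_path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["key", "printed_fraction", "estimated_fraction", "deviation", "flagged"])
            for r in rows:
                writer.writerow([r.key, r.printed_fraction, f"{r.estimated_fraction:.6f}",
                                 f"{r.deviation:.6f}", int(r.flagged)])
    if json_path is not None:
        payload = [asdict(r) for r in rows]
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                                   encoding="utf-8")


__all__ = [
    "KaryotypeRecord", "AuditRow", "KaryotypeError", "SchemaError", "ValidationError",
    "SYSTEMS", "ANALYSIS_SYSTEMS", "TABLE_COLUMNS",
    "species_key", "classify_shape", "acrocentric_fraction_from_counts",
    "estimate_acrocentric_fraction", "printed_fraction_matches",
    "audit_table", "load_karyotype_table", "write_karyotype_table",
    "write_audit_report", "system_counts",
]
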