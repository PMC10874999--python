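"""GWAS summary-statistics tables and auxiliary files.

This module holds the data model shared by the whole package: per-SNP
association records (effect allele, beta, SE, p-value, frequency, sample
size), datasets of such records for one trait, and the sparse long-format
linkage-disequilibrium (LD) table used by clumping.  Files are plain
tab-separated text with a header row; column names are resolved through an
explicit ``column_map`` so exports from different GWAS portals can be read
without guessing dialects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical column order used by :func:`write_sumstats`
CANONICAL_COLUMNS = (
    "snp",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "ncase",
    "ncontrol",
)

#: default file-column names for each canonical field
DEFAULT_COLUMN_MAP: dict[str, str] = {name: name for name in CANONICAL_COLUMNS}

_REQUIRED = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")


@dataclass
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` (log odds for
    binary traits).  Positions are 1-based.  Optional fields default to
    ``None`` when the source file does not carry them.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None
    n_case: float | None = None
    n_control: float | None = None

    def invariant_errors(self) -> list[str]:
        """Hard-invariant violations; non-empty means the record is invalid."""
        errors = []
        ea, oa = self.effect_allele, self.other_allele
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            errors.append(f"alleles must be single nucleotides A/C/G/T, got {ea!r}/{oa!r}")
        elif ea == oa:
            errors.append(f"effect and other allele identical ({ea})")
        if not (self.se > 0):
            errors.append(f"se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            errors.append(f"pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            errors.append(f"eaf must be in (0, 1), got {self.eaf}")
        return errors

    def consistency_warnings(self) -> list[str]:
        """Soft checks: reported p should roughly match the z-derived p."""
        warnings_ = []
        if self.se > 0 and 0 < self.pval <= 1:
            p_z = 2.0 * stats.norm.sf(abs(self.beta / self.se))
            if p_z > 0 and not (p_z / 10 <= self.pval <= min(1.0, p_z * 10)):
                warnings_.append(
                    f"{self.snp_id}: reported p={self.pval:.3g} differs from "
                    f"|beta/se| normal p={p_z:.3g} by more than a factor of 10"
                )
        return warnings_


@dataclass
class SummaryDataset:
    """An ordered collection of :class:`SummaryStatRecord` for one trait."""

    trait_label: str
    trait_type: str  # "binary" | "continuous"
    records: list[SummaryStatRecord] = field(default_factory=list)
    n_default: float | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def get(self, snp_id: str) -> SummaryStatRecord | None:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        return None

    def sample_size(self, record: SummaryStatRecord) -> float | None:
        """Per-SNP n, falling back to the dataset default."""
        if record.n is not None:
            return record.n
        if record.n_case is not None and record.n_control is not None:
            return record.n_case + record.n_control
        return self.n_default

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp": r.snp_id,
                "chr": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
                "ncase": r.n_case,
                "ncontrol": r.n_control,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass
class LoadReport:
    """Row-level outcome of parsing a summary-statistics file."""

    n_rows: int = 0
    n_kept: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (1-based data row, reason)
    warnings: list[str] = field(default_factory=list)

    @property
    def rejected_rows(self) -> list[int]:
        return [row for row, _ in self.rejected]


class ColumnMapError(KeyError):
    """A required column could not be resolved in the input file."""


class LDTable:
    """Sparse symmetric r-squared lookup.

    Pairs absent from the table are treated as unlinked (r2 = 0); the
    diagonal is 1 by definition.
    """

    def __init__(self, entries: Iterable[tuple[str, str, float]] = ()):
        self._r2: dict[frozenset[str], float] = {}
        for a, b, r2 in entries:
            self.add(a, b, r2)

    def add(self, snp_a: str, snp_b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0, 1], got {r2} for ({snp_a}, {snp_b})")
        if snp_a != snp_b:
            self._r2[frozenset((snp_a, snp_b))] = r2

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self._r2.get(frozenset((snp_a, snp_b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)


def _resolve_columns(header: Sequence[str], column_map: Mapping[str, str]) -> dict[str, str]:
    resolved = {}
    for canonical, file_col in column_map.items():
        if file_col in header:
            resolved[canonical] = file_col
    for canonical in _REQUIRED:
        if canonical not in resolved:
            raise ColumnMapError(
                f"required column {canonical!r} (mapped to "
                f"{column_map.get(canonical, canonical)!r}) not found in header {list(header)}"
            )
    return resolved


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "binary",
    trait_label: str | None = None,
    n_default: float | None = None,
) -> tuple[SummaryDataset, LoadReport]:
    """Parse a tab-separated summary-statistics file.

    Rows violating hard invariants (bad alleles, se <= 0, p outside (0,1],
    eaf outside (0,1), unparseable numerics) are rejected and recorded in
    the returned :class:`LoadReport` with their 1-based data-row numbers.
    Alleles are uppercased.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    resolved = _resolve_columns(frame.columns, cmap)

    report = LoadReport(n_rows=len(frame))
    records: list[SummaryStatRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        raw = dict(zip(frame.columns, row))
        try:
            rec = SummaryStatRecord(
                snp_id=str(raw[resolved["snp"]]).strip(),
                effect_allele=str(raw[resolved["effect_allele"]]).strip().upper(),
                other_allele=str(raw[resolved["other_allele"]]).strip().upper(),
                beta=float(raw[resolved["beta"]]),
                se=float(raw[resolved["se"]]),
                pval=float(raw[resolved["pval"]]),
                chrom=str(raw[resolved["chr"]]) if "chr" in resolved and raw[resolved["chr"]] != "" else None,
                pos=int(float(raw[resolved["pos"]])) if "pos" in resolved and raw[resolved["pos"]] != "" else None,
                eaf=_opt_float(raw.get(resolved.get("eaf", ""), None)) if "eaf" in resolved else None,
                n=_opt_float(raw.get(resolved.get("n", ""), None)) if "n" in resolved else None,
                n_case=_opt_float(raw.get(resolved.get("ncase", ""), None)) if "ncase" in resolved else None,
                n_control=_opt_float(raw.get(resolved.get("ncontrol", ""), None)) if "ncontrol" in resolved else None,
            )
        except (TypeError, ValueError) as exc:
            report.rejected.append((i, f"unparseable numeric field: {exc}"))
            continue
        errors = rec.invariant_errors()
        if errors:
            report.rejected.append((i, "; ".join(errors)))
            continue
        report.warnings.extend(rec.consistency_warnings())
        records.append(rec)
    report.n_kept = len(records)
    dataset = SummaryDataset(
        trait_label=trait_label or str(path),
        trait_type=trait_type,
        records=records,
        n_default=n_default,
    )
    return dataset, report


def write_sumstats(dataset: SummaryDataset, path) -> None:
    """Write the canonical tab-separated layout (read/write round-trips)."""
    frame = dataset.to_frame()
    # drop optional columns that are entirely absent, keep required ones
    keep = [c for c in CANONICAL_COLUMNS if c in _REQUIRED or frame[c].notna().any()]
    frame[keep].to_csv(path, sep="\t", index=False, na_rep="")


def dedup_records(dataset: SummaryDataset) -> SummaryDataset:
    """Keep one record per snp_id: smallest p-value, ties to first occurrence."""
    best: dict[str, SummaryStatRecord] = {}
    order: list[str] = []
    for rec in dataset.records:
        if rec.snp_id not in best:
            best[rec.snp_id] = rec
            order.append(rec.snp_id)
        elif rec.pval < best[rec.snp_id].pval:
            best[rec.snp_id] = rec
    n_removed = len(dataset.records) - len(order)
    if n_removed:
        logger.info("dedup_records: removed %d duplicate record(s)", n_removed)
    return replace(dataset, records=[best[s] for s in order])


def read_ld_table(path) -> tuple[LDTable, LoadReport]:
    """Read a long-format LD file (snp_a, snp_b, r2); bad rows are rejected."""
    table = LDTable()
    report = LoadReport()
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.shape[1] < 3:
        raise ValueError(f"LD table {path} must have columns snp_a, snp_b, r2")
    report.n_rows = len(frame)
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        a, b, raw_r2 = str(row[0]), str(row[1]), row[2]
        try:
            table.add(a, b, float(raw_r2))
        except ValueError as exc:
            report.rejected.append((i, str(exc)))
            continue
        report.n_kept += 1
    return table, report


def read_blocklist(path) -> set[str]:
    """Read a plain-text SNP blocklist, one id per line, '#' comments allowed."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                ids.add(entry)
    return ids
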