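"""Instrument selection from exposure summary statistics.

Valid instrumental variables must associate with the exposure at
genome-wide significance, be mutually independent (LD clumping), be strong
(F-statistic filter), and not act through known confounders (blocklist).
Every stage returns both the surviving dataset and a QC log whose per-SNP
dispositions partition the stage input exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from collections import Counter

from .sumstats import LDTable, SummaryDataset, SummaryStatRecord

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DEFAULT_WINDOW_KB = 10_000.0
DEFAULT_R2_MAX = 0.001
DEFAULT_F_MIN = 10.0


@dataclass
class ClumpSpec:
    """Significance and LD-independence thresholds for instrument selection."""

    p_threshold: float = GENOME_WIDE_P
    window_kb: float = DEFAULT_WINDOW_KB
    r2_max: float = DEFAULT_R2_MAX

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        if self.window_kb <= 0:
            raise ValueError(f"window_kb must be > 0, got {self.window_kb}")
        if not (0 <= self.r2_max <= 1):
            raise ValueError(f"r2_max must be in [0, 1], got {self.r2_max}")


@dataclass
class InstrumentQCLog:
    """Per-SNP disposition after one selection stage."""

    dispositions: dict[str, str] = field(default_factory=dict)

    def record(self, snp_id: str, disposition: str) -> None:
        self.dispositions[snp_id] = disposition

    def counts(self) -> dict[str, int]:
        return dict(Counter(self.dispositions.values()))

    def retained_ids(self) -> list[str]:
        return [s for s, d in self.dispositions.items() if d == "retained"]

    def dropped_ids(self) -> list[str]:
        return [s for s, d in self.dispositions.items() if d != "retained"]


def select_by_pvalue(dataset: SummaryDataset, p_threshold: float = GENOME_WIDE_P) -> SummaryDataset:
    """Keep records with pval strictly below the threshold."""
    kept = [r for r in dataset.records if r.pval < p_threshold]
    if not kept:
        warnings.warn(
            f"no SNPs reach p < {p_threshold:g} in {dataset.trait_label}; "
            "instrument set is empty",
            stacklevel=2,
        )
    return replace(dataset, records=kept)


def _clump_sort_key(rec: SummaryStatRecord):
    # smallest p wins; ties broken by position (missing last), then id
    pos = rec.pos if rec.pos is not None else float("inf")
    return (rec.pval, pos, rec.snp_id)


def _in_window(a: SummaryStatRecord, b: SummaryStatRecord, window_kb: float) -> bool:
    chrom_a = a.chrom if a.chrom is not None else "unknown"
    chrom_b = b.chrom if b.chrom is not None else "unknown"
    if chrom_a != chrom_b:
        return False
    if a.pos is None or b.pos is None:
        # positionless fallback: window treated as infinite within chromosome
        return True
    return abs(a.pos - b.pos) <= window_kb * 1000.0


def greedy_clump(
    dataset: SummaryDataset,
    ld: LDTable,
    spec: ClumpSpec | None = None,
) -> tuple[SummaryDataset, InstrumentQCLog]:
    """Greedy p-value-ordered LD clumping.

    Repeatedly takes the most significant remaining record as an index SNP
    and drops every other record on the same chromosome within
    ``window_kb`` whose r2 with the index exceeds ``r2_max``.
    """
    spec = spec or ClumpSpec()
    if any(r.pos is None or r.chrom is None for r in dataset.records):
        warnings.warn(
            "records without chrom/pos present: clump window treated as infinite "
            "for those records (LD-only exclusion)",
            stacklevel=2,
        )
    log = InstrumentQCLog()
    remaining = sorted(dataset.records, key=_clump_sort_key)
    kept_ids: set[str] = set()
    while remaining:
        index = remaining.pop(0)
        log.record(index.snp_id, "retained")
        kept_ids.add(index.snp_id)
        survivors = []
        for rec in remaining:
            if _in_window(index, rec, spec.window_kb) and ld.r2(index.snp_id, rec.snp_id) > spec.r2_max:
                log.record(rec.snp_id, f"dropped_clump({index.snp_id})")
            else:
                survivors.append(rec)
        remaining = survivors
    kept = [r for r in dataset.records if r.snp_id in kept_ids]
    return replace(dataset, records=kept), log


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F = beta^2 / se^2."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def filter_weak(dataset: SummaryDataset, f_min: float = DEFAULT_F_MIN) -> tuple[SummaryDataset, InstrumentQCLog]:
    """Drop weak instruments: records with F strictly below ``f_min``."""
    log = InstrumentQCLog()
    kept = []
    for rec in dataset.records:
        if f_statistic(rec.beta, rec.se) >= f_min:
            log.record(rec.snp_id, "retained")
            kept.append(rec)
        else:
            log.record(rec.snp_id, "dropped_weak_F")
    return replace(dataset, records=kept), log


def apply_blocklist(dataset: SummaryDataset, blocklist: set[str]) -> tuple[SummaryDataset, InstrumentQCLog]:
    """Remove SNPs listed as confounder-associated."""
    log = InstrumentQCLog()
    kept = []
    for rec in dataset.records:
        if rec.snp_id in blocklist:
            log.record(rec.snp_id, "dropped_blocklist")
        else:
            log.record(rec.snp_id, "retained")
            kept.append(rec)
    if dataset.records and not kept:
        warnings.warn("blocklist removed every instrument", stacklevel=2)
    return replace(dataset, records=kept), log
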