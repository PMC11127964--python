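"""Pol V transcript calling from RIP-seq reads.

Stage order mirrors the wet pipeline: UMI extraction -> adapter trimming
-> (external alignment) -> UMI deduplication -> background subtraction
against the nrpe1 control -> assignment to NRPE1 peaks.  Every stage
reports survivor counts so the filter narrative is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genome import AlignedRead, Peak

DEFAULT_UMI_LENGTH = 8
DEFAULT_FIVE_PRIME_TAG = "TATAGGG"
DEFAULT_MIN_LENGTH = 10


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty read sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length != sequence length")


@dataclass(frozen=True)
class ProcessedRead:
    id: str
    umi: str
    sequence: str


@dataclass
class StageReport:
    """Ordered per-stage counters; survivors + discards sum to the input."""

    counters: "dict[str, int]" = field(default_factory=dict)

    def add(self, stage: str, n: int = 1) -> None:
        self.counters[stage] = self.counters.get(stage, 0) + n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.counters.items()), columns=["stage", "count"]
        )


def extract_umi(
    read: RawRead, umi_length: int = DEFAULT_UMI_LENGTH
) -> Optional[ProcessedRead]:
    """Split off the leading UMI and append it to the read id.

    Returns None (discard) when nothing would remain after the UMI.
    """
    if len(read.sequence) <= umi_length:
        return None
    umi = read.sequence[:umi_length]
    return ProcessedRead(f"{read.id}_{umi}", umi, read.sequence[umi_length:])


def _matches_tag(seq: str, tag: str, max_mismatch: int) -> bool:
    if len(seq) < len(tag):
        return False
    mismatches = sum(a != b for a, b in zip(seq, tag))
    return mismatches <= max_mismatch


def _strip_polya(seq: str) -> str:
    """Remove a maximal trailing run of >=3 A's allowing one non-A interruption."""
    i = len(seq)
    interruptions = 0
    last_good = len(seq)
    while i > 0:
        if seq[i - 1] == "A":
            i -= 1
            last_good = i
        elif interruptions == 0 and i - 1 > 0 and seq[i - 2] == "A":
            interruptions += 1
            i -= 1
        else:
            break
    if seq[last_good:].count("A") >= 3:
        return seq[:last_good]
    return seq


def trim_read(
    read: ProcessedRead,
    five_prime_tag: str = DEFAULT_FIVE_PRIME_TAG,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_tag_mismatch: int = 1,
) -> Optional[ProcessedRead]:
    """Remove one leading 5' tag occurrence and the trailing poly(A).

    The tag match tolerates ``max_tag_mismatch`` mismatches (0 for exact
    matching only).  Reads shorter than ``min_length`` after trimming are
    discarded (None).
    """
    seq = read.sequence
    if five_prime_tag and _matches_tag(seq, five_prime_tag, max_tag_mismatch):
        seq = seq[len(five_prime_tag):]
    seq = _strip_polya(seq)
    if len(seq) < min_length:
        return None
    return ProcessedRead(read.id, read.umi, seq)


def process_raw_reads(
    reads: Sequence[RawRead],
    umi_length: int = DEFAULT_UMI_LENGTH,
    five_prime_tag: str = DEFAULT_FIVE_PRIME_TAG,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_tag_mismatch: int = 1,
) -> Tuple[List[ProcessedRead], StageReport]:
    """UMI extraction + trimming over a read collection, with counters."""
    report = StageReport()
    report.add("input", len(reads))
    out = []
    for r in reads:
        p = extract_umi(r, umi_length)
        if p is None:
            report.add("discarded_too_short_for_umi")
            continue
        t = trim_read(p, five_prime_tag, min_length, max_tag_mismatch)
        if t is None:
            report.add("discarded_below_min_length")
            continue
        out.append(t)
    report.add("surviving", len(out))
    return out, report


def deduplicate(
    reads: Sequence[AlignedRead],
) -> Tuple[List[AlignedRead], int]:
    """Collapse PCR duplicates on (chrom, 5'-end position, strand, UMI).

    Keeps the first read of each group in input order; returns survivors
    and the number removed.  Idempotent.
    """
    seen = set()
    out = []
    removed = 0
    for r in reads:
        if r.umi is None:
            raise ValueError(f"read {r.name!r} lacks a UMI")
        key = (r.chrom, r.five_prime, r.strand, r.umi)
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            out.append(r)
    return out, removed


def subtract_background(
    ip_reads: Sequence[AlignedRead],
    control_reads: Sequence[AlignedRead],
    strand_aware: bool = True,
) -> List[AlignedRead]:
    """Drop IP reads that overlap (>=1 bp) any control read.

    Strand-aware by default (Pol V transcripts are stranded); pass
    ``strand_aware=False`` for strand-blind intersection.  Input order of
    the survivors is preserved.
    """
    trees: dict = {}
    for c in control_reads:
        key = (c.chrom, c.strand) if strand_aware else c.chrom
        trees.setdefault(key, IntervalTree()).addi(c.start, c.end)
    out = []
    for r in ip_reads:
        key = (r.chrom, r.strand) if strand_aware else r.chrom
        tree = trees.get(key)
        if tree is None or not tree.overlap(r.start, r.end):
            out.append(r)
    return out


@dataclass
class TranscriptSet:
    """Reads surviving all filters, their per-peak counts, library total.

    A read spanning several peaks is retained once in ``reads`` but
    increments each overlapped peak's count, so both marginal totals are
    preserved.
    """

    reads: List[AlignedRead]
    counts: pd.DataFrame  # peak_id, count
    total_mapped: int
    by_peak: Dict[str, List[int]] = field(default_factory=dict)
    n_dropped: int = 0

    def peak_sequences(self) -> Dict[str, List[str]]:
        """Read sequences grouped by peak (transcript orientation)."""
        return {
            pid: [self.reads[i].sequence for i in idx if self.reads[i].sequence]
            for pid, idx in self.by_peak.items()
        }


def assign_to_peaks(
    reads: Sequence[AlignedRead],
    peaks: Sequence[Peak],
    total_mapped: Optional[int] = None,
) -> TranscriptSet:
    """Retain reads overlapping >=1 peak; count once per overlapped peak.

    ``total_mapped`` defaults to the input read count and is the
    denominator for RPM normalization.
    """
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p.id)
    kept: List[AlignedRead] = []
    by_peak: Dict[str, List[int]] = {p.id: [] for p in peaks}
    dropped = 0
    for r in reads:
        tree = trees.get(r.chrom)
        hits = tree.overlap(r.start, r.end) if tree is not None else set()
        if not hits:
            dropped += 1
            continue
        idx = len(kept)
        kept.append(r)
        for h in sorted(hits, key=lambda iv: iv.data):
            by_peak[h.data].append(idx)
    counts = pd.DataFrame(
        {"peak_id": [p.id for p in peaks], "count": [len(by_peak[p.id]) for p in peaks]}
    )
    return TranscriptSet(
        kept,
        counts,
        total_mapped if total_mapped is not None else len(reads),
        by_peak,
        dropped,
    )


def normalize_abundance(ts: TranscriptSet) -> pd.DataFrame:
    """Per-peak reads-per-million: count * 1e6 / total mapped reads."""
    if ts.total_mapped <= 0:
        raise ValueError("library total must be positive")
    out = ts.counts.copy()
    out["rpm"] = out["count"] * 1e6 / ts.total_mapped
    return out


def rank_sum_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> Tuple[float, float]:
    """Unpaired Wilcoxon rank-sum (Mann-Whitney U), two-sided.

    Exact null enumeration when min(n) <= 10 and there are no ties,
    normal approximation with tie and continuity correction otherwise.
    Identical samples return p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2), 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def read_length_distribution(ts: TranscriptSet) -> Tuple[np.ndarray, dict]:
    """Retained-read length multiset with median/quartile summary."""
    if not ts.reads:
        raise ValueError("empty transcript set")
    lengths = np.array([r.length for r in ts.reads])
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    return lengths, {"median": float(med), "q1": float(q1), "q3": float(q3),
                     "n": int(len(lengths))}
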