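"""AGO4 slicing signature: uridine at transcript position 10 (U-10).

AGO4-sliced Pol V transcripts carry a uridine at position 10 from the 5'
end.  This module tallies per-peak U-10 ratios (U counted as T in
DNA-space sequences, which must be in transcript orientation), stratifies
peaks into quantile groups by a reference (GRO-seq-derived) ratio, and
builds a within-peak shuffle null that preserves read lengths, strands
and local base composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import AlignedRead, Peak

U10_POSITION = 10
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def base_frequency(
    sequences: Sequence[str], max_position: int = 20
) -> pd.DataFrame:
    """Per-position base frequencies from the 5' end of the reads.

    Position p (1-based) counts every read of length >= p; frequencies are
    normalized per position.  Returns columns A, C, G, T plus ``support``.
    """
    if not sequences:
        raise ValueError("no reads")
    counts = np.zeros((max_position, 4))
    support = np.zeros(max_position, dtype=int)
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for seq in sequences:
        upto = min(len(seq), max_position)
        support[:upto] += 1
        for p in range(upto):
            i = index.get(seq[p])
            if i is not None:
                counts[p, i] += 1
    with np.errstate(invalid="ignore"):
        freqs = counts / np.where(support > 0, support, 1)[:, None]
    df = pd.DataFrame(freqs, columns=["A", "C", "G", "T"])
    df.insert(0, "position", np.arange(1, max_position + 1))
    df["support"] = support
    return df


def u10_stats(
    peak_sequences: Mapping[str, Sequence[str]],
    position: int = U10_POSITION,
) -> pd.DataFrame:
    """Per-peak U-10 statistics from transcript-orientation sequences.

    ``n_reads`` counts reads of length >= position; ``n_u10`` those whose
    1-based ``position``-th base is T.  Peaks with no eligible read get an
    undefined (NaN) ratio.
    """
    if position < 1:
        raise ValueError("position must be >= 1")
    rows = []
    for pid in sorted(peak_sequences):
        seqs = peak_sequences[pid]
        eligible = [s for s in seqs if len(s) >= position]
        n_u10 = sum(1 for s in eligible if s[position - 1] == "T")
        n = len(eligible)
        rows.append((pid, n, n_u10, n_u10 / n if n else np.nan))
    return pd.DataFrame(rows, columns=["peak_id", "n_reads", "n_u10", "ratio"])


@dataclass
class PeakGroups:
    """Quantile stratification of peaks by the reference U-10 ratio."""

    assignment: Dict[str, int]  # peak_id -> group in 1..n_groups
    boundaries: List[float]  # reference-ratio range edges per group
    excluded: List[Tuple[str, str]]  # (peak_id, reason)

    @property
    def n_groups(self) -> int:
        return max(self.assignment.values()) if self.assignment else 0

    def peaks_in(self, group: int) -> List[str]:
        return sorted(p for p, g in self.assignment.items() if g == group)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["peak_id", "group"]
        )


def group_peaks(
    reference_stats: pd.DataFrame,
    query_stats: pd.DataFrame,
    n_groups: int = 4,
    min_reads: int = 10,
    filter_mode: str = "both",
) -> PeakGroups:
    """Split peaks into equal-size groups by reference U-10 ratio rank.

    Low-coverage peaks are excluded first: with ``filter_mode='both'``
    (default) a peak must reach ``min_reads`` in BOTH the reference and the
    query set; ``'any'`` excludes only peaks below ``min_reads`` in both.
    Retained peaks are ranked by reference ratio (ties by peak id) and cut
    into ``n_groups`` groups whose sizes differ by at most one, group 1
    holding the lowest ratios.
    """
    if filter_mode not in ("both", "any"):
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    ref = reference_stats.set_index("peak_id")
    qry = query_stats.set_index("peak_id")
    universe = sorted(set(ref.index) | set(qry.index))
    excluded = []
    retained = []
    for pid in universe:
        n_ref = int(ref["n_reads"].get(pid, 0))
        n_qry = int(qry["n_reads"].get(pid, 0))
        low_ref, low_qry = n_ref < min_reads, n_qry < min_reads
        drop = (low_ref or low_qry) if filter_mode == "both" else (low_ref and low_qry)
        if drop:
            excluded.append(
                (pid, f"reference n={n_ref}, query n={n_qry} (min {min_reads})")
            )
        else:
            retained.append(pid)
    if len(retained) < n_groups:
        raise ValueError(
            f"{len(retained)} retained peaks < {n_groups} groups"
        )
    ranked = sorted(retained, key=lambda p: (float(ref.loc[p, "ratio"]), p))
    chunks = np.array_split(ranked, n_groups)
    assignment = {}
    boundaries = []
    for g, chunk in enumerate(chunks, start=1):
        for pid in chunk:
            assignment[pid] = g
        ratios = [float(ref.loc[p, "ratio"]) for p in chunk]
        boundaries.append((min(ratios), max(ratios)))
    return PeakGroups(assignment, boundaries, excluded)


def shuffle_within_peak(
    reads: Sequence[AlignedRead],
    peak: Peak,
    genome_sequences: Mapping[str, str],
    n_shuffles: int = 3,
    seed: int = 0,
) -> Tuple[List[List[AlignedRead]], int]:
    """Reposition each read uniformly at random inside its peak, n times.

    Lengths and strands are preserved; the shuffled sequence is
    re-extracted from the genome (reverse-complemented on the minus
    strand) so the null reflects local base composition.  Reads longer
    than the peak are kept in place and counted as unshufflable.
    """
    rng = np.random.default_rng(seed)
    chrom_seq = genome_sequences[peak.chrom]
    unshufflable = 0
    replicates: List[List[AlignedRead]] = []
    for _ in range(n_shuffles):
        shuffled = []
        for r in reads:
            max_start = peak.end - r.length
            if max_start < peak.start:
                shuffled.append(r)
                unshufflable += 1
                continue
            s = int(rng.integers(peak.start, max_start + 1))
            seq = chrom_seq[s : s + r.length]
            if r.strand == "-":
                seq = reverse_complement(seq)
            shuffled.append(
                AlignedRead(
                    r.chrom, s, s + r.length, r.strand, name=r.name, umi=r.umi,
                    sequence=seq,
                )
            )
        replicates.append(shuffled)
    return replicates, unshufflable


def eligible_t_frequency(
    peak: Peak,
    read_lengths: Sequence[int],
    strands: Sequence[str],
    genome_sequences: Mapping[str, str],
    position: int = U10_POSITION,
) -> float:
    """Expected shuffle-null U-10 ratio of a peak.

    For each read, the frequency of T (strand-adjusted) over the genomic
    positions that could be its ``position``-th base under a uniform
    in-peak placement; averaged over reads of length >= position.
    """
    chrom_seq = genome_sequences[peak.chrom]
    per_read = []
    for length, strand in zip(read_lengths, strands):
        if length < position or length > peak.length:
            continue
        if strand != "-":
            lo = peak.start + position - 1
            hi = peak.end - length + position - 1
            window = chrom_seq[lo : hi + 1]
            hits = window.count("T")
        else:
            # 10th base of a minus read ending at e is genome base e-position,
            # read base = complement -> count A
            lo = peak.start + length - position
            hi = peak.end - position
            window = chrom_seq[lo : hi + 1]
            hits = window.count("A")
        per_read.append(hits / len(window))
    if not per_read:
        raise ValueError("no eligible reads")
    return float(np.mean(per_read))


def group_u10_summary(
    groups: PeakGroups,
    stats_by_sample: Mapping[str, object],
) -> pd.DataFrame:
    """Mean per-peak U-10 ratio for every (group, sample).

    A sample given as a list of stat frames (shuffle replicates) is first
    averaged per peak across replicates.  Groups whose peaks all lack a
    defined ratio in a sample are flagged with a NaN mean.
    """
    per_sample_ratio: Dict[str, pd.Series] = {}
    for sample, stats_obj in stats_by_sample.items():
        if isinstance(stats_obj, (list, tuple)):
            frames = [s.set_index("peak_id")["ratio"] for s in stats_obj]
            per_sample_ratio[sample] = pd.concat(frames, axis=1).mean(axis=1)
        else:
            per_sample_ratio[sample] = stats_obj.set_index("peak_id")["ratio"]
    rows = []
    for g in range(1, groups.n_groups + 1):
        peaks = groups.peaks_in(g)
        for sample, ratios in per_sample_ratio.items():
            vals = ratios.reindex(peaks).dropna()
            rows.append((g, sample, float(vals.mean()) if len(vals) else np.nan,
                         len(vals)))
    return pd.DataFrame(rows, columns=["group", "sample", "mean_ratio", "n_peaks"])
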