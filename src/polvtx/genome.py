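"""Coordinate system, interval types, coverage and region arithmetic.

All coordinates are 0-based half-open (BED convention) internally.  GFF3
input is converted on read.  Strand is one of ``'+'``, ``'-'`` or ``'.'``
(unstranded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """An interval or record violates the coordinate contract."""


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names with their lengths in bp."""

    lengths: Mapping[str, int]

    def __post_init__(self):
        names = list(self.lengths)
        if len(names) != len(set(names)):
            raise ValidationError("duplicate chromosome names")
        for name, length in self.lengths.items():
            if int(length) <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length")
        object.__setattr__(self, "lengths", dict(self.lengths))

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"bad coordinates {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        # midpoint convention used by all distance profiles
        return (self.start + self.end) // 2

    def validate(self, genome: GenomeIndex) -> "Interval":
        if self.chrom not in genome:
            raise ValidationError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome[self.chrom]:
            raise ValidationError(
                f"{self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {genome[self.chrom]}"
            )
        return self

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A named (optionally scored) genomic interval, e.g. an NRPE1 peak."""

    chrom: str
    start: int
    end: int
    id: str
    score: Optional[float] = None
    strand: str = "."

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedRead:
    """An aligned read interval, optionally carrying a UMI and its sequence.

    ``sequence`` is in read (transcript) orientation, 5'->3'; for minus-strand
    reads it is therefore the reverse complement of the genome slice.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    umi: Optional[str] = None
    sequence: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad read coordinates {self.start}-{self.end}")
        if self.sequence is not None and len(self.sequence) != self.end - self.start:
            raise ValidationError(
                f"sequence length {len(self.sequence)} != span {self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """0-based genomic coordinate of the 5' end base."""
        return self.start if self.strand != "-" else self.end - 1

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)


@dataclass
class BinnedTrack:
    """Fixed-width binned signal, one non-negative vector per chromosome.

    The last bin of each chromosome may be shorter than ``bin_size``.
    """

    bin_size: int
    values: Mapping[str, np.ndarray]
    genome: GenomeIndex

    def __post_init__(self):
        for chrom, vec in self.values.items():
            expected = n_bins(self.genome[chrom], self.bin_size)
            if len(vec) != expected:
                raise ValidationError(
                    f"{chrom}: {len(vec)} bins, expected {expected}"
                )
            if not np.all(np.isfinite(vec)) or np.any(vec < 0):
                raise ValidationError(f"{chrom}: non-finite or negative values")

    def flat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.genome.names])

    def bin_lengths(self) -> np.ndarray:
        parts = []
        for chrom in self.genome.names:
            L, b = self.genome[chrom], self.bin_size
            k = n_bins(L, b)
            lens = np.full(k, b, dtype=float)
            if L % b:
                lens[-1] = L % b
            parts.append(lens)
        return np.concatenate(parts)


def n_bins(chrom_length: int, bin_size: int) -> int:
    return math.ceil(chrom_length / bin_size)


def bin_genome(genome: GenomeIndex, bin_size: int) -> list[Interval]:
    """Tile each chromosome with consecutive ``bin_size`` bins.

    The last bin is truncated at the chromosome end.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins = []
    for chrom in genome.names:
        L = genome[chrom]
        for s in range(0, L, bin_size):
            bins.append(Interval(chrom, s, min(s + bin_size, L)))
    return bins


def coverage_track(
    reads: Sequence[AlignedRead],
    genome: GenomeIndex,
    bin_size: int,
    normalize: str = "raw",
    effective_genome_size: Optional[int] = None,
) -> BinnedTrack:
    """Per-bin mean per-base read depth, optionally RPGC-normalized.

    RPGC (reads per genomic content, "1x" normalization) multiplies raw depth
    by ``effective_genome_size / (total reads x mean read length)`` so that
    mean coverage over the effective genome equals 1.  Mean read length is
    total aligned bases / read count, so the scale factor reduces to
    ``effective_genome_size / total aligned bases``.
    """
    if normalize not in ("raw", "RPGC"):
        raise ValueError(f"unknown normalization {normalize!r}")
    if normalize == "RPGC" and not reads:
        raise ValueError("RPGC normalization is undefined for an empty read set")
    depth_sums = {}
    total_bases = 0
    for chrom in genome.names:
        L = genome[chrom]
        diff = np.zeros(L + 1)
        depth_sums[chrom] = diff
    for r in reads:
        Interval(r.chrom, r.start, r.end).validate(genome)
        depth_sums[r.chrom][r.start] += 1
        depth_sums[r.chrom][r.end] -= 1
        total_bases += r.length
    values = {}
    for chrom in genome.names:
        L = genome[chrom]
        depth = np.cumsum(depth_sums[chrom][:L])
        edges = np.arange(0, L, bin_size)
        sums = np.add.reduceat(depth, edges)
        lens = np.minimum(edges + bin_size, L) - edges
        values[chrom] = sums / lens
    if normalize == "RPGC":
        G = effective_genome_size if effective_genome_size else genome.total_length
        scale = G / total_bases
        values = {c: v * scale for c, v in values.items()}
    return BinnedTrack(bin_size, values, genome)


def count_reads_in_regions(
    reads: Sequence[AlignedRead],
    regions: Sequence[Interval],
    size_range: Optional[Tuple[int, int]] = None,
) -> pd.DataFrame:
    """Count reads overlapping (>=1 bp) each region.

    A read overlapping several regions is counted once in each.
    ``size_range=(lo, hi)`` keeps only reads with lo <= length <= hi.
    """
    if size_range is not None:
        lo, hi = size_range
        reads = [r for r in reads if lo <= r.length <= hi]
    trees: dict[str, IntervalTree] = {}
    for i, r in enumerate(reads):
        # payload keeps identical read coordinates distinct in the tree
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, i)
    counts = [
        len(trees[reg.chrom].overlap(reg.start, reg.end)) if reg.chrom in trees else 0
        for reg in regions
    ]
    return pd.DataFrame(
        {
            "chrom": [reg.chrom for reg in regions],
            "start": [reg.start for reg in regions],
            "end": [reg.end for reg in regions],
            "count": counts,
        }
    )


def signal_correlation(
    track_a: BinnedTrack,
    track_b: BinnedTrack,
    regions: Optional[Sequence[Interval]] = None,
    log_transform: bool = False,
    pseudocount: float = 1.0,
) -> float:
    """Pearson correlation of two binned tracks over (optionally restricted) bins.

    With ``log_transform`` both tracks are mapped through log2(x + pseudocount)
    first; the +1 default keeps zero bins finite.
    """
    if track_a.bin_size != track_b.bin_size:
        raise ValueError("tracks have different bin sizes")
    if track_a.genome.names != track_b.genome.names:
        raise ValueError("tracks are on different genomes")
    a, b = track_a.flat(), track_b.flat()
    if regions is not None:
        mask = np.zeros(len(a), dtype=bool)
        offset = 0
        offsets = {}
        for chrom in track_a.genome.names:
            offsets[chrom] = offset
            offset += len(track_a.values[chrom])
        bsz = track_a.bin_size
        for reg in regions:
            first = reg.start // bsz
            last = (reg.end - 1) // bsz
            o = offsets[reg.chrom]
            mask[o + first : o + last + 1] = True
        a, b = a[mask], b[mask]
    if len(a) < 2:
        raise ValueError("need at least 2 bins for a correlation")
    if log_transform:
        a = np.log2(a + pseudocount)
        b = np.log2(b + pseudocount)
    return float(stats.pearsonr(a, b)[0])


def signed_tss_distance(center: int, tss: int, strand: str) -> int:
    """Signed distance of a point to a TSS: negative when the point lies
    upstream of the TSS in the gene's orientation."""
    return center - tss if strand != "-" else tss - center


def distance_to_nearest_tss(
    query: Interval, tss_set: Sequence[Tuple[int, str]]
) -> int:
    """Signed center-to-nearest-TSS distance.

    Upstream-of-TSS (in gene orientation) is negative.  Ties on absolute
    distance resolve to the upstream (more negative) candidate.
    """
    if not tss_set:
        raise ValueError("tss_set is empty")
    c = query.center
    dists = [signed_tss_distance(c, pos, strand) for pos, strand in tss_set]
    return min(dists, key=lambda d: (abs(d), d))
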