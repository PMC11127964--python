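"""Seeded synthetic-data generator with planted ground truth.

Emulates the statistical structure of the real inputs at desk scale: a
small random genome with genes, a six-state co-occupancy landscape over
200-bp bins for three ChIP marks (SPT6L, NRPE1, Pol II), short stranded
Pol V RIP reads with 8-bp UMIs, the 5' TATAGGG tag, poly(A) tails, PCR
duplicates and a per-peak-group "sliced" subpopulation whose 10th base is
a U, plus per-cytosine methylation reports with planted DMR windows.

One global seed drives independent per-component generator streams, so
regenerating one component does not shift the others, and every output is
byte-identical for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .genome import AlignedRead, BinnedTrack, GenomeIndex, Interval, Peak, n_bins
from .slicing import reverse_complement

STATE_NAMES = (
    "background",
    "NRPE1-only",
    "NRPE1-SPT6L",
    "genic-SPT6L",
    "PolII-only",
    "triple",
)
# mark enrichment pattern per state, marks = (SPT6L, NRPE1, Pol II)
STATE_PATTERNS = np.array(
    [
        [0, 0, 0],  # background
        [0, 1, 0],  # NRPE1-only (proximal, -200 bp of TSS)
        [1, 1, 0],  # NRPE1+SPT6L shared (distal, -400 bp of TSS)
        [1, 0, 1],  # genic SPT6L
        [0, 0, 1],  # Pol II only
        [1, 1, 1],  # all three
    ]
)
MARKS = ("SPT6L", "NRPE1", "Pol II")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline inputs."""

    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    gc: float = 0.36  # Arabidopsis-like base composition
    n_genes: int = 200
    gene_length: Tuple[int, int] = (800, 2000)
    bin_size: int = 200
    lambda_enriched: float = 20.0
    lambda_background: float = 1.0
    stay_prob: float = 0.85  # within-run persistence of an enriched state
    bg_stay_prob: float = 0.99  # background dominates the genome
    background_weight: float = 0.9  # initial mass on the background state
    n_peaks: int = 300
    peak_width: Tuple[int, int] = (300, 700)
    sliced_fractions: Tuple[float, ...] = (0.05, 0.15, 0.25, 0.40)
    reads_per_peak: Dict[str, float] = field(
        default_factory=lambda: {"wt_ip": 60.0, "mut_ip": 30.0, "gro": 60.0}
    )
    read_length_mean: Dict[str, float] = field(
        default_factory=lambda: {"wt_ip": 60.0, "mut_ip": 45.0, "gro": 60.0}
    )
    read_length_sd: float = 15.0
    ip_background_reads: int = 6000  # genome-wide non-Pol V RNA in the IP
    n_control_reads: int = 1500
    umi_length: int = 8
    five_prime_tag: str = "TATAGGG"
    duplication_rate: float = 0.1
    polya_range: Tuple[int, int] = (4, 12)
    methylome_chroms: Tuple[str, ...] = ("chr1",)
    coverage_mean: float = 20.0
    baseline_levels: Dict[str, float] = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.4, "CHH": 0.1}
    )
    n_dmrs: int = 40
    dmr_delta: float = 0.40
    dmr_win: int = 500

    def validate(self) -> "SimulationConfig":
        if not (0 <= self.gc <= 1):
            raise ValueError("gc must be a probability")
        if any(not (0 <= f <= 1) for f in self.sliced_fractions):
            raise ValueError("sliced fractions must be probabilities")
        if self.lambda_enriched < 0 or self.lambda_background < 0:
            raise ValueError("rates must be non-negative")
        min_len = min(self.chrom_lengths.values())
        if min_len < 10 * self.gene_length[1]:
            raise ValueError("genome too short for the requested features")
        return self


@dataclass
class GroundTruth:
    """Planted features, mutually consistent with the emitted files."""

    states: Dict[str, np.ndarray]
    peak_groups: Dict[str, int]
    sliced: Dict[str, bool]
    dmrs: pd.DataFrame
    sliced_fallbacks: int = 0


def _rng_streams(seed: int) -> Dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("genome", "chip", "rip", "methylome")
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


# ---------------------------------------------------------------------------
# Genome and annotation


def make_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
):
    """Random-composition genome with genes; returns (sequences, index, genes)."""
    config.validate()
    rng = rng if rng is not None else _rng_streams(config.seed)["genome"]
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    bases = np.frombuffer(b"ACGT", dtype="S1")
    sequences = {}
    for chrom, L in config.chrom_lengths.items():
        draw = rng.choice(4, size=L, p=p)
        sequences[chrom] = bases[draw].tobytes().decode()
    genome = GenomeIndex(dict(config.chrom_lengths))
    genes = _place_genes(config, genome, rng)
    return sequences, genome, genes


def _slots(genome: GenomeIndex, n_items: int, item_max: int, margin: int,
           rng: np.random.Generator) -> List[Tuple[str, int]]:
    """Pick n non-overlapping placement slots (chrom, slot_start) genome-wide."""
    slot_w = item_max + 400
    all_slots = []
    for chrom in genome.names:
        usable = genome[chrom] - 2 * margin
        for k in range(usable // slot_w):
            all_slots.append((chrom, margin + k * slot_w))
    if n_items > len(all_slots):
        raise ValueError("genome too short for the requested features")
    idx = rng.choice(len(all_slots), size=n_items, replace=False)
    return [all_slots[i] for i in sorted(idx)]


def _place_genes(
    config: SimulationConfig, genome: GenomeIndex, rng: np.random.Generator
) -> pd.DataFrame:
    lo, hi = config.gene_length
    slots = _slots(genome, config.n_genes, hi, margin=2500, rng=rng)
    rows = []
    for i, (chrom, slot_start) in enumerate(slots):
        length = int(rng.integers(lo, hi + 1))
        start = slot_start + int(rng.integers(0, 200))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else start + length - 1
        rows.append((f"gene_{i:04d}", chrom, start, start + length, strand, tss))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
    )


# ---------------------------------------------------------------------------
# ChIP co-occupancy landscape


def true_hmm_params(config: SimulationConfig):
    """(startprob, transmat, rate matrix lambda[state, mark]) of the planted model."""
    K = len(STATE_NAMES)
    startprob = np.full(K, (1 - config.background_weight) / (K - 1))
    startprob[0] = config.background_weight
    transmat = np.zeros((K, K))
    transmat[0, 0] = config.bg_stay_prob
    transmat[0, 1:] = (1 - config.bg_stay_prob) / (K - 1)
    for k in range(1, K):
        transmat[k, k] = config.stay_prob
        leave = 1 - config.stay_prob
        transmat[k, 0] = leave * 0.85  # enriched runs mostly return to background
        rest = [j for j in range(1, K) if j != k]
        transmat[k, rest] = leave * 0.15 / len(rest)
    rates = config.lambda_background + STATE_PATTERNS * (
        config.lambda_enriched - config.lambda_background
    )
    return startprob, transmat, rates.astype(float)


def make_chip_data(
    config: SimulationConfig,
    genome: GenomeIndex,
    genes: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
):
    """Planted state path + Poisson per-bin mark counts.

    The Markov state path is overridden around gene TSSs to realize the
    TSS-distance structure: the bin 200 bp upstream of each TSS (in gene
    orientation) becomes NRPE1-only (proximal) and the bin 400 bp upstream
    becomes NRPE1+SPT6L shared (distal).

    Returns (tracks dict per mark, true states dict per chrom).
    """
    rng = rng if rng is not None else _rng_streams(config.seed)["chip"]
    startprob, transmat, rates = true_hmm_params(config)
    K = len(STATE_NAMES)
    b = config.bin_size
    states: Dict[str, np.ndarray] = {}
    for chrom in genome.names:
        T = n_bins(genome[chrom], b)
        path = np.empty(T, dtype=int)
        path[0] = rng.choice(K, p=startprob)
        for t in range(1, T):
            path[t] = rng.choice(K, p=transmat[path[t - 1]])
        states[chrom] = path
    # TSS-offset conditioning realizes the proximal/distal population
    # structure: alternate genes carry an NRPE1-only bin 200 bp upstream
    # (proximal) or an NRPE1+SPT6L shared bin 400 bp upstream (distal).
    # One state per gene keeps the planted path locally Markov-like.
    for i, g in enumerate(genes.itertuples()):
        sign = 1 if g.strand != "-" else -1
        offset, state = (200, 1) if i % 2 == 0 else (400, 2)
        pos = g.tss - sign * offset
        if 0 <= pos < genome[g.chrom]:
            states[g.chrom][pos // b] = state
    tracks = {}
    for m, mark in enumerate(MARKS):
        values = {
            chrom: rng.poisson(rates[states[chrom], m]).astype(float)
            for chrom in genome.names
        }
        tracks[mark] = BinnedTrack(b, values, genome)
    return tracks, states


# ---------------------------------------------------------------------------
# Peaks and RIP reads


def place_peaks(
    config: SimulationConfig, genome: GenomeIndex, rng: np.random.Generator
) -> Tuple[List[Peak], Dict[str, int]]:
    """Non-overlapping peaks with a planted group (1..n_groups) each."""
    lo, hi = config.peak_width
    slots = _slots(genome, config.n_peaks, hi, margin=2000, rng=rng)
    n_groups = len(config.sliced_fractions)
    group_of = rng.permutation(
        np.arange(config.n_peaks) % n_groups + 1
    )
    peaks, groups = [], {}
    for i, (chrom, slot_start) in enumerate(slots):
        width = int(rng.integers(lo, hi + 1))
        start = slot_start + int(rng.integers(0, 200))
        pid = f"peak_{i:04d}"
        peaks.append(Peak(chrom, start, start + width, pid))
        groups[pid] = int(group_of[i])
    return peaks, groups


def _sliced_start_candidates(
    seq: str, peak: Peak, length: int, strand: str, position: int = 10
) -> np.ndarray:
    """Starts inside the peak putting a U (T) at read position 10."""
    if strand != "-":
        lo, hi = peak.start + position - 1, peak.end - length + position - 1
        window = np.frombuffer(seq[lo : hi + 1].encode(), dtype="S1")
        return np.flatnonzero(window == b"T") + lo - (position - 1)
    lo, hi = peak.start + length - position, peak.end - position
    window = np.frombuffer(seq[lo : hi + 1].encode(), dtype="S1")
    return np.flatnonzero(window == b"A") + lo + position - length


def make_rip_data(
    config: SimulationConfig,
    sequences: Mapping[str, str],
    peaks: Sequence[Peak],
    peak_groups: Mapping[str, int],
    rng: Optional[np.random.Generator] = None,
):
    """RIP/GRO/control read sets with planted sliced subpopulations.

    Returns ``(aligned, raw, truth_sliced, n_fallback)`` where ``aligned``
    maps sample -> list[AlignedRead] (samples wt_ip, mut_ip, gro, control)
    and ``raw`` maps IP samples -> FASTQ records (id, sequence, quality)
    of UMI + 5' tag + insert + poly(A).
    """
    rng = rng if rng is not None else _rng_streams(config.seed)["rip"]
    genome = GenomeIndex({c: len(s) for c, s in sequences.items()})
    aligned: Dict[str, List[AlignedRead]] = {}
    raw: Dict[str, List[Tuple[str, str, str]]] = {}
    truth_sliced: Dict[str, bool] = {}
    n_fallback = 0
    bases = "ACGT"
    for sample in ("wt_ip", "mut_ip", "gro"):
        reads: List[AlignedRead] = []
        fastq: List[Tuple[str, str, str]] = []
        mean_n = config.reads_per_peak[sample]
        mean_len = config.read_length_mean[sample]
        serial = 0
        for peak in peaks:
            frac = config.sliced_fractions[peak_groups[peak.id] - 1]
            n = int(rng.poisson(mean_n))
            for _ in range(n):
                length = int(
                    np.clip(
                        round(rng.normal(mean_len, config.read_length_sd)),
                        15,
                        min(150, peak.length),
                    )
                )
                strand = "+" if rng.random() < 0.5 else "-"
                sliced = bool(rng.random() < frac) and length >= 10
                seq_chrom = sequences[peak.chrom]
                if sliced:
                    cands = _sliced_start_candidates(seq_chrom, peak, length, strand)
                    if len(cands):
                        start = int(cands[rng.integers(len(cands))])
                    else:
                        start = int(rng.integers(peak.start, peak.end - length + 1))
                        sliced = False
                        n_fallback += 1
                else:
                    start = int(rng.integers(peak.start, peak.end - length + 1))
                insert = seq_chrom[start : start + length]
                if strand == "-":
                    insert = reverse_complement(insert)
                umi = "".join(bases[i] for i in rng.integers(0, 4, config.umi_length))
                rid = f"{sample}:{serial:06d}"
                serial += 1
                truth_sliced[rid] = sliced
                read = AlignedRead(
                    peak.chrom, start, start + length, strand,
                    name=f"{rid}_{umi}", umi=umi, sequence=insert,
                )
                reads.append(read)
                polya = "A" * int(rng.integers(*config.polya_range))
                fastq.append(
                    (rid, umi + config.five_prime_tag + insert + polya, None)
                )
                if rng.random() < config.duplication_rate:
                    reads.append(read)
                    fastq.append(fastq[-1])
        if sample != "gro":
            # genome-wide non-Pol V RNA pulled down in the IP: inflates the
            # mapped-library total so per-peak RPM reflects absolute abundance
            chroms = list(genome.names)
            chrom_p = np.array([genome[c] for c in chroms], dtype=float)
            chrom_p /= chrom_p.sum()
            for _ in range(config.ip_background_reads):
                chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
                length = int(np.clip(round(rng.normal(
                    config.read_length_mean[sample], config.read_length_sd)), 15, 150))
                start = int(rng.integers(0, genome[chrom] - length))
                strand = "+" if rng.random() < 0.5 else "-"
                insert = sequences[chrom][start : start + length]
                if strand == "-":
                    insert = reverse_complement(insert)
                umi = "".join(bases[j] for j in rng.integers(0, 4, config.umi_length))
                rid = f"{sample}:{serial:06d}"
                serial += 1
                truth_sliced[rid] = False
                reads.append(AlignedRead(chrom, start, start + length, strand,
                                         name=f"{rid}_{umi}", umi=umi,
                                         sequence=insert))
                polya = "A" * int(rng.integers(*config.polya_range))
                fastq.append((rid, umi + config.five_prime_tag + insert + polya, None))
        aligned[sample] = reads
        if sample != "gro":
            raw[sample] = fastq
    # sparse genome-wide background reads for the nrpe1 control
    control: List[AlignedRead] = []
    chroms = list(genome.names)
    chrom_p = np.array([genome[c] for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()
    for i in range(config.n_control_reads):
        chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
        length = int(np.clip(round(rng.normal(60, config.read_length_sd)), 15, 150))
        start = int(rng.integers(0, genome[chrom] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        insert = sequences[chrom][start : start + length]
        if strand == "-":
            insert = reverse_complement(insert)
        umi = "".join(bases[j] for j in rng.integers(0, 4, config.umi_length))
        control.append(
            AlignedRead(chrom, start, start + length, strand,
                        name=f"control:{i:06d}_{umi}", umi=umi, sequence=insert)
        )
    aligned["control"] = control
    return aligned, raw, truth_sliced, n_fallback


# ---------------------------------------------------------------------------
# Methylome


def cytosine_positions(seq: str) -> pd.DataFrame:
    """All cytosines on both strands with their CG/CHG/CHH context."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    L = len(arr)
    frames = []
    # plus strand: C at i; context from arr[i+1], arr[i+2]
    pos = np.flatnonzero(arr == b"C")
    nxt1 = np.where(pos + 1 < L, arr[np.minimum(pos + 1, L - 1)], b"N")
    nxt2 = np.where(pos + 2 < L, arr[np.minimum(pos + 2, L - 1)], b"N")
    ctx = np.where(nxt1 == b"G", "CG", np.where(nxt2 == b"G", "CHG", "CHH"))
    frames.append(pd.DataFrame({"pos": pos, "strand": "+", "context": ctx}))
    # minus strand: G at i is a C on the reverse strand; context leftwards
    pos = np.flatnonzero(arr == b"G")
    prv1 = np.where(pos - 1 >= 0, arr[np.maximum(pos - 1, 0)], b"N")
    prv2 = np.where(pos - 2 >= 0, arr[np.maximum(pos - 2, 0)], b"N")
    ctx = np.where(prv1 == b"C", "CG", np.where(prv2 == b"C", "CHG", "CHH"))
    frames.append(pd.DataFrame({"pos": pos, "strand": "-", "context": ctx}))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pos", "strand"]).reset_index(drop=True)


def _dmr_direction(baseline: float, delta: float) -> Tuple[str, float]:
    if baseline - delta >= 0.02:
        return "hypo", baseline - delta
    return "hyper", min(baseline + delta, 0.98)


def make_methylome(
    config: SimulationConfig,
    sequences: Mapping[str, str],
    rng: Optional[np.random.Generator] = None,
):
    """Cytosine reports for a reference (wt) and test (mutant) sample.

    Planted DMR windows cycle through the three contexts; the direction per
    context is whichever of +/- delta stays inside (0, 1) (hypo for CG,
    hyper for CHG/CHH at the default baselines).

    Returns (reports dict sample -> records frame, truth DMR frame).
    """
    rng = rng if rng is not None else _rng_streams(config.seed)["methylome"]
    reports = {"wt": [], "mut": []}
    truth_rows = []
    win = config.dmr_win
    for chrom in config.methylome_chroms:
        seq = sequences[chrom]
        cyt = cytosine_positions(seq)
        cyt["chrom"] = chrom
        base = cyt["context"].map(config.baseline_levels).to_numpy(dtype=float)
        level_wt = base.copy()
        level_mut = base.copy()
        n_windows = len(seq) // win
        chosen = np.sort(
            rng.choice(np.arange(2, n_windows - 2), size=config.n_dmrs, replace=False)
        )
        pos = cyt["pos"].to_numpy()
        ctx_arr = cyt["context"].to_numpy()
        for i, w in enumerate(chosen):
            ctx = ("CG", "CHG", "CHH")[i % 3]
            direction, shifted = _dmr_direction(
                config.baseline_levels[ctx], config.dmr_delta
            )
            mask = (pos >= w * win) & (pos < (w + 1) * win) & (ctx_arr == ctx)
            level_mut[mask] = shifted
            truth_rows.append(
                (chrom, int(w * win), int((w + 1) * win), ctx, direction,
                 100.0 * abs(shifted - config.baseline_levels[ctx]))
            )
        for sample, levels in (("wt", level_wt), ("mut", level_mut)):
            cov = rng.poisson(config.coverage_mean, size=len(cyt))
            meth = rng.binomial(cov, levels)
            rec = cyt[["chrom", "pos", "strand", "context"]].copy()
            rec["meth"] = meth
            rec["unmeth"] = cov - meth
            reports[sample].append(
                rec[["chrom", "pos", "strand", "meth", "unmeth", "context"]]
            )
    reports = {s: pd.concat(fs, ignore_index=True) for s, fs in reports.items()}
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start", "end", "context", "direction", "delta_pp"],
    )
    return reports, truth


# ---------------------------------------------------------------------------
# Full bundle


def simulate_all(config: SimulationConfig, outdir) -> GroundTruth:
    """Generate and write every pipeline input plus the ground-truth bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = _rng_streams(config.seed)
    sequences, genome, genes = make_genome(config, streams["genome"])
    pio.write_fasta(outdir / "genome.fa", sequences)
    pio.write_gff3_genes(outdir / "genes.gff3", genes)
    tracks, states = make_chip_data(config, genome, genes, streams["chip"])
    for mark, track in tracks.items():
        fname = "chip_" + mark.lower().replace(" ", "").replace("ii", "2") + ".bedgraph"
        pio.write_bedgraph(outdir / fname, track)
    peaks, peak_groups = place_peaks(config, genome, streams["rip"])
    pio.write_bed(outdir / "peaks.bed", peaks, genome)
    aligned, raw, truth_sliced, n_fallback = make_rip_data(
        config, sequences, peaks, peak_groups, streams["rip"]
    )
    for sample, reads in aligned.items():
        pio.write_reads_tsv(outdir / f"rip_{sample}_aligned.tsv", reads)
    for sample, records in raw.items():
        pio.write_fastq(outdir / f"rip_{sample}.fastq", records)
    reports, truth_dmrs = make_methylome(config, sequences, streams["methylome"])
    for sample, rec in reports.items():
        pio.write_cytosine_report(outdir / f"meth_{sample}.cx.tsv", rec)
    truth_dir = outdir / "ground_truth"
    truth_dir.mkdir(exist_ok=True)
    rows = []
    for chrom in genome.names:
        for i, s in enumerate(states[chrom]):
            rows.append((chrom, i * config.bin_size, int(s), STATE_NAMES[int(s)]))
    pd.DataFrame(rows, columns=["chrom", "bin_start", "state", "name"]).to_csv(
        truth_dir / "states.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(peak_groups.items()), columns=["peak_id", "group"]
    ).to_csv(truth_dir / "peak_groups.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth_sliced.items()), columns=["read_id", "sliced"]
    ).to_csv(truth_dir / "sliced.tsv", sep="\t", index=False)
    truth_dmrs.to_csv(truth_dir / "dmrs.tsv", sep="\t", index=False)
    return GroundTruth(states, peak_groups, truth_sliced, truth_dmrs, n_fallback)
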