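"""Stage orchestration: simulate -> segment -> ripseq -> slicing -> dmr.

Each stage reads plain-text inputs, writes plain-text outputs under the
run directory and contributes rows to a manifest (file, sha256 checksum,
parameters used).  A stage failure marks the run failed and skips the
stages downstream of it; reruns with unchanged inputs and seed produce
byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .config import RunConfig
from .genome import GenomeIndex, Interval
from .hmm import (
    BinaryMatrix,
    CooccupancyHMM,
    nearest_downstream_tss,
    state_tss_profile,
)
from .methylation import call_dmrs, dmrs_to_bed, region_methylation, window_counts
from .ripseq import (
    RawRead,
    assign_to_peaks,
    deduplicate,
    normalize_abundance,
    process_raw_reads,
    rank_sum_test,
    read_length_distribution,
    subtract_background,
)
from .simulate import MARKS, SimulationConfig, simulate_all
from .slicing import (
    base_frequency,
    group_peaks,
    group_u10_summary,
    shuffle_within_peak,
    u10_stats,
)

log = logging.getLogger("polvtx")

STAGES = ("simulate", "segment", "ripseq", "slicing", "dmr")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, root: Path):
        self.root = Path(root)
        self.rows: List[Tuple[str, str, str, str]] = []

    def add(self, stage: str, path, params: Mapping) -> None:
        rel = str(Path(path).relative_to(self.root))
        self.rows.append(
            (stage, rel, sha256_file(path), json.dumps(params, sort_keys=True))
        )

    def mark_failed(self, stage: str, error: str) -> None:
        self.rows.append((stage, "-", "FAILED", json.dumps({"error": error})))

    def write(self, path) -> None:
        pd.DataFrame(
            self.rows, columns=["stage", "file", "sha256", "params"]
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Stage implementations (also backing the standalone CLI subcommands)


def run_segment(
    genome_fa,
    mark_files: Mapping[str, str],
    outdir,
    genes_gff=None,
    bin_size: int = 200,
    k_states: int = 6,
    pthresh: float = 1e-4,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    decode_method: str = "posterior",
) -> List[Path]:
    """Binarize mark tracks, fit the co-occupancy HMM, decode and label."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences = pio.read_fasta(genome_fa)
    genome = pio.genome_index_from_fasta(sequences)
    tracks = {
        mark: pio.read_bedgraph(path, genome, bin_size)
        for mark, path in mark_files.items()
    }
    data = BinaryMatrix.from_tracks(tracks, p_threshold=pthresh)
    res = CooccupancyHMM(data, k_states).fit(seed=seed, max_iter=max_iter, tol=tol)
    seg = res.decode(method=decode_method)
    seg.labels = res.label_states()
    log.info("segment: loglik %.2f after %d EM iterations",
             res.llf, len(res.loglik_history))
    files = []
    model_path = outdir / "hmm_model.tsv"
    res.to_table().to_csv(model_path, sep="\t", index=False)
    files.append(model_path)
    seg_path = outdir / "segments.bed"
    frame = seg.to_frame()
    with open(seg_path, "w") as fh:
        for r in frame.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tS{r.state}|{r.label}\t.\t.\n")
    files.append(seg_path)
    if genes_gff is not None:
        genes = pio.read_gff3_genes(genes_gff, genome)
        tss_set = list(zip(genes["tss"], genes["strand"]))
        prof = state_tss_profile(seg, tss_set, window=1000, resolution=bin_size)
        prof.insert(0, "state", prof.index)
        prof_path = outdir / "state_tss_profile.tsv"
        prof.to_csv(prof_path, sep="\t", index=False)
        files.append(prof_path)
        labels = seg.labels or {}
        regions = [
            iv for iv, s in seg.segments if labels.get(s, "") != "background"
        ]
        assign = nearest_downstream_tss(regions, genes)
        assign_path = outdir / "nearest_downstream_tss.tsv"
        assign.to_csv(assign_path, sep="\t", index=False)
        files.append(assign_path)
    return files


def run_ripseq(
    aligned: Mapping[str, str],
    control_path,
    peaks_bed,
    genome_fa,
    outdir,
    fastq: Optional[Mapping[str, str]] = None,
    umi_len: int = 8,
    min_len: int = 10,
    tag: str = "TATAGGG",
    tag_mismatch: int = 1,
    strand_aware: bool = True,
) -> List[Path]:
    """Per-sample transcript calling plus the between-sample comparisons."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences = pio.read_fasta(genome_fa)
    genome = pio.genome_index_from_fasta(sequences)
    peaks = pio.read_bed(peaks_bed, genome, as_peaks=True)
    control, n_ctrl_dup = deduplicate(pio.read_reads_tsv(control_path, genome))
    files = []
    per_sample = {}
    for sample, path in aligned.items():
        stage_rows = []
        if fastq and sample in fastq:
            raws = [RawRead(rid, seq, qual or None)
                    for rid, seq, qual in pio.read_fastq(fastq[sample])]
            _, fq_report = process_raw_reads(
                raws, umi_len, tag, min_len, tag_mismatch
            )
            stage_rows += [("fastq_" + k, v) for k, v in fq_report.counters.items()]
        reads = pio.read_reads_tsv(path, genome)
        stage_rows.append(("aligned_input", len(reads)))
        dedup, n_dup = deduplicate(reads)
        stage_rows.append(("after_dedup", len(dedup)))
        stage_rows.append(("duplicates_removed", n_dup))
        clean = subtract_background(dedup, control, strand_aware=strand_aware)
        stage_rows.append(("after_background_subtraction", len(clean)))
        ts = assign_to_peaks(clean, peaks, total_mapped=len(dedup))
        stage_rows.append(("in_peaks", len(ts.reads)))
        stage_rows.append(("outside_peaks", ts.n_dropped))
        per_sample[sample] = ts
        counts = normalize_abundance(ts)
        p = outdir / f"{sample}_peak_counts.tsv"
        counts.to_csv(p, sep="\t", index=False)
        files.append(p)
        p = outdir / f"{sample}_transcripts.tsv"
        pio.write_reads_tsv(p, ts.reads)
        files.append(p)
        p = outdir / f"{sample}_stage_report.tsv"
        pd.DataFrame(stage_rows, columns=["stage", "count"]).to_csv(
            p, sep="\t", index=False
        )
        files.append(p)
        log.info("ripseq[%s]: %d reads in peaks (%d dup removed)",
                 sample, len(ts.reads), n_dup)
    if len(per_sample) >= 2:
        names = list(per_sample)
        a, b = per_sample[names[0]], per_sample[names[1]]
        rows = []
        rpm_a = normalize_abundance(a)["rpm"]
        rpm_b = normalize_abundance(b)["rpm"]
        stat, pval = rank_sum_test(rpm_a, rpm_b)
        rows.append(("per_peak_rpm", names[0], names[1], stat, pval))
        len_a, _ = read_length_distribution(a)
        len_b, _ = read_length_distribution(b)
        stat, pval = rank_sum_test(len_a, len_b)
        rows.append(("read_length", names[0], names[1], stat, pval))
        p = outdir / "ripseq_tests.tsv"
        pd.DataFrame(
            rows, columns=["quantity", "sample_a", "sample_b", "U", "p"]
        ).to_csv(p, sep="\t", index=False)
        files.append(p)
    return files


def run_slicing(
    rip_paths: Mapping[str, str],
    reference_path,
    peaks_bed,
    genome_fa,
    outdir,
    n_groups: int = 4,
    min_reads: int = 10,
    n_shuffles: int = 3,
    position: int = 10,
    filter_mode: str = "both",
    seed: int = 0,
) -> List[Path]:
    """U-10 statistics, peak grouping by the reference ratio, shuffle null."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences = pio.read_fasta(genome_fa)
    genome = pio.genome_index_from_fasta(sequences)
    peaks = pio.read_bed(peaks_bed, genome, as_peaks=True)
    files = []

    def peak_stats(reads):
        ts = assign_to_peaks(reads, peaks)
        return ts, u10_stats(ts.peak_sequences(), position)

    stats_by_sample: Dict[str, object] = {}
    ref_reads = pio.read_reads_tsv(reference_path, genome)
    ref_ts, ref_stats = peak_stats(ref_reads)
    stats_by_sample["reference"] = ref_stats
    first_sample = None
    for sample, path in rip_paths.items():
        reads = pio.read_reads_tsv(path, genome)
        ts, stats = peak_stats(reads)
        stats_by_sample[sample] = stats
        if first_sample is None:
            first_sample, first_ts = sample, ts
        bf = base_frequency([r.sequence for r in ts.reads if r.sequence], 20)
        p = outdir / f"{sample}_base_frequency.tsv"
        bf.to_csv(p, sep="\t", index=False)
        files.append(p)
    groups = group_peaks(
        ref_stats, stats_by_sample[first_sample], n_groups, min_reads, filter_mode
    )
    # within-peak shuffle null of the first RIP sample
    master = np.random.default_rng(seed)
    replicate_frames: List[Dict[str, list]] = [dict() for _ in range(n_shuffles)]
    peak_by_id = {p.id: p for p in peaks}
    for pid in sorted(first_ts.by_peak):
        idx = first_ts.by_peak[pid]
        if not idx:
            continue
        reads = [first_ts.reads[i] for i in idx]
        reps, _ = shuffle_within_peak(
            reads, peak_by_id[pid], sequences, n_shuffles,
            seed=int(master.integers(2**31)),
        )
        for j, rep in enumerate(reps):
            replicate_frames[j][pid] = [r.sequence for r in rep if r.sequence]
    shuffle_stats = [u10_stats(frame, position) for frame in replicate_frames]
    stats_by_sample["random"] = shuffle_stats
    summary = group_u10_summary(groups, stats_by_sample)
    p = outdir / "group_u10_summary.tsv"
    summary.to_csv(p, sep="\t", index=False)
    files.append(p)
    per_peak = stats_by_sample[first_sample].merge(
        groups.to_frame(), on="peak_id", how="left"
    )
    p = outdir / "peak_u10_stats.tsv"
    per_peak.to_csv(p, sep="\t", index=False)
    files.append(p)
    p = outdir / "excluded_peaks.tsv"
    pd.DataFrame(groups.excluded, columns=["peak_id", "reason"]).to_csv(
        p, sep="\t", index=False
    )
    files.append(p)
    log.info("slicing: %d peaks grouped, %d excluded",
             len(groups.assignment), len(groups.excluded))
    return files


def run_dmr(
    test_report,
    ref_report,
    outdir,
    win: int = 500,
    step: int = 500,
    mincov: int = 4,
    diff: float = 25.0,
    qvalue: float = 0.01,
) -> List[Path]:
    """Windowed Fisher-exact DMR calling between two cytosine reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    test = pio.read_cytosine_report(test_report)
    ref = pio.read_cytosine_report(ref_report)
    tw = window_counts(test, win, step, mincov)
    rw = window_counts(ref, win, step, mincov)
    table, skipped = call_dmrs(tw, rw, diff, qvalue)
    files = []
    p = outdir / "dmr_windows.tsv"
    table.to_csv(p, sep="\t", index=False)
    files.append(p)
    p = outdir / "dmrs.bed"
    bed = dmrs_to_bed(table)
    with open(p, "w") as fh:
        for r in bed.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t.\n")
    files.append(p)
    p = outdir / "dmr_skipped_windows.tsv"
    skipped.to_csv(p, sep="\t", index=False)
    files.append(p)
    log.info("dmr: %d/%d windows called", int(table["is_dmr"].sum()), len(table))
    return files


# ---------------------------------------------------------------------------
# Full pipeline


def run_pipeline(config: RunConfig) -> Tuple[int, Path]:
    """Execute all stages on the synthetic bundle; returns (exit status, manifest path)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    manifest = Manifest(out)
    sim_dir = out / "simulated"
    status = 0
    provenance = {"seed": config.seed, "stages": list(STAGES)}
    (out / "provenance.json").write_text(
        json.dumps({**provenance, "parameters": {
            s: getattr(config, s) for s in ("segment", "ripseq", "slicing", "dmr")
        }, "simulate": asdict(config.simulate)}, sort_keys=True, indent=1)
    )
    mark_files = {}
    try:
        # the run seed drives every stochastic stage, simulation included
        sim_cfg = replace(config.simulate, seed=config.seed)
        simulate_all(sim_cfg, sim_dir)
        for f in sorted(sim_dir.rglob("*")):
            if f.is_file():
                manifest.add("simulate", f, {"seed": sim_cfg.seed})
        mark_files = {
            "SPT6L": sim_dir / "chip_spt6l.bedgraph",
            "NRPE1": sim_dir / "chip_nrpe1.bedgraph",
            "Pol II": sim_dir / "chip_pol2.bedgraph",
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        log.error("simulate failed: %s", exc)
        manifest.mark_failed("simulate", str(exc))
        status = 1
    if status == 0:
        seg = config.segment
        try:
            for f in run_segment(
                sim_dir / "genome.fa", mark_files, out / "segment",
                genes_gff=sim_dir / "genes.gff3",
                bin_size=seg["bin"], k_states=seg["states"],
                pthresh=seg["pthresh"], seed=config.seed,
                max_iter=seg["max_iter"], tol=seg["tol"],
                decode_method=seg["decode"],
            ):
                manifest.add("segment", f, seg)
        except Exception as exc:
            log.error("segment failed: %s", exc)
            manifest.mark_failed("segment", str(exc))
            status = 1
    if status == 0:
        rip = config.ripseq
        try:
            for f in run_ripseq(
                {"wt_ip": sim_dir / "rip_wt_ip_aligned.tsv",
                 "mut_ip": sim_dir / "rip_mut_ip_aligned.tsv"},
                sim_dir / "rip_control_aligned.tsv",
                sim_dir / "peaks.bed", sim_dir / "genome.fa", out / "ripseq",
                fastq={"wt_ip": sim_dir / "rip_wt_ip.fastq",
                       "mut_ip": sim_dir / "rip_mut_ip.fastq"},
                umi_len=rip["umi_len"], min_len=rip["min_len"], tag=rip["tag"],
                tag_mismatch=rip["tag_mismatch"],
                strand_aware=rip["strand_aware"],
            ):
                manifest.add("ripseq", f, rip)
        except Exception as exc:
            log.error("ripseq failed: %s", exc)
            manifest.mark_failed("ripseq", str(exc))
            status = 1
    if status == 0:
        sli = config.slicing
        try:
            for f in run_slicing(
                {"wt_ip": out / "ripseq" / "wt_ip_transcripts.tsv",
                 "mut_ip": out / "ripseq" / "mut_ip_transcripts.tsv"},
                sim_dir / "rip_gro_aligned.tsv",
                sim_dir / "peaks.bed", sim_dir / "genome.fa", out / "slicing",
                n_groups=sli["groups"], min_reads=sli["min_reads"],
                n_shuffles=sli["shuffles"], position=sli["position"],
                filter_mode=sli["filter_mode"], seed=config.seed,
            ):
                manifest.add("slicing", f, sli)
        except Exception as exc:
            log.error("slicing failed: %s", exc)
            manifest.mark_failed("slicing", str(exc))
            status = 1
    if status == 0:
        dmr = config.dmr
        try:
            for f in run_dmr(
                sim_dir / "meth_mut.cx.tsv", sim_dir / "meth_wt.cx.tsv",
                out / "dmr",
                win=dmr["win"], step=dmr["step"], mincov=dmr["mincov"],
                diff=dmr["diff"], qvalue=dmr["qvalue"],
            ):
                manifest.add("dmr", f, dmr)
        except Exception as exc:
            log.error("dmr failed: %s", exc)
            manifest.mark_failed("dmr", str(exc))
            status = 1
    manifest_path = out / "manifest.tsv"
    manifest.write(manifest_path)
    return status, manifest_path
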