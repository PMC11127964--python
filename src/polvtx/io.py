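"""Readers and writers for the plain-text formats the pipeline consumes.

BED (3/6 column), bedGraph, GFF3 gene annotation, FASTA genomes, the TSV
dialect for aligned reads with sequences, and Bismark-style cytosine
reports.  All writers emit a deterministic ordering: chromosome order from
the GenomeIndex, then start coordinate, so repeated runs are byte-identical.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import (
    AlignedRead,
    BinnedTrack,
    GenomeIndex,
    Interval,
    Peak,
    ValidationError,
    n_bins,
)


class ParseError(ValueError):
    """Malformed input line (message carries the 1-based line number)."""


# ---------------------------------------------------------------------------
# BED


def read_bed(path, genome: GenomeIndex, as_peaks: bool = False):
    """Read BED3/BED6 into Intervals (or Peaks), validated against *genome*.

    Input order is preserved.  Strand '.' maps to unstranded.
    """
    out = []
    seen_ids = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = Interval(chrom, start, end, strand).validate(genome)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            if as_peaks:
                pid = name if name is not None else f"peak_{lineno}"
                if pid in seen_ids:
                    raise ValidationError(f"{path}:{lineno}: duplicate peak id {pid!r}")
                seen_ids.add(pid)
                out.append(Peak(chrom, start, end, pid, score, strand))
            else:
                out.append(iv)
    return out


def write_bed(path, items: Sequence, genome: GenomeIndex) -> None:
    """Write Intervals/Peaks as BED6, sorted by genome chromosome order then start."""
    order = {c: i for i, c in enumerate(genome.names)}
    items = sorted(items, key=lambda x: (order[x.chrom], x.start, x.end))
    with open(path, "w") as fh:
        for it in items:
            name = getattr(it, "id", None) or getattr(it, "name", None) or "."
            score = getattr(it, "score", None)
            score_s = "." if score is None else format(score, "g")
            fh.write(
                f"{it.chrom}\t{it.start}\t{it.end}\t{name}\t{score_s}\t{it.strand}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph <-> BinnedTrack


def write_bedgraph(path, track: BinnedTrack) -> None:
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            L = track.genome[chrom]
            b = track.bin_size
            for i, v in enumerate(track.values[chrom]):
                fh.write(f"{chrom}\t{i * b}\t{min((i + 1) * b, L)}\t{v:g}\n")


def read_bedgraph(path, genome: GenomeIndex, bin_size: int) -> BinnedTrack:
    """Read a bedGraph whose intervals align to a fixed bin grid."""
    values = {
        c: np.zeros(n_bins(genome[c], bin_size)) for c in genome.names
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if chrom not in genome:
                raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start % bin_size or (
                end != min(start + bin_size, genome[chrom])
            ):
                raise ParseError(
                    f"{path}:{lineno}: interval not on the {bin_size}-bp bin grid"
                )
            values[chrom][start // bin_size] = value
    return BinnedTrack(bin_size, values, genome)


# ---------------------------------------------------------------------------
# GFF3 genes


def read_gff3_genes(path, genome: GenomeIndex) -> pd.DataFrame:
    """Extract gene records from GFF3 (1-based inclusive -> 0-based half-open).

    Returns a frame with columns gene_id, chrom, start, end, strand, tss.
    The TSS is the strand-aware 5' end of the gene.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 fields")
            if fields[2] != "gene":
                continue
            chrom, start1, end1, strand = (
                fields[0],
                int(fields[3]),
                int(fields[4]),
                fields[6],
            )
            start, end = start1 - 1, end1
            Interval(chrom, start, end, strand if strand in "+-" else ".").validate(
                genome
            )
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", f"gene_{lineno}")
            tss = start if strand != "-" else end - 1
            rows.append((gene_id, chrom, start, end, strand, tss))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
    )


def write_gff3_genes(path, genes: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(
                f"{g.chrom}\tpolvtx\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t."
                f"\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def genome_index_from_fasta(sequences: dict[str, str]) -> GenomeIndex:
    return GenomeIndex({name: len(seq) for name, seq in sequences.items()})


# ---------------------------------------------------------------------------
# Aligned-read TSV dialect (chrom, start, end, strand, name, sequence)

READS_TSV_COLUMNS = ["chrom", "start", "end", "strand", "name", "sequence"]


def read_reads_tsv(path, genome: Optional[GenomeIndex] = None) -> list[AlignedRead]:
    """Read aligned reads from the 6-column TSV dialect.

    The UMI, when present, is the underscore-delimited suffix of the name
    (UMI-tools convention).  An empty sequence field means "unknown".
    """
    reads = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != READS_TSV_COLUMNS:
            raise ParseError(f"{path}:1: bad header {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 fields")
            chrom, start, end, strand, name, seq = fields
            umi = name.rsplit("_", 1)[1] if "_" in name else None
            read = AlignedRead(
                chrom,
                int(start),
                int(end),
                strand,
                name=name,
                umi=umi,
                sequence=seq or None,
            )
            if genome is not None:
                read.interval.validate(genome)
            reads.append(read)
    return reads


def write_reads_tsv(path, reads: Sequence[AlignedRead]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(READS_TSV_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.name or '.'}"
                f"\t{r.sequence or ''}\n"
            )


# ---------------------------------------------------------------------------
# FASTQ (read 1 only)


def read_fastq(path):
    """Yield (id, sequence, quality) triples from a FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ParseError(f"{path}: malformed FASTQ record {header!r}")
            yield header[1:].split()[0], seq, qual


def write_fastq(path, records: Iterable[Tuple[str, str, Optional[str]]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual or 'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Cytosine report (Bismark-style)

CYTOSINE_CONTEXTS = ("CG", "CHG", "CHH")


def read_cytosine_report(path, genome: Optional[GenomeIndex] = None) -> pd.DataFrame:
    """Read a per-cytosine methylation report.

    Columns: chrom, position (1-based), strand, methylated count,
    unmethylated count, context.  Positions are converted to 0-based on load.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "strand", "meth", "unmeth", "context"],
        usecols=range(6),
        dtype={"chrom": str, "strand": str, "context": str},
    )
    bad = ~df["context"].isin(CYTOSINE_CONTEXTS)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ParseError(
            f"{path}:{i + 1}: unknown context {df['context'].iloc[i]!r}"
        )
    if (df[["meth", "unmeth"]] < 0).any().any():
        raise ParseError(f"{path}: negative count")
    if (df["pos"] < 1).any():
        raise ParseError(f"{path}: position must be 1-based positive")
    df["pos"] = df["pos"] - 1
    if genome is not None:
        for chrom, grp in df.groupby("chrom"):
            if chrom not in genome:
                raise ValidationError(f"{path}: unknown chromosome {chrom!r}")
            if int(grp["pos"].max()) >= genome[chrom]:
                raise ValidationError(f"{path}: position beyond end of {chrom}")
    return df


def write_cytosine_report(path, records: pd.DataFrame) -> None:
    out = records.copy()
    out["pos"] = out["pos"] + 1
    out[["chrom", "pos", "strand", "meth", "unmeth", "context"]].to_csv(
        path, sep="\t", header=False, index=False
    )
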