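"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA via Bio.SeqIO (60-column wrap on output); BED6/BED12 via pandas;
gene models also writable as GFF3.  All coordinates on disk follow each
format's own convention (BED 0-based half-open, GFF3 1-based inclusive).
"""
from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModel, GenomicInterval

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed6(intervals: Sequence[GenomicInterval], names: Sequence[str], path,
               scores: Sequence[float] | None = None) -> None:
    if scores is None:
        scores = [0] * len(intervals)
    df = pd.DataFrame(
        {
            "chrom": [i.chrom for i in intervals],
            "start": [i.start for i in intervals],
            "end": [i.end for i in intervals],
            "name": list(names),
            "score": list(scores),
            "strand": [i.strand if i.strand != "." else "." for i in intervals],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> list[tuple[str, GenomicInterval]]:
    """(name, interval) pairs from a BED6 file."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLS,
                     dtype={"chrom": str, "name": str})
    return [
        (row["name"], GenomicInterval(row["chrom"], int(row["start"]),
                                      int(row["end"]), str(row["strand"])))
        for _, row in df.iterrows()
    ]


def write_bed12(genes: Sequence[GeneModel], path) -> None:
    """Gene models as single-block BED12."""
    rows = []
    for g in genes:
        iv = g.interval
        rows.append([
            iv.chrom, iv.start, iv.end, g.id, 0, iv.strand,
            iv.start, iv.end, "0,0,0", 1, iv.length, 0,
        ])
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bed12(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, usecols=range(6),
                     names=BED6_COLS, dtype={"chrom": str, "name": str})
    return [
        GeneModel(str(r["name"]),
                  GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]),
                                  str(r["strand"])))
        for _, r in df.iterrows()
    ]


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tmedipkit\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.id}\n"
            )


def read_gff3_genes(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            genes.append(
                GeneModel(attrs.get("ID", f"{f[0]}:{f[3]}"),
                          GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6]))
            )
    return genes


def write_reads_bed(reads: Sequence[GenomicInterval], sample: str, path) -> None:
    write_bed6(reads, [f"{sample}_r{i + 1}" for i in range(len(reads))], path)


def read_reads_bed(path) -> list[GenomicInterval]:
    return [iv for _, iv in read_bed6(path)]


def write_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
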