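"""MeDIP-score computation: read extension, regional scoring, status calls.

The MeDIP-score of a region is the number of extended reads overlapping it
(by >= 1 bp) per kb of region length.  Reads are first extended to a fixed
fragment length (default 250 bp) in their 3' direction, because the
sequenced read is much shorter than the immunoprecipitated fragment.
Status thresholds partition [0, inf): below 9.48 reads/kb a region is
called unmethylated, above 50.62 completely methylated, and partially
methylated in the closed interval between.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

UNMETHYLATED = "unmethylated"
PARTIAL = "partial"
METHYLATED = "methylated"


@dataclass(frozen=True)
class ScoringConfig:
    extension_length: int = 250
    unmethylated_max: float = 9.48
    methylated_min: float = 50.62
    normalize: str = "none"  # {"none", "per-million"}

    def __post_init__(self) -> None:
        if self.extension_length <= 0:
            raise ValueError("extension_length must be positive")
        if not (0 < self.unmethylated_max < self.methylated_min):
            raise ValueError("need 0 < unmethylated_max < methylated_min")
        if self.normalize not in ("none", "per-million"):
            raise ValueError("normalize must be 'none' or 'per-million'")


@dataclass(frozen=True)
class RegionScore:
    region: GenomicInterval
    sample: str
    score: float
    status: str


def extend_read(read: GenomicInterval, cfg: ScoringConfig = ScoringConfig()) -> GenomicInterval:
    """Extend a stranded read to ``extension_length`` from its 5' end.

    ``+`` reads keep their start; ``-`` reads keep their end.  Clipped at 0.
    """
    if read.strand == "+":
        return GenomicInterval(read.chrom, read.start, read.start + cfg.extension_length, "+")
    if read.strand == "-":
        start = read.end - cfg.extension_length
        if start < 0:
            log.warning("extended read clipped at contig start (%d -> 0)", start)
            start = 0
        return GenomicInterval(read.chrom, start, read.end, "-")
    raise ValueError("cannot extend read with ambiguous strand '.'")


def classify_status(score: float, cfg: ScoringConfig = ScoringConfig()) -> str:
    """Trichotomous status; boundary scores fall in the partial class."""
    if score < 0:
        raise ValueError(f"MeDIP-score must be non-negative, got {score}")
    if score < cfg.unmethylated_max:
        return UNMETHYLATED
    if score <= cfg.methylated_min:
        return PARTIAL
    return METHYLATED


def medip_score(
    region: GenomicInterval,
    extended_reads: Iterable[GenomicInterval],
    cfg: ScoringConfig = ScoringConfig(),
    library_size: int | None = None,
) -> float:
    """Extended reads overlapping ``region`` by >= 1 bp, per kb of region."""
    count = sum(1 for r in extended_reads if r.overlaps(region))
    if cfg.normalize == "per-million":
        if not library_size:
            raise ValueError("per-million normalization requires library_size")
        count = count * 1e6 / library_size
    return count / (region.length / 1000.0)


def _overlap_counts(
    regions: Sequence[GenomicInterval], reads: Sequence[GenomicInterval]
) -> np.ndarray:
    """Vector of per-region overlap counts, grouped by chromosome.

    A read [rs, re) overlaps region [s, e) iff rs < e and re > s, so the
    count is #(rs < e) - #(re <= s) over sorted read endpoints.
    """
    counts = np.zeros(len(regions), dtype=np.int64)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    sorted_ends: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, rs in by_chrom.items():
        starts = np.sort(np.array([r.start for r in rs]))
        ends = np.sort(np.array([r.end for r in rs]))
        sorted_ends[chrom] = (starts, ends)
    for i, region in enumerate(regions):
        se = sorted_ends.get(region.chrom)
        if se is None:
            continue
        starts, ends = se
        counts[i] = np.searchsorted(starts, region.end, side="left") - np.searchsorted(
            ends, region.start, side="right"
        )
    return counts


def score_matrix(
    sample_reads: Mapping[str, Sequence[GenomicInterval]],
    regions: Sequence[GenomicInterval],
    cfg: ScoringConfig = ScoringConfig(),
    region_ids: Sequence[str] | None = None,
    extend: bool = True,
) -> pd.DataFrame:
    """Long-format table of per-region, per-sample scores and status calls.

    ``sample_reads`` maps sample id -> raw reads (extended here unless
    ``extend=False``).  Rows are sorted by region coordinate then sample id.
    Raises if any sample's reads name chromosomes absent from ``regions``.
    """
    region_chroms = {r.chrom for r in regions}
    for sample, reads in sample_reads.items():
        bad = sorted({r.chrom for r in reads} - region_chroms)
        if bad:
            raise ValueError(
                f"sample {sample!r} has reads on chromosomes absent from the "
                f"region set: {', '.join(bad)}"
            )
    if region_ids is None:
        region_ids = [f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    order = sorted(
        range(len(regions)),
        key=lambda i: (regions[i].chrom, regions[i].start, regions[i].end),
    )
    rows = []
    lengths_kb = np.array([r.length / 1000.0 for r in regions])
    for sample in sorted(sample_reads):
        reads = sample_reads[sample]
        ext = [extend_read(r, cfg) for r in reads] if extend else list(reads)
        counts = _overlap_counts(regions, ext).astype(float)
        if cfg.normalize == "per-million":
            lib = max(len(ext), 1)
            counts = counts * 1e6 / lib
        scores = counts / lengths_kb if len(regions) else counts
        for i in order:
            rows.append(
                {
                    "region_id": region_ids[i],
                    "chrom": regions[i].chrom,
                    "start": regions[i].start,
                    "end": regions[i].end,
                    "strand": regions[i].strand,
                    "sample": sample,
                    "score": scores[i],
                    "status": classify_status(scores[i], cfg),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["region_id", "chrom", "start", "end", "strand", "sample", "score", "status"],
    )
    return df.sort_values(["chrom", "start", "end", "sample"], kind="stable").reset_index(drop=True)


def wide_scores(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long score table to regions x samples."""
    return matrix.pivot_table(index="region_id", columns="sample", values="score", sort=False)
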