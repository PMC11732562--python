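"""Synthetic inputs for the whole pipeline, with known planted truth.

Emulates a two-group (sedentary vs exercise-trained) MeDIP-seq design on a
small genome:

* a GC-heterogeneous, CpG-depleted background sequence (first-order
  suppression of CpG dinucleotides, as in mammalian genomes);
* non-overlapping single-isoform genes on both strands, each with a
  TSS-proximal CpG-enriched segment (most mammalian promoters are
  CpG-island promoters);
* optional intergenic CpG islands satisfying the island criteria by
  construction (count controlled by ``island_density``) — these are the
  island truth spans;
* a per-region ground-truth methylome for the two conditions, with a
  configurable fraction of promoters carrying planted DMRs of configurable
  multiplicative effect;
* MeDIP reads whose regional abundance is proportional to methylated-CpG
  mass (level x CpG count) plus a uniform background component;
* bisulfite-pyrosequencing C/T counts per CpG with conversion-control
  counts at non-CpG cytosines.

Every output is a pure function of (config, seed); per-sample RNG streams
are keyed by (seed, group, sample index) so adding samples never reshuffles
earlier ones.
"""
from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .annotation import AnnotationConfig, gc_content, cpg_obs_exp, gene_body_interval, promoter_interval
from .intervals import GeneModel, GenomicInterval
from .pyro import PyroSample

CHROM = "chrS"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
SEDENTARY = "sedentary"
TRAINED = "trained"
_GROUP_CODE = {SEDENTARY: 0, TRAINED: 1}


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 50_000
    n_genes: int = 10
    n_samples_per_group: int = 4
    island_density: float = 10.0  # intergenic islands per 100 kb
    planted_dmr_fraction: float = 0.1
    dmr_effect: float = 3.0  # multiplicative methylation shift, >= 1
    mean_depth: int = 10_000  # reads per sample (Poisson mean)
    background_rate: float = 0.1  # fraction of reads placed uniformly
    pyro_depth: int = 100  # reads per CpG in pyrosequencing
    conversion_efficiency: float = 0.99
    seed: int = 0
    # genome geometry (free parameters of the generator, not of the assay)
    gene_length_range: tuple[int, int] = (1200, 4000)
    gene_spacing: int = 1600  # must fit two facing promoters (2 x 700 bp)

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10,000 bp")
        for name in ("n_genes", "n_samples_per_group", "mean_depth", "pyro_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("planted_dmr_fraction", "background_rate", "conversion_efficiency"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dmr_effect < 1:
            raise ValueError("dmr_effect must be >= 1")
        if self.island_density < 0:
            raise ValueError("island_density must be >= 0")


@dataclass(frozen=True)
class SyntheticGenome:
    sequence: str
    genes: tuple[GeneModel, ...]
    island_truth: tuple[GenomicInterval, ...]

    @property
    def chrom(self) -> str:
        return CHROM


@dataclass(frozen=True)
class Methylome:
    """Non-overlapping regions with per-condition methylation levels."""

    regions: pd.DataFrame  # region_id, chrom, start, end, strand, kind,
    #                        cpg_count, level_sedentary, level_trained

    def __post_init__(self) -> None:
        df = self.regions
        for cond in (SEDENTARY, TRAINED):
            col = df[f"level_{cond}"]
            if ((col < 0) | (col > 1)).any():
                raise ValueError("methylation levels must lie in [0, 1]")
        srt = df.sort_values(["chrom", "start"])
        overlap = (srt["start"].to_numpy()[1:] < srt["end"].to_numpy()[:-1]) & (
            srt["chrom"].to_numpy()[1:] == srt["chrom"].to_numpy()[:-1]
        )
        if overlap.any():
            raise ValueError("methylome regions must be non-overlapping")

    def level(self, region_id: str, condition: str) -> float:
        row = self.regions.loc[self.regions["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"methylome has no region {region_id!r}")
        return float(row.iloc[0][f"level_{condition}"])

    def interval(self, region_id: str) -> GenomicInterval:
        row = self.regions.loc[self.regions["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"methylome has no region {region_id!r}")
        r = row.iloc[0]
        return GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), r["strand"])


# ---------------------------------------------------------------------------
# genome


def _random_background(rng: np.random.Generator, length: int) -> np.ndarray:
    """CpG-depleted background with per-kb GC heterogeneity (uint8 codes)."""
    n_blocks = length // 1000 + 1
    gc = np.clip(rng.normal(0.40, 0.04, size=n_blocks), 0.30, 0.47)
    gc_per_base = np.repeat(gc, 1000)[:length]
    p = np.column_stack(
        [(1 - gc_per_base) / 2, gc_per_base / 2, gc_per_base / 2, (1 - gc_per_base) / 2]
    )  # A, C, G, T
    u = rng.random(length)
    codes = (u[:, None] > p.cumsum(axis=1)).sum(axis=1).astype(np.uint8)
    # deplete CpGs: most C->G steps are mutated G->A, as in mammalian genomes
    is_cpg_g = np.zeros(length, dtype=bool)
    is_cpg_g[1:] = (codes[:-1] == 1) & (codes[1:] == 2)
    mutate = is_cpg_g & (rng.random(length) < 0.75)
    codes[mutate] = 0
    return codes


def _cpg_rich_segment(
    rng: np.random.Generator, length: int, gc: float, cpg_step: int
) -> np.ndarray:
    """GC-rich segment with CG dinucleotides planted every ~cpg_step bp."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    u = rng.random(length)
    codes = (u[:, None] > p.cumsum()).sum(axis=1).astype(np.uint8)
    starts = np.arange(0, length - 1, cpg_step)
    jitter = rng.integers(0, max(cpg_step // 2, 1), size=len(starts))
    pos = np.minimum(starts + jitter, length - 2)
    codes[pos] = 1  # C
    codes[pos + 1] = 2  # G
    return codes


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def simulate_genome(config: SimConfig) -> SyntheticGenome:
    """Genome sequence, gene models, and planted-island truth spans.

    Genes are placed left-to-right with ``gene_spacing`` gaps and alternating
    strands (shuffled); every TSS gets a 250 bp CpG-enriched segment;
    intergenic islands (>= island criteria by construction) are planted in
    the gaps at ``island_density`` per 100 kb.  Raises when the genome is too
    short to host the requested genes.
    """
    rng = np.random.default_rng([config.seed, 101])
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    required = int(lengths.sum()) + (config.n_genes + 1) * config.gene_spacing
    if required > config.genome_length:
        raise ValueError(
            f"genome too short to host {config.n_genes} genes: needs >= "
            f"{required} bp (gene lengths + {config.gene_spacing} bp spacing), "
            f"got genome_length={config.genome_length}"
        )
    codes = _random_background(rng, config.genome_length)
    # spread the slack evenly-ish between genes
    slack = config.genome_length - required
    extra = rng.multinomial(slack, np.ones(config.n_genes + 1) / (config.n_genes + 1))
    strands = np.array(["+", "-"])[rng.integers(0, 2, size=config.n_genes)]
    genes: list[GeneModel] = []
    cursor = config.gene_spacing + int(extra[0])
    gaps: list[tuple[int, int]] = [(0, cursor)]
    for i in range(config.n_genes):
        start = cursor
        end = start + int(lengths[i])
        genes.append(
            GeneModel(f"gene{i + 1:04d}", GenomicInterval(CHROM, start, end, strands[i]))
        )
        cursor = end + config.gene_spacing + int(extra[i + 1])
        gaps.append((end, min(cursor, config.genome_length)))
    # TSS-proximal CpG enrichment (not part of the island truth)
    for g in genes:
        tss = g.tss
        seg = _cpg_rich_segment(rng, 250, gc=0.55, cpg_step=10)
        s = max(0, min(tss - 125, config.genome_length - 250))
        codes[s : s + 250] = seg
    # intergenic planted islands
    n_islands = round(config.island_density * config.genome_length / 100_000)
    island_truth: list[GenomicInterval] = []
    promoter_spans = [
        (p.start, p.end) for p in (promoter_interval(g) for g in genes)
    ]
    usable_gaps = [
        (a, b) for a, b in gaps if b - a >= 800
    ]
    for k in range(n_islands):
        if not usable_gaps:
            break
        a, b = usable_gaps[k % len(usable_gaps)]
        length = int(rng.integers(250, 601))
        # keep clear of promoters that reach into the gap
        lo_ok = a + 720
        hi_ok = b - 720 - length
        if hi_ok <= lo_ok:
            continue
        s = int(rng.integers(lo_ok, hi_ok + 1))
        for _ in range(5):  # regenerate until the criteria hold (they nearly always do)
            seg = _cpg_rich_segment(rng, length, gc=0.65, cpg_step=8)
            text = _codes_to_str(seg)
            if gc_content(text) >= 0.55 and cpg_obs_exp(text) >= 0.7:
                break
        codes[s : s + length] = seg
        island_truth.append(GenomicInterval(CHROM, s, s + length, "."))
    return SyntheticGenome(
        sequence=_codes_to_str(codes),
        genes=tuple(genes),
        island_truth=tuple(sorted(island_truth)),
    )


def _interleave(piece_a: str, n_a: int, piece_b: str, n_b: int) -> str:
    """Evenly interleave n_a copies of piece_a with n_b of piece_b
    (Bresenham spread), so composition is homogeneous at any scale."""
    total = n_a + n_b
    is_b = [False] * total
    for j in range(n_b):
        is_b[int((j + 0.5) * total / max(n_b, 1))] = True
    return "".join(piece_b if flag else piece_a for flag in is_b)


def segment_with_gc(length: int, gc_percent: int) -> str:
    """Deterministic CpG-bearing segment of exact GC composition.

    Built from 'CGAT' units (50% GC, one CpG each) diluted with 'AT' pairs
    (below 50%) or enriched with 'CG' pairs (above 50%), interleaved evenly
    so every sub-window shares the global composition to within ~1%.  The
    CpG obs/exp ratio stays well above 1.  ``length`` must be a multiple of
    4 and the GC percentage reachable on that grid.
    """
    if length % 4:
        raise ValueError("length must be a multiple of 4")
    n_gc = length * gc_percent // 100
    if length * gc_percent % 100:
        raise ValueError(f"{gc_percent}% GC is not exact over {length} bp")
    if gc_percent <= 50:
        # a * CGAT + b * AT:  4a + 2b = length,  2a = n_gc
        a = n_gc // 2
        b = (length - 4 * a) // 2
        if n_gc % 2 or (length - 4 * a) % 2:
            raise ValueError("composition not representable")
        return _interleave("CGAT", a, "AT", b)
    # x * CG + y * CGAT:  2x + 4y = length,  2x + 2y = n_gc
    y = (length - n_gc) // 2
    x = (n_gc - 2 * y) // 2
    if x < 0 or 2 * x + 4 * y != length or 2 * x + 2 * y != n_gc:
        raise ValueError("composition not representable")
    return _interleave("CGAT", y, "CG", x)


def segment_with_obs_exp(length: int, n_cpg: int) -> str:
    """Deterministic GC-rich segment with an exact CpG count.

    Tiles of 15 bp, each with 5 C and 5 G and 0/1/2 internal CpGs, start
    and end with 'A' so junctions never create CpGs; tiles are interleaved
    evenly.  GC is fixed at 2/3 and obs/exp = n_cpg * length / (L/3)^2.
    ``length`` must be a multiple of 15 and n_cpg <= 2 * length / 15.
    """
    if length % 15:
        raise ValueError("length must be a multiple of 15")
    n_tiles = length // 15
    if not (0 <= n_cpg <= 2 * n_tiles):
        raise ValueError("n_cpg out of range for this length")
    tile0 = "AGGGGGCCCCCAAAA"  # 0 CpG
    tile1 = "AGGGGCGCCCCAAAA"  # 1 CpG
    tile2 = "AGGGCGCGCCCAAAA"  # 2 CpG
    if n_cpg <= n_tiles:
        return _interleave(tile0, n_tiles - n_cpg, tile1, n_cpg)
    n2 = n_cpg - n_tiles  # tile1 + tile2 mix: n1 + 2*n2 = n_cpg
    return _interleave(tile1, n_tiles - n2, tile2, n2)


# ---------------------------------------------------------------------------
# methylome


_LEVEL_RANGES = {
    "promoter": (0.10, 0.30),  # CpG-island promoters are lowly methylated
    "gene_body": (0.50, 0.80),  # gene bodies of expressed genes are methylated
    "island": (0.05, 0.20),  # intergenic islands mostly unmethylated
    "background": (0.40, 0.70),  # bulk genome
}


def _count_cpgs(sequence: str, start: int, end: int) -> int:
    return sequence.count("CG", start, max(start, end - 1) + 1)


def build_methylome(
    genome: SyntheticGenome,
    config: SimConfig,
    annotation_cfg: AnnotationConfig = AnnotationConfig(),
) -> tuple[Methylome, pd.DataFrame]:
    """Ground-truth methylome + TruthTable of planted promoter DMRs.

    Regions (all mutually non-overlapping, in priority order): promoters,
    gene bodies, planted intergenic islands, then 1 kb background bins over
    whatever remains.  Planted DMR count = round(fraction x n_promoters);
    directions alternate hyper/hypo over a seeded shuffle; hyper multiplies
    the sedentary level by ``dmr_effect`` (capped at 0.95), hypo divides.
    """
    rng = np.random.default_rng([config.seed, 202])
    L = len(genome.sequence)
    occupied: list[tuple[int, int]] = []
    rows: list[dict] = []

    def claim(start: int, end: int) -> tuple[int, int] | None:
        start, end = max(0, start), min(L, end)
        for a, b in occupied:
            if start < b and a < end:
                return None
        occupied.append((start, end))
        return start, end

    for g in genome.genes:
        p = promoter_interval(g, annotation_cfg)
        span = claim(p.start, p.end)
        if span is None:
            raise ValueError(f"promoter of {g.id} overlaps an already-claimed region")
        rows.append({"region_id": g.id, "kind": "promoter",
                     "start": span[0], "end": span[1], "strand": g.strand})
    for g in genome.genes:
        b = gene_body_interval(g, annotation_cfg)
        if b is None:
            continue
        span = claim(b.start, b.end)
        if span is not None:
            rows.append({"region_id": f"{g.id}_body", "kind": "gene_body",
                         "start": span[0], "end": span[1], "strand": g.strand})
    for i, isl in enumerate(genome.island_truth, 1):
        span = claim(isl.start, isl.end)
        if span is not None:
            rows.append({"region_id": f"island{i:04d}", "kind": "island",
                         "start": span[0], "end": span[1], "strand": "."})
    occupied.sort()
    free: list[tuple[int, int]] = []
    cursor = 0
    for a, b in occupied:
        if a > cursor:
            free.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < L:
        free.append((cursor, L))
    k = 0
    for a, b in free:
        for s in range(a, b, 1000):
            e = min(s + 1000, b)
            if e - s >= 200:
                k += 1
                rows.append({"region_id": f"bg{k:05d}", "kind": "background",
                             "start": s, "end": e, "strand": "."})
    df = pd.DataFrame(rows)
    df["chrom"] = CHROM
    df["cpg_count"] = [
        _count_cpgs(genome.sequence, s, e) for s, e in zip(df["start"], df["end"])
    ]
    lo = np.array([_LEVEL_RANGES[k][0] for k in df["kind"]])
    hi = np.array([_LEVEL_RANGES[k][1] for k in df["kind"]])
    sed = lo + (hi - lo) * rng.random(len(df))
    trn = sed.copy()
    promoter_ids = [g.id for g in genome.genes]
    n_planted = round(config.planted_dmr_fraction * len(promoter_ids))
    planted_idx = rng.choice(len(promoter_ids), size=n_planted, replace=False)
    directions = np.where(np.arange(n_planted) % 2 == 0, "hypo", "hyper")
    rng.shuffle(directions)
    truth_rows = []
    id_to_row = {rid: i for i, rid in enumerate(df["region_id"])}
    planted = {promoter_ids[i]: d for i, d in zip(planted_idx, directions)}
    for gid in promoter_ids:
        d = planted.get(gid)
        if d is not None:
            i = id_to_row[gid]
            if d == "hyper":
                trn[i] = min(sed[i] * config.dmr_effect, 0.95)
            else:
                trn[i] = sed[i] / config.dmr_effect
        truth_rows.append({
            "gene_id": gid,
            "is_planted_dmr": d is not None,
            "direction": d if d is not None else "",
            "effect": config.dmr_effect if d is not None else 1.0,
        })
    df["level_sedentary"] = sed
    df["level_trained"] = trn
    df = df[["region_id", "chrom", "start", "end", "strand", "kind",
             "cpg_count", "level_sedentary", "level_trained"]]
    df = df.sort_values(["start", "end"]).reset_index(drop=True)
    return Methylome(df), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# MeDIP reads


def simulate_medip_reads(
    genome: SyntheticGenome,
    methylome: Methylome,
    config: SimConfig,
    group: str,
) -> dict[str, list[GenomicInterval]]:
    """Aligned single-end reads per sample for one condition.

    Per sample: total reads ~ Poisson(mean_depth); a fraction
    ``background_rate`` is placed uniformly on the genome, the rest across
    regions with probability proportional to level x CpG count; read start
    uniform within the chosen region; length uniform in 36-150 bp; strand
    uniform.  Deterministic given (config.seed, group, sample index).
    """
    if group not in _GROUP_CODE:
        raise ValueError(f"group must be one of {sorted(_GROUP_CODE)}")
    for g in genome.genes:
        if not (methylome.regions["region_id"] == g.id).any():
            raise ValueError(f"methylome does not cover promoter region of {g.id}")
    df = methylome.regions
    level = df[f"level_{group}"].to_numpy()
    weight = level * df["cpg_count"].to_numpy(dtype=float)
    total_w = weight.sum()
    L = len(genome.sequence)
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    prefix = "sed" if group == SEDENTARY else "trn"
    out: dict[str, list[GenomicInterval]] = {}
    for s_idx in range(config.n_samples_per_group):
        rng = np.random.default_rng([config.seed, _GROUP_CODE[group], s_idx, 303])
        sample = f"{prefix}{s_idx + 1}"
        n_total = rng.poisson(config.mean_depth)
        if total_w == 0 and config.background_rate == 0:
            out[sample] = []
            continue
        n_bg = rng.binomial(n_total, config.background_rate)
        n_sig = n_total - n_bg if total_w > 0 else 0
        reads: list[GenomicInterval] = []
        if n_sig > 0:
            counts = rng.multinomial(n_sig, weight / total_w)
            for i in np.flatnonzero(counts):
                c = int(counts[i])
                pos = rng.integers(starts[i], ends[i], size=c)
                lens = rng.integers(36, 151, size=c)
                strands = rng.integers(0, 2, size=c)
                for p, ln, st in zip(pos, lens, strands):
                    e = min(int(p) + int(ln), L)
                    reads.append(
                        GenomicInterval(CHROM, int(p), e, "+" if st == 0 else "-")
                    )
        if n_bg > 0:
            pos = rng.integers(0, L - 36, size=n_bg)
            lens = rng.integers(36, 151, size=n_bg)
            strands = rng.integers(0, 2, size=n_bg)
            for p, ln, st in zip(pos, lens, strands):
                e = min(int(p) + int(ln), L)
                reads.append(GenomicInterval(CHROM, int(p), e, "+" if st == 0 else "-"))
        reads.sort(key=lambda r: (r.start, r.end))
        out[sample] = reads
    return out


# ---------------------------------------------------------------------------
# pyrosequencing


def simulate_pyro_counts(
    methylome: Methylome,
    region_id: str,
    genome: SyntheticGenome,
    config: SimConfig,
    site_sd: float = 0.03,
) -> list[PyroSample]:
    """Pyrosequencing counts for every sample of both conditions at one region.

    Per CpG site: nC ~ Binomial(pyro_depth, site level), where site levels
    are the regional truth level plus a small per-site offset (sd
    ``site_sd``, drawn once per region, shared across samples).  Conversion
    controls: unconverted ~ Binomial(depth, 1 - conversion_efficiency) at up
    to 5 non-CpG cytosines.  Raises when the region contains no CpG.
    """
    iv = methylome.interval(region_id)
    seq = genome.sequence[iv.start : iv.end]
    cpg_pos = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
    if not cpg_pos:
        raise ValueError(f"region {region_id!r} contains no CpG site")
    non_cpg_c = [i for i in range(len(seq)) if seq[i] == "C" and i not in cpg_pos][:5]
    n_ctrl = max(len(non_cpg_c), 1)
    region_rng = np.random.default_rng([config.seed, 404, iv.start])
    offsets = region_rng.normal(0.0, site_sd, size=len(cpg_pos))
    samples: list[PyroSample] = []
    for group in (SEDENTARY, TRAINED):
        base = methylome.level(region_id, group)
        levels = np.clip(base + offsets, 0.0, 1.0)
        for s_idx in range(config.n_samples_per_group):
            rng = np.random.default_rng(
                [config.seed, _GROUP_CODE[group], s_idx, 505, iv.start]
            )
            n_c = rng.binomial(config.pyro_depth, levels)
            counts = tuple(
                (int(c), int(config.pyro_depth - c)) for c in n_c
            )
            unconv = int(
                rng.binomial(config.pyro_depth * n_ctrl, 1 - config.conversion_efficiency)
            )
            samples.append(
                PyroSample(
                    sample_id=f"{'sed' if group == SEDENTARY else 'trn'}{s_idx + 1}",
                    condition=group,
                    site_counts=counts,
                    control_converted=config.pyro_depth * n_ctrl - unconv,
                    control_unconverted=unconv,
                )
            )
    return samples
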