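"""End-to-end orchestration: simulate -> annotate -> score -> DMR ->
enrich/scan -> pyro-validate, with every stage artifact written to disk and
an evaluation report against the planted truth.

The run is a pure function of the YAML-serializable :class:`PipelineConfig`
(one root seed drives every stage), and the report records the filter
cascade counts (all promoters -> p/FC filter -> score filter) together with
sensitivity and observed FDR against the truth table.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .annotation import AnnotationConfig, find_cpg_islands, promoter_interval
from .dmr import DmrConfig, call_dmrs, dmr_table, evaluate_against_truth, filter_candidates
from .enrichment import GeneSet, gsea_significance, write_gmt
from .intervals import GenomicInterval
from .motif import PositionWeightMatrix, hits_to_bed, scan_sequence, write_jaspar_pfm
from .pyro import analyze_samples
from .scoring import ScoringConfig, score_matrix
from .synthetic import (
    SEDENTARY,
    TRAINED,
    SimConfig,
    build_methylome,
    simulate_genome,
    simulate_medip_reads,
    simulate_pyro_counts,
)

log = logging.getLogger(__name__)

# A synthetic NBRE-like motif (nuclear-receptor half site AAAGGTCA):
# counts are invented for testing/demonstration, not a database matrix.
SYNTHETIC_NBRE_COUNTS = np.array(
    [
        [90, 88, 86, 2, 2, 3, 2, 88],  # A
        [4, 4, 5, 3, 3, 4, 90, 4],  # C
        [2, 4, 5, 92, 92, 3, 3, 4],  # G
        [4, 4, 4, 3, 3, 90, 5, 4],  # T
    ],
    dtype=float,
)


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    dmr: DmrConfig = field(default_factory=DmrConfig)
    gsea_permutations: int = 1000
    gsea_weight_p: float = 1.0
    motif_threshold: float = 0.8  # fraction of max achievable log-odds
    pyro_min_efficiency: float = 0.95
    n_pyro_regions: int = 3
    scan_islands: bool = True

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        sim = dict(raw.get("sim", {}))
        if "gene_length_range" in sim:
            sim["gene_length_range"] = tuple(sim["gene_length_range"])
        kwargs = {
            "sim": SimConfig(**sim),
            "annotation": AnnotationConfig(**raw.get("annotation", {})),
            "scoring": ScoringConfig(**raw.get("scoring", {})),
            "dmr": DmrConfig(**raw.get("dmr", {})),
        }
        for key in (
            "gsea_permutations", "gsea_weight_p", "motif_threshold",
            "pyro_min_efficiency", "n_pyro_regions", "scan_islands",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _log_thresholds(cfg: PipelineConfig) -> None:
    log.info(
        "thresholds: extension=%d bp, status=[%.2f, %.2f] reads/kb, "
        "p<%.2g, FC>%.2f, min MeDIP score>%.1f, promoter=-%d/+%d",
        cfg.scoring.extension_length, cfg.scoring.unmethylated_max,
        cfg.scoring.methylated_min, cfg.dmr.p_threshold, cfg.dmr.fc_threshold,
        cfg.dmr.min_medip_score, cfg.annotation.promoter_upstream,
        cfg.annotation.promoter_downstream,
    )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage, write artifacts under ``outdir``, return the report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _log_thresholds(config)
    (out / "config.yaml").write_text(config.to_yaml())

    # --- simulate ---------------------------------------------------------
    genome = simulate_genome(config.sim)
    methylome, truth = build_methylome(genome, config.sim, config.annotation)
    mio.write_fasta({genome.chrom: genome.sequence}, out / "genome.fa")
    mio.write_bed12(genome.genes, out / "genes.bed")
    mio.write_gff3(genome.genes, out / "genes.gff3")
    mio.write_tsv(methylome.regions, out / "methylome_truth.tsv")
    mio.write_tsv(truth, out / "dmr_truth.tsv")
    reads = {}
    for group in (SEDENTARY, TRAINED):
        reads.update(simulate_medip_reads(genome, methylome, config.sim, group))
    for sample, rs in reads.items():
        mio.write_reads_bed(rs, sample, out / f"reads_{sample}.bed")
    groups = {s: (SEDENTARY if s.startswith("sed") else TRAINED) for s in reads}

    # --- annotate ---------------------------------------------------------
    promoters = {g.id: promoter_interval(g, config.annotation) for g in genome.genes}
    islands = find_cpg_islands(genome.sequence, config.annotation, genome.chrom)
    mio.write_bed6(
        [i.interval for i in islands],
        [f"CpG_island_{k + 1}" for k in range(len(islands))],
        out / "cpg_islands.bed",
    )
    mio.write_bed6(list(promoters.values()), list(promoters), out / "promoters.bed")

    # --- score ------------------------------------------------------------
    matrix = score_matrix(
        reads, list(promoters.values()), config.scoring, region_ids=list(promoters)
    )
    mio.write_tsv(matrix, out / "promoter_scores.tsv",
                  header_comment=f"MeDIP-scores (reads/kb); {config.scoring}")

    # --- DMR cascade ------------------------------------------------------
    dmrs = call_dmrs(matrix, promoters, groups, config.dmr)
    passing = [r for r in dmrs if r.passes_filters]
    candidates = filter_candidates(dmrs, config.dmr)
    mio.write_tsv(dmr_table(dmrs), out / "dmr_all.tsv")
    mio.write_tsv(dmr_table(candidates), out / "dmr_candidates.tsv")
    evaluation = evaluate_against_truth(dmrs, truth)
    cascade = {
        "promoters_tested": len(dmrs),
        "pass_p_and_fc": len(passing),
        "pass_score_filter": len(candidates),
    }

    # --- enrichment -------------------------------------------------------
    ranked = sorted(dmrs, key=lambda r: r.log2fc, reverse=True)
    ranked_ids = [r.gene_id for r in ranked]
    metric = [r.log2fc for r in ranked]
    planted_ids = frozenset(truth.loc[truth["is_planted_dmr"], "gene_id"])
    rng = np.random.default_rng([config.sim.seed, 606])
    gene_sets = []
    if planted_ids:
        gene_sets.append(GeneSet("planted_dmr_genes", planted_ids,
                                 "genes with planted promoter DMRs"))
    n_rand = max(5, len(planted_ids) or 5)
    gene_sets.append(GeneSet(
        "random_genes",
        frozenset(rng.choice(ranked_ids, size=min(n_rand, len(ranked_ids)),
                             replace=False)),
        "seeded random control set",
    ))
    write_gmt(gene_sets, out / "gene_sets.gmt")
    enr_rows = []
    for gs in gene_sets:
        res = gsea_significance(
            ranked_ids, metric, gs, n_perm=config.gsea_permutations,
            seed=config.sim.seed, weight_p=config.gsea_weight_p,
        )
        enr_rows.append({
            "set": res.set_name, "es": res.es, "nes": res.nes,
            "p": res.p_value, "n_hits": res.n_hits,
            "leading_edge": ",".join(res.leading_edge),
        })
    enrichment = pd.DataFrame(enr_rows)
    mio.write_tsv(enrichment, out / "enrichment.tsv")

    # --- motif scan in candidate promoters --------------------------------
    pwm = PositionWeightMatrix("NBRE_synthetic", SYNTHETIC_NBRE_COUNTS)
    write_jaspar_pfm([pwm], out / "motifs.pfm")
    all_hits = []
    scan_targets = candidates if candidates else passing
    for rec in scan_targets:
        seq = genome.sequence[rec.region.start : rec.region.end]
        for h in scan_sequence(pwm, seq, config.motif_threshold, "fraction",
                               chrom=genome.chrom):
            iv = GenomicInterval(
                genome.chrom,
                rec.region.start + h.interval.start,
                rec.region.start + h.interval.end,
                h.strand,
            )
            all_hits.append(dataclasses.replace(h, interval=iv))
    (out / "motif_hits.bed").write_text(hits_to_bed(all_hits))

    # --- pyro validation of top candidates --------------------------------
    pyro_rows = []
    top = (candidates or passing or dmrs)[: config.n_pyro_regions]
    for rec in top:
        samples = simulate_pyro_counts(methylome, rec.gene_id, genome, config.sim)
        result = analyze_samples(samples, config.pyro_min_efficiency)
        per_site = result["per_site"]
        truth_sed = methylome.level(rec.gene_id, SEDENTARY) * 100
        truth_trn = methylome.level(rec.gene_id, TRAINED) * 100
        pyro_rows.append({
            "gene": rec.gene_id,
            "n_sites": int(per_site.shape[0]),
            "mean_sed_pct": float(per_site["mean_sedentary"].mean()),
            "mean_trn_pct": float(per_site["mean_trained"].mean()),
            "truth_sed_pct": truth_sed,
            "truth_trn_pct": truth_trn,
            "anova_condition_p": float(
                result["anova"].set_index("factor").loc["condition", "p"]
            ),
            "n_qc_fail": int((~result["qc"]["passes"]).sum()),
        })
    pyro_df = pd.DataFrame(pyro_rows)
    if not pyro_df.empty:
        mio.write_tsv(pyro_df, out / "pyro_validation.tsv")

    report = {
        "cascade": cascade,
        "evaluation": evaluation,
        "n_islands_detected": len(islands),
        "n_islands_planted": len(genome.island_truth),
        "n_motif_hits": len(all_hits),
        "enrichment": enr_rows,
        "pyro": pyro_rows,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _write_markdown_report(report, out / "report.md")
    return report


def _write_markdown_report(report: dict, path: Path) -> None:
    c = report["cascade"]
    e = report["evaluation"]
    lines = [
        "# Pipeline run report",
        "",
        "## Filter cascade",
        f"- promoters tested: {c['promoters_tested']}",
        f"- pass p/FC filter: {c['pass_p_and_fc']}",
        f"- pass MeDIP-score filter: {c['pass_score_filter']}",
        "",
        "## DMR evaluation vs planted truth",
        f"- sensitivity: {e['sensitivity']:.3f}" if e["sensitivity"] == e["sensitivity"]
        else "- sensitivity: n/a (nothing planted)",
        f"- observed FDR: {e['observed_fdr']:.3f}",
        f"- direction concordance: {e['direction_concordance']:.3f}"
        if e["direction_concordance"] == e["direction_concordance"]
        else "- direction concordance: n/a",
        "",
        f"## Islands: {report['n_islands_detected']} detected "
        f"({report['n_islands_planted']} planted)",
        f"## Motif hits in candidate promoters: {report['n_motif_hits']}",
    ]
    path.write_text("\n".join(lines) + "\n")
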