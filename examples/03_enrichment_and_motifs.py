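"""Rank-based gene-set enrichment of DMR results and promoter motif scanning.

Ranks 200 genes by a synthetic DMR log2 fold-change in which the members of
a 'lipid metabolism' toy set are concentrated at the hypermethylated end,
computes the GSEA enrichment score with a gene-permutation p-value, then
scans a promoter sequence carrying a planted NBRE-like (nuclear-receptor
half-site) motif on the reverse strand.
"""
import numpy as np

from medipkit import GeneSet, PositionWeightMatrix, gsea_significance, scan_sequence
from medipkit.pipeline import SYNTHETIC_NBRE_COUNTS

rng = np.random.default_rng(1)
genes = [f"gene{i:03d}" for i in range(200)]
metric = np.sort(rng.normal(0, 1, 200))[::-1]  # signed log2 fold-changes
lipid_set = GeneSet("lipid_metabolism_toy", frozenset(genes[:15]),
                    "toy set loaded at the top of the ranking")
random_set = GeneSet("random_toy", frozenset(rng.choice(genes, 15, replace=False)),
                     "seeded random control")

for gs in (lipid_set, random_set):
    res = gsea_significance(genes, metric.tolist(), gs, n_perm=1000, seed=3)
    print(f"{gs.name}: ES={res.es:+.3f}, NES={res.nes:+.2f}, p={res.p_value:.4f}, "
          f"leading edge {len(res.leading_edge)}/{res.n_hits} genes")
print("A positive ES near +1 with small p marks a set concentrated among "
      "hypermethylated promoters; the random set should be non-significant.\n")

pwm = PositionWeightMatrix("NBRE_synthetic", SYNTHETIC_NBRE_COUNTS)
consensus = pwm.consensus()
comp = str.maketrans("ACGT", "TGCA")
flank = "".join(rng.choice(list("ACGT"), 120))
promoter = flank + consensus.translate(comp)[::-1] + flank  # motif on '-' strand
hits = scan_sequence(pwm, promoter, threshold=0.95)
for h in hits:
    print(f"motif hit: {h.motif_id} at {h.interval.start}-{h.interval.end} "
          f"({h.strand}) score={h.score:.1f} bits, site={h.matched_sequence}")
print(f"(consensus {consensus}; the hit reports the strand whose sequence "
      "matches the motif)")
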