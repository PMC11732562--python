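"""Bisulfite-pyrosequencing validation of a planted promoter DMR.

Forces one promoter to a 60% (sedentary) vs 20% (trained) methylation
truth, simulates per-CpG C/T counts at depth 100 with conversion controls,
then runs conversion QC, the condition x CpG-site two-way ANOVA, and
unadjusted per-site t-tests — the analysis used to confirm individual
CpG hypomethylation after training.
"""
import logging

from medipkit import SimConfig, build_methylome, simulate_genome, simulate_pyro_counts
from medipkit.pyro import analyze_samples
from medipkit.synthetic import Methylome

logging.getLogger("medipkit").setLevel(logging.ERROR)

cfg = SimConfig(seed=5)
genome = simulate_genome(cfg)
methylome, _ = build_methylome(genome, cfg)
gid = genome.genes[0].id
forced = methylome.regions.copy()
forced.loc[forced["region_id"] == gid, "level_sedentary"] = 0.60
forced.loc[forced["region_id"] == gid, "level_trained"] = 0.20

samples = simulate_pyro_counts(Methylome(forced), gid, genome, cfg)
result = analyze_samples(samples, min_efficiency=0.95)

print("conversion QC (non-CpG control cytosines):")
print(result["qc"].to_string(index=False))

anova = result["anova"].set_index("factor")
print(f"\ntwo-way ANOVA: condition p={anova.loc['condition', 'p']:.2e}, "
      f"site p={anova.loc['site', 'p']:.3f}, "
      f"interaction p={anova.loc['interaction', 'p']:.3f}")

print("\nper-CpG means (percent methylation) and exercise-effect t-tests:")
per_site = result["per_site"]
for _, row in per_site.iterrows():
    star = " *" if row["p"] < 0.05 else ""
    print(f"  site {int(row['site']):2d}: sed {row['mean_sedentary']:5.1f}%  "
          f"trn {row['mean_trained']:5.1f}%  p={row['p']:.1e}{star}")
print("\nStars mark sites whose methylation differs between conditions at "
      "p < 0.05 — here every site, since a 40-point shift was planted.")
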