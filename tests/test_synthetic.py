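"""Generator contracts: determinism, planted truth, abundance model."""
import numpy as np
import pandas as pd
import pytest

from medipkit import (
    Methylome,
    SimConfig,
    build_methylome,
    simulate_genome,
    simulate_medip_reads,
    simulate_pyro_counts,
)
from medipkit.annotation import cpg_obs_exp, gc_content
from medipkit.synthetic import CHROM


class TestSimConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"genome_length": 5_000},
            {"n_genes": 0},
            {"planted_dmr_fraction": 1.5},
            {"dmr_effect": 0.5},
            {"conversion_efficiency": -0.1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestSimulateGenome:
    def test_lengths_and_counts_echo_config(self):
        g = simulate_genome(SimConfig(genome_length=50_000, n_genes=10, seed=7))
        assert len(g.sequence) == 50_000
        assert len(g.genes) == 10
        assert set(g.sequence) <= set("ACGT")

    def test_same_seed_is_byte_identical(self):
        cfg = SimConfig(genome_length=50_000, n_genes=10, seed=7)
        a, b = simulate_genome(cfg), simulate_genome(cfg)
        assert a.sequence == b.sequence
        assert a.genes == b.genes
        assert a.island_truth == b.island_truth

    def test_zero_island_density_means_no_island_truth(self):
        g = simulate_genome(SimConfig(island_density=0, seed=3))
        assert g.island_truth == ()

    def test_genome_too_short_raises_sizing_error(self):
        with pytest.raises(ValueError, match="genome too short"):
            simulate_genome(SimConfig(genome_length=10_000, n_genes=50))

    def test_genes_non_overlapping_both_strands(self):
        g = simulate_genome(SimConfig(seed=5))
        spans = sorted((x.interval.start, x.interval.end) for x in g.genes)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
        assert {x.strand for x in g.genes} == {"+", "-"}

    def test_planted_islands_satisfy_criteria_by_construction(self):
        g = simulate_genome(SimConfig(seed=5))
        assert g.island_truth
        for iv in g.island_truth:
            seg = g.sequence[iv.start : iv.end]
            assert len(seg) >= 200
            assert gc_content(seg) >= 0.50
            assert cpg_obs_exp(seg) >= 0.6


class TestMethylome:
    def test_levels_in_unit_interval_and_partition_disjoint(self, small_sim):
        _, _, methylome, _ = small_sim
        df = methylome.regions
        assert df[["level_sedentary", "level_trained"]].min().min() >= 0
        assert df[["level_sedentary", "level_trained"]].max().max() <= 1
        srt = df.sort_values("start")
        assert (srt["start"].to_numpy()[1:] >= srt["end"].to_numpy()[:-1]).all()

    def test_planted_count_and_nonzero_shift(self, small_sim):
        cfg, genome, methylome, truth = small_sim
        n_expected = round(cfg.planted_dmr_fraction * len(genome.genes))
        planted = truth[truth["is_planted_dmr"]]
        assert len(planted) == n_expected
        df = methylome.regions.set_index("region_id")
        for gid in planted["gene_id"]:
            lfc = np.log2(df.loc[gid, "level_trained"] / df.loc[gid, "level_sedentary"])
            assert abs(lfc) > 0

    def test_overlapping_regions_rejected(self):
        df = pd.DataFrame(
            {
                "region_id": ["a", "b"],
                "chrom": [CHROM, CHROM],
                "start": [0, 500],
                "end": [1_000, 1_500],
                "strand": [".", "."],
                "kind": ["background", "background"],
                "cpg_count": [5, 5],
                "level_sedentary": [0.5, 0.5],
                "level_trained": [0.5, 0.5],
            }
        )
        with pytest.raises(ValueError, match="non-overlapping"):
            Methylome(df)


class TestSimulateReads:
    def test_all_zero_levels_and_no_background_means_no_reads(self, small_sim):
        cfg, genome, methylome, _ = small_sim
        zeroed = methylome.regions.copy()
        zeroed["level_sedentary"] = 0.0
        zeroed["level_trained"] = 0.0
        reads = simulate_medip_reads(
            genome, Methylome(zeroed),
            SimConfig(seed=1, background_rate=0.0), "sedentary",
        )
        assert all(len(v) == 0 for v in reads.values())

    def test_same_seed_identical_reads(self, small_sim):
        cfg, genome, methylome, _ = small_sim
        a = simulate_medip_reads(genome, methylome, cfg, "trained")
        b = simulate_medip_reads(genome, methylome, cfg, "trained")
        assert a == b

    def test_adding_samples_preserves_earlier_streams(self, small_sim):
        cfg, genome, methylome, _ = small_sim
        import dataclasses

        bigger = dataclasses.replace(cfg, n_samples_per_group=cfg.n_samples_per_group + 2)
        a = simulate_medip_reads(genome, methylome, cfg, "sedentary")
        b = simulate_medip_reads(genome, methylome, bigger, "sedentary")
        for sample in a:
            assert a[sample] == b[sample]

    def test_abundance_follows_methylated_cpg_mass(self):
        """Two regions, levels 0.8 vs 0.2, equal CpG counts, no background:
        the read-count ratio must match the 4:1 multinomial expectation."""
        core = ("TTACG" * 200)[:1_000]  # identical sequence -> equal CpG count
        seq = core + "AT" * 2_000 + core + "AT" * 2_500
        genome_df = pd.DataFrame(
            {
                "region_id": ["r1", "r2"],
                "chrom": [CHROM, CHROM],
                "start": [0, 5_000],
                "end": [1_000, 6_000],
                "strand": [".", "."],
                "kind": ["background", "background"],
                "cpg_count": [core.count("CG"), core.count("CG")],
                "level_sedentary": [0.8, 0.2],
                "level_trained": [0.8, 0.2],
            }
        )
        from medipkit.synthetic import SyntheticGenome

        genome = SyntheticGenome(sequence=seq + "A" * (10_000 - len(seq)), genes=(),
                                 island_truth=())
        cfg = SimConfig(genome_length=10_000, mean_depth=10_000,
                        background_rate=0.0, n_samples_per_group=1, seed=0)
        reads = simulate_medip_reads(genome, Methylome(genome_df), cfg, "sedentary")
        rs = reads["sed1"]
        n1 = sum(1 for r in rs if r.start < 1_000)
        n2 = sum(1 for r in rs if r.start >= 5_000)
        assert n1 + n2 == len(rs)  # conservation: every read from a region
        p = 0.8 / (0.8 + 0.2)
        se = np.sqrt(len(rs) * p * (1 - p))
        assert abs(n1 - p * len(rs)) < 4 * se

    def test_missing_promoter_region_is_contract_error(self, small_sim):
        cfg, genome, methylome, _ = small_sim
        broken = methylome.regions[methylome.regions["region_id"] != genome.genes[0].id]
        with pytest.raises(ValueError, match="does not cover"):
            simulate_medip_reads(genome, Methylome(broken), cfg, "sedentary")

    def test_planted_signal_monotone_in_effect_size(self):
        """Mean planted-promoter score fold-change grows with dmr_effect."""
        from medipkit.annotation import promoter_interval
        from medipkit.scoring import score_matrix

        mean_fc = []
        for effect in (1.5, 3.0, 6.0):
            fcs = []
            for seed in range(20):
                cfg = SimConfig(
                    genome_length=60_000, n_genes=10, planted_dmr_fraction=0.4,
                    dmr_effect=effect, mean_depth=10_000, seed=seed,
                )
                g = simulate_genome(cfg)
                meth, truth = build_methylome(g, cfg)
                reads = {}
                for grp in ("sedentary", "trained"):
                    reads.update(simulate_medip_reads(g, meth, cfg, grp))
                promoters = {x.id: promoter_interval(x) for x in g.genes}
                m = score_matrix(reads, list(promoters.values()),
                                 region_ids=list(promoters))
                sed_cols = [s for s in reads if s.startswith("sed")]
                wide = m.pivot_table(index="region_id", columns="sample", values="score")
                for gid in truth.loc[truth["is_planted_dmr"], "gene_id"]:
                    ms = wide.loc[gid, sed_cols].mean()
                    mt = wide.loc[gid, [s for s in reads if s.startswith("trn")]].mean()
                    r = (mt + 0.5) / (ms + 0.5)
                    fcs.append(max(r, 1 / r))
            mean_fc.append(np.mean(fcs))
        assert mean_fc[0] < mean_fc[1] < mean_fc[2]


class TestSimulatePyro:
    def test_boundary_levels(self, small_sim):
        cfg, genome, methylome, _ = small_sim
        gid = genome.genes[0].id
        forced = methylome.regions.copy()
        forced.loc[forced["region_id"] == gid, ["level_sedentary", "level_trained"]] = [1.0, 0.0]
        samples = simulate_pyro_counts(
            Methylome(forced), gid, genome,
            SimConfig(seed=2, conversion_efficiency=1.0, pyro_depth=100),
            site_sd=0.0,
        )
        for s in samples:
            for nc, nt in s.site_counts:
                if s.condition == "sedentary":
                    assert (nc, nt) == (100, 0)
                else:
                    assert (nc, nt) == (0, 100)
            assert s.control_unconverted == 0

    def test_half_level_recovered_within_binomial_error(self, small_sim):
        cfg, genome, methylome, _ = small_sim
        gid = genome.genes[1].id
        forced = methylome.regions.copy()
        forced.loc[forced["region_id"] == gid, ["level_sedentary", "level_trained"]] = 0.5
        samples = simulate_pyro_counts(
            Methylome(forced), gid, genome,
            SimConfig(seed=3, pyro_depth=10_000), site_sd=0.0,
        )
        fracs = [nc / (nc + nt) for s in samples for nc, nt in s.site_counts]
        se = np.sqrt(0.25 / 10_000)
        assert abs(np.mean(fracs) - 0.5) < 3 * se

    def test_region_without_cpg_is_an_error(self, small_sim):
        cfg, genome, methylome, _ = small_sim
        from medipkit.synthetic import SyntheticGenome

        blank = SyntheticGenome("AT" * len(genome.sequence), genome.genes, ())
        gid = genome.genes[0].id
        with pytest.raises(ValueError, match="no CpG"):
            simulate_pyro_counts(methylome, gid, blank, cfg)

    def test_deterministic_given_seed(self, small_sim):
        cfg, genome, methylome, _ = small_sim
        gid = genome.genes[2].id
        a = simulate_pyro_counts(methylome, gid, genome, cfg)
        b = simulate_pyro_counts(methylome, gid, genome, cfg)
        assert a == b
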