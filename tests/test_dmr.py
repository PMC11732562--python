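"""Fold change, DMR tests, the calling cascade and truth evaluation."""
import numpy as np
import pandas as pd
import pytest

from medipkit import (
    DmrConfig,
    GenomicInterval,
    call_dmrs,
    dmr_test,
    evaluate_against_truth,
    filter_candidates,
    fold_change,
)
from medipkit.dmr import DmrRecord, _perm_pvalue


class TestFoldChange:
    def test_pseudocounted_ratio_and_direction(self):
        fc, direction = fold_change(30, 15, 0.5)
        assert fc == pytest.approx(30.5 / 15.5)
        assert direction == "hyper"

    def test_equal_means_is_a_tie(self):
        assert fold_change(10, 10, 0.5) == (1.0, "tie")

    def test_pseudocount_guards_zero_over_zero(self):
        assert fold_change(0, 0, 0.5) == (1.0, "tie")

    def test_group_swap_flips_direction_not_magnitude(self):
        fc_ab, d_ab = fold_change(30, 15, 0.5)
        fc_ba, d_ba = fold_change(15, 30, 0.5)
        assert fc_ab == pytest.approx(fc_ba)
        assert {d_ab, d_ba} == {"hyper", "hypo"}

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1, 5, 0.5)


class TestDmrTest:
    def test_identical_groups_give_p_one_under_exact_permutation(self):
        cfg = DmrConfig(test="permutation")
        vals = [4.0, 4.0, 4.0, 4.0]
        assert dmr_test(vals, vals, cfg) == 1.0

    def test_exact_enumeration_of_three_vs_three(self):
        # groups (1,2,3) vs (101,102,103): only the observed split and its
        # mirror reach the observed |mean difference| -> p = 2/20
        cfg = DmrConfig(test="permutation")
        assert dmr_test([1, 2, 3], [101, 102, 103], cfg) == pytest.approx(2 / 20)

    def test_welch_needs_two_samples_per_group(self):
        with pytest.raises(ValueError, match=">= 2"):
            dmr_test([1.0], [2.0, 3.0], DmrConfig())

    def test_degenerate_zero_variance_suggests_permutation(self):
        with pytest.raises(ValueError, match="permutation"):
            dmr_test([5.0, 5.0], [9.0, 9.0], DmrConfig())

    def test_monte_carlo_converges_to_exact_enumeration(self):
        """At n=4+4 the seeded Monte-Carlo p must approach the exact p."""
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 4)
        b = rng.normal(1.0, 1, 4)
        la = np.log2(np.asarray(a) ** 2 + 0.5)  # positive scores
        lb = np.log2(np.asarray(b) ** 2 + 0.5)
        exact = _perm_pvalue(la, lb, 0, 0)
        # force the Monte-Carlo path by asking for enumeration on a larger
        # problem size: directly call with n_mc and compare
        n_mc = 10_000
        pooled = np.concatenate([la, lb])
        obs = abs(la.mean() - lb.mean())
        mc_rng = np.random.default_rng(7)
        hits = sum(
            abs((p := mc_rng.permutation(pooled))[:4].mean() - p[4:].mean())
            >= obs - 1e-12
            for _ in range(n_mc)
        )
        mc = (1 + hits) / (1 + n_mc)
        se = np.sqrt(exact * (1 - exact) / n_mc)
        assert abs(mc - exact) <= 3 * se + 2 / n_mc

    def test_welch_type_one_error_near_nominal(self):
        """Null calibration of Welch's t on log scores (simulation oracle)."""
        rng = np.random.default_rng(12)
        n_rej = 0
        reps = 1_000
        for _ in range(reps):
            a = np.exp(rng.normal(3, 0.3, 4))
            b = np.exp(rng.normal(3, 0.3, 4))
            if dmr_test(a, b, DmrConfig()) < 0.05:
                n_rej += 1
        assert 0.03 <= n_rej / reps <= 0.07


def _matrix(scores: dict[str, list[float]], gene="gA") -> pd.DataFrame:
    rows = []
    for sample, vals in scores.items():
        rows.append(
            {"region_id": gene, "chrom": "chr1", "start": 0, "end": 900,
             "strand": "+", "sample": sample, "score": vals, "status": "partial"}
        )
    return pd.DataFrame(rows)


class TestCallDmrs:
    @pytest.fixture()
    def setup(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(6)]
        promoters = {g: GenomicInterval("chr1", 1_000 * i, 1_000 * i + 900, "+")
                     for i, g in enumerate(genes)}
        rows = []
        groups = {}
        for s in range(4):
            groups[f"sed{s}"] = "sedentary"
            groups[f"trn{s}"] = "trained"
        for i, g in enumerate(genes):
            base = 20.0 + i
            for s in range(4):
                sed = base + rng.normal(0, 1)
                trn = base * (3.0 if i == 0 else 1.0) + rng.normal(0, 1)
                rows.append({"region_id": g, "chrom": "chr1", "start": 1_000 * i,
                             "end": 1_000 * i + 900, "strand": "+",
                             "sample": f"sed{s}", "score": sed, "status": "partial"})
                rows.append({"region_id": g, "chrom": "chr1", "start": 1_000 * i,
                             "end": 1_000 * i + 900, "strand": "+",
                             "sample": f"trn{s}", "score": trn, "status": "partial"})
        return pd.DataFrame(rows), promoters, groups

    def test_one_record_per_promoter_sorted_by_p(self, setup):
        matrix, promoters, groups = setup
        recs = call_dmrs(matrix, promoters, groups)
        assert len(recs) == len(promoters)
        assert [r.p_value for r in recs] == sorted(r.p_value for r in recs)
        assert recs[0].gene_id == "g0"  # the planted 3-fold gene
        assert recs[0].passes_filters and recs[0].direction == "hyper"

    def test_label_swap_flips_directions_preserves_p(self, setup):
        matrix, promoters, groups = setup
        swapped = {s: ("trained" if g == "sedentary" else "sedentary")
                   for s, g in groups.items()}
        a = call_dmrs(matrix, promoters, groups)
        b = {r.gene_id: r for r in call_dmrs(matrix, promoters, swapped)}
        flip = {"hyper": "hypo", "hypo": "hyper", "tie": "tie"}
        for r in a:
            assert b[r.gene_id].p_value == pytest.approx(r.p_value)
            assert b[r.gene_id].direction == flip[r.direction]

    def test_infinite_fc_threshold_passes_nothing(self, setup):
        matrix, promoters, groups = setup
        recs = call_dmrs(matrix, promoters, groups, DmrConfig(fc_threshold=1e12))
        assert not any(r.passes_filters for r in recs)

    def test_missing_group_labels_is_an_error(self, setup):
        matrix, promoters, groups = setup
        del groups["sed0"]
        with pytest.raises(ValueError, match="sed0"):
            call_dmrs(matrix, promoters, groups)


def _rec(gene, mean_sed, mean_trn, p=0.01, passes=True):
    fc, direction = fold_change(mean_trn, mean_sed, 0.5)
    return DmrRecord(
        gene_id=gene, region=GenomicInterval("chr1", 0, 900, "+"),
        mean_sedentary=mean_sed, mean_trained=mean_trn, fold_change=fc,
        log2fc=np.log2((mean_trn + 0.5) / (mean_sed + 0.5)),
        direction=direction, p_value=p, passes_filters=passes,
    )


class TestFilterCascade:
    def test_score_filter_uses_larger_group_mean(self):
        kept = filter_candidates([_rec("a", 4, 6), _rec("b", 4, 12)])
        assert [r.gene_id for r in kept] == ["b"]

    def test_zero_threshold_is_identity_on_passing_records(self):
        recs = [_rec("a", 4, 6), _rec("b", 4, 12)]
        assert filter_candidates(recs, DmrConfig(min_medip_score=1e-9)) == recs

    def test_cascade_is_nested(self):
        recs = [_rec("a", 4, 6), _rec("b", 4, 12), _rec("c", 30, 31, p=0.9, passes=False)]
        kept = filter_candidates(recs)
        assert set(r.gene_id for r in kept) <= {r.gene_id for r in recs if r.passes_filters}


class TestTruthEvaluation:
    def test_counts_and_rates(self):
        truth = pd.DataFrame(
            {"gene_id": ["a", "b", "c", "d"],
             "is_planted_dmr": [True, True, False, False],
             "direction": ["hyper", "hypo", "", ""]}
        )
        recs = [_rec("a", 10, 35), _rec("c", 10, 20), _rec("b", 30, 30.1, p=0.9, passes=False)]
        ev = evaluate_against_truth(recs, truth)
        assert ev["n_true_positive"] == 1 and ev["n_false_positive"] == 1
        assert ev["sensitivity"] == pytest.approx(0.5)
        assert ev["observed_fdr"] == pytest.approx(0.5)
        assert ev["direction_concordance"] == pytest.approx(1.0)
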