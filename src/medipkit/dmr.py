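"""Differential promoter methylation: tests, fold changes, filter cascade.

Per promoter the two groups' MeDIP-scores are compared with either Welch's
t-test on log2(score + pseudocount) or an exact/Monte-Carlo permutation test
on the mean difference of the log scores.  A promoter passes the primary
filter when p < 0.05 and fold change > 1.5; a second filter keeps promoters
whose larger group-mean MeDIP-score exceeds 10 reads/kb, mirroring the
cascade that narrows the candidate list before enrichment analysis.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

HYPER = "hyper"  # methylation higher in trained than sedentary
HYPO = "hypo"
TIE = "tie"

_EXACT_PERM_LIMIT = 12870  # C(16, 8): enumerate exactly up to this many splits


@dataclass(frozen=True)
class DmrConfig:
    p_threshold: float = 0.05
    fc_threshold: float = 1.5
    min_medip_score: float = 10.0
    test: str = "welch_t_log"  # {"welch_t_log", "permutation"}
    pseudocount: float = 0.5
    candidate_window: int = 500  # +/- bp around TSS, reporting only
    n_permutations: int = 10000
    adjust: bool = False  # Benjamini-Hochberg q-values
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.test not in ("welch_t_log", "permutation"):
            raise ValueError("test must be 'welch_t_log' or 'permutation'")


@dataclass(frozen=True)
class DmrRecord:
    gene_id: str
    region: GenomicInterval
    mean_sedentary: float
    mean_trained: float
    fold_change: float
    log2fc: float
    direction: str
    p_value: float
    passes_filters: bool
    q_value: float = float("nan")


def fold_change(
    mean_trained: float, mean_sedentary: float, pseudocount: float
) -> tuple[float, str]:
    """Pseudocounted ratio folded to >= 1, with the direction of change.

    Direction is relative to the trained group: ``hyper`` when trained >
    sedentary.  Swapping the groups flips the direction, not the magnitude.
    """
    if mean_trained < 0 or mean_sedentary < 0:
        raise ValueError("group means must be non-negative")
    r = (mean_trained + pseudocount) / (mean_sedentary + pseudocount)
    if r > 1:
        return r, HYPER
    if r < 1:
        return 1.0 / r, HYPO
    return 1.0, TIE


def _perm_pvalue(
    a: np.ndarray, b: np.ndarray, n_mc: int, seed: int
) -> float:
    """Two-sided permutation p for the difference of group means.

    All C(n_a+n_b, n_a) label reassignments are enumerated when there are at
    most C(16, 8) of them; otherwise Monte-Carlo with ``n_mc`` seeded draws
    (the observed labelling counted once, the +1 convention).
    """
    pooled = np.concatenate([a, b])
    n_a = len(a)
    n = len(pooled)
    obs = abs(a.mean() - b.mean())
    total_sum = pooled.sum()
    n_splits = math.comb(n, n_a)
    tol = 1e-12 * max(1.0, abs(obs))
    if n_splits <= _EXACT_PERM_LIMIT:
        hits = 0
        for idx in combinations(range(n), n_a):
            sa = pooled[list(idx)].sum()
            stat = abs(sa / n_a - (total_sum - sa) / (n - n_a))
            if stat >= obs - tol:
                hits += 1
        return hits / n_splits
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(pooled)
        stat = abs(perm[:n_a].mean() - perm[n_a:].mean())
        if stat >= obs - tol:
            hits += 1
    return (1 + hits) / (1 + n_mc)


def dmr_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    cfg: DmrConfig = DmrConfig(),
) -> float:
    """Two-sided p-value for a difference in regional methylation.

    ``welch_t_log``: Welch's t on log2(score + pseudocount).
    ``permutation``: exact enumeration when feasible, else seeded Monte-Carlo,
    on the log-score mean difference.
    """
    a = np.log2(np.asarray(scores_a, dtype=float) + cfg.pseudocount)
    b = np.log2(np.asarray(scores_b, dtype=float) + cfg.pseudocount)
    if cfg.test == "permutation":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("permutation test needs >= 1 sample per group")
        return _perm_pvalue(a, b, cfg.n_permutations, cfg.seed)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t_log needs >= 2 samples per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 1.0
        raise ValueError(
            "both groups have zero variance under welch_t_log; "
            "use the permutation test for such degenerate inputs"
        )
    with warnings.catch_warnings():
        # near-identical groups trip scipy's catastrophic-cancellation
        # warning; they are a legitimate null case here
        warnings.simplefilter("ignore", RuntimeWarning)
        t = stats.ttest_ind(a, b, equal_var=False)
    return float(t.pvalue)


def call_dmrs(
    score_matrix: pd.DataFrame,
    promoters: Mapping[str, GenomicInterval],
    groups: Mapping[str, str],
    cfg: DmrConfig = DmrConfig(),
) -> list[DmrRecord]:
    """One DmrRecord per promoter, sorted by p-value.

    ``score_matrix`` is the long table from :func:`medipkit.scoring.score_matrix`
    restricted to promoter regions (region_id = gene id); ``groups`` maps
    sample id -> {"sedentary", "trained"}.
    """
    labels = set(groups.values())
    if labels != {"sedentary", "trained"}:
        raise ValueError(
            f"groups must label both 'sedentary' and 'trained' samples, got {sorted(labels)}"
        )
    missing = set(score_matrix["sample"]) - set(groups)
    if missing:
        raise ValueError(f"samples without group labels: {sorted(missing)}")
    records = []
    for gene_id, sub in score_matrix.groupby("region_id", sort=False):
        if gene_id not in promoters:
            continue
        sed = sub.loc[[groups[s] == "sedentary" for s in sub["sample"]], "score"].to_numpy()
        trn = sub.loc[[groups[s] == "trained" for s in sub["sample"]], "score"].to_numpy()
        fc, direction = fold_change(trn.mean(), sed.mean(), cfg.pseudocount)
        p = dmr_test(trn, sed, cfg)
        log2fc = math.log2(
            (trn.mean() + cfg.pseudocount) / (sed.mean() + cfg.pseudocount)
        )
        records.append(
            DmrRecord(
                gene_id=str(gene_id),
                region=promoters[gene_id],
                mean_sedentary=float(sed.mean()),
                mean_trained=float(trn.mean()),
                fold_change=fc,
                log2fc=log2fc,
                direction=direction,
                p_value=p,
                passes_filters=(p < cfg.p_threshold) and (fc > cfg.fc_threshold),
            )
        )
    records.sort(key=lambda r: (r.p_value, r.gene_id))
    if cfg.adjust and records:
        q = stats.false_discovery_control([r.p_value for r in records])
        records = [
            DmrRecord(**{**r.__dict__, "q_value": float(qv)})
            for r, qv in zip(records, q)
        ]
    return records


def filter_candidates(
    dmrs: Sequence[DmrRecord], cfg: DmrConfig = DmrConfig()
) -> list[DmrRecord]:
    """Keep filter-passing records whose larger group-mean score exceeds
    ``min_medip_score`` — the reliability filter applied after DMR calling."""
    return [
        r
        for r in dmrs
        if r.passes_filters
        and max(r.mean_sedentary, r.mean_trained) > cfg.min_medip_score
    ]


def evaluate_against_truth(
    dmrs: Sequence[DmrRecord], truth: pd.DataFrame
) -> dict[str, float]:
    """Sensitivity / observed FDR / direction concordance vs a truth table.

    ``truth`` needs columns gene_id, is_planted_dmr, direction.
    """
    t = truth.set_index("gene_id")
    called = [r for r in dmrs if r.passes_filters]
    tp = [r for r in called if bool(t.loc[r.gene_id, "is_planted_dmr"])]
    fp = [r for r in called if not bool(t.loc[r.gene_id, "is_planted_dmr"])]
    n_planted = int(t["is_planted_dmr"].sum())
    dir_ok = sum(1 for r in tp if r.direction == t.loc[r.gene_id, "direction"])
    return {
        "n_called": float(len(called)),
        "n_true_positive": float(len(tp)),
        "n_false_positive": float(len(fp)),
        "sensitivity": len(tp) / n_planted if n_planted else float("nan"),
        "observed_fdr": len(fp) / len(called) if called else 0.0,
        "direction_concordance": dir_ok / len(tp) if tp else float("nan"),
    }


def dmr_table(dmrs: Sequence[DmrRecord]) -> pd.DataFrame:
    """Stable-column TSV-ready table of DMR records."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene_id,
                "chrom": r.region.chrom,
                "start": r.region.start,
                "end": r.region.end,
                "strand": r.region.strand,
                "mean_sed": r.mean_sedentary,
                "mean_trn": r.mean_trained,
                "fc": r.fold_change,
                "log2fc": r.log2fc,
                "direction": r.direction,
                "p": r.p_value,
                "q": r.q_value,
                "passes": r.passes_filters,
            }
            for r in dmrs
        ],
        columns=[
            "gene", "chrom", "start", "end", "strand", "mean_sed", "mean_trn",
            "fc", "log2fc", "direction", "p", "q", "passes",
        ],
    )
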