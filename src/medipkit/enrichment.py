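"""Pre-ranked gene-set enrichment (GSEA-style running sum).

Given a list of genes ranked by a signed metric (here: the promoter DMR
log2 fold-change) and a gene set, the enrichment score (ES) is the signed
extremum of a Kolmogorov-Smirnov-like running sum: set members ("hits")
increment the sum by |metric|^p normalized over set members, non-members
decrement by 1/(N - N_hit).  Significance comes from gene-label
permutation — with four animals per group a sample permutation null is not
meaningful, so the competitive gene-permutation null is used and stated as
such.  A hypergeometric over-representation test is provided for unranked
inputs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "gsea_es",
    "gsea_significance",
    "hypergeometric_enrichment",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    leading_edge: tuple[str, ...]
    n_hits: int


def _running_sum(
    genes: Sequence[str],
    metric: np.ndarray,
    members: frozenset[str],
    weight_p: float,
) -> np.ndarray:
    n = len(genes)
    is_hit = np.array([g in members for g in genes])
    n_hit = int(is_hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    w = np.abs(metric) ** weight_p
    hit_w = np.where(is_hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all set members have zero metric: fall back to equal hit weights
        hit_w = is_hit.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom
    if n_hit < n:
        steps = steps - np.where(is_hit, 0.0, 1.0 / (n - n_hit))
    return np.cumsum(steps)


def gsea_es(
    ranked_genes: Sequence[str],
    metric: Sequence[float],
    gene_set: GeneSet,
    weight_p: float = 1.0,
) -> tuple[float, tuple[str, ...]]:
    """Enrichment score and leading edge for one set on one ranked list.

    ``ranked_genes`` must be ordered best-to-worst by ``metric`` and contain
    unique ids.  The ES is the running-sum value of largest magnitude; the
    leading edge is the set members at or before the ES position (after it,
    for negative ES).
    """
    if len(set(ranked_genes)) != len(ranked_genes):
        raise ValueError("ranked gene list contains duplicate ids")
    if len(ranked_genes) != len(metric):
        raise ValueError("ranked_genes and metric differ in length")
    rs = _running_sum(ranked_genes, np.asarray(metric, dtype=float), gene_set.members, weight_p)
    i_max = int(np.argmax(rs))
    i_min = int(np.argmin(rs))
    es = rs[i_max] if rs[i_max] >= -rs[i_min] else rs[i_min]
    if es >= 0:
        edge = tuple(g for g in ranked_genes[: i_max + 1] if g in gene_set.members)
    else:
        edge = tuple(g for g in ranked_genes[i_min + 1 :] if g in gene_set.members)
    return float(es), edge


def gsea_significance(
    ranked_genes: Sequence[str],
    metric: Sequence[float],
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> EnrichmentResult:
    """Gene-label permutation p-value and normalized ES for one set.

    p = (1 + #{|ES_null| >= |ES|}) / (1 + n_perm); NES = ES / mean|ES_null|
    over null scores of the same sign.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    es, edge = gsea_es(ranked_genes, metric, gene_set, weight_p)
    rng = np.random.default_rng(seed)
    met = np.asarray(metric, dtype=float)
    n = len(ranked_genes)
    n_hit = sum(1 for g in ranked_genes if g in gene_set.members)
    w = np.abs(met) ** weight_p
    miss_step = -1.0 / (n - n_hit) if n_hit < n else 0.0
    null = np.empty(n_perm)
    for i in range(n_perm):
        # permuting gene labels == drawing a random hit set of the same size
        idx = rng.choice(n, size=n_hit, replace=False)
        denom = w[idx].sum()
        steps = np.full(n, miss_step)
        steps[idx] = (w[idx] / denom) if denom > 0 else 1.0 / n_hit
        rs = np.cumsum(steps)
        null[i] = rs[np.argmax(np.abs(rs))]
    p = (1 + int(np.sum(np.abs(null) >= abs(es) - 1e-12))) / (1 + n_perm)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.mean(np.abs(same_sign)) if same_sign.size else np.mean(np.abs(null))
    nes = es / denom if denom > 0 else 0.0
    return EnrichmentResult(
        set_name=gene_set.name,
        es=es,
        nes=float(nes),
        p_value=float(p),
        leading_edge=edge,
        n_hits=n_hit,
    )


def hypergeometric_enrichment(
    selected: set[str], universe: set[str], gene_set: GeneSet
) -> float:
    """Over-representation p (upper tail) for unranked gene lists."""
    members = gene_set.members & universe
    if not members:
        raise ValueError("gene set has no overlap with the universe")
    k = len(selected & members)
    return float(
        stats.hypergeom.sf(k - 1, len(universe), len(members), len(selected))
    )


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (name <tab> description <tab> members...)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, >=1 member")
            out.append(GeneSet(parts[0], frozenset(parts[2:]), parts[1]))
    return out


def write_gmt(gene_sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")
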