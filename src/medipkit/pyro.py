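"""Bisulfite-pyrosequencing analysis: percent methylation, conversion QC,
two-way ANOVA and per-CpG condition tests.

Percent methylation at a CpG is 100 * nC / (nC + nT) — the fraction of
reads in which the site remained cytosine after bisulfite conversion.
Non-CpG cytosines must convert completely, so their residual C fraction
measures conversion efficiency; samples below the efficiency cut-off are
excluded.  Condition-by-site effects are assessed with a balanced
fixed-effects two-way ANOVA (condition x CpG site, with interaction), and
per-site exercise effects with unadjusted two-sample t-tests, matching how
per-site significance stars are conventionally reported.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PyroSample",
    "percent_methylation",
    "conversion_qc",
    "two_way_anova",
    "per_cpg_tests",
    "site_summary",
]


@dataclass(frozen=True)
class PyroSample:
    """Per-sample pyrosequencing counts: (nC, nT) per CpG site plus
    conversion-control counts at non-CpG cytosines."""

    sample_id: str
    condition: str  # {"sedentary", "trained"}
    site_counts: tuple[tuple[int, int], ...]  # (nC, nT) per CpG site
    control_converted: int = 0
    control_unconverted: int = 0

    def __post_init__(self) -> None:
        for nc, nt in self.site_counts:
            if nc < 0 or nt < 0:
                raise ValueError("counts must be non-negative")
            if nc + nt == 0:
                raise ValueError(
                    f"sample {self.sample_id}: analyzed CpG site with zero coverage"
                )


def percent_methylation(n_c: int, n_t: int) -> float:
    """100 * C / (C + T) at one CpG site."""
    if n_c < 0 or n_t < 0:
        raise ValueError("counts must be non-negative")
    total = n_c + n_t
    if total == 0:
        raise ValueError("no coverage: nC + nT must be positive")
    return 100.0 * n_c / total


def conversion_qc(
    converted: int, unconverted: int, min_efficiency: float = 0.95
) -> tuple[bool, float]:
    """Bisulfite conversion check from non-CpG control cytosines.

    Returns (passes, efficiency) where efficiency = converted / total.
    """
    total = converted + unconverted
    if total <= 0:
        raise ValueError("need >= 1 control cytosine observation")
    eff = converted / total
    return eff >= min_efficiency, eff


def _long_table(samples: Sequence[PyroSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        for site, (nc, nt) in enumerate(s.site_counts, start=1):
            rows.append(
                {
                    "sample": s.sample_id,
                    "condition": s.condition,
                    "site": site,
                    "percent": percent_methylation(nc, nt),
                }
            )
    return pd.DataFrame(rows)


def two_way_anova(table: pd.DataFrame) -> pd.DataFrame:
    """Balanced fixed-effects two-way ANOVA with interaction.

    ``table`` needs columns condition, site, percent; every
    (condition, site) cell must hold the same number (>= 2) of replicates.
    Returns a table with rows condition, site, interaction, residual and
    columns ss, df, ms, F, p.  Zero-variance data reports p = 1.
    """
    required = {"condition", "site", "percent"}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    cell_sizes = table.groupby(["condition", "site"]).size()
    n_rep = cell_sizes.iloc[0]
    if cell_sizes.nunique() != 1:
        raise ValueError("unbalanced design: all condition x site cells must have equal replicates")
    if n_rep < 2:
        raise ValueError("need >= 2 replicates per cell for the interaction ANOVA")
    y = table["percent"].to_numpy(dtype=float)
    grand = y.mean()
    a_levels = sorted(table["condition"].unique())
    b_levels = sorted(table["site"].unique())
    a, b = len(a_levels), len(b_levels)
    n = len(y)
    a_means = table.groupby("condition")["percent"].mean()
    b_means = table.groupby("site")["percent"].mean()
    cell_means = table.groupby(["condition", "site"])["percent"].mean()
    ss_a = n_rep * b * float(((a_means - grand) ** 2).sum())
    ss_b = n_rep * a * float(((b_means - grand) ** 2).sum())
    ss_cells = n_rep * float(((cell_means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = float(((y - grand) ** 2).sum())
    ss_res = ss_total - ss_cells
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_res = n - a * b
    rows = []
    ms_res = ss_res / df_res if df_res > 0 else float("nan")
    for name, ss, df in (
        ("condition", ss_a, df_a),
        ("site", ss_b, df_b),
        ("interaction", ss_ab, df_ab),
    ):
        ms = ss / df if df > 0 else float("nan")
        if ms_res > 0 and df > 0:
            F = ms / ms_res
            p = float(stats.f.sf(F, df, df_res))
        else:
            # zero residual variance (e.g. constant data): no evidence either way
            F, p = float("nan"), 1.0
        rows.append({"factor": name, "ss": ss, "df": df, "ms": ms, "F": F, "p": p})
    rows.append(
        {"factor": "residual", "ss": ss_res, "df": df_res, "ms": ms_res,
         "F": float("nan"), "p": float("nan")}
    )
    return pd.DataFrame(rows, columns=["factor", "ss", "df", "ms", "F", "p"])


def per_cpg_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Unadjusted two-sided two-sample t-test of condition, per CpG site.

    Mirrors per-site significance stars: each site tested independently,
    pooled-variance t (the convention of standard prism-style analyses).
    Returns columns site, mean_sedentary, mean_trained, delta, t, p.
    """
    rows = []
    for site, sub in table.groupby("site"):
        sed = sub.loc[sub["condition"] == "sedentary", "percent"].to_numpy()
        trn = sub.loc[sub["condition"] == "trained", "percent"].to_numpy()
        if len(sed) < 2 or len(trn) < 2:
            raise ValueError(f"site {site}: need >= 2 replicates per condition")
        if np.ptp(sed) == 0 and np.ptp(trn) == 0 and sed.mean() == trn.mean():
            t, p = 0.0, 1.0
        else:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(trn, sed, equal_var=True)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "site": site,
                "mean_sedentary": float(sed.mean()),
                "mean_trained": float(trn.mean()),
                "delta": float(trn.mean() - sed.mean()),
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows).sort_values("site").reset_index(drop=True)


def site_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM per condition per site (the per-site figure layout)."""
    g = table.groupby(["site", "condition"])["percent"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"count": "n"})


def analyze_samples(
    samples: Sequence[PyroSample], min_efficiency: float = 0.95
) -> dict:
    """QC-filter samples, then run the ANOVA and per-site tests.

    Returns a dict with keys qc (per-sample table), table (long percent
    table of passing samples), anova, per_site.
    """
    qc_rows = []
    passing = []
    for s in samples:
        ok, eff = conversion_qc(s.control_converted, s.control_unconverted, min_efficiency)
        qc_rows.append({"sample": s.sample_id, "condition": s.condition,
                        "efficiency": eff, "passes": ok})
        if ok:
            passing.append(s)
    table = _long_table(passing)
    return {
        "qc": pd.DataFrame(qc_rows),
        "table": table,
        "anova": two_way_anova(table) if not table.empty else None,
        "per_site": per_cpg_tests(table) if not table.empty else None,
    }
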