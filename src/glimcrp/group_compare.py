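"""Rank-based k-group comparison: Kruskal-Wallis omnibus and Conover post hoc.

Outcomes (binary flags included) are compared across the four GLIM groups
with the tie-corrected Kruskal-Wallis H test; pairwise differences use the
Conover-Iman procedure on the pooled ranks, whose variance estimate carries
both the tie correction and the (N-1-H)/(N-k) omnibus adjustment, with
two-sided p-values from Student's t on N-k degrees of freedom.  Raw and
Bonferroni-adjusted pairwise p-values are both reported: with 6 pairwise
tests an unadjusted p of 0.04 sits above the ~0.0083 Bonferroni threshold,
so the choice of adjustment can flip borderline calls and is left explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .outcomes_glim import GROUP_ORDER

#: Outcomes compared across groups: (name, column, kind).
OUTCOME_SPECS = (
    ("in_hospital_death", "in_hospital_death", "binary"),
    ("bi_lt_60", "bi_lt_60", "binary"),
    ("los_ge_14", "los_ge_14", "binary"),
    ("composite", "composite", "binary"),
    ("death_by_day14", "death_by_day14", "binary"),
    ("death_by_day28", "death_by_day28", "binary"),
    ("barthel_index", "barthel_index", "continuous"),
    ("hospital_los_days", "hospital_los_days", "continuous"),
)


@dataclass(frozen=True)
class GroupComparison:
    outcome_name: str
    kind: str
    groups: tuple[str, ...]
    group_n: tuple[int, ...]
    kw_h: float
    kw_p: float
    pairwise: np.ndarray
    adjusted_pairwise: np.ndarray
    group_summaries: tuple[str, ...]
    undefined: bool = False


def _check_samples(samples) -> list[np.ndarray]:
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least three observations in total")
    return arrays


def _pooled_ranks(arrays: list[np.ndarray]):
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    splits = np.cumsum([a.size for a in arrays])[:-1]
    return pooled, ranks, np.split(ranks, splits)


def _h_statistic(arrays: list[np.ndarray]) -> float:
    pooled, ranks, group_ranks = _pooled_ranks(arrays)
    n_total = pooled.size
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        gr.sum() ** 2 / gr.size for gr in group_ranks
    ) - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    denom = 1.0 - tie_term / (n_total**3 - n_total)
    if denom <= 0:  # all observations identical
        return 0.0
    return h / denom


def kruskal_wallis(samples) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df)."""
    arrays = _check_samples(samples)
    h = _h_statistic(arrays)
    p = float(stats.chi2.sf(h, len(arrays) - 1))
    return float(h), p


def conover_pairwise(samples) -> tuple[np.ndarray, np.ndarray]:
    """Conover-Iman pairwise p-values: (raw, Bonferroni-adjusted) k x k matrices.

    The statistic for groups i, j is
    t = (Rbar_i - Rbar_j) / sqrt(S^2 (N-1-H)/(N-k) (1/n_i + 1/n_j))
    with S^2 the variance of the pooled ranks and H the tie-corrected
    omnibus statistic; p is two-sided from t with N-k df.  Diagonals are NaN.
    """
    arrays = _check_samples(samples)
    k = len(arrays)
    pooled, ranks, group_ranks = _pooled_ranks(arrays)
    n_total = pooled.size
    if n_total <= k:
        raise ValueError("need more observations than groups")
    h = _h_statistic(arrays)
    s2 = (float((ranks**2).sum()) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)
    factor = s2 * (n_total - 1.0 - h) / (n_total - k)
    rbar = np.array([gr.mean() for gr in group_ranks])
    sizes = np.array([gr.size for gr in group_ranks], dtype=float)
    raw = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(rbar[i] - rbar[j])
            if factor <= 0:
                # perfect separation (H at its maximum): zero variance left
                p = 1.0 if diff == 0 else 0.0
            else:
                t = diff / np.sqrt(factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
                p = 2.0 * float(stats.t.sf(t, n_total - k))
            raw[i, j] = raw[j, i] = min(p, 1.0)
    m = k * (k - 1) / 2.0
    adjusted = np.minimum(raw * m, 1.0)
    return raw, adjusted


def _summarise(values: np.ndarray, kind: str) -> str:
    if kind == "binary":
        count = int(values.sum())
        pct = 100.0 * count / values.size if values.size else float("nan")
        return f"{count} ({pct:.1f}%)"
    q1, med, q3 = np.percentile(values, [25, 50, 75]) if values.size else (np.nan,) * 3
    return f"{med:g} ({q1:g}, {q3:g})"


def compare_four_groups(cohort: pd.DataFrame, outcome_specs=OUTCOME_SPECS) -> list[GroupComparison]:
    """One GroupComparison per outcome across the four GLIM groups.

    An empty group marks that outcome's tests undefined instead of raising.
    """
    groups = tuple(g.value for g in GROUP_ORDER)
    comparisons = []
    for name, column, kind in outcome_specs:
        samples = [
            cohort.loc[cohort["four_group"] == g, column].to_numpy(float)
            for g in groups
        ]
        sizes = tuple(int(s.size) for s in samples)
        summaries = tuple(_summarise(s, kind) for s in samples)
        k = len(groups)
        if any(s.size == 0 for s in samples):
            comparisons.append(
                GroupComparison(
                    outcome_name=name,
                    kind=kind,
                    groups=groups,
                    group_n=sizes,
                    kw_h=float("nan"),
                    kw_p=float("nan"),
                    pairwise=np.full((k, k), np.nan),
                    adjusted_pairwise=np.full((k, k), np.nan),
                    group_summaries=summaries,
                    undefined=True,
                )
            )
            continue
        h, p = kruskal_wallis(samples)
        raw, adjusted = conover_pairwise(samples)
        comparisons.append(
            GroupComparison(
                outcome_name=name,
                kind=kind,
                groups=groups,
                group_n=sizes,
                kw_h=h,
                kw_p=p,
                pairwise=raw,
                adjusted_pairwise=adjusted,
                group_summaries=summaries,
            )
        )
    return comparisons


def comparisons_to_tables(
    comparisons: list[GroupComparison],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render comparisons as (outcomes table, long-format p-value table)."""
    outcome_rows = []
    pvalue_rows = []
    for comp in comparisons:
        row: dict[str, object] = {
            "outcome": comp.outcome_name,
            "kind": comp.kind,
            "kw_h": comp.kw_h,
            "kw_p": comp.kw_p,
        }
        for g, n, summary in zip(comp.groups, comp.group_n, comp.group_summaries):
            row[f"{g}_n"] = n
            row[f"{g}_summary"] = summary
        outcome_rows.append(row)
        for i, gi in enumerate(comp.groups):
            for j in range(i + 1, len(comp.groups)):
                pvalue_rows.append(
                    {
                        "outcome": comp.outcome_name,
                        "group_a": gi,
                        "group_b": comp.groups[j],
                        "p_raw": comp.pairwise[i, j],
                        "p_adjusted": comp.adjusted_pairwise[i, j],
                    }
                )
    return pd.DataFrame(outcome_rows), pd.DataFrame(pvalue_rows)
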