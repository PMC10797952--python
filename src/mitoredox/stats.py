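"""Group-comparison statistics for per-mitochondrion ratio tables.

Two-condition comparisons use the Mann–Whitney test (exact for small
samples without ties, tie-corrected normal approximation otherwise) or the
paired t-test; three or more conditions use Kruskal–Wallis ANOVA followed by
Dunn's multiple-comparison test; correlations are Pearson's.  Multiple
testing across a family of p-values uses the Benjamini–Hochberg step-up
procedure (selection threshold defaults to an FDR of 0.25).

Aggregation follows the experimental hierarchy: objects → per-stack (field
of view) means → per-subject means, unweighted at each level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupSummary:
    name: str
    mean: float
    sem: float
    n: int


@dataclass
class StatResult:
    test: str
    statistic: Optional[float]
    p_value: Optional[float]
    adjusted_p: Optional[float] = None
    groups: list[GroupSummary] = field(default_factory=list)
    level: Optional[str] = None  # "per_stack" | "per_subject"
    note: str = ""

    @property
    def degenerate(self) -> bool:
        return self.p_value is None


@dataclass
class CorrelationResult:
    """Pearson correlation with its square; optionally a binned profile."""

    r: Optional[float]
    r_squared: Optional[float]
    p_value: Optional[float]
    n: int
    profile: Optional[pd.DataFrame] = None
    r_per_record: Optional[float] = None
    p_per_record: Optional[float] = None
    note: str = ""

    @property
    def defined(self) -> bool:
        return self.r is not None


def _summaries(groups: Sequence[np.ndarray], names: Sequence[str]) -> list[GroupSummary]:
    out = []
    for g, name in zip(groups, names):
        g = np.asarray(g, dtype=float)
        n = len(g)
        sem = float(g.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        out.append(GroupSummary(name=name, mean=float(g.mean()), sem=sem, n=n))
    return out


# --------------------------------------------------------------- aggregation


def aggregate(table: pd.DataFrame, level: str = "per_stack") -> pd.DataFrame:
    """Collapse an object-level MeasurementTable to per-stack or per-subject means.

    per_stack: unweighted mean ratio over objects within each stack.
    per_subject: unweighted mean over that subject's stack means.
    Idempotent: aggregating already-aggregated output returns it unchanged.
    """
    if level not in ("per_stack", "per_subject"):
        raise ValueError("level must be 'per_stack' or 'per_subject'")
    if table.empty:
        return table.copy()
    df = table.copy()
    carry = [c for c in ("condition", "timepoint") if c in df.columns]
    if "stack_id" in df.columns and df["stack_id"].notna().any():
        keys = [k for k in ("subject_id", "stack_id") if k in df.columns] + carry
        per_stack = (
            df.groupby(keys, dropna=False, sort=True)["ratio"]
            .agg(ratio="mean", n_objects="count")
            .reset_index()
        )
    else:  # already stack-level or subject-level
        per_stack = df
    if level == "per_stack":
        return per_stack
    keys = [k for k in ("subject_id",) if k in per_stack.columns] + carry
    per_subject = (
        per_stack.groupby(keys, dropna=False, sort=True)["ratio"]
        .agg(ratio="mean", n_stacks="count")
        .reset_index()
    )
    return per_subject


# --------------------------------------------------------------------- tests


def mann_whitney(a, b, names: tuple[str, str] = ("a", "b"),
                 level: Optional[str] = None) -> StatResult:
    """Two-sided Mann–Whitney U.

    Exact p by enumeration of rankings when n1+n2 ≤ 12 and there are no
    ties; tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) + len(b) <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(
        test=f"mann_whitney[{method}]",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        groups=_summaries([a, b], names),
        level=level,
    )


def paired_t(before, after, names: tuple[str, str] = ("before", "after"),
             level: Optional[str] = None) -> StatResult:
    """Two-sided paired t-test on after − before differences."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    if len(before) < 2:
        raise ValueError("need at least 2 pairs")
    d = after - before
    if np.allclose(d, d[0]):
        return StatResult(
            test="paired_t",
            statistic=None,
            p_value=None,
            groups=_summaries([before, after], names),
            level=level,
            note="degenerate: constant differences",
        )
    res = sps.ttest_rel(after, before)
    return StatResult(
        test="paired_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        groups=_summaries([before, after], names),
        level=level,
    )


def kruskal_wallis(groups: Sequence, names: Optional[Sequence[str]] = None,
                   level: Optional[str] = None) -> StatResult:
    """Kruskal–Wallis H (tie-corrected) with a chi-square p on k−1 df."""
    if len(groups) < 3:
        raise ValueError(
            "kruskal_wallis needs >= 3 groups; use mann_whitney or paired_t for two"
        )
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be nonempty")
    names = list(names) if names is not None else [f"g{i}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        return StatResult(
            test="kruskal_wallis", statistic=0.0, p_value=1.0,
            groups=_summaries(arrays, names), level=level,
            note="all values identical",
        )
    h, p = sps.kruskal(*arrays)
    return StatResult(
        test="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        groups=_summaries(arrays, names),
        level=level,
    )


def dunn_posthoc(groups: Sequence, names: Optional[Sequence[str]] = None,
                 adjust: str = "bonferroni",
                 level: Optional[str] = None) -> list[StatResult]:
    """Dunn's pairwise post-hoc test on mean ranks after Kruskal–Wallis.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j))
    with tie term T = Σ(t³ − t).  Adjustment across all pairs defaults to
    Bonferroni; "none" reports raw p.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) == 0 for g in arrays):
        raise ValueError("need >= 2 nonempty groups")
    names = list(names) if names is not None else [f"g{i}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_base -= tie_term / (12.0 * (n_total - 1))
    mean_ranks, sizes = [], []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    pairs = [(i, j) for i in range(len(arrays)) for j in range(i + 1, len(arrays))]
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
        adj = min(1.0, p * m) if adjust == "bonferroni" else p
        out.append(
            StatResult(
                test=f"dunn[{names[i]} vs {names[j]}]",
                statistic=float(z),
                p_value=float(p),
                adjusted_p=float(adj),
                groups=_summaries([arrays[i], arrays[j]], [names[i], names[j]]),
                level=level,
            )
        )
    return out


def pearson(x, y) -> CorrelationResult:
    """Pearson's r with r² and a two-sided p from the t distribution (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        return CorrelationResult(None, None, None, n, note="need >= 3 pairs")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return CorrelationResult(None, None, None, n, note="constant input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(r) ** 2, float(p), n)


# ----------------------------------------------------- multiple comparisons


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def bh_select(p_values, threshold: float = 0.25) -> np.ndarray:
    """Indices whose BH-adjusted p is ≤ the FDR threshold (default 0.25)."""
    q = bh_adjust(p_values)
    return np.flatnonzero(q <= threshold)
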