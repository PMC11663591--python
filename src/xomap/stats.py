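"""The statistical tests used throughout the crossover analyses.

Thin, explicit wrappers around established SciPy routines, plus a
hand-rolled Dunn post hoc (not available in SciPy), all returning a
uniform :class:`StatResult`.  Conventions that matter downstream:

* Mann-Whitney U is two-sided; with ``min(n) <= 8`` and no ties the exact
  permutation distribution is used (p = doubled smaller tail, capped at 1),
  otherwise the normal approximation with tie and continuity corrections.
* Pearson chi-square carries no continuity correction.
* Dunn pairwise p-values are reported unadjusted by default (optional
  Bonferroni / Holm flags); no multiple-testing correction is applied
  anywhere else by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "mann_whitney_u",
    "welch_t",
    "anova_tukey",
    "pearson_chi2",
    "kruskal_dunn",
]


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    df: float | None = None
    n_per_group: tuple[int, ...] = ()
    method_detail: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _as_arrays(*samples) -> list[np.ndarray]:
    out = [np.asarray(s, dtype=float).ravel() for s in samples]
    for a in out:
        if a.size == 0:
            raise ValueError("empty sample")
    return out


def mann_whitney_u(x, y) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Exact permutation p when ``min(n) <= 8`` and the pooled sample has no
    ties; normal approximation with tie and continuity corrections
    otherwise.  The statistic is U for the first sample.
    """
    x, y = _as_arrays(x, y)
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    n1, n2 = len(x), len(y)
    if np.ptp(pooled) == 0:
        return StatResult(
            "mann-whitney-u", n1 * n2 / 2.0, 1.0, None, (n1, n2),
            "degenerate: all observations identical",
        )
    exact = min(n1, n2) <= 8 and not ties
    if exact:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        detail = "exact (full permutation distribution)"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        detail = "normal approximation with tie and continuity corrections"
    return StatResult(
        "mann-whitney-u", float(res.statistic), float(min(res.pvalue, 1.0)),
        None, (n1, n2), detail,
    )


def welch_t(x, y) -> StatResult:
    """Two-sided Welch (unequal-variance) t test with Satterthwaite df."""
    x, y = _as_arrays(x, y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return StatResult(
                "welch-t", 0.0, 1.0, None, (len(x), len(y)),
                "degenerate: zero variance, equal means",
            )
        return StatResult(
            "welch-t", np.inf, 0.0, None, (len(x), len(y)),
            "degenerate: zero variance, distinct means",
        )
    res = sps.ttest_ind(x, y, equal_var=False)
    return StatResult(
        "welch-t", float(res.statistic), float(res.pvalue), float(res.df),
        (len(x), len(y)), "Welch-Satterthwaite degrees of freedom",
    )


def anova_tukey(groups: dict[str, np.ndarray]) -> tuple[StatResult, "list[dict]"]:
    """One-way ANOVA F test plus Tukey HSD pairwise comparisons.

    ``groups`` maps group name -> observations.  Returns the omnibus result
    and a list of pairwise dicts (group_1, group_2, diff, p_adj) with
    studentized-range adjusted p-values.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = _as_arrays(*[groups[k] for k in names])
    for name, a in zip(names, arrays):
        if len(a) < 2:
            raise ValueError(f"group '{name}' needs n >= 2")
    if np.ptp(np.concatenate(arrays)) == 0:
        omnibus = StatResult(
            "anova-f", 0.0, 1.0, None, tuple(len(a) for a in arrays),
            "degenerate: all observations identical",
        )
        pairwise = [
            {"group_1": g1, "group_2": g2, "diff": 0.0, "p_adj": 1.0}
            for i, g1 in enumerate(names) for g2 in names[i + 1:]
        ]
        return omnibus, pairwise
    f = sps.f_oneway(*arrays)
    k, n = len(arrays), sum(len(a) for a in arrays)
    omnibus = StatResult(
        "anova-f", float(f.statistic), float(f.pvalue), float(k - 1),
        tuple(len(a) for a in arrays), f"between df={k - 1}, within df={n - k}",
    )
    hsd = sps.tukey_hsd(*arrays)
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            pairwise.append(
                {
                    "group_1": names[i],
                    "group_2": names[j],
                    "diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    return omnibus, pairwise


def pearson_chi2(table) -> StatResult:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need a table with >= 2 rows and >= 2 columns")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    stat, p, df, expected = sps.chi2_contingency(table, correction=False)
    detail = "Pearson chi-square"
    if np.any(expected < 5):
        warnings.warn("expected count below 5; chi-square approximation is weak",
                      stacklevel=2)
        detail += " (warning: expected count < 5)"
    return StatResult("pearson-chi2", float(stat), float(p), float(df),
                      tuple(int(r) for r in table.sum(axis=1)), detail)


def kruskal_dunn(
    groups: dict[str, np.ndarray], adjust: str | None = None
) -> tuple[StatResult, "list[dict]"]:
    """Kruskal-Wallis H (tie corrected) plus Dunn pairwise z tests.

    Dunn p-values are two-sided and unadjusted by default; pass
    ``adjust='bonferroni'`` or ``'holm'`` for family-wise control.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = _as_arrays(*[groups[k] for k in names])
    pooled = np.concatenate(arrays)
    ns = np.array([len(a) for a in arrays])
    if np.ptp(pooled) == 0:
        omnibus = StatResult("kruskal-wallis-h", 0.0, 1.0, float(len(names) - 1),
                             tuple(ns), "degenerate: all observations identical")
        pairwise = [
            {"group_1": g1, "group_2": g2, "z": 0.0, "p": 1.0}
            for i, g1 in enumerate(names) for g2 in names[i + 1:]
        ]
        return omnibus, pairwise
    h = sps.kruskal(*arrays)
    omnibus = StatResult(
        "kruskal-wallis-h", float(h.statistic), float(h.pvalue),
        float(len(names) - 1), tuple(ns), "tie-corrected H",
    )
    # Dunn: z tests on mean ranks with tie-corrected variance
    ranks = sps.rankdata(pooled)
    splits = np.cumsum(ns)[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    n_tot = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_tot - 1))
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_term
    raw = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(base_var * (1.0 / ns[i] + 1.0 / ns[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            raw.append((names[i], names[j], float(z), float(2 * sps.norm.sf(abs(z)))))
    pvals = np.array([r[3] for r in raw])
    if adjust == "bonferroni":
        pvals = np.minimum(pvals * len(pvals), 1.0)
    elif adjust == "holm":
        order = np.argsort(pvals)
        adj = np.empty_like(pvals)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (len(pvals) - rank) * pvals[idx])
            adj[idx] = min(running, 1.0)
        pvals = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment '{adjust}'")
    pairwise = [
        {"group_1": g1, "group_2": g2, "z": z, "p": float(p)}
        for (g1, g2, z, _), p in zip(raw, pvals)
    ]
    return omnibus, pairwise
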