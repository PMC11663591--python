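"""Genome-scale crossover landscapes: fixed windows and scaled arm profiles.

Two aggregation schemes over called crossovers:

* fixed windows of ``window_bp`` (default 300 kb) per chromosome, each call
  assigned to the window containing its midpoint;
* telomere -> centromere scaled profile: each call is placed at the
  fractional position of its arm (0 at the telomere, 1 at the centromere
  edge) and pooled over both arms of all chromosomes, so chromosomes of
  different lengths contribute comparably.

Counts are conserved exactly by both schemes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genome import RegionAnnotation
from .stats import StatResult, mann_whitney_u

__all__ = [
    "bin_fixed",
    "scale_tel_cen",
    "compare_regions",
    "compare_chromosome_totals",
]


def bin_fixed(
    calls: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_bp: int = 300_000,
    n_individuals: int | None = None,
    annotation: RegionAnnotation | None = None,
) -> pd.DataFrame:
    """Window profile: crossover events per fixed window per F2.

    Returns a DataFrame with ``chrom, start, end, count, per_f2`` (and a
    ``label`` column when an annotation is supplied; windows straddling a
    region boundary take the label covering the majority of their span).
    The final partial window keeps its true width.
    """
    if n_individuals is None or n_individuals <= 0:
        raise ValueError("n_individuals must be a positive count")
    rows = []
    for chrom, length in chrom_lengths.items():
        n_win = int(np.ceil(length / window_bp))
        starts = np.arange(n_win, dtype=np.int64) * window_bp + 1
        ends = np.minimum(starts + window_bp - 1, length)
        sub = calls.loc[calls["chrom"] == chrom]
        mid = sub["midpoint"].to_numpy(dtype=float)
        if np.any(mid > length) or np.any(mid < 1):
            raise ValueError(f"{chrom}: call midpoint outside [1, {length}]")
        win = np.minimum(((mid - 1) // window_bp).astype(int), n_win - 1)
        counts = np.bincount(win, weights=sub["multiplicity"].to_numpy(), minlength=n_win)
        for s, e, c in zip(starts, ends, counts):
            rows.append((chrom, int(s), int(e), float(c), float(c) / n_individuals))
    profile = pd.DataFrame(rows, columns=["chrom", "start", "end", "count", "per_f2"])
    if annotation is not None:
        profile["label"] = [
            _majority_label(annotation, chrom, s, e)
            for chrom, s, e in zip(profile["chrom"], profile["start"], profile["end"])
        ]
    return profile


def _majority_label(annotation: RegionAnnotation, chrom: str, start: int, end: int) -> str:
    overlaps = {"arm": 0, "pericentromere": 0, "centromere": 0}
    for name in overlaps:
        for lo, hi in annotation.regions[chrom].get(name, []):
            overlaps[name] += max(0, min(end, hi) - max(start, lo) + 1)
    return max(overlaps, key=lambda k: (overlaps[k], k == "arm"))


def scale_tel_cen(
    calls: pd.DataFrame,
    annotation: RegionAnnotation,
    n_bins: int = 50,
    n_individuals: int | None = None,
    reference_window_bp: int = 300_000,
) -> pd.DataFrame:
    """Pooled telomere -> centromere profile over all chromosome arms.

    Each call is assigned ``x = (distance from its arm's telomere) /
    (arm length)`` with the arm running from the telomere to the edge of
    the centromere, then binned uniformly on [0, 1].  Per-bin frequency is
    normalized per F2 and per ``reference_window_bp`` of the mean physical
    bin width, so values are comparable to fixed-window profiles.  Calls
    inside a centromere are assigned x = 1 and flagged.
    """
    if n_individuals is None or n_individuals <= 0:
        raise ValueError("n_individuals must be a positive count")
    chroms = set(calls["chrom"])
    unknown = chroms - set(annotation.lengths)
    if unknown:
        raise ValueError(f"calls on unannotated chromosomes: {sorted(unknown)}")
    xs = np.empty(len(calls))
    flagged = np.zeros(len(calls), dtype=bool)
    mids = calls["midpoint"].to_numpy(dtype=float)
    for i, (chrom, mid) in enumerate(zip(calls["chrom"], mids)):
        clo, chi = annotation.centromere(chrom)
        length = annotation.lengths[chrom]
        if mid < clo:  # left arm, telomere at position 1
            xs[i] = (mid - 1) / (clo - 1)
        elif mid > chi:  # right arm, telomere at chromosome end
            xs[i] = (length - mid) / (length - chi)
        else:
            xs[i] = 1.0
            flagged[i] = True
    if np.any(flagged):
        warnings.warn(
            f"{int(flagged.sum())} call(s) inside a centromere assigned to the x = 1 bin",
            stacklevel=2,
        )
    bin_idx = np.minimum((xs * n_bins).astype(int), n_bins - 1)
    weights = calls["multiplicity"].to_numpy(dtype=float)
    counts = np.bincount(bin_idx, weights=weights, minlength=n_bins)
    arm_lengths = []
    for chrom in sorted(annotation.lengths):
        clo, chi = annotation.centromere(chrom)
        arm_lengths.extend([clo - 1, annotation.lengths[chrom] - chi])
    mean_bin_bp = float(np.mean(arm_lengths)) / n_bins
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return pd.DataFrame(
        {
            "x_lo": edges[:-1],
            "x_hi": edges[1:],
            "count": counts,
            "per_f2_per_ref": counts / n_individuals / (mean_bin_bp / reference_window_bp),
            "mean_bin_bp": mean_bin_bp,
        }
    )


def compare_regions(
    profile_a: pd.DataFrame, profile_b: pd.DataFrame, region_label: str
) -> StatResult:
    """Mann-Whitney U on per-window per-F2 frequencies restricted to a label."""
    for name, profile in (("a", profile_a), ("b", profile_b)):
        if "label" not in profile.columns:
            raise ValueError(f"profile {name} lacks region labels")
    a = profile_a.loc[profile_a["label"] == region_label, "per_f2"].to_numpy()
    b = profile_b.loc[profile_b["label"] == region_label, "per_f2"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"no windows labelled '{region_label}' in one of the profiles")
    result = mann_whitney_u(a, b)
    result.extras["median_a"] = float(np.median(a))
    result.extras["median_b"] = float(np.median(b))
    return result


def compare_chromosome_totals(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    n_a: int,
    n_b: int,
) -> pd.DataFrame:
    """Per-chromosome comparison of per-individual crossover counts.

    Individuals absent from a chromosome's calls contribute a zero count.
    Returns one row per chromosome with group means, standard errors and
    the Mann-Whitney U result.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("both populations must be non-empty")
    chroms = sorted(set(calls_a["chrom"]) | set(calls_b["chrom"]))
    rows = []
    for chrom in chroms:
        per_ind = []
        for calls, n in ((calls_a, n_a), (calls_b, n_b)):
            sub = calls.loc[calls["chrom"] == chrom]
            if isinstance(calls["individual"].dtype, pd.CategoricalDtype):
                counts = sub.groupby("individual", observed=False)["multiplicity"].sum()
                counts = counts.reindex(calls["individual"].cat.categories, fill_value=0)
                vals = counts.to_numpy(dtype=float)
                if len(vals) != n:
                    vals = np.concatenate([vals, np.zeros(n - len(vals))])
            else:
                counts = sub.groupby("individual")["multiplicity"].sum()
                vals = np.concatenate(
                    [counts.to_numpy(dtype=float), np.zeros(n - len(counts))]
                )
            per_ind.append(vals)
        a, b = per_ind
        res = mann_whitney_u(a, b)
        rows.append(
            (
                chrom,
                float(a.mean()),
                float(a.std(ddof=1) / np.sqrt(len(a))),
                float(b.mean()),
                float(b.std(ddof=1) / np.sqrt(len(b))),
                res.statistic,
                res.p_value,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "mean_a", "se_a", "mean_b", "se_b", "U", "p_value"],
    )
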