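"""Fine-scale crossover localization and hotspot usage within a short interval.

Recombinant plants selected from a fluorescent short-interval line are
sequenced across the interval; each accepted recombinant shows exactly one
parental-origin transition along the SNP scaffold and contributes one
breakpoint, localized between the flanking retained SNPs.  Breakpoints are
then aggregated into per-hotspot usage, per-SNP-section crossover rates
(scaled to the interval's measured genetic distance) and mutant/wild-type
rate ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import StatResult, kruskal_dunn, pearson_chi2

__all__ = [
    "HotspotDef",
    "thin_snps",
    "localize_breakpoints",
    "hotspot_usage",
    "usage_homogeneity_test",
    "section_rates",
    "section_ratios",
]


@dataclass(frozen=True)
class HotspotDef:
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: empty interval")

    def contains(self, pos: float) -> bool:
        return self.start <= pos <= self.end


def _check_disjoint(hotspots: list[HotspotDef]) -> None:
    ordered = sorted(hotspots, key=lambda h: h.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ValueError(f"hotspots {a.name} and {b.name} overlap")


def thin_snps(snps: np.ndarray, min_spacing: int = 100) -> np.ndarray:
    """Greedy left-to-right thinning to >= min_spacing bp between SNPs."""
    snps = np.asarray(snps, dtype=float)
    if len(snps) == 0:
        raise ValueError("empty SNP scaffold")
    kept = [snps[0]]
    for p in snps[1:]:
        if p - kept[-1] >= min_spacing:
            kept.append(p)
    return np.asarray(kept)


def localize_breakpoints(
    vectors: pd.DataFrame, min_spacing: int = 100
) -> tuple[pd.DataFrame, dict]:
    """Breakpoint intervals from recombinant genotype vectors.

    ``vectors`` has an ``id`` column then one column per SNP position
    (column names are bp positions) with calls in {P1, P2, missing marks
    '-'/NaN}.  SNPs are greedily thinned to ``min_spacing``; vectors with
    zero or more than one transition on the retained scaffold are excluded.

    Returns ``(breakpoints, report)`` where breakpoints has
    ``id, left_snp, right_snp, midpoint`` and the report tallies accepted /
    rejected vectors by reason.
    """
    snp_cols = [c for c in vectors.columns if c != "id"]
    if not snp_cols:
        raise ValueError("empty SNP scaffold")
    positions = np.array([float(c) for c in snp_cols])
    if np.any(np.diff(positions) <= 0):
        raise ValueError("SNP columns must be sorted and unique")
    kept_pos = thin_snps(positions, min_spacing)
    kept_cols = [snp_cols[i] for i in np.searchsorted(positions, kept_pos)]
    rows, rejected = [], {"no_transition": 0, "multiple_transitions": 0, "uncallable": 0}
    for _, row in vectors.iterrows():
        calls = row[kept_cols].to_numpy(dtype=object)
        valid = np.array([c in ("P1", "P2") for c in calls])
        pos_v = kept_pos[valid]
        calls_v = calls[valid]
        if len(calls_v) < 2:
            rejected["uncallable"] += 1
            continue
        flips = np.nonzero(calls_v[:-1] != calls_v[1:])[0]
        if len(flips) == 0:
            rejected["no_transition"] += 1
        elif len(flips) > 1:
            rejected["multiple_transitions"] += 1
        else:
            i = flips[0]
            left, right = float(pos_v[i]), float(pos_v[i + 1])
            rows.append((row["id"], int(left), int(right), (int(left) + int(right)) // 2))
    breakpoints = pd.DataFrame(rows, columns=["id", "left_snp", "right_snp", "midpoint"])
    report = {
        "n_input": len(vectors),
        "n_accepted": len(breakpoints),
        **rejected,
    }
    return breakpoints, report


def hotspot_usage(
    breakpoints: pd.DataFrame,
    hotspots: list[HotspotDef],
    include_background: bool = True,
) -> pd.DataFrame:
    """Per-hotspot breakpoint counts and proportions (midpoint assignment).

    With ``include_background`` (default) events outside every hotspot form
    a ``background`` category and proportions sum to 1 over all rows;
    otherwise background events are dropped and proportions renormalize
    over the hotspots.
    """
    _check_disjoint(hotspots)
    names = [h.name for h in hotspots] + (["background"] if include_background else [])
    counts = {name: 0 for name in names}
    for mid in breakpoints["midpoint"]:
        hit = next((h.name for h in hotspots if h.contains(mid)), None)
        if hit is not None:
            counts[hit] += 1
        elif include_background:
            counts["background"] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "category": names,
            "count": [counts[n] for n in names],
            "proportion": [counts[n] / total if total else 0.0 for n in names],
        }
    )


def usage_homogeneity_test(usage_a: pd.DataFrame, usage_b: pd.DataFrame) -> StatResult:
    """Pearson chi-square homogeneity test on two usage tables."""
    if list(usage_a["category"]) != list(usage_b["category"]):
        raise ValueError("usage tables have mismatched categories")
    table = np.vstack([usage_a["count"].to_numpy(), usage_b["count"].to_numpy()])
    nonzero = table.sum(axis=0) > 0
    return pearson_chi2(table[:, nonzero])


def section_rates(
    breakpoints: pd.DataFrame,
    thinned_snps: np.ndarray,
    n_samples: int,
    interval_cm: float,
) -> pd.DataFrame:
    """Per-SNP-section crossover rates, scaled to the interval's cM.

    Sections are consecutive pairs of retained SNPs.  A breakpoint whose
    interval spans several sections is spread fractionally and uniformly
    over them.  ``cm_scaled`` renormalizes section rates so they sum to
    ``interval_cm`` exactly.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    if interval_cm <= 0:
        raise ValueError("interval_cm must be > 0")
    snps = np.asarray(thinned_snps, dtype=float)
    if len(snps) < 2:
        raise ValueError("need >= 2 SNPs for sections")
    n_sec = len(snps) - 1
    counts = np.zeros(n_sec)
    for left, right in zip(breakpoints["left_snp"], breakpoints["right_snp"]):
        i = int(np.searchsorted(snps, left))
        j = int(np.searchsorted(snps, right))
        if snps[i] != left or snps[j] != right:
            raise ValueError(
                f"breakpoint ({left}, {right}) not aligned to the thinned scaffold"
            )
        span = max(j - i, 1)
        counts[i:j] += 1.0 / span
    rates = counts / n_samples
    total = rates.sum()
    cm_scaled = rates * interval_cm / total if total > 0 else np.zeros(n_sec)
    return pd.DataFrame(
        {
            "snp_left": snps[:-1].astype(int),
            "snp_right": snps[1:].astype(int),
            "count": counts,
            "rate": rates,
            "cm_scaled": cm_scaled,
        }
    )


def section_ratios(
    rates_mut: pd.DataFrame,
    rates_wt: pd.DataFrame,
    hotspots: list[HotspotDef],
    adjust: str | None = None,
) -> dict:
    """Mutant / wild-type rate ratio per SNP section, grouped by hotspot.

    Sections whose wild-type rate is zero are excluded (and reported).
    Hotspot membership is by section midpoint.  Returns the per-section
    ratio table, per-hotspot mean ratios and a Kruskal-Wallis + Dunn
    comparison of ratios across hotspots.
    """
    _check_disjoint(hotspots)
    for col in ("snp_left", "snp_right"):
        if not np.array_equal(rates_mut[col].to_numpy(), rates_wt[col].to_numpy()):
            raise ValueError("section scaffolds differ between groups")
    mid = (rates_mut["snp_left"].to_numpy() + rates_mut["snp_right"].to_numpy()) / 2.0
    hotspot_of = np.array(
        [next((h.name for h in hotspots if h.contains(m)), None) for m in mid],
        dtype=object,
    )
    wt = rates_wt["rate"].to_numpy(dtype=float)
    mut = rates_mut["rate"].to_numpy(dtype=float)
    usable = wt > 0
    ratios = pd.DataFrame(
        {
            "snp_left": rates_mut["snp_left"].to_numpy()[usable],
            "snp_right": rates_mut["snp_right"].to_numpy()[usable],
            "hotspot": hotspot_of[usable],
            "ratio": mut[usable] / wt[usable],
        }
    )
    excluded = pd.DataFrame(
        {
            "snp_left": rates_mut["snp_left"].to_numpy()[~usable],
            "snp_right": rates_mut["snp_right"].to_numpy()[~usable],
            "hotspot": hotspot_of[~usable],
        }
    )
    in_hotspot = ratios.loc[ratios["hotspot"].notna()]
    groups = {
        name: sub["ratio"].to_numpy()
        for name, sub in in_hotspot.groupby("hotspot", sort=False)
        if len(sub) > 0
    }
    if len(groups) >= 2:
        omnibus, pairwise = kruskal_dunn(groups, adjust=adjust)
    else:
        omnibus, pairwise = None, []
    mean_ratio = {name: float(np.mean(vals)) for name, vals in groups.items()}
    return {
        "ratios": ratios,
        "excluded": excluded,
        "mean_ratio": mean_ratio,
        "omnibus": omnibus,
        "pairwise": pairwise,
    }
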