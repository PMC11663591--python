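"""Forward simulation of F2 populations, genotype observations and seed assays.

The meiosis model mixes two crossover pathways:

* Class I (interfering): chiasmata form along the bivalent as a stationary
  gamma renewal process with shape ``nu`` and intensity 2 per Morgan of the
  Class-I map share ``(1 - p_class2) * map_length``; each chiasma involves
  the sampled chromatid with probability 1/2 (chromatid thinning), so the
  expected Class I crossovers per gamete equal the Class-I map share.
* Class II (non-interfering): a homogeneous Poisson overlay with mean
  ``p_class2 * map_length`` per gamete.

The overlay *partitions* the map length, so the expected total crossover
count per gamete equals ``map_length`` for every interference setting.
An F2 individual is the union of two independent gametes; genotypes are
read off at marker positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ChromosomeModel

__all__ = [
    "MeiosisParams",
    "ObservationParams",
    "sample_gamete_crossovers",
    "genetic_to_physical",
    "simulate_f2_population",
    "observe_genotypes",
    "seed_class_probabilities",
    "simulate_seed_counts",
    "simulate_recombinant_breakpoints",
    "marker_resolvable_truth",
]

TRUTH_COLUMNS = ["individual", "chrom", "pos_bp", "gamete", "xo_class"]


@dataclass(frozen=True)
class MeiosisParams:
    """Interference and pathway-mixture parameters of the meiosis model.

    nu : gamma-renewal shape (>= 1); nu = 1 recovers a Poisson (no
        interference), larger values space Class I events more evenly.
    p_class2 : fraction of the map length carried by the non-interfering
        overlay (0..1).
    obligate : when True, bivalents with zero chiasmata are rejection
        sampled away (at least one chiasma per bivalent).  This slightly
        inflates the realized map length of short chromosomes.
    """

    nu: float = 5.0
    p_class2: float = 0.12
    obligate: bool = False

    def __post_init__(self) -> None:
        if self.nu < 1:
            raise ValueError("nu must be >= 1")
        if not 0 <= self.p_class2 <= 1:
            raise ValueError("p_class2 must be in [0, 1]")


@dataclass(frozen=True)
class ObservationParams:
    """Sparse sequencing observation model (low-coverage genotyping)."""

    mean_depth: float = 1.5
    allele_error: float = 0.005

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0 <= self.allele_error < 0.5:
            raise ValueError("allele_error must be in [0, 0.5)")


def _stationary_gamma_renewal(length: float, nu: float, rate: float, rng) -> np.ndarray:
    """Points of a stationary gamma renewal process on [0, length].

    ``rate`` is the event intensity (events per unit length); inter-arrival
    times are Gamma(nu, scale=1/(rate*nu)).  The first arrival is drawn from
    the equilibrium (stationary forward-recurrence) distribution, sampled as
    U * X with X length-biased, i.e. X ~ Gamma(nu + 1, scale).
    """
    if length <= 0 or rate <= 0:
        return np.empty(0)
    scale = 1.0 / (rate * nu)
    first = rng.uniform() * rng.gamma(nu + 1.0, scale)
    if first > length:
        return np.empty(0)
    points = [first]
    # draw inter-arrivals in blocks
    while True:
        block = rng.gamma(nu, scale, size=max(8, int(rate * (length - points[-1])) + 8))
        arrivals = points[-1] + np.cumsum(block)
        inside = arrivals[arrivals <= length]
        points.extend(inside.tolist())
        if len(inside) < len(block):
            break
    return np.asarray(points)


def sample_gamete_crossovers(
    map_length: float, params: MeiosisParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one gamete's crossovers in genetic coordinates.

    Returns ``(positions, classes)`` with positions in Morgans on
    ``[0, map_length]`` (sorted) and classes ``"I"`` / ``"II"`` per event.
    Expected total count equals ``map_length`` when ``obligate`` is False.
    """
    if map_length < 0:
        raise ValueError("map_length must be >= 0")
    if map_length == 0:
        return np.empty(0), np.empty(0, dtype=object)
    p2 = params.p_class2
    rate_1 = 2.0 * (1.0 - p2)  # chiasma intensity per Morgan, Class I
    mean_2 = 2.0 * p2 * map_length  # chiasma mean, Class II overlay
    while True:
        chiasmata_1 = _stationary_gamma_renewal(map_length, params.nu, rate_1, rng)
        n2 = rng.poisson(mean_2)
        chiasmata_2 = rng.uniform(0.0, map_length, size=n2)
        if not params.obligate or (len(chiasmata_1) + n2) > 0:
            break
    # chromatid thinning: each chiasma involves the sampled chromatid w.p. 1/2
    keep_1 = chiasmata_1[rng.uniform(size=len(chiasmata_1)) < 0.5]
    keep_2 = chiasmata_2[rng.uniform(size=n2) < 0.5]
    pos = np.concatenate([keep_1, keep_2])
    cls = np.concatenate(
        [np.repeat("I", len(keep_1)), np.repeat("II", len(keep_2))]
    ).astype(object)
    order = np.argsort(pos, kind="stable")
    return pos[order], cls[order]


def genetic_to_physical(
    positions, chrom: ChromosomeModel, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Invert the chromosome's cumulative intensity (Morgans -> bp)."""
    return chrom.genetic_to_physical(positions, rng)


def simulate_f2_population(
    genome: list[ChromosomeModel],
    params: MeiosisParams,
    n: int,
    markers: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n`` selfed-F1 (F2) individuals on a marker scaffold.

    Parameters
    ----------
    markers:
        DataFrame with columns ``chrom`` and ``pos`` (1-based bp), sorted
        within each chromosome.
    Returns
    -------
    genotypes:
        DataFrame with columns ``chrom``, ``pos`` then one column per
        individual holding calls in {"A", "H", "B"} (noise free).
    truth:
        DataFrame with columns ``individual, chrom, pos_bp, gamete,
        xo_class`` listing every crossover of every individual.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    markers = markers.reset_index(drop=True)
    by_name = {c.name: c for c in genome}
    unknown = set(markers["chrom"]) - set(by_name)
    if unknown:
        raise ValueError(f"markers reference unknown chromosomes: {sorted(unknown)}")
    individuals = [f"F2_{i:04d}" for i in range(n)]
    truth_rows: list[tuple] = []
    code_to_call = np.array(["A", "H", "B"])
    columns: dict[str, np.ndarray] = {}
    for ind in individuals:
        col = np.empty(len(markers), dtype="U1")
        for chrom_name, sub in markers.groupby("chrom", sort=False):
            chrom = by_name[chrom_name]
            pos_bp = sub["pos"].to_numpy(dtype=float)
            dose = np.zeros(len(sub), dtype=np.int8)
            for gamete in (1, 2):
                gpos, gcls = sample_gamete_crossovers(chrom.map_length, params, rng)
                xo_bp = genetic_to_physical(gpos, chrom, rng) if len(gpos) else np.empty(0)
                start = rng.integers(0, 2)
                allele = (start + np.searchsorted(np.sort(xo_bp), pos_bp)) % 2
                dose += allele.astype(np.int8)
                for bp, c in zip(np.sort(xo_bp), gcls[np.argsort(xo_bp, kind="stable")]):
                    truth_rows.append((ind, chrom_name, float(bp), gamete, c))
            col[sub.index] = code_to_call[dose]
        columns[ind] = col
    geno = pd.concat(
        [markers[["chrom", "pos"]], pd.DataFrame(columns, index=markers.index)], axis=1
    )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["individual", "chrom", "pos_bp"], kind="stable").reset_index(
        drop=True
    )
    return geno, truth


def observe_genotypes(
    truth_geno: pd.DataFrame,
    params: ObservationParams,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Push a noiseless genotype matrix through the sequencing model.

    Per cell, depth ~ Poisson(mean_depth); each read reports one allele
    (either allele with probability 1/2 for hets), miscalled with
    probability ``allele_error``.  The observed call is ``-`` at depth 0,
    ``H`` when both alleles were seen, else the observed homozygote.

    Returns ``(observed, depths)`` shaped like the input.
    """
    ind_cols = [c for c in truth_geno.columns if c not in ("chrom", "pos")]
    obs_cols: dict[str, np.ndarray] = {}
    depth_cols: dict[str, np.ndarray] = {}
    e = params.allele_error
    for col in ind_cols:
        calls = truth_geno[col].to_numpy()
        d = rng.poisson(params.mean_depth, size=len(calls))
        # number of reads reporting the parent-2 allele
        p_alt = np.where(calls == "A", e, np.where(calls == "B", 1.0 - e, 0.5))
        n_alt = rng.binomial(d, p_alt)
        out = np.full(len(calls), "-", dtype="U1")
        seen = d > 0
        out[seen & (n_alt == 0)] = "A"
        out[seen & (n_alt == d)] = "B"
        out[seen & (n_alt > 0) & (n_alt < d)] = "H"
        obs_cols[col] = out
        depth_cols[col] = d
    scaffold = truth_geno[["chrom", "pos"]]
    observed = pd.concat(
        [scaffold, pd.DataFrame(obs_cols, index=truth_geno.index)], axis=1
    )
    depths = pd.concat(
        [scaffold, pd.DataFrame(depth_cols, index=truth_geno.index)], axis=1
    )
    return observed, depths


# -- fluorescent-seed assay -------------------------------------------------


def seed_class_probabilities(r: float) -> dict[str, float]:
    """Seed fluorescence class probabilities for a hemizygous two-reporter F1.

    Gametes are RG:(1-r)/2, ++:(1-r)/2, R+:r/2, +G:r/2; a selfed seed is
    green iff it received >= 1 G allele and red iff >= 1 R allele.
    """
    if not 0 <= r <= 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5]")
    single = (1.0 - (1.0 - r) ** 2) / 4.0
    none = ((1.0 - r) / 2.0) ** 2
    both = 1.0 - 2.0 * single - none
    return {
        "n_green_only": single,
        "n_red_only": single,
        "n_both": both,
        "n_none": none,
    }


def simulate_seed_counts(r: float, n_seeds: int, rng: np.random.Generator):
    """Multinomial seed-class tallies for one plant as a SeedCounts record."""
    from .seeds import SeedCounts

    probs = seed_class_probabilities(r)
    keys = list(probs)
    draws = rng.multinomial(n_seeds, [probs[k] for k in keys])
    return SeedCounts(**{k: int(v) for k, v in zip(keys, draws)})


# -- fine-interval recombinants ---------------------------------------------


def simulate_recombinant_breakpoints(
    hotspots: list[tuple[str, int, int]],
    weights: list[float],
    background_weight: float,
    snps: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw recombinant genotype vectors from a hotspot mixture.

    Parameters
    ----------
    hotspots:
        ``(name, start, end)`` intervals within the SNP scaffold (bp).
    weights, background_weight:
        Mixture weights (>= 0, summing to 1 with the background); the
        background component is uniform over the scaffold outside hotspots.
    snps:
        Sorted SNP positions (>= 2 of them).
    Returns
    -------
    vectors:
        DataFrame with an ``id`` column then one column per SNP position,
        values in {"P1", "P2"}: parent-1 left of the breakpoint and
        parent-2 right of it, orientation randomized per recombinant.
    true_positions:
        The sampled breakpoint positions (bp), one per recombinant.
    """
    snps = np.asarray(snps, dtype=float)
    if len(snps) < 2:
        raise ValueError("need at least 2 SNPs")
    if n < 0:
        raise ValueError("n must be >= 0")
    w = np.asarray(list(weights) + [background_weight], dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights plus background must be nonnegative and sum to 1")
    lo, hi = snps[0], snps[-1]
    spans = [(float(s), float(e)) for _, s, e in hotspots]
    # background = complement of hotspots within [lo, hi]
    gaps: list[tuple[float, float]] = []
    cursor = lo
    for s, e in sorted(spans):
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < hi:
        gaps.append((cursor, hi))
    gap_len = np.array([e - s for s, e in gaps], dtype=float)

    columns = [f"{int(p)}" for p in snps]
    rows = []
    positions = np.empty(n)
    for i in range(n):
        comp = rng.choice(len(w), p=w)
        if comp < len(spans):
            s, e = spans[comp]
            bp = rng.uniform(s, e)
        else:
            if gap_len.sum() <= 0:
                raise ValueError("background weight > 0 but no background span")
            g = rng.choice(len(gaps), p=gap_len / gap_len.sum())
            bp = rng.uniform(*gaps[g])
        positions[i] = bp
        left_is_p1 = rng.uniform() < 0.5
        left, right = ("P1", "P2") if left_is_p1 else ("P2", "P1")
        rows.append([f"rec_{i:04d}"] + [left if p < bp else right for p in snps])
    vectors = pd.DataFrame(rows, columns=["id"] + columns)
    return vectors, positions


# -- ground-truth bookkeeping -----------------------------------------------


def marker_resolvable_truth(
    truth: pd.DataFrame,
    markers: pd.DataFrame,
    genotypes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Reduce simulator truth to what a genotype matrix can express.

    Crossovers outside the marker span are invisible.  An even number of
    crossovers of the *same gamete* between one pair of adjacent markers
    cancels (the haplotype re-enters its previous phase before the next
    marker) and an odd number collapses to one effective event.  When both
    gametes carry an effective event in the same interval, the pair is
    visible only if it flips the genotype (a direct A<->B switch); if the
    flanking genotypes are equal (an H -> H co-event) the pair is invisible
    and is dropped — this last case requires the noiseless ``genotypes``
    matrix, without which such pairs are conservatively kept.
    """
    out = []
    for (ind, chrom), sub in truth.groupby(["individual", "chrom"], sort=False):
        pos_markers = np.sort(
            markers.loc[markers["chrom"] == chrom, "pos"].to_numpy(dtype=float)
        )
        kept = []
        for gamete, g in sub.groupby("gamete", sort=False):
            bp = g["pos_bp"].to_numpy(dtype=float)
            inside = (bp >= pos_markers[0]) & (bp < pos_markers[-1])
            g = g.loc[inside]
            interval = np.searchsorted(pos_markers, g["pos_bp"].to_numpy(), side="right")
            for iv, grp in g.groupby(interval, sort=False):
                if len(grp) % 2 == 1:
                    kept.append((int(iv), grp.iloc[[0]]))
        if genotypes is not None:
            by_interval: dict[int, list] = {}
            for iv, rec in kept:
                by_interval.setdefault(iv, []).append(rec)
            sub_geno = genotypes.loc[genotypes["chrom"] == chrom]
            calls = sub_geno[ind].to_numpy()
            kept = []
            for iv, recs in by_interval.items():
                if len(recs) == 2 and calls[iv - 1] == calls[iv]:
                    continue  # opposite-phase co-event: genotype unchanged
                kept.extend((iv, r) for r in recs)
        out.extend(rec for _, rec in kept)
    if not out:
        return truth.iloc[0:0]
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["individual", "chrom", "pos_bp"], kind="stable").reset_index(
        drop=True
    )
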