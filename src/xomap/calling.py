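"""Crossover calling from (possibly sparse and noisy) F2 genotype matrices.

Crossovers are genotype switches along a chromosome, assigned to the
midpoint between the flanking informative markers.  The caller works in
three deterministic stages per individual and chromosome:

1. *Window smoothing* — every informative marker is re-labeled from the
   composition of a centered window of ``w`` informative calls.  The rule
   is asymmetric by design: a homozygous label requires near-unanimity
   (at most ``m`` contrary calls, ``m`` scaling with ``w``), because under
   low-coverage sequencing a heterozygous site is frequently miscalled as
   either homozygote, while a true homozygous stretch produces almost no
   opposite-parent calls.  Windows containing both parental classes but no
   het call are treated as a direct A<->B switch zone and decided by the
   A/B majority (ties keep the previous label; the first marker keeps its
   own call).  With ``w = 1`` the stage is the identity, so the caller
   reduces to an exact transition scan on clean data.
2. *Minimum-segment merging* — maximal runs form segments; segments with
   fewer than ``min_segment_markers`` informative markers are merged into
   the flanking segment with more informative markers (ties merge left).
3. *Boundary refinement* — each boundary between adjacent segments is
   re-placed at the split of the raw informative calls that maximizes
   agreement with the two segment genotypes (the split nearest the coarse
   boundary on ties).  On noise-free data this restores the exact
   transition position regardless of the smoothing window.

A direct A<->B switch emits one call of multiplicity 2: in an F2 both
gametes must have exchanged in that interval.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CallerParams",
    "Segment",
    "CrossoverCall",
    "filter_libraries",
    "filter_markers",
    "segment_individual",
    "call_crossovers",
    "call_population",
    "count_per_individual",
]

CALL_CODES = {"A": 0, "H": 1, "B": 2, "-": -1}
CODE_CALLS = np.array(["A", "H", "B"])


@dataclass(frozen=True)
class CallerParams:
    """Tunable thresholds of the caller.

    w : odd number of informative markers in the smoothing window.
    min_segment_markers : minimum informative markers per retained segment.
    min_quality : markers kept iff quality is strictly greater.
    min_coverage : markers kept iff mean depth is strictly greater.
    min_reads_per_library : individuals kept iff total reads >= this.
    """

    w: int = 15
    min_segment_markers: int = 5
    min_quality: float = 100.0
    min_coverage: float = 2.5
    min_reads_per_library: int = 95_000

    def __post_init__(self) -> None:
        if self.w < 1 or self.w % 2 == 0:
            raise ValueError("w must be an odd count >= 1")
        if self.min_segment_markers < 1:
            raise ValueError("min_segment_markers must be >= 1")

    @property
    def hom_tolerance(self) -> int:
        """Max contrary calls tolerated in a homozygous window."""
        return max(0, int(round(0.13 * self.w)))


@dataclass
class Segment:
    """Maximal run of one genotype over informative markers."""

    individual: str
    chromosome: str
    genotype: str  # A / H / B
    first: int  # index into the informative-marker scaffold
    last: int
    first_pos: int
    last_pos: int
    n_informative: int


@dataclass(frozen=True)
class CrossoverCall:
    individual: str
    chromosome: str
    left_pos: int
    right_pos: int
    midpoint: int
    multiplicity: int


# -- filters ----------------------------------------------------------------


def filter_libraries(read_counts: dict[str, int], min_reads: int = 95_000) -> list[str]:
    """Individuals whose library has at least ``min_reads`` reads."""
    for ind, count in read_counts.items():
        if count < 0:
            raise ValueError(f"negative read count for {ind}")
    return [ind for ind, count in read_counts.items() if count >= min_reads]


def filter_markers(
    markers: pd.DataFrame, min_quality: float = 100.0, min_coverage: float = 2.5
) -> pd.DataFrame:
    """Keep markers with quality and coverage strictly above the thresholds."""
    for col in ("quality", "coverage"):
        if col not in markers.columns:
            raise KeyError(f"marker table lacks required column '{col}'")
    keep = (markers["quality"] > min_quality) & (markers["coverage"] > min_coverage)
    return markers.loc[keep].reset_index(drop=True)


# -- smoothing --------------------------------------------------------------


def _window_counts(codes: np.ndarray, w: int) -> np.ndarray:
    """Per-marker counts of A/H/B in a centered window of w informative calls."""
    n = len(codes)
    half = w // 2
    onehot = np.zeros((n + 1, 3), dtype=np.int32)
    for k in range(3):
        onehot[1:, k] = np.cumsum(codes == k)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return onehot[hi] - onehot[lo]


def _smooth(codes: np.ndarray, w: int, m: int) -> np.ndarray:
    """Relabel informative calls; see module docstring for the rule."""
    n = len(codes)
    if n == 0:
        return codes
    if w == 1:
        return codes.copy()
    counts = _window_counts(codes, w)
    nA, nH, nB = counts[:, 0], counts[:, 1], counts[:, 2]
    out = np.empty(n, dtype=np.int8)
    hom_a = (nH + nB) <= m
    hom_b = (nH + nA) <= m
    switch_zone = ~hom_a & ~hom_b & (nH == 0)
    het = ~hom_a & ~hom_b & ~switch_zone
    out[hom_a] = 0
    out[hom_b] = 2
    out[het] = 1
    # direct A<->B switch zone: majority of parental calls, sequential tie rule
    idxs = np.nonzero(switch_zone)[0]
    for i in idxs:
        if nA[i] > nB[i]:
            out[i] = 0
        elif nB[i] > nA[i]:
            out[i] = 2
        else:
            out[i] = out[i - 1] if i > 0 else codes[i]
    # degenerate double-match (hom_a and hom_b can overlap only for tiny windows)
    both = hom_a & hom_b
    if np.any(both):
        out[both] = codes[both]
    return out


# -- segmentation -----------------------------------------------------------


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(code, start, end_inclusive) for maximal constant runs."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((int(labels[start]), start, i - 1))
            start = i
    return runs


def _merge_short(runs: list[tuple[int, int, int]], min_markers: int) -> list[tuple[int, int, int]]:
    runs = list(runs)
    while len(runs) > 1:
        short = [
            i for i, (_, s, e) in enumerate(runs) if (e - s + 1) < min_markers
        ]
        if not short:
            break
        i = short[0]
        code, s, e = runs[i]
        if i == 0:
            target = 1
        elif i == len(runs) - 1:
            target = i - 1
        else:
            ln = runs[i - 1][2] - runs[i - 1][1] + 1
            rn = runs[i + 1][2] - runs[i + 1][1] + 1
            target = i - 1 if ln >= rn else i + 1
        tcode, ts, te = runs[target]
        merged = (tcode, min(ts, s), max(te, e))
        lo, hi = sorted((i, target))
        runs[lo:hi + 1] = [merged]
        # coalesce equal-genotype neighbours created by the merge
        j = 0
        while j < len(runs) - 1:
            if runs[j][0] == runs[j + 1][0]:
                runs[j:j + 2] = [(runs[j][0], runs[j][1], runs[j + 1][2])]
            else:
                j += 1
    return runs


def _refine_boundaries(
    codes: np.ndarray, runs: list[tuple[int, int, int]]
) -> list[tuple[int, int, int]]:
    """Re-place each boundary at the max-agreement split of the raw calls."""
    if len(runs) < 2:
        return runs
    bounds = []  # index of first marker of the right segment, per boundary
    prev = 0
    for k in range(len(runs) - 1):
        gl, gr = runs[k][0], runs[k + 1][0]
        lo = max(runs[k][1], prev) + 1  # split s: right segment starts at s
        hi = runs[k + 1][2]
        coarse = runs[k + 1][1]
        match_l = np.concatenate([[0], np.cumsum(codes == gl)])
        match_r = np.concatenate([[0], np.cumsum(codes == gr)])
        splits = np.arange(lo, hi + 1)
        score = match_l[splits] + (match_r[-1] - match_r[splits])
        best = np.flatnonzero(score == score.max())
        s = int(splits[best[np.argmin(np.abs(splits[best] - coarse))]])
        bounds.append(s)
        prev = s
    refined = []
    starts = [runs[0][1]] + bounds
    ends = [b - 1 for b in bounds] + [runs[-1][2]]
    for (code, _, _), s, e in zip(runs, starts, ends):
        refined.append((code, s, e))
    return refined


def segment_individual(
    calls: np.ndarray,
    positions: np.ndarray,
    params: CallerParams,
    individual: str = "",
    chromosome: str = "",
) -> list[Segment]:
    """Segment one individual's chromosome into maximal genotype runs.

    ``calls`` holds symbols in {A, H, B, -} (or their integer codes);
    missing calls are dropped, never imputed.
    """
    calls = np.asarray(calls)
    if calls.dtype.kind in "OUS":
        codes = np.array([CALL_CODES[c] for c in calls], dtype=np.int8)
    else:
        codes = calls.astype(np.int8)
    positions = np.asarray(positions)
    keep = codes >= 0
    codes, positions = codes[keep], positions[keep]
    if len(codes) == 0:
        return []
    smoothed = _smooth(codes, params.w, params.hom_tolerance)
    runs = _runs(smoothed)
    runs = _merge_short(runs, params.min_segment_markers)
    runs = _refine_boundaries(codes, runs)
    segments = []
    for code, s, e in runs:
        segments.append(
            Segment(
                individual=individual,
                chromosome=chromosome,
                genotype=str(CODE_CALLS[code]),
                first=s,
                last=e,
                first_pos=int(positions[s]),
                last_pos=int(positions[e]),
                n_informative=e - s + 1,
            )
        )
    return segments


def call_crossovers(segments: list[Segment]) -> list[CrossoverCall]:
    """One crossover call per adjacent segment pair.

    The call interval runs from the last informative marker of the left
    segment to the first informative marker of the right one; the midpoint
    is the floor of their mean.  Direct A<->B transitions have
    multiplicity 2 (both gametes recombined in that interval).
    """
    calls = []
    for left, right in itertools.pairwise(segments):
        if (left.individual, left.chromosome) != (right.individual, right.chromosome):
            raise ValueError("segments from different individuals/chromosomes")
        if left.last_pos >= right.first_pos:
            raise ValueError("overlapping or unsorted segments")
        mult = 2 if {left.genotype, right.genotype} == {"A", "B"} else 1
        calls.append(
            CrossoverCall(
                individual=left.individual,
                chromosome=left.chromosome,
                left_pos=left.last_pos,
                right_pos=right.first_pos,
                midpoint=(left.last_pos + right.first_pos) // 2,
                multiplicity=mult,
            )
        )
    return calls


def call_population(
    genotypes: pd.DataFrame, params: CallerParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment and call every individual of a genotype matrix.

    ``genotypes`` must hold ``chrom`` and ``pos`` columns, then one column
    per individual with calls in {A, H, B, -}.

    Returns ``(segments, calls)`` as tidy DataFrames.  ``calls`` carries
    ``individual, chrom, left_pos, right_pos, midpoint, multiplicity`` and
    always contains every individual of the input in its ``individual``
    categories, so zero-crossover individuals are not silently dropped.
    """
    params = params or CallerParams()
    ind_cols = [c for c in genotypes.columns if c not in ("chrom", "pos")]
    seg_rows, call_rows = [], []
    for chrom_name, sub in genotypes.groupby("chrom", sort=False):
        positions = sub["pos"].to_numpy()
        for ind in ind_cols:
            segs = segment_individual(
                sub[ind].to_numpy(), positions, params, individual=ind, chromosome=chrom_name
            )
            for s in segs:
                seg_rows.append(
                    (s.individual, s.chromosome, s.genotype, s.first, s.last,
                     s.first_pos, s.last_pos, s.n_informative)
                )
            for c in call_crossovers(segs):
                call_rows.append(
                    (c.individual, c.chromosome, c.left_pos, c.right_pos,
                     c.midpoint, c.multiplicity)
                )
    segments = pd.DataFrame(
        seg_rows,
        columns=["individual", "chrom", "genotype", "first", "last",
                 "first_pos", "last_pos", "n_informative"],
    )
    calls = pd.DataFrame(
        call_rows,
        columns=["individual", "chrom", "left_pos", "right_pos", "midpoint", "multiplicity"],
    )
    calls["individual"] = pd.Categorical(calls["individual"], categories=ind_cols)
    return segments, calls


def count_per_individual(
    calls: pd.DataFrame, n_individuals: int | None = None
) -> tuple[pd.Series, float]:
    """Per-individual crossover totals (sum of multiplicities) and group mean.

    The mean is total events over ``n_individuals``; when not given, the
    number of distinct individuals in ``calls`` (categorical individuals
    contribute even with zero calls).
    """
    if len(calls) == 0:
        totals = pd.Series(dtype=float)
    elif isinstance(calls["individual"].dtype, pd.CategoricalDtype):
        totals = calls.groupby("individual", observed=False)["multiplicity"].sum()
    else:
        totals = calls.groupby("individual")["multiplicity"].sum()
    n = n_individuals if n_individuals is not None else len(totals)
    if n == 0:
        raise ValueError("cannot compute a mean over zero individuals")
    mean = float(totals.sum()) / n
    return totals, mean
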