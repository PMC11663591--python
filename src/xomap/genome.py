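"""Chromosome models: physical layout, region annotation and recombination intensity.

A :class:`ChromosomeModel` couples the physical map of one chromosome
(length, centromere, pericentromeres) with a genetic map length (Morgans
per gamete) and a piecewise-constant relative crossover intensity over
base-pair intervals.  The intensity is only defined up to a scale factor:
events are placed by inverting the normalized cumulative intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChromosomeModel",
    "RegionAnnotation",
    "arabidopsis_like_genome",
    "default_annotation",
]


@dataclass(frozen=True)
class ChromosomeModel:
    """Physical + genetic model of one chromosome.

    Parameters
    ----------
    name:
        Chromosome name (e.g. ``"Chr1"``).
    length_bp:
        Physical length in base pairs (1-based coordinates run 1..length_bp).
    centromere:
        ``(start, end)`` of the centromere in bp.
    pericentromere:
        List of ``(start, end)`` intervals flanking the centromere.
    map_length:
        Genetic length in Morgans *per gamete* (expected crossovers per
        gamete on this chromosome).
    intensity_bounds, intensity_values:
        Piecewise-constant relative recombination intensity:
        ``intensity_values[i]`` holds on ``[intensity_bounds[i],
        intensity_bounds[i + 1])``.  ``intensity_bounds`` spans
        ``[0, length_bp]``.  Values are relative weights (>= 0) and need not
        integrate to anything in particular.
    """

    name: str
    length_bp: int
    centromere: tuple[int, int]
    pericentromere: tuple[tuple[int, int], ...] = ()
    map_length: float = 0.0
    intensity_bounds: tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    intensity_values: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.name}: length_bp must be positive")
        if self.map_length < 0:
            raise ValueError(f"{self.name}: map_length must be >= 0")
        if self.intensity_bounds is None:
            object.__setattr__(self, "intensity_bounds", (0.0, float(self.length_bp)))
            object.__setattr__(self, "intensity_values", (1.0,))
        bounds = np.asarray(self.intensity_bounds, dtype=float)
        values = np.asarray(self.intensity_values, dtype=float)
        if bounds.ndim != 1 or len(bounds) != len(values) + 1:
            raise ValueError(f"{self.name}: intensity bounds/values size mismatch")
        if np.any(np.diff(bounds) <= 0):
            raise ValueError(f"{self.name}: intensity bounds must be increasing")
        if bounds[0] != 0 or bounds[-1] != self.length_bp:
            raise ValueError(f"{self.name}: intensity must cover [0, length_bp]")
        if np.any(values < 0):
            raise ValueError(f"{self.name}: intensity must be >= 0")
        mass = float(np.sum(values * np.diff(bounds)))
        if mass <= 0 and self.map_length > 0:
            raise ValueError(f"{self.name}: zero total intensity with map_length > 0")
        for lo, hi in [self.centromere, *self.pericentromere]:
            if not (1 <= lo < hi <= self.length_bp):
                raise ValueError(f"{self.name}: region ({lo}, {hi}) outside chromosome")

    # -- intensity geometry -------------------------------------------------

    def _cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        bounds = np.asarray(self.intensity_bounds, dtype=float)
        values = np.asarray(self.intensity_values, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(values * np.diff(bounds))])
        return bounds, cum

    def genetic_to_physical(self, positions, rng=None) -> np.ndarray:
        """Map genetic positions (Morgans in ``[0, map_length]``) to bp.

        Inverts the normalized cumulative intensity; the result is strictly
        monotone in genetic position and never falls inside a
        zero-intensity interval (up to the interval's left edge).
        ``rng`` is accepted for interface symmetry; the inversion is
        deterministic.
        """
        pos = np.atleast_1d(np.asarray(positions, dtype=float))
        if self.map_length == 0:
            if pos.size:
                raise ValueError(f"{self.name}: no genetic map, cannot place events")
            return np.empty(0)
        if np.any((pos < 0) | (pos > self.map_length)):
            raise ValueError(
                f"{self.name}: genetic position outside [0, {self.map_length}]"
            )
        bounds, cum = self._cumulative()
        target = pos / self.map_length * cum[-1]
        idx = np.searchsorted(cum, target, side="left")
        idx = np.clip(idx, 1, len(cum) - 1)
        values = np.asarray(self.intensity_values, dtype=float)
        v = values[idx - 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(v > 0, (target - cum[idx - 1]) / v, 0.0)
        return bounds[idx - 1] + frac

    def region_of(self, pos_bp: float) -> str:
        """Label a bp position as arm / pericentromere / centromere."""
        lo, hi = self.centromere
        if lo <= pos_bp <= hi:
            return "centromere"
        for plo, phi in self.pericentromere:
            if plo <= pos_bp <= phi:
                return "pericentromere"
        return "arm"


@dataclass(frozen=True)
class RegionAnnotation:
    """Per-chromosome arm / pericentromere / centromere intervals (1-based bp)."""

    regions: dict[str, dict[str, list[tuple[int, int]]]]
    lengths: dict[str, int]

    def centromere(self, chrom: str) -> tuple[int, int]:
        cen = self.regions[chrom]["centromere"]
        if len(cen) != 1:
            raise ValueError(f"{chrom}: expected a single centromere interval")
        return cen[0]

    def label(self, chrom: str, pos: float) -> str:
        for name in ("centromere", "pericentromere", "arm"):
            for lo, hi in self.regions[chrom].get(name, []):
                if lo <= pos <= hi:
                    return name
        return "arm"

    @classmethod
    def from_genome(cls, genome: list[ChromosomeModel]) -> "RegionAnnotation":
        regions: dict[str, dict[str, list[tuple[int, int]]]] = {}
        lengths: dict[str, int] = {}
        for chrom in genome:
            occupied = sorted([chrom.centromere, *chrom.pericentromere])
            arms: list[tuple[int, int]] = []
            cursor = 1
            for lo, hi in occupied:
                if lo > cursor:
                    arms.append((cursor, lo - 1))
                cursor = hi + 1
            if cursor <= chrom.length_bp:
                arms.append((cursor, chrom.length_bp))
            regions[chrom.name] = {
                "arm": arms,
                "pericentromere": list(chrom.pericentromere),
                "centromere": [chrom.centromere],
            }
            lengths[chrom.name] = chrom.length_bp
        return cls(regions=regions, lengths=lengths)


# -- default genome ---------------------------------------------------------

# Physical lengths follow the A. thaliana TAIR10 assembly; centromere /
# pericentromere extents are rounded approximations of the cytologically
# defined regions.  Genetic lengths are proportional to physical length and
# total ~4.04 Morgans per gamete (~8.1 crossovers per F2), the scale seen in
# Col x Ler F2 mapping populations.
_CHROM_SPECS = [
    # name, length, cen(lo,hi), peri extent beyond cen on each side (bp)
    ("Chr1", 30_427_671, (14_000_000, 15_500_000), 2_500_000),
    ("Chr2", 19_698_289, (3_000_000, 4_000_000), 1_500_000),
    ("Chr3", 23_459_830, (13_000_000, 14_500_000), 2_500_000),
    ("Chr4", 18_585_056, (3_500_000, 4_500_000), 1_500_000),
    ("Chr5", 26_975_502, (11_000_000, 12_500_000), 2_500_000),
]
_TOTAL_MAP = 4.04  # Morgans per gamete, all chromosomes


def arabidopsis_like_genome(
    arm_intensity: float = 1.0,
    peri_intensity: float = 0.4,
    cen_intensity: float = 0.0,
    total_map: float = _TOTAL_MAP,
) -> list[ChromosomeModel]:
    """Five-chromosome genome emulating an Arabidopsis Col x Ler cross.

    Crossover intensity is uniform within arms, suppressed over
    pericentromeres and (by default) zero over centromeres; genetic lengths
    are split across chromosomes in proportion to physical length.
    """
    total_bp = sum(s[1] for s in _CHROM_SPECS)
    genome = []
    for name, length, (clo, chi), peri_ext in _CHROM_SPECS:
        plo = max(1, clo - peri_ext)
        phi = min(length, chi + peri_ext)
        peri = ((plo, clo - 1), (chi + 1, phi))
        bounds = [0.0, float(plo - 1), float(clo - 1), float(chi), float(phi), float(length)]
        values = [arm_intensity, peri_intensity, cen_intensity, peri_intensity, arm_intensity]
        # collapse degenerate intervals at chromosome ends
        keep = [i for i in range(5) if bounds[i + 1] > bounds[i]]
        bounds_f = [bounds[0]] + [bounds[i + 1] for i in keep]
        values_f = [values[i] for i in keep]
        genome.append(
            ChromosomeModel(
                name=name,
                length_bp=length,
                centromere=(clo, chi),
                pericentromere=peri,
                map_length=total_map * length / total_bp,
                intensity_bounds=tuple(bounds_f),
                intensity_values=tuple(values_f),
            )
        )
    return genome


def default_annotation(genome: list[ChromosomeModel] | None = None) -> RegionAnnotation:
    return RegionAnnotation.from_genome(genome or arabidopsis_like_genome())
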