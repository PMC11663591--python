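"""Crossover frequency from fluorescent seed class counts.

An F1 hemizygous for two linked seed-fluorescence reporters (R and G on one
homolog) segregates four seed classes on selfing: green-only, red-only,
both colors, and non-fluorescent.  Two estimators of the genetic distance
between the reporters:

* :func:`ftl_cm` — the closed-form inverse of the seed-class model,
  ``cM = 100 * (1 - sqrt(1 - 2 (NG + NR) / NT))``; exact for any interval
  width, bounded by 100 cM.
* :func:`esil_rf` — the linear proportion ``100 * (NG + NR) / NT`` used
  for extremely short intervals (< 50 kb), where the quadratic term of the
  seed-class model is negligible.

``ftl_cm >= esil_rf`` holds for all counts, with equality only at zero
recombinants, since ``1 - sqrt(1 - x) >= x / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stats import StatResult, anova_tukey, welch_t

__all__ = ["SeedCounts", "CmEstimate", "ftl_cm", "esil_rf", "compare_cm_groups"]


@dataclass(frozen=True)
class SeedCounts:
    """Fluorescence class tallies for one plant's seed set."""

    n_green_only: int
    n_red_only: int
    n_both: int
    n_none: int

    def __post_init__(self) -> None:
        for name in ("n_green_only", "n_red_only", "n_both", "n_none"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_green_only + self.n_red_only + self.n_both + self.n_none

    @property
    def n_single(self) -> int:
        return self.n_green_only + self.n_red_only


@dataclass(frozen=True)
class CmEstimate:
    value: float
    n_total: int
    method: str  # "ftl" or "esil"


def ftl_cm(counts: SeedCounts, *, literal_formula: bool = False,
           acknowledge_literal: bool = False) -> CmEstimate:
    """Interval genetic distance (cM) from seed classes, square-root form.

    The estimator inverts the hemizygous two-reporter seed-class model at
    its expectation: with recombination fraction r per gamete the expected
    single-color seed share is ``(1 - (1 - r)^2) / 2``, so
    ``r = 1 - sqrt(1 - 2 (NG + NR) / NT)``.

    ``literal_formula=True`` computes ``100 * (1 - (1 - 2 (NG + NR) / NT) / 2)``
    instead — a linearized variant kept only for comparison with legacy
    spreadsheets.  It returns 50 cM at zero recombinants and is therefore
    refused unless ``acknowledge_literal=True`` is passed as well.
    """
    nt = counts.n_total
    if nt <= 0:
        raise ValueError("no seeds counted")
    x = 2.0 * counts.n_single / nt
    if literal_formula:
        if not acknowledge_literal:
            raise ValueError(
                "the literal formula is biased (50 cM at zero recombinants); "
                "pass acknowledge_literal=True to use it anyway"
            )
        return CmEstimate(100.0 * (1.0 - (1.0 - x) / 2.0), nt, "ftl-literal")
    if x > 1.0:
        raise ValueError(
            f"single-color share {x / 2:.3f} exceeds 1/2: distance not estimable"
        )
    return CmEstimate(100.0 * (1.0 - math.sqrt(1.0 - x)), nt, "ftl")


def esil_rf(counts: SeedCounts) -> CmEstimate:
    """Linear recombination frequency for extremely short intervals (cM)."""
    nt = counts.n_total
    if nt <= 0:
        raise ValueError("no seeds counted")
    return CmEstimate(100.0 * counts.n_single / nt, nt, "esil")


def compare_cm_groups(
    groups: dict[str, list[CmEstimate] | list[float]],
    design: str = "two",
) -> dict:
    """Compare per-plant cM estimates between genotypes.

    Each plant contributes one estimate (the experimental unit).  Two-group
    designs use a Welch t test; multi-group designs a one-way ANOVA with
    Tukey HSD pairwise comparisons.
    """
    values = {}
    for name, ests in groups.items():
        vals = np.array(
            [e.value if isinstance(e, CmEstimate) else float(e) for e in ests]
        )
        if len(vals) < 2:
            raise ValueError(f"group '{name}' has fewer than 2 plants")
        values[name] = vals
    if design == "two":
        if len(values) != 2:
            raise ValueError("two-group design requires exactly two groups")
        (na, a), (nb, b) = values.items()
        result: StatResult = welch_t(a, b)
        return {"omnibus": result, "pairwise": [], "groups": list(values)}
    if design == "multi":
        omnibus, pairwise = anova_tukey(values)
        return {"omnibus": omnibus, "pairwise": pairwise, "groups": list(values)}
    raise ValueError("design must be 'two' or 'multi'")
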