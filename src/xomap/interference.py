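"""Cis double-crossover (cis-DCO) distances as an interference readout.

In an F2, two crossovers that occurred in *cis* on one chromosome leave a
parental - heterozygous - parental genotype run (A-H-A or B-H-B).  The
distance between the two flanking genotype switches measures inter-event
spacing; crossover interference stretches it.  Triples with opposite
parental flanks (A-H-B) are excluded: they may arise from events on
different gametes (a trans configuration).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import mann_whitney_u

__all__ = ["extract_cis_dco", "compare_cis_dco"]

_PARENTAL = {"A", "B"}


def extract_cis_dco(segments: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """All parental-het-parental segment triples with their call distances.

    ``segments`` and ``calls`` must come from the same
    :func:`~xomap.calling.call_population` run: call *i* of an
    individual/chromosome sits between its segments *i* and *i + 1*.
    Overlapping triples (e.g. A-H-A-H-A) each contribute a record.

    Returns a DataFrame ``individual, chrom, flank, midpoint_1, midpoint_2,
    distance`` (bp).
    """
    records = []
    calls_by_key = dict(tuple(calls.groupby(["individual", "chrom"], observed=True)))
    for (ind, chrom), segs in segments.groupby(["individual", "chrom"], sort=False):
        genos = segs["genotype"].tolist()
        if len(genos) < 3:
            continue
        sub_calls = calls_by_key.get((ind, chrom))
        if sub_calls is None or len(sub_calls) != len(genos) - 1:
            raise ValueError(
                f"{ind}/{chrom}: calls do not match segment structure "
                "(were segments and calls produced together?)"
            )
        mids = sub_calls["midpoint"].to_numpy()
        for i in range(len(genos) - 2):
            g1, g2, g3 = genos[i:i + 3]
            if g2 == "H" and g1 == g3 and g1 in _PARENTAL:
                records.append(
                    (ind, chrom, g1, int(mids[i]), int(mids[i + 1]),
                     int(mids[i + 1] - mids[i]))
                )
    return pd.DataFrame(
        records,
        columns=["individual", "chrom", "flank", "midpoint_1", "midpoint_2", "distance"],
    )


def compare_cis_dco(records_a: pd.DataFrame, records_b: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome Mann-Whitney U on cis-DCO distances.

    Chromosomes with zero records in either group are skipped with a
    warning.  Returns one row per tested chromosome with medians, sample
    sizes, U and p.
    """
    chroms = sorted(set(records_a["chrom"]) | set(records_b["chrom"]))
    rows = []
    for chrom in chroms:
        a = records_a.loc[records_a["chrom"] == chrom, "distance"].to_numpy(dtype=float)
        b = records_b.loc[records_b["chrom"] == chrom, "distance"].to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"{chrom}: no cis-DCO records in one group, skipped",
                          stacklevel=2)
            continue
        res = mann_whitney_u(a, b)
        rows.append(
            (chrom, len(a), len(b), float(np.median(a)), float(np.median(b)),
             res.statistic, res.p_value)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "n_a", "n_b", "median_a", "median_b", "U", "p_value"],
    )
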