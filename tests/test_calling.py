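"""Tests of the genotype-switch crossover caller against forced examples,
hand-executed smoothing rules and the simulator's ground truth."""

import numpy as np
import pandas as pd
import pytest

from xomap.calling import (
    CallerParams,
    call_crossovers,
    call_population,
    count_per_individual,
    filter_libraries,
    filter_markers,
    segment_individual,
)
from xomap.simulate import (
    MeiosisParams,
    ObservationParams,
    marker_resolvable_truth,
    observe_genotypes,
    simulate_f2_population,
)


def brute_force_transition_scan(calls: np.ndarray, positions: np.ndarray):
    """Independent oracle: scan informative calls for genotype switches."""
    keep = np.isin(calls, ["A", "H", "B"])
    calls, positions = calls[keep], positions[keep]
    out = []
    for i in range(len(calls) - 1):
        if calls[i] != calls[i + 1]:
            mult = 2 if {calls[i], calls[i + 1]} == {"A", "B"} else 1
            out.append((int(positions[i]), int(positions[i + 1]), mult))
    return out


class TestFilters:
    @pytest.mark.parametrize(
        "count,kept", [(94_999, False), (95_000, True), (0, False)]
    )
    def test_library_read_threshold_boundary(self, count, kept):
        retained = filter_libraries({"lib": count}, min_reads=95_000)
        assert ("lib" in retained) is kept

    def test_empty_library_table(self):
        assert filter_libraries({}, 95_000) == []

    @pytest.mark.parametrize(
        "quality,coverage,kept",
        [(100.0, 10.0, False), (150.0, 2.5, False), (150.0, 3.0, True)],
    )
    def test_marker_filters_are_strict(self, quality, coverage, kept):
        markers = pd.DataFrame(
            {"chrom": ["c"], "pos": [100], "quality": [quality], "coverage": [coverage]}
        )
        out = filter_markers(markers, 100.0, 2.5)
        assert (len(out) == 1) is kept

    def test_missing_annotation_column_is_an_error(self):
        markers = pd.DataFrame({"chrom": ["c"], "pos": [1], "quality": [200.0]})
        with pytest.raises(KeyError):
            filter_markers(markers)


class TestSegmentation:
    def _positions(self, n):
        return np.arange(1, n + 1) * 1000

    def test_all_het_single_segment(self):
        calls = np.array(["H"] * 12)
        segs = segment_individual(calls, self._positions(12), CallerParams(w=5))
        assert len(segs) == 1 and segs[0].genotype == "H"

    def test_w1_boundary_between_blocks(self):
        calls = np.array(["A"] * 10 + ["H"] * 10)
        segs = segment_individual(
            calls, self._positions(20), CallerParams(w=1, min_segment_markers=1)
        )
        assert [s.genotype for s in segs] == ["A", "H"]
        assert segs[0].last_pos == 10_000 and segs[1].first_pos == 11_000

    def test_singleton_opposite_call_smoothed_away(self):
        calls = np.array(["A"] * 10)
        calls[4] = "B"
        segs = segment_individual(
            calls, self._positions(10), CallerParams(w=5, min_segment_markers=3)
        )
        assert len(segs) == 1 and segs[0].genotype == "A"

    def test_missing_calls_dropped_not_imputed(self):
        calls = np.array(["A", "-", "A", "-", "H", "H"])
        segs = segment_individual(
            calls, self._positions(6), CallerParams(w=1, min_segment_markers=1)
        )
        assert [s.genotype for s in segs] == ["A", "H"]
        assert segs[0].n_informative == 2 and segs[1].n_informative == 2

    def test_empty_row(self):
        segs = segment_individual(np.array([]), np.array([]), CallerParams())
        assert segs == []

    def test_short_segment_merges_into_larger_flank(self):
        calls = np.array(["A"] * 10 + ["H"] * 2 + ["B"] * 4)
        segs = segment_individual(
            calls, self._positions(16), CallerParams(w=1, min_segment_markers=3)
        )
        assert [s.genotype for s in segs] == ["A", "B"]
        assert segs[0].n_informative == 12  # tie-free: H run joins the bigger A flank

    def test_idempotent_on_long_segments(self, genome, rng):
        """Re-segmenting the smoothed labels reproduces the same segments
        (holds when segments are longer than the window)."""
        from xomap.pipeline import make_marker_scaffold

        markers = make_marker_scaffold(genome, 50_000)
        geno, _ = simulate_f2_population(genome, MeiosisParams(), 5, markers, rng)
        params = CallerParams(w=15, min_segment_markers=5)
        sub = geno[geno["chrom"] == "Chr1"]
        for col in geno.columns[2:]:
            segs = segment_individual(sub[col].to_numpy(), sub["pos"].to_numpy(), params)
            labels = np.concatenate(
                [[s.genotype] * s.n_informative for s in segs]
            )
            pos = sub["pos"].to_numpy()[: len(labels)]
            segs2 = segment_individual(labels, pos, params)
            assert [s.genotype for s in segs] == [s.genotype for s in segs2]
            assert [s.n_informative for s in segs] == [s.n_informative for s in segs2]


class TestCallCrossovers:
    def _segs(self, genos, bounds):
        from xomap.calling import Segment

        segs = []
        for g, (lo, hi) in zip(genos, bounds):
            segs.append(Segment("i1", "c", g, 0, 0, lo, hi, 5))
        return segs

    def test_midpoint_arithmetic(self):
        segs = self._segs(["A", "H"], [(1, 500_000), (600_000, 900_000)])
        calls = call_crossovers(segs)
        assert len(calls) == 1
        c = calls[0]
        assert (c.left_pos, c.right_pos, c.midpoint) == (500_000, 600_000, 550_000)
        assert c.multiplicity == 1

    def test_single_segment_no_calls(self):
        assert call_crossovers(self._segs(["H"], [(1, 100)])) == []

    def test_direct_parental_switch_is_double(self):
        calls = call_crossovers(self._segs(["A", "B"], [(1, 100), (200, 300)]))
        assert calls[0].multiplicity == 2

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            call_crossovers(self._segs(["A", "H"], [(1, 500), (400, 600)]))


class TestCounts:
    def _calls_frame(self, n_events, n_individuals):
        return pd.DataFrame(
            {
                "individual": [f"i{k % n_individuals}" for k in range(n_events)],
                "chrom": "Chr1",
                "left_pos": 1,
                "right_pos": 3,
                "midpoint": 2,
                "multiplicity": 1,
            }
        )

    @pytest.mark.parametrize(
        "n_events,n_individuals,expected",
        [(2_016, 220, 9.16), (1_922, 238, 8.08)],
    )
    def test_population_means_from_event_totals(self, n_events, n_individuals, expected):
        _, mean = count_per_individual(self._calls_frame(n_events, n_individuals),
                                       n_individuals)
        assert round(mean, 2) == expected

    def test_empty_calls_zero_mean(self):
        _, mean = count_per_individual(
            self._calls_frame(0, 1).iloc[0:0], n_individuals=10
        )
        assert mean == 0.0


class TestCallerAgainstSimulator:
    def test_noiseless_calls_match_transition_scan_and_truth(self, genome, rng,
                                                             markers_50kb):
        geno, truth = simulate_f2_population(
            genome, MeiosisParams(), 40, markers_50kb, rng
        )
        params = CallerParams(w=1, min_segment_markers=1)
        segments, calls = call_population(geno, params)
        # oracle equivalence: identical to the brute-force scan
        for chrom, sub in geno.groupby("chrom", sort=False):
            positions = sub["pos"].to_numpy()
            for col in geno.columns[2:]:
                expected = brute_force_transition_scan(sub[col].to_numpy(), positions)
                got = calls[(calls["individual"] == col) & (calls["chrom"] == chrom)]
                assert [
                    (l, r, m) for l, r, m in zip(got["left_pos"], got["right_pos"],
                                                 got["multiplicity"])
                ] == expected
        # count equivalence with marker-resolvable simulator truth
        resolvable = marker_resolvable_truth(truth, markers_50kb, geno)
        called = calls.groupby("individual", observed=False)["multiplicity"].sum()
        true_counts = (
            resolvable.groupby("individual")["xo_class"].count()
            .reindex(called.index, fill_value=0)
        )
        assert (called == true_counts).all()

    def test_noiseless_localization_soundness(self, genome, rng, markers_50kb):
        """Every resolvable truth event lies inside a call interval."""
        geno, truth = simulate_f2_population(
            genome, MeiosisParams(), 25, markers_50kb, rng
        )
        _, calls = call_population(geno, CallerParams(w=1, min_segment_markers=1))
        resolvable = marker_resolvable_truth(truth, markers_50kb, geno)
        grouped = calls.groupby(["individual", "chrom"], observed=True)
        for (ind, chrom), sub in resolvable.groupby(["individual", "chrom"]):
            c = grouped.get_group((ind, chrom))
            for bp in sub["pos_bp"]:
                assert ((c["left_pos"] <= bp) & (bp <= c["right_pos"])).any()

    def test_noisy_defaults_recover_mean_count(self, genome, rng, markers_50kb):
        geno, truth = simulate_f2_population(
            genome, MeiosisParams(), 100, markers_50kb, rng
        )
        observed, _ = observe_genotypes(geno, ObservationParams(), rng)
        _, calls = call_population(observed, CallerParams())
        called_mean = calls["multiplicity"].sum() / 100
        true_mean = len(truth) / 100
        assert abs(called_mean - true_mean) / true_mean < 0.10
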