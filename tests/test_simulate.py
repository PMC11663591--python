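"""Unit and property tests for the meiosis / observation / seed simulators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from xomap.calling import CallerParams, call_population
from xomap.genome import ChromosomeModel
from xomap.pipeline import make_marker_scaffold
from xomap.seeds import ftl_cm
from xomap.simulate import (
    MeiosisParams,
    ObservationParams,
    genetic_to_physical,
    observe_genotypes,
    sample_gamete_crossovers,
    seed_class_probabilities,
    simulate_f2_population,
    simulate_recombinant_breakpoints,
    simulate_seed_counts,
)


def _uniform_chrom(length=10_000_000, map_length=1.0, name="c"):
    return ChromosomeModel(
        name=name, length_bp=length, centromere=(length // 2 - 100, length // 2 + 100),
        map_length=map_length,
    )


class TestGameteSampling:
    def test_zero_map_length_yields_no_events(self, rng):
        pos, cls = sample_gamete_crossovers(0.0, MeiosisParams(), rng)
        assert len(pos) == 0 and len(cls) == 0

    def test_negative_map_length_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_gamete_crossovers(-1.0, MeiosisParams(), rng)

    def test_nu1_counts_are_poisson(self, rng):
        """Without interference the per-gamete count is Poisson(map_length)."""
        params = MeiosisParams(nu=1, p_class2=0.0)
        counts = np.array(
            [len(sample_gamete_crossovers(1.0, params, rng)[0]) for _ in range(10_000)]
        )
        assert abs(counts.mean() - 1.0) < 0.03
        kmax = counts.max()
        obs = np.bincount(counts, minlength=kmax + 1)
        exp = sps.poisson.pmf(np.arange(kmax + 1), 1.0) * len(counts)
        obs_p = np.concatenate([obs[:5], [obs[5:].sum()]])
        exp_p = np.concatenate([exp[:5], [exp[5:].sum()]])
        stat = ((obs_p - exp_p) ** 2 / exp_p).sum()
        assert sps.chi2.sf(stat, len(obs_p) - 1) > 0.01

    def test_interference_underdisperses_counts(self, rng):
        """Higher nu means more regular spacing, hence lower count variance."""
        variances = {}
        for nu in (1, 10):
            params = MeiosisParams(nu=nu, p_class2=0.0)
            counts = [
                len(sample_gamete_crossovers(2.0, params, rng)[0]) for _ in range(10_000)
            ]
            variances[nu] = np.var(counts)
        assert variances[10] < variances[1]

    def test_mean_spacing_nondecreasing_in_nu(self, rng):
        means = []
        for nu in (1, 2, 5, 10):
            params = MeiosisParams(nu=nu, p_class2=0.0)
            spacings = []
            for _ in range(4_000):
                pos, _ = sample_gamete_crossovers(2.0, params, rng)
                if len(pos) > 1:
                    spacings.extend(np.diff(pos))
            means.append(np.mean(spacings))
        assert all(a <= b + 1e-3 for a, b in zip(means, means[1:]))

    def test_obligate_rejects_zero_chiasma_bivalents(self, rng):
        params = MeiosisParams(nu=1, p_class2=0.0, obligate=True)
        counts = [
            len(sample_gamete_crossovers(0.3, params, rng)[0]) for _ in range(2_000)
        ]
        # the bivalent always has >= 1 chiasma; the sampled chromatid may
        # still escape, but the mean must exceed the non-obligate expectation
        assert np.mean(counts) > 0.3


class TestGeneticToPhysical:
    def test_uniform_intensity_is_linear(self):
        chrom = _uniform_chrom()
        assert genetic_to_physical([0.5], chrom)[0] == pytest.approx(5_000_000)

    def test_zero_intensity_region_receives_no_events(self, rng):
        length = 10_000_000
        chrom = ChromosomeModel(
            name="c", length_bp=length, centromere=(4_000_001, 6_000_000),
            map_length=1.0,
            intensity_bounds=(0.0, 4e6, 6e6, float(length)),
            intensity_values=(1.0, 0.0, 1.0),
        )
        g = rng.uniform(0, 1, size=5_000)
        bp = genetic_to_physical(g, chrom)
        assert not np.any((bp > 4e6) & (bp < 6e6))

    def test_relative_intensity_sets_event_shares(self, rng):
        # arm 6 Mb at intensity 2 vs pericentromere 4 Mb at intensity 1
        chrom = ChromosomeModel(
            name="c", length_bp=10_000_000, centromere=(9_999_998, 9_999_999),
            map_length=1.0,
            intensity_bounds=(0.0, 6e6, 1e7),
            intensity_values=(2.0, 1.0),
        )
        bp = genetic_to_physical(rng.uniform(0, 1, size=20_000), chrom)
        share = np.mean(bp < 6e6)
        assert share == pytest.approx(12 / 16, abs=0.02)

    def test_monotone_in_genetic_position(self, rng):
        chrom = _uniform_chrom()
        g = np.sort(rng.uniform(0, 1, size=100))
        bp = genetic_to_physical(g, chrom)
        assert np.all(np.diff(bp) > 0)

    def test_position_outside_map_rejected(self):
        with pytest.raises(ValueError):
            genetic_to_physical([1.5], _uniform_chrom(map_length=1.0))


class TestF2Population:
    def test_zero_map_gives_constant_genotypes(self, rng):
        chrom = _uniform_chrom(map_length=0.0)
        markers = make_marker_scaffold([chrom], 1_000_000)
        geno, truth = simulate_f2_population([chrom], MeiosisParams(), 20, markers, rng)
        assert truth.empty
        for col in geno.columns[2:]:
            assert geno[col].nunique() == 1

    def test_expected_crossovers_two_gametes_per_individual(self, genome, rng):
        markers = make_marker_scaffold(genome, 2_000_000)
        n = 2_000
        _, truth = simulate_f2_population(genome, MeiosisParams(), n, markers, rng)
        expected = 2 * sum(c.map_length for c in genome)
        assert len(truth) / n == pytest.approx(expected, rel=0.03)

    def test_mendelian_segregation_at_markers(self, genome, rng):
        markers = make_marker_scaffold(genome, 5_000_000)
        geno, _ = simulate_f2_population(genome, MeiosisParams(), 3_000, markers, rng)
        calls = geno.iloc[0, 2:].to_numpy()
        het = np.mean(calls == "H")
        assert het == pytest.approx(0.5, abs=0.03)

    def test_truth_events_match_genotype_transitions(self, genome, rng):
        """Count conservation: truth events = noiseless genotype switches
        (A<->B transitions counting 2), up to marker-resolution collisions."""
        from xomap.simulate import marker_resolvable_truth

        markers = make_marker_scaffold(genome, 50_000)
        geno, truth = simulate_f2_population(genome, MeiosisParams(), 30, markers, rng)
        resolvable = marker_resolvable_truth(truth, markers, geno)
        transitions = 0
        for chrom, sub in geno.groupby("chrom", sort=False):
            for col in geno.columns[2:]:
                codes = sub[col].map({"A": 0, "H": 1, "B": 2}).to_numpy()
                transitions += np.abs(np.diff(codes)).sum()
        assert transitions == len(resolvable)


class TestObservation:
    def test_zero_depth_is_all_missing(self, genome, rng):
        markers = make_marker_scaffold(genome, 5_000_000)
        geno, _ = simulate_f2_population(genome, MeiosisParams(), 5, markers, rng)
        obs, depths = observe_genotypes(geno, ObservationParams(mean_depth=0.0), rng)
        assert (obs.iloc[:, 2:] == "-").all().all()

    def test_high_depth_no_error_recovers_truth(self, genome, rng):
        markers = make_marker_scaffold(genome, 1_000_000)
        geno, _ = simulate_f2_population(genome, MeiosisParams(), 10, markers, rng)
        obs, _ = observe_genotypes(
            geno, ObservationParams(mean_depth=60.0, allele_error=0.0), rng
        )
        truth_calls = geno.iloc[:, 2:].to_numpy()
        obs_calls = obs.iloc[:, 2:].to_numpy()
        # hets can still miscall with probability (1/2)^(d-1) ~ 1e-18 at d=60
        assert (truth_calls == obs_calls).mean() > 0.999999

    def test_single_read_never_calls_het(self, rng):
        geno = pd.DataFrame({"chrom": ["c"] * 2000, "pos": range(1, 2001),
                             "ind": ["H"] * 2000})
        obs, depths = observe_genotypes(
            geno, ObservationParams(mean_depth=1.0, allele_error=0.0), rng
        )
        single = depths["ind"].to_numpy() == 1
        assert single.any()
        assert np.all(np.isin(obs["ind"].to_numpy()[single], ["A", "B"]))


class TestSeedSimulation:
    def test_no_recombination_class_shares(self, rng):
        counts = simulate_seed_counts(0.0, 200_000, rng)
        assert counts.n_green_only == 0 and counts.n_red_only == 0
        assert counts.n_none / counts.n_total == pytest.approx(0.25, abs=0.01)
        assert counts.n_both / counts.n_total == pytest.approx(0.75, abs=0.01)

    def test_single_color_share_closed_form(self, rng):
        counts = simulate_seed_counts(0.2, 200_000, rng)
        share = counts.n_single / counts.n_total
        assert share == pytest.approx(0.18, abs=0.005)

    def test_estimator_round_trip_at_expectation(self):
        """ftl_cm applied to the exact expected class counts returns 100 r."""
        import sympy

        r = sympy.Rational(1, 5)
        single = (1 - (1 - r) ** 2) / 4
        # symbolic identity: 100 * (1 - sqrt(1 - 4*single)) == 100 r
        assert sympy.simplify(100 * (1 - sympy.sqrt(1 - 4 * single)) - 100 * r) == 0
        probs = seed_class_probabilities(0.2)
        from xomap.seeds import SeedCounts

        nt = 10_000
        counts = SeedCounts(*(round(probs[k] * nt) for k in
                              ("n_green_only", "n_red_only", "n_both", "n_none")))
        assert ftl_cm(counts).value == pytest.approx(20.0, abs=1e-9)

    @given(st.floats(min_value=0.0, max_value=0.5))
    @settings(max_examples=50, deadline=None)
    def test_class_probabilities_sum_to_one(self, r):
        probs = seed_class_probabilities(r)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(p >= 0 for p in probs.values())

    def test_invalid_r_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_seed_counts(0.6, 100, rng)


class TestRecombinantBreakpoints:
    SNPS = np.arange(0, 26_000, 120)
    HOTSPOTS = [("Aro", 2_000, 6_000), ("Coco", 10_000, 16_000), ("Nala", 20_000, 24_000)]

    def test_single_hotspot_contains_all_breakpoints(self, rng):
        vec, pos = simulate_recombinant_breakpoints(
            [self.HOTSPOTS[0]], [1.0], 0.0, self.SNPS, 50, rng
        )
        assert np.all((pos >= 2_000) & (pos <= 6_000))

    def test_vector_encodes_one_transition(self, rng):
        vec, pos = simulate_recombinant_breakpoints(
            self.HOTSPOTS, [0.3, 0.5, 0.2], 0.0, self.SNPS, 20, rng
        )
        for _, row in vec.iterrows():
            calls = row.iloc[1:].to_numpy()
            assert np.sum(calls[:-1] != calls[1:]) == 1

    def test_empty_population(self, rng):
        vec, pos = simulate_recombinant_breakpoints(
            self.HOTSPOTS, [0.3, 0.5, 0.2], 0.0, self.SNPS, 0, rng
        )
        assert len(vec) == 0 and len(pos) == 0

    def test_bad_weights_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_recombinant_breakpoints(
                self.HOTSPOTS, [0.5, 0.5, 0.2], 0.0, self.SNPS, 10, rng
            )


class TestStationarity:
    def test_uniform_intensity_gives_uniform_positions(self, rng):
        """With nu=1 and flat intensity, event bp positions are uniform."""
        chrom = _uniform_chrom(map_length=1.0)
        params = MeiosisParams(nu=1, p_class2=0.0)
        positions = []
        while len(positions) < 10_000:
            g, _ = sample_gamete_crossovers(chrom.map_length, params, rng)
            positions.extend(genetic_to_physical(g, chrom))
        counts, _ = np.histogram(positions, bins=20, range=(0, chrom.length_bp))
        assert sps.chisquare(counts).pvalue > 0.01
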