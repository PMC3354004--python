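"""Dip statistic/test, histograms, mode selection and foraging thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pelagitrack.modality_analysis import (
    dip_statistic, dip_test, speed_histogram, find_modes,
    modal_transiting_speed, classify_foraging, analyze_speeds)

from _dip_oracle import dip_oracle


class TestDipStatistic:
    def test_equally_spaced_attains_lower_bound(self):
        # the most uniform-like sample: dip = 1/(2n)
        assert dip_statistic(np.arange(1, 9)) == pytest.approx(1 / 16, abs=1e-12)
        assert dip_statistic(np.arange(500.0)) == pytest.approx(1 / 1000,
                                                                abs=1e-12)

    def test_two_equal_atoms_attain_upper_bound(self):
        assert dip_statistic([0.0] * 50 + [1.0] * 50) == pytest.approx(0.25)

    def test_unbalanced_atoms(self):
        # closed form: min(p, q)/2 of the two atom masses
        assert dip_statistic([0.0] * 3 + [1.0] * 4) == pytest.approx(3 / 14)

    def test_affine_invariance(self):
        x = np.random.default_rng(0).normal(size=200)
        assert dip_statistic(x) == pytest.approx(dip_statistic(5.0 * x + 3.0),
                                                 abs=1e-12)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            dip_statistic([1.0, 2.0, 3.0])

    def test_well_separated_clusters_near_upper_bound(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1e-4, 50), rng.normal(1, 1e-4, 50)])
        assert dip_statistic(x) > 0.24
        assert dip_statistic(x) > dip_statistic(rng.random(100))

    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=4,
                    max_size=200))
    def test_bounds(self, xs):
        x = np.asarray(xs)
        d = dip_statistic(x)
        assert 0.0 <= d <= 0.25 + 1e-12
        if np.unique(x).size > 1:
            assert d >= 1 / (2 * x.size) - 1e-12


class TestDipOracleEquivalence:
    """The production GCM/LCM iteration against the exhaustive LP oracle."""

    CASES = [
        np.arange(1.0, 9.0),
        np.array([0.0, 0.4, 0.6, 1.0]),
        np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0]),
        np.array([2.0, 1.0, 0.0, 0.0]),
        np.array([1.0, 3.0, 0.0, 1.0]),
        np.array([-2.7, -3.2, -3.0, 3.0, 3.0, 2.6, 3.0]),
    ]

    @pytest.mark.parametrize("case", range(len(CASES)))
    def test_fixed_cases(self, case):
        x = self.CASES[case]
        assert dip_statistic(x) == pytest.approx(dip_oracle(x), abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        if seed % 3 == 0:
            x = rng.integers(0, 4, n).astype(float)   # tie-heavy
            if np.unique(x).size == 1:
                x[-1] += 1.0
        elif seed % 3 == 1:
            x = rng.normal(size=n)
        else:
            x = np.concatenate([rng.normal(-3, 0.3, n // 2),
                                rng.normal(3, 0.3, n - n // 2)])
        assert dip_statistic(x) == pytest.approx(dip_oracle(x), abs=1e-6)


class TestDipTest:
    def test_deterministic_under_seed(self):
        x = np.random.default_rng(2).normal(size=100)
        r1 = dip_test(x, n_boot=200, seed=7)
        r2 = dip_test(x, n_boot=200, seed=7)
        assert r1.p_value == r2.p_value

    def test_uniform_sample_not_rejected(self):
        x = np.random.default_rng(3).random(500)
        assert dip_test(x, n_boot=500, seed=0).p_value > 0.05

    def test_separated_mixture_strongly_rejected(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(12.5, 2, 250), rng.normal(37.5, 2, 250)])
        assert dip_test(x, n_boot=500, seed=0).p_value < 0.01

    def test_peaked_unimodal_sample_conservative(self):
        """Uniform-null calibration is conservative for peaked densities:
        normal samples reject at well below the nominal rate."""
        rej = sum(dip_test(np.random.default_rng(100 + i).normal(size=500),
                           n_boot=200, seed=i).p_value < 0.05
                  for i in range(40))
        assert rej / 40 <= 0.08    # at/below nominal + binomial slack

    def test_n_boot_floor(self):
        with pytest.raises(ValueError, match="n_boot"):
            dip_test(np.arange(10.0), n_boot=50)


class TestSpeedHistogram:
    def test_basic_counts(self):
        h = speed_histogram([1.0, 6.0, 6.0], bin_width=5.0)
        assert list(h.counts) == [1, 2]
        assert list(h.bin_centers) == [2.5, 7.5]

    def test_empty_series(self):
        assert speed_histogram([], bin_width=5.0).counts.size == 0

    def test_half_open_bins(self):
        h = speed_histogram([5.0], bin_width=5.0)
        assert list(h.counts) == [0, 1]

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            speed_histogram([-1.0])

    @given(st.lists(st.floats(0, 500, allow_nan=False), min_size=1,
                    max_size=300))
    def test_mass_conservation(self, xs):
        assert speed_histogram(xs, 5.0).counts.sum() == len(xs)


class TestFindModes:
    def _hist(self, counts, width=5.0):
        from pelagitrack.modality_analysis import SpeedHistogram
        counts = np.asarray(counts)
        edges = np.arange(counts.size + 1) * width
        return SpeedHistogram(edges, counts, width)

    def test_single_interior_peak(self):
        assert list(find_modes(self._hist([5, 10, 5]))) == [7.5]

    def test_printed_mode_locations(self):
        # peaks in the 10-15 and 35-40 bins, trough at 15-20:
        counts = [2, 4, 9, 1, 2, 4, 6, 10, 4, 2]
        assert list(find_modes(self._hist(counts))) == [12.5, 37.5]

    def test_monotone_counts_single_terminal_mode(self):
        assert list(find_modes(self._hist([1, 2, 3, 5]))) == [17.5]

    def test_low_prominence_bump_suppressed(self):
        counts = [2, 40, 38, 39, 5, 2]     # tiny bump at index 3
        assert list(find_modes(self._hist(counts), min_prominence=0.05)) == [7.5]


class TestModalTransitingSpeed:
    def _hist(self, counts, width=5.0):
        from pelagitrack.modality_analysis import SpeedHistogram
        counts = np.asarray(counts)
        return SpeedHistogram(np.arange(counts.size + 1) * width, counts, width)

    def test_mode_with_most_mass_wins(self):
        # slow band holds 29, fast band 42 (plus tails): pick 37.5
        counts = [5, 9, 15, 0, 5, 10, 12, 20, 8, 5]
        h = self._hist(counts)
        modal, masses = modal_transiting_speed(h, np.array([12.5, 37.5]))
        assert modal == 37.5
        assert masses.sum() == pytest.approx(1.0)
        assert masses[1] > masses[0]

    def test_single_mode_mass_one(self):
        h = self._hist([1, 5, 9, 5, 2])
        modal, masses = modal_transiting_speed(h, np.array([21.0]))
        assert modal == 21.0 and list(masses) == [1.0]

    def test_tie_breaks_to_faster_mode(self):
        counts = [10, 2, 10]
        modal, masses = modal_transiting_speed(self._hist(counts),
                                               np.array([2.5, 12.5]))
        assert modal == 12.5

    def test_no_modes_rejected(self):
        with pytest.raises(ValueError):
            modal_transiting_speed(self._hist([1, 2]), np.array([]))


class TestClassifyForaging:
    @pytest.mark.parametrize("modal,expected_threshold", [
        (37.5, 15.0),      # the published NA threshold
        (21.0, 8.4),       # the published EP threshold
    ])
    def test_threshold_arithmetic(self, modal, expected_threshold):
        mask, rel = classify_foraging(np.array([expected_threshold]), modal)
        assert mask[0]                     # exactly at threshold -> foraging
        assert rel[0] == pytest.approx(40.0)
        mask2, _ = classify_foraging(np.array([expected_threshold + 1e-9]),
                                     modal)
        assert not mask2[0]

    def test_relative_speed_percent(self):
        _, rel = classify_foraging(np.array([37.5, 75.0]), 37.5)
        np.testing.assert_allclose(rel, [100.0, 200.0])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_foraging([1.0], 0.0)
        with pytest.raises(ValueError):
            classify_foraging([1.0], 10.0, fraction=1.5)


class TestAnalyzeSpeeds:
    def test_na_like_summary(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(12.5, 1.5, 300),
                            rng.normal(37.5, 3.0, 450)])
        x = x[x > 0]
        res = analyze_speeds(x, bin_width=5.0, n_boot=300, seed=1)
        assert res.p_value < 0.01
        assert res.modal_transiting_speed == 37.5
        assert res.foraging_threshold == pytest.approx(15.0)
        assert 12.5 in list(res.modes)
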