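"""Gaussian decomposition, FRET arithmetic and population bookkeeping."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretscape import (
    AcquisitionConfig,
    LifetimeDistribution,
    LifetimeGrid,
    average_fret,
    build_landscape,
    count_peaks,
    fit_gaussians,
    fret_efficiency,
    mem_fit,
    simulate_decay,
)

from conftest import TAU_D, THREE_STATE


def log_gaussian_dist(centers_areas, width=0.10, noise=0.0, seed=0):
    """Construct a distribution as a sum of log10-lifetime Gaussians."""
    grid = LifetimeGrid()
    x = np.log10(grid.taus)
    a = np.zeros_like(x)
    for center, area in centers_areas:
        mu = np.log10(center)
        a += (area / (width * np.sqrt(2 * np.pi))) * np.exp(
            -0.5 * ((x - mu) / width) ** 2
        )
    if noise:
        rng = np.random.default_rng(seed)
        a = np.clip(a + rng.normal(0.0, noise * a.max(), a.size), 0.0, None)
    return LifetimeDistribution(grid, a)


class TestFretEfficiency:
    @pytest.mark.parametrize(
        "tau_da, expected",
        [(0.32, 0.9347), (1.1, 0.7755), (4.4, 0.1020), (0.40, 0.9184)],
    )
    def test_values_against_hand_arithmetic(self, tau_da, expected):
        assert fret_efficiency(tau_da, TAU_D) == pytest.approx(expected,
                                                               abs=5e-4)

    def test_identity_gives_zero(self):
        assert fret_efficiency(4.9, 4.9) == 0.0

    def test_negative_raw_is_clamped_to_zero(self):
        raw = fret_efficiency(5.2, 4.9)
        assert raw == pytest.approx(-0.0612, abs=1e-3)
        assert fret_efficiency(5.2, 4.9, clamp=True) == 0.0

    def test_nonpositive_lifetimes_error(self):
        with pytest.raises(ValueError):
            fret_efficiency(0.0, 4.9)
        with pytest.raises(ValueError):
            fret_efficiency(1.0, -4.9)

    @settings(max_examples=50, deadline=None)
    @given(
        tau1=st.floats(0.01, 50.0),
        dtau=st.floats(0.01, 10.0),
        tau_d=st.floats(0.1, 50.0),
        scale=st.floats(0.1, 10.0),
    )
    def test_monotone_decreasing_and_scale_invariant(self, tau1, dtau, tau_d,
                                                     scale):
        e1 = fret_efficiency(tau1, tau_d)
        e2 = fret_efficiency(tau1 + dtau, tau_d)
        assert e2 < e1
        assert fret_efficiency(scale * tau1, scale * tau_d) == pytest.approx(
            e1, abs=1e-9
        )


class TestAverageFret:
    def test_single_component_reduces_to_fret_efficiency(self):
        assert average_fret([(1.7, 1.0)], TAU_D) == pytest.approx(
            fret_efficiency(1.7, TAU_D)
        )

    def test_three_state_hand_arithmetic(self):
        # sum(A_i tau_i) = 0.39*0.40 + 0.33*1.7 + 0.28*5.2 = 2.173
        assert average_fret(THREE_STATE, TAU_D) == pytest.approx(
            1.0 - 2.173 / 4.9, abs=1e-12
        )

    def test_limit_all_amplitude_at_zero_lifetime(self):
        assert average_fret([(1e-9, 1.0)], TAU_D) == pytest.approx(1.0,
                                                                   abs=1e-6)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            average_fret([], TAU_D)


class TestFitGaussians:
    def test_self_fit_single_component(self):
        dist = log_gaussian_dist([(1.7, 100.0)], width=0.12)
        peaks = fit_gaussians(dist)
        assert len(peaks) == 1
        assert peaks[0].center == pytest.approx(1.7, rel=0.01)
        assert peaks[0].area == pytest.approx(100.0, rel=0.01)
        assert peaks[0].fraction == pytest.approx(1.0, abs=1e-9)

    def test_three_state_modes_select_three_components(self):
        dist = log_gaussian_dist(
            [(0.40, 39.0), (1.7, 33.0), (5.2, 28.0)], noise=0.01
        )
        peaks = fit_gaussians(dist)
        assert len(peaks) == 3
        for peak, (tau, amp) in zip(peaks, THREE_STATE):
            assert peak.center == pytest.approx(tau, rel=0.05)
            assert peak.fraction == pytest.approx(amp, abs=0.02)

    def test_close_modes_merge_to_one_component(self):
        """Modes closer than one half-width are reported as one Gaussian."""
        dist = log_gaussian_dist([(1.5, 50.0), (1.75, 50.0)], width=0.15,
                                 noise=0.01)
        peaks = fit_gaussians(dist)
        assert len(peaks) == 1

    def test_fractions_sum_to_one(self):
        dist = log_gaussian_dist([(0.5, 10.0), (5.0, 30.0)], noise=0.005)
        peaks = fit_gaussians(dist)
        assert sum(p.fraction for p in peaks) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_inputs(self):
        dist = log_gaussian_dist([(1.0, 10.0)])
        with pytest.raises(ValueError):
            fit_gaussians(dist, max_components=0)
        zero = LifetimeDistribution(LifetimeGrid(), np.zeros(120))
        with pytest.raises(ValueError):
            fit_gaussians(zero)


class TestCountPeaks:
    def test_counts_for_constructed_distributions(self):
        assert count_peaks(log_gaussian_dist([(4.9, 50.0)])) == 1
        assert count_peaks(
            log_gaussian_dist([(0.4, 39.0), (1.7, 33.0), (5.2, 28.0)])
        ) == 3

    def test_all_zero_distribution_counts_zero(self):
        zero = LifetimeDistribution(LifetimeGrid(), np.zeros(120))
        assert count_peaks(zero) == 0

    def test_threshold_suppresses_minor_bumps(self):
        dist = log_gaussian_dist([(0.4, 100.0), (5.0, 0.5)])
        assert count_peaks(dist, threshold_fraction=0.02) == 1


class TestLandscape:
    def test_end_to_end_three_state_landscape(self):
        """Simulate -> invert -> decompose reproduces the input landscape."""
        tr = simulate_decay(THREE_STATE, AcquisitionConfig(seed=0))
        dist = mem_fit(tr)
        ls = build_landscape(dist, TAU_D)
        assert len(ls.peaks) == 3
        for peak, (tau, amp) in zip(ls.peaks, THREE_STATE):
            assert abs(np.log10(peak.center / tau)) < 0.12
            assert peak.fraction == pytest.approx(amp, abs=0.08)
        # <E> from Gaussian peaks agrees with <E> from raw grid amplitudes
        assert ls.mean_e == pytest.approx(average_fret(dist, TAU_D), abs=0.02)
        # clamped negative-FRET peak keeps its raw value
        slowest = ls.peaks[-1]
        assert slowest.e_peak >= 0.0
        assert slowest.e_raw <= slowest.e_peak

    def test_population_normalization_invariant(self):
        dist = log_gaussian_dist([(0.4, 39.0), (1.7, 33.0), (5.2, 28.0)],
                                 noise=0.01)
        ls = build_landscape(dist, TAU_D)
        assert ls.populations().sum() == pytest.approx(1.0, abs=1e-6)

    def test_weights_choice_recorded(self):
        dist = log_gaussian_dist([(1.0, 10.0)])
        ls = build_landscape(dist, TAU_D, weights="grid")
        assert ls.meta["weights"] == "grid"
        with pytest.raises(ValueError):
            build_landscape(dist, TAU_D, weights="bogus")
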