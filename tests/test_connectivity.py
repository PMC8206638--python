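"""wPLI estimator, surrogates, and the SD-gate: analytic limits and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megnet.connectivity import (
    SpectralParams,
    SurrogateNull,
    WpliSpectrum,
    build_surrogate_null,
    cross_spectrum,
    pairwise_wpli,
    phase_randomize,
    select_connection,
    wpli,
    wpli_spectrum,
)
from megnet.synthetic import CouplingSpec, generate_coupled_sources

FS = 200.0


def _sine(f, duration=60.0, fs=FS, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * f * t + phase)


class TestCrossSpectrum:
    def test_identical_signals_zero_phase(self, params):
        x = _sine(10.0)
        s, freqs = cross_spectrum(x, x, FS, params)
        k = int(np.argmin(np.abs(freqs - 10.0)))
        assert np.allclose(np.angle(s[:, k]), 0.0, atol=1e-8)

    def test_quarter_cycle_delay_gives_half_pi_phase(self, params):
        x = _sine(10.0)
        y = _sine(10.0, phase=-np.pi / 2)  # quarter cycle later
        s, freqs = cross_spectrum(x, y, FS, params)
        k = int(np.argmin(np.abs(freqs - 10.0)))
        assert np.allclose(np.abs(np.angle(s[:, k])), np.pi / 2, atol=1e-6)

    def test_segment_bookkeeping(self, params):
        rng = np.random.default_rng(0)
        # 16 segments of 2 s at 50% overlap need (16+1) s of data
        x = rng.standard_normal(int(17 * FS))
        s, freqs = cross_spectrum(x, rng.standard_normal(x.size), FS, params)
        assert s.shape == (16, freqs.size)
        assert freqs[0] >= params.f_min and freqs[-1] <= params.f_max

    def test_too_short_raises_with_minimum(self, params):
        x = np.zeros(int(3 * FS))
        with pytest.raises(ValueError, match="at least"):
            cross_spectrum(x, x, FS, params)

    def test_mismatched_lengths_rejected(self, params):
        with pytest.raises(ValueError):
            cross_spectrum(np.zeros(4000), np.zeros(4001), FS, params)


class TestWpli:
    def test_constant_lag_gives_one(self, coupled_pair, params):
        w = wpli_spectrum(coupled_pair, "roi00", "roi01", params)
        k = int(np.argmin(np.abs(w.freqs - 10.0)))
        assert w.wpli[k] == pytest.approx(1.0, abs=1e-9)
        assert not w.degenerate[k]

    def test_zero_lag_flagged_zero(self, zero_lag_pair, params):
        w = wpli_spectrum(zero_lag_pair, "roi00", "roi01", params)
        k = int(np.argmin(np.abs(w.freqs - 10.0)))
        assert w.wpli[k] == 0.0
        assert w.degenerate[k]

    def test_perfect_cancellation(self):
        # segments with imaginary parts {+a, -a} cancel exactly
        s = np.array([[1 + 2j], [1 - 2j]])
        w, flag = wpli(s)
        assert w[0] == 0.0
        assert not flag[0]

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError, match="2 segments"):
            wpli(np.ones((1, 4), dtype=complex))

    def test_independent_noise_wpli_small(self, params):
        vals = []
        for seed in range(10):
            spec = CouplingSpec(pairs=(), noise_sd=1.0)
            ss = generate_coupled_sources(spec, 2, 60, FS, seed=seed)
            w = wpli_spectrum(ss, "roi00", "roi01", params)
            vals.append(w.wpli.mean())
        assert np.mean(vals) < 0.2

    @given(cx=st.floats(0.01, 100), cy=st.floats(0.01, 100))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_amplitude_invariance(self, cx, cy):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000)
        p = SpectralParams()
        w1, _ = wpli(cross_spectrum(x, y, FS, p)[0])
        w2, _ = wpli(cross_spectrum(cx * x, cy * y, FS, p)[0])
        assert np.allclose(w1, w2, atol=1e-12)

    def test_symmetry(self, noise_pair, params):
        a = wpli_spectrum(noise_pair, "roi00", "roi01", params)
        b = wpli_spectrum(noise_pair, "roi01", "roi00", params)
        assert np.array_equal(a.wpli, b.wpli)

    def test_pairwise_matches_single_pair(self, coupled_pair, params):
        table = pairwise_wpli(coupled_pair, params)
        single = wpli_spectrum(coupled_pair, "roi00", "roi01", params)
        assert np.allclose(table[("roi00", "roi01")].wpli, single.wpli)


class TestPhaseRandomize:
    def test_amplitude_spectrum_preserved(self):
        x = np.random.default_rng(0).standard_normal(5001)  # odd length too
        s = phase_randomize(x, seed=4)
        ax, asur = np.abs(np.fft.rfft(x)), np.abs(np.fft.rfft(s))
        assert np.all(np.abs(asur - ax) <= 1e-9 * np.maximum(ax, 1e-12))

    def test_constant_series_unchanged(self):
        x = np.full(1000, 3.7)
        assert np.allclose(phase_randomize(x, seed=1), x, atol=1e-12)

    def test_deterministic(self):
        x = np.random.default_rng(2).standard_normal(1000)
        assert np.array_equal(phase_randomize(x, 9), phase_randomize(x, 9))

    def test_output_is_real_and_decorrelated(self):
        x = _sine(10.0, duration=10)
        s = phase_randomize(x, seed=5)
        assert np.isrealobj(s)
        assert not np.allclose(s, x)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            phase_randomize(np.array([1.0, np.nan, 2.0]), seed=0)


class TestSurrogateNull:
    def test_reported_draw_count_and_positive_sigma(self, noise_pair, params):
        null = build_surrogate_null(noise_pair, params, n_pairs=150, seed=0)
        assert null.n_pairs == 150
        assert np.all(null.sigma > 0)
        assert np.all(null.mu > 0)  # wPLI >= 0 and biased up under H0

    def test_minimum_draws_enforced(self, noise_pair, params):
        with pytest.raises(ValueError, match="100"):
            build_surrogate_null(noise_pair, params, n_pairs=50, seed=0)

    def test_disjoint_seeds_agree_within_sampling_error(self, noise_pair, params):
        a = build_surrogate_null(noise_pair, params, n_pairs=300, seed=1)
        b = build_surrogate_null(noise_pair, params, n_pairs=300, seed=2)
        # the difference of two independent means has SE sqrt(2)*sigma/sqrt(n);
        # 4.5 SE keeps the family-wise false-alarm rate over all ~159
        # frequencies around 1e-3
        tol = 4.5 * np.sqrt(2.0) * np.maximum(a.sigma, b.sigma) / np.sqrt(300)
        assert np.all(np.abs(a.mu - b.mu) <= tol + 1e-12)

    def test_deterministic(self, noise_pair, params):
        a = build_surrogate_null(noise_pair, params, n_pairs=120, seed=3)
        b = build_surrogate_null(noise_pair, params, n_pairs=120, seed=3)
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.sigma, b.sigma)

    def test_degenerate_null_rejected(self, params):
        # strictly periodic noiseless data -> zero surrogate variance at
        # almost all frequencies -> the null must refuse to build
        spec = CouplingSpec(pairs=((0, 1, 10.0, np.pi / 4, 1.0),), noise_sd=0.0)
        ss = generate_coupled_sources(spec, 2, 60, FS, seed=1)
        with pytest.raises(ValueError, match="degenerate"):
            build_surrogate_null(ss, params, n_pairs=100, seed=0)


class TestSelectConnection:
    def _null(self, freqs, mu=0.2, sigma=0.05):
        return SurrogateNull(
            subject_id="s",
            freqs=freqs,
            mu=np.full(freqs.size, mu),
            sigma=np.full(freqs.size, sigma),
            n_pairs=100,
        )

    def test_wpli_equal_to_mu_is_unconnected(self):
        freqs = np.arange(1, 81, 0.5)
        spec = WpliSpectrum(("a", "b"), freqs, np.full(freqs.size, 0.2))
        cand = select_connection(spec, self._null(freqs))
        assert cand.z_max == 0.0 and not cand.connected

    def test_tie_breaks_to_lowest_frequency(self):
        freqs = np.arange(1, 81, 0.5)
        w = np.full(freqs.size, 0.2)
        w[freqs == 6.0] = 0.9
        w[freqs == 20.0] = 0.9
        cand = select_connection(WpliSpectrum(("a", "b"), freqs, w), self._null(freqs))
        assert cand.f_star == 6.0
        assert cand.connected and cand.z_max == pytest.approx((0.9 - 0.2) / 0.05)

    def test_grid_mismatch_rejected(self):
        f1 = np.arange(1, 81, 0.5)
        f2 = np.arange(1, 80, 0.5)
        spec = WpliSpectrum(("a", "b"), f1, np.full(f1.size, 0.2))
        with pytest.raises(ValueError, match="grid"):
            select_connection(spec, self._null(f2))

    def test_planted_coupling_detected_at_its_frequency(self, params):
        # several uncoupled channels keep the pooled null honest: with only
        # the coupled pair in the pool, every surrogate draw would retain the
        # (phase-shifted but still constant-lag) shared oscillation and the
        # null would absorb the coupling itself
        spec = CouplingSpec(pairs=((0, 1, 10.0, np.pi / 3, 1.0),), noise_sd=0.3)
        ss = generate_coupled_sources(spec, 10, 60, FS, seed=4)
        null = build_surrogate_null(ss, params, n_pairs=200, seed=5)
        cand = select_connection(wpli_spectrum(ss, "roi00", "roi01", params), null)
        assert cand.connected
        assert abs(cand.f_star - 10.0) <= 0.5 + 1e-9


def test_spectral_params_validation():
    with pytest.raises(ValueError):
        SpectralParams(f_min=0.0)
    with pytest.raises(ValueError):
        SpectralParams(overlap_fraction=1.0)
    with pytest.raises(ValueError, match="grid_step"):
        SpectralParams(segment_length_s=1.0, grid_step=0.5)
    with pytest.raises(ValueError, match="Nyquist"):
        SpectralParams(f_max=150.0).freq_grid(200.0)
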