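"""Lomb-Scargle spatial periodicity analysis."""

import numpy as np
import pytest

from msm.periodogram import (
    Profile1D,
    control_preset,
    default_frequency_grid,
    dominant_period,
    latb_preset,
    lomb_scargle,
    synth_profile,
)


def brute_force_ls_power(x, y, freqs):
    """Independent oracle: per-frequency least-squares sinusoid fit.

    For each angular frequency, fit ``a cos(wx) + b sin(wx)`` to the
    mean-centred data by ordinary least squares and report half the
    explained sum of squares — the classical Lomb normalisation.
    """
    y = y - y.mean()
    out = np.empty(len(freqs))
    for i, w in enumerate(freqs):
        X = np.column_stack([np.cos(w * x), np.sin(w * x)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fit = X @ beta
        out[i] = 0.5 * np.sum(fit * y)  # = 0.5 * ||fit||^2 at the optimum
    return out


class TestLombScargle:
    def test_matches_least_squares_oracle_on_sinusoid(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 200, 180))  # uneven sampling
        y = 2.0 + 1.3 * np.sin(0.21 * x + 0.7) + rng.normal(0, 0.1, len(x))
        prof = Profile1D(x, y)
        freqs = np.linspace(0.02, 1.0, 300)
        spec = lomb_scargle(prof, freqs)
        oracle = brute_force_ls_power(x, y, freqs)
        # same peak location and near-identical power at the peak
        assert np.argmax(spec.power) == np.argmax(oracle)
        np.testing.assert_allclose(spec.power, oracle, rtol=0.05, atol=0.3)

    def test_recovers_known_frequency_within_one_grid_step(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            f0 = 0.21
            x = np.arange(0.0, 300.0)
            y = np.sin(f0 * x) + rng.normal(0, 0.2, len(x))  # SNR ~ 5
            prof = Profile1D(x, y)
            freqs = np.geomspace(0.03, 1.5, 600)
            spec = lomb_scargle(prof, freqs)
            fpk = spec.peak[0]
            i = np.searchsorted(freqs, f0)
            grid_step = freqs[i + 1] - freqs[i - 1]
            assert abs(fpk - f0) <= grid_step

    def test_agrees_with_fft_periodogram_on_even_sampling(self):
        """On evenly spaced data the Lomb power matches the classical
        FFT periodogram (up to normalisation) for 20 random signals."""
        rng = np.random.default_rng(3)
        n = 256
        x = np.arange(n, dtype=float)
        fft_freqs = 2 * np.pi * np.arange(1, n // 2) / n
        for _ in range(20):
            y = rng.normal(size=n)
            prof = Profile1D(x, y)
            spec = lomb_scargle(prof, fft_freqs)
            fft_power = np.abs(np.fft.rfft(y - y.mean())[1: n // 2]) ** 2 / n
            np.testing.assert_allclose(spec.power, fft_power, rtol=1e-6, atol=1e-8)

    def test_offset_invariance(self):
        rng = np.random.default_rng(5)
        x = np.arange(100.0)
        y = np.sin(0.3 * x) + rng.normal(0, 0.1, 100)
        freqs = np.linspace(0.05, 1.0, 100)
        a = lomb_scargle(Profile1D(x, y), freqs).power
        b = lomb_scargle(Profile1D(x, y + 57.0), freqs).power
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_constant_profile_gives_zero_power(self):
        prof = Profile1D(np.arange(50.0), np.full(50, 3.3))
        spec = lomb_scargle(prof, np.linspace(0.05, 1.0, 50))
        assert np.all(spec.power < 1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            lomb_scargle(Profile1D([0.0, 1, 2], [1.0, 2, 1]))


class TestDominantPeriod:
    def test_period_frequency_relation(self):
        assert dominant_period(0.07) == pytest.approx(2 * np.pi / 0.07)
        assert dominant_period(2 * np.pi) == pytest.approx(1.0)

    def test_control_like_frequency_gives_period_about_90(self):
        assert round(dominant_period(0.07)) == 90

    def test_dc_band_excluded_from_dominance(self):
        """A slow full-span mode (offset-like) must not win over a genuine
        periodic mode, even with larger raw power."""
        x = np.arange(0.0, 900.0)
        y = np.sin(2 * np.pi * x / 90.0) + 3.0 * np.sin(2 * np.pi * x / 2000.0)
        spec = lomb_scargle(Profile1D(x, y))
        f, _, period = spec.peak
        assert period == pytest.approx(90.0, rel=0.05)

    def test_no_peak_on_flat_spectrum(self):
        prof = Profile1D(np.arange(50.0), np.full(50, 1.0))
        spec = lomb_scargle(prof, np.linspace(0.05, 1.0, 50))
        assert spec.peak is None
        assert dominant_period(spec) is None


class TestSynthProfile:
    def test_noiseless_profile_peaks_at_construction_frequency(self):
        prof = synth_profile(
            period=90.0, n_bumps=10, amplitude_noise=0.0,
            position_jitter=0.0, noise_floor=0.0, seed=0,
        )
        spec = lomb_scargle(prof)
        f, _, period = spec.peak
        assert period == pytest.approx(90.0, rel=0.05)

    def test_control_preset_has_a_sharp_peak(self):
        spec = lomb_scargle(control_preset(seed=1))
        _, power, period = spec.peak
        assert period == pytest.approx(90.0, rel=0.1)
        assert power > 2 * np.median(spec.power)

    def test_latb_preset_loses_over_half_the_peak_power(self):
        """Filopodia-loss-like profiles lose more than half of the
        ~0.07 rad/length mode amplitude relative to matched-seed controls."""
        losses = []
        for seed in range(6):
            ctrl = lomb_scargle(control_preset(seed=seed))
            latb = lomb_scargle(latb_preset(seed=seed))
            f0 = ctrl.peak[0]
            # power of the LatB spectrum at the control peak mode
            i = np.argmin(np.abs(latb.frequencies - f0))
            losses.append(latb.power[i] / ctrl.peak[1])
        assert np.mean(losses) < 0.5
        assert np.median(losses) < 0.5

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            synth_profile(period=-1)
        with pytest.raises(ValueError):
            synth_profile(n_bumps=1)
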