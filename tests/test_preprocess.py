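"""Baseline removal, FIR filtering, resampling and trimming contracts."""

import numpy as np
import pytest

from mlecg import (ECGRecord, SynthConfig, downsample, fir_bandlimit,
                   generate_record, preprocess_record, remove_baseline, trim)
from mlecg.preprocess import design_firs, fir_frequency_response, median_window


def _rec(signal, fs=500.0):
    return ECGRecord(np.atleast_2d(signal), fs=fs)


class TestRemoveBaseline:
    def test_constant_maps_to_zero(self):
        out = remove_baseline(_rec(np.full(2000, 3.7)))
        assert np.allclose(out.signal, 0.0)

    def test_zero_maps_to_zero(self):
        out = remove_baseline(_rec(np.zeros(2000)))
        assert np.allclose(out.signal, 0.0)

    def test_drift_power_reduced_90_percent(self):
        """0.2 Hz 0.5 mV drift on a clean beat train loses >= 90% power."""
        cfg = SynthConfig(hr_jitter=0.0, seed=5)
        rec, _ = generate_record(cfg)
        t = np.arange(rec.n_samples) / rec.fs
        drift = 0.5 * np.sin(2 * np.pi * 0.2 * t)
        noisy = rec.with_signal(rec.signal + drift)
        out = remove_baseline(noisy)
        freqs = np.fft.rfftfreq(rec.n_samples, 1 / rec.fs)
        k = np.argmin(np.abs(freqs - 0.2))
        p_in = np.abs(np.fft.rfft(noisy.signal[1]))[k] ** 2
        p_out = np.abs(np.fft.rfft(out.signal[1]))[k] ** 2
        assert p_out <= 0.10 * p_in

    def test_window_is_odd_and_errors_on_short_record(self):
        assert median_window(0.9, 500) == 451
        assert median_window(0.9, 500) % 2 == 1
        with pytest.raises(ValueError):
            remove_baseline(_rec(np.zeros(100)))


class TestFirBandlimit:
    def test_50hz_attenuation_matches_designed_response(self):
        t = np.arange(5000) / 500.0
        x = np.sin(2 * np.pi * 50 * t)
        out = fir_bandlimit(_rec(x))
        lp, hp = design_firs(40.0, 2.0, 8, 500.0)
        expected = (fir_frequency_response(lp, 50.0, 500.0)
                    * fir_frequency_response(hp, 50.0, 500.0))
        mid = slice(500, 4500)  # away from filtfilt edge transients
        ratio = np.sqrt(np.mean(out.signal[0][mid] ** 2)
                        / np.mean(x[mid] ** 2))
        assert ratio < 1.0
        assert ratio == pytest.approx(expected, rel=0.02)

    def test_10hz_passband_matches_designed_response(self):
        t = np.arange(5000) / 500.0
        x = np.sin(2 * np.pi * 10 * t)
        out = fir_bandlimit(_rec(x))
        lp, hp = design_firs(40.0, 2.0, 8, 500.0)
        expected = (fir_frequency_response(lp, 10.0, 500.0)
                    * fir_frequency_response(hp, 10.0, 500.0))
        mid = slice(500, 4500)
        ratio = np.sqrt(np.mean(out.signal[0][mid] ** 2)
                        / np.mean(x[mid] ** 2))
        assert ratio == pytest.approx(expected, rel=0.02)

    def test_zero_signal(self):
        out = fir_bandlimit(_rec(np.zeros(1000)))
        assert np.allclose(out.signal, 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        fx = fir_bandlimit(_rec(x)).signal
        fy = fir_bandlimit(_rec(y)).signal
        fxy = fir_bandlimit(_rec(2.0 * x - 0.5 * y)).signal
        assert np.allclose(fxy, 2.0 * fx - 0.5 * fy, rtol=1e-9, atol=1e-12)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            fir_bandlimit(_rec(np.zeros(1000)), f_clp=300.0)


class TestDownsample:
    def test_500_to_200_sample_count(self):
        out = downsample(_rec(np.zeros(5000), fs=500.0), 200.0)
        assert out.n_samples == 2000
        assert out.fs == 200.0

    def test_sine_amplitude_preserved(self):
        t = np.arange(5000) / 500.0
        x = np.sin(2 * np.pi * 10 * t)
        out = downsample(_rec(x, fs=500.0), 200.0)
        t2 = np.arange(out.n_samples) / 200.0
        ref = np.sin(2 * np.pi * 10 * t2)
        mid = slice(100, 1900)
        assert np.max(np.abs(out.signal[0][mid] - ref[mid])) < 0.01

    def test_identity_when_rates_match(self):
        x = np.random.default_rng(1).normal(size=1000)
        out = downsample(_rec(x, fs=200.0), 200.0)
        assert np.array_equal(out.signal[0], x)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            downsample(_rec(np.zeros(100), fs=200.0), 500.0)


class TestTrim:
    def test_2000_to_1900(self):
        out = trim(_rec(np.arange(2000.0)), 50, 50)
        assert out.n_samples == 1900
        assert out.signal[0][0] == 50.0

    def test_zero_trim_identity(self):
        x = np.arange(100.0)
        assert np.array_equal(trim(_rec(x), 0, 0).signal[0], x)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            trim(_rec(np.zeros(100)), 50, 50)


def test_stages_are_per_lead_independent():
    """Applying a stage to a 1-lead slice equals slicing the 12-lead result."""
    rec, _ = generate_record(SynthConfig(noise_emg_amp=0.05, seed=6))
    for op in (lambda r: remove_baseline(r),
               lambda r: fir_bandlimit(r),
               lambda r: downsample(r, 200.0),
               lambda r: trim(r, 50, 50)):
        full = op(rec).signal
        single = op(ECGRecord(rec.signal[4:5], fs=rec.fs)).signal
        assert np.allclose(full[4], single[0], rtol=1e-12, atol=1e-12)


def test_full_pipeline_yields_12x1900(clean_record):
    rec, _, _ = clean_record
    out = preprocess_record(rec)
    assert out.signal.shape == (12, 1900)
    assert out.fs == 200.0
    assert np.all(np.isfinite(out.signal))
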