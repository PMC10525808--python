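"""Total Power Spectrum and the seven frequency-domain features."""

import numpy as np
import pytest

from emgrisk import (AlignmentError, EmgRecording, ParameterError, Roi,
                     UndefinedFeatureError, compute_tps, extract_features,
                     mean_frequency, median_frequency, peak_frequency,
                     peak_power, spectral_shape_moments, total_power)
from emgrisk.spectral import FEATURE_COLUMNS, PowerSpectrum

FS = 1600.0


def flat_spectrum(lo=15.0, hi=400.0, value=2.0, df=0.5) -> PowerSpectrum:
    freqs = np.arange(lo, hi + df / 2, df)
    return PowerSpectrum(freqs, np.full_like(freqs, value), df)


def delta_spectrum(f0: float, lo=0.0, hi=800.0, df=1.0) -> PowerSpectrum:
    freqs = np.arange(lo, hi + df / 2, df)
    power = np.zeros_like(freqs)
    power[np.argmin(np.abs(freqs - f0))] = 5.0
    return PowerSpectrum(freqs, power, df)


def brute_force_median(spec: PowerSpectrum) -> float:
    """Oracle: scan the cumulative trapezoidal area bin by bin."""
    area = 0.0
    total = np.trapezoid(spec.power, spec.freqs)
    for i in range(1, len(spec.freqs)):
        step = 0.5 * (spec.power[i] + spec.power[i - 1]) * \
            (spec.freqs[i] - spec.freqs[i - 1])
        if area + step >= total / 2:
            return spec.freqs[i - 1] + (total / 2 - area) / step * \
                (spec.freqs[i] - spec.freqs[i - 1])
        area += step
    return spec.freqs[-1]


class TestComputeTps:
    def test_zero_segment_gives_zero_spectrum(self):
        spec = compute_tps(np.zeros(1000), FS)
        assert np.all(spec.power == 0.0)

    def test_sine_concentrates_at_its_frequency(self):
        t = np.arange(3200) / FS
        x = np.sin(2 * np.pi * 100.0 * t)  # integer periods in window
        spec = compute_tps(x, FS)
        assert peak_frequency(spec) == pytest.approx(100.0, abs=spec.df)
        assert total_power(spec) == pytest.approx(0.5, rel=0.01)

    def test_white_noise_parseval(self, rng):
        x = rng.normal(0.0, 2.0, size=32000)
        spec = compute_tps(x, FS)
        assert total_power(spec) == pytest.approx(np.var(x), rel=0.05)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ParameterError):
            compute_tps(np.array([1.0]), FS)


class TestScalarFeatures:
    def test_total_power_of_flat_rectangle(self):
        spec = flat_spectrum(0.0, 100.0, value=3.0, df=1.0)
        assert total_power(spec) == pytest.approx(300.0, abs=1e-12)

    def test_peak_ties_break_to_lowest_frequency(self):
        spec = flat_spectrum()
        assert peak_frequency(spec) == spec.freqs[0]

    def test_peak_frequency_attains_peak_power(self):
        spec = delta_spectrum(80.0)
        idx = np.argmin(np.abs(spec.freqs - peak_frequency(spec)))
        assert spec.power[idx] == peak_power(spec)

    def test_flat_spectrum_median_and_mean_at_band_midpoint(self):
        spec = flat_spectrum(15.0, 400.0)
        assert median_frequency(spec) == pytest.approx(207.5, abs=spec.df)
        assert mean_frequency(spec) == pytest.approx(207.5, abs=spec.df)

    def test_median_matches_brute_force_oracle_on_random_spectra(self, rng):
        for _ in range(20):
            freqs = np.arange(15.0, 400.0, 0.5)
            power = rng.random(len(freqs)) ** 3
            spec = PowerSpectrum(freqs, power, 0.5)
            assert median_frequency(spec) == pytest.approx(
                brute_force_median(spec), abs=spec.df)

    def test_delta_spectrum_mean_is_its_location(self):
        assert mean_frequency(delta_spectrum(120.0)) == pytest.approx(120.0)

    def test_shift_property_of_delta_spectra(self):
        m0 = median_frequency(delta_spectrum(100.0))
        m1 = median_frequency(delta_spectrum(150.0))
        assert m1 - m0 == pytest.approx(50.0, abs=1.0)
        assert (mean_frequency(delta_spectrum(150.0))
                - mean_frequency(delta_spectrum(100.0))
                == pytest.approx(50.0, abs=1e-9))

    def test_zero_power_raises_undefined_feature(self):
        spec = PowerSpectrum(np.arange(10.0), np.zeros(10), 1.0)
        with pytest.raises(UndefinedFeatureError):
            median_frequency(spec)
        with pytest.raises(UndefinedFeatureError):
            mean_frequency(spec)

    def test_scale_invariance_of_frequency_features(self, rng):
        """Scaling the segment by c multiplies power-like features by c^2
        and leaves the three frequency features unchanged."""
        x = rng.standard_normal(3200) * 1e-4
        c = 7.5
        s1 = compute_tps(x, FS)
        s2 = compute_tps(c * x, FS)
        assert total_power(s2) == pytest.approx(c ** 2 * total_power(s1),
                                                rel=1e-9)
        assert peak_power(s2) == pytest.approx(c ** 2 * peak_power(s1),
                                               rel=1e-9)
        for feat in (median_frequency, mean_frequency, peak_frequency):
            assert feat(s2) == pytest.approx(feat(s1), abs=1e-9)


class TestShapeMoments:
    def test_hand_vector_matches_direct_moment_formula(self):
        values = np.array([1.0, 1.0, 1.0, 9.0])
        spec = PowerSpectrum(np.arange(4.0), values, 1.0)
        skew, kurt = spectral_shape_moments(spec)
        d = values - values.mean()
        m2, m3, m4 = (np.mean(d ** k) for k in (2, 3, 4))
        assert skew == pytest.approx(m3 / m2 ** 1.5, abs=1e-12)
        assert kurt == pytest.approx(m4 / m2 ** 2, abs=1e-12)

    def test_gaussian_values_give_skew_zero_kurtosis_three(self, rng):
        n = 200_000
        values = rng.standard_normal(n)
        spec = PowerSpectrum(np.arange(n, dtype=float), values, 1.0)
        skew, kurt = spectral_shape_moments(spec)
        se_skew, se_kurt = np.sqrt(6 / n), np.sqrt(24 / n)
        assert abs(skew) < 3 * se_skew
        assert abs(kurt - 3.0) < 3 * se_kurt

    def test_constant_spectrum_is_undefined(self):
        spec = flat_spectrum()
        with pytest.raises(UndefinedFeatureError):
            spectral_shape_moments(spec)

    def test_frequency_target_delta_has_zero_spread_guard(self):
        spec = delta_spectrum(100.0)
        with pytest.raises(UndefinedFeatureError):
            spectral_shape_moments(spec, moment_target="frequency")

    def test_unknown_target_rejected(self):
        with pytest.raises(ParameterError):
            spectral_shape_moments(flat_spectrum(), moment_target="bogus")


def _tiny_recording(amplitudes, fs=FS, n=48000):
    rng = np.random.default_rng(0)
    samples = {}
    for ch in ("ER_L", "ER_R", "ML_L", "ML_R"):
        x = np.zeros(n)
        for k, a in enumerate(amplitudes):
            s = 8000 + 16000 * k
            x[s:s + 3200] = a * rng.standard_normal(3200)
        samples[ch] = x
    return EmgRecording("S01", "NO-RISK", fs, samples)


def _rois(channels, k_bursts):
    return {ch: [Roi(ch, 8000 + 16000 * k, 8000 + 16000 * k + 3200, k)
                 for k in range(k_bursts)] for ch in channels}


class TestExtractFeatures:
    def test_row_count_and_columns(self):
        rec = _tiny_recording([1e-4, 1e-4])
        table = extract_features(rec, _rois(rec.channels, 2))
        assert len(table) == 2
        assert set(FEATURE_COLUMNS) <= set(table.columns)
        assert table["valid"].all()

    def test_zero_amplitude_burst_flagged_not_raised(self):
        rec = _tiny_recording([1e-4, 0.0])
        table = extract_features(rec, _rois(rec.channels, 2))
        assert table["valid"].tolist() == [True, False]
        assert np.isnan(table.loc[1, "Power_ER"])

    def test_roi_count_mismatch_raises_alignment_error(self):
        rec = _tiny_recording([1e-4, 1e-4])
        rois = _rois(rec.channels, 2)
        rois["ML_L"] = rois["ML_L"][:1]
        with pytest.raises(AlignmentError):
            extract_features(rec, rois)

    def test_left_right_fusion_is_arithmetic_mean(self):
        rec = _tiny_recording([1e-4])
        rois = _rois(rec.channels, 1)
        table = extract_features(rec, rois)
        from emgrisk.spectral import roi_features
        left = roi_features(rec.samples["ER_L"][8000:11200], FS)
        right = roi_features(rec.samples["ER_R"][8000:11200], FS)
        expected = 0.5 * (left["F_mean"] + right["F_mean"])
        assert table.loc[0, "F_mean_ER"] == pytest.approx(expected, rel=1e-12)
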