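"""Total Power Spectrum and frequency-domain features.

Each ROI of the raw EMG is turned into a one-sided periodogram (the Total
Power Spectrum, TPS): mean-removed, rectangular window, density scaling
(V^2/Hz), so the integral of the spectrum equals the segment variance
(Parseval).  Seven features are read off each TPS:

==============  ========  ====================================================
feature         units     definition
==============  ========  ====================================================
power           V^2       integral under the spectrum curve
p_power         V^2/Hz    maximum of the TPS
f_median        Hz        frequency splitting spectral power into equal halves
f_mean          Hz        power-weighted mean frequency
f_peak          Hz        frequency at which p_power is attained
kurtosis        --        standardized fourth moment
skewness        --        standardized third moment
==============  ========  ====================================================

Kurtosis and skewness are, by default, moments of the *vector of TPS
values* (the spectrum treated as a sample of power readings) — the only
reading under which their typical magnitudes (kurtosis in the tens for a
peaky spectrum) match what lifting-trial EMG produces.  Alternative
interpretations (moments of the frequency variable weighted by power, or
of the time-domain amplitude distribution) are available via
``moment_target``.

Features are computed on the spectrum restricted to the 15-400 Hz
analysis band, the pass-band of the preprocessing filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import signal as sps

from .errors import AlignmentError, ParameterError, UndefinedFeatureError
from .preprocess import BAND_HIGH_HZ, BAND_LOW_HZ, Roi
from .simulate import MUSCLES, EmgRecording

#: Column order of the 14-feature table fed to the classifiers.
FEATURE_NAMES = ("Power", "P_power", "F_peak", "F_median", "F_mean",
                 "Kurtosis", "Skewness")
FEATURE_COLUMNS = tuple(f"{name}_{muscle}" for muscle in ("ER", "ML")
                        for name in FEATURE_NAMES)
MOMENT_TARGETS = ("spectrum_values", "frequency", "amplitude")


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray  # Hz, ascending
    power: np.ndarray  # V^2/Hz, nonnegative
    df: float  # Hz

    def band(self, lo: float, hi: float) -> "PowerSpectrum":
        """Restrict the spectrum to [lo, hi] Hz (inclusive)."""
        mask = (self.freqs >= lo) & (self.freqs <= hi)
        return PowerSpectrum(self.freqs[mask], self.power[mask], self.df)


def compute_tps(segment: np.ndarray, fs: float) -> PowerSpectrum:
    """One-sided periodogram of the mean-removed segment, density scaling."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise ParameterError("segment must contain at least 2 samples")
    freqs, power = sps.periodogram(segment, fs=fs, window="boxcar",
                                   detrend="constant", scaling="density")
    return PowerSpectrum(freqs, power, float(freqs[1] - freqs[0]))


def total_power(spec: PowerSpectrum) -> float:
    """Integral under the spectrum curve (trapezoidal), in V^2."""
    return float(np.trapezoid(spec.power, spec.freqs))


def peak_power(spec: PowerSpectrum) -> float:
    """Maximum value of the TPS, in V^2/Hz."""
    return float(spec.power.max())


def peak_frequency(spec: PowerSpectrum) -> float:
    """Frequency at which the peak power is attained; ties -> lowest."""
    return float(spec.freqs[int(np.argmax(spec.power))])


def median_frequency(spec: PowerSpectrum) -> float:
    """Frequency splitting the spectral area into two equal halves.

    Smallest frequency at which the cumulative trapezoidal power reaches
    half the total, linearly interpolated within the crossing bin.
    """
    cum = integrate.cumulative_trapezoid(spec.power, spec.freqs, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise UndefinedFeatureError("median frequency undefined: zero power")
    half = total / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        return float(spec.freqs[0])
    # Linear interpolation of the cumulative curve within the crossing bin.
    f0, f1 = spec.freqs[i - 1], spec.freqs[i]
    c0, c1 = cum[i - 1], cum[i]
    if c1 == c0:
        return float(f0)
    return float(f0 + (half - c0) / (c1 - c0) * (f1 - f0))


def mean_frequency(spec: PowerSpectrum) -> float:
    """Power-weighted mean frequency: sum(f*p) / sum(p)."""
    total = spec.power.sum()
    if total <= 0:
        raise UndefinedFeatureError("mean frequency undefined: zero power")
    return float(np.sum(spec.freqs * spec.power) / total)


def _standardized_moments(values: np.ndarray,
                          weights: np.ndarray | None = None
                          ) -> tuple[float, float]:
    """(skewness g1, non-excess Pearson kurtosis) of a (weighted) sample."""
    if weights is None:
        mean = values.mean()
        d = values - mean
        m2 = np.mean(d ** 2)
        m3 = np.mean(d ** 3)
        m4 = np.mean(d ** 4)
    else:
        w = weights / weights.sum()
        mean = np.sum(w * values)
        d = values - mean
        m2 = np.sum(w * d ** 2)
        m3 = np.sum(w * d ** 3)
        m4 = np.sum(w * d ** 4)
    if m2 <= 0:
        raise UndefinedFeatureError("moments undefined: zero variance")
    return float(m3 / m2 ** 1.5), float(m4 / m2 ** 2)


def spectral_shape_moments(spec: PowerSpectrum,
                           moment_target: str = "spectrum_values",
                           segment: np.ndarray | None = None
                           ) -> tuple[float, float]:
    """(skewness, kurtosis) of the TPS under the chosen interpretation.

    ``spectrum_values`` (default): moments of the vector of spectral power
    values.  ``frequency``: moments of the frequency variable with the
    spectrum as weights.  ``amplitude``: moments of the time-domain
    samples (requires ``segment``).
    """
    if moment_target == "spectrum_values":
        if spec.power.size < 3:
            raise ParameterError("need at least 3 spectral bins")
        return _standardized_moments(spec.power)
    if moment_target == "frequency":
        return _standardized_moments(spec.freqs, weights=spec.power)
    if moment_target == "amplitude":
        if segment is None:
            raise ParameterError("amplitude moments require the segment")
        return _standardized_moments(np.asarray(segment, dtype=float))
    raise ParameterError(f"unknown moment_target {moment_target!r}")


def roi_features(segment: np.ndarray, fs: float,
                 band: tuple[float, float] = (BAND_LOW_HZ, BAND_HIGH_HZ),
                 moment_target: str = "spectrum_values") -> dict[str, float]:
    """The seven features of one ROI segment (one channel)."""
    spec = compute_tps(segment, fs).band(*band)
    skew, kurt = spectral_shape_moments(spec, moment_target, segment=segment)
    return {
        "Power": total_power(spec),
        "P_power": peak_power(spec),
        "F_peak": peak_frequency(spec),
        "F_median": median_frequency(spec),
        "F_mean": mean_frequency(spec),
        "Kurtosis": kurt,
        "Skewness": skew,
    }


def extract_features(recording: EmgRecording,
                     rois: dict[str, list[Roi]],
                     band: tuple[float, float] = (BAND_LOW_HZ, BAND_HIGH_HZ),
                     moment_target: str = "spectrum_values") -> pd.DataFrame:
    """Per-lift feature rows for one recording.

    For every lift, the left and right channels of each muscle are
    processed independently and their feature values averaged into one
    per-muscle set, giving 14 feature columns per row plus metadata.
    Lifts whose features are undefined (e.g. zero-amplitude segments) are
    kept as rows flagged ``valid = False`` with NaN features.
    """
    counts = {ch: len(r) for ch, r in rois.items()}
    if len(set(counts.values())) != 1:
        raise AlignmentError(f"ROI count mismatch across channels: {counts}")
    n_lifts = next(iter(counts.values()))
    rows = []
    for k in range(n_lifts):
        row: dict[str, object] = {
            "subject_id": recording.subject_id,
            "lift_index": k,
            "label": recording.condition,
            "valid": True,
        }
        for muscle, channels in MUSCLES.items():
            per_channel = []
            for ch in channels:
                roi = rois[ch][k]
                segment = recording.samples[ch][roi.start:roi.stop]
                try:
                    per_channel.append(
                        roi_features(segment, recording.fs, band,
                                     moment_target))
                except UndefinedFeatureError:
                    row["valid"] = False
            if per_channel:
                for name in FEATURE_NAMES:
                    row[f"{name}_{muscle}"] = float(
                        np.mean([f[name] for f in per_channel]))
            else:
                for name in FEATURE_NAMES:
                    row[f"{name}_{muscle}"] = np.nan
        rows.append(row)
    columns = ["subject_id", "lift_index", "label", "valid",
               *FEATURE_COLUMNS]
    return pd.DataFrame(rows, columns=columns)


def cohort_features(recordings: list[EmgRecording],
                    rois_by_recording: list[dict[str, list[Roi]]],
                    **kwargs) -> pd.DataFrame:
    """Concatenate per-recording feature tables into the pooled table."""
    tables = [extract_features(rec, rois, **kwargs)
              for rec, rois in zip(recordings, rois_by_recording)]
    return pd.concat(tables, ignore_index=True)
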