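"""Synthetic surface-EMG lifting cohorts.

Real recordings of the study design this package analyses (8 subjects, one
NO-RISK and one RISK trial each, 30 lifts per trial, four back-muscle
channels at 1600 Hz) are not publicly available, so this module generates
surrogate cohorts with the statistical structure the downstream analysis
assumes, together with ground-truth annotations that make every stage
testable.

Each lifting contraction is modelled as band-limited Gaussian noise (white
noise passed through a Butterworth band-pass around a planted centre
frequency) shaped by a raised-cosine on/off envelope and scaled to a target
RMS — the standard stationary surrogate for a surface-EMG burst.  The RISK
condition carries two planted effects that mirror the physiology of risky
lifting: higher burst power (stronger contraction) and a downward drift of
the spectral centre frequency across the 30 lifts (fatigue-induced spectral
compression).  Multifidus channels receive a larger condition contrast than
erector spinae channels, matching the lumbar muscles' greater involvement
in load lifting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ParameterError

NO_RISK = "NO-RISK"
RISK = "RISK"
CONDITIONS = (NO_RISK, RISK)

#: Channel labels: erector spinae left/right, multifidus left/right.
CHANNELS = ("ER_L", "ER_R", "ML_L", "ML_R")
ER_CHANNELS = ("ER_L", "ER_R")
ML_CHANNELS = ("ML_L", "ML_R")

MUSCLES = {"ER": ER_CHANNELS, "ML": ML_CHANNELS}


@dataclass(frozen=True)
class BurstSpectrum:
    """Spectral parameters of one condition's contraction bursts."""

    center_freq: float  # Hz
    bandwidth: float  # Hz, full width of the noise band
    rms_amplitude: float  # V


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort layout and planted effect sizes.

    Defaults reproduce the study conditions: 8 subjects x 2 trials
    (NO-RISK with lifting index 0.5, RISK with 1.3), 30 lifts per trial,
    1600 Hz sampling, 2 s contractions separated by 4 s of rest.  The RISK
    bursts have their RMS multiplied by ``power_ratio_risk`` and their
    centre frequency drifts down by ``fatigue_drift_risk`` (fractional)
    from the first to the last lift; the NO-RISK trial has no drift.
    Multifidus channels get the condition contrast (both the power ratio
    and the centre-frequency shift) amplified by ``ml_contrast`` and sit
    ``ml_center_offset_hz`` above the erector spinae baseline.
    """

    n_subjects: int = 8
    lifts_per_trial: int = 30
    fs: float = 1600.0
    burst_duration_s: float = 2.0
    rest_duration_s: float = 4.0
    lead_s: float = 3.0  # quiet lead-in/out, excluded from threshold estimation downstream
    no_risk: BurstSpectrum = BurstSpectrum(90.0, 100.0, 1.0e-4)
    risk: BurstSpectrum = BurstSpectrum(84.0, 100.0, 1.0e-4)
    fatigue_drift_risk: float = 0.15
    fatigue_drift_no_risk: float = 0.0
    power_ratio_risk: float = 1.4
    ml_contrast: float = 1.25
    ml_center_offset_hz: float = 10.0
    noise_floor_rms: float = 2.0e-5
    subject_center_jitter_hz: float = 4.0
    subject_amplitude_cv: float = 0.15
    onset_jitter_s: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.lifts_per_trial < 1:
            raise ParameterError("lifts_per_trial must be >= 1")
        if not (0.0 <= self.fatigue_drift_risk < 1.0
                and 0.0 <= self.fatigue_drift_no_risk < 1.0):
            raise ParameterError("fatigue drifts must lie in [0, 1)")
        if self.noise_floor_rms <= 0:
            raise ParameterError("noise_floor_rms must be positive")
        for spec in (self.no_risk, self.risk):
            top = spec.center_freq + spec.bandwidth / 2.0
            if self.fs <= 2.0 * top:
                raise ParameterError(
                    f"fs={self.fs} too low for burst band up to {top} Hz")
            if spec.rms_amplitude <= self.noise_floor_rms:
                raise ParameterError(
                    "burst rms_amplitude must exceed noise_floor_rms")

    def drift(self, condition: str) -> float:
        return (self.fatigue_drift_risk if condition == RISK
                else self.fatigue_drift_no_risk)


@dataclass(frozen=True)
class PlantedBurst:
    """Ground-truth annotation of one generated contraction."""

    start: int  # sample index, inclusive
    stop: int  # sample index, exclusive
    center_freq: float  # Hz
    rms: float  # V


@dataclass
class EmgRecording:
    """One multichannel trial: per-channel sample series plus metadata.

    ``truth`` maps each channel label to the planted burst annotations;
    it is ``None`` for recordings read back from disk without a sidecar.
    """

    subject_id: str
    condition: str
    fs: float
    samples: dict[str, np.ndarray]
    truth: dict[str, list[PlantedBurst]] | None = None

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.samples.keys())

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.samples.values())))

    def validate(self) -> None:
        lengths = {len(v) for v in self.samples.values()}
        if len(lengths) != 1:
            raise ParameterError("all channels must have the same length")
        for name, x in self.samples.items():
            if not np.all(np.isfinite(x)):
                raise ParameterError(f"non-finite samples in channel {name}")


def generate_burst(fs: float, duration_s: float, center_freq: float,
                   bandwidth: float, rms_amplitude: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Generate one contraction burst.

    White Gaussian noise is band-pass filtered (4th-order Butterworth,
    zero-phase) to the band ``center_freq +/- bandwidth/2``, shaped by
    raised-cosine on/off ramps of 10% of the duration on each side, and
    rescaled so the series RMS equals ``rms_amplitude``.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    lo = center_freq - bandwidth / 2.0
    hi = center_freq + bandwidth / 2.0
    if lo < 0:
        raise ParameterError("center_freq - bandwidth/2 must be >= 0")
    if hi >= fs / 2.0:
        raise ParameterError("burst band must lie below the Nyquist frequency")
    n = int(round(duration_s * fs))
    if rms_amplitude == 0.0:
        return np.zeros(n)
    pad = int(fs)  # one second of settle padding on each side
    white = rng.standard_normal(n + 2 * pad)
    if lo <= 0.0:  # degenerate band touching DC: low-pass instead
        sos = sps.butter(4, hi, btype="low", fs=fs, output="sos")
    else:
        sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)[pad:pad + n]
    m = max(int(0.1 * n), 1)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(m) / m))
    env = np.ones(n)
    env[:m] = ramp
    env[-m:] = np.minimum(env[-m:], ramp[::-1])
    x = x * env
    x *= rms_amplitude / np.sqrt(np.mean(x ** 2))
    return x


def _channel_params(config: SimulationConfig, channel: str,
                    condition: str) -> tuple[float, float]:
    """Planted (centre frequency, RMS) for the first lift of a channel."""
    base = config.no_risk
    center0 = base.center_freq
    rms0 = base.rms_amplitude
    is_ml = channel in ML_CHANNELS
    if is_ml:
        center0 += config.ml_center_offset_hz
    if condition == RISK:
        shift = base.center_freq - config.risk.center_freq
        ratio = config.power_ratio_risk
        if is_ml:
            shift *= config.ml_contrast
            ratio *= config.ml_contrast
        center0 -= shift
        rms0 = config.risk.rms_amplitude * ratio
    return center0, rms0


def generate_trial(config: SimulationConfig, subject_id: str, condition: str,
                   rng: np.random.Generator, *,
                   center_offset_hz: float = 0.0,
                   amplitude_factor: float = 1.0) -> EmgRecording:
    """Generate one trial recording (all four channels).

    Burst k's centre frequency is ``f0 * (1 - drift * k/(n-1))``; lift
    onsets are shared across channels (one physical lift) with a small
    uniform jitter, while the noise realisations are independent per
    channel.  ``center_offset_hz`` and ``amplitude_factor`` carry the
    per-subject idiosyncrasy drawn by :func:`generate_cohort`.
    """
    config.validate()
    if condition not in CONDITIONS:
        raise ParameterError(f"unknown condition {condition!r}")
    fs = config.fs
    n_lifts = config.lifts_per_trial
    period = config.burst_duration_s + config.rest_duration_s
    total_s = 2 * config.lead_s + n_lifts * period
    n_total = int(round(total_s * fs))
    drift = config.drift(condition)
    bw = (config.risk if condition == RISK else config.no_risk).bandwidth

    # One onset jitter per lift, common to all channels.
    jitters = rng.uniform(-config.onset_jitter_s, config.onset_jitter_s,
                          size=n_lifts)

    samples: dict[str, np.ndarray] = {}
    truth: dict[str, list[PlantedBurst]] = {}
    for channel in CHANNELS:
        x = rng.standard_normal(n_total) * config.noise_floor_rms
        center0, rms = _channel_params(config, channel, condition)
        center0 += center_offset_hz
        rms *= amplitude_factor
        bursts: list[PlantedBurst] = []
        for k in range(n_lifts):
            frac = k / (n_lifts - 1) if n_lifts > 1 else 0.0
            center_k = center0 * (1.0 - drift * frac)
            onset = config.lead_s + k * period + jitters[k]
            start = int(round(onset * fs))
            b = generate_burst(fs, config.burst_duration_s, center_k, bw,
                               rms, rng)
            x[start:start + len(b)] += b
            bursts.append(PlantedBurst(start, start + len(b), center_k, rms))
        samples[channel] = x
        truth[channel] = bursts
    return EmgRecording(subject_id=subject_id, condition=condition, fs=fs,
                        samples=samples, truth=truth)


def generate_cohort(config: SimulationConfig) -> list[EmgRecording]:
    """Generate the full cohort: ``n_subjects`` x 2 conditions.

    Deterministic for a given config (seeded); subjects are exchangeable
    but not identical — each gets a random centre-frequency offset and a
    multiplicative amplitude factor, shared by both of their trials so the
    paired within-subject structure is preserved.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    subject_streams = root.spawn(config.n_subjects)
    recordings: list[EmgRecording] = []
    for i, ss in enumerate(subject_streams):
        subject_id = f"S{i + 1:02d}"
        meta_stream, *trial_streams = ss.spawn(1 + len(CONDITIONS))
        meta_rng = np.random.default_rng(meta_stream)
        offset = meta_rng.normal(0.0, config.subject_center_jitter_hz)
        amp = float(np.exp(meta_rng.normal(0.0, config.subject_amplitude_cv)))
        for condition, stream in zip(CONDITIONS, trial_streams):
            recordings.append(
                generate_trial(config, subject_id, condition,
                               np.random.default_rng(stream),
                               center_offset_hz=offset,
                               amplitude_factor=amp))
    return recordings
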