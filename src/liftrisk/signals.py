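"""Signal conditioning for lifting trials.

Covers the standard conditioning chain used before any modelling:

* zero-phase 4th-order Butterworth low-pass at 6 Hz for kinematic and force
  channels;
* lift-cycle segmentation from the vertical box velocity with a 0.025 m/s
  threshold (start = first upward crossing; end = first sample after the
  displacement maximum where the velocity drops back below the threshold);
* surface-EMG envelope extraction: 20–400 Hz band-pass, full-wave
  rectification, 5 Hz low-pass, amplitude normalisation to the mean of the
  three iMVC peaks, and time normalisation of each lift cycle to 201 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

__all__ = [
    "TimeSeries",
    "SegmentationConfig",
    "LiftCycle",
    "EnvelopeConfig",
    "SignalError",
    "NoLiftDetectedError",
    "lowpass_motion",
    "segment_lift",
    "emg_envelope",
    "normalize_envelope",
    "time_normalize",
]


class SignalError(ValueError):
    """Invalid signal input (sampling, length, or alignment)."""


class NoLiftDetectedError(SignalError):
    """The vertical velocity never exceeds the segmentation threshold."""


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled time series; ``values`` is (n,) or (channels, n)."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise SignalError(f"sampling frequency must be positive, got {self.fs}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim not in (1, 2):
            raise SignalError("values must be 1-D or (channels, n)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[-1]

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return TimeSeries(values=values, fs=self.fs, t0=self.t0)


@dataclass(frozen=True)
class SegmentationConfig:
    velocity_threshold: float = 0.025  # m/s, vertical axis

    def __post_init__(self) -> None:
        if self.velocity_threshold <= 0:
            raise SignalError("velocity_threshold must be positive")


@dataclass(frozen=True)
class LiftCycle:
    """Sample-index span of one detected lift, [start_index, end_index]."""

    start_index: int
    end_index: int
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.start_index >= self.end_index:
            raise SignalError("cycle start must precede its end")

    @property
    def start_time(self) -> float:
        return self.t0 + self.start_index / self.fs

    @property
    def end_time(self) -> float:
        return self.t0 + self.end_index / self.fs

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass(frozen=True)
class EnvelopeConfig:
    """EMG conditioning parameters (band-pass, envelope low-pass, resampling)."""

    bandpass: tuple[float, float] = (20.0, 400.0)
    bandpass_order: int = 4
    lowpass: float = 5.0
    lowpass_order: int = 4
    n_points: int = 201
    imvc_peaks: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise SignalError("n_points must be >= 2")
        if any(p <= 0 for p in self.imvc_peaks):
            raise SignalError("iMVC peaks must all be positive")


def _sos_filtfilt(values: np.ndarray, sos: np.ndarray, order: int) -> np.ndarray:
    # reflective padding of 3x the filter order suppresses edge transients
    padlen = min(3 * 2 * order, values.shape[-1] - 1)
    return sps.sosfiltfilt(sos, values, axis=-1, padtype="odd", padlen=padlen)


def lowpass_motion(series: TimeSeries, cutoff: float = 6.0, order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth low-pass for kinematic/force channels."""
    if series.fs <= 2 * cutoff:
        raise SignalError(
            f"fs={series.fs} Hz too low for a {cutoff} Hz low-pass"
        )
    if series.n_samples <= 3 * 2 * order:
        raise SignalError("series shorter than the filter warm-up length")
    sos = sps.butter(order, cutoff, btype="low", fs=series.fs, output="sos")
    return series.with_values(_sos_filtfilt(series.values, sos, order))


def segment_lift(
    box_height: TimeSeries,
    box_velocity: TimeSeries,
    cfg: SegmentationConfig | None = None,
) -> LiftCycle:
    """Detect one lift cycle from vertical box kinematics.

    Start: first sample whose vertical velocity exceeds the threshold.
    End: first sample after the global displacement maximum where the
    velocity falls back below the threshold (covers both settling to rest
    and a small negative overshoot).
    """
    cfg = cfg or SegmentationConfig()
    if box_height.n_samples != box_velocity.n_samples:
        raise SignalError("height and velocity series must be aligned")
    v = np.atleast_1d(np.squeeze(box_velocity.values))
    h = np.atleast_1d(np.squeeze(box_height.values))
    above = v > cfg.velocity_threshold
    if not above.any():
        raise NoLiftDetectedError(
            f"velocity never exceeds {cfg.velocity_threshold} m/s"
        )
    start = int(np.argmax(above))
    peak = int(np.argmax(h))
    after = np.nonzero(v[peak + 1 :] < cfg.velocity_threshold)[0]
    end = peak + 1 + int(after[0]) if after.size else box_height.n_samples - 1
    if end <= start:
        end = min(start + 1, box_height.n_samples - 1)
    return LiftCycle(start_index=start, end_index=end, fs=box_height.fs, t0=box_height.t0)


def emg_envelope(raw: TimeSeries, cfg: EnvelopeConfig | None = None) -> TimeSeries:
    """Linear envelope of raw sEMG: band-pass, full-wave rectify, low-pass."""
    cfg = cfg or EnvelopeConfig()
    lo, hi = cfg.bandpass
    if raw.fs < 2 * hi:
        raise SignalError(
            f"fs={raw.fs} Hz cannot represent the {hi} Hz band edge"
        )
    bp = sps.butter(cfg.bandpass_order, (lo, hi), btype="band", fs=raw.fs, output="sos")
    lp = sps.butter(cfg.lowpass_order, cfg.lowpass, btype="low", fs=raw.fs, output="sos")
    x = _sos_filtfilt(raw.values, bp, cfg.bandpass_order)
    x = np.abs(x)
    x = _sos_filtfilt(x, lp, cfg.lowpass_order)
    # zero-phase low-pass of a non-negative signal can undershoot slightly
    return raw.with_values(np.clip(x, 0.0, None))


def normalize_envelope(env: TimeSeries, imvc_peaks) -> TimeSeries:
    """Divide the envelope by the mean of the iMVC peak values."""
    peaks = np.asarray(imvc_peaks, dtype=float)
    if peaks.size == 0 or np.any(peaks <= 0):
        raise SignalError("iMVC peaks must be a non-empty list of positive values")
    return env.with_values(env.values / peaks.mean())


def time_normalize(env: TimeSeries, cycle: LiftCycle, n_points: int = 201) -> np.ndarray:
    """Resample one lift cycle onto ``n_points`` equally spaced cycle fractions.

    Piecewise-cubic (PCHIP) interpolation on the normalised time axis:
    shape-preserving and exact at the cycle endpoints.
    """
    if n_points < 2:
        raise SignalError("n_points must be >= 2")
    if cycle.end_index >= env.n_samples:
        raise SignalError("cycle extends beyond the series")
    seg = env.values[..., cycle.start_index : cycle.end_index + 1]
    n = seg.shape[-1]
    if n < 2:
        raise SignalError("cycle shorter than 2 samples")
    tau = np.linspace(0.0, 1.0, n)
    tau_out = np.linspace(0.0, 1.0, n_points)
    return PchipInterpolator(tau, seg, axis=-1)(tau_out)
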