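"""Raw-ECG conditioning: baseline removal, powerline notch, high-pass, normalization.

The chain turns a raw single-lead trace into a zero-baseline, notch-filtered,
high-pass-filtered signal rescaled to [-1, 1].  All filtering is zero-phase
(forward-backward), so R-peak sample positions are preserved for the
index-based segmentation that follows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import DegenerateInputError, InvalidConfigError, InvalidInputError

__all__ = [
    "RawRecord",
    "FilterSpec",
    "CleanSignal",
    "remove_baseline",
    "suppress_powerline",
    "iir_notch",
    "highpass_filter",
    "minmax_normalize",
    "preprocess_record",
]


@dataclass
class RawRecord:
    """A sampled single-lead ECG trace.

    Parameters
    ----------
    samples : array-like
        Signal amplitudes in millivolts.
    fs : float
        Sampling rate in Hz (> 0).
    subject_id : str
        Identity label of the person the trace was recorded from.
    source : str
        Free-text provenance (record name, file, simulator seed, ...).
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InvalidInputError("RawRecord.samples must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise InvalidConfigError(f"sampling rate must be positive, got {self.fs}")


@dataclass
class FilterSpec:
    """Parameters of the noise-suppression filters.

    ``notch_freq``/``notch_order`` configure the band-reject filter for mains
    interference; ``highpass_cutoff``/``highpass_order`` the Butterworth
    high-pass for baseline drift.  ``pole_radius`` only affects the optional
    second-order IIR notch variant (:func:`iir_notch`), not the default
    Butterworth band-stop.
    """

    notch_freq: float = 50.0
    notch_order: int = 5
    notch_halfwidth: float = 2.0
    highpass_cutoff: float = 0.5
    highpass_order: int = 5
    pole_radius: float = 0.95

    def validate(self, fs: float) -> None:
        if not 0 < self.highpass_cutoff < self.notch_freq:
            raise InvalidConfigError(
                f"need 0 < highpass_cutoff ({self.highpass_cutoff}) < notch_freq ({self.notch_freq})"
            )
        if self.notch_freq >= fs / 2:
            raise InvalidConfigError(
                f"notch frequency {self.notch_freq} Hz is not below Nyquist ({fs / 2} Hz)"
            )
        if not 0 < self.pole_radius < 1:
            raise InvalidConfigError("pole_radius must lie in (0, 1)")


@dataclass
class CleanSignal:
    """Preprocessed trace: same length as the source record, range [-1, 1]."""

    samples: np.ndarray
    fs: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        eps = 1e-9
        if self.samples.size and (
            self.samples.min() < -1 - eps or self.samples.max() > 1 + eps
        ):
            raise InvalidInputError("CleanSignal samples must lie in [-1, 1]")


def _as_signal(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InvalidInputError("signal must be a non-empty 1-D sequence")
    return x


def remove_baseline(x) -> np.ndarray:
    """Subtract the arithmetic mean (DC baseline) from the signal."""
    x = _as_signal(x)
    return x - x.mean()


def suppress_powerline(x, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Attenuate mains interference with a zero-phase Butterworth band-stop.

    The stop band is ``notch_freq +/- notch_halfwidth`` Hz; passband gain stays
    within a few percent of unity away from the notch.
    """
    spec = spec or FilterSpec()
    x = _as_signal(x)
    if spec.notch_freq >= fs / 2:
        raise InvalidConfigError(
            f"notch frequency {spec.notch_freq} Hz must be below Nyquist ({fs / 2} Hz)"
        )
    lo = spec.notch_freq - spec.notch_halfwidth
    hi = spec.notch_freq + spec.notch_halfwidth
    sos = sps.butter(spec.notch_order, [lo, hi], btype="bandstop", fs=fs, output="sos")
    padlen = min(x.size - 1, int(fs))
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def iir_notch(x, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Optional second-order pole-radius notch: zeros on the unit circle at the
    mains frequency, poles at radius ``r`` just inside.  Sharper but not
    zero-phase; the pipeline default is :func:`suppress_powerline`."""
    spec = spec or FilterSpec()
    x = _as_signal(x)
    if spec.notch_freq >= fs / 2:
        raise InvalidConfigError("notch frequency must be below Nyquist")
    r = spec.pole_radius
    w0 = 2 * np.pi * spec.notch_freq / fs
    b = np.array([1.0, -2.0 * np.cos(w0), 1.0])
    a = np.array([1.0, -2.0 * r * np.cos(w0), r * r])
    # unit gain at DC
    b *= a.sum() / b.sum()
    return sps.lfilter(b, a, x)


def highpass_filter(x, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth high-pass removing baseline drift below the cutoff."""
    spec = spec or FilterSpec()
    x = _as_signal(x)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("signal contains non-finite samples")
    if fs <= 2 * spec.highpass_cutoff:
        raise InvalidConfigError("sampling rate too low for the high-pass cutoff")
    sos = sps.butter(spec.highpass_order, spec.highpass_cutoff, btype="highpass", fs=fs, output="sos")
    # the filter's settling time is ~1/cutoff seconds; reflect-pad accordingly
    padlen = min(x.size - 1, int(3 * fs / spec.highpass_cutoff))
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def minmax_normalize(x) -> np.ndarray:
    """Affine rescale to [-1, 1]: ``2 (x - min) / (max - min) - 1``.

    Raises
    ------
    DegenerateInputError
        If the signal is constant (no amplitude information to rescale).
    """
    x = _as_signal(x)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise DegenerateInputError("constant signal cannot be min-max normalized")
    y = 2.0 * (x - lo) / (hi - lo) - 1.0
    # guarantee exact endpoints despite rounding
    y[np.argmin(x)] = -1.0
    y[np.argmax(x)] = 1.0
    return np.clip(y, -1.0, 1.0)


def preprocess_record(record: RawRecord, spec: FilterSpec | None = None) -> CleanSignal:
    """Full conditioning chain: baseline -> notch -> high-pass -> normalize."""
    spec = spec or FilterSpec()
    spec.validate(record.fs)
    x = remove_baseline(record.samples)
    x = suppress_powerline(x, record.fs, spec)
    x = highpass_filter(x, record.fs, spec)
    x = minmax_normalize(x)
    return CleanSignal(samples=x, fs=record.fs, subject_id=record.subject_id)
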