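"""Band-pass filtering and edge trimming of EHG channels.

The analysis band is 0.08-4 Hz (contraction activity; excludes baseline
drift below and maternal ECG/noise above), realised as a fourth-order
Butterworth filter in second-order sections — the 0.08 Hz corner at a 20 Hz
sampling rate is numerically fragile in transfer-function form.  The filter
is applied forward-backward (zero phase) by default so contraction timing is
preserved; five minutes are then discarded from each end of the recording to
drop filter transients, leaving the 20-minute analysis segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io_ehg import EHGRecord

__all__ = ["FilterSpec", "bandpass", "trim", "preprocess_record"]

#: seconds removed from each end of a recording
DEFAULT_TRIM_S = 300.0


class NyquistError(ValueError):
    """Band edge at or above the Nyquist frequency."""


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification (zero-phase by default)."""

    low_hz: float = 0.08
    high_hz: float = 4.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"band edges must satisfy 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})")

    def validate(self, fs: float) -> None:
        if self.high_hz >= fs / 2.0:
            raise NyquistError(
                f"high edge {self.high_hz} Hz >= Nyquist {fs / 2.0} Hz")

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return sps.butter(self.order, (self.low_hz, self.high_hz),
                          btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, fs: float,
             spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Band-pass one signal; output has the input's length.

    Zero-phase application filters forward and backward, squaring the
    magnitude response (effective order 8) and cancelling phase delay.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("bandpass: non-finite samples in input")
    if x.size <= 3 * spec.order:
        raise ValueError(f"bandpass: signal too short ({x.size} samples)")
    sos = spec.sos(fs)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def trim(x: np.ndarray, fs: float, trim_s: float = DEFAULT_TRIM_S) -> np.ndarray:
    """Drop ``trim_s`` seconds from each end of the signal."""
    x = np.asarray(x)
    k = int(round(trim_s * fs))
    if x.size <= 2 * k:
        raise ValueError(
            f"trim: signal of {x.size} samples too short to trim "
            f"{trim_s} s from both ends at fs={fs}")
    return x[k:x.size - k]


def preprocess_record(record: EHGRecord,
                      spec: FilterSpec = FilterSpec(),
                      trim_s: float = DEFAULT_TRIM_S) -> EHGRecord:
    """Filter then trim every channel of a record (filter-first order, so
    the discarded ends absorb the filter transients)."""
    channels = np.stack([
        trim(bandpass(ch, record.fs, spec), record.fs, trim_s)
        for ch in record.channels
    ])
    return record.replace_channels(channels)
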