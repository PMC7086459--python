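"""Temporal filtering and epoch windowing.

Raw multichannel EEG trials are decomposed by a bank of overlapping
zero-phase Butterworth band-pass filters (the classic FBCSP front end),
after which the motor-imagery window following the cue onset is cut out.
Filtering happens before windowing so that filter edge transients fall
outside the analysed segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


#: The standard bank of ten overlapping 4-Hz bands covering mu and beta.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = tuple(
    (lo, lo + 4.0) for lo in np.arange(8.0, 27.0, 2.0)
)


@dataclass
class EpochSet:
    """Labelled multichannel trial tensor.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal in microvolts.
    labels : ndarray, shape (n_trials,)
        Per-trial class labels; exactly two distinct values (binary task).
    fs : float
        Sampling frequency in Hz.
    cue_onset_s : float
        Cue onset in seconds from trial start.
    channel_names : list of str, optional
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    cue_onset_s: float = 0.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must match trial count")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass(frozen=True)
class FilterBankSpec:
    """Zero-phase Butterworth filter-bank specification.

    ``order`` is the band-pass filter order of a single pass (default 8,
    i.e. four conjugate pole pairs); the forward–reverse application
    cancels the phase response and doubles the effective magnitude order.
    """

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    order: int = 8

    def __post_init__(self) -> None:
        for lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}) must have low < high")
        if self.order < 2 or self.order % 2:
            raise ValueError("band-pass order must be a positive even number")


def _design_sos(band: tuple[float, float], order: int, fs: float) -> np.ndarray:
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(
            f"band edge {hi} Hz violates Nyquist for fs={fs} Hz"
        )
    # scipy's butter(N, ..., 'bandpass') yields a filter of order 2N
    return signal.butter(order // 2, [lo, hi], btype="bandpass", fs=fs,
                         output="sos")


def bandpass_filter(epochs: EpochSet, band: tuple[float, float],
                    order: int = 8) -> EpochSet:
    """Zero-phase band-pass filter one epoch set.

    Forward–reverse second-order-section filtering with reflect padding;
    the effective magnitude response is the squared single-pass response
    and the phase response is identically zero.
    """
    sos = _design_sos(band, order, epochs.fs)
    # maximal reflect padding: narrow bands ring for hundreds of samples,
    # so the transient must die inside the padding, not inside the trial
    padlen = epochs.n_samples - 1
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1,
                                  padtype="even", padlen=padlen)
    return replace(epochs, data=filtered, labels=epochs.labels.copy())


def bandpass_filterbank(epochs: EpochSet,
                        spec: FilterBankSpec | None = None) -> list[EpochSet]:
    """Apply every band of the filter bank, returning one EpochSet per band."""
    spec = spec or FilterBankSpec()
    return [bandpass_filter(epochs, band, spec.order) for band in spec.bands]


def extract_mi_window(epochs: EpochSet, start_s: float = 0.0,
                      length_s: float = 3.0) -> EpochSet:
    """Cut the motor-imagery window relative to the cue onset.

    The window is half-open, ``[cue + start, cue + start + length)``, with
    the first sample at ``floor(t * fs)`` (0-based) and exactly
    ``round(length_s * fs)`` samples.  Labels are preserved in order.
    """
    if length_s <= 0:
        raise ValueError("window length must be positive")
    first = int(np.floor((epochs.cue_onset_s + start_s) * epochs.fs))
    n_out = int(round(length_s * epochs.fs))
    if first < 0 or first + n_out > epochs.n_samples:
        raise ValueError(
            f"window [{first}, {first + n_out}) overruns trial of "
            f"{epochs.n_samples} samples"
        )
    return replace(
        epochs,
        data=epochs.data[:, :, first:first + n_out].copy(),
        labels=epochs.labels.copy(),
        cue_onset_s=0.0,
    )
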