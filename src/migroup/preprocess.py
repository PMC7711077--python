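"""Filter-bank decomposition, surface Laplacian, window grids and intervals.

The analysis decomposes 4-40 Hz EEG into 17 overlapping 4 Hz bands stepped
by 2 Hz (so consecutive bands share 2 Hz), applies a small surface Laplacian
for spatial sharpening, and evaluates features on sliding-window grids.
Named intervals dT1..dT5 partition the 7 s trial into task-negative,
cue-onset, motor-imagery, decay and break periods; dT0 is the pre-cue
reference interval for baseline normalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import EEGTrialSet

__all__ = [
    "FilterBank", "WindowGrid", "IntervalRegistry",
    "build_filterbank", "bandpass", "surface_laplacian",
    "make_window_grid", "default_intervals", "rereference",
]

logger = logging.getLogger(__name__)

BETA_SPLIT_BANDS: list[tuple[float, float]] = [(16.0, 20.0), (20.0, 24.0), (24.0, 28.0)]
MU_BAND: tuple[float, float] = (8.0, 12.0)


@dataclass(frozen=True)
class FilterBank:
    bands: tuple[tuple[float, float], ...]
    f_min: float
    f_max: float
    width: float
    step: float

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def centers(self) -> np.ndarray:
        return np.asarray([(lo + hi) / 2 for lo, hi in self.bands])


def build_filterbank(f_min: float = 4.0, f_max: float = 40.0,
                     width: float = 4.0, step: float = 2.0) -> FilterBank:
    """Ordered overlapping band list covering [f_min, f_max].

    The band count is ``floor((f_max - f_min - width) / step) + 1``; with the
    defaults (4-40 Hz, 4 Hz bands, 2 Hz step) that is 17 bands whose
    neighbors overlap by 2 Hz.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    if f_min + width > f_max:
        raise ValueError("f_min + width must not exceed f_max")
    n = math.floor((f_max - f_min - width) / step) + 1
    bands = tuple((f_min + i * step, f_min + i * step + width) for i in range(n))
    return FilterBank(bands=bands, f_min=f_min, f_max=f_max, width=width, step=step)


def _band_sos(band: tuple[float, float], fs: float, order: int = 4):
    lo, hi = band
    nyq = fs / 2
    if hi >= nyq:
        raise ValueError(f"band {band} exceeds the Nyquist frequency {nyq} Hz")
    if lo <= 0:
        raise ValueError("band lower edge must be positive")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass(trials: EEGTrialSet, band: tuple[float, float], order: int = 4) -> EEGTrialSet:
    """Zero-phase Butterworth band-pass of every trial and channel."""
    sos = _band_sos(band, trials.sample_rate, order)
    out = signal.sosfiltfilt(sos, trials.data, axis=-1)
    return trials.copy_with(out)


def bandpass_array(x: np.ndarray, band: tuple[float, float], fs: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase band-pass of a bare array along its last axis."""
    return signal.sosfiltfilt(_band_sos(band, fs, order), x, axis=-1)


def surface_laplacian(trials: EEGTrialSet) -> EEGTrialSet:
    """Small surface Laplacian: each channel minus the mean of its montage neighbors.

    A channel without neighbors under the montage's radius is passed through
    unchanged and logged. Rejects montages with fewer than 5 channels, where
    a spatial high-pass is not meaningful.
    """
    m = trials.montage
    if m.n_channels < 5:
        raise ValueError("surface Laplacian requires at least 5 channels")
    # build the C x C Laplacian operator once; linear in the data
    L = np.eye(m.n_channels)
    for i in range(m.n_channels):
        nb = m.neighbors(i)
        if not nb:
            logger.warning("channel %s has no montage neighbors; passed through",
                           m.channels[i])
            continue
        L[i, nb] = -1.0 / len(nb)
    out = np.einsum("ij,njs->nis", L, trials.data)
    return trials.copy_with(out)


def rereference(trials: EEGTrialSet, reference: str = "Cz") -> EEGTrialSet:
    """Re-reference all channels to a single electrode (default Cz)."""
    ref = trials.montage.index(reference)
    out = trials.data - trials.data[:, ref:ref + 1, :]
    return trials.copy_with(out)


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window positions (start times, seconds) over a trial."""

    window_length: float
    overlap_fraction: float
    trial_span: float
    sample_rate: float
    positions: np.ndarray
    mode: str = "fixed-step"

    def __len__(self) -> int:
        return len(self.positions)

    def sample_slices(self) -> list[slice]:
        """Half-open sample index ranges [start, start + window) per position."""
        fs = self.sample_rate
        w = max(int(round(self.window_length * fs)), 1)
        n_total = int(round(self.trial_span * fs)) + 1
        out = []
        for t in self.positions:
            s = int(round(t * fs))
            out.append(slice(s, min(s + w, n_total)))
        return out


def make_window_grid(tau: float, overlap: float, trial_span: float,
                     sample_rate: float, mode: str = "fixed-step") -> WindowGrid:
    """Build a sliding-window grid.

    ``fixed-step`` starts at 0 with step tau * (1 - overlap); the last window
    lies fully inside [0, trial_span]. ``per-sample`` places one position at
    every sample instant, both endpoints inclusive, giving
    ``round(trial_span * sample_rate) + 1`` positions (1751 for a 7 s trial
    at 250 Hz).
    """
    if mode == "per-sample":
        n = int(round(trial_span * sample_rate)) + 1
        pos = np.arange(n) / sample_rate
        return WindowGrid(1.0 / sample_rate, 0.0, trial_span, sample_rate, pos, mode)
    if mode != "fixed-step":
        raise ValueError(f"unknown window mode {mode!r}")
    if tau > trial_span:
        raise ValueError("window length exceeds the trial span")
    if not 0 <= overlap < 1:
        raise ValueError("overlap fraction must be in [0, 1)")
    step = tau * (1 - overlap)
    n = math.floor((trial_span - tau) / step + 1e-9) + 1
    pos = np.arange(n) * step
    return WindowGrid(tau, overlap, trial_span, sample_rate, pos, mode)


@dataclass(frozen=True)
class IntervalRegistry:
    """Named analysis intervals (start, end) in seconds.

    dT0 is the pre-cue reference; dT1 task-negative, dT2 cue onset, dT3
    motor imagery, dT4 MI decay, dT5 break.
    """

    intervals: dict[str, tuple[float, float]]
    trial_span: float = 7.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.intervals.items():
            if not (0 <= lo < hi <= self.trial_span):
                raise ValueError(f"interval {name} = ({lo}, {hi}) outside [0, {self.trial_span}]")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.intervals[name]

    def __contains__(self, name: str) -> bool:
        return name in self.intervals

    @property
    def names(self) -> list[str]:
        return list(self.intervals)


def default_intervals(trial_span: float = 7.0) -> IntervalRegistry:
    """The standard cue-paced MI trial segmentation."""
    return IntervalRegistry(
        intervals={
            "dT0": (0.5, 1.5),
            "dT1": (0.0, 2.0),
            "dT2": (0.8, 2.0),
            "dT3": (2.6, 4.6),
            "dT4": (3.8, 5.8),
            "dT5": (4.4, 6.4),
        },
        trial_span=trial_span,
    )
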