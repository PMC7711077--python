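"""Core in-memory containers shared across the pipeline.

``EEGTrialSet`` is the universal input: a labeled trial tensor
(trials x channels x samples) with montage and sampling metadata.
``TFDynamics`` holds a per-channel activity/relevance map theta(f, tau; c)
on a (frequency band x window position) grid, optionally per class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage

__all__ = ["EEGTrialSet", "TFDynamics", "GroupDynamics"]


@dataclass
class EEGTrialSet:
    """Labeled multi-trial EEG.

    Parameters
    ----------
    data
        Array of shape (n_trials, n_channels, n_samples), in microvolts.
    labels
        One class label string per trial; exactly two distinct labels with
        at least two trials each.
    sample_rate
        Sampling frequency in Hz.
    montage
        Channel layout; channel count must match ``data``.
    subject_id
        Free-form subject identifier.
    """

    data: np.ndarray
    labels: np.ndarray
    sample_rate: float
    montage: Montage
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per trial required")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[1]} channels but montage "
                f"{self.montage.name!r} has {self.montage.n_channels}"
            )
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) != 2 or counts.min() < 2:
            raise ValueError("two classes with >= 2 trials each are required")

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
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def classes(self) -> tuple[str, str]:
        c = sorted(np.unique(self.labels).tolist())
        return (str(c[0]), str(c[1]))

    def select(self, label: str) -> np.ndarray:
        """Trial tensor restricted to one class."""
        mask = self.labels == label
        if not mask.any():
            raise ValueError(f"no trials with label {label!r}")
        return self.data[mask]

    def copy_with(self, data: np.ndarray) -> "EEGTrialSet":
        return EEGTrialSet(data=data, labels=self.labels.copy(),
                           sample_rate=self.sample_rate, montage=self.montage,
                           subject_id=self.subject_id)


@dataclass
class TFDynamics:
    """Per-channel dynamics theta(f, tau; c), optionally per label.

    ``values`` maps a label (or ``None`` for label-merged extractors such as
    CSP) to an array of shape (n_bands, n_positions, n_channels).
    """

    values: dict[str | None, np.ndarray]
    bands: list[tuple[float, float]]
    positions: np.ndarray  # window start times, seconds
    channels: tuple[str, ...]
    extractor: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        shape = (len(self.bands), len(self.positions), len(self.channels))
        for lab, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(f"values[{lab!r}] has shape {arr.shape}, expected {shape}")
            self.values[lab] = arr

    @property
    def labels(self) -> list[str | None]:
        return list(self.values)

    def position_slice(self, interval: tuple[float, float]) -> np.ndarray:
        """Indices of window positions falling inside [start, end]."""
        lo, hi = interval
        return np.flatnonzero((self.positions >= lo) & (self.positions <= hi))


@dataclass
class GroupDynamics:
    """Multi-subject aggregated dynamics with per-cell provenance.

    ``support`` counts contributing subjects per cell; cells with zero
    support are NaN in ``theta`` (undefined, not zero). ``reliable`` marks
    cells whose support reaches the aggregation's minimum-support fraction.
    """

    theta: TFDynamics
    support: dict[str | None, np.ndarray]
    reliable: dict[str | None, np.ndarray]
    subject_ids: list[str] = field(default_factory=list)
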