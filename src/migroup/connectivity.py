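"""Dynamic functional connectivity via the weighted phase lag index (wPLI).

wPLI measures the asymmetry of the phase-difference distribution between
two channels across trials, weighting each trial's phase-difference sign by
the magnitude of the imaginary cross-spectrum:

    wpli = | E_n{ |Im S_n| sgn(Im S_n) } | / E_n{ |Im S_n| }

where S_n is the per-trial cross-spectrum of Morlet wavelet coefficients.
Zero-lag (volume-conduction) coupling has a purely real cross-spectrum and
scores 0; a constant non-trivial lag scores 1. Node strength sums wPLI over
all pairs containing a channel; max-normalized per (band, window) cell it
forms the connectivity dynamics theta_phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .containers import EEGTrialSet, TFDynamics
from .preprocess import FilterBank, WindowGrid, rereference

__all__ = [
    "WaveletSpec", "ConnectivityDynamics",
    "wavelet_coefficients", "wpli_pair", "wpli_windows",
    "baseline_normalize", "node_strength", "connectivity_dynamics",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Morlet wavelet parameters (cycles >= 3 for a usable t-f trade-off)."""

    cycles: float = 7.0

    def __post_init__(self) -> None:
        if self.cycles < 3:
            raise ValueError("Morlet cycles must be >= 3")

    def support(self, freq: float) -> float:
        """Approximate one-sided wavelet support in seconds."""
        return self.cycles / (2.0 * freq)


def wavelet_coefficients(trials: EEGTrialSet, freq: float,
                         spec: WaveletSpec = WaveletSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Complex Morlet coefficients at one center frequency.

    Returns ``(coeffs, valid)``: coefficients of shape
    (n_trials, n_channels, n_samples) and a boolean per-sample mask that is
    False within one wavelet support of the trial edges (boundary-unreliable
    samples).
    """
    fs = trials.sample_rate
    if freq >= fs / 2:
        raise ValueError(f"frequency {freq} Hz at or above Nyquist")
    support = spec.support(freq)
    if 2 * support >= trials.duration:
        raise ValueError("wavelet support exceeds the trial length")
    coeffs = tfr_array_morlet(trials.data, sfreq=fs, freqs=[freq],
                              n_cycles=spec.cycles, output="complex",
                              zero_mean=True)[:, :, 0, :]
    t = np.arange(trials.n_samples) / fs
    valid = (t >= support) & (t <= trials.duration - support)
    return coeffs, valid


def wpli_pair(coeffs_a: np.ndarray, coeffs_b: np.ndarray) -> np.ndarray:
    """Trial-ensemble wPLI from two coefficient arrays (trials on axis 0).

    Any trailing axes (time, windows) are preserved. Returns 0 where the
    denominator vanishes. Requires >= 10 trials for a stable estimate.
    """
    coeffs_a, coeffs_b = np.asarray(coeffs_a), np.asarray(coeffs_b)
    if coeffs_a.shape[0] < 10:
        raise ValueError("wPLI is a trial-ensemble estimator; >= 10 trials required")
    S = coeffs_a * np.conj(coeffs_b)
    im = S.imag
    num = np.abs(im.mean(axis=0))
    den = np.abs(im).mean(axis=0)
    # a vanishing imaginary part (zero/pi lag) leaves only rounding noise in
    # im; treat the denominator as zero relative to the cross-spectrum scale
    tol = 1e-10 * np.abs(S).mean(axis=0)
    return np.divide(num, den, out=np.zeros_like(num), where=den > tol)


def _pair_list(n_channels: int, exclude: int | None = None) -> list[tuple[int, int]]:
    return [(a, b) for a in range(n_channels) for b in range(a + 1, n_channels)
            if exclude not in (a, b)]


def wpli_windows(coeffs: np.ndarray, slices: list[slice],
                 pairs: list[tuple[int, int]]) -> np.ndarray:
    """wPLI per (window, pair) with the per-trial imaginary cross-spectrum
    averaged over window samples before the trial expectation."""
    if coeffs.shape[0] < 10:
        raise ValueError("wPLI is a trial-ensemble estimator; >= 10 trials required")
    a_idx = np.asarray([a for a, _ in pairs])
    b_idx = np.asarray([b for _, b in pairs])
    out = np.zeros((len(slices), len(pairs)))
    for wi, sl in enumerate(slices):
        S = coeffs[:, a_idx, sl] * np.conj(coeffs[:, b_idx, sl])
        im = S.imag.mean(axis=-1)  # (trials, pairs)
        num = np.abs(im.mean(axis=0))
        den = np.abs(im).mean(axis=0)
        tol = 1e-10 * np.abs(S).mean(axis=(0, -1))
        out[wi] = np.divide(num, den, out=np.zeros_like(num), where=den > tol)
    return out


def baseline_normalize(phi: np.ndarray, positions: np.ndarray,
                       baseline: tuple[float, float],
                       mode: str = "divide") -> tuple[np.ndarray, np.ndarray]:
    """Normalize wPLI time-courses by their reference-interval mean.

    ``phi`` has window positions on its second-to-last axis. Returns the
    normalized array and a boolean flag per (..., pair) where the baseline
    mean was 0 (those entries keep the raw values).
    """
    sel = (positions >= baseline[0]) & (positions <= baseline[1])
    if not sel.any():
        raise ValueError("baseline interval contains no window positions")
    base = phi[..., sel, :].mean(axis=-2, keepdims=True)
    flagged = (base == 0)
    if mode == "divide":
        out = np.divide(phi, base, out=phi.copy(), where=~flagged)
    elif mode == "subtract":
        out = np.where(flagged, phi, phi - base)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return out, np.broadcast_to(flagged, phi.shape).any(axis=-2)


def node_strength(phi: np.ndarray, pairs: list[tuple[int, int]],
                  n_channels: int) -> np.ndarray:
    """Sum wPLI over all pairs containing each channel (marginal node strength).

    ``phi``'s last axis enumerates pairs; the result replaces it with a
    channel axis.
    """
    out = np.zeros(phi.shape[:-1] + (n_channels,))
    for v, (a, b) in enumerate(pairs):
        out[..., a] += phi[..., v]
        out[..., b] += phi[..., v]
    return out


@dataclass
class ConnectivityDynamics:
    """Pairwise wPLI over the (band, window) grid plus node-strength dynamics."""

    phi: dict[str, np.ndarray]            # label -> (n_bands, n_windows, n_pairs)
    phi_norm: dict[str, np.ndarray]
    pairs: list[tuple[int, int]]
    theta: TFDynamics
    baseline_flags: dict[str, np.ndarray] = field(default_factory=dict)


def connectivity_dynamics(trials: EEGTrialSet, bank: FilterBank,
                          grid: WindowGrid,
                          wavelet: WaveletSpec = WaveletSpec(),
                          reference: str | None = "Cz",
                          baseline: tuple[float, float] | None = (0.5, 1.5),
                          baseline_mode: str = "divide") -> ConnectivityDynamics:
    """Full per-label wPLI dynamics over a filter bank and window grid.

    Data are re-referenced to ``reference`` first (that channel is then
    excluded from the pair set); theta_phi is the max-normalized node
    strength of the baseline-normalized wPLI.
    """
    ref_idx = None
    if reference is not None and reference in trials.montage.channels:
        trials = rereference(trials, reference)
        ref_idx = trials.montage.index(reference)
    C = trials.n_channels
    pairs = _pair_list(C, exclude=ref_idx)
    slices = grid.sample_slices()
    labels = trials.classes
    phi = {lab: np.zeros((len(bank), len(grid), len(pairs))) for lab in labels}
    for fi, band in enumerate(bank):
        f0 = (band[0] + band[1]) / 2
        coeffs, _ = wavelet_coefficients(trials, f0, wavelet)
        for lab in labels:
            phi[lab][fi] = wpli_windows(coeffs[trials.labels == lab], slices,
                                        pairs)
    phi_norm, flags = {}, {}
    for lab in labels:
        if baseline is not None:
            phi_norm[lab], flags[lab] = baseline_normalize(
                phi[lab], grid.positions, baseline, baseline_mode)
        else:
            phi_norm[lab] = phi[lab]
            flags[lab] = np.zeros(phi[lab].shape[:-2] + phi[lab].shape[-1:], bool)
    theta_vals = {}
    for lab in labels:
        strength = node_strength(phi_norm[lab], pairs, C)
        m = strength.max(axis=-1, keepdims=True)
        theta_vals[lab] = np.divide(strength, m, out=np.zeros_like(strength),
                                    where=m > 0)
    theta = TFDynamics(values=theta_vals, bands=list(bank.bands),
                       positions=grid.positions,
                       channels=trials.montage.channels, extractor="wpli")
    return ConnectivityDynamics(phi=phi, phi_norm=phi_norm, pairs=pairs,
                                theta=theta, baseline_flags=flags)
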