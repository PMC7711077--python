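"""Event-related de/synchronization (ERD/S) dynamics.

For a band-passed channel, the instantaneous power averaged over trials,
xi(tau), is referenced to its mean over a pre-cue interval, xi_bar, giving
the relative power change

    zeta(tau) = (xi(tau) - xi_bar) / xi_bar  in  [-1, inf),

negative values marking desynchronization (ERD) and positive values
synchronization (ERS). Significance is assessed per instant by a seeded
percentile bootstrap over trials; collected over channels, zeta forms the
ERD/S dynamics theta_zeta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import EEGTrialSet, TFDynamics
from .preprocess import FilterBank, bandpass

__all__ = [
    "ERDSDynamics", "power_timecourse", "erds_map",
    "erds_significance", "erds_dynamics",
]


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average along the last axis (edges use partial windows)."""
    if width <= 1:
        return x
    kernel = np.ones(width)
    num = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), -1, x)
    den = np.convolve(np.ones(x.shape[-1]), kernel, mode="same")
    return num / den


def power_timecourse(trials: EEGTrialSet, band: tuple[float, float],
                     channel: str, label: str,
                     smooth_seconds: float = 0.0) -> np.ndarray:
    """Trial-averaged instantaneous power xi(tau) on the per-sample grid.

    Band-passes the named channel's trials of one class, squares the samples
    and averages over trials; optional moving-average smoothing.
    """
    ci = trials.montage.index(channel)
    X = trials.select(label)[:, ci, :]
    from .preprocess import bandpass_array
    Xf = bandpass_array(X, band, trials.sample_rate)
    xi = (Xf ** 2).mean(axis=0)
    if smooth_seconds > 0:
        xi = _smooth(xi, max(int(round(smooth_seconds * trials.sample_rate)), 1))
    return xi


def erds_map(xi: np.ndarray, positions: np.ndarray,
             baseline: tuple[float, float]) -> tuple[np.ndarray, float]:
    """Relative power change zeta and the reference power xi_bar.

    Raises on an identically-zero baseline (zeta undefined).
    """
    sel = (positions >= baseline[0]) & (positions <= baseline[1])
    if not sel.any():
        raise ValueError("baseline interval contains no samples")
    xi_bar = float(xi[..., sel].mean(axis=-1))
    if xi_bar == 0:
        raise ValueError("reference power is zero; zeta undefined")
    return xi / xi_bar - 1.0, xi_bar


def erds_significance(trials: EEGTrialSet, band: tuple[float, float],
                      channel: str, label: str,
                      baseline: tuple[float, float] = (0.5, 1.5),
                      alpha: float = 0.01, n_boot: int = 1000,
                      seed: int = 0,
                      smooth_seconds: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-instant bootstrap significance of zeta.

    zeta differs from 0 exactly when the trial-mean power difference
    d(tau) = xi(tau) - xi_bar does; that mean is tested with a seeded
    studentized (bootstrap-t) interval over trials, which keeps the type-I
    rate close to nominal for the skewed per-instant power values. An
    instant is significant when the two-sided interval at level ``alpha``
    excludes 0. Returns (significant mask, zeta point estimate).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    ci = trials.montage.index(channel)
    X = trials.select(label)[:, ci, :]
    n = X.shape[0]
    if n < 20:
        raise ValueError("bootstrap significance requires >= 20 trials")
    from .preprocess import bandpass_array
    P = bandpass_array(X, band, trials.sample_rate) ** 2
    if smooth_seconds > 0:
        P = _smooth(P, max(int(round(smooth_seconds * trials.sample_rate)), 1))
    t = np.arange(P.shape[-1]) / trials.sample_rate
    sel = (t >= baseline[0]) & (t <= baseline[1])
    xi = P.mean(axis=0)
    xi_bar = xi[sel].mean()
    if xi_bar == 0:
        raise ValueError("reference power is zero; zeta undefined")
    zeta = xi / xi_bar - 1.0
    # per-trial deviation from that trial's own baseline power
    d = P - P[:, sel].mean(axis=1, keepdims=True)      # (n_trials, n_samples)
    mean_d = d.mean(axis=0)
    se = d.std(axis=0, ddof=1) / np.sqrt(n)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    counts = np.zeros((n_boot, n))
    np.add.at(counts, (np.repeat(np.arange(n_boot), n), idx.ravel()), 1.0)
    bm = counts @ d / n                                 # resample means
    bs2 = counts @ d**2 / n - bm**2
    bs = np.sqrt(np.maximum(bs2, 0) * n / (n - 1)) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstar = np.where(bs > 0, (bm - mean_d) / bs, 0.0)
    tlo = np.quantile(tstar, alpha / 2, axis=0)
    thi = np.quantile(tstar, 1 - alpha / 2, axis=0)
    ci_lo = mean_d - thi * se
    ci_hi = mean_d - tlo * se
    significant = (ci_lo > 0) | (ci_hi < 0)
    return significant, zeta


@dataclass
class ERDSDynamics:
    """Per-label ERD/S maps with baseline bookkeeping and dynamics theta_zeta."""

    zeta: dict[str, np.ndarray]       # label -> (n_bands, n_samples, n_channels)
    xi_bar: dict[str, np.ndarray]     # label -> (n_bands, n_channels)
    theta: TFDynamics
    significance: dict[str, np.ndarray] | None = None


def erds_dynamics(trials: EEGTrialSet, bank: FilterBank,
                  baseline: tuple[float, float] = (0.5, 1.5),
                  smooth_seconds: float = 0.0,
                  channels: Sequence[str] | None = None) -> ERDSDynamics:
    """zeta over (band, sample, channel) per label, plus theta_zeta.

    theta_zeta keeps the signed zeta values; for topographic export use
    magnitude normalization per cell (handled at export time).
    """
    chans = tuple(channels) if channels is not None else trials.montage.channels
    positions = np.arange(trials.n_samples) / trials.sample_rate
    labels = trials.classes
    zeta = {lab: np.zeros((len(bank), trials.n_samples, len(chans))) for lab in labels}
    xi_bar = {lab: np.zeros((len(bank), len(chans))) for lab in labels}
    for fi, band in enumerate(bank):
        bp = bandpass(trials, band)
        for lab in labels:
            X = bp.select(lab)
            P = X ** 2
            if smooth_seconds > 0:
                P = _smooth(P, max(int(round(smooth_seconds * trials.sample_rate)), 1))
            xi = P.mean(axis=0)  # (C, n_samples)
            sel = (positions >= baseline[0]) & (positions <= baseline[1])
            bar = xi[:, sel].mean(axis=1)
            for k, ch in enumerate(chans):
                ci = trials.montage.index(ch)
                if bar[ci] == 0:
                    zeta[lab][fi, :, k] = np.nan
                    xi_bar[lab][fi, k] = 0.0
                else:
                    zeta[lab][fi, :, k] = xi[ci] / bar[ci] - 1.0
                    xi_bar[lab][fi, k] = bar[ci]
    theta = TFDynamics(values={lab: zeta[lab] for lab in labels},
                       bands=list(bank.bands), positions=positions,
                       channels=chans, extractor="erds")
    return ERDSDynamics(zeta=zeta, xi_bar=xi_bar, theta=theta)
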