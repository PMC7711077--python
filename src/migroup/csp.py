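"""Sliding-window, filter-band Common Spatial Patterns.

For each (band, window) cell, CSP solves

    max_w  J(w) = (w' S_l w) / (w' (S_l + S_l') w),   ||w||_2 = 1,

a generalized symmetric eigenproblem whose eigenvalues J lie in (0, 1);
J = 0.5 means no class contrast. The k largest- and k smallest-J
eigenvectors form the spatial filter matrix W; log-variance of the
projected trials gives the classification features; the first column of
the inverse (pattern) matrix, taken in absolute value and max-normalized,
gives the per-channel spatial-pattern dynamics theta_J(f, tau).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .containers import EEGTrialSet, TFDynamics
from .preprocess import FilterBank, WindowGrid, bandpass

__all__ = [
    "ClassCovariances", "SpatialFilterSet", "CSPFeatureMatrix",
    "class_covariances", "csp_fit", "csp_features",
    "csp_pattern_dynamics", "fit_dynamics", "accuracy_timecourse",
]

LOG_VARIANCE_FLOOR = 1e-20


@dataclass
class ClassCovariances:
    """Per-class spatial covariances for one (band, window) cell."""

    sigma: dict[str, np.ndarray]
    n_trials: dict[str, int]

    @property
    def classes(self) -> tuple[str, str]:
        c = sorted(self.sigma)
        return (c[0], c[1])

    @property
    def composite(self) -> np.ndarray:
        a, b = self.classes
        return self.sigma[a] + self.sigma[b]


@dataclass
class SpatialFilterSet:
    """CSP filters (rows of W), their Rayleigh quotients, and patterns.

    ``W @ W_inv`` is the identity on the retained 2k-dimensional subspace.
    ``rq_values`` are sorted descending, so column 0 of ``W_inv`` is the
    pattern of the most class-l-dominant component.
    """

    W: np.ndarray        # (2k, C), rows unit-norm
    rq_values: np.ndarray
    W_inv: np.ndarray    # (C, 2k)
    k: int


def _window_data(data: np.ndarray, window: slice | tuple[float, float] | None,
                 fs: float) -> np.ndarray:
    if window is None:
        return data
    if isinstance(window, slice):
        return data[..., window]
    lo, hi = window
    return data[..., int(round(lo * fs)): int(round(hi * fs))]


def class_covariances(trials: EEGTrialSet, window=None,
                      gamma: float | str | None = "auto") -> ClassCovariances:
    """Average per-trial X X' over each class on the window samples.

    ``gamma`` shrinks toward the scaled identity nu*I (nu = trace/C):
    a float in [0, 1], "auto" for Ledoit-Wolf estimation on the pooled
    window samples, or None/0 for the plain estimate.
    """
    sigma, counts = {}, {}
    for lab in trials.classes:
        X = _window_data(trials.select(lab), window, trials.sample_rate)
        if X.shape[0] < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 trials")
        n_samp = X.shape[-1]
        S = np.einsum("ncs,nds->cd", X, X) / (X.shape[0] * n_samp)
        if gamma == "auto":
            # Ledoit-Wolf coefficient from the pooled (samples x channels) view
            samples = X.transpose(0, 2, 1).reshape(-1, X.shape[1])
            g = float(ledoit_wolf_shrinkage(samples, assume_centered=True))
        else:
            g = float(gamma or 0.0)
        if g > 0:
            nu = np.trace(S) / S.shape[0]
            S = (1 - g) * S + g * nu * np.eye(S.shape[0])
        sigma[lab] = (S + S.T) / 2
        counts[lab] = X.shape[0]
    return ClassCovariances(sigma=sigma, n_trials=counts)


def csp_fit(cov: ClassCovariances, k: int = 3) -> SpatialFilterSet:
    """Solve S_l w = J (S_l + S_l') w and retain the k top and k bottom components.

    Rows of W are l2-normalized with the largest-magnitude entry positive;
    the pattern matrix ``W_inv`` is rescaled so W @ W_inv stays the identity
    on the retained subspace.
    """
    a, b = cov.classes
    S1, St = cov.sigma[a], cov.composite
    C = S1.shape[0]
    if 2 * k > C:
        raise ValueError(f"2k = {2 * k} exceeds the channel count {C}")
    try:
        evals, evecs = linalg.eigh(S1, St)
    except linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "composite covariance is singular; use shrinkage gamma > 0"
        ) from e
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = np.r_[np.arange(k), np.arange(C - k, C)]
    W_full_inv = linalg.inv(evecs.T)  # columns are spatial patterns
    W = evecs.T[keep]
    W_inv = W_full_inv[:, keep]
    norms = np.linalg.norm(W, axis=1)
    signs = np.sign(W[np.arange(len(keep)), np.argmax(np.abs(W), axis=1)])
    scale = signs / norms
    W = W * scale[:, None]
    W_inv = W_inv / scale[None, :]
    return SpatialFilterSet(W=W, rq_values=np.clip(evals[keep], 0.0, 1.0),
                            W_inv=W_inv, k=k)


@dataclass
class CSPFeatureMatrix:
    """Trial-by-feature log-variance matrix with its cell bookkeeping.

    ``block_index`` maps (band_index, window_index) to the column slice of
    that cell's 2k features; assembled over a full grid the column count is
    Q = n_bands * n_windows * 2k.
    """

    D: np.ndarray
    labels: np.ndarray
    block_index: dict[tuple[int, int], slice]
    k: int


def csp_features(filters: SpatialFilterSet, trials: EEGTrialSet,
                 window=None) -> np.ndarray:
    """Log-variance of the CSP-projected window samples, one row per trial."""
    X = _window_data(trials.data, window, trials.sample_rate)
    Z = np.einsum("kc,ncs->nks", filters.W, X)
    v = Z.var(axis=-1)
    return np.log(np.maximum(v, LOG_VARIANCE_FLOOR))


def csp_pattern_dynamics(filter_grid: dict[tuple[int, int], SpatialFilterSet],
                         bands: list[tuple[float, float]],
                         grid: WindowGrid,
                         channels: tuple[str, ...]) -> TFDynamics:
    """theta_J(f, tau): |first pattern column|, max-normalized per cell.

    Uses only the highest-variance component (K=1); merges both labels by
    construction of the Rayleigh quotient.
    """
    theta = np.zeros((len(bands), len(grid), len(channels)))
    for (fi, wi), fs in filter_grid.items():
        pat = np.abs(fs.W_inv[:, 0])
        m = pat.max()
        theta[fi, wi] = pat / m if m > 0 else pat
    return TFDynamics(values={None: theta}, bands=list(bands),
                      positions=grid.positions, channels=channels,
                      extractor="csp")


def fit_dynamics(trials: EEGTrialSet, bank: FilterBank, grid: WindowGrid,
                 k: int = 3, gamma="auto") -> tuple[TFDynamics, CSPFeatureMatrix]:
    """Fit CSP on every (band, window) cell; return theta_J and the feature matrix.

    The feature matrix concatenates the per-cell 2k log-variance blocks over
    the whole grid (Q = n_bands * n_windows * 2k columns).
    """
    slices = grid.sample_slices()
    filter_grid: dict[tuple[int, int], SpatialFilterSet] = {}
    blocks, block_index = [], {}
    col = 0
    for fi, band in enumerate(bank):
        bp = bandpass(trials, band)
        for wi, sl in enumerate(slices):
            cov = class_covariances(bp, window=sl, gamma=gamma)
            fs = csp_fit(cov, k=k)
            filter_grid[(fi, wi)] = fs
            feats = csp_features(fs, bp, window=sl)
            blocks.append(feats)
            block_index[(fi, wi)] = slice(col, col + feats.shape[1])
            col += feats.shape[1]
    D = np.concatenate(blocks, axis=1)
    theta = csp_pattern_dynamics(filter_grid, list(bank.bands), grid,
                                 trials.montage.channels)
    return theta, CSPFeatureMatrix(D=D, labels=trials.labels.copy(),
                                   block_index=block_index, k=k)


def _trial_covariances(trials: EEGTrialSet, bank: FilterBank,
                       slices: list[slice]) -> np.ndarray:
    """Per-trial spatial covariances, shape (n_bands, n_windows, n_trials, C, C)."""
    n, C = trials.n_trials, trials.n_channels
    out = np.empty((len(bank), len(slices), n, C, C))
    for fi, band in enumerate(bank):
        bp = bandpass(trials, band)
        for wi, sl in enumerate(slices):
            X = bp.data[..., sl]
            out[fi, wi] = np.einsum("ncs,nds->ncd", X, X) / X.shape[-1]
    return out


def accuracy_timecourse(trials: EEGTrialSet, bank: FilterBank, grid: WindowGrid,
                        k: int = 3, n_folds: int = 10, seed: int = 0,
                        gamma: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated accuracy of the CSP log-variance features per window.

    CSP filters are refit on each training fold (no test-set leakage); each
    window's feature block pools all bands at that position (n_bands * 2k
    columns). Classifier: shrinkage LDA with seeded stratified k-fold CV.
    Returns (mean, sd) of accuracy across folds per window. ``gamma`` is a
    small identity-shrinkage guard for the fold covariances.
    """
    labs = trials.labels
    classes, counts = np.unique(labs, return_counts=True)
    if counts.min() < 8:
        raise ValueError("accuracy_timecourse requires >= 8 trials per class")
    if counts.max() / counts.min() > 4:
        import warnings
        warnings.warn("class imbalance beyond 4:1; accuracies may be misleading")
    y = (labs == classes[1]).astype(int)
    slices = grid.sample_slices()
    covs = _trial_covariances(trials, bank, slices)  # (F, W, n, C, C)
    C = trials.n_channels
    eye = np.eye(C)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    n_windows = len(slices)
    fold_acc = np.zeros((n_folds, n_windows))
    for fold, (tr, te) in enumerate(cv.split(np.zeros(len(y)), y)):
        for wi in range(n_windows):
            feats = np.empty((len(y), len(bank) * 2 * k))
            for fi in range(len(bank)):
                cell = covs[fi, wi]
                sig = {}
                for lab_val in (0, 1):
                    S = cell[tr][y[tr] == lab_val].mean(axis=0)
                    nu = np.trace(S) / C
                    sig[lab_val] = (1 - gamma) * S + gamma * nu * eye
                fs = csp_fit(ClassCovariances(
                    sigma={"a": sig[0], "b": sig[1]},
                    n_trials={"a": int((y[tr] == 0).sum()),
                              "b": int((y[tr] == 1).sum())}), k=k)
                v = np.einsum("kc,ncd,kd->nk", fs.W, cell, fs.W)
                feats[:, fi * 2 * k:(fi + 1) * 2 * k] = np.log(
                    np.maximum(v, LOG_VARIANCE_FLOOR))
            clf = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
            clf.fit(feats[tr], y[tr])
            fold_acc[fold, wi] = clf.score(feats[te], y[te])
    return fold_acc.mean(axis=0), fold_acc.std(axis=0)
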