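"""Multi-subject inference on time-frequency channel dynamics.

Pipeline: per subject and frequency band, a Mann-Whitney rank test compares
a channel's dynamics between the two classes over an analysis interval
(kappa = 1 where p falls below the level); the pooled subject-by-channel
p-values are corrected with Storey's positive false discovery rate (pFDR);
group dynamics average the subject maps over the surviving cells, recording
per-cell support. Cohorts are split into BCI-literate/illiterate assemblies
by Mahalanobis trimming of a (mean, sd) accuracy predictor, and group-model
stability under subject removal is scored with a Gaussian-kernel similarity

    <eta, eta'>_sigma = exp(-||eta - eta'||^2 / sigma^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GroupDynamics, TFDynamics

__all__ = [
    "SignificanceMask", "LiteracySplit", "DesegregationCurve",
    "channel_relevance", "cohort_relevance", "pfdr_correct",
    "group_aggregate", "literacy_split", "kernel_similarity",
    "median_sigma", "desegregation_curve", "MOTOR_AREA_CHANNELS",
]

logger = logging.getLogger(__name__)

MOTOR_AREA_CHANNELS = ("C3", "Cz", "C4", "FC3", "FC4", "CP3", "CP4")

#: default spacing (s) between window positions entering the rank test;
#: positions closer than this are autocorrelated under the 4 Hz analysis
#: bandwidth and would invalidate the test's independence assumption
DECORRELATION_STRIDE = 0.25


def _subsample_positions(positions: np.ndarray, interval: tuple[float, float],
                         stride: float) -> np.ndarray:
    lo, hi = interval
    idx = np.flatnonzero((positions >= lo) & (positions <= hi))
    if len(idx) == 0:
        return idx
    keep = [idx[0]]
    for i in idx[1:]:
        if positions[i] - positions[keep[-1]] >= stride - 1e-12:
            keep.append(i)
    return np.asarray(keep)


@dataclass
class RelevanceResult:
    """Per-channel rank-test results for one (subject, band, interval) cell."""

    p_values: np.ndarray
    kappa: np.ndarray
    ks_p: np.ndarray        # normality diagnostic (pooled samples)
    bartlett_p: np.ndarray  # homoscedasticity diagnostic
    alpha: float


def channel_relevance(theta: TFDynamics, band_index: int,
                      interval: tuple[float, float], alpha: float = 0.05,
                      contrast_interval: tuple[float, float] | None = None,
                      stride: float = DECORRELATION_STRIDE,
                      min_samples: int = 8) -> RelevanceResult:
    """Mann-Whitney channel relevance over an analysis interval.

    For labeled dynamics the two classes' theta values across the interval's
    (stride-subsampled) window positions are compared per channel. For
    label-merged dynamics (CSP), ``contrast_interval`` (typically the
    task-negative pre-cue interval) supplies the comparison sample.
    Kolmogorov-Smirnov normality and Bartlett homoscedasticity diagnostics
    are recorded per channel but do not alter the test.
    """
    labels = theta.labels
    idx = _subsample_positions(theta.positions, interval, stride)
    if len(labels) == 2:
        x = theta.values[labels[0]][band_index, idx, :]
        y = theta.values[labels[1]][band_index, idx, :]
    elif labels == [None]:
        if contrast_interval is None:
            raise ValueError("label-merged dynamics need a contrast_interval")
        jdx = _subsample_positions(theta.positions, contrast_interval, stride)
        x = theta.values[None][band_index, idx, :]
        y = theta.values[None][band_index, jdx, :]
    else:
        raise ValueError("theta must carry either two labels or none")
    if x.shape[0] < min_samples or y.shape[0] < min_samples:
        raise ValueError(
            f"interval yields {min(x.shape[0], y.shape[0])} decorrelated window "
            f"samples; >= {min_samples} required")
    C = x.shape[1]
    p = np.ones(C)
    ks_p = np.ones(C)
    bart_p = np.ones(C)
    for c in range(C):
        xc, yc = x[:, c], y[:, c]
        if np.ptp(np.concatenate([xc, yc])) == 0:
            continue  # constant series: no evidence either way
        p[c] = stats.mannwhitneyu(xc, yc, alternative="two-sided").pvalue
        pooled = np.concatenate([xc, yc])
        z = (pooled - pooled.mean()) / (pooled.std() or 1.0)
        ks_p[c] = stats.kstest(z, "norm").pvalue
        if xc.std() > 0 and yc.std() > 0:
            bart_p[c] = stats.bartlett(xc, yc).pvalue
    return RelevanceResult(p_values=p, kappa=(p < alpha).astype(int),
                           ks_p=ks_p, bartlett_p=bart_p, alpha=alpha)


@dataclass
class SignificanceMask:
    """Cohort-level relevance mask kappa with raw and corrected p-values."""

    kappa: np.ndarray          # (M, C) corrected mask
    kappa_raw: np.ndarray      # (M, C) uncorrected p < alpha
    p_values: np.ndarray       # (M, C)
    q_values: np.ndarray       # (M, C)
    pi0: float
    channels: tuple[str, ...]
    diagnostics: dict = field(default_factory=dict)


def cohort_relevance(thetas: list[TFDynamics], band_index: int,
                     interval: tuple[float, float], alpha: float = 0.05,
                     q: float = 0.05,
                     contrast_interval: tuple[float, float] | None = None,
                     stride: float = DECORRELATION_STRIDE,
                     method: str = "pfdr") -> SignificanceMask:
    """Per-subject channel relevance pooled and pFDR-corrected across the cohort.

    The correction family pools all (subject, channel) p-values of the given
    (band, interval) cell.
    """
    results = [channel_relevance(t, band_index, interval, alpha,
                                 contrast_interval, stride) for t in thetas]
    P = np.stack([r.p_values for r in results])
    qv, pi0, mask = pfdr_correct(P.ravel(), q=q, method=method)
    M, C = P.shape
    return SignificanceMask(
        kappa=mask.reshape(M, C).astype(int),
        kappa_raw=np.stack([r.kappa for r in results]),
        p_values=P, q_values=qv.reshape(M, C), pi0=pi0,
        channels=thetas[0].channels,
        diagnostics={"ks_p": np.stack([r.ks_p for r in results]),
                     "bartlett_p": np.stack([r.bartlett_p for r in results])},
    )


def _storey_pi0(p: np.ndarray) -> float:
    """Storey's smoothed null-proportion estimate.

    Evaluates pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a lambda
    grid and extrapolates a cubic fit to lambda -> 1. Falls back to 1
    (Benjamini-Hochberg behavior) for small families where the smoother is
    unstable.
    """
    m = len(p)
    if m < 30:
        return 1.0
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1 - l)) for l in lam])
    coef = np.polyfit(lam, pi0_lam, 3)
    pi0 = float(np.polyval(coef, lam.max()))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def pfdr_correct(p_values: np.ndarray, q: float = 0.05,
                 method: str = "pfdr") -> tuple[np.ndarray, float, np.ndarray]:
    """Storey-style pFDR q-values and the discovery mask at level ``q``.

    Returns (q_values, pi0_hat, mask). ``method="bh"`` delegates to
    Benjamini-Hochberg (equivalent to pi0 = 1). Requires >= 10 p-values for
    the pFDR route; smaller families fall back to BH with a log record.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if method == "bh" or m < 10:
        if method != "bh":
            logger.info("family of %d p-values too small for pFDR; using BH", m)
        rej, qv, *_ = multipletests(p, alpha=q, method="fdr_bh")
        return qv, 1.0, rej
    if method != "pfdr":
        raise ValueError(f"unknown correction method {method!r}")
    pi0 = _storey_pi0(p)
    order = np.argsort(p)
    qv = np.empty(m)
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    qv[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.clip(qv, 0, 1)
    return qv, pi0, qv <= q


def group_aggregate(thetas: list[TFDynamics],
                    masks: list[np.ndarray] | None = None,
                    min_support_frac: float = 0.5) -> GroupDynamics:
    """Masked mean of subject dynamics with per-cell support counts.

    ``masks[m]`` is boolean, broadcastable to theta's (band, position,
    channel) grid (e.g. a per-channel kappa row). Cells with zero support
    are NaN; cells with support below ``ceil(min_support_frac * M)`` are
    marked unreliable.
    """
    ref = thetas[0]
    shape = (len(ref.bands), len(ref.positions), len(ref.channels))
    for i, t in enumerate(thetas[1:], 1):
        for axis, (a, b) in enumerate([(len(t.bands), shape[0]),
                                       (len(t.positions), shape[1]),
                                       (len(t.channels), shape[2])]):
            if a != b:
                name = ["band", "position", "channel"][axis]
                raise ValueError(f"subject {i} grid mismatch on the {name} axis")
    M = len(thetas)
    if masks is None:
        masks = [np.ones(shape, bool)] * M
    min_support = math.ceil(min_support_frac * M)
    out_vals, out_support, out_reliable = {}, {}, {}
    for lab in ref.labels:
        acc = np.zeros(shape)
        sup = np.zeros(shape)
        for t, mk in zip(thetas, masks):
            mk = np.broadcast_to(np.asarray(mk, bool), shape)
            v = np.nan_to_num(t.values[lab], nan=0.0)
            acc += np.where(mk, v, 0.0)
            sup += mk
        with np.errstate(invalid="ignore"):
            mean = np.where(sup > 0, acc / np.maximum(sup, 1), np.nan)
        out_vals[lab] = mean
        out_support[lab] = sup.astype(int)
        out_reliable[lab] = sup >= min_support
    theta = TFDynamics(values=out_vals, bands=list(ref.bands),
                       positions=ref.positions, channels=ref.channels,
                       extractor=ref.extractor)
    return GroupDynamics(theta=theta, support=out_support,
                         reliable=out_reliable,
                         subject_ids=[f"m{i}" for i in range(M)])


@dataclass
class LiteracySplit:
    """Mahalanobis-trimmed split of a cohort into literate/illiterate sets."""

    literate: list[int]
    illiterate: list[int]
    predictor_points: np.ndarray   # (M, 2): per-subject (mean, sd) accuracy
    distances: np.ndarray
    trimmed: list[int]
    accuracy_cut: float


def literacy_split(predictor_points: np.ndarray,
                   trim_fraction: float = 0.10) -> LiteracySplit:
    """Split subjects by the Mahalanobis-trimmed accuracy predictor.

    The ``ceil(trim_fraction * M)`` subjects farthest (Mahalanobis) from the
    (mean, sd)-accuracy center are trimmed; the assignment cut is the mean
    accuracy of the retained subjects, and every subject strictly below it
    is illiterate. A singular predictor covariance falls back to
    standardized Euclidean distance; distance ties are broken toward the
    higher subject index.
    """
    pts = np.asarray(predictor_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("predictor_points must be (M, 2) of (mean, sd) accuracy")
    M = pts.shape[0]
    if M < 5:
        raise ValueError("literacy split requires at least 5 subjects")
    center = pts.mean(axis=0)
    dev = pts - center
    cov = np.cov(pts, rowvar=False)
    try:
        VI = np.linalg.inv(cov)
        d = np.sqrt(np.einsum("ij,jk,ik->i", dev, VI, dev))
        if not np.all(np.isfinite(d)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        logger.warning("singular predictor covariance; using standardized Euclidean")
        sd = pts.std(axis=0)
        sd[sd == 0] = 1.0
        d = np.linalg.norm(dev / sd, axis=1)
    n_trim = math.ceil(trim_fraction * M)
    # ties broken toward the higher subject index
    order = sorted(range(M), key=lambda i: (d[i], i), reverse=True)
    trimmed = sorted(order[:n_trim])
    retained = [i for i in range(M) if i not in trimmed]
    cut = float(pts[retained, 0].mean())
    illiterate = [i for i in range(M) if pts[i, 0] < cut]
    literate = [i for i in range(M) if i not in illiterate]
    return LiteracySplit(literate=literate, illiterate=illiterate,
                         predictor_points=pts, distances=d,
                         trimmed=trimmed, accuracy_cut=cut)


def kernel_similarity(eta: np.ndarray, eta_prime: np.ndarray,
                      sigma: float) -> float:
    """Gaussian-kernel similarity exp(-||eta - eta'||^2 / sigma^2) in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    eta = np.asarray(eta, float).ravel()
    eta_prime = np.asarray(eta_prime, float).ravel()
    if eta.shape != eta_prime.shape:
        raise ValueError("vectors must have equal length")
    d2 = float(np.sum((eta - eta_prime) ** 2))
    return float(np.exp(-d2 / sigma ** 2))


def median_sigma(vectors: list[np.ndarray]) -> float:
    """Median pairwise Euclidean distance (the standard kernel-width heuristic).

    Returns 1.0 when all vectors coincide (any sigma then gives similarity 1).
    """
    arr = np.stack([np.asarray(v, float).ravel() for v in vectors])
    dists = [np.linalg.norm(arr[i] - arr[j])
             for i in range(len(arr)) for j in range(i + 1, len(arr))]
    med = float(np.median(dists)) if dists else 0.0
    # distances at rounding-noise level mean the vectors coincide
    floor = 1e-9 * max(float(np.abs(arr).max()), 1.0)
    return med if med > floor else 1.0


@dataclass
class DesegregationCurve:
    """Group models after successive worst-subject removal, with similarities."""

    removed_counts: list[int]
    models: list[GroupDynamics]
    vectors: list[np.ndarray]
    similarity_to_full: list[float]
    pairwise: np.ndarray
    sigma: float
    removal_order: list[int]


def _model_vector(gd: GroupDynamics, interval: tuple[float, float],
                  channel_subset: tuple[str, ...]) -> np.ndarray:
    th = gd.theta
    pos = th.position_slice(interval)
    ch_idx = [th.channels.index(c) for c in channel_subset if c in th.channels]
    parts = []
    for lab in th.labels:
        v = th.values[lab][:, pos][:, :, ch_idx]
        parts.append(np.nan_to_num(v, nan=0.0).ravel())
    return np.concatenate(parts)


def desegregation_curve(thetas: list[TFDynamics],
                        accuracies: np.ndarray,
                        interval: tuple[float, float],
                        channel_subset: tuple[str, ...] = MOTOR_AREA_CHANNELS,
                        masks: list[np.ndarray] | None = None,
                        sigma: float | None = None,
                        min_support_frac: float = 0.5) -> DesegregationCurve:
    """Group models with the worst-accuracy subjects removed one by one.

    Model r excludes the r lowest-accuracy subjects; each model is compared
    (Gaussian kernel, restricted to the MI-interval cells of the
    motor-area channel subset) to the full-cohort model, and pairwise
    between all models. The curve truncates when fewer than 3 subjects
    would remain. ``sigma`` defaults to the median pairwise distance among
    the model vectors.
    """
    M = len(thetas)
    accuracies = np.asarray(accuracies, float)
    if len(accuracies) != M:
        raise ValueError("one accuracy per subject required")
    removal_order = list(np.argsort(accuracies, kind="stable"))  # worst first
    max_removed = M - 3
    if max_removed < 0:
        raise ValueError("desegregation requires at least 3 subjects")
    models, vectors, counts = [], [], []
    for r in range(max_removed + 1):
        removed = set(removal_order[:r])
        keep = [i for i in range(M) if i not in removed]
        sub_masks = None if masks is None else [masks[i] for i in keep]
        gd = group_aggregate([thetas[i] for i in keep], sub_masks,
                             min_support_frac)
        models.append(gd)
        vectors.append(_model_vector(gd, interval, channel_subset))
        counts.append(r)
    if max_removed < M - 3:
        logger.info("desegregation curve truncated at %d removals", max_removed)
    if sigma is None:
        sigma = median_sigma(vectors)
    sims = [kernel_similarity(v, vectors[0], sigma) for v in vectors]
    n = len(vectors)
    pairwise = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pairwise[i, j] = pairwise[j, i] = kernel_similarity(
                vectors[i], vectors[j], sigma)
    return DesegregationCurve(removed_counts=counts, models=models,
                              vectors=vectors, similarity_to_full=sims,
                              pairwise=pairwise, sigma=sigma,
                              removal_order=removal_order)
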