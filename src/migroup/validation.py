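"""End-to-end validation benchmarks on synthetic cohorts with known truth.

Each function regenerates its inputs from a seed, runs the corresponding
pipeline stage, and returns the measured quantities. They double as the
package's reproducibility suite: the problem sizes are fixed study
conditions (documented in docs/methods.md), not tunables.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.optimize import minimize

from .connectivity import wavelet_coefficients, wpli_pair, wpli_windows
from .containers import EEGTrialSet
from .csp import ClassCovariances, csp_fit
from .erds import erds_dynamics, erds_significance, erds_map, power_timecourse
from .group import (cohort_relevance, desegregation_curve, group_aggregate,
                    kernel_similarity)
from .preprocess import (FilterBank, build_filterbank, default_intervals,
                         make_window_grid)
from .synth import (CouplingPlant, ERDPlant, SynthSpec, default_cohort_spec,
                    expected_zeta, generate_cohort, generate_subject)

MU = FilterBank(bands=((8.0, 12.0),), f_min=8, f_max=12, width=4, step=2)


def _seed_int(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# configuration-derived counts

def filterbank_band_count() -> int:
    """Bands in the canonical 4-40 Hz bank (4 Hz width, 2 Hz step)."""
    return len(build_filterbank(4, 40, 4, 2))


def per_sample_grid_count() -> int:
    """Positions of the per-sample window grid over a 7 s trial at 250 Hz."""
    return len(make_window_grid(0.004, 0.0, 7.0, 250.0, mode="per-sample"))


# ---------------------------------------------------------------------------
# CSP eigen-solution vs direct Rayleigh-quotient maximization

def brute_force_max_rq(S1: np.ndarray, St: np.ndarray,
                       n_restarts: int = 20, seed: int = 0) -> float:
    """Independent oracle: multi-start direct maximization of
    w'S1w / w'Stw on the unit sphere (no eigendecomposition)."""
    rng = np.random.default_rng(seed)
    C = S1.shape[0]

    def neg_rq(w):
        w = w / np.linalg.norm(w)
        return -(w @ S1 @ w) / (w @ St @ w)

    best = -np.inf
    for _ in range(n_restarts):
        res = minimize(neg_rq, rng.standard_normal(C), method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 3000})
        best = max(best, -res.fun)
    return best


def csp_oracle_check(seed: int = 0, n_pairs: int = 102) -> dict:
    """Max |J_eigen - J_brute-force| over random SPD pairs (C in 2..4), plus
    the J value under equal class covariances (exactly 0.5 by symmetry)."""
    rng = np.random.default_rng(_seed_int(seed, 1))
    errs = []
    per_c = int(np.ceil(n_pairs / 3))
    for C in (2, 3, 4):
        for rep in range(per_c):
            A, B = rng.standard_normal((2, C, C))
            S1 = A @ A.T + 0.1 * np.eye(C)
            S2 = B @ B.T + 0.1 * np.eye(C)
            cov = ClassCovariances(sigma={"a": S1, "b": S2},
                                   n_trials={"a": 10, "b": 10})
            j_eig = csp_fit(cov, k=1).rq_values[0]
            j_bf = brute_force_max_rq(S1, S1 + S2, seed=rep)
            errs.append(abs(j_eig - j_bf))
    A = rng.standard_normal((4, 4))
    S = A @ A.T + np.eye(4)
    cov_eq = ClassCovariances(sigma={"a": S, "b": S.copy()},
                              n_trials={"a": 10, "b": 10})
    j_eq = csp_fit(cov_eq, k=1).rq_values[0]
    return {"n_pairs": 3 * per_c, "max_error": float(max(errs)),
            "j_equal_covariances": float(j_eq)}


# ---------------------------------------------------------------------------
# wPLI limits

def wpli_limit_checks(seed: int = 0, n_null: int = 500,
                      n_trials: int = 200) -> dict:
    """Constant-lag limits and the finite-trial null of the wPLI estimator.

    The pi/2-lag value is measured end to end: a planted full-strength
    coupled pair, Morlet coefficients, window-averaged cross-spectra. The
    zero-lag limit uses equal-phase unit phasors (the exact-cancellation
    case). The null draws independent uniform phases per trial.
    """
    spec = SynthSpec(
        n_subjects=1, n_trials_per_class=n_trials // 2, subject_jitter=0.0,
        coupling_plants=(CouplingPlant(("C3", "CP3"), (8, 12), (2.6, 4.6),
                                       np.pi / 2, 1.0),),
        seed=_seed_int(seed, 2))
    s = generate_subject(spec, 0)
    coeffs, _ = wavelet_coefficients(s, 10.0)
    grid = make_window_grid(0.1, 0.0, 7.0, 250.0)
    a, b = s.montage.index("C3"), s.montage.index("CP3")
    phi = wpli_windows(coeffs[:, [a, b], :], grid.sample_slices(), [(0, 1)])
    in_task = (grid.positions >= 2.8) & (grid.positions + 0.1 <= 4.4)
    lag_value = float(phi[in_task, 0].mean())

    rng = np.random.default_rng(_seed_int(seed, 3))
    ph = rng.uniform(0, 2 * np.pi, n_trials)
    zero_lag = float(wpli_pair(np.exp(1j * ph)[:, None],
                               np.exp(1j * ph)[:, None])[0])

    nulls = np.empty(n_null)
    for i in range(n_null):
        pa = rng.uniform(0, 2 * np.pi, n_trials)
        pb = rng.uniform(0, 2 * np.pi, n_trials)
        nulls[i] = wpli_pair(np.exp(1j * pa)[:, None],
                             np.exp(1j * pb)[:, None])[0]
    return {"lag_pi_half": lag_value, "zero_lag": zero_lag,
            "null_below_015": float(np.mean(nulls < 0.15)),
            "null_median": float(np.median(nulls)), "n_null": n_null}


# ---------------------------------------------------------------------------
# ERD recovery and significance calibration

def erd_recovery_check(seed: int = 0, n_trials: int = 200) -> dict:
    """Recover a planted depth -0.5 mu ERD at C3 in the MI interval."""
    spec = SynthSpec(
        n_subjects=1, n_trials_per_class=n_trials, subject_jitter=0.0,
        erd_plants=(ERDPlant("C3", (8, 12), (2.6, 4.6), -0.5, "right"),),
        seed=_seed_int(seed, 4))
    s = generate_subject(spec, 0)
    xi = power_timecourse(s, (8, 12), "C3", "right")
    pos = np.arange(s.n_samples) / s.sample_rate
    zeta, _ = erds_map(xi, pos, (0.5, 1.5))
    cell = float(zeta[(pos >= 2.8) & (pos <= 4.4)].mean())
    return {"recovered_zeta": cell, "planted_depth": -0.5,
            "expected_zeta": expected_zeta(spec, -0.5), "n_trials": n_trials}


def erds_type1_check(seed: int = 0, alpha: float = 0.01,
                     n_subjects: int = 10, n_trials: int = 100) -> dict:
    """Empirical type-I rate of the significance mask on plant-free subjects.

    Cells are (subject, label, channel, instant) with instants 0.5 s apart
    (beyond the band's power autocorrelation length).
    """
    rej = []
    channels = ("C3", "Cz", "C4", "FC3", "CP4")
    for m in range(n_subjects):
        spec = SynthSpec(n_subjects=1, n_trials_per_class=n_trials,
                         subject_jitter=0.0, seed=_seed_int(seed, 50 + m))
        s = generate_subject(spec, 0)
        t = np.arange(s.n_samples) / s.sample_rate
        idx = np.arange(s.n_samples)[(t > 1.8) & (t < 6.5)][::125][:10]
        for ch in channels:
            for lab in ("left", "right"):
                sig, _ = erds_significance(s, (8, 12), ch, lab, alpha=alpha,
                                           seed=_seed_int(seed, 900 + m))
                rej.extend(sig[idx].tolist())
    return {"type1_rate": float(np.mean(rej)), "alpha": alpha,
            "n_cells": len(rej)}


# ---------------------------------------------------------------------------
# relevance thresholding + pFDR

def relevance_calibration_check(seed: int = 0, n_cohorts: int = 3,
                                q: float = 0.05) -> dict:
    """Corrected discovery proportion on plant-free cohorts and per-channel
    detection power on the canonical planted cohort."""
    ivl = default_intervals()["dT3"]
    null_prop = []
    for c in range(n_cohorts):
        spec = SynthSpec(n_subjects=9, n_trials_per_class=40,
                         subject_jitter=0.0, seed=_seed_int(seed, 100 + c))
        subs, _ = generate_cohort(spec)
        thetas = [erds_dynamics(s, MU).theta for s in subs]
        mask = cohort_relevance(thetas, 0, ivl, alpha=0.05, q=q)
        null_prop.append(mask.kappa.mean())
    spec = default_cohort_spec(seed=_seed_int(seed, 5))
    subs, truth = generate_cohort(spec)
    thetas = [erds_dynamics(s, MU).theta for s in subs]
    mask = cohort_relevance(thetas, 0, ivl, alpha=0.05, q=q)
    c3 = thetas[0].channels.index("C3")
    c4 = thetas[0].channels.index("C4")
    power = float(mask.kappa[:, [c3, c4]].mean())
    return {"null_discovery_proportion": float(np.mean(null_prop)),
            "n_null_cells": n_cohorts * 9 * 22,
            "plant_power": power, "q": q}


# ---------------------------------------------------------------------------
# group recovery and desegregation

def _group_argmin_channel(thetas, mask, interval) -> str:
    masks = [np.broadcast_to(mask.kappa[m].astype(bool),
                             (len(thetas[m].bands), len(thetas[m].positions),
                              len(mask.channels)))
             for m in range(len(thetas))]
    gd = group_aggregate(thetas, masks)
    sel = gd.theta.position_slice(interval)
    cell = gd.theta.values["right"][0, sel]
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col = np.nanmean(cell, axis=0)
    col = np.where(np.isnan(col), 0.0, col)  # unsupported channels: no ERD
    return gd.theta.channels[int(np.argmin(col))]  # deepest group ERD


def group_recovery_check(seed: int = 0, n_runs: int = 20) -> dict:
    """Fraction of cohorts whose group ERD model peaks at the planted channel.

    Study conditions: M = 9, 72 trials/class, contralateral C3 plant for
    right-hand trials, log-normal subject jitter.
    """
    ivl = default_intervals()["dT3"]
    hits = 0
    for r in range(n_runs):
        spec = default_cohort_spec(seed=_seed_int(seed, 200 + r))
        subs, _ = generate_cohort(spec)
        thetas = [erds_dynamics(s, MU).theta for s in subs]
        mask = cohort_relevance(thetas, 0, ivl, alpha=0.05, q=0.05)
        hits += _group_argmin_channel(thetas, mask, ivl) == "C3"
    return {"argmax_hit_rate": hits / n_runs, "n_runs": n_runs}


def desegregation_check(seed: int = 0, n_seeds: int = 20) -> dict:
    """Similarity to the clean-subgroup model while removing 3 null subjects.

    Cohorts mix 6 planted subjects with 3 plant-free ones ranked worst by
    accuracy; the kernel similarity of the leave-worst-out group models to
    the clean-subgroup model should not decrease as the null subjects leave.
    """
    monotone = 0
    curves = []
    for r in range(n_seeds):
        spec = default_cohort_spec(seed=_seed_int(seed, 300 + r),
                                   n_subjects=6, n_trials_per_class=30,
                                   subject_jitter=0.0)
        clean, _ = generate_cohort(spec)
        null_spec = replace(spec, erd_plants=(), n_subjects=3,
                            seed=_seed_int(seed, 600 + r))
        nulls, _ = generate_cohort(null_spec)
        cohort = clean + nulls
        thetas = [erds_dynamics(s, MU).theta for s in cohort]
        acc = np.array([0.9] * 6 + [0.5] * 3)
        curve = desegregation_curve(thetas, acc, default_intervals()["dT3"],
                                    channel_subset=("C3", "Cz", "C4"))
        ref = curve.vectors[3]  # all three null subjects removed
        sims = [kernel_similarity(v, ref, curve.sigma)
                for v in curve.vectors[:4]]
        curves.append(sims)
        monotone += all(a <= b + 1e-12 for a, b in zip(sims, sims[1:]))
    mean_curve = np.mean(curves, axis=0)
    return {"monotone_fraction": monotone / n_seeds,
            "mean_curve": [float(x) for x in mean_curve],
            "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# kernel similarity unit values

def kernel_unit_checks() -> dict:
    v = np.arange(6.0)
    w = v.copy()
    w[0] += 1.5  # distance exactly sigma
    ladder = [kernel_similarity(v, v + d, sigma=2.0) for d in (0.5, 1.0, 2.0, 4.0)]
    return {"self_similarity": kernel_similarity(v, v, sigma=1.5),
            "at_sigma": kernel_similarity(v, w, sigma=1.5),
            "ladder_strictly_decreasing": bool(
                all(a > b for a, b in zip(ladder, ladder[1:]))),
            "symmetric": kernel_similarity(v, w, 1.5) == kernel_similarity(w, v, 1.5)}
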