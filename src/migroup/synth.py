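"""Synthetic multi-subject motor-imagery EEG cohorts with known ground truth.

Each trial is 1/f-shaped Gaussian background noise plus amplitude-modulated
sinusoidal oscillations. Two kinds of effects can be planted:

* **ERD/S plants** — a band-limited oscillator on one channel whose amplitude
  is scaled by ``sqrt(1 + depth * subject_gain)`` inside a time interval for
  one class, so the planted band-power change relative to baseline equals
  ``depth * subject_gain`` exactly (the generator is its own oracle for the
  downstream relative-power estimate).
* **Coupling plants** — a shared oscillator injected into a channel pair with
  a fixed phase lag; the second channel mixes the shared oscillator (weight
  ``strength``) with an independent one (weight ``1 - strength``), so a
  phase-lag-index estimate approaches 1 as strength approaches 1.

Per-subject effect sizes are jittered by a log-normal gain. All randomness
derives from ``numpy.random.SeedSequence(seed, spawn_key=(subject, stream))``,
so cohorts are bit-reproducible and invariant to subject re-ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import EEGTrialSet
from .montage import Montage, get_montage
from .preprocess import MU_BAND

__all__ = [
    "ERDPlant", "CouplingPlant", "SynthSpec", "SynthTruth",
    "generate_subject", "generate_cohort", "default_cohort_spec",
]


@dataclass(frozen=True)
class ERDPlant:
    """Class-conditional band-power modulation on one channel.

    ``depth`` is the fractional power change versus baseline (-0.5 means the
    in-band power halves inside the interval); must be >= -1. ``label`` is
    the class the modulation applies to (None modulates both classes).
    """

    channel: str
    band: tuple[float, float]
    interval: tuple[float, float]
    depth: float
    label: str | None = "right"


@dataclass(frozen=True)
class CouplingPlant:
    """Phase-lagged coupling between a channel pair inside an interval."""

    pair: tuple[str, str]
    band: tuple[float, float]
    interval: tuple[float, float]
    phase_lag: float
    strength: float
    label: str | None = None


@dataclass(frozen=True)
class SynthSpec:
    """Cohort-level generation parameters (the study conditions).

    ``snr_db`` is the in-band oscillation-to-background power ratio;
    ``subject_jitter`` is the sigma of the log-normal per-subject gain on
    planted effect sizes; ``noise_exponent`` is the 1/f^alpha slope of the
    background.
    """

    n_subjects: int = 9
    n_trials_per_class: int = 72
    n_channels: int = 22
    sample_rate: float = 250.0
    trial_duration: float = 7.0
    montage_name: str = "mi22"
    erd_plants: tuple[ERDPlant, ...] = ()
    coupling_plants: tuple[CouplingPlant, ...] = ()
    subject_jitter: float = 0.2
    noise_exponent: float = 1.0
    snr_db: float = 20.0
    labels: tuple[str, str] = ("left", "right")
    seed: int = 0

    @property
    def montage(self) -> Montage:
        return get_montage(self.montage_name, self.n_channels)

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sample_rate)) + 1

    def validate(self) -> None:
        mont = self.montage
        for p in self.erd_plants:
            if p.depth < -1:
                raise ValueError(f"ERD depth {p.depth} < -1: power cannot go below zero")
            self._check_plant(p, mont)
        for p in self.coupling_plants:
            if not 0 <= p.strength <= 1:
                raise ValueError(f"coupling strength {p.strength} outside [0, 1]")
            for ch in p.pair:
                mont.index(ch)
            self._check_interval(p.interval)
            self._check_band(p.band)

    def _check_plant(self, p: ERDPlant, mont: Montage) -> None:
        mont.index(p.channel)
        self._check_interval(p.interval)
        self._check_band(p.band)
        if p.label is not None and p.label not in self.labels:
            raise ValueError(f"plant label {p.label!r} not among {self.labels}")

    def _check_interval(self, interval: tuple[float, float]) -> None:
        lo, hi = interval
        if not (0 <= lo < hi <= self.trial_duration):
            raise ValueError(f"plant interval {interval} outside [0, {self.trial_duration}]")

    def _check_band(self, band: tuple[float, float]) -> None:
        lo, hi = band
        if not (0 < lo < hi < self.sample_rate / 2):
            raise ValueError(f"plant band {band} outside (0, Nyquist)")


@dataclass
class SynthTruth:
    """Planted ground truth for recovery tests.

    ``erd_map`` has one entry per (subject, ERD plant) with the effective
    depth (``depth * gain``, floored at -1) and the expected relative power
    change after accounting for the in-band noise floor. ``wpli_map`` has
    one entry per (subject, coupling plant).
    """

    erd_map: list[dict] = field(default_factory=list)
    wpli_map: list[dict] = field(default_factory=list)
    discriminative_channels: set[str] = field(default_factory=set)
    subject_gains: list[float] = field(default_factory=list)


def _noise_shape(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude response H_k on rfft bins (unit output variance) and bin weights."""
    n = spec.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sample_rate)
    H = np.maximum(freqs, 1.0) ** (-spec.noise_exponent / 2.0)
    H[0] = 0.0  # zero-mean background
    w = np.full(len(freqs), 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    # white input of unit variance -> output variance (1/n) sum w_k H_k^2
    H /= np.sqrt((w * H**2).sum() / n)
    return H, w


def noise_band_fraction(spec: SynthSpec, band: tuple[float, float]) -> float:
    """Fraction of background noise power lying inside ``band``."""
    H, w = _noise_shape(spec)
    freqs = np.fft.rfftfreq(spec.n_samples, d=1.0 / spec.sample_rate)
    total = (w * H**2).sum()
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float((w[sel] * H[sel]**2).sum() / total)


def oscillation_amplitude(spec: SynthSpec, band: tuple[float, float]) -> float:
    """Sinusoid amplitude giving ``snr_db`` oscillation-to-background in-band ratio."""
    p_noise = noise_band_fraction(spec, band)  # background has unit total variance
    return float(np.sqrt(2.0 * 10 ** (spec.snr_db / 10.0) * p_noise))


def expected_zeta(spec: SynthSpec, depth_eff: float) -> float:
    """Relative power change a band-power estimator should recover.

    The estimate includes the in-band noise floor, shrinking the planted
    depth by s/(1+s) where s is the linear in-band SNR.
    """
    s = 10 ** (spec.snr_db / 10.0)
    return depth_eff * s / (1.0 + s)


def _subject_rng(spec: SynthSpec, subject_index: int, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(subject_index, stream))
    return np.random.default_rng(ss)


def subject_gain(spec: SynthSpec, subject_index: int) -> float:
    """Log-normal per-subject multiplicative effect-size gain (median 1)."""
    if spec.subject_jitter == 0:
        return 1.0
    rng = _subject_rng(spec, subject_index, 0)
    return float(np.exp(rng.normal(0.0, spec.subject_jitter)))


def _interval_mask(spec: SynthSpec, interval: tuple[float, float]) -> np.ndarray:
    t = np.arange(spec.n_samples) / spec.sample_rate
    return (t >= interval[0]) & (t <= interval[1])


def generate_subject(spec: SynthSpec, subject_index: int) -> EEGTrialSet:
    """Generate one subject's labeled trial set.

    Trials are ordered first class then second class (labels carry the class;
    downstream code never relies on ordering).
    """
    spec.validate()
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(f"subject_index {subject_index} outside [0, {spec.n_subjects})")
    rng = _subject_rng(spec, subject_index, 1)
    gain = subject_gain(spec, subject_index)
    mont = spec.montage
    n_per, n_samp, C = spec.n_trials_per_class, spec.n_samples, spec.n_channels
    n_trials = 2 * n_per
    labels = np.asarray([spec.labels[0]] * n_per + [spec.labels[1]] * n_per)
    t = np.arange(n_samp) / spec.sample_rate

    # 1/f^alpha background, unit variance, independent per trial and channel
    H, _ = _noise_shape(spec)
    white = rng.standard_normal((n_trials, C, n_samp))
    data = np.fft.irfft(np.fft.rfft(white, axis=-1) * H, n=n_samp, axis=-1)

    for p in spec.erd_plants:
        ci = mont.index(p.channel)
        f0 = (p.band[0] + p.band[1]) / 2.0
        amp = oscillation_amplitude(spec, p.band)
        depth_eff = max(p.depth * gain, -1.0)
        mask = _interval_mask(spec, p.interval)
        phase = rng.uniform(0, 2 * np.pi, size=n_trials)
        osc = np.cos(2 * np.pi * f0 * t[None, :] + phase[:, None])
        env = np.ones((n_trials, n_samp))
        modulated = p.label is None or labels == p.label
        env[np.ix_(np.flatnonzero(modulated), np.flatnonzero(mask))] = np.sqrt(1.0 + depth_eff)
        data[:, ci, :] += amp * env * osc

    for p in spec.coupling_plants:
        ai, bi = mont.index(p.pair[0]), mont.index(p.pair[1])
        f0 = (p.band[0] + p.band[1]) / 2.0
        amp = oscillation_amplitude(spec, p.band)
        mask = _interval_mask(spec, p.interval).astype(float)
        applies = np.ones(n_trials, bool) if p.label is None else labels == p.label
        phase = rng.uniform(0, 2 * np.pi, size=n_trials)
        phase_b = rng.uniform(0, 2 * np.pi, size=n_trials)
        theta = 2 * np.pi * f0 * t[None, :] + phase[:, None]
        shared_b = np.cos(theta + p.phase_lag)
        indep_b = np.cos(2 * np.pi * f0 * t[None, :] + phase_b[:, None])
        a_osc = amp * mask[None, :] * np.cos(theta)
        b_osc = amp * mask[None, :] * (p.strength * shared_b + (1 - p.strength) * indep_b)
        data[applies, ai, :] += a_osc[applies]
        data[applies, bi, :] += b_osc[applies]

    return EEGTrialSet(data=data, labels=labels, sample_rate=spec.sample_rate,
                       montage=mont, subject_id=f"S{subject_index + 1:02d}")


def generate_cohort(spec: SynthSpec) -> tuple[list[EEGTrialSet], SynthTruth]:
    """Generate all subjects plus the planted ground truth."""
    spec.validate()
    subjects = [generate_subject(spec, m) for m in range(spec.n_subjects)]
    truth = SynthTruth()
    for m in range(spec.n_subjects):
        g = subject_gain(spec, m)
        truth.subject_gains.append(g)
        for p in spec.erd_plants:
            depth_eff = max(p.depth * g, -1.0)
            truth.erd_map.append({
                "subject": m, "channel": p.channel, "band": p.band,
                "interval": p.interval, "label": p.label,
                "depth_eff": depth_eff,
                "expected_zeta": expected_zeta(spec, depth_eff),
            })
        for p in spec.coupling_plants:
            truth.wpli_map.append({
                "subject": m, "pair": p.pair, "band": p.band,
                "interval": p.interval, "label": p.label,
                "phase_lag": p.phase_lag, "strength": p.strength,
                "expected_wpli": 1.0 if p.strength == 1.0 else None,
            })
    truth.discriminative_channels = {
        p.channel for p in spec.erd_plants if p.label is not None
    } | {c for p in spec.coupling_plants if p.label is not None for c in p.pair}
    return subjects, truth


def default_cohort_spec(seed: int = 0, **overrides) -> SynthSpec:
    """The canonical study conditions: contralateral mu-band ERD plants.

    Right-hand imagery depresses C3 power by 50% during the MI interval
    (2.6-4.6 s), left-hand imagery depresses C4, matching the contralateral
    dominance the method is designed to recover.
    """
    plants = (
        ERDPlant("C3", MU_BAND, (2.6, 4.6), -0.5, label="right"),
        ERDPlant("C4", MU_BAND, (2.6, 4.6), -0.5, label="left"),
    )
    base = SynthSpec(erd_plants=plants, seed=seed)
    return replace(base, **overrides) if overrides else base
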