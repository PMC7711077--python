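import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from migroup.connectivity import (WaveletSpec, baseline_normalize,
                                  connectivity_dynamics, node_strength,
                                  wavelet_coefficients, wpli_pair,
                                  wpli_windows)
from migroup.containers import EEGTrialSet
from migroup.preprocess import FilterBank, make_window_grid
from migroup.synth import CouplingPlant, SynthSpec, generate_subject


def phasors(phases, amplitudes=1.0):
    """Direct construction of single-sample complex coefficients per trial."""
    return (np.asarray(amplitudes) * np.exp(1j * np.asarray(phases)))[:, None]


class TestWaveletCoefficients:
    def test_phase_advances_at_carrier_rate(self, mi22):
        fs, f0 = 250.0, 10.0
        t = np.arange(1751) / fs
        data = np.tile(np.cos(2 * np.pi * f0 * t), (4, 22, 1))
        trials = EEGTrialSet(data=data, labels=np.array(["l", "l", "r", "r"]),
                             sample_rate=fs, montage=mi22)
        co, valid = wavelet_coefficients(trials, f0)
        ph = np.unwrap(np.angle(co[0, 0, valid]))
        rate = np.polyfit(t[valid], ph, 1)[0] / (2 * np.pi)
        assert abs(rate - f0) / f0 < 0.01

    def test_magnitude_tracks_envelope(self, mi22):
        fs, f0 = 250.0, 10.0
        t = np.arange(1751) / fs
        env = 1 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
        data = np.tile(env * np.cos(2 * np.pi * f0 * t), (4, 22, 1))
        trials = EEGTrialSet(data=data, labels=np.array(["l", "l", "r", "r"]),
                             sample_rate=fs, montage=mi22)
        co, valid = wavelet_coefficients(trials, f0)
        r = np.corrcoef(np.abs(co[0, 0, valid]), env[valid])[0, 1]
        assert r > 0.99

    def test_edges_flagged_unreliable(self, white_trials):
        spec = WaveletSpec(cycles=7)
        _, valid = wavelet_coefficients(white_trials, 10.0, spec)
        support = int(spec.support(10.0) * 250)
        assert not valid[:support].any()
        assert not valid[-support:].any()
        assert valid.sum() > 0

    def test_support_longer_than_trial_rejected(self, mi22):
        data = np.zeros((4, 22, 100))
        trials = EEGTrialSet(data=data, labels=np.array(["l", "l", "r", "r"]),
                             sample_rate=250.0, montage=mi22)
        with pytest.raises(ValueError, match="support"):
            wavelet_coefficients(trials, 4.0, WaveletSpec(cycles=10))


class TestWPLI:
    def test_constant_lag_gives_one(self):
        rng = np.random.default_rng(0)
        ph = rng.uniform(0, 2 * np.pi, 50)
        assert wpli_pair(phasors(ph), phasors(ph - np.pi / 2)) == pytest.approx(1.0)

    def test_zero_lag_gives_zero(self):
        rng = np.random.default_rng(1)
        ph = rng.uniform(0, 2 * np.pi, 50)
        assert wpli_pair(phasors(ph), phasors(ph)) == 0.0

    def test_pi_lag_gives_zero(self):
        rng = np.random.default_rng(2)
        ph = rng.uniform(0, 2 * np.pi, 50)
        assert wpli_pair(phasors(ph), phasors(ph + np.pi)) == pytest.approx(0.0)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="trial"):
            wpli_pair(phasors([0.1] * 5), phasors([0.2] * 5))

    def test_independent_phases_small(self):
        rng = np.random.default_rng(3)
        vals = [wpli_pair(phasors(rng.uniform(0, 2 * np.pi, 200)),
                          phasors(rng.uniform(0, 2 * np.pi, 200)))
                for _ in range(200)]
        vals = np.asarray(vals).ravel()
        # finite-trial null floor ~ sqrt(pi/(2n)); median well below 0.15
        assert np.median(vals) < 0.1
        assert np.mean(vals < 0.15) > 0.85

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_range_and_symmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((12, 8)) + 1j * rng.standard_normal((12, 8))
        b = rng.standard_normal((12, 8)) + 1j * rng.standard_normal((12, 8))
        w_ab = wpli_pair(a, b)
        w_ba = wpli_pair(b, a)
        assert np.all((0 <= w_ab) & (w_ab <= 1))
        assert np.allclose(w_ab, w_ba)

    def test_volume_conduction_zero_lag_mixture_below_null(self):
        # shared source mixed into both channels with no lag, plus sensor noise
        rng = np.random.default_rng(4)
        n = 200
        src = rng.standard_normal((n, 40)) + 1j * rng.standard_normal((n, 40))
        a = src + 0.3 * (rng.standard_normal((n, 40)) + 1j * rng.standard_normal((n, 40)))
        b = 0.8 * src + 0.3 * (rng.standard_normal((n, 40)) + 1j * rng.standard_normal((n, 40)))
        mixed = np.mean([wpli_pair(
            src + 0.3 * (rng.standard_normal((n, 40)) + 1j * rng.standard_normal((n, 40))),
            0.8 * src + 0.3 * (rng.standard_normal((n, 40)) + 1j * rng.standard_normal((n, 40)))
        ).mean() for _ in range(30)])
        null = [wpli_pair(
            rng.standard_normal((n, 40)) + 1j * rng.standard_normal((n, 40)),
            rng.standard_normal((n, 40)) + 1j * rng.standard_normal((n, 40))).mean()
            for _ in range(100)]
        assert mixed < np.quantile(null, 0.95)

    def test_variance_shrinks_with_trials(self):
        rng = np.random.default_rng(5)
        var = []
        for n in (20, 80, 320):
            est = [wpli_pair(phasors(rng.uniform(0, 2 * np.pi, n)),
                             phasors(rng.uniform(0, 2 * np.pi, n)))[0]
                   for _ in range(150)]
            var.append(np.var(est))
        assert var[0] > var[1] > var[2]


class TestBaselineAndStrength:
    def test_stationary_coupling_normalizes_to_one(self):
        positions = np.arange(0, 7, 0.1)
        phi = np.full((2, len(positions), 5), 0.6)
        out, flags = baseline_normalize(phi, positions, (0.5, 1.5))
        assert np.allclose(out, 1.0)
        assert not flags.any()

    def test_zero_baseline_flagged_raw_retained(self):
        positions = np.arange(0, 7, 0.1)
        phi = np.zeros((1, len(positions), 2))
        phi[0, 40:, 0] = 0.5  # coupling appears only after the baseline
        out, flags = baseline_normalize(phi, positions, (0.5, 1.5))
        assert flags[0, 0]
        assert np.array_equal(out[0, :, 0], phi[0, :, 0])

    def test_task_only_coupling_amplified(self):
        positions = np.arange(0, 7, 0.1)
        phi = np.full((1, len(positions), 1), 0.1)
        phi[0, (positions >= 2.6) & (positions <= 4.6), 0] = 0.8
        out, _ = baseline_normalize(phi, positions, (0.5, 1.5))
        task = out[0, (positions >= 2.6) & (positions <= 4.6), 0]
        assert task.min() > 5.0

    def test_pair_count_and_symmetric_strength(self):
        pairs = [(a, b) for a in range(22) for b in range(a + 1, 22)]
        assert len(pairs) == 231
        phi = np.zeros((1, 1, 231))
        pair_idx = pairs.index((2, 7))
        phi[0, 0, pair_idx] = 0.9
        strength = node_strength(phi, pairs, 22)
        assert strength[0, 0, 2] == strength[0, 0, 7] == 0.9
        assert strength.sum() == 2 * 0.9

    def test_hub_channel_has_max_strength(self):
        rng = np.random.default_rng(6)
        pairs = [(a, b) for a in range(8) for b in range(a + 1, 8)]
        phi = rng.uniform(0, 0.1, (1, 3, len(pairs)))
        for v, (a, b) in enumerate(pairs):
            if 0 in (a, b):
                phi[..., v] += 0.5
        strength = node_strength(phi, pairs, 8)
        assert (strength.argmax(axis=-1) == 0).all()


class TestEndToEnd:
    def test_planted_coupling_detected_in_interval(self):
        spec = SynthSpec(
            n_subjects=1, n_trials_per_class=30, subject_jitter=0.0,
            coupling_plants=(CouplingPlant(("C3", "CP3"), (8, 12), (2.6, 4.6),
                                           np.pi / 2, 1.0),),
            seed=13)
        s = generate_subject(spec, 0)
        bank = FilterBank(bands=((8.0, 12.0),), f_min=8, f_max=12, width=4, step=2)
        grid = make_window_grid(0.1, 0.0, 7.0, 250.0)
        conn = connectivity_dynamics(s, bank, grid, reference=None,
                                     baseline=(0.5, 1.5))
        a = s.montage.index("C3")
        b = s.montage.index("CP3")
        v = conn.pairs.index((min(a, b), max(a, b)))
        task = conn.phi["left"][0, (grid.positions >= 2.8) & (grid.positions <= 4.4), v]
        base = conn.phi["left"][0, grid.positions <= 1.5, v]
        assert task.mean() > 0.8
        assert task.mean() > base.mean() + 0.4
        # raw-phi node strength peaks at the coupled channels (the divisive
        # baseline normalization amplifies null-pair noise and is checked on
        # its own above)
        strength = node_strength(conn.phi["left"], conn.pairs, 22)
        sel = (grid.positions >= 2.8) & (grid.positions <= 4.4)
        cell = strength[0, sel].mean(axis=0)
        top2 = {s.montage.channels[i] for i in np.argsort(cell)[-2:]}
        assert top2 == {"C3", "CP3"}

    def test_reference_channel_excluded_from_pairs(self, white_trials):
        bank = FilterBank(bands=((8.0, 12.0),), f_min=8, f_max=12, width=4, step=2)
        grid = make_window_grid(0.5, 0.0, 7.0, 250.0)
        conn = connectivity_dynamics(white_trials, bank, grid, reference="Cz",
                                     baseline=None)
        cz = white_trials.montage.index("Cz")
        assert all(cz not in p for p in conn.pairs)
        assert len(conn.pairs) == 21 * 20 // 2
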