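import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from migroup.containers import TFDynamics
from migroup.group import (channel_relevance, cohort_relevance,
                           desegregation_curve, group_aggregate,
                           kernel_similarity, literacy_split, median_sigma,
                           pfdr_correct)


def make_theta(rng, n_bands=1, n_pos=80, n_ch=6, labels=("left", "right"),
               shift=None, shift_channel=0, shift_interval=(2.6, 4.6)):
    """Labeled dynamics of iid noise, optionally with a class shift on one
    channel inside an interval."""
    positions = np.linspace(0, 7, n_pos)
    channels = tuple(f"ch{i}" for i in range(n_ch))
    values = {lab: rng.standard_normal((n_bands, n_pos, n_ch)) for lab in labels}
    if shift is not None:
        sel = (positions >= shift_interval[0]) & (positions <= shift_interval[1])
        values[labels[1]][:, sel, shift_channel] += shift
    return TFDynamics(values=values, bands=[(8.0, 12.0)], positions=positions,
                      channels=channels)


class TestChannelRelevance:
    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(0)
        rej = []
        for _ in range(120):
            th = make_theta(rng)
            r = channel_relevance(th, 0, (2.6, 4.6), alpha=0.05)
            rej.extend(r.kappa.tolist())
        rate = np.mean(rej)  # 720 null cells
        assert 0.025 < rate < 0.08

    def test_large_shift_always_detected(self):
        rng = np.random.default_rng(1)
        hits = []
        for _ in range(40):
            th = make_theta(rng, shift=5.0)
            r = channel_relevance(th, 0, (2.6, 4.6), alpha=0.05)
            hits.append(r.kappa[0])
        assert np.mean(hits) >= 0.99

    def test_alpha_zero_rejects_nothing(self):
        rng = np.random.default_rng(2)
        th = make_theta(rng, shift=5.0)
        r = channel_relevance(th, 0, (2.6, 4.6), alpha=0.0)
        assert not r.kappa.any()

    def test_merged_dynamics_need_contrast_interval(self):
        rng = np.random.default_rng(3)
        positions = np.linspace(0, 7, 80)
        th = TFDynamics(values={None: rng.standard_normal((1, 80, 4))},
                        bands=[(8.0, 12.0)], positions=positions,
                        channels=("a", "b", "c", "d"))
        with pytest.raises(ValueError, match="contrast"):
            channel_relevance(th, 0, (2.6, 4.6))
        r = channel_relevance(th, 0, (2.6, 4.6), contrast_interval=(0.0, 2.0))
        assert r.p_values.shape == (4,)

    def test_short_interval_rejected(self):
        rng = np.random.default_rng(4)
        th = make_theta(rng, n_pos=40)
        with pytest.raises(ValueError, match="decorrelated"):
            channel_relevance(th, 0, (2.6, 3.0))


class TestPFDR:
    def test_uniform_p_few_discoveries(self):
        rng = np.random.default_rng(5)
        prop = []
        for _ in range(100):
            qv, pi0, mask = pfdr_correct(rng.uniform(size=200), q=0.05)
            prop.append(mask.mean())
        assert np.mean(prop) <= 0.05

    def test_overwhelming_signal_all_retained(self):
        qv, pi0, mask = pfdr_correct(np.full(10, 1e-6), q=0.05)
        assert mask.all()

    def test_single_p_reduces_to_raw_threshold(self):
        qv, pi0, mask = pfdr_correct(np.array([0.04]), q=0.05, method="bh")
        assert mask[0]

    def test_small_family_falls_back_to_bh(self):
        qv, pi0, mask = pfdr_correct(np.array([0.001] * 5), q=0.05)
        assert pi0 == 1.0
        assert mask.all()

    def test_pfdr_at_least_as_powerful_as_bh_on_mixtures(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = np.concatenate([rng.uniform(size=150),
                                rng.uniform(0, 1e-4, size=50)])
            _, pi0, mask_pfdr = pfdr_correct(p, q=0.05)
            _, _, mask_bh = pfdr_correct(p, q=0.05, method="bh")
            assert pi0 <= 1.0
            assert mask_pfdr.sum() >= mask_bh.sum()

    def test_all_ones_empty_mask(self):
        qv, pi0, mask = pfdr_correct(np.ones(50), q=0.05)
        assert not mask.any()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            pfdr_correct(np.array([0.1, 1.5]))


class TestGroupAggregate:
    def test_identical_subjects_full_masks_idempotent(self):
        rng = np.random.default_rng(7)
        th = make_theta(rng)
        gd = group_aggregate([th] * 5)
        for lab in th.labels:
            np.testing.assert_allclose(gd.theta.values[lab], th.values[lab])
            assert (gd.support[lab] == 5).all()
            assert gd.reliable[lab].all()

    def test_empty_masks_all_undefined(self):
        rng = np.random.default_rng(8)
        th = make_theta(rng)
        gd = group_aggregate([th] * 4, masks=[np.zeros((1, 80, 6), bool)] * 4)
        for lab in th.labels:
            assert np.isnan(gd.theta.values[lab]).all()
            assert not gd.reliable[lab].any()

    def test_grid_mismatch_names_axis(self):
        rng = np.random.default_rng(9)
        a = make_theta(rng, n_pos=80)
        b = make_theta(rng, n_pos=60)
        with pytest.raises(ValueError, match="position"):
            group_aggregate([a, b])

    def test_minority_masked_cell_unreliable(self):
        rng = np.random.default_rng(10)
        th = make_theta(rng)
        masks = [np.ones((1, 80, 6), bool) for _ in range(5)]
        for m in masks[:4]:
            m[..., 0] = False
        gd = group_aggregate([th] * 5, masks=masks)
        lab = th.labels[0]
        assert not gd.reliable[lab][..., 0].any()
        assert gd.support[lab][..., 0].max() == 1
        # value still equals the single supporting subject's theta
        np.testing.assert_allclose(gd.theta.values[lab][..., 0],
                                   th.values[lab][..., 0])


class TestCohortRelevance:
    def test_null_cohort_controlled_discoveries(self):
        rng = np.random.default_rng(11)
        thetas = [make_theta(rng) for _ in range(9)]
        mask = cohort_relevance(thetas, 0, (2.6, 4.6), alpha=0.05, q=0.05)
        assert mask.p_values.shape == (9, 6)
        assert mask.kappa.mean() <= 0.05
        assert ((mask.q_values >= 0) & (mask.q_values <= 1)).all()

    def test_planted_channel_survives_correction(self):
        rng = np.random.default_rng(12)
        thetas = [make_theta(rng, shift=3.0) for _ in range(9)]
        mask = cohort_relevance(thetas, 0, (2.6, 4.6), alpha=0.05, q=0.05)
        assert mask.kappa[:, 0].mean() >= 0.9
        assert mask.kappa[:, 1:].mean() < 0.1


class TestLiteracySplit:
    def test_extreme_outlier_trimmed_first(self):
        pts = np.array([[0.8, 0.05]] * 8 + [[0.2, 0.3]])
        split = literacy_split(pts)
        assert split.trimmed == [8]
        assert 8 in split.illiterate

    def test_identical_points_tie_broken_by_index(self):
        pts = np.tile([0.7, 0.1], (6, 1))
        split = literacy_split(pts)
        assert split.trimmed == [5]  # highest index trimmed on full tie
        assert split.illiterate == []  # nobody strictly below the cut

    def test_low_performers_land_illiterate(self):
        rng = np.random.default_rng(13)
        high = np.column_stack([rng.normal(0.9, 0.02, 6),
                                rng.normal(0.05, 0.01, 6)])
        low = np.column_stack([rng.normal(0.55, 0.02, 3),
                               rng.normal(0.12, 0.01, 3)])
        split = literacy_split(np.vstack([high, low]))
        assert set(split.illiterate) == {6, 7, 8}

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="5"):
            literacy_split(np.zeros((4, 2)))


class TestKernelSimilarity:
    def test_unit_checks(self):
        v = np.arange(5.0)
        assert kernel_similarity(v, v, sigma=2.0) == 1.0
        w = v.copy()
        w[0] += 2.0  # distance exactly sigma
        assert kernel_similarity(v, w, sigma=2.0) == pytest.approx(np.exp(-1))

    def test_monotone_decreasing_on_distance_ladder(self):
        v = np.zeros(4)
        sims = [kernel_similarity(v, v + d / 2, sigma=1.0)
                for d in range(6)]
        assert all(a > b for a, b in zip(sims, sims[1:]))
        assert all(0 < s <= 1 for s in sims)

    def test_symmetry(self):
        rng = np.random.default_rng(14)
        a, b = rng.standard_normal((2, 8))
        assert kernel_similarity(a, b, 1.3) == kernel_similarity(b, a, 1.3)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            kernel_similarity(np.zeros(3), np.ones(3), sigma=0.0)

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=30, deadline=None)
    def test_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal((2, 6))
        s = kernel_similarity(a, b, sigma=abs(rng.standard_normal()) + 0.1)
        assert 0 <= s <= 1  # exact 0 only through floating-point underflow
        if s == 1:
            assert np.allclose(a, b)

    def test_median_sigma_degenerate(self):
        assert median_sigma([np.zeros(3), np.zeros(3)]) == 1.0


class TestDesegregation:
    def test_identity_and_homogeneous_curve(self):
        rng = np.random.default_rng(15)
        th = make_theta(rng)
        curve = desegregation_curve([th] * 6, np.arange(6) / 10, (2.6, 4.6),
                                    channel_subset=("ch0", "ch1"))
        assert curve.similarity_to_full[0] == 1.0
        assert all(s > 0.999 for s in curve.similarity_to_full)
        assert np.allclose(curve.pairwise, 1.0, atol=1e-9)

    def test_worst_removed_first_and_truncation(self):
        rng = np.random.default_rng(16)
        thetas = [make_theta(rng) for _ in range(5)]
        acc = np.array([0.9, 0.5, 0.8, 0.95, 0.6])
        curve = desegregation_curve(thetas, acc, (2.6, 4.6),
                                    channel_subset=("ch0",))
        assert curve.removal_order[:2] == [1, 4]
        assert curve.removed_counts == [0, 1, 2]  # stops at 3 remaining

    def test_removing_null_subjects_recovers_clean_model(self):
        rng = np.random.default_rng(17)
        clean = [make_theta(rng, shift=2.0) for _ in range(6)]
        null = [make_theta(rng) for _ in range(3)]
        acc = np.array([0.9] * 6 + [0.5] * 3)
        curve = desegregation_curve(clean + null, acc, (2.6, 4.6),
                                    channel_subset=("ch0", "ch1", "ch2"))
        ref = curve.vectors[3]  # the clean-subgroup model
        sims = [kernel_similarity(v, ref, curve.sigma) for v in curve.vectors[:4]]
        assert all(a <= b + 1e-12 for a, b in zip(sims, sims[1:]))
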