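"""Generalized softmax, LD/KD losses, region selection, and the composite
objective."""

import numpy as np
import pytest
from scipy.special import softmax as scipy_softmax
from scipy.stats import entropy

from ldprompt.distill import (DistillConfig, RegionAssignment,
                              generalized_softmax, kd_class_loss, ld_loss,
                              ld_loss_tensor, select_regions,
                              tempered_kl_tensor, total_distill_loss)
from ldprompt.geometry import Box, diou
from ldprompt.nn import Tensor


def direct_kl(t_logits, s_logits, tau):
    """Independent KL summation oracle via explicit exp/sum arithmetic."""
    pt = scipy_softmax(np.asarray(t_logits, dtype=np.float64) / tau)
    ps = scipy_softmax(np.asarray(s_logits, dtype=np.float64) / tau)
    return float(np.sum(pt * (np.log(pt) - np.log(ps))))


class TestGeneralizedSoftmax:
    def test_constant_logits_give_uniform(self):
        for tau in (0.5, 1.0, 10.0):
            p = generalized_softmax(np.full(6, 3.7), tau)
            assert p == pytest.approx(np.full(6, 1 / 6), abs=1e-12)

    def test_tau_one_is_standard_softmax(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            z = rng.normal(size=10) * 5
            assert generalized_softmax(z, 1.0) == pytest.approx(
                scipy_softmax(z), abs=1e-12)

    def test_matches_high_precision_oracle_at_tau_ten(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            z = rng.normal(size=8) * 10
            expect = np.exp(z / 10.0) / np.exp(z / 10.0).sum()
            assert generalized_softmax(z, 10.0) == pytest.approx(expect, abs=1e-12)

    def test_sums_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            z = rng.normal(size=12) * rng.uniform(0.1, 50)
            assert generalized_softmax(z, rng.uniform(0.1, 30)).sum() == \
                pytest.approx(1.0, abs=1e-12)

    def test_entropy_nondecreasing_in_temperature(self):
        rng = np.random.default_rng(3)
        taus = [0.5, 1.0, 2.0, 5.0, 10.0, 20.0]
        for _ in range(100):
            z = rng.normal(size=8) * 5
            ents = [entropy(generalized_softmax(z, t)) for t in taus]
            assert all(b >= a - 1e-12 for a, b in zip(ents, ents[1:]))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            generalized_softmax(np.zeros(4), 0.0)
        with pytest.raises(ValueError):
            generalized_softmax(np.array([1.0, np.inf]), 1.0)


class TestLdLoss:
    cfg = DistillConfig()  # tau=10, rescale on

    def test_zero_iff_student_equals_teacher(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(4, 8))
        assert ld_loss(z, z.copy(), self.cfg) == pytest.approx(0.0, abs=1e-12)
        z2 = z.copy()
        z2[0, 0] += 1.0
        assert ld_loss(z2, z, self.cfg) > 1e-6

    def test_two_bin_point_mass_vs_uniform_is_log2(self):
        teacher = np.array([[1e4, -1e4]] * 4, dtype=float)  # point mass limit
        student = np.zeros((4, 2))
        cfg = DistillConfig(temperature=1.0, tau_square_rescale=False)
        assert ld_loss(student, teacher, cfg) == pytest.approx(
            4 * np.log(2), rel=1e-6)

    def test_matches_direct_kl_summation(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            s = rng.normal(size=(4, 8)) * 4
            t = rng.normal(size=(4, 8)) * 4
            expect = 100.0 * sum(direct_kl(t[e], s[e], 10.0) for e in range(4))
            assert ld_loss(s, t, self.cfg) == pytest.approx(expect, abs=1e-9)

    def test_nonnegative(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            s, t = rng.normal(size=(2, 4, 8)) * 6
            assert ld_loss(s, t, self.cfg) >= 0.0

    def test_tau_square_flag(self):
        rng = np.random.default_rng(7)
        s, t = rng.normal(size=(2, 4, 8))
        on = ld_loss(s, t, DistillConfig(temperature=10))
        off = ld_loss(s, t, DistillConfig(temperature=10, tau_square_rescale=False))
        assert on == pytest.approx(100.0 * off, rel=1e-12)

    def test_rejects_bin_mismatch(self):
        with pytest.raises(ValueError):
            ld_loss(np.zeros((4, 8)), np.zeros((4, 6)), self.cfg)

    def test_edge_distribution_inputs(self):
        from ldprompt.geometry import EdgeDistribution
        rng = np.random.default_rng(8)
        z = rng.normal(size=(4, 8))
        dists_s = [EdgeDistribution(z[e], 8.0) for e in range(4)]
        assert ld_loss(dists_s, z, self.cfg) == pytest.approx(0.0, abs=1e-12)

    def test_tensor_variant_agrees_with_numpy(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=(5, 4, 8))
        t = rng.normal(size=(5, 4, 8))
        per_anchor = ld_loss_tensor(Tensor(s), t, self.cfg).data
        for k in range(5):
            assert per_anchor[k] == pytest.approx(
                ld_loss(s[k], t[k], self.cfg), abs=1e-9)


class TestKdClassLoss:
    def test_identical_logits_zero(self):
        z = np.array([1.0, -2.0, 0.5])
        assert kd_class_loss(z, z, tau=10.0) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_limit_vs_uniform_is_log_c(self):
        c = 5
        teacher = np.full(c, -1e4)
        teacher[2] = 1e4
        assert kd_class_loss(np.zeros(c), teacher, tau=1.0,
                             tau_square_rescale=False) == pytest.approx(
            np.log(c), rel=1e-6)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            s, t = rng.normal(size=(2, 6)) * 4
            expect = 100.0 * direct_kl(t, s, 10.0)
            assert kd_class_loss(s, t, tau=10.0) == pytest.approx(expect, abs=1e-9)

    def test_rejects_class_count_mismatch(self):
        with pytest.raises(ValueError):
            kd_class_loss(np.zeros(3), np.zeros(4), tau=10.0)


def brute_force_regions(decoded, gt, cfg):
    """Exhaustive double loop over all anchor-gt pairs."""
    main, vlr, scores, matched = [], [], [], []
    for k, db in enumerate(decoded):
        best, best_j = -np.inf, -1
        for j, g in enumerate(gt):
            s = diou(db, g)
            if s > best:
                best, best_j = s, j
        scores.append(best)
        matched.append(best_j)
        if best >= cfg.alpha_pos:
            main.append(k)
        elif cfg.gamma * cfg.alpha_pos <= best < cfg.alpha_pos:
            vlr.append(k)
    return np.array(scores), np.array(main, int), np.array(vlr, int), \
        np.array(matched, int)


def random_boxes(rng, n, size=64.0):
    out = []
    for _ in range(n):
        x1, y1 = rng.uniform(0, size * 0.7, 2)
        w, h = rng.uniform(2, size * 0.4, 2)
        out.append(Box(x1, y1, x1 + w, y1 + h))
    return out


class TestSelectRegions:
    def test_gamma_one_empties_vlr(self):
        rng = np.random.default_rng(11)
        cfg = DistillConfig(gamma=1.0, alpha_pos=0.5)
        assign = select_regions(random_boxes(rng, 50), random_boxes(rng, 3), cfg)
        assert assign.omega_vlr.size == 0

    def test_all_below_band_gives_empty_sets(self):
        far_anchor = [Box(0, 0, 1, 1)]
        far_gt = [Box(60, 60, 63, 63)]
        assign = select_regions(far_anchor, far_gt,
                                DistillConfig(alpha_pos=0.7, gamma=0.5))
        assert assign.omega_main.size == 0 and assign.omega_vlr.size == 0

    def test_empty_gt_returns_sentinel(self):
        assign = select_regions([Box(0, 0, 4, 4)], [], DistillConfig())
        assert (assign.scores == -1.0).all()
        assert assign.omega_main.size == 0 and assign.omega_vlr.size == 0
        assert (assign.matched_gt == -1).all()

    def test_empty_anchors_rejected(self):
        with pytest.raises(ValueError):
            select_regions([], [Box(0, 0, 4, 4)], DistillConfig())

    def test_matches_exhaustive_double_loop(self):
        cfg = DistillConfig(alpha_pos=0.7, gamma=0.5)
        for trial in range(20):
            rng = np.random.default_rng(1000 + trial)
            decoded = random_boxes(rng, 200)
            gt = random_boxes(rng, 5)
            got = select_regions(decoded, gt, cfg)
            scores, main, vlr, matched = brute_force_regions(decoded, gt, cfg)
            np.testing.assert_allclose(got.scores, scores, atol=1e-12)
            np.testing.assert_array_equal(got.omega_main, main)
            np.testing.assert_array_equal(got.omega_vlr, vlr)
            np.testing.assert_array_equal(got.matched_gt, matched)

    def test_regions_disjoint_and_order_invariant(self):
        cfg = DistillConfig(alpha_pos=0.4, gamma=0.3)
        rng = np.random.default_rng(12)
        decoded = random_boxes(rng, 100)
        gt = random_boxes(rng, 4)
        a = select_regions(decoded, gt, cfg)
        assert np.intersect1d(a.omega_main, a.omega_vlr).size == 0
        perm = rng.permutation(100)
        b = select_regions([decoded[i] for i in perm], gt, cfg)
        # anchors relabeled by perm: membership must map through it
        assert set(perm[b.omega_main]) == set(a.omega_main)
        assert set(perm[b.omega_vlr]) == set(a.omega_vlr)

    def test_argmax_tie_goes_to_lowest_gt_index(self):
        g = Box(0, 0, 10, 10)
        assign = select_regions([Box(0, 0, 10, 10)], [g, g], DistillConfig())
        assert assign.matched_gt[0] == 0


class TestTotalLoss:
    def make_assign(self, main, vlr, n=10):
        return RegionAssignment(scores=np.zeros(n),
                                omega_main=np.asarray(main, int),
                                omega_vlr=np.asarray(vlr, int),
                                matched_gt=np.zeros(n, int))

    def test_zero_weights_reduce_to_detection_loss(self):
        cfg = DistillConfig(lambda_main=0.0, lambda_vlr=0.0)
        ld = np.arange(10.0)
        assert total_distill_loss(2.5, ld, self.make_assign([1, 2], [3]), cfg) == 2.5

    def test_empty_regions_reduce_to_detection_loss(self):
        cfg = DistillConfig()
        assert total_distill_loss(1.25, np.ones(10), self.make_assign([], []),
                                  cfg) == 1.25

    def test_hand_summation(self):
        cfg = DistillConfig(lambda_main=1.0, lambda_vlr=1.0)
        ld = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        total = total_distill_loss(1.0, ld, self.make_assign([0, 2, 4], [1, 5], 6),
                                   cfg)
        assert total == pytest.approx(1.0 + (0.1 + 0.3 + 0.5) + (0.2 + 0.6))

    def test_linear_in_region_weights(self):
        ld = np.array([0.5, 1.5, 2.5, 3.5])
        assign = self.make_assign([0, 1], [2], 4)
        base = total_distill_loss(0.0, ld, assign,
                                  DistillConfig(lambda_main=1.0, lambda_vlr=0.0))
        vlr = total_distill_loss(0.0, ld, assign,
                                 DistillConfig(lambda_main=0.0, lambda_vlr=1.0))
        for lm, lv in [(2.0, 0.5), (0.25, 3.0)]:
            combo = total_distill_loss(
                0.0, ld, assign, DistillConfig(lambda_main=lm, lambda_vlr=lv))
            assert combo == pytest.approx(lm * base + lv * vlr)


class TestDistillConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            DistillConfig(temperature=0.0)
        with pytest.raises(ValueError):
            DistillConfig(gamma=0.0)
        with pytest.raises(ValueError):
            DistillConfig(gamma=1.5)
        with pytest.raises(ValueError):
            DistillConfig(alpha_pos=0.0)
        with pytest.raises(ValueError):
            DistillConfig(lambda_main=-1.0)

    def test_yaml_key_round_trip(self):
        cfg = DistillConfig(temperature=5.0, gamma=0.25)
        d = cfg.to_dict()
        assert set(d) == {"temperature", "lambda_main", "lambda_vlr",
                          "alpha_pos", "gamma", "tau_square_rescale"}
        assert DistillConfig.from_dict(d) == cfg

    def test_region_assignment_rejects_overlap(self):
        with pytest.raises(ValueError):
            RegionAssignment(scores=np.zeros(4),
                             omega_main=np.array([1, 2]),
                             omega_vlr=np.array([2, 3]),
                             matched_gt=np.zeros(4, int))


def test_tempered_kl_tensor_gradient_direction():
    """The student gradient of KL(teacher || student) pulls toward the teacher."""
    t = np.array([2.0, 0.0, -2.0])
    s = Tensor(np.zeros(3), requires_grad=True)
    loss = tempered_kl_tensor(t, s, tau=1.0)
    loss.backward()
    # moving along -grad must increase the teacher-favored logit most
    assert s.grad[0] < s.grad[2]
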