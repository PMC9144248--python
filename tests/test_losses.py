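"""Composite objective: hand-computed fixtures, scalar-loop oracles,
reduction identities, and finite-difference gradient checks."""

import math

import numpy as np
import pytest

from miunet._exceptions import ConfigurationError, DimensionError
from miunet.losses import (
    EPS,
    LossWeights,
    bce_loss,
    dsc_loss,
    joint_loss,
    seg_loss,
    spatial_consistency,
    tv_penalty,
)
from miunet.nn import Tensor

# ---------------------------------------------------------------------------
# independent scalar-loop oracles (plain Python floats, no array math)


def oracle_dsc(x, t):
    x, t = np.ravel(x), np.ravel(t)
    inter = sum(float(a) * float(b) for a, b in zip(x, t))
    denom = sum(float(a) ** 2 for a in x) + sum(float(b) ** 2 for b in t)
    if denom == 0:
        return 0.0
    return 1.0 - 2.0 * inter / denom


def oracle_bce(p, t):
    p, t = np.ravel(p), np.ravel(t)
    total = 0.0
    for pi, ti in zip(p, t):
        pc = min(max(float(pi), EPS), 1.0 - EPS)
        total += float(ti) * math.log(pc) + (1.0 - float(ti)) * math.log(1.0 - pc)
    return -total / len(p)


def oracle_tv(img):
    h, w = img.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            if i + 1 < h:
                total += abs(float(img[i + 1, j]) - float(img[i, j]))
            if j + 1 < w:
                total += abs(float(img[i, j + 1]) - float(img[i, j]))
    return total / (h * w)


def oracle_multiclass_seg(prob, onehot, lam1):
    dice = sum(oracle_dsc(prob[c], onehot[c]) for c in (1, 2, 3)) / 3.0
    bce = oracle_bce(prob, onehot)
    return lam1 * dice + (1 - lam1) * bce


def oracle_joint(pc, pl, tc, tl, w):
    seg = oracle_multiclass_seg(pc, tc, w.lambda1) + oracle_multiclass_seg(
        pl, tl, w.lambda1
    )
    tv = sum(oracle_tv(pc[c]) for c in (1, 2, 3)) / 3.0
    tv += sum(oracle_tv(pl[c]) for c in (1, 2, 3)) / 3.0
    sp = oracle_bce(pc, pl)
    return seg + w.lambda_tv * tv + w.lambda_sp * sp


def random_probmap(rng, shape=(4, 8, 8)):
    z = rng.random(shape)
    return z / z.sum(axis=0, keepdims=True)


def random_onehot(rng, shape=(4, 8, 8)):
    labels = rng.integers(0, shape[0], shape[1:])
    out = np.zeros(shape)
    for c in range(shape[0]):
        out[c] = labels == c
    return out


# ---------------------------------------------------------------------------


class TestDscLoss:
    def test_identity_is_zero(self):
        assert dsc_loss([1, 0, 1, 0], [1, 0, 1, 0]) == 0.0

    def test_disjoint_is_one(self):
        assert dsc_loss([1, 1, 0, 0], [0, 0, 1, 1]) == 1.0

    def test_hand_computed_squared_denominator(self):
        # 1 - 2*1/(2+1): the squared-sum denominator, not |A|+|B|
        assert abs(dsc_loss([1, 1, 0, 0], [1, 0, 0, 0]) - 1 / 3) < 1e-12

    def test_both_empty_is_perfect(self):
        assert dsc_loss([0.0, 0.0], [0, 0]) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            dsc_loss([1, 0], [1, 0, 0])

    def test_matches_oracle_on_random_fixtures(self, rng):
        for _ in range(100):
            x = rng.random(16)
            t = (rng.random(16) > 0.5).astype(float)
            assert abs(dsc_loss(x, t) - oracle_dsc(x, t)) < 1e-6

    def test_permutation_invariant(self, rng):
        x, t = rng.random(20), (rng.random(20) > 0.5).astype(float)
        perm = rng.permutation(20)
        assert abs(dsc_loss(x, t) - dsc_loss(x[perm], t[perm])) < 1e-12


class TestBceLoss:
    def test_perfect_binary_prediction_vanishes(self):
        t = np.array([1.0, 0.0, 1.0])
        assert bce_loss(t, t) <= 1e-6

    def test_uniform_half_gives_ln2(self, rng):
        t = (rng.random(10) > 0.5).astype(float)
        assert abs(bce_loss(np.full(10, 0.5), t) - math.log(2)) < 1e-12

    def test_hand_computed_two_pixel_fixture(self):
        expected = -0.5 * (math.log(0.9) + math.log(0.8))
        assert abs(bce_loss([0.9, 0.2], [1, 0]) - expected) < 1e-12
        assert abs(expected - 0.16425) < 5e-5

    def test_matches_oracle_on_random_fixtures(self, rng):
        for _ in range(100):
            p, t = rng.random(16), (rng.random(16) > 0.5).astype(float)
            assert abs(bce_loss(p, t) - oracle_bce(p, t)) < 1e-6


class TestSegLoss:
    def test_boundary_lambdas_collapse(self, rng):
        p, t = rng.random(12), (rng.random(12) > 0.5).astype(float)
        assert seg_loss(p, t, 1.0) == pytest.approx(dsc_loss(p, t), abs=1e-12)
        assert seg_loss(p, t, 0.0) == pytest.approx(bce_loss(p, t), abs=1e-12)

    def test_convex_combination(self, rng):
        p, t = rng.random(12), (rng.random(12) > 0.5).astype(float)
        expected = 0.5 * dsc_loss(p, t) + 0.5 * bce_loss(p, t)
        assert seg_loss(p, t, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ConfigurationError):
            seg_loss([0.5], [1.0], 1.5)

    def test_multiclass_aggregation_matches_per_class_mean(self, rng):
        prob, onehot = random_probmap(rng), random_onehot(rng)
        got = seg_loss(prob, onehot, 1.0)
        expected = np.mean([dsc_loss(prob[c], onehot[c]) for c in (1, 2, 3)])
        assert got == pytest.approx(expected, abs=1e-9)


class TestTvPenalty:
    def test_constant_is_zero(self):
        assert tv_penalty(np.full((5, 5), 0.3)) == 0.0

    def test_two_by_two_step(self):
        assert tv_penalty(np.array([[0.0, 0.0], [1.0, 1.0]])) == 0.5

    def test_alternating_columns(self):
        img = np.tile([0.0, 1.0], (4, 2))
        assert tv_penalty(img) == 0.75

    def test_matches_oracle_on_random_fixtures(self, rng):
        for _ in range(100):
            img = rng.random((8, 8))
            assert abs(tv_penalty(img) - oracle_tv(img)) < 1e-6

    def test_non_2d_rejected(self):
        with pytest.raises(DimensionError):
            tv_penalty(np.zeros(5))


class TestSpatialConsistency:
    def test_identical_binary_maps_vanish(self, rng):
        m = random_onehot(rng)
        assert spatial_consistency(m, m) <= 1e-6

    def test_uniform_half_prediction_gives_ln2(self, rng):
        other = random_probmap(rng)
        got = spatial_consistency(np.full((4, 8, 8), 0.5), other)
        assert abs(got - math.log(2)) < 1e-12

    def test_matches_oracle_on_fixture_pair(self, rng):
        a, b = rng.random((2, 2)), rng.random((2, 2))
        assert abs(spatial_consistency(a, b) - oracle_bce(a, b)) < 1e-12

    def test_stop_gradient_detaches_one_side(self, rng):
        a = Tensor(rng.random((4, 4, 4)), requires_grad=True)
        b = Tensor(rng.random((4, 4, 4)), requires_grad=True)
        spatial_consistency(a, b, stop_gradient="lge").backward()
        assert a.grad is not None and b.grad is None


class TestJointLoss:
    def test_reduces_to_branch_sum_without_constraints(self, rng):
        pc, pl = random_probmap(rng), random_probmap(rng)
        tc, tl = random_onehot(rng), random_onehot(rng)
        w = LossWeights(0.5, 0.0, 0.0)
        total, terms = joint_loss(pc, pl, tc, tl, w)
        expected = seg_loss(pc, tc, 0.5) + seg_loss(pl, tl, 0.5)
        assert total == pytest.approx(expected, abs=1e-9)
        assert total == pytest.approx(terms["seg_cine"] + terms["seg_lge"], abs=1e-9)

    def test_perfect_predictions_vanish(self, rng):
        # co-located pair: both contrasts share one mask, so the
        # consistency term vanishes too at any weight
        t = random_onehot(rng)
        for lam_sp in (0.0, 0.5, 2.0):
            total, _ = joint_loss(t, t, t, t, LossWeights(0.5, 0.0, lam_sp))
            assert total <= 2e-6

    def test_default_constraint_weights_match_oracle(self, rng):
        w = LossWeights(0.5, 0.15, 0.5)
        for _ in range(20):
            pc, pl = random_probmap(rng), random_probmap(rng)
            tc, tl = random_onehot(rng), random_onehot(rng)
            total, _ = joint_loss(pc, pl, tc, tl, w)
            assert abs(total - oracle_joint(pc, pl, tc, tl, w)) < 1e-6

    def test_breakdown_conserves_total(self, rng):
        w = LossWeights(0.3, 0.2, 0.7)
        pc, pl = random_probmap(rng), random_probmap(rng)
        tc, tl = random_onehot(rng), random_onehot(rng)
        total, t = joint_loss(pc, pl, tc, tl, w)
        recomposed = (
            t["seg_cine"]
            + t["seg_lge"]
            + w.lambda_tv * (t["tv_cine"] + t["tv_lge"])
            + w.lambda_sp * t["spatial"]
        )
        assert total == pytest.approx(recomposed, abs=1e-9)

    def test_dice_term_never_worsened_by_true_prediction(self, rng):
        tc, tl = random_onehot(rng), random_onehot(rng)
        for _ in range(10):
            pc = random_probmap(rng)
            imperfect = seg_loss(pc, tc, 1.0)
            perfect = seg_loss(tc.astype(float), tc, 1.0)
            assert perfect <= imperfect + 1e-12

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            LossWeights(lambda1=1.2)
        with pytest.raises(ConfigurationError):
            LossWeights(lambda_tv=-0.1)


class TestGradients:
    """Analytic gradients vs central differences (h = 1e-4) on 3x3 fixtures."""

    @staticmethod
    def _gradcheck(fn, x0, h=1e-4, tol=1e-3):
        xt = Tensor(x0.copy(), requires_grad=True)
        out = fn(xt)
        out.backward()
        ana = xt.grad
        num = np.zeros_like(x0)
        it = np.nditer(x0, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            num[i] = (fn(Tensor(xp)).item() - fn(Tensor(xm)).item()) / (2 * h)
        scale = np.abs(ana) + np.abs(num) + 1e-8
        assert (np.abs(ana - num) / scale).max() <= tol

    def test_dsc_gradient(self, rng):
        t = Tensor((rng.random((3, 3)) > 0.5).astype(float))
        self._gradcheck(lambda x: dsc_loss(x, t), rng.uniform(0.1, 0.9, (3, 3)))

    def test_bce_gradient(self, rng):
        t = Tensor((rng.random((3, 3)) > 0.5).astype(float))
        self._gradcheck(lambda x: bce_loss(x, t), rng.uniform(0.1, 0.9, (3, 3)))

    def test_tv_gradient(self, rng):
        self._gradcheck(tv_penalty, rng.uniform(0.1, 0.9, (3, 3)))

    def test_spatial_gradient_both_sides(self, rng):
        other = Tensor(rng.uniform(0.2, 0.8, (3, 3)))
        self._gradcheck(
            lambda x: spatial_consistency(x, other), rng.uniform(0.1, 0.9, (3, 3))
        )
        self._gradcheck(
            lambda x: spatial_consistency(other, x), rng.uniform(0.1, 0.9, (3, 3))
        )

    def test_joint_gradient(self, rng):
        tc = Tensor(random_onehot(rng, (4, 3, 3)))
        tl = Tensor(random_onehot(rng, (4, 3, 3)))
        pl = Tensor(random_probmap(rng, (4, 3, 3)))
        w = LossWeights(0.5, 0.15, 0.5)
        self._gradcheck(
            lambda x: joint_loss(x, pl, tc, tl, w)[0],
            rng.uniform(0.1, 0.9, (4, 3, 3)),
        )

    def test_losses_finite_on_extreme_inputs(self):
        p = np.array([0.0, 1.0, 0.5])
        t = np.array([1.0, 0.0, 1.0])
        assert np.isfinite(bce_loss(p, t))
        assert np.isfinite(dsc_loss(p, t))
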