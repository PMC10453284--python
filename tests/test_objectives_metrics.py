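import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscnet._nn import Tensor
from mscnet.io_datasets import AVLabel
from mscnet.objectives_metrics import (
    EPSILON,
    ConfusionCounts,
    av_ce_loss,
    bce_loss,
    confusion,
    dice_loss,
    metrics,
    total_loss,
)

from .oracles import confusion_naive


class TestBceLoss:
    def test_perfect_prediction(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert bce_loss(y, y) < 1e-6

    def test_single_pixel_half(self):
        assert bce_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(
            -math.log(0.5), abs=1e-12)

    def test_symmetry(self, rng):
        p = rng.uniform(0.01, 0.99, size=(8, 8))
        y = (rng.uniform(size=(8, 8)) > 0.5).astype(float)
        assert bce_loss(p, y) == pytest.approx(bce_loss(1 - p, 1 - y), abs=1e-12)

    def test_sum_reduction_is_scaled_mean(self, rng):
        p = rng.uniform(0.01, 0.99, size=(4, 4))
        y = (rng.uniform(size=(4, 4)) > 0.5).astype(float)
        assert bce_loss(p, y, reduction="sum") == pytest.approx(
            16 * bce_loss(p, y), rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(np.ones(3) * 0.5, np.ones(4))


class TestDiceLoss:
    def test_perfect(self, rng):
        y = (rng.uniform(size=(8, 8)) > 0.5).astype(float)
        assert dice_loss(y, y) < 1e-6

    def test_empty_sets_give_zero(self):
        z = np.zeros((4, 4))
        assert dice_loss(z, z) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        y = np.array([1.0, 0.0])
        p = np.array([0.5, 0.5])
        expect = 1 - (2 * 0.5 + EPSILON) / (1 + 1 + EPSILON)
        assert dice_loss(p, y) == pytest.approx(expect, abs=1e-12)
        assert dice_loss(p, y) == pytest.approx(0.5, abs=1e-6)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10 ** 6))
    def test_bounded_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(size=20)
        y = (r.uniform(size=20) > 0.5).astype(float)
        assert 0.0 <= dice_loss(p, y) <= 1.0


class TestAvCeLoss:
    def test_one_hot_perfect(self):
        av = np.array([[AVLabel.ARTERY, AVLabel.VEIN]], dtype=np.uint8)
        logits = np.zeros((3, 1, 2))
        logits[1, 0, 0] = 50.0
        logits[2, 0, 1] = 50.0
        assert av_ce_loss(logits, av) < 1e-3

    def test_uniform_logits_ln3(self):
        av = np.zeros((4, 4), dtype=np.uint8)
        assert av_ce_loss(np.zeros((3, 4, 4)), av) == pytest.approx(
            math.log(3.0), abs=1e-9)

    def test_uncertain_pixels_masked(self, rng):
        av = rng.integers(0, 3, size=(8, 8)).astype(np.uint8)
        av[2:4, 2:4] = AVLabel.UNCERTAIN
        logits = rng.normal(size=(3, 8, 8))
        base = av_ce_loss(logits, av)
        tweaked = logits.copy()
        tweaked[:, 2:4, 2:4] += rng.normal(size=(3, 2, 2)) * 10
        assert av_ce_loss(tweaked, av) == pytest.approx(base, abs=1e-12)

    def test_all_uncertain_rejected(self):
        av = np.full((4, 4), int(AVLabel.UNCERTAIN), dtype=np.uint8)
        with pytest.raises(ValueError, match="UNCERTAIN"):
            av_ce_loss(np.zeros((3, 4, 4)), av)


class TestTotalLoss:
    def test_perfect_predictions(self, synth_sample):
        s = synth_sample
        vp = s.vessel_mask.astype(np.float64)[None]
        logits = np.zeros((3, *s.shape))
        for cls in (0, 1, 2):
            logits[cls][s.av_labels == cls] = 60.0
        terms, tot = total_loss(vp, s.vessel_mask[None].astype(float),
                                logits, s.av_labels)
        assert terms.total < 1e-3

    def test_invariants_exact(self, rng):
        vp = rng.uniform(0.01, 0.99, size=(1, 8, 8))
        gt = (rng.uniform(size=(1, 8, 8)) > 0.5).astype(float)
        logits = rng.normal(size=(3, 8, 8))
        av = rng.integers(0, 3, size=(8, 8)).astype(np.uint8)
        terms, _ = total_loss(vp, gt, logits, av)
        assert terms.l_v == pytest.approx(terms.l_bce + 0.1 * terms.l_dice,
                                          rel=1e-12)
        assert terms.total == pytest.approx(terms.l_v + terms.l_a, rel=1e-12)
        assert terms.epsilon == 1e-6
        assert 0.0 <= terms.l_dice <= 1.0

    def test_gradient_matches_finite_differences(self):
        # three-pixel example, float64 graph
        p0 = np.array([0.3, 0.6, 0.9])
        y = np.array([0.0, 1.0, 1.0])
        pt = Tensor(p0)
        pt.requires_grad = True
        loss = bce_loss(pt, y) + 0.1 * dice_loss(pt, y)
        loss.backward()
        eps = 1e-7
        for i in range(3):
            pp = p0.copy()
            pp[i] += eps
            fd = ((bce_loss(pp, y) + 0.1 * dice_loss(pp, y))
                  - (bce_loss(p0, y) + 0.1 * dice_loss(p0, y))) / eps
            assert pt.grad[i] == pytest.approx(fd, abs=1e-4)


class TestConfusion:
    def test_perfect_prediction_no_errors(self, synth_sample):
        c = confusion(synth_sample.vessel_mask, synth_sample.vessel_mask,
                      "VESSEL")
        assert c.fp == 0 and c.fn == 0
        assert c.total == synth_sample.vessel_mask.size

    def test_av_small_example(self):
        A, V = int(AVLabel.ARTERY), int(AVLabel.VEIN)
        gt = np.array([[A, A, V, V]], dtype=np.uint8)
        pred = np.array([[A, V, V, A]], dtype=np.uint8)
        c = confusion(pred, gt, "AV")
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_vessel_constructed_fixture(self):
        gt = np.zeros(20, dtype=np.uint8)
        pred = np.zeros(20, dtype=np.uint8)
        gt[:9] = 1          # 9 positives
        pred[:8] = 1        # 8 tp, 1 fn
        pred[9:11] = 1      # 2 fp
        c = confusion(pred.reshape(4, 5), gt.reshape(4, 5), "VESSEL")
        assert (c.tp, c.fp, c.fn, c.tn) == (8, 2, 1, 9)

    def test_av_uses_artery_vein_channels_only(self):
        gt = np.array([[AVLabel.ARTERY, AVLabel.VEIN]], dtype=np.uint8)
        logits = np.zeros((3, 1, 2))
        logits[0] = 100.0  # background channel dominant everywhere: ignored
        logits[1, 0, 0] = 1.0
        logits[2, 0, 1] = 1.0
        c = confusion(logits, gt, "AV")
        assert c.fp == 0 and c.fn == 0

    def test_av_excludes_uncertain_and_background(self, rng):
        gt = rng.integers(0, 4, size=(10, 10)).astype(np.uint8)
        logits = rng.normal(size=(3, 10, 10))
        c = confusion(logits, gt, "AV")
        n_eval = int(((gt == 1) | (gt == 2)).sum())
        assert c.total == n_eval

    def test_empty_av_mask_rejected(self):
        gt = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(ValueError, match="empty"):
            confusion(np.zeros((3, 4, 4)), gt, "AV")

    def test_matches_naive_counting_vessel(self, rng):
        pred = rng.uniform(size=(32, 32)) > 0.4
        gt = rng.uniform(size=(32, 32)) > 0.6
        c = confusion(pred, gt.astype(np.uint8), "VESSEL")
        assert (c.tp, c.tn, c.fp, c.fn) == confusion_naive(pred, gt)

    def test_pooling_is_additive(self, rng):
        a = confusion(rng.uniform(size=(8, 8)) > 0.5,
                      (rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8), "VESSEL")
        b = confusion(rng.uniform(size=(8, 8)) > 0.5,
                      (rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8), "VESSEL")
        pooled = a + b
        assert pooled.tp == a.tp + b.tp and pooled.total == a.total + b.total


class TestMetrics:
    def test_all_perfect(self):
        m = metrics(ConfusionCounts(tp=1, tn=1, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_hand_arithmetic(self):
        m = metrics(ConfusionCounts(tp=8, fp=2, fn=1, tn=9))
        assert m["sen"] == pytest.approx(8 / 9, abs=1e-4)
        assert m["spe"] == pytest.approx(9 / 11, abs=1e-4)
        assert m["acc"] == pytest.approx(0.85, abs=1e-12)
        assert m["f1"] == pytest.approx(16 / 19, abs=1e-4)

    def test_acc_invariant_under_class_swap(self, rng):
        tp, tn, fp, fn = map(int, rng.integers(1, 50, size=4))
        a = metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        b = metrics(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
        assert a["acc"] == pytest.approx(b["acc"], rel=1e-12)

    def test_nan_contract(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(m["sen"])

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10 ** 6))
    def test_formulas_match_brute_force(self, seed):
        r = np.random.default_rng(seed)
        pred = r.uniform(size=(32, 32)) > r.uniform(0.2, 0.8)
        gt = (r.uniform(size=(32, 32)) > r.uniform(0.2, 0.8)).astype(np.uint8)
        c = confusion(pred, gt, "VESSEL")
        tp, tn, fp, fn = confusion_naive(pred, gt)
        m = metrics(c)
        if tp + fn:
            assert m["sen"] == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert m["spe"] == pytest.approx(tn / (tn + fp))
        assert m["acc"] == pytest.approx((tp + tn) / (tp + tn + fp + fn))
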