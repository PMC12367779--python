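"""Composite loss components against brute-force per-element oracles."""

import math

import numpy as np
import pytest

from rotphenex.errors import InvalidArgumentError
from rotphenex.losses import (
    LossConfig, TargetAssignment, bce_class_loss, ciou_loss, confidence_loss,
    csl_loss, csl_target, total_loss,
)


class TestBCE:
    def test_saturated_correct_is_zero(self):
        assert bce_class_loss(np.array([30.0]), np.array([1.0])) < 1e-12
        assert bce_class_loss(np.array([-30.0]), np.array([0.0])) < 1e-12

    def test_logit_zero_is_ln2(self):
        assert bce_class_loss(np.array([0.0]), np.array([1.0])) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_random_batch_matches_elementwise_sum(self, rng):
        x = rng.normal(0, 3, size=(4, 7))
        t = rng.integers(0, 2, size=(4, 7)).astype(float)
        expected = 0.0
        for xi, ti in zip(x.ravel(), t.ravel()):
            s = 1.0 / (1.0 + math.exp(-xi))
            expected += -(ti * math.log(s) + (1 - ti) * math.log(1 - s))
        expected /= x.size
        assert bce_class_loss(x, t) == pytest.approx(expected, abs=1e-7)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bce_class_loss(np.zeros(3), np.zeros(4))


class TestConfidenceLoss:
    def test_zero_at_perfect(self, rng):
        mask = np.array([1.0, 1.0, 0.0, 0.0])
        iou = np.array([0.7, 0.9, 0.0, 0.0])
        conf = np.array([0.7, 0.9, 0.0, 0.0])
        assert confidence_loss(conf, mask, iou, 0.5) == pytest.approx(0.0)

    def test_single_empty_cell_closed_form(self):
        lam = 0.37
        c = 0.42
        out = confidence_loss(np.array([c]), np.array([0.0]), np.array([0.0]), lam)
        assert out == pytest.approx(lam * c * c, abs=1e-12)

    def test_mixed_random_matches_double_sum(self, rng):
        n = 50
        conf = rng.uniform(0, 1, n)
        mask = (rng.uniform(size=n) < 0.3).astype(float)
        iou = rng.uniform(0, 1, n) * mask
        lam = 0.5
        expected = sum(
            (c - i) ** 2 if m else lam * c * c
            for c, m, i in zip(conf, mask, iou)
        )
        assert confidence_loss(conf, mask, iou, lam) == pytest.approx(expected, 1e-12)


class TestCSLTarget:
    def test_radius_zero_one_hot(self):
        t = csl_target(42, radius=0, n_bins=180)
        assert t[42] == 1.0 and t.sum() == 1.0

    def test_wraps_at_boundary(self):
        t = csl_target(0, radius=6, n_bins=180)
        assert t[1] == pytest.approx(t[179])
        assert t[0] == 1.0

    def test_matches_explicit_gaussian_formula(self):
        t = csl_target(90, radius=6, n_bins=180)
        for k in range(180):
            d = min(abs(k - 90), 180 - abs(k - 90))
            g = math.exp(-(d ** 2) / (2 * (6 / 3) ** 2)) if d <= 6 else 0.0
            assert t[k] == pytest.approx(g, abs=1e-12)

    def test_circular_shift_property(self):
        base = csl_target(10, radius=6, n_bins=180)
        for k in (1, 37, 170):
            assert np.allclose(np.roll(base, k), csl_target((10 + k) % 180, 6, 180))

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            csl_target(180, radius=6, n_bins=180)

    def test_csl_loss_zero_at_exact_soft_target(self):
        t = csl_target(33, radius=6, n_bins=180)
        eps = 1e-12
        logits = np.log((t + eps) / (1 - t + eps))
        assert csl_loss(logits, t) == pytest.approx(0.0, abs=1e-6)


class TestCIoU:
    def test_zero_at_identity(self):
        box = np.array([10.0, 20.0, 5.0, 30.0])
        assert float(ciou_loss(box, box)) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_exceeds_one(self):
        a = np.array([0.0, 0.0, 4.0, 4.0])
        b = np.array([100.0, 100.0, 4.0, 4.0])
        assert float(ciou_loss(a, b)) > 1.0

    def test_matches_independent_reference(self, rng):
        """Second implementation of the published complete-IoU formula."""

        def reference(p, g):
            px, py, pw, ph = p
            gx, gy, gw, gh = g
            x1, x2 = max(px - pw / 2, gx - gw / 2), min(px + pw / 2, gx + gw / 2)
            y1, y2 = max(py - ph / 2, gy - gh / 2), min(py + ph / 2, gy + gh / 2)
            inter = max(0, x2 - x1) * max(0, y2 - y1)
            union = pw * ph + gw * gh - inter
            iou = inter / (union + 1e-9)
            cw = max(px + pw / 2, gx + gw / 2) - min(px - pw / 2, gx - gw / 2)
            ch = max(py + ph / 2, gy + gh / 2) - min(py - ph / 2, gy - gh / 2)
            rho2 = (px - gx) ** 2 + (py - gy) ** 2
            c2 = cw ** 2 + ch ** 2 + 1e-9
            v = 4 / math.pi ** 2 * (math.atan(gw / gh) - math.atan(pw / ph)) ** 2
            alpha = v / ((1 - iou) + v + 1e-9)
            return 1 - iou + rho2 / c2 + alpha * v

        for _ in range(100):
            p = np.array([rng.uniform(0, 50), rng.uniform(0, 50),
                          rng.uniform(1, 20), rng.uniform(1, 20)])
            g = np.array([rng.uniform(0, 50), rng.uniform(0, 50),
                          rng.uniform(1, 20), rng.uniform(1, 20)])
            assert float(ciou_loss(p, g)) == pytest.approx(reference(p, g), abs=1e-7)

    def test_degenerate_gt_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ciou_loss(np.array([0, 0, 1.0, 1.0]), np.array([0, 0, 0.0, 1.0]))

    def test_giou_variant_zero_at_identity(self):
        box = np.array([3.0, 4.0, 2.0, 9.0])
        assert float(ciou_loss(box, box, kind="giou")) == pytest.approx(0.0, abs=1e-9)


def _perfect_predictions(assignment, cfg, n, n_bins):
    rng = np.random.default_rng(0)
    boxes = assignment.boxes.copy()
    boxes[assignment.obj_mask == 0] = [5, 5, 2, 8]
    cls_logits = np.where(assignment.classes > 0, 40.0, -40.0)
    eps = 1e-12
    angle = np.full((n, n_bins), -40.0)
    for i in np.flatnonzero(assignment.obj_mask):
        t = np.clip(csl_target(int(assignment.angle_bins[i]), cfg.csl_window_radius,
                               n_bins), eps, 1 - eps)
        angle[i] = np.log(t / (1 - t))
    conf = assignment.obj_mask.astype(float)
    return {"boxes": boxes, "conf": conf, "class_logits": cls_logits,
            "angle_logits": angle}


class TestTotalLoss:
    def _assignment(self, rng, n=40, n_pos=6):
        mask = np.zeros(n)
        mask[rng.choice(n, n_pos, replace=False)] = 1.0
        boxes = np.zeros((n, 4))
        boxes[mask > 0] = np.column_stack([
            rng.uniform(10, 80, n_pos), rng.uniform(10, 80, n_pos),
            rng.uniform(2, 10, n_pos), rng.uniform(15, 40, n_pos),
        ])
        bins = np.zeros(n, dtype=int)
        bins[mask > 0] = rng.integers(0, 180, n_pos)
        cls = np.zeros((n, 1))
        cls[mask > 0, 0] = 1.0
        return TargetAssignment(mask, boxes, bins, cls,
                                iou_with_gt=mask.astype(float))

    def test_zero_at_perfect_predictions(self, rng):
        cfg = LossConfig()
        asn = self._assignment(rng)
        preds = _perfect_predictions(asn, cfg, 40, cfg.n_angle_bins)
        total, comps = total_loss(preds, asn, cfg)
        assert float(total) == pytest.approx(0.0, abs=1e-6)

    def test_total_is_sum_of_components(self, rng):
        cfg = LossConfig()
        asn = self._assignment(rng)
        preds = {
            "boxes": np.abs(rng.normal(20, 5, (40, 4))) + 1,
            "conf": rng.uniform(0.01, 0.99, 40),
            "class_logits": rng.normal(0, 2, (40, 1)),
            "angle_logits": rng.normal(0, 2, (40, 180)),
        }
        total, comps = total_loss(preds, asn, cfg)
        assert float(total) == pytest.approx(
            sum(float(c) for c in comps.values()), abs=1e-12
        )

    def test_lambda2_zero_ignores_angle_logits(self, rng):
        cfg = LossConfig(lambda2=0.0)
        asn = self._assignment(rng)
        base = {
            "boxes": np.abs(rng.normal(20, 5, (40, 4))) + 1,
            "conf": rng.uniform(0.01, 0.99, 40),
            "class_logits": rng.normal(0, 2, (40, 1)),
            "angle_logits": rng.normal(0, 2, (40, 180)),
        }
        t1, _ = total_loss(base, asn, cfg)
        shuffled = dict(base, angle_logits=rng.permutation(base["angle_logits"]))
        t2, _ = total_loss(shuffled, asn, cfg)
        assert float(t1) == pytest.approx(float(t2), abs=1e-12)

    def test_all_components_nonnegative(self, rng):
        cfg = LossConfig()
        asn = self._assignment(rng)
        for _ in range(10):
            preds = {
                "boxes": np.abs(rng.normal(20, 5, (40, 4))) + 1,
                "conf": rng.uniform(0.01, 0.99, 40),
                "class_logits": rng.normal(0, 2, (40, 1)),
                "angle_logits": rng.normal(0, 2, (40, 180)),
            }
            total, comps = total_loss(preds, asn, cfg)
            assert float(total) >= 0
            assert all(float(c) >= -1e-9 for c in comps.values())

    def test_monotone_improvement_toward_target(self, rng):
        """Interpolating predictions toward the target lowers the loss."""
        cfg = LossConfig()
        asn = self._assignment(rng)
        perfect = _perfect_predictions(asn, cfg, 40, cfg.n_angle_bins)
        noisy = {
            "boxes": perfect["boxes"] + rng.normal(0, 4, (40, 4)).clip(-3, 3),
            "conf": np.clip(perfect["conf"] + rng.normal(0, 0.2, 40), 0.01, 0.99),
            "class_logits": perfect["class_logits"] * 0.05,
            "angle_logits": perfect["angle_logits"] * 0.05,
        }
        noisy["boxes"] = np.abs(noisy["boxes"]) + 0.5
        losses = []
        for lam in (0.0, 0.5, 1.0):
            preds = {
                k: noisy[k] * (1 - lam) + perfect[k] * lam for k in noisy
            }
            preds["boxes"] = np.abs(preds["boxes"]) + 1e-3
            preds["conf"] = np.clip(preds["conf"], 1e-6, 1 - 1e-6)
            losses.append(float(total_loss(preds, asn, cfg)[0]))
        assert losses[0] >= losses[1] >= losses[2]
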