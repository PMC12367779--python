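"""Detector components: ECA, MobileOne blocks, reparameterization, assembly,
decoding, and a short learning smoke check."""

import numpy as np
import pytest

from rotphenex import _autograd as F
from rotphenex._autograd import Tensor
from rotphenex.losses import LossConfig
from rotphenex.model import (
    HeadOutput, ModelConfig, TrainConfig, build_wheat_rynet, decode_detections,
    flatten_outputs, load_checkpoint, reparameterize, save_checkpoint,
    theta_to_bin, train,
)
from rotphenex.nn import BatchNorm2d, ECA, MobileOneBlock, eca_kernel_size
from rotphenex.rotgeom import RotatedBox


def _tiny_config(**kw):
    defaults = dict(
        input_size=64, width_mult=0.25, seed=0,
        anchors=(((6.0, 24.0), (10.0, 40.0)),
                 ((8.0, 48.0), (14.0, 56.0)),
                 ((12.0, 64.0), (20.0, 80.0))),
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestECA:
    @pytest.mark.parametrize("channels,expected", [(256, 5), (64, 3), (128, 5),
                                                   (512, 5)])
    def test_adaptive_kernel_size(self, channels, expected):
        assert eca_kernel_size(channels, gamma=2.0, b=1.0) == expected

    def test_global_pool_of_constant_channels(self, rng):
        eca = ECA(4)
        c_vals = np.array([1.0, -2.0, 0.5, 3.0])
        x = np.broadcast_to(c_vals[None, :, None, None], (1, 4, 5, 5)).copy()
        z = F.tmean(Tensor(x), axis=(2, 3))
        assert np.allclose(z.data[0], c_vals)

    def test_zero_weights_halve_input(self, rng):
        eca = ECA(8)
        eca.weight.data[:] = 0.0
        x = rng.normal(0, 1, (2, 8, 4, 4))
        out = eca(Tensor(x))
        assert np.allclose(out.data, x / 2.0)

    def test_contraction_and_shape(self, rng):
        eca = ECA(16, rng=rng)
        x = rng.normal(0, 1, (1, 16, 6, 6))
        out = eca(Tensor(x)).data
        assert out.shape == x.shape
        assert np.all(np.abs(out) <= np.abs(x) + 1e-12)


class TestMobileOneBlock:
    def _freeze(self, block, rng, cin, n=5):
        """Populate running statistics, then switch to eval mode."""
        block.train()
        for _ in range(n):
            block(Tensor(rng.normal(0, 1, (2, cin, 8, 8))))
        block.eval()

    def test_train_mode_output_is_sum_of_branches(self, rng):
        block = MobileOneBlock(4, 4, "depthwise", k_branches=3, rng=rng)
        self._freeze(block, rng, 4)
        x = Tensor(rng.normal(0, 1, (1, 4, 8, 8)))
        manual = block.branches[0](x).data
        for br in block.branches[1:]:
            manual = manual + br(x).data
        manual = manual + block.scale_branch(x).data + block.skip_bn(x).data
        assert np.allclose(block(x).data, np.maximum(manual, 0.0), atol=1e-10)

    @pytest.mark.parametrize("kind,cin,cout,stride", [
        ("depthwise", 6, 6, 1), ("depthwise", 6, 6, 2),
        ("pointwise", 6, 10, 1), ("pointwise", 6, 6, 1),
    ])
    def test_reparameterization_equivalence(self, kind, cin, cout, stride, rng):
        """Deployed output equals train-structure output with frozen stats,
        elementwise within 1e-5, over 100 random inputs."""
        block = MobileOneBlock(cin, cout, kind, stride=stride, k_branches=4, rng=rng)
        self._freeze(block, rng, cin)
        xs = [rng.normal(0, 1, (1, cin, 8, 8)) for _ in range(100)]
        before = [block(Tensor(x)).data for x in xs]
        block.reparameterize()
        after = [block(Tensor(x)).data for x in xs]
        worst = max(np.abs(a - b).max() for a, b in zip(before, after))
        assert worst <= 1e-5

    def test_reparameterize_idempotent(self, rng):
        block = MobileOneBlock(4, 4, "depthwise", rng=rng)
        self._freeze(block, rng, 4)
        block.reparameterize()
        w = block.fused_conv.weight.data.copy()
        block.reparameterize()
        assert np.array_equal(block.fused_conv.weight.data, w)

    def test_k1_identity_free_block_equals_plain_conv(self, rng):
        """One branch, no scale/skip contributions: fused kernel equals the
        BN-folded branch kernel exactly."""
        block = MobileOneBlock(4, 8, "pointwise", k_branches=1, rng=rng)
        block.skip_bn = None
        self._freeze(block, rng, 4)
        w_ref, b_ref = block.branches[0].fused()
        block.reparameterize()
        assert np.allclose(block.fused_conv.weight.data, w_ref)
        assert np.allclose(block.fused_conv.bias.data, b_ref)


class TestNetwork:
    def test_forward_shapes_three_scales(self):
        cfg = _tiny_config()
        net = build_wheat_rynet(cfg).eval()
        outs = net(np.zeros((1, 3, 64, 64)))
        assert [o.raw.shape for o in outs] == [
            (1, 2 * cfg.out_per_anchor, 8, 8),
            (1, 2 * cfg.out_per_anchor, 4, 4),
            (1, 2 * cfg.out_per_anchor, 2, 2),
        ]
        assert [o.stride for o in outs] == [8, 16, 32]

    def test_eca_toggle_changes_structure_only(self, rng):
        cfg_on = _tiny_config(use_eca=True)
        cfg_off = _tiny_config(use_eca=False)
        n_on = build_wheat_rynet(cfg_on).num_parameters()
        n_off = build_wheat_rynet(cfg_off).num_parameters()
        assert n_on > n_off  # ECA adds only its small 1-D kernels

    def test_network_level_reparam_equivalence(self, rng):
        net = build_wheat_rynet(_tiny_config())
        net.train()
        for _ in range(3):
            net(Tensor(rng.random((1, 3, 64, 64))))
        net.eval()
        xs = [rng.random((1, 3, 64, 64)) for _ in range(5)]
        before = [[o.raw.data for o in net(x)] for x in xs]
        reparameterize(net)
        after = [[o.raw.data for o in net(x)] for x in xs]
        worst = max(
            np.abs(a - b).max()
            for bs, as_ in zip(before, after)
            for a, b in zip(bs, as_)
        )
        assert worst <= 1e-4

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = build_wheat_rynet(_tiny_config()).eval()
        x = rng.random((1, 3, 64, 64))
        ref = net(x)[0].raw.data
        save_checkpoint(net, tmp_path / "m.ckpt", epoch=3)
        net2, meta = load_checkpoint(tmp_path / "m.ckpt")
        net2.eval()
        assert meta["epoch"] == 3
        assert np.allclose(net2(x)[0].raw.data, ref)


class TestDecode:
    def test_silent_head_gives_no_detections(self):
        net = build_wheat_rynet(_tiny_config()).eval()
        outs = net(np.zeros((1, 3, 64, 64)))
        for o in outs:
            o.raw.data[:, :] = 0.0
            # push objectness strongly negative everywhere
            per = _tiny_config().out_per_anchor
            o.raw.data.reshape(2, per, *o.raw.shape[2:])[:, 4] = -20.0
        assert decode_detections(outs, conf_threshold=0.25) == []

    def test_hand_built_logits_recover_box(self):
        """Inverse-encoding oracle: logits built from a target box decode to
        that box within quantization (sub-pixel center, <= 1 degree)."""
        cfg = _tiny_config()
        net = build_wheat_rynet(cfg).eval()
        outs = net(np.zeros((1, 3, 64, 64)))
        target = RotatedBox(33.0, 29.0, 9.0, 38.0, 41.0)
        per = cfg.out_per_anchor
        for o in outs:
            r = o.raw.data.reshape(len(o.anchors), per, *o.raw.shape[2:])
            r[:] = 0.0
            r[:, 4] = -30.0
        # encode on scale 0 (stride 8), anchor 1 (10, 40)
        o = outs[0]
        r = o.raw.data.reshape(2, per, 8, 8)
        gx, gy = target.cx / 8, target.cy / 8
        cx, cy = int(gx), int(gy)

        def inv_sig(p):
            return np.log(p / (1 - p))

        r[1, 0, cy, cx] = inv_sig((gx - cx + 0.5) / 2)
        r[1, 1, cy, cx] = inv_sig((gy - cy + 0.5) / 2)
        r[1, 2, cy, cx] = inv_sig(np.sqrt(target.w / 10.0) / 2)
        r[1, 3, cy, cx] = inv_sig(np.sqrt(target.h / 40.0) / 2)
        r[1, 4, cy, cx] = 8.0  # objectness
        r[1, 5, cy, cx] = 8.0  # class
        bin_idx = theta_to_bin(target.theta, cfg.n_angle_bins)
        r[1, 5 + 1 + bin_idx, cy, cx] = 10.0
        dets = decode_detections(outs, conf_threshold=0.25)
        assert len(dets) == 1
        box, score = dets[0]
        assert (box.cx, box.cy) == pytest.approx((33.0, 29.0), abs=0.01)
        assert (box.w, box.h) == pytest.approx((9.0, 38.0), rel=0.01)
        assert abs(box.theta - 41.0) <= 1.0
        assert score > 0.9

    def test_duplicate_encodings_suppressed_by_nms(self):
        cfg = _tiny_config()
        net = build_wheat_rynet(cfg).eval()
        outs = net(np.zeros((1, 3, 64, 64)))
        per = cfg.out_per_anchor
        for o in outs:
            r = o.raw.data.reshape(len(o.anchors), per, *o.raw.shape[2:])
            r[:] = 0.0
            r[:, 4] = -30.0
        o = outs[0]
        r = o.raw.data.reshape(2, per, 8, 8)

        def inv_sig(p):
            return np.log(p / (1 - p))

        # both anchors encode the same physical box (8, 36) at the same spot
        for anchor, (aw, ah) in enumerate(o.anchors):
            r[anchor, 0:2, 3, 3] = 0.0
            r[anchor, 2, 3, 3] = inv_sig(np.sqrt(8.0 / aw) / 2)
            r[anchor, 3, 3, 3] = inv_sig(np.sqrt(36.0 / ah) / 2)
            r[anchor, 4, 3, 3] = 8.0
            r[anchor, 5, 3, 3] = 8.0
            r[anchor, 6 + 90, 3, 3] = 10.0
        dets = decode_detections(outs, conf_threshold=0.25, iou_threshold=0.4)
        assert len(dets) == 1


class TestTrainingLoop:
    def _scenes(self, n=2):
        from rotphenex.synthdata import SceneSpec, generate_scene

        spec = SceneSpec(canvas=(64, 64), n_leaves=(1, 2), length_range=(20, 40),
                         aspect_range=(3, 5), noise_sigma=2.0,
                         overlap_allowed=False, seed=5)
        return [generate_scene(spec, seed=s)[1] for s in range(n)]

    def test_loss_decreases_on_tiny_overfit(self):
        records = self._scenes()
        tcfg = TrainConfig(epochs=120, batch_size=2, lr=0.02, seed=0,
                           log_every=100, freeze_bn_frac=1.1)
        net, log = train(records, _tiny_config(), tcfg)
        assert log[-1]["loss"] < 0.7 * log[0]["loss"]

    def test_lambda2_zero_leaves_angle_head_untrained(self):
        """With the angle-loss weight off, angle logits receive no gradient,
        so the angle head's final-layer weights stay at initialization."""
        records = self._scenes()
        cfg = _tiny_config()
        loss_off = LossConfig(lambda2=0.0)
        tcfg = TrainConfig(epochs=3, batch_size=2, lr=0.02, seed=0,
                           weight_decay=0.0, loss=loss_off, log_every=100)
        net0 = build_wheat_rynet(cfg)
        init = [h.weight.data.copy() for h in net0.heads]
        net, _ = train(records, cfg, tcfg)
        per = cfg.out_per_anchor
        for h, w0 in zip(net.heads, init):
            w = h.weight.data.reshape(len(cfg.anchors[0]), per, -1)
            w0r = w0.reshape(len(cfg.anchors[0]), per, -1)
            angle = slice(5 + cfg.num_classes, per)
            assert np.allclose(w[:, angle], w0r[:, angle])
            assert not np.allclose(w[:, :5], w0r[:, :5])

    def test_resume_from_checkpoint(self, tmp_path):
        records = self._scenes()
        cfg = _tiny_config()
        t1 = TrainConfig(epochs=4, batch_size=2, lr=0.01, seed=0, log_every=100)
        net, log = train(records, cfg, t1, checkpoint_path=tmp_path / "a.ckpt")
        t2 = TrainConfig(epochs=6, batch_size=2, lr=0.01, seed=0, log_every=100)
        net2, log2 = train(records, cfg, t2, resume_from=tmp_path / "a.ckpt")
        assert log2[0]["epoch"] == 5
        # resumed loss continues near where the first run stopped
        assert log2[0]["loss"] < 1.5 * log[-1]["loss"] + 1.0
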