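"""The rotated-box leaf detector: backbone, neck, angle-aware head, training.

Architecture: a MobileOne backbone (reparameterizable depthwise-separable
stages) feeds a compact CSP/PAN neck; after each CSP fusion block and before
each head's final convolution sits an ECA channel-attention module; three
detection heads at strides 8/16/32 emit, per anchor and grid cell, box
offsets (x, y, w, h), an objectness score, class scores and logits over the
angle bins.  Angles are predicted as a circular classification over
one-degree bins (180 by default) rather than regressed, and decoded boxes go
through rotated NMS.

Training is plain SGD with momentum and weight decay on the composite loss
of :mod:`rotphenex.losses`; all randomness flows from a single seed.  Width
and depth multipliers scale the network from desk-scale (CPU-trainable on a
handful of scenes) upward.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import _autograd as F
from ._autograd import Tensor
from .annotations import ImageRecord
from .errors import ConfigError, InvalidArgumentError
from .losses import LossConfig, TargetAssignment, total_loss
from .nn import (
    CSPBlock, Conv2d, ConvBNAct, ECA, MobileOneBlock, MobileOneUnit, Module,
)
from .rotgeom import RotatedBox, rotated_iou, rotated_nms, wrap_angle

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig", "HeadOutput", "WheatRYNet", "build_wheat_rynet",
    "reparameterize", "decode_detections", "train", "detect",
    "save_checkpoint", "load_checkpoint",
]

_BASE_CHANNELS = (16, 32, 64, 128, 256)  # scaled by width_mult
_DEFAULT_ANCHORS = (
    ((12.0, 16.0), (19.0, 36.0), (40.0, 28.0)),     # stride 8
    ((36.0, 75.0), (76.0, 55.0), (72.0, 146.0)),    # stride 16
    ((142.0, 110.0), (192.0, 243.0), (459.0, 401.0)),  # stride 32
)


@dataclass
class ModelConfig:
    input_size: int = 640
    num_classes: int = 1
    n_angle_bins: int = 180
    width_mult: float = 1.0
    k_branches: int = 4
    use_eca: bool = True
    anchors: tuple = _DEFAULT_ANCHORS
    anchor_match_threshold: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % 32:
            raise ConfigError("input size must be a multiple of 32")
        if len(self.anchors) != 3:
            raise ConfigError("expect anchors for exactly 3 scales (8/16/32)")
        if self.num_classes < 1 or self.n_angle_bins < 2:
            raise ConfigError("need >= 1 class and >= 2 angle bins")

    @property
    def channels(self) -> tuple:
        return tuple(max(4, int(round(c * self.width_mult))) for c in _BASE_CHANNELS)

    @property
    def strides(self) -> tuple:
        return (8, 16, 32)

    @property
    def out_per_anchor(self) -> int:
        return 4 + 1 + self.num_classes + self.n_angle_bins


@dataclass
class HeadOutput:
    """Raw head tensor plus the geometry needed to decode it."""

    raw: Tensor  # (B, A*(5+nc+nbins), H, W)
    stride: int
    anchors: tuple
    n_classes: int
    n_angle_bins: int

    @property
    def grid_hw(self) -> tuple[int, int]:
        return self.raw.shape[2], self.raw.shape[3]


class _Identity(Module):
    def forward(self, x):
        return x

    __call__ = forward


class WheatRYNet(Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c0, c1, c2, c3, c4 = config.channels
        kb = config.k_branches
        eca = (lambda c: ECA(c, rng=rng)) if config.use_eca else (lambda c: _Identity())

        # MobileOne backbone: strides 2,2,2,2,2 -> features at /8, /16, /32
        self.stem = ConvBNAct(3, c0, 3, stride=2, padding=1, rng=rng)
        self.stage1 = MobileOneUnit(c0, c1, stride=2, k_branches=kb, rng=rng)
        self.stage2 = MobileOneUnit(c1, c2, stride=2, k_branches=kb, rng=rng)  # P3 /8
        self.stage3 = MobileOneUnit(c2, c3, stride=2, k_branches=kb, rng=rng)  # P4 /16
        self.stage4 = MobileOneUnit(c3, c4, stride=2, k_branches=kb, rng=rng)  # P5 /32

        # PAN neck with ECA after each CSP2 block
        self.lat5 = ConvBNAct(c4, c3, 1, rng=rng)
        self.csp4 = CSPBlock(c3 + c3, c3, rng=rng)
        self.eca4 = eca(c3)
        self.lat4 = ConvBNAct(c3, c2, 1, rng=rng)
        self.csp3 = CSPBlock(c2 + c2, c2, rng=rng)
        self.eca3 = eca(c2)
        self.down3 = ConvBNAct(c2, c2, 3, stride=2, padding=1, rng=rng)
        self.csp4b = CSPBlock(c2 + c2, c3, rng=rng)
        self.eca4b = eca(c3)
        self.down4 = ConvBNAct(c3, c3, 3, stride=2, padding=1, rng=rng)
        self.csp5b = CSPBlock(c3 + c3, c4, rng=rng)
        self.eca5b = eca(c4)

        # heads: ECA then the final 1x1 convolution
        na = len(config.anchors[0])
        out_c = na * config.out_per_anchor
        self.head_eca = [eca(c) for c in (c2, c3, c4)]
        self.heads = [
            Conv2d(c, out_c, 1, bias=True, rng=rng) for c in (c2, c3, c4)
        ]
        self._init_head_bias()

    def _init_head_bias(self) -> None:
        # start objectness strongly negative so early confidence is low
        cfg = self.config
        na = len(cfg.anchors[0])
        for head in self.heads:
            b = head.bias.data.reshape(na, cfg.out_per_anchor)
            b[:, 4] = -4.0
            head.bias.data = b.reshape(-1)

    def forward(self, x) -> list[HeadOutput]:
        cfg = self.config
        if not isinstance(x, Tensor):
            x = Tensor(x)
        p1 = self.stage1(self.stem(x))
        p3 = self.stage2(p1)
        p4 = self.stage3(p3)
        p5 = self.stage4(p4)

        t5 = self.lat5(p5)
        m4 = self.eca4(self.csp4(F.concatenate([F.upsample_nearest(t5, 2), p4], axis=1)))
        t4 = self.lat4(m4)
        n3 = self.eca3(self.csp3(F.concatenate([F.upsample_nearest(t4, 2), p3], axis=1)))
        n4 = self.eca4b(self.csp4b(F.concatenate([self.down3(n3), t4], axis=1)))
        n5 = self.eca5b(self.csp5b(F.concatenate([self.down4(n4), t5], axis=1)))

        outs = []
        for feat, head_eca, head, stride, anchors in zip(
            (n3, n4, n5), self.head_eca, self.heads, cfg.strides, cfg.anchors
        ):
            raw = head(head_eca(feat))
            outs.append(
                HeadOutput(raw, stride, anchors, cfg.num_classes, cfg.n_angle_bins)
            )
        return outs

    __call__ = forward


def build_wheat_rynet(config: Optional[ModelConfig] = None) -> WheatRYNet:
    """Construct the detector and log its parameter count."""
    config = config or ModelConfig()
    net = WheatRYNet(config)
    logger.info("built detector with %d parameters", net.num_parameters())
    return net


def reparameterize(net: WheatRYNet) -> WheatRYNet:
    """Fuse every MobileOne block in place for deployment (idempotent)."""
    for m in net.modules():
        if isinstance(m, MobileOneBlock):
            m.reparameterize()
    return net


# ---------------------------------------------------------------------------
# decoding


def _flatten_head(out: HeadOutput):
    """Split one head tensor into per-anchor flat fields (differentiable).

    Returns dict of Tensors with leading dim N = A*H*W: decoded pixel boxes
    (x, y, w, h), objectness probability, class logits, angle logits.
    """
    raw = out.raw
    B, _, H, W = raw.shape
    if B != 1:
        raise InvalidArgumentError("flatten expects batch size 1 per image")
    A = len(out.anchors)
    C = out.n_classes
    nb = out.n_angle_bins
    per = 4 + 1 + C + nb
    r = raw.reshape(A, per, H, W).transpose((0, 2, 3, 1)).reshape(A * H * W, per)

    gy, gx = np.mgrid[0:H, 0:W]
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1)  # (H*W, 2)
    grid = np.tile(grid, (A, 1))
    anchor_wh = np.repeat(np.asarray(out.anchors, dtype=float), H * W, axis=0)

    xy = (F.sigmoid(r[:, 0:2]) * 2.0 - 0.5 + grid) * float(out.stride)
    # floor guards against sigmoid underflow producing zero-sized boxes
    wh = F.clip_min((F.sigmoid(r[:, 2:4]) * 2.0) ** 2 * anchor_wh, 1e-3)
    boxes = F.concatenate([xy, wh], axis=1)
    conf = F.sigmoid(r[:, 4])
    cls_logits = r[:, 5 : 5 + C]
    angle_logits = r[:, 5 + C :]
    return {
        "boxes": boxes,
        "conf": conf,
        "class_logits": cls_logits,
        "angle_logits": angle_logits,
        "grid": grid,
        "anchor_wh": anchor_wh,
        "stride": out.stride,
    }


def flatten_outputs(outputs: Sequence[HeadOutput]) -> dict:
    """Concatenate all scales into flat per-anchor prediction arrays."""
    fields = [_flatten_head(o) for o in outputs]
    flat = {
        key: F.concatenate([f[key] for f in fields], axis=0)
        for key in ("boxes", "conf", "class_logits", "angle_logits")
    }
    flat["scale_sizes"] = [f["conf"].shape[0] for f in fields]
    return flat


def decode_detections(
    outputs: Sequence[HeadOutput],
    conf_threshold: float = 0.25,
    iou_threshold: float = 0.45,
) -> list[tuple[RotatedBox, float]]:
    """Head outputs of one image -> final scored rotated boxes after NMS."""
    flat = flatten_outputs(outputs)
    boxes = F.asdata(flat["boxes"])
    conf = F.asdata(flat["conf"])
    cls_prob = 1.0 / (1.0 + np.exp(-F.asdata(flat["class_logits"])))
    angle_logits = F.asdata(flat["angle_logits"])
    n_bins = angle_logits.shape[1]

    score = conf * cls_prob.max(axis=1)
    keep = np.flatnonzero(score >= conf_threshold)
    dets = []
    for i in keep:
        x, y, w, h = boxes[i]
        if w <= 0 or h <= 0:
            continue
        theta = wrap_angle(float(np.argmax(angle_logits[i])) * (180.0 / n_bins) - 90.0)
        dets.append((RotatedBox(x, y, w, h, theta), float(score[i])))
    kept = rotated_nms(dets, iou_threshold=iou_threshold)
    return [dets[i] for i in kept]


# ---------------------------------------------------------------------------
# target assignment


def theta_to_bin(theta: float, n_bins: int) -> int:
    """Angle in [-90, 90) -> circular bin index."""
    return int(np.floor((wrap_angle(theta) + 90.0) * n_bins / 180.0)) % n_bins


def build_targets(
    record: ImageRecord,
    flat: dict,
    config: ModelConfig,
) -> TargetAssignment:
    """Anchor assignment for one image (shape-ratio matching, cross-grid).

    A ground-truth box is assigned to every anchor whose (w, h) ratio with
    the box is within ``anchor_match_threshold`` at its scale, in its center
    cell and the up-to-two neighbor cells its center is closest to.
    """
    cfg = config
    sizes = flat["scale_sizes"]
    n_total = sum(sizes)
    obj_mask = np.zeros(n_total, dtype=float)
    tboxes = np.zeros((n_total, 4))
    tbins = np.zeros(n_total, dtype=int)
    tcls = np.zeros((n_total, cfg.num_classes))
    offsets = np.cumsum([0] + sizes)

    for ann in record.annotations:
        b = ann.box
        # regression sides: first the short (w), second the long (h)
        gw, gh = b.w, b.h
        for si, (stride, anchors) in enumerate(zip(cfg.strides, cfg.anchors)):
            grid_w = config.input_size // stride
            gx, gy = b.cx / stride, b.cy / stride
            cx_cell, cy_cell = int(gx), int(gy)
            if not (0 <= cx_cell < grid_w and 0 <= cy_cell < grid_w):
                continue
            cells = {(cx_cell, cy_cell)}
            fx, fy = gx - cx_cell, gy - cy_cell
            if fx < 0.5 and cx_cell > 0:
                cells.add((cx_cell - 1, cy_cell))
            if fx >= 0.5 and cx_cell + 1 < grid_w:
                cells.add((cx_cell + 1, cy_cell))
            if fy < 0.5 and cy_cell > 0:
                cells.add((cx_cell, cy_cell - 1))
            if fy >= 0.5 and cy_cell + 1 < grid_w:
                cells.add((cx_cell, cy_cell + 1))
            for ai, (aw, ah) in enumerate(anchors):
                r1, r2 = gw / aw, gh / ah
                ratio = max(r1, 1.0 / r1, r2, 1.0 / r2)
                if ratio >= cfg.anchor_match_threshold:
                    continue
                for (cx_c, cy_c) in cells:
                    idx = offsets[si] + ai * grid_w * grid_w + cy_c * grid_w + cx_c
                    obj_mask[idx] = 1.0
                    tboxes[idx] = (b.cx, b.cy, gw, gh)
                    tbins[idx] = theta_to_bin(b.theta, cfg.n_angle_bins)
                    tcls[idx, 0] = 1.0
    return TargetAssignment(obj_mask, tboxes, tbins, tcls)


def _assignment_iou(flat: dict, assignment: TargetAssignment) -> np.ndarray:
    """Rotated IoU of current predictions with their targets (positives only)."""
    iou = np.zeros_like(assignment.obj_mask)
    boxes = F.asdata(flat["boxes"])
    angle_logits = F.asdata(flat["angle_logits"])
    n_bins = angle_logits.shape[1]
    for idx in np.flatnonzero(assignment.obj_mask > 0):
        x, y, w, h = boxes[idx]
        if w <= 0 or h <= 0:
            continue
        theta = wrap_angle(float(np.argmax(angle_logits[idx])) * 180.0 / n_bins - 90.0)
        gx, gy, gw, gh = assignment.boxes[idx]
        gtheta = wrap_angle(assignment.angle_bins[idx] * 180.0 / n_bins - 90.0)
        try:
            iou[idx] = rotated_iou(
                RotatedBox(x, y, w, h, theta), RotatedBox(gx, gy, gw, gh, gtheta)
            )
        except Exception:
            iou[idx] = 0.0
    return iou


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 8
    lr: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    checkpoint_every: int = 0  # 0 = only final
    log_every: int = 10
    freeze_bn_frac: float = 0.5  # freeze norm statistics after this fraction
    cosine_decay: bool = True  # cosine-anneal the learning rate to lr/10


class SGD:
    def __init__(self, params, lr, momentum=0.9, weight_decay=0.0, max_grad_norm=10.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.max_grad_norm = max_grad_norm
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        if self.max_grad_norm:
            total = np.sqrt(sum(
                float(np.sum(p.grad ** 2)) for p in self.params if p.grad is not None
            ))
            if total > self.max_grad_norm:
                scale = self.max_grad_norm / (total + 1e-12)
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= scale
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _record_to_input(record: ImageRecord, input_size: int) -> np.ndarray:
    """Image -> (1, 3, S, S) float input in [0, 1]; no letterboxing, the
    synthetic pipeline renders at the network size."""
    img = record.load_image()
    if img.shape[0] != input_size or img.shape[1] != input_size:
        from PIL import Image

        img = np.asarray(
            Image.fromarray(img).resize((input_size, input_size), Image.BILINEAR)
        )
    return img.transpose(2, 0, 1)[None].astype(np.float64) / 255.0


def train(
    dataset: Sequence[ImageRecord],
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
    checkpoint_path=None,
    resume_from=None,
) -> tuple[WheatRYNet, list[dict]]:
    """SGD training loop; returns the trained network and per-epoch log.

    Images are processed one at a time (batch-of-one forward passes) and
    gradients are averaged over ``batch_size`` images before each SGD step,
    which is equivalent to mini-batch training for every loss term used.
    """
    dataset = list(dataset)
    if not dataset:
        raise ConfigError("empty training dataset")
    mcfg = model_config or ModelConfig()
    tcfg = train_config or TrainConfig()
    net = build_wheat_rynet(mcfg)
    start_epoch = 0
    if resume_from is not None:
        net, meta = load_checkpoint(resume_from)
        start_epoch = int(meta.get("epoch", 0))
    opt = SGD(net.parameters(), tcfg.lr, tcfg.momentum, tcfg.weight_decay)
    rng = np.random.default_rng(tcfg.seed)
    log: list[dict] = []

    inputs = [_record_to_input(r, mcfg.input_size) for r in dataset]
    scale = mcfg.input_size / dataset[0].width
    scaled_records = dataset
    if abs(scale - 1.0) > 1e-9:
        from dataclasses import replace as _replace

        scaled_records = []
        for r in dataset:
            anns = [
                _replace(
                    a,
                    box=RotatedBox(
                        a.box.cx * scale, a.box.cy * scale,
                        a.box.w * scale, a.box.h * scale, a.box.theta,
                    ),
                )
                for a in r.annotations
            ]
            scaled_records.append(
                ImageRecord(r.image_path, mcfg.input_size, mcfg.input_size, anns)
            )

    net.train()
    from .nn import BatchNorm2d

    freeze_at = int(tcfg.freeze_bn_frac * tcfg.epochs)
    for epoch in range(start_epoch, tcfg.epochs):
        if epoch == freeze_at:
            for m in net.modules():
                if isinstance(m, BatchNorm2d):
                    m.freeze_stats()
        if tcfg.cosine_decay:
            frac = epoch / max(1, tcfg.epochs - 1)
            opt.lr = tcfg.lr * (0.55 + 0.45 * np.cos(np.pi * frac))
        order = rng.permutation(len(dataset))
        t0 = time.time()
        epoch_tot, epoch_comp = 0.0, {"class": 0.0, "conf": 0.0, "loc": 0.0}
        n_seen = 0
        for batch_start in range(0, len(order), tcfg.batch_size):
            batch = order[batch_start : batch_start + tcfg.batch_size]
            opt.zero_grad()
            for bi in batch:
                x = Tensor(inputs[bi], requires_grad=False)
                outputs = net(x)
                flat = flatten_outputs(outputs)
                assignment = build_targets(scaled_records[bi], flat, mcfg)
                assignment.iou_with_gt = _assignment_iou(flat, assignment)
                loss, comps = total_loss(flat, assignment, tcfg.loss)
                loss.backward(np.asarray(1.0 / len(batch)))
                epoch_tot += float(loss.data)
                for k in epoch_comp:
                    epoch_comp[k] += float(F.asdata(comps[k]))
                n_seen += 1
            opt.step()
        entry = {
            "epoch": epoch + 1,
            "loss": epoch_tot / max(1, n_seen),
            **{k: v / max(1, n_seen) for k, v in epoch_comp.items()},
            "seconds": round(time.time() - t0, 2),
        }
        log.append(entry)
        if (epoch + 1) % tcfg.log_every == 0 or epoch == tcfg.epochs - 1:
            logger.info(
                "epoch %d/%d loss %.4f (class %.4f conf %.4f loc %.4f)",
                entry["epoch"], tcfg.epochs, entry["loss"],
                entry["class"], entry["conf"], entry["loc"],
            )
        if checkpoint_path and tcfg.checkpoint_every and (
            (epoch + 1) % tcfg.checkpoint_every == 0
        ):
            save_checkpoint(net, checkpoint_path, epoch=epoch + 1, log=log)
    if checkpoint_path:
        save_checkpoint(net, checkpoint_path, epoch=tcfg.epochs, log=log)
    return net, log


def detect(
    net: WheatRYNet,
    record: ImageRecord,
    conf_threshold: float = 0.25,
    iou_threshold: float = 0.45,
) -> list[tuple[RotatedBox, float]]:
    """Run inference on one record; boxes are returned in the record's pixel frame."""
    was_training = net.training
    net.eval()
    x = Tensor(_record_to_input(record, net.config.input_size))
    outputs = net(x)
    dets = decode_detections(outputs, conf_threshold, iou_threshold)
    if was_training:
        net.train()
    scale = record.width / net.config.input_size
    if abs(scale - 1.0) > 1e-9:
        dets = [
            (RotatedBox(b.cx * scale, b.cy * scale, b.w * scale, b.h * scale, b.theta), s)
            for b, s in dets
        ]
    return dets


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(net: WheatRYNet, path, epoch: int = 0, log=None) -> None:
    """Self-describing archive: config JSON + every parameter/buffer array."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = net.named_state()
    meta = {
        "config": asdict(net.config),
        "epoch": epoch,
        "log": log or [],
        "deployed": any(
            isinstance(m, MobileOneBlock) and m.deployed for m in net.modules()
        ),
    }
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> tuple[WheatRYNet, dict]:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg_dict = meta["config"]
    cfg_dict["anchors"] = tuple(tuple(tuple(a) for a in s) for s in cfg_dict["anchors"])
    cfg = ModelConfig(**cfg_dict)
    net = build_wheat_rynet(cfg)
    if meta.get("deployed"):
        reparameterize(net)
    net.load_state(state)
    return net, meta
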