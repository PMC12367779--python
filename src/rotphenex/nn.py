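"""Neural-network layers on the autodiff engine.

Includes the two structurally reparameterizable MobileOne blocks (depthwise
and pointwise), each trained as a sum of parallel over-parameterized
convolution branches with per-branch batch normalization and algebraically
fused into a single convolution for deployment, and the efficient channel
attention (ECA) module: global average pooling followed by a shared 1-D
convolution across channels and a sigmoid gate.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from . import _autograd as F
from ._autograd import Tensor
from .errors import ConfigError, InvalidArgumentError

__all__ = [
    "Module", "Conv2d", "BatchNorm2d", "ConvBN", "ConvBNAct",
    "MobileOneBlock", "MobileOneUnit", "ECA", "CSPBlock", "eca_kernel_size",
]


class Module:
    """Base class: parameter discovery, train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        seen = set()
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                    seen.add(id(v))
                    yield v

    def named_state(self):
        """Flat name -> ndarray map of parameters and buffers, for checkpoints."""
        out = {}

        def walk(mod, prefix):
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Tensor):
                    out[key] = v.data
                elif isinstance(v, np.ndarray):
                    out[key] = v
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return out

    def load_state(self, state: dict) -> None:
        own = self.named_state()
        missing = set(own) - set(state)
        if missing:
            raise ConfigError(f"checkpoint missing arrays: {sorted(missing)[:5]} ...")
        def walk(mod, prefix):
            for name, v in list(mod.__dict__.items()):
                key = f"{prefix}{name}"
                if isinstance(v, Tensor):
                    v.data = np.array(state[key], dtype=np.float64)
                elif isinstance(v, np.ndarray):
                    setattr(mod, name, np.array(state[key]))
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
        walk(self, "")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, padding=0, groups=1, bias=True, rng=None):
        super().__init__()
        if cin % groups or cout % groups:
            raise InvalidArgumentError("channels must be divisible by groups")
        rng = rng or np.random.default_rng(0)
        fan_in = cin // groups * k * k
        std = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0, std, (cout, cin // groups, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups
        self.k = k

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.groups)

    __call__ = forward


class BatchNorm2d(Module):
    """Batch normalization with freezable statistics.

    After :meth:`freeze_stats` the running estimates are used even in
    training mode (the affine parameters keep learning); freezing late in
    training removes the train/eval statistics mismatch of very small
    batches and is a precondition for exact branch fusion.
    """

    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.eps, self.momentum = eps, momentum
        self.stats_frozen = False

    def freeze_stats(self) -> None:
        self.stats_frozen = True

    def forward(self, x):
        shape = (1, -1, 1, 1)
        if self.training and not self.stats_frozen:
            xd = F.asdata(x)
            mean = xd.mean(axis=(0, 2, 3))
            var = xd.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            if isinstance(x, Tensor) and x.requires_grad:
                mu = x.mean(axis=(0, 2, 3), keepdims=True)
                v = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
                xhat = (x - mu) * (v + self.eps) ** -0.5
            else:
                xhat = (xd - mean.reshape(shape)) / np.sqrt(
                    var.reshape(shape) + self.eps
                )
        else:
            xhat = (x - self.running_mean.reshape(shape)) * (
                1.0 / np.sqrt(self.running_var + self.eps)
            ).reshape(shape)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)

    __call__ = forward

    def affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-channel (scale, shift) equivalent at the frozen running stats."""
        s = self.gamma.data / np.sqrt(self.running_var + self.eps)
        t = self.beta.data - self.running_mean * s
        return s, t


class ConvBN(Module):
    """Convolution followed by batch norm; fusable into one convolution."""

    def __init__(self, cin, cout, k, stride=1, padding=0, groups=1, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, padding, groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x))

    __call__ = forward

    def fused(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (kernel, bias) of the single equivalent convolution."""
        s, t = self.bn.affine()
        w = self.conv.weight.data * s[:, None, None, None]
        return w, t


def _relu(x):
    return F.relu(x)


class ConvBNAct(ConvBN):
    def forward(self, x):
        return _relu(super().forward(x))

    __call__ = forward


class MobileOneBlock(Module):
    """One reparameterizable convolution block.

    ``kind="depthwise"``: k parallel over-parameterized 3x3 depthwise
    branches, a 1x1 depthwise "scale" branch, and a BN-only skip branch
    (stride 1 only) — three path types.  ``kind="pointwise"``: k parallel
    1x1 branches plus a BN-only skip — two path types.  Each branch carries
    its own batch norm; at deployment :meth:`reparameterize` folds the norms
    into the kernels, pads everything to a common kernel size and sums, after
    which the block holds exactly one fused convolution.
    """

    def __init__(self, cin, cout, kind, stride=1, k_branches=4, rng=None):
        super().__init__()
        if kind not in ("depthwise", "pointwise"):
            raise InvalidArgumentError(f"unknown block kind {kind!r}")
        if kind == "depthwise" and cin != cout:
            raise InvalidArgumentError("depthwise block keeps the channel count")
        if k_branches < 1:
            raise InvalidArgumentError("need k >= 1 over-parameterized branches")
        self.kind, self.stride = kind, stride
        self.cin, self.cout = cin, cout
        self.groups = cin if kind == "depthwise" else 1
        self.ksize = 3 if kind == "depthwise" else 1
        self.padding = 1 if kind == "depthwise" else 0
        self.branches = [
            ConvBN(cin, cout, self.ksize, stride, self.padding, self.groups, rng=rng)
            for _ in range(k_branches)
        ]
        self.scale_branch = (
            ConvBN(cin, cout, 1, stride, 0, self.groups, rng=rng)
            if kind == "depthwise"
            else None
        )
        self.skip_bn = (
            BatchNorm2d(cin) if (stride == 1 and cin == cout) else None
        )
        self.deployed = False
        self.fused_conv: Optional[Conv2d] = None

    def forward(self, x):
        if self.deployed:
            return _relu(self.fused_conv(x))
        out = self.branches[0](x)
        for br in self.branches[1:]:
            out = out + br(x)
        if self.scale_branch is not None:
            out = out + self.scale_branch(x)
        if self.skip_bn is not None:
            out = out + self.skip_bn(x)
        return _relu(out)

    __call__ = forward

    def _identity_kernel(self) -> np.ndarray:
        """Kernel of the identity map in this block's convolution geometry."""
        k = self.ksize
        w = np.zeros((self.cout, self.cin // self.groups, k, k))
        for c in range(self.cout):
            w[c, 0 if self.groups > 1 else c, k // 2, k // 2] = 1.0
        return w

    def reparameterize(self) -> None:
        """Fuse all branches into one convolution (idempotent)."""
        if self.deployed:
            return
        k = self.ksize
        total_w = np.zeros((self.cout, self.cin // self.groups, k, k))
        total_b = np.zeros(self.cout)
        for br in self.branches:
            w, b = br.fused()
            total_w += w
            total_b += b
        if self.scale_branch is not None:
            w1, b1 = self.scale_branch.fused()
            pad = (k - 1) // 2
            total_w += np.pad(w1, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
            total_b += b1
        if self.skip_bn is not None:
            s, t = self.skip_bn.affine()
            total_w += self._identity_kernel() * s[:, None, None, None]
            total_b += t
        conv = Conv2d(self.cin, self.cout, k, self.stride, self.padding,
                      self.groups, bias=True)
        conv.weight = Tensor(total_w, requires_grad=True)
        conv.bias = Tensor(total_b, requires_grad=True)
        self.fused_conv = conv
        self.deployed = True


class MobileOneUnit(Module):
    """Depthwise 3x3 block followed by pointwise 1x1 block (one stage step)."""

    def __init__(self, cin, cout, stride=1, k_branches=4, rng=None):
        super().__init__()
        self.dw = MobileOneBlock(cin, cin, "depthwise", stride, k_branches, rng)
        self.pw = MobileOneBlock(cin, cout, "pointwise", 1, k_branches, rng)

    def forward(self, x):
        return self.pw(self.dw(x))

    __call__ = forward


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive odd 1-D kernel size: |log2(C)/gamma + b/gamma|, forced odd."""
    t = int(abs(math.log2(channels) / gamma + b / gamma))
    return t if t % 2 == 1 else t + 1


class ECA(Module):
    """Efficient channel attention without dimensionality reduction.

    Global average pooling gives one value per channel; a shared 1-D
    convolution of adaptive odd kernel size mixes neighboring channels; a
    sigmoid turns the result into per-channel weights in (0, 1) that rescale
    the input map.  Output magnitudes never exceed the input's.
    """

    def __init__(self, channels: int, gamma: float = 2.0, b: float = 1.0, rng=None):
        super().__init__()
        self.channels = channels
        self.ksize = eca_kernel_size(channels, gamma, b)
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(
            rng.normal(0, 1.0 / math.sqrt(self.ksize), (1, 1, self.ksize, 1)),
            requires_grad=True,
        )

    def forward(self, x):
        B, C = x.shape[0], x.shape[1]
        z = F.tmean(x, axis=(2, 3))  # (B, C) global average pool
        z4 = z.reshape(B, 1, C, 1) if isinstance(z, Tensor) else z.reshape(B, 1, C, 1)
        mixed = F.conv2d(z4, self.weight, None, stride=1,
                         padding=(self.ksize // 2, 0))
        attn = F.sigmoid(mixed.reshape(B, C, 1, 1))
        return x * attn

    __call__ = forward


class CSPBlock(Module):
    """Compact CSP-style fusion block (the neck's CSP2_x role).

    The input is split through two 1x1 projections; one half passes through a
    3x3 ConvBN stack, the halves are concatenated and fused by a final 1x1.
    """

    def __init__(self, cin, cout, rng=None):
        super().__init__()
        mid = max(2, cout // 2)
        self.cv1 = ConvBNAct(cin, mid, 1, rng=rng)
        self.cv2 = ConvBNAct(cin, mid, 1, rng=rng)
        self.inner = ConvBNAct(mid, mid, 3, padding=1, rng=rng)
        self.out = ConvBNAct(2 * mid, cout, 1, rng=rng)

    def forward(self, x):
        a = self.inner(self.cv1(x))
        b = self.cv2(x)
        return self.out(F.concatenate([a, b], axis=1))

    __call__ = forward
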