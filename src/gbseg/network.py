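"""SegNet-style encoder–decoder with optional pyramid pooling fusion.

The encoder is a stack of conv→(batch-norm)→ReLU blocks, each followed by a
2x2 max pool that records the argmax position of every pooling window.  The
decoder mirrors the encoder: each stage first *unpools* — scattering the
coarse feature map back to the stored argmax positions, zeros elsewhere —
then convolves.  Reusing the pooling indices instead of learned or
interpolated upsampling is the SegNet signature: boundary positions survive
the bottleneck without storing full-resolution feature maps.

The optional pyramid pooling module sits on the deepest encoder output.  It
average-pools the bottleneck map to several coarse grids (e.g. 1x1, 2x2,
3x3, 6x6), projects each grid down with a learned 1x1 convolution, upsamples
each back bilinearly, concatenates all branches with the original map, and
fuses with a final convolution.  This injects multi-scale context that plain
pooling discards, at unchanged spatial resolution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gbseg import nn
from gbseg.nn import F32


class ShapeError(ValueError):
    """Input spatial size incompatible with the architecture."""


class ConfigurationError(ValueError):
    """Invalid architecture description."""


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture description.

    ``encoder_widths`` gives the channel count of each encoder stage; there is
    one 2x2 max pool per stage, so valid inputs have spatial sizes divisible
    by ``2**len(encoder_widths)``.  Empty ``pyramid_bins`` means plain SegNet.
    """

    in_channels: int = 1
    n_classes: int = 5
    encoder_widths: tuple[int, ...] = (32, 64, 128)
    pyramid_bins: tuple[int, ...] = (1, 2, 3, 6)
    conv_kernel: int = 3
    use_batchnorm: bool = True

    def validate(self) -> None:
        if not self.encoder_widths:
            raise ConfigurationError("encoder_widths must be nonempty")
        if any(w < 1 for w in self.encoder_widths):
            raise ConfigurationError("encoder widths must be positive")
        if any(b < 1 for b in self.pyramid_bins):
            raise ConfigurationError("every pyramid bin must be >= 1")
        if self.conv_kernel % 2 == 0 or self.conv_kernel < 1:
            raise ConfigurationError("conv_kernel must be odd and positive")

    @property
    def n_stages(self) -> int:
        return len(self.encoder_widths)

    @property
    def size_multiple(self) -> int:
        return 2 ** self.n_stages

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for k in ("encoder_widths", "pyramid_bins"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PoolingIndices:
    """Per-stage argmax positions of each 2x2 pooling window."""

    indices: np.ndarray          # (N, C, Ho, Wo) flat positions into the pre-pool map
    input_hw: tuple[int, int]    # spatial size of the map that was pooled


def relu(x):
    """Rectifier: identity for positive inputs, zero otherwise; idempotent."""
    return np.maximum(x, 0)


def _as_nchw(fm: np.ndarray) -> tuple[np.ndarray, int]:
    fm = np.asarray(fm)
    added = 0
    while fm.ndim < 4:
        fm = fm[None]
        added += 1
    if fm.ndim != 4:
        raise ShapeError(f"expected <=4-D feature map, got {fm.ndim}-D")
    return fm, added


def max_pool_with_indices(fm: np.ndarray) -> tuple[np.ndarray, PoolingIndices]:
    """2x2 stride-2 max pooling, recording the winning position per window."""
    x, added = _as_nchw(fm)
    h, w = x.shape[2:]
    if h % 2 or w % 2:
        raise ShapeError(f"2x2 pooling needs even spatial dims, got {h}x{w}")
    pooled, idx = nn.max_pool2d(x.astype(F32, copy=False))
    for _ in range(added):
        pooled, idx = pooled[0], idx[0]
    return pooled, PoolingIndices(indices=idx, input_hw=(h, w))


def max_unpool(fm: np.ndarray, idx: PoolingIndices,
               out_size: tuple[int, int] | None = None) -> np.ndarray:
    """Place fm's values at the stored argmax positions; zeros elsewhere."""
    out_size = tuple(out_size) if out_size is not None else idx.input_hw
    x, added = _as_nchw(fm)
    indices, _ = _as_nchw(idx.indices)
    try:
        out = nn.max_unpool2d(x.astype(F32, copy=False), indices, out_size)
    except ValueError as exc:
        raise ShapeError(str(exc)) from exc
    for _ in range(added):
        out = out[0]
    return out


class ConvBlock(nn.Layer):
    """conv → optional batch-norm → ReLU."""

    def __init__(self, cin: int, cout: int, kernel: int, batchnorm: bool,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, kernel, rng)
        self.bn = nn.BatchNorm2d(cout) if batchnorm else None
        self.act = nn.ReLU()

    def forward(self, x):
        x = self.conv.forward(x)
        if self.bn is not None:
            x = self.bn.forward(x)
        return self.act.forward(x)

    def backward(self, g):
        g = self.act.backward(g)
        if self.bn is not None:
            g = self.bn.backward(g)
        return self.conv.backward(g)

    def parameters(self):
        ps = self.conv.parameters()
        if self.bn is not None:
            ps += self.bn.parameters()
        return ps

    def buffers(self):
        return self.bn.buffers() if self.bn is not None else []

    def set_training(self, mode):
        for layer in (self.conv, self.bn, self.act):
            if layer is not None:
                layer.set_training(mode)


class PyramidPooling(nn.Layer):
    """Multi-scale context fusion at the bottleneck.

    Each branch: adaptive average pool to b x b → 1x1 conv projecting to
    channels // len(bins) → optional BN → ReLU → bilinear upsample back.
    Branches are concatenated with the input and fused by a conv block, so
    the output has the input's channel count and spatial size.
    """

    def __init__(self, channels: int, bins: tuple[int, ...], kernel: int,
                 batchnorm: bool, rng: np.random.Generator):
        super().__init__()
        if not bins:
            raise ConfigurationError("pyramid bins must be nonempty")
        self.bins = tuple(bins)
        self.channels = channels
        proj_c = max(1, channels // len(bins))
        self.pools = [nn.AdaptiveAvgPool2d(b) for b in bins]
        self.projs = [ConvBlock(channels, proj_c, 1, batchnorm, rng) for _ in bins]
        self.ups: list[nn.BilinearUpsample] = []
        self.fuse = ConvBlock(channels + proj_c * len(bins), channels,
                              kernel, batchnorm, rng)
        self._split: list[int] | None = None

    def forward(self, x):
        h, w = x.shape[2:]
        if max(self.bins) > min(h, w):
            raise ConfigurationError(
                f"pyramid bin {max(self.bins)} exceeds feature-map size {h}x{w}")
        self.ups = [nn.BilinearUpsample((h, w)) for _ in self.bins]
        branches = [x]
        for pool, proj, up in zip(self.pools, self.projs, self.ups):
            branches.append(up.forward(proj.forward(pool.forward(x))))
        self._split = [b.shape[1] for b in branches]
        return self.fuse.forward(np.concatenate(branches, axis=1))

    def backward(self, g):
        g = self.fuse.backward(g)
        offsets = np.cumsum([0] + self._split)
        grad_in = g[:, offsets[0]:offsets[1]].copy()
        for k, (pool, proj, up) in enumerate(zip(self.pools, self.projs, self.ups)):
            gb = g[:, offsets[k + 1]:offsets[k + 2]]
            grad_in += pool.backward(proj.backward(up.backward(gb)))
        return grad_in

    def parameters(self):
        ps = []
        for proj in self.projs:
            ps += proj.parameters()
        return ps + self.fuse.parameters()

    def buffers(self):
        bs = []
        for proj in self.projs:
            bs += proj.buffers()
        return bs + self.fuse.buffers()

    def set_training(self, mode):
        for proj in self.projs:
            proj.set_training(mode)
        self.fuse.set_training(mode)


def pyramid_pool(fm: np.ndarray, bins: list[int], seed: int = 0) -> np.ndarray:
    """Apply a freshly initialized pyramid pooling module to one feature map.

    Convenience functional form (projection weights drawn from ``seed``); for
    training, the module lives inside :class:`SegNet`.
    """
    x, added = _as_nchw(np.asarray(fm, dtype=F32))
    module = PyramidPooling(x.shape[1], tuple(bins), 3, False,
                            np.random.default_rng(seed))
    module.set_training(False)
    out = module.forward(x)
    for _ in range(added):
        out = out[0]
    return out


class SegNet:
    """The full encoder–decoder; forward/backward are explicit methods."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        widths = config.encoder_widths
        k, bn = config.conv_kernel, config.use_batchnorm

        self.enc_blocks: list[ConvBlock] = []
        cin = config.in_channels
        for w in widths:
            self.enc_blocks.append(ConvBlock(cin, w, k, bn, rng))
            cin = w
        self.pools = [nn.MaxPool2d() for _ in widths]
        self.pyramid = (PyramidPooling(widths[-1], config.pyramid_bins, k, bn, rng)
                        if config.pyramid_bins else None)
        self.unpools = [nn.MaxUnpool2d() for _ in widths]
        self.dec_blocks: list[ConvBlock] = []
        dec_out = list(widths[:-1][::-1]) + [widths[0]]
        cin = widths[-1]
        for w in dec_out:
            self.dec_blocks.append(ConvBlock(cin, w, k, bn, rng))
            cin = w
        self.classifier = nn.Conv2d(widths[0], config.n_classes, 1, rng)
        self.training = True

    # -- plumbing -----------------------------------------------------------

    def _modules(self):
        mods = list(self.enc_blocks) + self.pools
        if self.pyramid is not None:
            mods.append(self.pyramid)
        return mods + self.unpools + list(self.dec_blocks) + [self.classifier]

    def parameters(self) -> list[nn.Parameter]:
        ps = []
        for m in self._modules():
            ps += m.parameters()
        return ps

    def buffers(self) -> list[np.ndarray]:
        bs = []
        for m in self._modules():
            bs += m.buffers()
        return bs

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self):
        self.training = True
        for m in self._modules():
            m.set_training(True)

    def eval(self):
        self.training = False
        for m in self._modules():
            m.set_training(False)

    # -- computation --------------------------------------------------------

    def _prepare(self, image: np.ndarray) -> tuple[np.ndarray, int]:
        x = np.asarray(image, dtype=F32)
        added = 0
        if x.ndim == 2:
            x = x[None, None]
            added = 2
        elif x.ndim == 3:
            x = x[:, None]
            added = 1
        elif x.ndim != 4:
            raise ShapeError(f"expected 2-D, 3-D or 4-D input, got {x.ndim}-D")
        h, w = x.shape[2:]
        mult = self.config.size_multiple
        if h % mult or w % mult:
            raise ShapeError(
                f"input spatial size {h}x{w} must be divisible by {mult} "
                f"({self.config.n_stages} pooling stages)")
        return x, added

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel class scores at input resolution.

        2-D input gives (n_classes, H, W); batched input gives
        (N, n_classes, H, W).  Channel argmax is the predicted label mask.
        """
        x, added = self._prepare(image)
        self._sizes = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x)
            self._sizes.append(x.shape[2:])
            x = pool.forward(x)
        if self.pyramid is not None:
            x = self.pyramid.forward(x)
        for unpool, block, pool, size in zip(self.unpools, self.dec_blocks,
                                             self.pools[::-1], self._sizes[::-1]):
            x = unpool.forward(x, pool.indices, size)
            x = block.forward(x)
        x = self.classifier.forward(x)
        if added == 2:
            return x[0]
        return x

    def backward(self, grad_logits: np.ndarray) -> None:
        g = grad_logits
        if g.ndim == 3:
            g = g[None]
        g = self.classifier.backward(g.astype(F32, copy=False))
        for unpool, block in zip(self.unpools[::-1], self.dec_blocks[::-1]):
            g = block.backward(g)
            g = unpool.backward(g)
        if self.pyramid is not None:
            g = self.pyramid.backward(g)
        for block, pool in zip(self.enc_blocks[::-1], self.pools[::-1]):
            g = pool.backward(g)
            g = block.backward(g)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Predicted label mask (argmax over class scores), in eval mode."""
        was_training = self.training
        self.eval()
        scores = self.forward(image)
        if was_training:
            self.train()
        axis = 0 if scores.ndim == 3 else 1
        return scores.argmax(axis=axis)

    # -- checkpointing ------------------------------------------------------

    def save(self, path: Path) -> None:
        """Single-file checkpoint: every parameter and buffer plus the config."""
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        arrays.update({f"buffer_{i}": b for i, b in enumerate(self.buffers())})
        np.savez(path, config=json.dumps(self.config.to_dict()), **arrays)

    @classmethod
    def load(cls, path: Path) -> "SegNet":
        with np.load(path, allow_pickle=False) as ckpt:
            config = NetworkConfig.from_dict(json.loads(str(ckpt["config"])))
            model = cls(config)
            for i, p in enumerate(model.parameters()):
                p.data[...] = ckpt[f"param_{i}"]
            for i, b in enumerate(model.buffers()):
                b[...] = ckpt[f"buffer_{i}"]
        return model
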