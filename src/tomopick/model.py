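"""Lightweight 3D residual U-Net for voxel-wise particle segmentation.

The network maps a subtomogram to per-voxel class probabilities (background
plus one channel per particle class). Architecture: a stem block at full
resolution followed by three encoder stages, each halving the spatial size
(2x2x2 max pooling) and doubling the channel width; a mirrored decoder using
2x2x2 transpose convolutions and skip concatenations; a 1x1x1 head followed
by a per-voxel softmax. ELU activations throughout.

Three architectural options mirror the ablation axes of the method:

* ``use_residual`` — encoder/decoder blocks are residual (two 3x3x3
  convolutions plus an identity skip, with a 1x1x1 projection when channel
  counts differ) instead of plain double convolutions;
* ``use_coordconv`` — three channels of per-axis coordinates normalized to
  [-1, 1] are appended to the input, giving the filters spatial context;
* ``use_pyramid`` — 2x/4x/8x average-downsampled copies of the raw input are
  concatenated to the inputs of encoder stages 1-3, preserving coarse image
  features at every resolution level.

The three max-poolings require input side lengths divisible by 8.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from tomopick.nn import (
    Conv3d, ConvTranspose3d, ELU, MaxPool2, Norm3d, Param, avg_downsample,
)

__all__ = ["ModelConfig", "ScoreMap", "ResUNet3D", "build_model",
           "count_parameters", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``n_classes`` includes the background channel, so a single particle
    species needs ``n_classes=2``. ``base_channels`` sets the width of the
    full-resolution stage; widths double at each of the three (fixed)
    downsampling stages.
    """

    n_classes: int = 2
    base_channels: int = 32
    use_residual: bool = True
    use_coordconv: bool = True
    use_pyramid: bool = True
    use_norm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2 (background + particles)")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")


@dataclass
class ScoreMap:
    """Per-class probability volumes, shape (n_classes, z, y, x)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("score map must be 4D (class, z, y, x)")

    @property
    def n_classes(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


class _Block:
    """Double-convolution block, optionally residual."""

    def __init__(self, name: str, cin: int, cout: int, residual: bool,
                 use_norm: bool, rng: np.random.Generator):
        self.residual = residual
        self.conv1 = Conv3d(f"{name}.conv1", cin, cout, 3, rng)
        self.conv2 = Conv3d(f"{name}.conv2", cout, cout, 3, rng)
        self.n1 = Norm3d(f"{name}.n1", cout) if use_norm else None
        self.n2 = Norm3d(f"{name}.n2", cout) if use_norm else None
        self.act1 = ELU()
        self.act2 = ELU()
        self.proj = None
        self.nproj = None
        if residual and cin != cout:
            self.proj = Conv3d(f"{name}.proj", cin, cout, 1, rng)
            if use_norm:
                self.nproj = Norm3d(f"{name}.nproj", cout)

    def sublayers(self):
        out = [self.conv1, self.conv2]
        if self.n1 is not None:
            out += [self.n1, self.n2]
        if self.proj is not None:
            out.append(self.proj)
        if self.nproj is not None:
            out.append(self.nproj)
        return out

    def params(self) -> list[Param]:
        return [p for l in self.sublayers() for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.conv1.forward(x, train)
        if self.n1 is not None:
            h = self.n1.forward(h, train)
        h = self.act1.forward(h, train)
        h = self.conv2.forward(h, train)
        if self.n2 is not None:
            h = self.n2.forward(h, train)
        if self.residual:
            s = x
            if self.proj is not None:
                s = self.proj.forward(s, train)
                if self.nproj is not None:
                    s = self.nproj.forward(s, train)
            h = h + s
        return self.act2.forward(h, train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.act2.backward(g)
        gs = g if self.residual else None
        if self.n2 is not None:
            g = self.n2.backward(g)
        g = self.conv2.backward(g)
        g = self.act1.backward(g)
        if self.n1 is not None:
            g = self.n1.backward(g)
        gx = self.conv1.backward(g)
        if self.residual:
            if self.proj is not None:
                gp = gs
                if self.nproj is not None:
                    gp = self.nproj.backward(gp)
                gx = gx + self.proj.backward(gp)
            else:
                gx = gx + gs
        return gx


class _SingleConv:
    """Conv-norm-ELU unit used for the full-resolution stem and its mirror."""

    def __init__(self, name: str, cin: int, cout: int, use_norm: bool,
                 rng: np.random.Generator):
        self.conv = Conv3d(f"{name}.conv1", cin, cout, 3, rng)
        self.n1 = Norm3d(f"{name}.n1", cout) if use_norm else None
        self.act = ELU()

    def sublayers(self):
        return [self.conv] + ([self.n1] if self.n1 is not None else [])

    def params(self) -> list[Param]:
        return [p for l in self.sublayers() for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.conv.forward(x, train)
        if self.n1 is not None:
            h = self.n1.forward(h, train)
        return self.act.forward(h, train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.act.backward(g)
        if self.n1 is not None:
            g = self.n1.backward(g)
        return self.conv.backward(g)


class ResUNet3D:
    """Encoder-decoder segmentation network; see module docstring."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        b = config.base_channels
        res, norm = config.use_residual, config.use_norm
        cin = 1 + (3 if config.use_coordconv else 0)
        pyr = 1 if config.use_pyramid else 0
        self.stem = _SingleConv("stem", cin, b, norm, rng)
        self.stem.conv.need_input_grad = False
        self.enc1 = _Block("enc1", b + pyr, 2 * b, res, norm, rng)
        self.enc2 = _Block("enc2", 2 * b + pyr, 4 * b, res, norm, rng)
        self.enc3 = _Block("enc3", 4 * b + pyr, 8 * b, res, norm, rng)
        self.up3 = ConvTranspose3d("up3", 8 * b, 4 * b, rng)
        self.dec3 = _Block("dec3", 8 * b, 4 * b, res, norm, rng)
        self.up2 = ConvTranspose3d("up2", 4 * b, 2 * b, rng)
        self.dec2 = _Block("dec2", 4 * b, 2 * b, res, norm, rng)
        self.up1 = ConvTranspose3d("up1", 2 * b, b, rng)
        self.dec1 = _SingleConv("dec1", 2 * b, b, norm, rng)
        self.head = Conv3d("head", b, config.n_classes, 1, rng)
        self.pools = [MaxPool2() for _ in range(3)]
        self._pyr_channels = pyr

    # -- parameter plumbing -------------------------------------------------
    def _blocks(self):
        return [self.stem, self.enc1, self.enc2, self.enc3,
                self.dec3, self.dec2, self.dec1]

    def params(self) -> list[Param]:
        out = []
        for blk in self._blocks():
            out += blk.params()
        for l in (self.up3, self.up2, self.up1, self.head):
            out += l.params()
        return out

    def norm_layers(self) -> list[Norm3d]:
        out = []
        for blk in self._blocks():
            out += [l for l in blk.sublayers() if isinstance(l, Norm3d)]
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- forward / backward -------------------------------------------------
    @staticmethod
    def _check_shape(shape) -> None:
        if any(s % 8 for s in shape):
            raise ValueError(
                f"input side lengths must be divisible by 8 (three halvings), got {tuple(shape)}")

    @staticmethod
    def _coord_channels(shape) -> np.ndarray:
        axes = [np.linspace(-1.0, 1.0, s, dtype=np.float32) if s > 1
                else np.zeros(s, dtype=np.float32) for s in shape]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        return np.stack([zz, yy, xx])

    def forward_logits(self, volume: np.ndarray, train: bool = False) -> np.ndarray:
        """Pre-softmax class scores for a (z, y, x) volume."""
        volume = np.asarray(volume, dtype=np.float32)
        if volume.ndim != 3:
            raise ValueError("expected a 3D (z, y, x) volume")
        self._check_shape(volume.shape)
        x = volume[None]
        if self.config.use_coordconv:
            x = np.concatenate([x, self._coord_channels(volume.shape)])
        pyramids = []
        if self.config.use_pyramid:
            pyramids = [avg_downsample(volume[None], f) for f in (2, 4, 8)]

        s = self.stem.forward(x, train)
        h = self.pools[0].forward(s, train)
        if pyramids:
            h = np.concatenate([h, pyramids[0]])
        e1 = self.enc1.forward(h, train)
        h = self.pools[1].forward(e1, train)
        if pyramids:
            h = np.concatenate([h, pyramids[1]])
        e2 = self.enc2.forward(h, train)
        h = self.pools[2].forward(e2, train)
        if pyramids:
            h = np.concatenate([h, pyramids[2]])
        e3 = self.enc3.forward(h, train)

        h = np.concatenate([self.up3.forward(e3, train), e2])
        d3 = self.dec3.forward(h, train)
        h = np.concatenate([self.up2.forward(d3, train), e1])
        d2 = self.dec2.forward(h, train)
        h = np.concatenate([self.up1.forward(d2, train), s])
        d1 = self.dec1.forward(h, train)
        return self.head.forward(d1, train)

    def backward(self, g_logits: np.ndarray) -> None:
        """Accumulate parameter gradients given d(loss)/d(logits)."""
        b = self.config.base_channels
        pyr = self._pyr_channels
        g = self.head.backward(g_logits)
        g = self.dec1.backward(g)
        g_up, g_stem = g[:b], g[b:]
        g = self.dec2.backward(self.up1.backward(g_up))
        g_up, g_e1 = g[:2 * b], g[2 * b:]
        g = self.dec3.backward(self.up2.backward(g_up))
        g_up, g_e2 = g[:4 * b], g[4 * b:]
        g = self.enc3.backward(self.up3.backward(g_up))
        if pyr:
            g = g[:-pyr]  # pyramid branch carries no trainable upstream
        g_e2 = g_e2 + self.pools[2].backward(g)
        g = self.enc2.backward(g_e2)
        if pyr:
            g = g[:-pyr]
        g_e1 = g_e1 + self.pools[1].backward(g)
        g = self.enc1.backward(g_e1)
        if pyr:
            g = g[:-pyr]
        g_stem = g_stem + self.pools[0].backward(g)
        self.stem.backward(g_stem)

    def predict_proba(self, volume: np.ndarray) -> "ScoreMap":
        """Softmax probabilities for a (z, y, x) volume (evaluation mode)."""
        logits = self.forward_logits(volume, train=False)
        return ScoreMap(softmax_channels(logits))

    # -- state --------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data for p in self.params()}
        for i, n in enumerate(self.norm_layers()):
            for key, val in n.state().items():
                state[f"norm{i}.{key}"] = val
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.data = np.array(state[p.name], dtype=np.float32)
        for i, n in enumerate(self.norm_layers()):
            n.running_mean = np.array(state[f"norm{i}.running_mean"], dtype=np.float32)
            n.running_var = np.array(state[f"norm{i}.running_var"], dtype=np.float32)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the leading (class) axis."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def build_model(config: ModelConfig) -> ResUNet3D:
    """Construct a :class:`ResUNet3D` from its configuration."""
    return ResUNet3D(config)


def count_parameters(model: ResUNet3D, include_head: bool = True) -> int:
    """Exact trainable-parameter count."""
    params = model.params()
    if not include_head:
        head_names = {p.name for p in model.head.params()}
        params = [p for p in params if p.name not in head_names]
    return int(sum(p.data.size for p in params))


def save_checkpoint(model: ResUNet3D, path: str | os.PathLike) -> Path:
    """Save weights plus the embedded config to a single ``.npz`` file."""
    path = Path(path)
    state = model.state_dict()
    np.savez(path, __config__=np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8), **state)
    return path


def load_checkpoint(path: str | os.PathLike) -> ResUNet3D:
    """Rebuild a model (config included) from :func:`save_checkpoint` output."""
    with np.load(Path(path)) as f:
        cfg = ModelConfig(**json.loads(bytes(f["__config__"]).decode()))
        model = build_model(cfg)
        model.load_state_dict({k: f[k] for k in f.files if k != "__config__"})
    return model
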