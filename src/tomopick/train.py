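"""Weakly supervised training of the segmentation network.

Training pairs are subtomograms centered on annotated particles (shifted
inward at volume boundaries, never padded), so every training window
contains at least one particle and all annotations are used. The loss is a
multi-class Dice loss over foreground classes computed on softmax
probabilities; optimization uses AdamW. After every epoch the model is run
through the full inference chain (overlap-tile prediction + MP-NMS picking)
on a held-out validation scene and scored with the recall-weighted F1
variant ``F1_alpha = 2*P*R^alpha / (P + R^alpha)``; the checkpoint with the
best validation score is returned. ``alpha > 1`` favors recall, which is
the right bias for picking: false positives are cheap to discard during
later subtomogram classification, missed particles are gone for good.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter, map_coordinates

from tomopick.io import ParticleSet, Tomogram
from tomopick.labels import LabelVolume
from tomopick.model import ResUNet3D, ScoreMap, softmax_channels
from tomopick.nn import AdamW

__all__ = [
    "TrainConfig", "TrainSample", "TrainResult",
    "sample_training_subtomograms", "augment_sample",
    "dice_loss", "f1_alpha", "train", "write_history",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    ``N`` is the cubic subtomogram side (divisible by 8); ``alpha`` the
    recall exponent of the validation score; ``epsilon`` the Dice
    stabilizer.
    """

    N: int = 64
    lr: float = 1e-3
    weight_decay: float = 0.01
    epochs: int = 60
    batch_size: int = 4
    alpha: float = 3.0
    epsilon: float = 1e-8
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N % 8:
            raise ValueError(f"subtomogram side N must be divisible by 8, got {self.N}")
        if self.lr <= 0 or self.weight_decay <= 0:
            raise ValueError("lr and weight_decay must be positive")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainSample:
    """A training window and its label crop (shapes match)."""

    volume: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        if self.volume.shape != self.label.shape:
            raise ValueError("volume and label shapes must match")


@dataclass
class TrainResult:
    """Trained model, per-epoch history, and the best-validation epoch."""

    model: ResUNet3D
    history: list[dict]
    best_epoch: int | None = None
    best_f1_alpha: float | None = None


def sample_training_subtomograms(tomogram: Tomogram, labels: LabelVolume,
                                 particles: ParticleSet, N: int,
                                 seed: int | np.random.Generator = 0
                                 ) -> list[TrainSample]:
    """One particle-centered N-cube window per annotated particle.

    Windows whose particle lies within N/2 of a boundary are shifted inward
    rather than padded. Each returned label crop contains foreground.
    """
    data = tomogram.data
    shape = np.array(data.shape)
    if np.any(shape < N):
        raise ValueError(f"subtomogram size {N} exceeds tomogram shape {tuple(shape)}")
    samples = []
    for rec in particles:
        c = np.floor(rec.center + 0.5).astype(int)
        lo = np.clip(c - N // 2, 0, shape - N)
        sl = tuple(slice(a, a + N) for a in lo)
        vol = np.ascontiguousarray(data[sl], dtype=np.float32)
        lab = np.ascontiguousarray(labels.data[sl])
        if not np.any(lab):
            raise ValueError(
                f"window for particle at {rec.center} contains no foreground label")
        samples.append(TrainSample(vol, lab))
    return samples


def _affine_zyx(sample: TrainSample, scale: float, angle_deg: float) -> TrainSample:
    """Scale about the center and rotate about the z axis."""
    theta = np.deg2rad(angle_deg)
    cos, sin = np.cos(theta), np.sin(theta)
    # output->input map on (z, y, x): inverse rotation in the (y, x) plane / scale
    mat = np.array([[1.0, 0.0, 0.0],
                    [0.0, cos, sin],
                    [0.0, -sin, cos]]) / scale
    center = (np.array(sample.volume.shape) - 1) / 2.0
    offset = center - mat @ center
    vol = affine_transform(sample.volume, mat, offset=offset, order=1, mode="nearest")
    lab = affine_transform(sample.label, mat, offset=offset, order=0, mode="nearest")
    return TrainSample(vol.astype(np.float32), lab)


def _elastic(sample: TrainSample, rng: np.random.Generator, max_frac: float = 0.05
             ) -> TrainSample:
    """Smooth random displacement field with max magnitude < max_frac * N."""
    shape = sample.volume.shape
    n = shape[0]
    disp = np.stack([gaussian_filter(rng.normal(size=shape), sigma=n / 8.0)
                     for _ in range(3)])
    norms = np.sqrt((disp ** 2).sum(axis=0))
    peak = norms.max()
    if peak > 0:
        disp *= rng.uniform(0.0, max_frac) * n / peak
    grid = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    coords = [g + d for g, d in zip(grid, disp)]
    vol = map_coordinates(sample.volume, coords, order=1, mode="nearest")
    lab = map_coordinates(sample.label, coords, order=0, mode="nearest")
    return TrainSample(vol.astype(np.float32), lab)


def augment_sample(sample: TrainSample, rng: np.random.Generator) -> TrainSample:
    """Randomized augmentation; each transform fires independently (p=0.5).

    Mirrors along random axes; scaling in [0.95, 1.05] combined with a
    rotation about z within +/-15 degrees; elastic deformation below 5% of
    the window side. Volumes are interpolated trilinearly, labels with
    nearest-neighbor; the shape never changes.
    """
    vol, lab = sample.volume, sample.label
    if rng.random() < 0.5:
        axes = [ax for ax in range(3) if rng.random() < 0.5]
        if axes:
            vol = np.flip(vol, axis=axes).copy()
            lab = np.flip(lab, axis=axes).copy()
    out = TrainSample(vol, lab)
    do_scale = rng.random() < 0.5
    do_rot = rng.random() < 0.5
    scale = rng.uniform(0.95, 1.05) if do_scale else 1.0
    angle = rng.uniform(-15.0, 15.0) if do_rot else 0.0
    if do_scale or do_rot:
        out = _affine_zyx(out, scale, angle)
    if rng.random() < 0.5:
        out = _elastic(out, rng)
    return out


def _one_hot(label: np.ndarray, n_classes: int) -> np.ndarray:
    eye = np.eye(n_classes, dtype=np.float32)
    return np.moveaxis(eye[label], -1, 0)


def dice_loss(pred: ScoreMap | np.ndarray, truth: LabelVolume | np.ndarray,
              epsilon: float = 1e-8) -> float:
    """Multi-class Dice loss averaged over foreground classes.

    Per foreground class c: ``1 - (2*sum(p*g) + eps) / (sum(p^2) + sum(g^2)
    + eps)`` with g the one-hot truth; the background channel is supervised
    implicitly through the softmax. The value lies in [0, 1].
    """
    p = pred.data if isinstance(pred, ScoreMap) else np.asarray(pred)
    g = truth.data if isinstance(truth, LabelVolume) else np.asarray(truth)
    if p.shape[1:] != g.shape:
        raise ValueError(f"prediction {p.shape[1:]} and truth {g.shape} shapes differ")
    onehot = _one_hot(g.astype(int), p.shape[0])
    loss, _ = _dice_fg(p.astype(np.float64), onehot.astype(np.float64), epsilon,
                       want_grad=False)
    return float(loss)


def _dice_fg(p: np.ndarray, onehot: np.ndarray, epsilon: float, want_grad: bool
             ) -> tuple[float, np.ndarray | None]:
    """Dice loss over foreground channels and (optionally) d(loss)/d(p)."""
    n_classes = p.shape[0]
    n_fg = n_classes - 1
    loss = 0.0
    grad = np.zeros_like(p) if want_grad else None
    for c in range(1, n_classes):
        pc, gc = p[c], onehot[c]
        s1 = float((pc * gc).sum())
        s2 = float((pc * pc).sum())
        s3 = float((gc * gc).sum())
        denom = s2 + s3 + epsilon
        loss += 1.0 - (2.0 * s1 + epsilon) / denom
        if want_grad:
            grad[c] = (-(2.0 * gc * denom - (2.0 * s1 + epsilon) * 2.0 * pc)
                       / (denom * denom)) / n_fg
    return loss / n_fg, grad


def f1_alpha(p: float, r: float, alpha: float = 3.0) -> float:
    """Recall-weighted F1: ``2*P*R^alpha / (P + R^alpha)``; 0/0 -> 0."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("P and R must lie in [0, 1]")
    denom = p + r ** alpha
    return 2.0 * p * r ** alpha / denom if denom > 0 else 0.0


def _loss_and_backward(model: ResUNet3D, sample: TrainSample, epsilon: float,
                       grad_scale: float) -> float:
    """Forward, Dice loss, and gradient accumulation for one sample."""
    logits = model.forward_logits(sample.volume, train=True)
    p = softmax_channels(logits).astype(np.float32)
    onehot = _one_hot(sample.label.astype(int), p.shape[0])
    loss, dldp = _dice_fg(p, onehot, epsilon, want_grad=True)
    # softmax Jacobian: dL/dz = p * (dL/dp - sum_c p_c dL/dp_c)
    inner = (p * dldp).sum(axis=0, keepdims=True)
    dlogits = (p * (dldp - inner) * grad_scale).astype(np.float32)
    model.backward(dlogits)
    return float(loss)


def train(model: ResUNet3D, scenes: Sequence[tuple[Tomogram, LabelVolume, ParticleSet]],
          config: TrainConfig,
          validation: tuple[Tomogram, ParticleSet] | None = None,
          tiling=None, mpnms=None, particle_r: int = 3,
          match_r: float | None = None) -> TrainResult:
    """Train on particle-centered subtomograms with AdamW and Dice loss.

    ``scenes`` are (tomogram, label volume, annotations) triples, assumed
    already intensity-normalized. If ``validation`` (tomogram, truth) is
    given, each epoch ends with full inference on it; picks are matched to
    the truth within ``match_r`` (default: ``particle_r``) and the state
    with the best ``F1_alpha`` is restored into the returned model.
    Deterministic for a fixed ``config.seed`` (up to floating-point
    reassociation in BLAS).
    """
    from tomopick.infer import MPNMSConfig, TilingConfig, pick_particles, predict_scoremap
    from tomopick.metrics import match_picks, precision_recall_f1

    if not scenes:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    all_samples = []
    for tomo, labels, particles in scenes:
        all_samples.extend(
            sample_training_subtomograms(tomo, labels, particles, config.N, rng))
    if not all_samples:
        raise ValueError("no training samples (no annotated particles)")

    tiling = tiling or TilingConfig(N=config.N, pad_size=min(8, config.N // 8))
    mpnms = mpnms or MPNMSConfig()
    match_r = match_r if match_r is not None else float(particle_r)

    opt = AdamW(model.params(), lr=config.lr, weight_decay=config.weight_decay)
    history: list[dict] = []
    best = (-1.0, None, None)  # (f1_alpha, epoch, state)

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(all_samples))
        losses = []
        pending = 0
        opt.zero_grad()
        for pos, idx in enumerate(order):
            sample = all_samples[idx]
            if config.augment:
                sample = augment_sample(sample, rng)
            loss = _loss_and_backward(model, sample, config.epsilon,
                                      grad_scale=1.0 / config.batch_size)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            losses.append(loss)
            pending += 1
            if pending == config.batch_size or pos == len(order) - 1:
                opt.step()
                opt.zero_grad()
                pending = 0
        row = {"epoch": epoch, "loss": float(np.mean(losses)),
               "val_P": np.nan, "val_R": np.nan, "val_F1a": np.nan}
        if validation is not None:
            val_tomo, val_truth = validation
            score = predict_scoremap(model, val_tomo, tiling)
            picks = pick_particles(score, mpnms, particle_r)
            p, r, _ = precision_recall_f1(match_picks(picks, val_truth, match_r))
            f1a = f1_alpha(p, r, config.alpha)
            row.update(val_P=p, val_R=r, val_F1a=f1a)
            # ties go to the later epoch: among equally-scoring checkpoints
            # the longer-trained one has the lower training loss
            if f1a >= best[0]:
                best = (f1a, epoch, copy.deepcopy(model.state_dict()))
        history.append(row)

    if validation is not None and best[2] is not None:
        model.load_state_dict(best[2])
        return TrainResult(model, history, best_epoch=best[1], best_f1_alpha=best[0])
    return TrainResult(model, history)


def write_history(history: list[dict], path: str | Path) -> Path:
    """Write the per-epoch training log as CSV."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame(history).to_csv(path, index=False)
    return path
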