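"""Tiled inference and pooling-based particle-center extraction.

Two pieces turn a trained segmentation network into a particle picker:

* **Overlap-tile (OT) prediction.** The tomogram is reflect-padded by
  ``pad_size`` on every face and scanned with cubic tiles of side ``N`` at
  stride ``s = N - 2*pad_size``. Only each tile's central ``s``-cube is
  written into the stitched score map, so voxels near tile borders — where
  segmentation quality degrades — never reach the output.

* **Mean-pooling non-maximum suppression (MP-NMS).** A binarized class map
  is mean-filtered (kernel ``k^3``, stride 1, zero-padded) for ``n_iter``
  iterations, which turns each connected blob into a soft peak whose
  maximum sits at the blob center; peaks are then read off as strict
  26-neighborhood local maxima. After ``i`` iterations each voxel's
  receptive field is ``1 + (k-1)*i``, so resolving a particle of radius
  ``r`` needs at least ``ceil(2r/(k-1))`` iterations.

Because the input of MP-NMS is binary, the iterated mean filter is computed
in integer arithmetic (iterated box sums divided by ``k^(3i)``), which makes
local-maximum comparisons and their lexicographic tie-breaks exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

from tomopick.io import ParticleRecord, ParticleSet, Tomogram
from tomopick.model import ResUNet3D, ScoreMap

__all__ = [
    "TilingConfig", "MPNMSConfig", "receptive_field", "min_iterations",
    "binarize", "mp_nms", "predict_scoremap", "pick_particles",
]


@dataclass(frozen=True)
class TilingConfig:
    """Inference geometry: tile side ``N``, border margin ``pad_size``.

    The scan stride is derived, never stored: ``s = N - 2*pad_size``.
    """

    N: int = 48
    pad_size: int = 4

    def __post_init__(self) -> None:
        if self.N % 8:
            raise ValueError(f"tile side N must be divisible by 8, got {self.N}")
        if not (0 <= self.pad_size < self.N / 2):
            raise ValueError(f"need 0 <= pad_size < N/2, got pad_size={self.pad_size}")

    @property
    def stride(self) -> int:
        return self.N - 2 * self.pad_size


@dataclass(frozen=True)
class MPNMSConfig:
    """Postprocessing parameters.

    ``t_seg`` binarizes the score map; local maxima with soft value below
    ``t_lm`` are removed; of two maxima closer than ``t_dist`` voxels the
    smaller is discarded. ``n_iter=None`` uses the per-class minimum
    iteration count for the class's particle radius.
    """

    k: int = 3
    n_iter: int | None = None
    t_seg: float = 0.5
    t_lm: float = 0.1
    t_dist: float | None = None

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"MP kernel side k must be odd and >= 3, got {self.k}")
        if self.n_iter is not None and self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.t_seg < 0 or self.t_lm < 0 or (self.t_dist is not None and self.t_dist < 0):
            raise ValueError("thresholds must be >= 0")


def receptive_field(k: int, i: int) -> int:
    """Receptive-field side of one voxel after ``i`` mean-pooling iterations."""
    if k < 3 or k % 2 == 0:
        raise ValueError(f"k must be odd and >= 3, got {k}")
    if i < 0:
        raise ValueError("iteration count must be >= 0")
    return 1 + (k - 1) * i

def min_iterations(r: int, k: int) -> int:
    """Minimum mean-pooling iterations to resolve a particle of radius ``r``.

    Chosen so that the receptive field covers the particle diameter
    ``2r + 1``: ``ceil(2r / (k-1))``.
    """
    if r < 1:
        raise ValueError(f"particle radius must be >= 1, got {r}")
    n = math.ceil(2 * r / (k - 1))
    assert receptive_field(k, n) >= 2 * r + 1
    return n


def binarize(score: np.ndarray, t_seg: float) -> np.ndarray:
    """Threshold one score-map channel: 1 where score >= t_seg."""
    return (np.asarray(score) >= t_seg).astype(np.uint8)


_NEIGHBORS = [(dz, dy, dx)
              for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
              if (dz, dy, dx) != (0, 0, 0)]


def _box_sum_iterated(binary: np.ndarray, k: int, n_iter: int) -> np.ndarray:
    """``n_iter``-fold k^3 box-sum of a binary volume, zero-padded, int64."""
    out = binary.astype(np.int64)
    kernel = np.ones(k, dtype=np.int64)
    for _ in range(n_iter):
        for axis in range(3):
            out = correlate1d(out, kernel, axis=axis, mode="constant", cval=0)
    return out


def _local_maxima(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Strict 26-neighborhood maxima with lexicographic tie-breaking.

    A voxel qualifies if it strictly exceeds every neighbor, except that
    equality with a neighbor is tolerated when the voxel precedes that
    neighbor in (z, y, x) lexicographic order. Zero-valued voxels never
    qualify. Comparisons on the integer box-sum array are exact.
    """
    ok = values > 0
    shape = values.shape
    neg_inf = np.iinfo(values.dtype).min if np.issubdtype(values.dtype, np.integer) else -np.inf
    padded = np.full(tuple(s + 2 for s in shape), neg_inf, dtype=values.dtype)
    padded[1:-1, 1:-1, 1:-1] = values
    for dz, dy, dx in _NEIGHBORS:
        neighbor = padded[1 + dz:1 + dz + shape[0],
                          1 + dy:1 + dy + shape[1],
                          1 + dx:1 + dx + shape[2]]
        # voxel precedes its neighbor iff the offset is lexicographically positive
        if (dz, dy, dx) > (0, 0, 0):
            ok &= values >= neighbor
        else:
            ok &= values > neighbor
    return [tuple(int(c) for c in p) for p in np.argwhere(ok)]


def mp_nms(binary: np.ndarray, k: int = 3, n_iter: int = 3
           ) -> tuple[np.ndarray, list[tuple[tuple[int, int, int], float]]]:
    """Iterated mean pooling plus non-maximum suppression.

    Returns the soft volume (the ``n_iter``-fold k^3 mean filter of the
    binary input, zero-padded borders) and the list of local maxima as
    ``((z, y, x), soft_value)`` pairs.
    """
    binary = np.asarray(binary)
    vals = np.unique(binary)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mp_nms input must be binary (values 0/1)")
    sums = _box_sum_iterated(binary, k, n_iter)
    scale = float(k) ** (3 * n_iter)
    soft = sums / scale
    maxima = [(pos, float(sums[pos] / scale)) for pos in _local_maxima(sums)]
    return soft, maxima


def predict_scoremap(model: ResUNet3D, tomogram: Tomogram,
                     tiling: TilingConfig) -> ScoreMap:
    """Overlap-tile inference over a full tomogram.

    The tomogram is reflect-padded by ``pad_size`` on all faces, scanned
    with stride ``s = N - 2*pad_size``, and only each tile's central region
    is written to the output, whose center regions jointly cover the volume
    (trailing tiles are clamped flush with the padded volume).
    """
    data = np.asarray(tomogram.data, dtype=np.float32)
    N, p = tiling.N, tiling.pad_size
    s = tiling.stride
    shape = data.shape
    if any(d + 2 * p < N for d in shape):
        raise ValueError(
            f"volume {shape} smaller than tile size {N} even after padding by {p}")
    padded = np.pad(data, p, mode="reflect") if p else data
    out = np.zeros((model.config.n_classes,) + shape, dtype=np.float32)

    def starts(dim: int) -> list[int]:
        last = dim + 2 * p - N
        pos = list(range(0, last + 1, s))
        if pos[-1] != last:
            pos.append(last)
        return pos

    for z0 in starts(shape[0]):
        for y0 in starts(shape[1]):
            for x0 in starts(shape[2]):
                tile = padded[z0:z0 + N, y0:y0 + N, x0:x0 + N]
                probs = model.predict_proba(tile).data
                center = probs[:, p:N - p, p:N - p, p:N - p] if p else probs
                out[:, z0:z0 + N - 2 * p, y0:y0 + N - 2 * p, x0:x0 + N - 2 * p] = center
    return ScoreMap(out)


def _deduplicate(maxima: list[tuple[tuple[int, int, int], float]],
                 t_dist: float) -> list[tuple[tuple[int, int, int], float]]:
    """Greedy duplicate suppression: keep maxima in decreasing-value order,
    dropping any candidate within ``t_dist`` of an already-kept one."""
    order = sorted(maxima, key=lambda m: (-m[1], m[0]))
    kept: list[tuple[tuple[int, int, int], float]] = []
    kept_pos = np.zeros((0, 3))
    for pos, val in order:
        if len(kept) and np.min(np.linalg.norm(kept_pos - np.array(pos), axis=1)) < t_dist:
            continue
        kept.append((pos, val))
        kept_pos = np.vstack([kept_pos, pos])
    return kept


def pick_particles(score: ScoreMap, mpnms: MPNMSConfig,
                   particle_r: dict[int, int] | int,
                   cross_class_dedup: bool = False) -> ParticleSet:
    """Extract particle centers from a stitched score map.

    Per foreground class: binarize at ``t_seg``; run MP-NMS (``n_iter``
    defaults to :func:`min_iterations` for the class radius); drop maxima
    with soft value below ``t_lm``; suppress duplicates closer than
    ``t_dist`` (default: the class radius), keeping the larger value. Pick
    scores are soft values normalized to [0, 1] by the class-wise maximum.

    Deduplication is per class; ``cross_class_dedup`` additionally
    suppresses, across classes, any pick whose normalized score is smaller
    than that of another pick within its own ``t_dist``.
    """
    n_classes = score.n_classes
    if isinstance(particle_r, (int, np.integer)):
        particle_r = {c: int(particle_r) for c in range(1, n_classes)}
    records: list[ParticleRecord] = []
    t_dist_by_class: dict[int, float] = {}
    for c in range(1, n_classes):
        r = int(particle_r[c])
        n_iter = mpnms.n_iter if mpnms.n_iter is not None else min_iterations(r, mpnms.k)
        t_dist = mpnms.t_dist if mpnms.t_dist is not None else float(r)
        t_dist_by_class[c] = t_dist
        binary = binarize(score.data[c], mpnms.t_seg)
        _, maxima = mp_nms(binary, mpnms.k, n_iter)
        maxima = [(pos, val) for pos, val in maxima if val >= mpnms.t_lm]
        maxima = _deduplicate(maxima, t_dist)
        if not maxima:
            continue
        vmax = max(val for _, val in maxima)
        for pos, val in maxima:
            records.append(ParticleRecord(c, np.array(pos, dtype=float),
                                          val / vmax if vmax > 0 else 0.0))
    if cross_class_dedup and records:
        records.sort(key=lambda rec: -rec.score)
        kept: list[ParticleRecord] = []
        for rec in records:
            t = t_dist_by_class[rec.class_id]
            if any(np.linalg.norm(rec.center - other.center) < t for other in kept):
                continue
            kept.append(rec)
        records = kept
    return ParticleSet(records, source_shape=score.shape)
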