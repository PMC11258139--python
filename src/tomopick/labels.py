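"""Simplified weak-supervision masks and voxel-level label volumes.

Full segmentation masks of macromolecular particles are rarely available in
practice; training labels are instead painted as simple geometric masks
centered on annotated particle coordinates. Three mask families are
supported, all defined on the integer lattice ``[-r, r]^3``:

* ``cubic``  — every lattice point of the cube,
* ``ball``   — points with Euclidean norm strictly below ``r``,
* ``tball``  — truncated ball: points with norm strictly below ``sqrt(2)*r``.

The truncated ball is the default (with constant diameter d = 2r+1 = 7): it
is a compromise between the ball (which under-covers the particle) and the
cube (which over-covers its corners) and gives the most stable training
behavior across particle sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from tomopick.io import ParticleRecord, ParticleSet

__all__ = ["MaskSpec", "LabelVolume", "generate_mask", "paint_labels", "jitter_centers"]

MASK_TYPES = ("cubic", "ball", "tball")


@dataclass(frozen=True)
class MaskSpec:
    """Weak-label mask definition: type, radius ``r`` (voxels) and class id.

    The mask diameter ``d = 2r+1`` must not exceed the particle diameter it
    stands in for; particle diameters outside the 7-25 voxel range merely
    trigger a warning (re-binning the tomogram is the usual fix).
    """

    mask_type: str
    r: int
    class_id: int = 1
    particle_diameter: float | None = None

    def __post_init__(self) -> None:
        if self.mask_type not in MASK_TYPES:
            raise ValueError(f"mask_type must be one of {MASK_TYPES}, got {self.mask_type!r}")
        if int(self.r) < 1:
            raise ValueError(f"mask radius r must be >= 1, got {self.r}")
        if int(self.class_id) < 1:
            raise ValueError(f"class_id must be >= 1, got {self.class_id}")
        if self.particle_diameter is not None:
            d = 2 * int(self.r) + 1
            if d > self.particle_diameter:
                raise ValueError(
                    f"mask diameter {d} exceeds particle diameter {self.particle_diameter}")
            if not (7 <= self.particle_diameter <= 25):
                warnings.warn(
                    f"particle diameter {self.particle_diameter} outside the recommended "
                    "7-25 voxel range; consider re-binning the tomogram", stacklevel=2)

    @property
    def diameter(self) -> int:
        return 2 * int(self.r) + 1


@dataclass
class LabelVolume:
    """Voxel-level class labels (0 = background), same shape as its tomogram."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.data))


def generate_mask(spec: MaskSpec) -> np.ndarray:
    """Generate a ``(2r+1)^3`` mask with values in ``{0, class_id}``.

    The center voxel is always foreground; ``ball`` keeps lattice points with
    norm < r, ``tball`` those with norm < sqrt(2)*r, ``cubic`` all of them.
    """
    r = int(spec.r)
    ax = np.arange(-r, r + 1)
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    norm2 = x * x + y * y + z * z
    if spec.mask_type == "cubic":
        inside = np.ones_like(norm2, dtype=bool)
    elif spec.mask_type == "ball":
        inside = norm2 < r * r
    else:
        # truncated ball: norm < sqrt(2)*r, evaluated integer-exactly as
        # norm^2 < 2 r^2 (lattice points exactly on the sphere excluded)
        inside = norm2 < 2 * r * r
    return np.where(inside, spec.class_id, 0).astype(np.int16)


def paint_labels(shape: tuple[int, int, int], particles: ParticleSet,
                 spec_per_class: Mapping[int, MaskSpec]) -> LabelVolume:
    """Stamp per-particle masks into a label volume.

    Masks are centered at each particle's center rounded half-up per axis and
    cropped at the volume boundary. Where two stamps overlap, the voxel is
    assigned to the nearer particle center (ties go to the earlier record).
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 1:
        raise ValueError(f"invalid volume shape {shape}")
    labels = np.zeros(shape, dtype=np.int16)
    # distance from each painted voxel to the center of the particle that owns it
    owner_dist = np.full(shape, np.inf, dtype=np.float64)
    for rec in particles:
        if rec.class_id not in spec_per_class:
            raise KeyError(f"no MaskSpec for particle class {rec.class_id}")
        spec = spec_per_class[rec.class_id]
        r = int(spec.r)
        mask = generate_mask(MaskSpec(spec.mask_type, r, rec.class_id))
        cz, cy, cx = (int(np.floor(c + 0.5)) for c in rec.center)
        lo = np.array([cz - r, cy - r, cx - r])
        hi = lo + 2 * r + 1
        src_lo = np.maximum(-lo, 0)
        src_hi = (2 * r + 1) - np.maximum(hi - shape, 0)
        dst_lo = np.maximum(lo, 0)
        dst_hi = np.minimum(hi, shape)
        if np.any(src_lo >= src_hi):
            continue  # stamp entirely outside the volume
        sub = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))
        msub = mask[tuple(slice(a, b) for a, b in zip(src_lo, src_hi))]
        zz, yy, xx = np.meshgrid(*(np.arange(a, b) for a, b in zip(dst_lo, dst_hi)),
                                 indexing="ij")
        d2 = ((zz - rec.center[0]) ** 2 + (yy - rec.center[1]) ** 2
              + (xx - rec.center[2]) ** 2)
        take = (msub > 0) & (d2 < owner_dist[sub])
        labels[sub] = np.where(take, msub, labels[sub])
        owner_dist[sub] = np.where(take, d2, owner_dist[sub])
    return LabelVolume(labels)


def jitter_centers(particles: ParticleSet, r: float, lo: float, hi: float,
                   seed: int | np.random.Generator = 0) -> ParticleSet:
    """Displace each center by a random vector of magnitude in ``[lo*r, hi*r]``.

    Directions are isotropic; magnitudes are uniform on the interval. This
    emulates the center bias introduced by manual annotation at low SNR.
    """
    if lo < 0 or hi < lo:
        raise ValueError(f"need 0 <= lo <= hi, got lo={lo}, hi={hi}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for rec in particles:
        direction = rng.normal(size=3)
        n = np.linalg.norm(direction)
        while n < 1e-12:  # degenerate draw; essentially never happens
            direction = rng.normal(size=3)
            n = np.linalg.norm(direction)
        magnitude = rng.uniform(lo * r, hi * r)
        out.append(ParticleRecord(rec.class_id, rec.center + direction / n * magnitude,
                                  rec.score))
    return ParticleSet(out, source_shape=None)
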