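"""Synthetic tomogram scenes with known ground truth.

The simulator places non-overlapping geometric particles (balls, cubes,
cylinders) in a volume, optionally smooths the clean density with a Gaussian
kernel, and adds i.i.d. Gaussian noise. This emulates the additive-noise
robustness protocol used to stress particle pickers on reconstructed
volumes; it deliberately omits CTF and missing-wedge effects, which belong
to the reconstruction chain, not the picker.

Particles are bright ("white") on a zero background by default; real cryo-ET
density is dark, so downstream tools expose an invert option.

The signal-to-noise ratio reported by :func:`snr_of` is the global ratio
``std(clean density) / noise_sigma``. Because foreground occupies only a few
percent of a scene, this is far smaller than the per-voxel contrast-to-noise
ratio: a scene with SNR 2 under this definition is an easy picking task, and
degradation sets in roughly below SNR 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
from scipy.ndimage import gaussian_filter

from tomopick.io import ParticleSet, Tomogram

__all__ = ["ClassSpec", "SceneSpec", "SyntheticScene", "simulate_scene", "snr_of"]

SHAPE_KINDS = ("ball", "cube", "cylinder")


@dataclass(frozen=True)
class ClassSpec:
    """One particle class: geometry kind, diameter (voxels) and contrast."""

    class_id: int
    shape_kind: str = "ball"
    diameter: float = 9.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.class_id < 1:
            raise ValueError("class_id must be >= 1")
        if self.shape_kind not in SHAPE_KINDS:
            raise ValueError(f"shape_kind must be one of {SHAPE_KINDS}")
        if self.diameter < 3:
            raise ValueError(f"diameter must be >= 3 voxels, got {self.diameter}")


@dataclass(frozen=True)
class SceneSpec:
    """Scene geometry and noise model.

    ``min_separation`` is the minimum center-to-center distance enforced by
    rejection sampling; it must be at least the largest particle diameter so
    that stamps never overlap. ``noise_sigma`` is the standard deviation of
    the additive Gaussian noise; ``smooth_sigma`` the width of the Gaussian
    kernel applied to the clean density before noise is added.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    classes: tuple[ClassSpec, ...] = (ClassSpec(1),)
    n_particles: tuple[int, ...] = (20,)
    min_separation: float = 12.0
    noise_sigma: float = 0.05
    smooth_sigma: float = 1.0
    seed: int = 0
    max_tries: int = field(default=10_000, repr=False)

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.n_particles):
            raise ValueError("classes and n_particles must have equal length")
        if self.noise_sigma < 0 or self.smooth_sigma < 0:
            raise ValueError("noise_sigma and smooth_sigma must be >= 0")
        dmax = max(c.diameter for c in self.classes)
        if dmax > min(self.shape) / 2:
            raise ValueError(
                f"largest diameter {dmax} exceeds half the smallest volume side")
        if self.min_separation < dmax:
            raise ValueError(
                f"min_separation {self.min_separation} below largest diameter {dmax}")


@dataclass
class SyntheticScene:
    """A simulated tomogram plus its ground truth."""

    tomogram: Tomogram
    truth: ParticleSet
    density: np.ndarray  # clean (noise-free) volume, after smoothing
    spec: SceneSpec


def _kernel_indicator(kind: str, diameter: float, shape: tuple[int, int, int],
                      center: np.ndarray) -> np.ndarray:
    """Solid indicator volume of the particle at ``center`` (z,y,x)."""
    radius = diameter / 2.0
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij", sparse=True)
    dz, dy, dx = zz - center[0], yy - center[1], xx - center[2]
    if kind == "ball":
        return (dz * dz + dy * dy + dx * dx) <= radius * radius
    if kind == "cube":
        return (np.abs(dz) <= radius) & (np.abs(dy) <= radius) & (np.abs(dx) <= radius)
    # cylinder: axis along z, height = diameter
    return ((dy * dy + dx * dx) <= radius * radius) & (np.abs(dz) <= radius)


def simulate_scene(spec: SceneSpec) -> SyntheticScene:
    """Generate a scene by rejection-sampled placement plus additive noise.

    Deterministic for a fixed ``spec.seed``. Raises if the requested packing
    cannot be realized within the retry cap.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    centers: list[np.ndarray] = []
    class_ids: list[int] = []
    for cls, n in zip(spec.classes, spec.n_particles):
        margin = cls.diameter / 2.0
        lo = np.full(3, margin)
        hi = np.array(shape, dtype=float) - 1 - margin
        if np.any(hi < lo):
            raise ValueError(f"volume too small for particles of diameter {cls.diameter}")
        placed = 0
        tries = 0
        while placed < n:
            if tries >= spec.max_tries:
                raise RuntimeError(
                    f"could not place {n} particles of class {cls.class_id} with "
                    f"min_separation={spec.min_separation} in volume {shape}: "
                    f"packing constraint unsatisfiable after {spec.max_tries} tries")
            tries += 1
            cand = rng.uniform(lo, hi)
            if centers and np.min(np.linalg.norm(np.array(centers) - cand, axis=1)) < spec.min_separation:
                continue
            centers.append(cand)
            class_ids.append(cls.class_id)
            placed += 1

    clean = np.zeros(shape, dtype=np.float64)
    for center, cid in zip(centers, class_ids):
        cls = next(c for c in spec.classes if c.class_id == cid)
        clean += cls.amplitude * _kernel_indicator(cls.shape_kind, cls.diameter, shape, center)
    if spec.smooth_sigma > 0:
        clean = gaussian_filter(clean, spec.smooth_sigma)
    noise = rng.normal(0.0, spec.noise_sigma, size=shape) if spec.noise_sigma > 0 else 0.0
    tomo = Tomogram((clean + noise).astype(np.float32))
    truth = ParticleSet.from_arrays(
        np.array(centers).reshape(-1, 3), class_ids, source_shape=shape)
    return SyntheticScene(tomogram=tomo, truth=truth,
                          density=clean.astype(np.float32), spec=spec)


def snr_of(scene: SyntheticScene) -> float:
    """Global signal-to-noise ratio: ``std(clean density) / noise_sigma``."""
    if scene.spec.noise_sigma == 0:
        return float("inf")
    return float(scene.density.std() / scene.spec.noise_sigma)


def noise_sigma_for_snr(spec: SceneSpec, snr: float) -> float:
    """Noise level that realizes a target global SNR for this scene geometry.

    Runs the noiseless placement for ``spec`` and returns
    ``std(density) / snr`` so that ``snr_of`` of the regenerated scene equals
    the target.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    clean_spec = SceneSpec(shape=spec.shape, classes=spec.classes,
                           n_particles=spec.n_particles,
                           min_separation=spec.min_separation,
                           noise_sigma=0.0, smooth_sigma=spec.smooth_sigma,
                           seed=spec.seed)
    scene = simulate_scene(clean_spec)
    return float(scene.density.std() / snr)
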