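"""Particle-level evaluation metrics and map-resolution estimation.

Matching between picked and reference particles is one-to-one and greedy in
increasing distance: the closest unmatched (pick, truth) pair is matched
while its distance is below the acceptance radius. The same machinery
underlies both precision/recall evaluation and the intersection/difference
set comparison between two pickers, which keeps the two mutually consistent.

Map resolution uses the Fourier shell correlation between two independent
reconstructions, with shells one frequency voxel wide, and the standard
0.143 cut-off with linear interpolation at the crossing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from tomopick.io import ParticleSet, Tomogram

__all__ = [
    "MatchResult", "FSCCurve", "Resolution",
    "match_picks", "precision_recall_f1", "average_distance", "pr_curve",
    "compare_particle_sets", "fsc_curve", "resolution_at",
]


@dataclass
class MatchResult:
    """Outcome of matching picks against a reference set."""

    TP: int
    FP: int
    FN: int
    matched_pairs: list[tuple[int, int, float]]  # (pick idx, truth idx, distance)

    def __post_init__(self) -> None:
        assert self.TP == len(self.matched_pairs)


@dataclass
class FSCCurve:
    """Fourier shell correlation per integer-radius frequency shell.

    ``shell_freq`` is in cycles/voxel (shell index divided by the box side).
    """

    shell_freq: np.ndarray
    correlation: np.ndarray

    def __post_init__(self) -> None:
        self.shell_freq = np.asarray(self.shell_freq, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.shell_freq.shape != self.correlation.shape:
            raise ValueError("shell_freq and correlation must have equal length")


class Resolution(NamedTuple):
    """A resolution estimate; ``is_bound`` marks a Nyquist-limited bound."""

    value: float
    is_bound: bool

    def __float__(self) -> float:
        return float(self.value)


def _greedy_pairs(a: np.ndarray, b: np.ndarray, max_dist: float
                  ) -> list[tuple[int, int, float]]:
    """One-to-one greedy pairing by increasing distance (< max_dist)."""
    if len(a) == 0 or len(b) == 0:
        return []
    diff = a[:, None, :] - b[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    ii, jj = np.nonzero(dist < max_dist)
    order = np.argsort(dist[ii, jj], kind="stable")
    used_a = np.zeros(len(a), dtype=bool)
    used_b = np.zeros(len(b), dtype=bool)
    pairs = []
    for idx in order:
        i, j = ii[idx], jj[idx]
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        pairs.append((int(i), int(j), float(dist[i, j])))
    return pairs


def match_picks(picks: ParticleSet, truth: ParticleSet, r: float) -> MatchResult:
    """Match picks to ground truth within acceptance radius ``r`` (voxels).

    A pick is a true positive if it is matched one-to-one to a truth
    particle of the same class at distance < r; unmatched picks are false
    positives and unmatched truths false negatives.
    """
    if not (r > 0):
        raise ValueError("acceptance radius r must be positive")
    pairs: list[tuple[int, int, float]] = []
    pick_idx = {id(rec): i for i, rec in enumerate(picks)}
    truth_idx = {id(rec): i for i, rec in enumerate(truth)}
    classes = sorted(set(picks.class_ids().tolist()) | set(truth.class_ids().tolist()))
    for c in classes:
        pc = [rec for rec in picks if rec.class_id == c]
        tc = [rec for rec in truth if rec.class_id == c]
        for i, j, d in _greedy_pairs(np.array([r.center for r in pc]).reshape(-1, 3),
                                     np.array([r.center for r in tc]).reshape(-1, 3), r):
            pairs.append((pick_idx[id(pc[i])], truth_idx[id(tc[j])], d))
    pairs.sort()
    tp = len(pairs)
    return MatchResult(TP=tp, FP=len(picks) - tp, FN=len(truth) - tp,
                       matched_pairs=pairs)


def precision_recall_f1(match: MatchResult) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0/0 -> 0."""
    tp, fp, fn = match.TP, match.FP, match.FN
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def average_distance(match: MatchResult) -> float:
    """Mean Euclidean distance (voxels) over matched pairs; needs TP >= 1."""
    if match.TP == 0:
        raise ValueError("average distance undefined with zero matches")
    return float(np.mean([d for _, _, d in match.matched_pairs]))


def pr_curve(picks: ParticleSet, truth: ParticleSet, r: float
             ) -> list[tuple[float, float, float]]:
    """Precision/recall at every distinct pick-score threshold (descending).

    Returns ``(threshold, P, R)`` rows; recall is non-decreasing as the
    threshold drops.
    """
    scores = picks.scores()
    if scores is None:
        raise ValueError("pr_curve requires picks with scores")
    rows = []
    for t in sorted(set(scores.tolist()), reverse=True):
        kept = ParticleSet([rec for rec in picks if rec.score >= t])
        p, rec_, _ = precision_recall_f1(match_picks(kept, truth, r))
        rows.append((float(t), p, rec_))
    return rows


def compare_particle_sets(a: ParticleSet, b: ParticleSet, t_dist: float
                          ) -> tuple[ParticleSet, ParticleSet, ParticleSet]:
    """Intersection and difference sets of two pickers' outputs.

    Particles closer than ``t_dist`` (normally half the particle diameter)
    are considered the same; pairing is one-to-one greedy by increasing
    distance. Returns ``(A∩B, A−B, B−A)`` with the intersection reported at
    A's coordinates.
    """
    if not (t_dist > 0):
        raise ValueError("t_dist must be positive")
    pairs = _greedy_pairs(a.centers(), b.centers(), t_dist)
    a_matched = {i for i, _, _ in pairs}
    b_matched = {j for _, j, _ in pairs}
    inter = ParticleSet([a[i] for i in sorted(a_matched)])
    a_only = ParticleSet([a[i] for i in range(len(a)) if i not in a_matched])
    b_only = ParticleSet([b[j] for j in range(len(b)) if j not in b_matched])
    return inter, a_only, b_only


def fsc_curve(vol1: Tomogram | np.ndarray, vol2: Tomogram | np.ndarray) -> FSCCurve:
    """Fourier shell correlation between two equally-shaped cubic volumes.

    Per shell of integer radius ``j`` (width one frequency voxel):
    ``FSC(j) = Re(sum F1 conj(F2)) / sqrt(sum |F1|^2 * sum |F2|^2)``.
    """
    d1 = vol1.data if isinstance(vol1, Tomogram) else np.asarray(vol1)
    d2 = vol2.data if isinstance(vol2, Tomogram) else np.asarray(vol2)
    if d1.shape != d2.shape:
        raise ValueError(f"volume shapes differ: {d1.shape} vs {d2.shape}")
    if len(set(d1.shape)) != 1:
        raise ValueError("FSC requires cubic volumes")
    n = d1.shape[0]
    f1 = np.fft.fftn(d1)
    f2 = np.fft.fftn(d2)
    freq = np.fft.fftfreq(n)  # cycles/voxel
    kz, ky, kx = np.meshgrid(freq, freq, freq, indexing="ij", sparse=True)
    radius = np.sqrt(kz * kz + ky * ky + kx * kx) * n  # in frequency voxels
    shell = np.rint(radius).astype(int)
    n_shells = n // 2 + 1
    mask = shell < n_shells
    idx = shell[mask]
    cross = np.bincount(idx, weights=(f1 * np.conj(f2)).real[mask], minlength=n_shells)
    p1 = np.bincount(idx, weights=(np.abs(f1) ** 2)[mask], minlength=n_shells)
    p2 = np.bincount(idx, weights=(np.abs(f2) ** 2)[mask], minlength=n_shells)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cross / np.sqrt(p1 * p2)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    return FSCCurve(shell_freq=np.arange(n_shells) / n, correlation=corr)


def resolution_at(curve: FSCCurve, threshold: float = 0.143,
                  voxel_size: float = 1.0) -> Resolution:
    """Resolution at an FSC cut-off, in the units of ``voxel_size``.

    Finds the first shell where the correlation drops below ``threshold``
    and linearly interpolates the crossing frequency f* (cycles/voxel);
    returns ``voxel_size / f*``. If the curve never crosses, returns the
    Nyquist-limited bound ``2 * voxel_size`` flagged via ``is_bound``.
    """
    if len(curve.shell_freq) == 0:
        raise ValueError("empty FSC curve")
    if not (voxel_size > 0):
        raise ValueError("voxel_size must be positive")
    c = curve.correlation
    f = curve.shell_freq
    below = np.nonzero(c < threshold)[0]
    below = below[below > 0]  # ignore the DC shell
    if len(below) == 0:
        return Resolution(2.0 * voxel_size, True)
    j = int(below[0])
    c0, c1 = c[j - 1], c[j]
    frac = (c0 - threshold) / (c0 - c1) if c0 != c1 else 0.0
    f_star = f[j - 1] + frac * (f[j] - f[j - 1])
    if f_star <= 0:
        return Resolution(2.0 * voxel_size, True)
    return Resolution(float(voxel_size / f_star), False)
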