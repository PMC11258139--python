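"""Tomogram and coordinate-table I/O.

Conventions fixed here and relied on by every other module:

* Volumes are numpy arrays in ``(z, y, x)`` axis order.
* Particle centers are continuous, 0-based voxel coordinates stored as
  ``(z, y, x)``; a center at integer coordinates lies on a voxel center.
* Public coordinate tables (CSV/TSV/STAR) use ``x, y, z`` columns. The STAR
  dialect follows the RELION convention of 1-based coordinates: +1 is added
  on write and subtracted on read.

MRC2014 volumes are read and written through :mod:`gemmi` (modes 0/1/2 are
accepted on input and promoted to ``float32``; output is always mode 2).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Tomogram", "ParticleRecord", "ParticleSet",
    "read_tomogram", "write_tomogram",
    "read_particles", "write_particles",
    "normalize_tomogram",
]


@dataclass
class Tomogram:
    """A 3D scalar volume with voxel-size metadata.

    Parameters
    ----------
    data : ndarray
        3D intensity array, axis order ``(z, y, x)``.
    voxel_size : float
        Physical edge length of a voxel in Angstrom (default 1.0).
    origin : ndarray
        Origin offset in voxels, ``(z, y, x)`` (default zeros).
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"tomogram data must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError(f"tomogram axes must have length >= 1, got {self.data.shape}")
        if not (self.voxel_size > 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("tomogram intensities must be finite")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ParticleRecord:
    """A single annotated or picked particle.

    ``center`` is a continuous ``(z, y, x)`` voxel coordinate; ``class_id``
    is a positive integer (0 is reserved for background); ``score`` is an
    optional confidence in [0, 1].
    """

    class_id: int
    center: np.ndarray
    score: float | None = None

    def __post_init__(self) -> None:
        self.class_id = int(self.class_id)
        if self.class_id < 1:
            raise ValueError(f"class_id must be >= 1, got {self.class_id}")
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,) or not np.all(np.isfinite(self.center)):
            raise ValueError("center must be a finite 3-vector")


class ParticleSet:
    """An ordered collection of :class:`ParticleRecord`.

    Iteration and indexing preserve insertion (file) order. ``source_shape``
    optionally records the shape of the volume the coordinates refer to; when
    given, no center may lie more than one voxel outside it.
    """

    def __init__(self, records: Sequence[ParticleRecord] = (),
                 source_shape: tuple[int, int, int] | None = None):
        self.records = list(records)
        self.source_shape = tuple(int(s) for s in source_shape) if source_shape is not None else None
        if self.source_shape is not None:
            hi = np.asarray(self.source_shape, dtype=float)
            for rec in self.records:
                if np.any(rec.center < -1.0) or np.any(rec.center > hi - 1 + 1.0):
                    raise ValueError(
                        f"center {rec.center} more than 1 voxel outside volume of shape {self.source_shape}")

    @classmethod
    def from_arrays(cls, centers_zyx: np.ndarray,
                    class_ids: Sequence[int] | int = 1,
                    scores: Sequence[float] | None = None,
                    source_shape: tuple[int, int, int] | None = None) -> "ParticleSet":
        centers_zyx = np.atleast_2d(np.asarray(centers_zyx, dtype=float))
        n = len(centers_zyx)
        if np.isscalar(class_ids):
            class_ids = [int(class_ids)] * n
        recs = [
            ParticleRecord(cid, c, None if scores is None else float(scores[i]))
            for i, (cid, c) in enumerate(zip(class_ids, centers_zyx))
        ]
        return cls(recs, source_shape=source_shape)

    def centers(self) -> np.ndarray:
        """All centers as an (n, 3) array in (z, y, x) order."""
        if not self.records:
            return np.zeros((0, 3))
        return np.array([r.center for r in self.records])

    def class_ids(self) -> np.ndarray:
        return np.array([r.class_id for r in self.records], dtype=int)

    def scores(self) -> np.ndarray | None:
        if any(r.score is None for r in self.records):
            return None
        return np.array([r.score for r in self.records], dtype=float)

    def select_class(self, class_id: int) -> "ParticleSet":
        return ParticleSet([r for r in self.records if r.class_id == class_id],
                           source_shape=self.source_shape)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticleRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ParticleRecord:
        return self.records[i]

    def __repr__(self) -> str:
        return f"ParticleSet(n={len(self)}, classes={sorted(set(self.class_ids().tolist())) if len(self) else []})"


# ---------------------------------------------------------------------------
# MRC volumes
# ---------------------------------------------------------------------------

def read_tomogram(path: str | os.PathLike) -> Tomogram:
    """Read an MRC2014 volume.

    Modes 0, 1 and 2 are accepted and promoted to float32. The returned data
    is in (z, y, x) axis order and the voxel size is taken from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such MRC file: {path}")
    try:
        m = gemmi.read_ccp4_map(str(path))
    except Exception as exc:  # gemmi raises RuntimeError for bad modes/headers
        raise ValueError(f"cannot read {path} as an MRC2014 volume: {exc}") from exc
    arr = np.array(m.grid, copy=True).astype(np.float32)
    if arr.ndim != 3 or min(arr.shape) < 1:
        raise ValueError(f"{path} is not a 3D volume (shape {arr.shape})")
    # gemmi's grid axes follow the unit-cell a/b/c axes = file x/y/z;
    # transpose to the internal (z, y, x) order.
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    spacing = np.array([m.grid.spacing[2], m.grid.spacing[1], m.grid.spacing[0]])
    voxel_size = float(np.mean(spacing)) if np.all(spacing > 0) else 1.0
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path} contains non-finite intensities")
    return Tomogram(data=data, voxel_size=voxel_size)


def write_tomogram(tomogram: Tomogram, path: str | os.PathLike) -> Path:
    """Write a volume as an MRC2014 mode-2 (float32) file."""
    path = Path(path)
    data = np.ascontiguousarray(tomogram.data.astype(np.float32).transpose(2, 1, 0))
    grid = gemmi.FloatGrid(data)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    nx, ny, nz = data.shape
    v = float(tomogram.voxel_size)
    grid.set_unit_cell(gemmi.UnitCell(nx * v, ny * v, nz * v, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    try:
        m.write_ccp4_map(str(path))
    except Exception as exc:
        raise OSError(f"cannot write MRC file {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Coordinate tables
# ---------------------------------------------------------------------------

_STAR_TAGS = {
    "x": "_rlnCoordinateX",
    "y": "_rlnCoordinateY",
    "z": "_rlnCoordinateZ",
    "class": "_rlnClassNumber",
    "score": "_rlnAutopickFigureOfMerit",
}


def _records_from_xyz(df: pd.DataFrame, offset: float = 0.0) -> list[ParticleRecord]:
    recs = []
    has_class = "class" in df.columns
    has_score = "score" in df.columns
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        center = np.array([d["z"], d["y"], d["x"]], dtype=float) + offset
        cid = int(d["class"]) if has_class else 1
        score = float(d["score"]) if has_score else None
        recs.append(ParticleRecord(cid, center, score))
    return recs


def read_particles(path: str | os.PathLike, dialect: str = "csv") -> ParticleSet:
    """Read a particle coordinate table.

    ``dialect`` is one of ``csv``, ``tsv`` (header ``x,y,z[,class][,score]``)
    or ``star`` (RELION ``_rlnCoordinateX/Y/Z`` loop, 1-based coordinates).
    Missing class columns default to class 1; file order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such particle table: {path}")
    if dialect in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if dialect == "csv" else "\t")
        df.columns = [c.strip().lower() for c in df.columns]
        missing = {"x", "y", "z"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing coordinate columns {sorted(missing)}")
        for col in ("x", "y", "z"):
            if len(df) and not np.issubdtype(df[col].dtype, np.number):
                raise ValueError(f"{path}: non-numeric values in column '{col}'")
        return ParticleSet(_records_from_xyz(df))
    if dialect == "star":
        doc = gemmi.cif.read_file(str(path))
        for block in doc:
            cols = {}
            for key, tag in _STAR_TAGS.items():
                col = block.find_loop(tag)
                if len(col) > 0:
                    cols[key] = [float(v) for v in col]
            if {"x", "y", "z"} <= set(cols):
                df = pd.DataFrame(cols)
                return ParticleSet(_records_from_xyz(df, offset=-1.0))
        raise ValueError(f"{path}: no _rlnCoordinateX/Y/Z loop found")
    raise ValueError(f"unknown dialect {dialect!r} (expected csv, tsv or star)")


def write_particles(particles: ParticleSet, path: str | os.PathLike,
                    dialect: str = "csv") -> Path:
    """Write a particle table; round-trips through :func:`read_particles`."""
    path = Path(path)
    centers = particles.centers()
    cols: dict[str, np.ndarray] = {}
    if len(particles):
        cols["x"] = centers[:, 2]
        cols["y"] = centers[:, 1]
        cols["z"] = centers[:, 0]
        cols["class"] = particles.class_ids()
        scores = particles.scores()
        if scores is not None:
            cols["score"] = scores
    df = pd.DataFrame(cols, columns=["x", "y", "z", "class"] + (["score"] if "score" in cols else []))
    if dialect in ("csv", "tsv"):
        df.to_csv(path, sep="," if dialect == "csv" else "\t", index=False, float_format="%.6f")
        return path
    if dialect == "star":
        doc = gemmi.cif.Document()
        block = doc.add_new_block("particles")
        tags = ["_rlnCoordinateX", "_rlnCoordinateY", "_rlnCoordinateZ", "_rlnClassNumber"]
        has_score = "score" in df.columns
        if has_score:
            tags.append("_rlnAutopickFigureOfMerit")
        loop = block.init_loop("", tags)
        for _, row in df.iterrows():
            vals = [f"{row['x'] + 1:.6f}", f"{row['y'] + 1:.6f}", f"{row['z'] + 1:.6f}",
                    str(int(row["class"]))]
            if has_score:
                vals.append(f"{row['score']:.6f}")
            loop.add_row(vals)
        doc.write_file(str(path))
        return path
    raise ValueError(f"unknown dialect {dialect!r} (expected csv, tsv or star)")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_tomogram(tomogram: Tomogram, mode: str = "zscore") -> Tomogram:
    """Standardize intensities.

    ``zscore`` maps to zero mean, unit standard deviation (fails on constant
    volumes); ``percentile_clip`` clips at the 0.5/99.5 percentiles and
    rescales to [0, 1] (a constant volume maps to all zeros).
    """
    data = tomogram.data.astype(np.float64)
    if mode == "zscore":
        sd = data.std()
        if sd == 0:
            raise ValueError("zscore normalization undefined for a constant volume")
        out = (data - data.mean()) / sd
    elif mode == "percentile_clip":
        lo, hi = np.percentile(data, [0.5, 99.5])
        out = np.clip(data, lo, hi)
        if hi > lo:
            out = (out - lo) / (hi - lo)
        else:
            out = np.zeros_like(data)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return Tomogram(out.astype(np.float32), voxel_size=tomogram.voxel_size,
                    origin=tomogram.origin.copy())
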