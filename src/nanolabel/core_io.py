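"""Shared domain types and readers/writers for volumes and particle tables.

Conventions used throughout the package:

* All internal geometry is in ångströms (Å); nanometres appear only at
  reporting boundaries.
* Volume arrays are indexed ``[z, y, x]`` (MRC section/row/column order),
  while positions, offsets and origins are ``(x, y, z)`` vectors.
* Voxel ``i`` along an axis with spacing ``s`` covers ``[i*s, (i+1)*s)``;
  its *center* sits at ``(i + 0.5) * s + origin``.  Rasterization and
  centroid arithmetic both use this voxel-center convention.
* Orientations are intrinsic ZYZ Euler angles ``(rot, tilt, psi)`` in
  degrees, the common subtomogram-averaging dialect.  STAR files written
  by this module use the ``rlnAngleRot/Tilt/Psi`` columns with that
  meaning.
* Contrast is explicit.  Raw cryo-EM tomograms are ``density_dark``
  (dense material = low values); every intensity-thresholding operation
  requires ``density_bright`` input, and conversion is never implicit.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import mrcfile
import numpy as np
import pandas as pd

__all__ = [
    "Contrast",
    "VolumeGrid",
    "ParticleRecord",
    "ParticleTable",
    "GoldDetection",
    "DetectionParams",
    "EfficiencyResult",
    "TetherModel",
    "read_volume",
    "write_volume",
    "read_particles",
    "write_particles",
    "voxel_center_positions",
]


class Contrast(str, Enum):
    """Contrast convention of a volume."""

    DENSITY_DARK = "density_dark"
    DENSITY_BRIGHT = "density_bright"


@dataclass
class VolumeGrid:
    """A 3D intensity grid with physical voxel size and contrast convention.

    Parameters
    ----------
    data
        3D scalar array indexed ``[z, y, x]`` (arbitrary intensity units).
    voxel_size
        Isotropic voxel edge length in Å; must be positive.
    contrast
        Whether dense objects are dark (raw cryo-EM) or bright.
    origin
        Physical position of the volume origin as an ``(x, y, z)`` vector, Å.
    """

    data: np.ndarray
    voxel_size: float
    contrast: Contrast = Contrast.DENSITY_DARK
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be 3D with all dimensions >= 1")
        if not (self.voxel_size > 0):
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.contrast = Contrast(self.contrast)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape ``(nz, ny, nx)``."""
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent(self) -> np.ndarray:
        """Physical edge lengths as an ``(x, y, z)`` vector, Å."""
        nz, ny, nx = self.data.shape
        return np.array([nx, ny, nz], dtype=float) * self.voxel_size

    def with_data(self, data: np.ndarray, contrast: Contrast | None = None) -> "VolumeGrid":
        """Return a copy carrying ``data`` (same voxel size and origin)."""
        return VolumeGrid(
            data=data,
            voxel_size=self.voxel_size,
            contrast=self.contrast if contrast is None else contrast,
            origin=self.origin.copy(),
        )

    def invert_contrast(self) -> "VolumeGrid":
        """Explicitly flip the contrast convention by negating intensities."""
        flipped = (
            Contrast.DENSITY_BRIGHT
            if self.contrast is Contrast.DENSITY_DARK
            else Contrast.DENSITY_DARK
        )
        return self.with_data(-self.data, contrast=flipped)

    def require_bright(self, op: str) -> None:
        """Raise unless this volume is ``density_bright``."""
        if self.contrast is not Contrast.DENSITY_BRIGHT:
            raise ValueError(
                f"{op} requires density_bright input (dense objects = high values); "
                "call invert_contrast() explicitly first"
            )


def voxel_center_positions(indices_zyx: np.ndarray, voxel_size: float,
                           origin: Sequence[float] = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Convert ``(k, 3)`` integer ``(z, y, x)`` indices to ``(x, y, z)`` Å positions."""
    idx = np.atleast_2d(np.asarray(indices_zyx, dtype=float))
    return (idx[:, ::-1] + 0.5) * voxel_size + np.asarray(origin, dtype=float)


@dataclass
class ParticleRecord:
    """One picked macromolecule: position (Å), ZYZ Euler angles (deg), id."""

    position: np.ndarray
    euler: np.ndarray = field(default_factory=lambda: np.zeros(3))
    id: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.euler = np.asarray(self.euler, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.euler)):
            raise ValueError("Euler angles must be finite")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position must be finite")


@dataclass
class ParticleTable:
    """Ordered collection of :class:`ParticleRecord` with provenance."""

    records: list[ParticleRecord]
    pixel_size_of_source: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("particle ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def positions(self) -> np.ndarray:
        """``(n, 3)`` array of ``(x, y, z)`` positions, Å."""
        return np.array([r.position for r in self.records], dtype=float).reshape(-1, 3)

    @property
    def eulers(self) -> np.ndarray:
        """``(n, 3)`` array of ``(rot, tilt, psi)`` angles, degrees."""
        return np.array([r.euler for r in self.records], dtype=float).reshape(-1, 3)

    @property
    def ids(self) -> np.ndarray:
        return np.array([r.id for r in self.records], dtype=int)

    @classmethod
    def from_arrays(cls, positions: np.ndarray, eulers: np.ndarray | None = None,
                    ids: Iterable[int] | None = None, pixel_size_of_source: float = 1.0,
                    provenance: str = "") -> "ParticleTable":
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = positions.shape[0]
        if eulers is None:
            eulers = np.zeros((n, 3))
        eulers = np.atleast_2d(np.asarray(eulers, dtype=float))
        if ids is None:
            ids = range(n)
        records = [
            ParticleRecord(position=p, euler=e, id=int(i))
            for p, e, i in zip(positions, eulers, ids)
        ]
        return cls(records=records, pixel_size_of_source=pixel_size_of_source,
                   provenance=provenance)


@dataclass
class GoldDetection:
    """A detected gold blob: centroid (Å), voxel count, peak intensity, id."""

    centroid: np.ndarray
    voxel_count: int
    peak_intensity: float
    component_id: int

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(3)
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")


@dataclass
class DetectionParams:
    """Parameters of the whole-tomogram gold-detection procedure.

    Defaults target 1.4-nm gold (7 Å radius) on a 3 Å working grid: a
    sphere of that size theoretically occupies 53 voxels, gated between
    40 (undersampling allowance) and 55 (larger blobs are gallium, ice or
    membrane).
    """

    k_sd: float = 3.3
    slab_width: int = 10
    connectivity: int = 26
    min_voxels: int = 40
    max_voxels: int = 55
    remove_singletons: bool = True
    working_pixel_size: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.min_voxels <= self.max_voxels):
            raise ValueError("require 0 < min_voxels <= max_voxels")
        if not (self.k_sd > 0):
            raise ValueError("k_sd must be > 0")
        if self.slab_width < 1:
            raise ValueError("slab_width must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")
        if not (self.working_pixel_size > 0):
            raise ValueError("working_pixel_size must be > 0")


@dataclass
class EfficiencyResult:
    """Labeled/unlabeled counts and the labeling-efficiency fraction."""

    n_labeled: int
    n_unlabeled: int
    efficiency: float

    def __post_init__(self) -> None:
        if self.n_labeled < 0 or self.n_unlabeled < 0:
            raise ValueError("counts must be non-negative")
        denom = self.n_labeled + self.n_unlabeled
        if denom == 0:
            raise ValueError("n_labeled + n_unlabeled must be > 0")
        expected = self.n_labeled / denom
        if abs(self.efficiency - expected) > 1e-12:
            raise ValueError("efficiency must equal n_labeled / (n_labeled + n_unlabeled)")

    @property
    def as_fraction(self) -> Fraction:
        """Exact rational value of the statistic."""
        return Fraction(self.n_labeled, self.n_labeled + self.n_unlabeled)


@dataclass
class TetherModel:
    """Flexible tether between the tag site and the gold center.

    ``rigid_extension`` covers the dextran carrier (~36 Å diameter) plus
    the ligand (~22 Å end-to-end); ``max_distance`` is the adopted upper
    bound on the tag-to-gold separation (100 Å by default).
    """

    n_flexible_residues: int = 20
    contour_per_residue: float = 3.8
    persistence_length: float = 4.0
    rigid_extension: float = 58.0
    max_distance: float | None = 100.0

    def __post_init__(self) -> None:
        if self.n_flexible_residues < 0:
            raise ValueError("n_flexible_residues must be >= 0")
        for name in ("contour_per_residue", "persistence_length", "rigid_extension"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.max_distance is not None and not (self.max_distance > 0):
            raise ValueError("max_distance must be > 0 when set")


# ---------------------------------------------------------------------------
# MRC volumes
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike, contrast: Contrast = Contrast.DENSITY_DARK) -> VolumeGrid:
    """Read an MRC2014 volume.

    The voxel size must be isotropic; ``contrast`` defaults to
    ``density_dark``, the raw cryo-EM convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with mrcfile.open(path, mode="r") as mrc:
        vs = mrc.voxel_size
        sizes = np.array([float(vs.x), float(vs.y), float(vs.z)])
        if np.any(sizes <= 0):
            raise ValueError(f"{path}: voxel size missing or non-positive in header")
        if not np.allclose(sizes, sizes[0], rtol=1e-4, atol=1e-6):
            raise ValueError(
                f"{path}: anisotropic voxel size {tuple(sizes)} is not supported"
            )
        if mrc.data.ndim != 3:
            raise ValueError(f"{path}: expected a single 3D volume")
        data = np.asarray(mrc.data, dtype=np.float32).copy()
        org = mrc.header.origin
        origin = np.array([float(org.x), float(org.y), float(org.z)])
    return VolumeGrid(data=data, voxel_size=float(sizes[0]), contrast=contrast,
                      origin=origin)


def write_volume(vol: VolumeGrid, path: str | os.PathLike) -> None:
    """Write ``vol`` as an MRC2014 file (mode 2, 32-bit float)."""
    if not np.all(np.isfinite(vol.data)):
        raise ValueError("volume contains non-finite values")
    path = Path(path)
    with mrcfile.new(path, overwrite=True) as mrc:
        mrc.set_data(np.asarray(vol.data, dtype=np.float32))
        mrc.voxel_size = vol.voxel_size
        mrc.header.origin.x = vol.origin[0]
        mrc.header.origin.y = vol.origin[1]
        mrc.header.origin.z = vol.origin[2]


# ---------------------------------------------------------------------------
# Particle tables (STAR / CSV)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["id", "x_A", "y_A", "z_A", "rot_deg", "tilt_deg", "psi_deg"]
_STAR_COORD = ["rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ"]
_STAR_ANGLE = ["rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi"]


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("star", "csv"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    suffix = path.suffix.lower()
    if suffix == ".star":
        return "star"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer dialect from {path.name!r}; pass dialect=")


def _parse_star(text: str) -> pd.DataFrame:
    """Parse the first ``loop_`` block of a STAR file into a DataFrame."""
    lines = text.splitlines()
    i = 0
    while i < len(lines) and lines[i].strip() != "loop_":
        i += 1
    if i == len(lines):
        raise ValueError("no loop_ block found in STAR file")
    i += 1
    columns: list[str] = []
    while i < len(lines):
        stripped = lines[i].strip()
        if stripped.startswith("_"):
            columns.append(stripped.split()[0].lstrip("_"))
            i += 1
        else:
            break
    rows: list[list[str]] = []
    while i < len(lines):
        stripped = lines[i].strip()
        if not stripped or stripped.startswith(("data_", "loop_", "#")):
            break
        tokens = stripped.split()
        if len(tokens) != len(columns):
            raise ValueError(
                f"STAR row has {len(tokens)} fields, expected {len(columns)}"
            )
        rows.append(tokens)
        i += 1
    frame = pd.DataFrame(rows, columns=columns)
    return frame


def read_particles(path: str | os.PathLike, dialect: str | None = None,
                   pixel_size: float | None = None) -> ParticleTable:
    """Read a particle table from CSV (Å) or a STAR particle loop (pixels).

    CSV columns: ``id,x_A,y_A,z_A,rot_deg,tilt_deg,psi_deg`` (``id``
    optional).  STAR loops carry ``rlnCoordinateX/Y/Z`` in pixels of a
    declared pixel size — either an ``rlnImagePixelSize`` column or the
    ``pixel_size`` argument — plus the three ZYZ angle columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        frame = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS[1:] if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        if frame.empty:
            raise ValueError(f"{path}: no particles")
        coords = frame[["x_A", "y_A", "z_A"]].to_numpy(dtype=float)
        eulers = frame[["rot_deg", "tilt_deg", "psi_deg"]].to_numpy(dtype=float)
        ids = frame["id"].to_numpy(dtype=int) if "id" in frame.columns else None
        return ParticleTable.from_arrays(coords, eulers, ids,
                                         pixel_size_of_source=1.0,
                                         provenance=str(path))
    frame = _parse_star(path.read_text())
    missing = [c for c in _STAR_COORD + _STAR_ANGLE if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing STAR columns {missing}")
    if frame.empty:
        raise ValueError(f"{path}: no particles")
    try:
        coords_px = frame[_STAR_COORD].to_numpy(dtype=float)
        eulers = frame[_STAR_ANGLE].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric STAR fields ({exc})") from exc
    if "rlnImagePixelSize" in frame.columns:
        sizes = frame["rlnImagePixelSize"].to_numpy(dtype=float)
        if not np.allclose(sizes, sizes[0]):
            raise ValueError(f"{path}: inconsistent rlnImagePixelSize values")
        ps = float(sizes[0])
        if pixel_size is not None and not np.isclose(pixel_size, ps):
            raise ValueError(
                f"{path}: pixel_size argument {pixel_size} disagrees with file ({ps})"
            )
    elif pixel_size is not None:
        ps = float(pixel_size)
    else:
        raise ValueError(
            f"{path}: STAR file declares no pixel size; pass pixel_size="
        )
    ids = None
    if "nanolabelParticleId" in frame.columns:
        ids = frame["nanolabelParticleId"].to_numpy(dtype=int)
    return ParticleTable.from_arrays(coords_px * ps, eulers, ids,
                                     pixel_size_of_source=ps,
                                     provenance=str(path))


def write_particles(table: ParticleTable, path: str | os.PathLike,
                    dialect: str | None = None,
                    pixel_size: float | None = None) -> None:
    """Write a particle table; the inverse of :func:`read_particles`.

    For the STAR dialect, coordinates are written in pixels of
    ``pixel_size`` (default: ``table.pixel_size_of_source``) and the
    pixel size is recorded in an ``rlnImagePixelSize`` column; angles
    are intrinsic ZYZ ``(rot, tilt, psi)`` degrees.
    """
    path = Path(path)
    if len(table) == 0:
        raise ValueError("refusing to write an empty particle table")
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        frame = pd.DataFrame({
            "id": table.ids,
            "x_A": np.round(table.positions[:, 0], 3),
            "y_A": np.round(table.positions[:, 1], 3),
            "z_A": np.round(table.positions[:, 2], 3),
            "rot_deg": np.round(table.eulers[:, 0], 3),
            "tilt_deg": np.round(table.eulers[:, 1], 3),
            "psi_deg": np.round(table.eulers[:, 2], 3),
        })
        frame.to_csv(path, index=False)
        return
    ps = float(pixel_size) if pixel_size is not None else float(table.pixel_size_of_source)
    if not (ps > 0):
        raise ValueError("pixel size must be > 0 for STAR output")
    coords_px = table.positions / ps
    buf = io.StringIO()
    buf.write("# ZYZ intrinsic Euler angles (rot, tilt, psi), degrees\n")
    buf.write("data_particles\n\nloop_\n")
    cols = ["nanolabelParticleId"] + _STAR_COORD + _STAR_ANGLE + ["rlnImagePixelSize"]
    for j, col in enumerate(cols, start=1):
        buf.write(f"_{col} #{j}\n")
    for rid, xyz, ang in zip(table.ids, coords_px, table.eulers):
        buf.write(
            f"{rid:d} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f} "
            f"{ang[0]:.6f} {ang[1]:.6f} {ang[2]:.6f} {ps:.6f}\n"
        )
    path.write_text(buf.getvalue())
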