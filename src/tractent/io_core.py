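"""Streamline and volume I/O plus the shared grid-geometry model.

Conventions used throughout the package:

* world coordinates are RAS millimetres;
* voxel indices are 0-based with the voxel *center* at the integer index;
* ``GridGeometry.affine`` maps voxel index -> world mm (NIfTI convention).

TRK files natively store coordinates in a voxel-scaled frame with the corner
of the first voxel at the origin; nibabel converts them to RAS mm on load and
back on save, so both formats present the same world-mm streamlines here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile


class FormatError(ValueError):
    """A file could not be parsed as the declared (or any known) format."""


@dataclass(frozen=True)
class GridGeometry:
    """A regular 3-D voxel lattice embedded in world space.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis; every component >= 1.
    affine : (4, 4) ndarray
        Invertible voxel-index -> world-mm transform.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (norms of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_mm: float = 2.0,
                  origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "GridGeometry":
        """Axis-aligned grid with isotropic voxels, e.g. the 2 mm dMRI lattice."""
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        affine[:3, 3] = origin
        return cls(tuple(shape), affine)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclass
class Tractogram:
    """An ordered collection of streamlines bound to a reference grid.

    ``streamlines`` is a list of (n_i, 3) float arrays of world-mm points
    (n_i >= 2); ``ids`` is a stable integer per fiber, unique and ordered.
    """

    streamlines: list[np.ndarray]
    geometry: GridGeometry
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError("each streamline needs >= 2 three-dimensional points")
            if not np.all(np.isfinite(s)):
                raise ValueError("streamline contains non-finite coordinates")
        if self.ids is None:
            self.ids = np.arange(len(self.streamlines))
        else:
            self.ids = np.asarray(self.ids, dtype=int)
            if len(self.ids) != len(self.streamlines):
                raise ValueError("one id per streamline required")
            if len(np.unique(self.ids)) != len(self.ids) or np.any(np.diff(self.ids) <= 0):
                raise ValueError("ids must be unique and strictly increasing")

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, keep_ids) -> "Tractogram":
        """New tractogram restricted to ``keep_ids`` (original ids retained)."""
        keep = set(int(i) for i in keep_ids)
        pairs = [(i, s) for i, s in zip(self.ids, self.streamlines) if int(i) in keep]
        return Tractogram([s for _, s in pairs], self.geometry,
                          np.array([i for i, _ in pairs], dtype=int))


@dataclass
class ScalarVolume:
    """A 3-D scalar lattice with its geometry and a free-text unit tag."""

    values: np.ndarray
    geometry: GridGeometry
    unit: str = "unitless"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}")


def world_to_voxel(points: np.ndarray, g: GridGeometry) -> np.ndarray:
    """Map world-mm points to continuous 0-based voxel indices.

    Points outside the grid come back with out-of-range indices; callers
    decide how to treat them.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inv = g.inverse_affine
    return pts @ inv[:3, :3].T + inv[:3, 3]


def voxel_to_world(indices: np.ndarray, g: GridGeometry) -> np.ndarray:
    """Inverse of :func:`world_to_voxel` (continuous indices allowed)."""
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    return idx @ g.affine[:3, :3].T + g.affine[:3, 3]


def _geometry_from_trk_header(header: dict) -> GridGeometry:
    affine = np.array(header["voxel_to_rasmm"], dtype=float)
    shape = tuple(int(d) for d in header["dimensions"])
    return GridGeometry(shape, affine)


def _resolve_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    suffix = path.suffix.lower()
    if suffix == ".tck":
        return "tck"
    if suffix == ".trk":
        return "trk"
    raise FormatError(f"cannot infer streamline format from {path.name!r}")


def read_tractogram(path, format: str = "auto",
                    reference: GridGeometry | None = None) -> Tractogram:
    """Read a TCK or TRK file into a world-mm :class:`Tractogram`.

    TCK carries no grid, so ``reference`` is required for it (TRK headers
    define their own grid; an explicit ``reference`` overrides it).
    Streamlines with fewer than 2 points are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    cls = {"tck": TckFile, "trk": TrkFile}.get(fmt)
    if cls is None:
        raise FormatError(f"unknown streamline format {fmt!r}")
    try:
        f = cls.load(str(path), lazy_load=False)
    except Exception as exc:  # nibabel raises several header/data error types
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc

    geometry = reference
    if geometry is None:
        if fmt == "trk":
            geometry = _geometry_from_trk_header(f.header)
        else:
            raise ValueError("TCK files carry no grid geometry; pass reference=")

    streamlines = [np.asarray(s, dtype=float) for s in f.tractogram.streamlines]
    n_short = sum(1 for s in streamlines if s.shape[0] < 2)
    if n_short:
        warnings.warn(f"dropped {n_short} streamline(s) with < 2 points")
        streamlines = [s for s in streamlines if s.shape[0] >= 2]
    if not streamlines:
        warnings.warn(f"{path.name}: empty tractogram")
        t = Tractogram.__new__(Tractogram)
        t.streamlines, t.geometry, t.ids = [], geometry, np.arange(0)
        return t
    return Tractogram(streamlines, geometry)


def write_tractogram(t: Tractogram, path, format: str = "auto") -> None:
    """Write a tractogram as TCK or TRK; round-trips through read_tractogram."""
    path = Path(path)
    fmt = _resolve_format(path, format)
    sl = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in t.streamlines],
        affine_to_rasmm=np.eye(4))
    if fmt == "tck":
        f = TckFile(sl)
    elif fmt == "trk":
        header = {
            "voxel_to_rasmm": t.geometry.affine.astype(np.float32),
            "voxel_sizes": t.geometry.voxel_size.astype(np.float32),
            "dimensions": np.asarray(t.geometry.shape, dtype=np.int16),
            "voxel_order": "".join(nib.aff2axcodes(t.geometry.affine)),
        }
        f = TrkFile(sl, header=header)
    else:
        raise FormatError(f"unknown streamline format {fmt!r}")
    f.save(str(path))


def read_volume(path) -> ScalarVolume:
    """Read a NIfTI scalar volume."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise FormatError(f"{path}: non-invertible affine in header")
    unit = img.header.get("descrip", b"")
    unit = unit.tobytes().split(b"\x00")[0].decode(errors="replace") if hasattr(unit, "tobytes") else ""
    return ScalarVolume(data, GridGeometry(data.shape, affine), unit or "unitless")


def write_volume(v: ScalarVolume, path) -> None:
    """Write a scalar volume as NIfTI-1 (unit tag stored in descrip)."""
    img = nib.Nifti1Image(v.values.astype(np.float64), v.geometry.affine)
    img.header["descrip"] = v.unit.encode()[:79]
    nib.save(img, str(path))


def read_vector_volume(path) -> tuple[np.ndarray, GridGeometry]:
    """Read a 4-D NIfTI whose last axis holds 3-vectors."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(f"{path}: expected shape (i, j, k, 3), got {data.shape}")
    return data, GridGeometry(data.shape[:3], np.asarray(img.affine, dtype=float))


def write_vector_volume(vectors: np.ndarray, g: GridGeometry, path) -> None:
    img = nib.Nifti1Image(np.asarray(vectors, dtype=np.float64), g.affine)
    nib.save(img, str(path))
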