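"""Orientation-histogram Shannon entropy of a fiber tangent field.

The unit sphere is decomposed into ``n_bins`` regions of equal area by the
recursive zonal equal-area construction (two polar caps plus collar rings
subdivided in longitude).  The cones joining those regions to the sphere
center bin the tangent vectors of a cubic voxel neighborhood into a
spherical orientation histogram whose Shannon entropy (bits) measures the
local orientation disorder: 0 for a perfectly coherent bundle, up to
``log2(n_bins)`` for isotropically scattered fibers.  Averaging the entropy
map along each fiber yields the per-fiber score used for filtering: coherent
(anatomically plausible) fibers score low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_core import GridGeometry, Tractogram, world_to_voxel
from .field import OrientationField

#: number of histogram bins matching a 32-direction dMRI acquisition
DEFAULT_N_BINS = 32


class SpherePartition:
    """Recursive zonal equal-area partition of the unit sphere.

    The sphere is split into a north polar cap, ``n_collars`` collar rings
    each cut into equal-longitude sectors, and a south polar cap; every
    region has area exactly ``4*pi/n_bins``.  Region indices run north to
    south, west to east; ties on a region boundary resolve to the lower
    index.
    """

    def __init__(self, n_bins: int):
        n_bins = int(n_bins)
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        self.n_bins = n_bins
        if n_bins == 1:
            self._boundaries = np.array([])        # colatitudes between zones
            self._collar_counts = np.array([], int)
            return
        if n_bins == 2:
            self._boundaries = np.array([np.pi / 2])
            self._collar_counts = np.array([], int)
            return

        n = n_bins
        theta_c = 2 * np.arcsin(np.sqrt(1.0 / n))   # cap of area 4*pi/n
        delta_ideal = np.sqrt(4 * np.pi / n)        # side of a square of that area
        n_collars = max(1, int(round((np.pi - 2 * theta_c) / delta_ideal)))
        delta_fit = (np.pi - 2 * theta_c) / n_collars

        # ideal region count per collar, rounded with a carried remainder so
        # the counts sum to exactly n - 2
        counts = np.empty(n_collars, int)
        carry = 0.0
        for i in range(n_collars):
            t0 = theta_c + i * delta_fit
            t1 = theta_c + (i + 1) * delta_fit
            ideal = n * (np.cos(t0) - np.cos(t1)) / 2.0
            counts[i] = int(round(ideal + carry))
            carry += ideal - counts[i]
        assert counts.sum() == n - 2

        # adjust collar boundaries so each zone's area is an exact multiple
        # of 4*pi/n: a cap holding k regions has colatitude 2*asin(sqrt(k/n))
        cum = 1 + np.concatenate([[0], np.cumsum(counts)])
        self._boundaries = 2 * np.arcsin(np.sqrt(cum / n))
        self._collar_counts = counts

    @property
    def region_areas(self) -> np.ndarray:
        """Analytic area of every region (all equal to ``4*pi/n_bins``)."""
        n = self.n_bins
        if n == 1:
            return np.array([4 * np.pi])
        caps = np.concatenate([[0.0], self._boundaries, [np.pi]])
        zone_areas = 2 * np.pi * (np.cos(caps[:-1]) - np.cos(caps[1:]))
        per_zone = np.concatenate([[1], self._collar_counts, [1]]) if n > 2 else np.array([1, 1])
        return np.repeat(zone_areas / per_zone, per_zone)

    def lookup(self, vectors: np.ndarray) -> np.ndarray:
        """Bin index in ``[0, n_bins)`` for each unit vector (deterministic)."""
        v = np.atleast_2d(np.asarray(vectors, dtype=float))
        if self.n_bins == 1:
            return np.zeros(len(v), dtype=int)
        theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
        if self.n_bins == 2:
            return (theta > np.pi / 2).astype(int)

        # zone 0 = north cap, zones 1..n_collars = collars, last = south cap
        zone = np.searchsorted(self._boundaries, theta, side="left")
        zone = np.clip(zone, 0, len(self._collar_counts) + 1)
        first_in_zone = 1 + np.concatenate([[0], np.cumsum(self._collar_counts)])

        out = np.empty(len(v), dtype=int)
        north = zone == 0
        south = zone == len(self._collar_counts) + 1
        out[north] = 0
        out[south] = self.n_bins - 1
        collar = ~north & ~south
        if collar.any():
            j = zone[collar] - 1
            m = self._collar_counts[j]
            phi = np.mod(np.arctan2(v[collar, 1], v[collar, 0]), 2 * np.pi)
            width = 2 * np.pi / m
            sector = np.ceil(phi / width).astype(int) - 1   # boundary -> lower sector
            sector = np.clip(sector, 0, m - 1)
            out[collar] = first_in_zone[j] + sector
        return out


def partition_sphere(n_bins: int = DEFAULT_N_BINS) -> SpherePartition:
    """Equal-area sphere partition with ``n_bins`` regions."""
    return SpherePartition(n_bins)


@dataclass
class OrientationHistogram:
    """Counts of orientation vectors per sphere-partition bin."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or np.any(self.counts < 0):
            raise ValueError("counts must be a 1-D non-negative array")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def canonicalize_axial(vectors: np.ndarray) -> np.ndarray:
    """Flip vectors into the hemisphere with non-negative last nonzero
    coordinate, so ``v`` and ``-v`` become identical (axial identification)."""
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    sign = np.where(v[:, 2] != 0, np.sign(v[:, 2]),
                    np.where(v[:, 1] != 0, np.sign(v[:, 1]),
                             np.where(v[:, 0] != 0, np.sign(v[:, 0]), 1.0)))
    return v * sign[:, None]


def orientation_histogram(vectors: np.ndarray, p: SpherePartition,
                          axial: bool = True) -> OrientationHistogram:
    """Spherical orientation histogram of unit vectors.

    With ``axial=True`` (the default: fiber tangents carry no sign) each
    vector is canonicalized to a hemisphere before lookup so that antipodal
    directions share a bin.
    """
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    if v.size == 0:
        return OrientationHistogram(np.zeros(p.n_bins))
    norms = np.linalg.norm(v, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("vectors must be unit-norm within 1e-6")
    if axial:
        v = canonicalize_axial(v)
    bins = p.lookup(v)
    return OrientationHistogram(np.bincount(bins, minlength=p.n_bins).astype(float))


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts / total
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def shannon_entropy(h: OrientationHistogram) -> float:
    """Plug-in Shannon entropy of a histogram, in bits.

    ``e = -sum p_i log2 p_i`` with ``p_i = C_i / sum C_j``; empty bins
    contribute nothing.  Lies in ``[0, log2(n_bins)]``.
    """
    if h.total <= 0:
        raise ValueError("entropy of an empty histogram is undefined")
    return _entropy_bits(h.counts)


@dataclass
class EntropyMap:
    """Per-voxel orientation entropy (bits) with a validity mask."""

    values: np.ndarray
    valid: np.ndarray
    geometry: GridGeometry
    n_bins: int

    def __post_init__(self) -> None:
        if self.values.shape != self.geometry.shape or self.valid.shape != self.geometry.shape:
            raise ValueError("values/valid must match the grid shape")

    @property
    def max_entropy(self) -> float:
        return float(np.log2(self.n_bins)) if self.n_bins > 1 else 0.0


def _box_sum(a: np.ndarray, size: int) -> np.ndarray:
    """Sum over a centered size^3 window, clipped at the volume borders.

    Integer-exact: uses prefix sums of int64 arrays.
    """
    half = size // 2
    out = a
    for axis in range(3):
        n = out.shape[axis]
        zeros_shape = list(out.shape)
        zeros_shape[axis] = 1
        prefix = np.concatenate([np.zeros(zeros_shape, dtype=out.dtype),
                                 np.cumsum(out, axis=axis)], axis=axis)
        hi = np.minimum(np.arange(n) + half + 1, n)
        lo = np.maximum(np.arange(n) - half, 0)
        out = np.take(prefix, hi, axis=axis) - np.take(prefix, lo, axis=axis)
    return out


def entropy_map(field: OrientationField, neighborhood: int,
                p: SpherePartition | None = None, axial: bool = True) -> EntropyMap:
    """Shannon-entropy map of an orientation field.

    Every voxel gathers the valid orientation vectors of its centered
    ``neighborhood^3`` cube (clipped at the borders), bins them on the sphere
    partition and records the histogram entropy; voxels whose neighborhood
    holds no valid vector are masked out.
    """
    if p is None:
        p = partition_sphere(DEFAULT_N_BINS)
    neighborhood = int(neighborhood)
    if neighborhood < 1 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be an odd positive integer")

    shape = field.geometry.shape
    flat_valid = field.valid.reshape(-1)
    vecs = field.vectors.reshape(-1, 3)[flat_valid]
    bins = np.full(int(np.prod(shape)), -1, dtype=int)
    if len(vecs):
        v = canonicalize_axial(vecs) if axial else vecs
        bins[flat_valid] = p.lookup(v)
    bins = bins.reshape(shape)

    counts = np.zeros((*shape, p.n_bins), dtype=np.int64)
    for b in range(p.n_bins):
        counts[..., b] = _box_sum((bins == b).astype(np.int64), neighborhood)

    total = counts.sum(axis=-1)
    valid = total > 0
    flat_counts = counts.reshape(-1, p.n_bins).astype(float)
    flat_values = np.zeros(flat_counts.shape[0])
    for i in np.nonzero(valid.reshape(-1))[0]:
        flat_values[i] = _entropy_bits(flat_counts[i])
    return EntropyMap(flat_values.reshape(shape), valid, field.geometry, p.n_bins)


def neighborhood_for_diameter(d_mm: float, g: GridGeometry) -> int:
    """Cubic-neighborhood edge (voxels) proportional to a nerve diameter.

    ``round(d / mean voxel size)`` (half-up) forced odd upward, floored at 3,
    so e.g. a 7 mm trigeminal nerve on a 2 mm grid uses a 5-voxel cube.
    """
    if d_mm <= 0:
        raise ValueError("diameter must be positive")
    k = int(np.floor(d_mm / float(np.mean(g.voxel_size)) + 0.5))
    if k % 2 == 0:
        k += 1
    return max(k, 3)


@dataclass
class FiberScores:
    """One scalar per fiber plus the convention for ranking it.

    ``order`` is ``"keep_low"`` when filtering retains the lowest-scoring
    fibers first (entropy, imported SIFT2 weights) and ``"keep_high"`` for
    scores where high is good (mean FA).
    """

    ids: np.ndarray
    values: np.ndarray
    order: str
    method: str

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.order not in ("keep_low", "keep_high"):
            raise ValueError("order must be 'keep_low' or 'keep_high'")
        if len(self.ids) != len(self.values):
            raise ValueError("one value per id required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")


def score_fibers_entropy(t: Tractogram, e: EntropyMap) -> FiberScores:
    """Per-fiber score: mean map entropy over the voxels its points visit.

    Each fiber point maps to its nearest voxel; points landing on invalid or
    out-of-grid voxels are skipped (repeat visits are not deduplicated).
    Fibers with no usable point receive the max-entropy sentinel.
    """
    if e.geometry != t.geometry:
        raise ValueError("entropy map geometry differs from the tractogram's")
    shape = np.asarray(e.geometry.shape)
    scores = np.empty(len(t))
    n_sentinel = 0
    for k, s in enumerate(t.streamlines):
        idx = np.floor(world_to_voxel(s, e.geometry) + 0.5).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        idx = idx[ok]
        if len(idx):
            ok2 = e.valid[idx[:, 0], idx[:, 1], idx[:, 2]]
            idx = idx[ok2]
        if len(idx) == 0:
            scores[k] = e.max_entropy
            n_sentinel += 1
        else:
            scores[k] = e.values[idx[:, 0], idx[:, 1], idx[:, 2]].mean()
    if n_sentinel:
        warnings.warn(f"{n_sentinel} fiber(s) had no usable point; "
                      "assigned the max-entropy sentinel")
    return FiberScores(t.ids.copy(), scores, order="keep_low", method="entropy")
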