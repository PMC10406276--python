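"""Fiber-level Sørensen-Dice comparison of tractograms and the filter sweep.

Two tractograms are compared by discretizing one onto the reference voxel
grid (a binary nerve segmentation) and counting how many fibers of the
other are included in that segmentation:

    SD  = 2 |Z|  / (|X| + |Y|)   with Z  = fibers of Y inside mask(X)
    RSD = 2 |RZ| / (|X| + |Y|)   with RZ = fibers of X inside mask(Y)

SD punishes spurious fibers (and low fiber counts); RSD punishes truncation.
Sweeping the keep-percentage from 0 to 100 in 1 % steps yields the filtering
gain SD_diff = SD_max - SD_init.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .entropy import FiberScores
from .field import rasterize_density
from .filters import half_up
from .io_core import GridGeometry, ScalarVolume, Tractogram, world_to_voxel


def discretize(t: Tractogram, g: GridGeometry | None = None) -> ScalarVolume:
    """Binary segmentation: 1 where at least one fiber segment traverses
    the voxel (the support of the fiber-density image)."""
    density = rasterize_density(t, g)
    return ScalarVolume((density.values > 0).astype(float), density.geometry,
                        unit="binary")


def fibers_in_mask(t: Tractogram, mask: ScalarVolume,
                   inclusion_fraction: float = 1.0) -> np.ndarray:
    """Ids of fibers whose points lie in the mask.

    A fiber qualifies when the fraction of its points falling on mask = 1
    voxels (nearest voxel; out-of-grid points count as outside) is at least
    ``inclusion_fraction``; the default 1.0 demands full inclusion.
    """
    if not 0.0 < inclusion_fraction <= 1.0:
        raise ValueError("inclusion_fraction must lie in (0, 1]")
    inside_flags = _points_in_mask_fraction(t, mask)
    return t.ids[inside_flags >= inclusion_fraction]


def _points_in_mask_fraction(t: Tractogram, mask: ScalarVolume) -> np.ndarray:
    """Per-fiber fraction of points on mask voxels."""
    shape = np.asarray(mask.geometry.shape)
    m = mask.values > 0
    out = np.empty(len(t))
    for k, s in enumerate(t.streamlines):
        idx = np.floor(world_to_voxel(s, mask.geometry) + 0.5).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        hits = np.zeros(len(idx), bool)
        hits[ok] = m[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        out[k] = hits.mean()
    return out


@dataclass
class OverlapReport:
    """SD/RSD pair with the fiber-set cardinalities behind them."""

    sd: float
    rsd: float
    n_X: int
    n_Y: int
    n_Z: int
    n_RZ: int

    def as_dict(self) -> dict:
        return {"sd": self.sd, "rsd": self.rsd, "n_X": self.n_X,
                "n_Y": self.n_Y, "n_Z": self.n_Z, "n_RZ": self.n_RZ}


def sd_score(X: Tractogram, Y: Tractogram,
             inclusion_fraction: float = 1.0) -> OverlapReport:
    """Sørensen-Dice and reverse Sørensen-Dice between two tractograms.

    ``X`` is the reference (ground truth), ``Y`` the candidate.  Both scores
    share the denominator |X| + |Y|; RSD equals the SD obtained by swapping
    the arguments.
    """
    if X.geometry != Y.geometry:
        raise ValueError("tractograms must share a geometry")
    n_x, n_y = len(X), len(Y)
    if n_x + n_y == 0:
        raise ValueError("SD is undefined for two empty tractograms")
    n_z = len(fibers_in_mask(Y, discretize(X), inclusion_fraction)) if n_x and n_y else 0
    n_rz = len(fibers_in_mask(X, discretize(Y), inclusion_fraction)) if n_x and n_y else 0
    denom = n_x + n_y
    return OverlapReport(sd=2 * n_z / denom, rsd=2 * n_rz / denom,
                         n_X=n_x, n_Y=n_y, n_Z=n_z, n_RZ=n_rz)


@dataclass
class SweepResult:
    """SD curve over keep percentages 0..100 and its summary indices."""

    keep_percentages: np.ndarray   # 0..100 step 1
    sd_curve: np.ndarray           # SD at each percentage, length 101
    sd_init: float                 # SD at 100 % (before filtering)
    sd_max: float                  # best SD over the sweep
    best_percentage: int           # argmax (ties -> largest percentage)
    sd_diff: float                 # sd_max - sd_init: the filtering gain

    def as_dict(self) -> dict:
        return {
            "keep_percentages": self.keep_percentages.tolist(),
            "sd_curve": self.sd_curve.tolist(),
            "sd_init": self.sd_init,
            "sd_max": self.sd_max,
            "best_percentage": self.best_percentage,
            "sd_diff": self.sd_diff,
        }


def threshold_sweep(gt: Tractogram, cand: Tractogram, scores: FiberScores,
                    inclusion_fraction: float = 1.0) -> SweepResult:
    """SD of the filtered candidate against the ground truth at every keep
    percentage from 0 to 100 (step 1 %).

    Equivalent to filtering at each fraction and re-scoring, but computed
    from one pass: each fiber's in-mask flag against the ground-truth
    segmentation is fixed, so the SD at n kept fibers is
    ``2 * (in-mask among the n best) / (|X| + n)``.
    """
    if len(scores.ids) != len(cand.ids) or not np.array_equal(
            np.sort(scores.ids), cand.ids):
        raise ValueError("scores do not cover the candidate's fiber ids")
    n_x, n = len(gt), len(cand)
    if n_x == 0:
        raise ValueError("empty ground truth")
    mask = discretize(gt)
    frac = _points_in_mask_fraction(cand, mask)
    in_mask = frac >= inclusion_fraction

    key = scores.values if scores.order == "keep_low" else -scores.values
    rank = np.lexsort((scores.ids, key))
    # cum_z[k] = fibers of the k best that fall inside the ground-truth mask
    cum_z = np.concatenate([[0], np.cumsum(in_mask[rank])])

    pcts = np.arange(101)
    sd = np.empty(101)
    for p in pcts:
        n_keep = half_up(p / 100.0 * n)
        sd[p] = 2.0 * cum_z[n_keep] / (n_x + n_keep) if (n_x + n_keep) else 0.0
    sd_init = float(sd[100])
    best = int(np.flatnonzero(sd == sd.max()).max())   # ties -> largest keep %
    sd_max = float(sd[best])
    return SweepResult(pcts, sd, sd_init, sd_max, best, sd_max - sd_init)
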