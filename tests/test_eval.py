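import numpy as np
import pytest

from tractent.entropy import FiberScores
from tractent.evaluation import (discretize, fibers_in_mask, sd_score,
                                 threshold_sweep)
from tractent.field import rasterize_density
from tractent.io_core import GridGeometry, ScalarVolume, Tractogram

from conftest import random_tractogram


# ---------------------------------------------------------------------------
# independent brute-force oracle: voxel AABB vs segment slab intersection,
# nearest-voxel point lookup written from scratch
# ---------------------------------------------------------------------------

def _oracle_mask(t: Tractogram) -> np.ndarray:
    """Voxel support by a slab (segment vs voxel-AABB) intersection test --
    a different geometric predicate than the production boundary splitter."""
    g = t.geometry
    inv = np.linalg.inv(g.affine)
    centers = np.stack(np.meshgrid(*[np.arange(n) for n in g.shape],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
    lo = centers - 0.5
    hi = centers + 0.5
    mask = np.zeros(len(centers), bool)
    for s in t.streamlines:
        v = s @ inv[:3, :3].T + inv[:3, 3]
        for a, b in zip(v[:-1], v[1:]):
            d = b - a
            t0 = np.zeros(len(centers))
            t1 = np.ones(len(centers))
            ok = np.ones(len(centers), bool)
            for ax in range(3):
                if abs(d[ax]) < 1e-300:
                    ok &= (a[ax] >= lo[:, ax]) & (a[ax] <= hi[:, ax])
                else:
                    u0 = (lo[:, ax] - a[ax]) / d[ax]
                    u1 = (hi[:, ax] - a[ax]) / d[ax]
                    lo_u, hi_u = np.minimum(u0, u1), np.maximum(u0, u1)
                    t0 = np.maximum(t0, lo_u)
                    t1 = np.minimum(t1, hi_u)
            mask |= ok & (t0 < t1)
    return mask.reshape(g.shape)


def _oracle_in_mask_ids(t: Tractogram, mask: np.ndarray) -> set:
    g = t.geometry
    inv = np.linalg.inv(g.affine)
    out = set()
    for fid, s in zip(t.ids, t.streamlines):
        v = s @ inv[:3, :3].T + inv[:3, 3]
        inside = True
        for p in v:
            idx = [int(np.floor(c + 0.5)) for c in p]
            if any(c < 0 or c >= n for c, n in zip(idx, g.shape)) \
                    or not mask[idx[0], idx[1], idx[2]]:
                inside = False
                break
        if inside:
            out.add(int(fid))
    return out


def _oracle_sd(X: Tractogram, Y: Tractogram):
    z = _oracle_in_mask_ids(Y, _oracle_mask(X))
    rz = _oracle_in_mask_ids(X, _oracle_mask(Y))
    denom = len(X) + len(Y)
    return 2 * len(z) / denom, 2 * len(rz) / denom, len(z), len(rz)


# ---------------------------------------------------------------------------


def test_discretize_single_row(grid2mm):
    g = GridGeometry.isotropic((10, 10, 10), 2.0, origin=(1.0, 0.0, 0.0))
    t = Tractogram([np.array([[0.0, 0, 0], [10.0, 0, 0]])], g)
    m = discretize(t)
    assert m.values[:5, 0, 0].sum() == 5
    assert m.values.sum() == 5


def test_discretize_is_density_support(grid16):
    rng = np.random.default_rng(7)
    t = random_tractogram(grid16, 5, rng)
    m = discretize(t)
    d = rasterize_density(t)
    assert np.array_equal(m.values > 0, d.values > 0)
    assert set(np.unique(m.values)) <= {0.0, 1.0}


def test_fibers_in_mask_inclusion_fraction(grid2mm):
    mask = np.zeros((10, 10, 10))
    mask[:5] = 1.0                       # x < 9 mm half-space (voxels 0..4)
    vol = ScalarVolume(mask, grid2mm)
    # 10-point fiber: 9 points inside the half, 1 outside
    x = np.concatenate([np.linspace(0, 8, 9), [12.0]])
    t = Tractogram([np.stack([x, np.full(10, 4.0), np.full(10, 4.0)], axis=1)],
                   grid2mm)
    assert len(fibers_in_mask(t, vol, 1.0)) == 0
    assert len(fibers_in_mask(t, vol, 0.8)) == 1
    inside = Tractogram([np.array([[0.0, 4, 4], [8.0, 4, 4]])], grid2mm)
    assert len(fibers_in_mask(inside, vol, 1.0)) == 1
    outside = Tractogram([np.array([[12.0, 4, 4], [18.0, 4, 4]])], grid2mm)
    assert len(fibers_in_mask(outside, vol, 0.5)) == 0


def test_sd_identity_and_disjoint(grid16):
    rng = np.random.default_rng(8)
    X = random_tractogram(grid16, 6, rng)
    rep = sd_score(X, X)
    assert rep.sd == 1.0 and rep.rsd == 1.0
    shifted = Tractogram([s + [0.0, 14.0, 0.0] for s in X.streamlines],
                         grid16)
    far = sd_score(X, shifted)
    assert far.sd == 0.0 and far.rsd == 0.0


def test_sd_half_overlap_toy(grid2mm):
    row = np.array([[0.0, 4, 4], [8.0, 4, 4]])
    X = Tractogram([row, row + [0, 2, 0]], grid2mm)
    Y = Tractogram([row + 0.01, row + [0, 8, 0]], grid2mm)
    rep = sd_score(X, Y)
    assert rep.n_X == 2 and rep.n_Y == 2 and rep.n_Z == 1
    assert rep.sd == pytest.approx(0.5)


def test_sd_penalizes_low_fiber_count(grid2mm):
    """A subset of true fibers scores below 1 and grows with its size."""
    rows = [np.array([[0.0, 2.0 * i, 4], [8.0, 2.0 * i, 4]])
            for i in range(4)]
    X = Tractogram(rows, grid2mm)
    prev = 0.0
    for n in (1, 2, 3):
        Y = Tractogram(rows[:n], grid2mm)
        rep = sd_score(X, Y)
        assert rep.sd == pytest.approx(2 * n / (4 + n))
        assert prev < rep.sd < 1.0
        prev = rep.sd


def test_sd_matches_brute_force_oracle(grid16):
    rng = np.random.default_rng(9)
    for trial in range(5):
        X = random_tractogram(grid16, 4, rng, n_points=20)
        Y = random_tractogram(grid16, 5, rng, n_points=20)
        rep = sd_score(X, Y)
        sd_o, rsd_o, nz_o, nrz_o = _oracle_sd(X, Y)
        assert rep.sd == sd_o and rep.rsd == rsd_o
        assert rep.n_Z == nz_o and rep.n_RZ == nrz_o


def test_rsd_duality(grid16):
    rng = np.random.default_rng(10)
    X = random_tractogram(grid16, 5, rng)
    Y = random_tractogram(grid16, 7, rng)
    fwd = sd_score(X, Y)
    swapped = sd_score(Y, X)
    assert fwd.rsd == swapped.sd
    assert fwd.sd == swapped.rsd


def test_sd_empty_pair_undefined(grid2mm):
    empty = Tractogram([], grid2mm)
    with pytest.raises(ValueError):
        sd_score(empty, empty)


def _scores(ids, values):
    return FiberScores(ids, values, "keep_low", "entropy")


def test_sweep_perfect_candidate(grid16):
    rng = np.random.default_rng(11)
    X = random_tractogram(grid16, 6, rng)
    res = threshold_sweep(X, X, _scores(X.ids, rng.uniform(size=6)))
    assert len(res.sd_curve) == 101
    assert res.sd_init == 1.0
    assert res.sd_diff == 0.0
    assert res.sd_curve[0] == 0.0


def test_sweep_against_closed_form(grid2mm):
    """Ground truth plus k far-away fibers, true fibers scored strictly
    better: the SD curve is 2*min(n, n_gt) / (n_gt + n) exactly."""
    rows = [np.array([[0.0, 2.0 * i, 4], [8.0, 2.0 * i, 4]])
            for i in range(3)]
    gt = Tractogram(rows, grid2mm)
    k = 2
    far = [r + [0.0, 0.0, 10.0] for r in rows[:k]]
    cand = Tractogram(rows + far, grid2mm)
    scores = _scores(cand.ids, np.concatenate([np.zeros(3), np.ones(k)]))
    res = threshold_sweep(gt, cand, scores)
    n_gt, n_tot = 3, 5
    for p in range(101):
        n_keep = int(np.floor(p / 100 * n_tot + 0.5))
        expect = 2 * min(n_keep, n_gt) / (n_gt + n_keep)
        assert res.sd_curve[p] == pytest.approx(expect, abs=1e-12)
    assert res.sd_max == 1.0
    assert res.best_percentage == 69    # largest p whose rounding keeps 3
    # sd_init = 2*n_gt/(2*n_gt + k), sd_max = 1, so the gain is k/(2*n_gt + k)
    assert res.sd_diff == pytest.approx(k / (2 * n_gt + k), abs=1e-12)


def test_sweep_gain_nonnegative_random(grid16):
    rng = np.random.default_rng(12)
    gt = random_tractogram(grid16, 5, rng)
    cand = random_tractogram(grid16, 8, rng)
    res = threshold_sweep(gt, cand, _scores(cand.ids, rng.uniform(size=8)))
    assert res.sd_max >= res.sd_init
    assert res.sd_diff >= 0.0
    assert res.sd_max == res.sd_curve.max()
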