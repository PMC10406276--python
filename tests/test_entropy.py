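import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tractent.entropy import (EntropyMap, OrientationHistogram,
                              canonicalize_axial, entropy_map,
                              neighborhood_for_diameter,
                              orientation_histogram, partition_sphere,
                              score_fibers_entropy, shannon_entropy)
from tractent.field import OrientationField
from tractent.io_core import GridGeometry, Tractogram


def _random_unit(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


@pytest.mark.parametrize("n_bins", [1, 2, 4, 32, 100])
def test_partition_areas_equal(n_bins):
    p = partition_sphere(n_bins)
    areas = p.region_areas
    assert len(areas) == n_bins
    assert np.allclose(areas, 4 * np.pi / n_bins, atol=1e-9)
    assert areas.sum() == pytest.approx(4 * np.pi, abs=1e-9)


def test_partition_lookup_total_and_deterministic():
    p = partition_sphere(32)
    v = _random_unit(np.random.default_rng(0), 1000)
    b1, b2 = p.lookup(v), p.lookup(v)
    assert np.array_equal(b1, b2)
    assert b1.min() >= 0 and b1.max() < 32


def test_partition_monte_carlo_uniformity():
    p = partition_sphere(32)
    n = 20000
    v = _random_unit(np.random.default_rng(1), n)
    freq = np.bincount(p.lookup(v), minlength=32) / n
    se = math.sqrt((1 / 32) * (1 - 1 / 32) / n)
    assert np.all(np.abs(freq - 1 / 32) < 4 * se)


def test_partition_rejects_bad_bins():
    with pytest.raises(ValueError):
        partition_sphere(0)


def test_histogram_counts_and_axial_identification():
    p = partition_sphere(32)
    z = np.tile([0.0, 0.0, 1.0], (5, 1))
    h = orientation_histogram(z, p)
    assert h.total == 5
    assert np.sort(h.counts)[-1] == 5
    both = np.array([[0.0, 0, 1], [0.0, 0, -1]])
    h2 = orientation_histogram(both, p, axial=True)
    assert np.count_nonzero(h2.counts) == 1
    h3 = orientation_histogram(np.empty((0, 3)), p)
    assert h3.total == 0
    with pytest.raises(ValueError):
        orientation_histogram(np.array([[0.0, 0, 2.0]]), p)


def test_canonicalize_axial_sign_rules():
    v = np.array([[0.0, 0, -1], [0.0, -1, 0], [-1.0, 0, 0], [0.3, 0.4, 0.5]])
    c = canonicalize_axial(v)
    assert np.allclose(c[0], [0, 0, 1])
    assert np.allclose(c[1], [0, 1, 0])
    assert np.allclose(c[2], [1, 0, 0])
    assert np.allclose(c[3], v[3])


def test_shannon_entropy_reference_values():
    assert shannon_entropy(OrientationHistogram([5, 0, 0, 0])) == 0.0
    assert shannon_entropy(OrientationHistogram(np.ones(32))) == 5.0
    assert shannon_entropy(OrientationHistogram([3, 1])) == pytest.approx(
        0.8112781244591328, abs=1e-12)
    with pytest.raises(ValueError):
        shannon_entropy(OrientationHistogram(np.zeros(4)))


@given(st.lists(st.integers(min_value=0, max_value=50), min_size=2,
                max_size=16).filter(lambda c: sum(c) > 0),
       st.integers(min_value=1, max_value=5))
def test_entropy_scale_and_permutation_invariant(counts, k):
    h = OrientationHistogram(np.asarray(counts, dtype=float))
    e = shannon_entropy(h)
    assert 0.0 <= e <= np.log2(len(counts)) + 1e-12
    scaled = OrientationHistogram(np.asarray(counts, dtype=float) * k)
    assert shannon_entropy(scaled) == pytest.approx(e, abs=1e-12)
    perm = OrientationHistogram(np.asarray(sorted(counts), dtype=float))
    assert shannon_entropy(perm) == pytest.approx(e, abs=1e-12)


def _uniform_field(g, rng, valid_fraction=1.0):
    shape = g.shape
    v = rng.normal(size=(*shape, 3))
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    valid = rng.uniform(size=shape) < valid_fraction
    v[~valid] = 0.0
    return OrientationField(v, valid, g)


def test_entropy_map_identical_vectors_zero():
    g = GridGeometry.isotropic((6, 6, 6), 2.0)
    v = np.broadcast_to([0.0, 0.0, 1.0], (6, 6, 6, 3)).copy()
    f = OrientationField(v, np.ones((6, 6, 6), bool), g)
    e = entropy_map(f, 3, partition_sphere(32))
    assert e.valid.all()
    assert np.all(e.values == 0.0)


def test_entropy_map_neighborhood_one_is_zero():
    g = GridGeometry.isotropic((5, 5, 5), 2.0)
    f = _uniform_field(g, np.random.default_rng(0), valid_fraction=0.7)
    e = entropy_map(f, 1, partition_sphere(32))
    assert np.array_equal(e.valid, f.valid)
    assert np.all(e.values[e.valid] == 0.0)


def test_entropy_map_uniform_orientations_near_log2_bins():
    """125 i.i.d. uniform samples per histogram: plug-in entropy slightly
    below log2(32), comfortably inside [4.5, 5.0].  Full-sphere binning
    (axial=False): uniform *directions* cover all 32 bins, whereas the
    axial default folds them onto a hemisphere of bins."""
    g = GridGeometry.isotropic((12, 12, 12), 2.0)
    f = _uniform_field(g, np.random.default_rng(4))
    e = entropy_map(f, 5, partition_sphere(32), axial=False)
    interior = e.values[2:-2, 2:-2, 2:-2]
    assert 4.5 <= interior.mean() <= 5.0


def test_entropy_map_rejects_even_neighborhood():
    g = GridGeometry.isotropic((5, 5, 5), 2.0)
    f = _uniform_field(g, np.random.default_rng(1))
    with pytest.raises(ValueError):
        entropy_map(f, 4)


def test_entropy_map_matches_brute_force():
    """Vectorized map equals an independent per-voxel loop, histogram counts
    and entropy values alike."""
    g = GridGeometry.isotropic((10, 10, 10), 2.0)
    rng = np.random.default_rng(5)
    f = _uniform_field(g, rng, valid_fraction=0.75)
    p = partition_sphere(16)
    e = entropy_map(f, 3, p)

    for _ in range(200):   # spot-check random voxels with an independent loop
        x, y, z = rng.integers(0, 10, size=3)
        gathered = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    i, j, k = x + dx, y + dy, z + dz
                    if 0 <= i < 10 and 0 <= j < 10 and 0 <= k < 10 \
                            and f.valid[i, j, k]:
                        vec = f.vectors[i, j, k].copy()
                        # independent axial flip: last nonzero coord >= 0
                        for ax in (2, 1, 0):
                            if vec[ax] != 0:
                                if vec[ax] < 0:
                                    vec = -vec
                                break
                        gathered.append(vec)
        if not gathered:
            assert not e.valid[x, y, z]
            continue
        counts = np.bincount(p.lookup(np.array(gathered)), minlength=16)
        expected = shannon_entropy(OrientationHistogram(counts.astype(float)))
        assert e.valid[x, y, z]
        assert e.values[x, y, z] == expected


def test_neighborhood_for_diameter_table_presets():
    g = GridGeometry.isotropic((10, 10, 10), 2.0)
    assert neighborhood_for_diameter(7.0, g) == 5   # trigeminal
    assert neighborhood_for_diameter(2.0, g) == 3   # lower nerves, floored
    assert neighborhood_for_diameter(10.0, g) == 5  # optic chiasma
    assert neighborhood_for_diameter(5.0, g) == 3   # oculomotor
    with pytest.raises(ValueError):
        neighborhood_for_diameter(0.0, g)


def _entropy_map_from_values(values, valid, g, n_bins=32):
    return EntropyMap(values, valid, g, n_bins)


def test_score_fibers_mean_of_visited_entropy():
    g = GridGeometry.isotropic((10, 10, 10), 2.0)
    values = np.zeros((10, 10, 10))
    values[5:] = 5.0                       # half the grid at 5 bits
    emap = _entropy_map_from_values(values, np.ones((10, 10, 10), bool), g)
    # fiber with 4 points at entropy 0 and 4 points at entropy 5
    pts = np.array([[2.0, 4, 4], [4.0, 4, 4], [6.0, 4, 4], [8.0, 4, 4],
                    [10.0, 4, 4], [12.0, 4, 4], [14.0, 4, 4], [16.0, 4, 4]])
    t = Tractogram([pts, pts.copy(), pts[:4]], g)
    s = score_fibers_entropy(t, emap)
    assert s.order == "keep_low" and s.method == "entropy"
    assert s.values[0] == pytest.approx(2.5)
    assert s.values[1] == s.values[0]      # identical geometry, identical score
    assert s.values[2] == 0.0              # constant-entropy region


def test_score_fibers_sentinel_for_unusable_fiber():
    g = GridGeometry.isotropic((10, 10, 10), 2.0)
    emap = _entropy_map_from_values(np.zeros((10, 10, 10)),
                                    np.zeros((10, 10, 10), bool), g)
    t = Tractogram([np.array([[2.0, 2, 2], [4.0, 4, 4]])], g)
    with pytest.warns(UserWarning, match="sentinel"):
        s = score_fibers_entropy(t, emap)
    assert s.values[0] == emap.max_entropy
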