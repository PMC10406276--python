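"""Synthetic streamline phantoms: a coherent nerve bundle plus controlled
contamination.

A phantom emulates the statistical structure the filtering method assumes: a
ground-truth curved bundle of known diameter (cranial-nerve presets, 2-10 mm)
sampled much finer than the 2 mm voxel grid, contaminated either by "false
continuations" (coherent fibers that leave the bundle and fan into a
neighboring structure) or by disordered fibers (locally incoherent correlated
random walks, as where brainstem fibers mingle).  Degradation suites map the
effects of bad tractography parameters -- a lowered FA cutoff or an
enlarged/translated seed region -- onto their documented consequences for the
tractogram: extra spurious fibers and bundle truncation.  No tractography is
performed.

Everything is reproducible from (spec, seed); contaminants draw from a
derived sub-seed so adding contamination never perturbs the bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_core import GridGeometry, ScalarVolume, Tractogram, voxel_to_world, world_to_voxel

#: estimated cisternal diameters (mm) of the studied cranial nerves
NERVE_DIAMETERS_MM = {
    "Chiasma": 10.0,  # optic
    "III": 5.0,       # oculomotor
    "V": 7.0,         # trigeminal
    "AFB": 3.0,       # acoustic-facial bundle
    "LN": 2.0,        # lower nerves
}


def default_grid() -> GridGeometry:
    """40^3 voxels at 2 mm isotropic: the acquisition scale, desk-sized."""
    return GridGeometry.isotropic((40, 40, 40), 2.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a coherent fiber bundle around a parametric centerline."""

    centerline: str = "arc"            # straight | arc | helix
    diameter_mm: float = 7.0
    length_mm: float = 60.0
    curve_radius_mm: float = 60.0      # arc / helix radius
    pitch_mm: float = 20.0             # helix only
    n_fibers: int = 200
    step_mm: float = 0.1               # fiber sampling step (<< voxel size)
    jitter_mm: float = 0.2             # per-point Gaussian dispersion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.centerline not in ("straight", "arc", "helix"):
            raise ValueError(f"unknown centerline {self.centerline!r}")
        if self.diameter_mm <= 0 or self.length_mm <= 0 or self.step_mm <= 0:
            raise ValueError("diameter, length and step must be positive")
        if self.jitter_mm < 0 or self.n_fibers < 1:
            raise ValueError("jitter must be >= 0 and n_fibers >= 1")


def preset(nerve: str, n_fibers: int = 200, seed: int = 0, **kwargs) -> PhantomSpec:
    """Phantom spec for a named cranial nerve (diameter from the presets)."""
    return PhantomSpec(diameter_mm=NERVE_DIAMETERS_MM[nerve],
                       n_fibers=n_fibers, seed=seed, **kwargs)


def _grid_center(g: GridGeometry) -> np.ndarray:
    return voxel_to_world((np.asarray(g.shape) - 1) / 2.0, g)[0]


def bundle_centerline(spec: PhantomSpec, g: GridGeometry) -> np.ndarray:
    """Centerline points at ``step_mm`` spacing, centered in the grid."""
    n_pts = int(round(spec.length_mm / spec.step_mm)) + 1
    s = np.arange(n_pts) * spec.step_mm - spec.length_mm / 2.0
    c = _grid_center(g)
    if spec.centerline == "straight":
        pts = c + np.outer(s, [1.0, 0.0, 0.0])
    elif spec.centerline == "arc":
        r = spec.curve_radius_mm
        theta = s / r
        pts = c + np.stack([r * np.sin(theta), -r * (1 - np.cos(theta)),
                            np.zeros_like(theta)], axis=1)
    else:  # helix
        r = spec.curve_radius_mm
        k = spec.pitch_mm / (2 * np.pi)
        theta = s / np.sqrt(r * r + k * k)
        pts = c + np.stack([r * np.sin(theta), -r * (1 - np.cos(theta)),
                            k * theta], axis=1)
    return pts


def _parallel_transport_frame(points: np.ndarray):
    """Tangent / normal / binormal frame along a polyline (twist-free)."""
    t = np.gradient(points, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    n0 = np.cross(t[0], [0.0, 0.0, 1.0])
    if np.linalg.norm(n0) < 1e-8:
        n0 = np.cross(t[0], [0.0, 1.0, 0.0])
    n0 /= np.linalg.norm(n0)
    n = np.empty_like(t)
    n[0] = n0
    for i in range(1, len(t)):
        v = n[i - 1] - np.dot(n[i - 1], t[i]) * t[i]
        norm = np.linalg.norm(v)
        n[i] = v / norm if norm > 1e-12 else n[i - 1]
    b = np.cross(t, n)
    return t, n, b


def _check_fits(points: np.ndarray, g: GridGeometry, margin_mm: float) -> None:
    idx = world_to_voxel(points, g)
    margin_vox = margin_mm / g.voxel_size
    lo = idx.min(axis=0) - margin_vox
    hi = idx.max(axis=0) + margin_vox
    if np.any(lo < -0.5) or np.any(hi > np.asarray(g.shape) - 0.5):
        raise ValueError("centerline (plus bundle radius) exceeds the grid")


def _bundle_fibers(rng, center_pts, frame, radius_scale, diameter_mm,
                   jitter_mm, n_fibers):
    """Copies of a centerline offset by in-disk displacements carried along
    a parallel-transport frame, with optional radius growth and jitter."""
    _, n, b = frame
    fibers = []
    for _ in range(n_fibers):
        r = (diameter_mm / 2.0) * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        offset = (r * np.cos(phi)) * n + (r * np.sin(phi)) * b
        pts = center_pts + radius_scale[:, None] * offset
        if jitter_mm > 0:
            pts = pts + rng.normal(0.0, jitter_mm, pts.shape)
        fibers.append(pts)
    return fibers


def make_bundle(spec: PhantomSpec, g: GridGeometry | None = None
                ) -> tuple[Tractogram, np.ndarray]:
    """Generate the ground-truth bundle; returns (tractogram, true ids)."""
    if g is None:
        g = default_grid()
    center = bundle_centerline(spec, g)
    _check_fits(center, g, spec.diameter_mm / 2.0 + 3 * spec.jitter_mm)
    frame = _parallel_transport_frame(center)
    rng = np.random.default_rng(spec.seed)
    ones = np.ones(len(center))
    fibers = _bundle_fibers(rng, center, frame, ones, spec.diameter_mm,
                            spec.jitter_mm, spec.n_fibers)
    t = Tractogram(fibers, g)
    return t, t.ids.copy()


def straight_tube(g: GridGeometry | None = None, diameter_mm: float = 7.0,
                  n_fibers: int = 200, jitter_mm: float = 0.2, seed: int = 0
                  ) -> tuple[Tractogram, np.ndarray]:
    """A straight bundle spanning the whole grid along the first axis.

    Unlike :func:`make_bundle` the fibers run border to border, so no bundle
    termination (end cap) lies inside the volume -- the cylinder
    idealization used to characterize the tangent-field estimator, whose
    cross-product reorientation is only defined against fiber walls, not
    terminations.  Returns (tractogram, centerline axis point (y, z) in mm).
    """
    if g is None:
        g = default_grid()
    rng = np.random.default_rng(seed)
    lo = voxel_to_world([-0.5, 0, 0], g)[0]
    hi = voxel_to_world([g.shape[0] - 0.5, 0, 0], g)[0]
    step = 0.1
    n_pts = int(round((hi[0] - lo[0]) / step)) + 1
    x = np.linspace(lo[0], hi[0], n_pts)
    yz = _grid_center(g)[1:]
    fibers = []
    for _ in range(n_fibers):
        r = (diameter_mm / 2.0) * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        pts = np.stack([x,
                        np.full(n_pts, yz[0] + r * np.cos(phi)),
                        np.full(n_pts, yz[1] + r * np.sin(phi))], axis=1)
        if jitter_mm > 0:
            pts = pts + rng.normal(0.0, jitter_mm, pts.shape)
        fibers.append(pts)
    return Tractogram(fibers, g), yz


@dataclass(frozen=True)
class ContaminationSpec:
    """Recipe for appending spurious fibers to a bundle phantom.

    ``false_continuation`` fibers share the bundle's trunk up to
    ``branch_fraction`` of its length, then veer off by ``branch_angle_deg``
    and fan out (spread grows by ``fan_factor``) into a neighboring
    structure.  ``disordered`` fibers are correlated random walks with the
    given directional ``persistence`` (< 1; 0 = isotropic) confined to a
    spherical region beside the bundle.
    """

    kind: str                          # false_continuation | disordered
    n_fibers: int
    bundle: PhantomSpec
    branch_fraction: float = 0.5
    branch_angle_deg: float = 60.0
    branch_ramp_mm: float = 10.0
    fan_factor: float = 3.0
    persistence: float = 0.9
    region_radius_mm: float = 15.0
    region_offset_mm: tuple[float, float, float] = (0.0, 10.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("false_continuation", "disordered"):
            raise ValueError(f"unknown contamination kind {self.kind!r}")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must lie in [0, 1)")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (v * np.cos(angle) + np.cross(axis, v) * np.sin(angle)
            + axis * np.dot(axis, v) * (1 - np.cos(angle)))


def _branch_centerline(c: ContaminationSpec, g: GridGeometry):
    """Branch curve: bundle trunk, then a ramped turn away from it."""
    spec = c.bundle
    center = bundle_centerline(spec, g)
    t, n, b = _parallel_transport_frame(center)
    j = int(np.floor(c.branch_fraction * (len(center) - 1)))
    n_ramp = max(1, int(round(c.branch_ramp_mm / spec.step_mm)))
    angle = np.deg2rad(c.branch_angle_deg)
    pts = [center[: j + 1]]
    pos = center[j].copy()
    out = []
    for k in range(1, len(center) - j):
        a = angle * min(1.0, k / n_ramp)
        d = _rotate(t[j], b[j], a)
        pos = pos + spec.step_mm * d
        out.append(pos.copy())
    branch = np.concatenate([pts[0], np.asarray(out)]) if out else pts[0]
    # spread growth: 1 on the trunk, ramping to fan_factor at the far end
    scale = np.ones(len(branch))
    tail = len(branch) - (j + 1)
    if tail > 0:
        scale[j + 1:] = 1.0 + (c.fan_factor - 1.0) * np.arange(1, tail + 1) / tail
    return branch, scale


def _disordered_fibers(rng, c: ContaminationSpec, g: GridGeometry):
    spec = c.bundle
    center = _grid_center(g) + np.asarray(c.region_offset_mm)
    n_steps = int(round(spec.length_mm / spec.step_mm))
    fibers = []
    for _ in range(c.n_fibers):
        u = rng.normal(size=3)
        start = center + (c.region_radius_mm * 0.5 * rng.uniform() ** (1 / 3)
                          ) * u / np.linalg.norm(u)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts = np.empty((n_steps + 1, 3))
        pts[0] = start
        pos = start.copy()
        for k in range(n_steps):
            noise = rng.normal(size=3)
            noise /= np.linalg.norm(noise)
            d = c.persistence * d + (1.0 - c.persistence) * noise
            d /= np.linalg.norm(d)
            nxt = pos + spec.step_mm * d
            off = nxt - center
            if np.linalg.norm(off) > c.region_radius_mm:   # reflect at the wall
                nrm = off / np.linalg.norm(off)
                d = d - 2 * np.dot(d, nrm) * nrm
                nxt = pos + spec.step_mm * d
            pos = nxt
            pts[k + 1] = pos
        fibers.append(pts)
    return fibers


def add_contamination(t: Tractogram, c: ContaminationSpec, seed: int
                      ) -> tuple[Tractogram, np.ndarray]:
    """Append contaminant fibers; returns (tractogram, contaminant ids).

    Ids of the incoming fibers are preserved; contaminants get fresh ids
    after the current maximum.
    """
    if c.n_fibers == 0:
        return t, np.array([], dtype=int)
    g = t.geometry
    rng = np.random.default_rng(seed)
    if c.kind == "disordered":
        fibers = _disordered_fibers(rng, c, g)
    else:
        branch, scale = _branch_centerline(c, g)
        frame = _parallel_transport_frame(branch)
        fibers = _bundle_fibers(rng, branch, frame, scale,
                                c.bundle.diameter_mm, c.bundle.jitter_mm,
                                c.n_fibers)
    start = int(t.ids.max()) + 1 if len(t) else 0
    new_ids = np.arange(start, start + c.n_fibers)
    return (Tractogram(list(t.streamlines) + fibers, g,
                       np.concatenate([t.ids, new_ids])), new_ids)


def synthetic_fa_volume(t: Tractogram, g: GridGeometry | None = None,
                        seed: int = 0, smooth_vox: float = 1.0,
                        noise_sigma: float = 0.05) -> ScalarVolume:
    """Synthetic FA-like map for phantom experiments (no dMRI involved).

    Emulates what makes FA filtering punctual: FA is high wherever fibrous
    tissue is dense, regardless of whether the local orientations are
    coherent.  Built as a smoothed, normalized fiber-occupancy map rescaled
    to a white-matter-like range (~0.15 background, ~0.8 core) plus smooth
    Gaussian noise.  Labelled synthetic; stands in for a tensor-derived FA
    map, which needs raw dMRI.
    """
    from .field import rasterize_density
    if g is None:
        g = t.geometry
    density = rasterize_density(t, g).values
    occ = gaussian_filter((density > 0).astype(float), smooth_vox)
    m = occ.max()
    if m > 0:
        occ = occ / m
    rng = np.random.default_rng(seed)
    noise = gaussian_filter(rng.normal(0.0, 1.0, g.shape), smooth_vox)
    sd = noise.std()
    if sd > 0:
        noise = noise / sd * noise_sigma
    fa = np.clip(0.15 + 0.65 * occ + noise, 0.0, 1.0)
    return ScalarVolume(fa, g, unit="unitless")


@dataclass
class DegradationCase:
    """One (ground truth, degraded) pair with per-fiber truth labels."""

    kind: str
    level: int
    gt: Tractogram
    degraded: Tractogram
    true_ids: np.ndarray
    contaminant_ids: np.ndarray

    @property
    def labels(self) -> dict[int, str]:
        cont = set(int(i) for i in self.contaminant_ids)
        return {int(i): ("contaminant" if int(i) in cont else "true")
                for i in self.degraded.ids}


def _truncate_bundle(t: Tractogram, spec: PhantomSpec, g: GridGeometry,
                     fraction: float, shift_mm: np.ndarray) -> Tractogram:
    """Drop the fraction of fibers whose start points lie farthest from a
    shifted virtual seed region (the translated-ROI effect)."""
    seed_point = bundle_centerline(spec, g)[0] + shift_mm
    starts = np.array([s[0] for s in t.streamlines])
    dist = np.linalg.norm(starts - seed_point, axis=1)
    n_drop = int(round(fraction * len(t)))
    if n_drop == 0:
        return t
    order = np.argsort(dist)          # keep the closest
    keep = np.sort(t.ids[order[: len(t) - n_drop]])
    return t.subset(keep)


def make_degradation_suite(base: PhantomSpec,
                           levels: list[tuple[str, int]] | None = None,
                           g: GridGeometry | None = None,
                           ) -> list[DegradationCase]:
    """Phantom pairs emulating the non-optimal tractography datasets.

    Each level maps a tractography-parameter change onto its documented
    effect on the tractogram:

    * ``("optimal", 0)`` -- the degraded tractogram is the same bundle
      regenerated with a new seed (residual stochastic variability only);
    * ``("fa_threshold", k)`` -- a lowered FA cutoff lets tracking wander
      into incoherent tissue: k-proportional disordered contamination;
    * ``("roi_size", k)`` -- an enlarged seed region recruits a neighboring
      structure: k-proportional false-continuation contamination;
    * ``("roi_translation", k)`` -- a shifted seed region both truncates the
      bundle (k-proportional, shift of k*D/5) and adds spurious fibers.
    """
    if g is None:
        g = default_grid()
    if levels is None:
        levels = ([("optimal", 0)]
                  + [("fa_threshold", k) for k in (1, 2, 3)]
                  + [("roi_size", k) for k in (1, 2, 3)]
                  + [("roi_translation", k) for k in (1, 2)])
    gt, _ = make_bundle(base, g)
    cases = []
    for kind, level in levels:
        kind_tag = sum(ord(ch) for ch in kind)   # stable across processes
        sub = int(np.random.default_rng([base.seed, kind_tag,
                                         level]).integers(2 ** 31))
        degraded, _ = make_bundle(replace(base, seed=sub), g)
        true_ids = degraded.ids.copy()
        cont_ids = np.array([], dtype=int)
        if kind == "optimal" or level == 0:
            pass
        elif kind == "fa_threshold":
            c = ContaminationSpec("disordered", level * base.n_fibers // 2, base)
            degraded, cont_ids = add_contamination(degraded, c, sub + 1)
        elif kind == "roi_size":
            c = ContaminationSpec("false_continuation",
                                  level * base.n_fibers // 2, base)
            degraded, cont_ids = add_contamination(degraded, c, sub + 1)
        elif kind == "roi_translation":
            shift = np.array([0.0, level * base.diameter_mm / 5.0, 0.0])
            degraded = _truncate_bundle(degraded, base, g, 0.15 * level, shift)
            true_ids = degraded.ids.copy()
            c = ContaminationSpec("disordered", level * base.n_fibers // 4, base)
            degraded, cont_ids = add_contamination(degraded, c, sub + 1)
        else:
            raise ValueError(f"unknown degradation kind {kind!r}")
        cases.append(DegradationCase(kind, level, gt, degraded,
                                     true_ids, cont_ids))
    return cases


def benchmark_phantom(kind: str, seed: int, nerve: str = "V",
                      n_true: int = 200, n_contaminant: int = 100,
                      g: GridGeometry | None = None):
    """The standard benchmark pair: a V-nerve bundle (200 fibers) as ground
    truth plus a degraded copy carrying 100 contaminants of ``kind``.

    Returns (gt, degraded, true_ids, contaminant_ids).  The ground truth and
    the degraded bundle use different sub-seeds, emulating the stochastic
    variability of probabilistic tracking.
    """
    if g is None:
        g = default_grid()
    rng = np.random.default_rng(seed)
    s_gt, s_deg, s_cont = rng.integers(2 ** 31, size=3)
    base = preset(nerve, n_fibers=n_true, seed=int(s_gt))
    gt, _ = make_bundle(base, g)
    degraded, _ = make_bundle(replace(base, seed=int(s_deg)), g)
    true_ids = degraded.ids.copy()
    c = ContaminationSpec(kind, n_contaminant, base)
    degraded, cont_ids = add_contamination(degraded, c, int(s_cont))
    return gt, degraded, true_ids, cont_ids
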