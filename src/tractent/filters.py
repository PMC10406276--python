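"""Turn per-fiber scores into filtered tractograms.

Three score sources share one filtering path: the entropy score (keep the
least entropic fibers), the fractional-anisotropy baseline (mean FA along
the fiber by trilinear interpolation, keep the highest), and externally
computed per-fiber weights such as SIFT2's, imported from TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .entropy import FiberScores
from .io_core import ScalarVolume, Tractogram, world_to_voxel


def half_up(x: float) -> int:
    """Round half away from zero for non-negative x (e.g. 2.5 -> 3)."""
    return int(np.floor(x + 0.5))


def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy from the diffusion-tensor eigenvalues.

    ``FA = sqrt(1/2) * sqrt(((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2)
    / (l1^2 + l2^2 + l3^2))``; ranges from 0 (isotropic) to 1, and is
    invariant under scaling of the eigenvalues.  Accepts scalars or arrays.
    """
    l1, l2, l3 = (np.asarray(v, dtype=float) for v in (l1, l2, l3))
    if np.any(~np.isfinite(l1) | ~np.isfinite(l2) | ~np.isfinite(l3)):
        raise ValueError("eigenvalues must be finite")
    if np.any((l1 < 0) | (l2 < 0) | (l3 < 0)):
        raise ValueError("eigenvalues must be non-negative")
    denom = l1 ** 2 + l2 ** 2 + l3 ** 2
    if np.any(denom == 0):
        raise ValueError("FA is undefined for all-zero eigenvalues")
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    out = np.sqrt(0.5 * num / denom)
    return float(out) if out.ndim == 0 else out


def mean_along_fiber(v: ScalarVolume, s: np.ndarray) -> float:
    """Mean of trilinear interpolations of a volume at every fiber point.

    Points outside the grid (beyond the outermost voxel centers) are
    skipped rather than zero-filled, so border-hugging fibers are not
    biased low.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] < 2:
        raise ValueError("fiber needs >= 2 points")
    idx = world_to_voxel(s, v.geometry)
    upper = np.asarray(v.geometry.shape) - 1
    inside = np.all((idx >= 0) & (idx <= upper), axis=1)
    if not inside.any():
        raise ValueError("all fiber points lie outside the grid")
    vals = map_coordinates(v.values, idx[inside].T, order=1, mode="nearest")
    return float(vals.mean())


def score_fibers_fa(t: Tractogram, fa: ScalarVolume) -> FiberScores:
    """Mean-FA score per fiber; high FA is kept first (keep_high)."""
    values = np.array([mean_along_fiber(fa, s) for s in t.streamlines])
    return FiberScores(t.ids.copy(), values, order="keep_high", method="fa")


def import_external_scores(path, t: Tractogram, order: str = "keep_low") -> FiberScores:
    """Bind externally computed per-fiber weights (TSV) to a tractogram.

    The TSV needs columns ``fiber_id`` and ``score`` (or two unnamed
    columns in that order) with exactly one finite value per fiber id of
    ``t``.  SIFT2 weights use the default keep_low filtering rank.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if "fiber_id" not in df.columns or "score" not in df.columns:
        if df.shape[1] == 2:
            df.columns = ["fiber_id", "score"]
        else:
            raise ValueError(f"{path}: expected columns fiber_id, score")
    try:
        ids = df["fiber_id"].astype(int).to_numpy()
        values = df["score"].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        bad = df[pd.to_numeric(df["score"], errors="coerce").isna()]
        line = int(bad.index[0]) + 2 if len(bad) else "?"
        raise ValueError(f"{path}: non-numeric score at line {line}") from exc
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite score values")
    lookup = dict(zip(ids, values))
    missing = [int(i) for i in t.ids if int(i) not in lookup]
    if missing:
        raise ValueError(f"{path}: no score for fiber id(s) {missing[:5]}")
    if len(lookup) != len(t.ids):
        extra = sorted(set(lookup) - set(int(i) for i in t.ids))
        raise ValueError(f"{path}: scores for unknown fiber id(s) {extra[:5]}")
    ordered = np.array([lookup[int(i)] for i in t.ids])
    return FiberScores(t.ids.copy(), ordered, order=order, method="external")


def normalize_scores(scores: FiberScores) -> FiberScores:
    """Min-max rescale scores to [0, 1] (per-dataset threshold normalization).

    Rank order is preserved, so filtering by fraction is unaffected; only the
    threshold scale changes.
    """
    lo, hi = scores.values.min(), scores.values.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize constant scores")
    return FiberScores(scores.ids.copy(), (scores.values - lo) / (hi - lo),
                       scores.order, scores.method)


@dataclass
class FilterResult:
    """Outcome of keeping a fraction of fibers by score rank."""

    kept_ids: np.ndarray
    removed_ids: np.ndarray
    keep_fraction: float
    threshold: float          # score of the last kept fiber (nan if none)
    method: str
    order: str

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)


def filter_by_fraction(t: Tractogram, scores: FiberScores,
                       keep_fraction: float) -> FilterResult:
    """Keep the best-scoring ``round(keep_fraction * N)`` fibers.

    ``keep_low`` sorts ascending (entropy, SIFT2); ``keep_high`` descending
    (FA).  Ties break by ascending fiber id; rounding is half-up.
    """
    if not 0.0 <= keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in [0, 1]")
    if len(scores.ids) != len(t.ids) or not np.array_equal(
            np.sort(scores.ids), t.ids):
        raise ValueError("scores do not cover the tractogram's fiber ids")
    n = len(t)
    n_keep = half_up(keep_fraction * n)
    key = scores.values if scores.order == "keep_low" else -scores.values
    rank = np.lexsort((scores.ids, key))       # stable: ties by ascending id
    kept = np.sort(scores.ids[rank[:n_keep]])
    removed = np.sort(scores.ids[rank[n_keep:]])
    threshold = float(scores.values[rank[n_keep - 1]]) if n_keep else float("nan")
    return FilterResult(kept, removed, keep_fraction, threshold,
                        scores.method, scores.order)


def apply_filter(t: Tractogram, result: FilterResult) -> Tractogram:
    """Materialize a filter result as a new tractogram (ids retained)."""
    return t.subset(result.kept_ids)
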