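"""Corticostriatal configuration profiles (CSCPs) and their divergence metrics.

A CSCP is, per striatal voxel, the vector of Fisher-z connectivity values
with a set of cortical ROIs.  Three per-voxel scalars quantify how a profile
diverges between two conditions (typically drug vs placebo):

* **AD** (aggregate divergence): sum over ROIs of |Δz| — absolute change in
  connectivity magnitude.
* **ROR** (rank-order rearrangement): sum over ROIs of the absolute change in
  the ROI's connectivity-strength rank (rank 1 = strongest) — change in
  *relative* connectivity.
* **ES** (entropy shift): absolute change in the Shannon entropy of the
  |z|-normalized profile — change in how concentrated the profile is.

The within-session placebo null compares the first and second halves of the
placebo run through the same machinery.  Voxelwise paired tests localize
drug effects into contiguous striatal nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sstats

from .timeseries_io import RoiTimeseries, VoxelTimeseries

log = logging.getLogger(__name__)

_R_CLIP = 1.0 - 1e-7
_ES_EPS = 1e-12


@dataclass
class ProfileMatrix:
    """Voxels × cortical-ROIs Fisher-z connectivity for one run/condition."""

    z_values: np.ndarray
    voxel_coords: np.ndarray
    roi_names: tuple[str, ...]
    condition: str = ""

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        if self.z_values.shape[0] != self.voxel_coords.shape[0]:
            raise ValueError("one coordinate triplet per profile row required")
        if len(self.roi_names) != self.z_values.shape[1]:
            raise ValueError("one ROI name per profile column required")

    @property
    def n_voxels(self) -> int:
        return self.z_values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.z_values.shape[1]


@dataclass
class CSCPMap:
    """Per-voxel divergence scalar for one subject and condition pair."""

    metric: str  # "AD" | "ROR" | "ES"
    values: np.ndarray
    voxel_coords: np.ndarray
    condition_pair: str = ""
    subject: str = ""


@dataclass
class StriatalNode:
    """One contiguous cluster of voxels surviving the voxelwise test."""

    voxel_indices: np.ndarray
    coords: np.ndarray
    size: int
    peak_t: float
    peak_coord: tuple[int, int, int]
    label: str = ""


@dataclass
class NodeSet:
    nodes: list[StriatalNode] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def connectivity_profile(
    striatal: VoxelTimeseries, cortical: RoiTimeseries, condition: str = ""
) -> ProfileMatrix:
    """Fisher-z Pearson connectivity between every striatal voxel and cortical ROI.

    r is clipped to |r| <= 1 - 1e-7 before atanh so noise-free identical
    series yield a large finite z rather than infinity.  Zero-variance voxel
    or ROI columns are flagged and their entries set to NaN (excluded
    downstream).
    """
    if striatal.n_frames != cortical.n_frames:
        raise ValueError("striatal and cortical series must share frame count")
    if striatal.n_frames < 10:
        raise ValueError("need at least 10 frames for a connectivity profile")
    x = striatal.values - striatal.values.mean(axis=0)
    y = cortical.values - cortical.values.mean(axis=0)
    sx = np.linalg.norm(x, axis=0)
    sy = np.linalg.norm(y, axis=0)
    bad_v, bad_r = sx == 0, sy == 0
    if bad_v.any() or bad_r.any():
        log.warning(
            "zero-variance columns: %d voxel(s), %d ROI(s); entries set to NaN",
            int(bad_v.sum()), int(bad_r.sum()),
        )
    sx[bad_v] = 1.0
    sy[bad_r] = 1.0
    r = (x / sx).T @ (y / sy)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    z[bad_v, :] = np.nan
    z[:, bad_r] = np.nan
    return ProfileMatrix(z, striatal.voxel_coords, cortical.roi_names, condition)


def split_half_profiles(
    striatal: VoxelTimeseries, cortical: RoiTimeseries
) -> tuple[ProfileMatrix, ProfileMatrix]:
    """Within-session null: profiles from the first ⌊N/2⌋ and remaining frames."""
    n = striatal.n_frames
    if n < 20:
        raise ValueError("need at least 20 frames to split")
    half = n // 2

    def cut(vals, lo, hi):
        return vals[lo:hi]

    s1 = VoxelTimeseries(cut(striatal.values, 0, half), striatal.voxel_coords,
                         striatal.tr_seconds)
    s2 = VoxelTimeseries(cut(striatal.values, half, n), striatal.voxel_coords,
                         striatal.tr_seconds)
    c1 = RoiTimeseries(cut(cortical.values, 0, half), cortical.roi_names,
                       cortical.tr_seconds)
    c2 = RoiTimeseries(cut(cortical.values, half, n), cortical.roi_names,
                       cortical.tr_seconds)
    return (
        connectivity_profile(s1, c1, "PBO_firsthalf"),
        connectivity_profile(s2, c2, "PBO_secondhalf"),
    )


def _check_matched(p_a: ProfileMatrix, p_b: ProfileMatrix) -> None:
    if p_a.z_values.shape != p_b.z_values.shape:
        raise ValueError(
            f"profile shapes differ: {p_a.z_values.shape} vs {p_b.z_values.shape}"
        )
    if p_a.roi_names != p_b.roi_names:
        raise ValueError("profiles must share ROI ordering")
    if not np.array_equal(p_a.voxel_coords, p_b.voxel_coords):
        raise ValueError("profiles must share voxel coordinates")


def _pair_name(p_a: ProfileMatrix, p_b: ProfileMatrix) -> str:
    if p_a.condition or p_b.condition:
        return f"{p_a.condition}-{p_b.condition}"
    return ""


# ---------------------------------------------------------------------------
# divergence metrics
# ---------------------------------------------------------------------------

def aggregate_divergence(p_a: ProfileMatrix, p_b: ProfileMatrix) -> CSCPMap:
    """AD(v) = Σ_roi |z_a(v, roi) − z_b(v, roi)|."""
    _check_matched(p_a, p_b)
    vals = np.nansum(np.abs(p_a.z_values - p_b.z_values), axis=1)
    vals[np.all(np.isnan(p_a.z_values) | np.isnan(p_b.z_values), axis=1)] = np.nan
    return CSCPMap("AD", vals, p_a.voxel_coords, _pair_name(p_a, p_b))


def profile_ranks(z: np.ndarray) -> np.ndarray:
    """Ordinal ranks per voxel row, rank 1 = most positive z, ties broken by
    ROI order (stable sort)."""
    z = np.asarray(z, dtype=float)
    order = np.argsort(-z, axis=1, kind="stable")
    ranks = np.empty_like(order)
    cols = np.arange(1, z.shape[1] + 1)
    rows = np.arange(z.shape[0])[:, None]
    ranks[rows, order] = cols
    return ranks


def rank_order_rearrangement(p_a: ProfileMatrix, p_b: ProfileMatrix) -> CSCPMap:
    """ROR(v) = Σ_roi |rank_a(v, roi) − rank_b(v, roi)| (rank 1 = strongest)."""
    _check_matched(p_a, p_b)
    ra = profile_ranks(p_a.z_values)
    rb = profile_ranks(p_b.z_values)
    vals = np.abs(ra - rb).sum(axis=1).astype(float)
    nan_rows = np.isnan(p_a.z_values).any(axis=1) | np.isnan(p_b.z_values).any(axis=1)
    vals[nan_rows] = np.nan
    return CSCPMap("ROR", vals, p_a.voxel_coords, _pair_name(p_a, p_b))


def profile_entropy(z_row: np.ndarray) -> float:
    """Shannon entropy (nats) of the |z|-normalized profile with an ε floor.

    An all-zero profile degrades gracefully to the maximum-entropy value ln K
    through the floor.
    """
    w = np.abs(np.asarray(z_row, dtype=float)) + _ES_EPS
    q = w / w.sum()
    return float(-(q * np.log(q)).sum())


def entropy_shift(p_a: ProfileMatrix, p_b: ProfileMatrix) -> CSCPMap:
    """ES(v) = |H_a(v) − H_b(v)|, entropies of the |z|-normalized profiles."""
    _check_matched(p_a, p_b)
    n = p_a.n_voxels
    vals = np.empty(n)
    for v in range(n):
        za, zb = p_a.z_values[v], p_b.z_values[v]
        if np.isnan(za).any() or np.isnan(zb).any():
            vals[v] = np.nan
            continue
        vals[v] = abs(profile_entropy(za) - profile_entropy(zb))
    return CSCPMap("ES", vals, p_a.voxel_coords, _pair_name(p_a, p_b))


METRIC_FUNCS = {
    "AD": aggregate_divergence,
    "ROR": rank_order_rearrangement,
    "ES": entropy_shift,
}


def subject_cscp_score(
    cmap: CSCPMap, voxel_subset: np.ndarray | None = None
) -> float:
    """Mean of the per-voxel metric over the whole striatum or a voxel subset.

    ``voxel_subset`` is a list of (i, j, k) coordinates; NaN voxels are
    skipped.
    """
    vals = cmap.values
    if voxel_subset is not None:
        subset = {tuple(c) for c in np.asarray(voxel_subset, dtype=int)}
        mask = np.array([tuple(c) in subset for c in cmap.voxel_coords])
        if not mask.any():
            raise ValueError("voxel subset does not intersect the map")
        vals = vals[mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined voxels to average")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# localization
# ---------------------------------------------------------------------------

def voxelwise_paired_test(
    maps_a: list[CSCPMap],
    maps_b: list[CSCPMap],
    p_threshold: float = 0.001,
    min_extent: int = 10,
) -> NodeSet:
    """Per-voxel paired t across subjects (one-sided, a > b), clustered.

    Voxels with p < ``p_threshold`` are grouped by 6-connectivity on the voxel
    grid; clusters smaller than ``min_extent`` are discarded; the surviving
    nodes are returned sorted by size (largest first).
    """
    if len(maps_a) != len(maps_b) or len(maps_a) < 3:
        raise ValueError("need matched per-subject maps from at least 3 subjects")
    coords = maps_a[0].voxel_coords
    for m in maps_a + maps_b:
        if not np.array_equal(m.voxel_coords, coords):
            raise ValueError("all maps must share the voxel grid")
    a = np.vstack([m.values for m in maps_a])
    b = np.vstack([m.values for m in maps_b])
    diff = a - b
    n = diff.shape[0]
    mean = np.nanmean(diff, axis=0)
    sd = np.nanstd(diff, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = sstats.t.sf(t, df=n - 1)  # one-sided a > b
    sig = np.where(np.isnan(p), False, p < p_threshold)

    # scatter significance onto the 3-D grid for contiguity labeling
    dims = coords.max(axis=0) + 1
    grid = np.zeros(dims, dtype=bool)
    grid[coords[:, 0], coords[:, 1], coords[:, 2]] = sig
    labeled, n_clusters = ndimage.label(grid)  # default structure = 6-connectivity
    cluster_id = labeled[coords[:, 0], coords[:, 1], coords[:, 2]]

    nodes = []
    for cid in range(1, n_clusters + 1):
        idx = np.where(cluster_id == cid)[0]
        if idx.size < min_extent:
            continue
        peak = idx[np.nanargmax(t[idx])]
        nodes.append(StriatalNode(
            voxel_indices=idx,
            coords=coords[idx],
            size=int(idx.size),
            peak_t=float(t[peak]),
            peak_coord=tuple(int(c) for c in coords[peak]),
        ))
    nodes.sort(key=lambda nd: nd.size, reverse=True)
    return NodeSet(nodes)


def rank_shift_summary(
    node: StriatalNode,
    p_a: ProfileMatrix,
    p_b: ProfileMatrix,
    min_shift: float = 5,
) -> pd.DataFrame:
    """Mean signed rank change per cortical ROI over a node's voxels.

    The shift is rank_b − rank_a, so a positive value means the ROI's
    connectivity climbed in rank (became relatively stronger) under
    condition a.  Rows with |mean shift| >= ``min_shift`` are returned,
    sorted by magnitude.
    """
    _check_matched(p_a, p_b)
    ra = profile_ranks(p_a.z_values)[node.voxel_indices]
    rb = profile_ranks(p_b.z_values)[node.voxel_indices]
    mean_shift = (rb - ra).mean(axis=0)
    df = pd.DataFrame({"roi": p_a.roi_names, "mean_rank_shift": mean_shift})
    df = df[df["mean_rank_shift"].abs() >= min_shift]
    return df.reindex(
        df["mean_rank_shift"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
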