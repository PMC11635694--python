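"""Synthetic multi-subject, three-condition cohorts with planted ground truth.

The generator emulates the structure of a within-subject pharmacological
resting-state study: each subject is scanned under placebo (PBO), a
methylphenidate-like drug (MPH) and a haloperidol-like drug (HAL).  A run is
built in three layers:

1. a first-order Markov chain over ``n_states`` transient network states,
   with a condition-specific transition matrix (drugs alter the entry
   probabilities into particular states while leaving within-state
   persistence untouched);
2. ROI frames equal to the active state's centroid map plus i.i.d. Gaussian
   noise (optionally AR(1) in time);
3. striatal voxel time courses formed as fixed weighted mixtures of the
   cortical ROI time courses plus noise — a drug may permute the weight
   vector of a subset of voxels, planting a known rank-order rearrangement.

Everything is driven by a single seed; the planted transition matrices,
stationary occupancies, weight profiles and permutations are returned as a
:class:`GroundTruth` ledger for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries_io import (
    CentroidSet,
    RoiTimeseries,
    VoxelTimeseries,
    write_roi_timeseries,
    write_voxel_timeseries,
    read_roi_timeseries,
    read_voxel_timeseries,
)
from .cap_dynamics import StateLabelSequence

CONDITIONS = ("PBO", "MPH", "HAL")

# Entry-probability multipliers defining the simulated drug effects, applied
# to the off-diagonal transition probabilities into the named states (diagonal
# persistence untouched, so drugs alter transitions, not persistence).  The
# MPH DMN/DAN boost is calibrated so the paired effect on total time in state
# is d ~ 0.7 at n = 59 subjects and 235 frames; see docs/methods.md.
MPH_ENTRY_BOOSTS = {"DMN": 1.55, "DAN": 1.50, "FPN": 0.80}
HAL_ENTRY_BOOSTS = {"SM-DMN": 1.35}

#: Demographics of the emulated sample: age ~ Normal(39.32, 11.25) truncated
#: to [18, 55]; sex ratio 17 male : 42 female.
AGE_MEAN, AGE_SD, AGE_RANGE = 39.32, 11.25, (18.0, 55.0)
P_MALE = 17 / 59


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def validate_transition_matrix(p: np.ndarray, name: str = "transition matrix") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError(f"{name} must be square, got shape {p.shape}")
    if np.any(p < 0):
        raise ValueError(f"{name} has negative entries")
    bad = np.where(np.abs(p.sum(axis=1) - 1.0) > 1e-12)[0]
    if bad.size:
        raise ValueError(
            f"{name}: row {bad[0]} sums to {p[bad[0]].sum():.15g}, expected 1"
        )
    return p


def stationary_distribution(p: np.ndarray) -> np.ndarray:
    """Stationary occupancy of an ergodic chain (left eigenvector for eigenvalue 1)."""
    p = validate_transition_matrix(p)
    w, v = np.linalg.eig(p.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def baseline_transition_matrix(n_states: int = 8, stay: float = 0.6) -> np.ndarray:
    """Exchangeable chain: stay probability ``stay``, uniform off-diagonal mass.

    With stay = 0.6 the mean visit length is 2.5 frames (5 s at TR = 2 s) and
    the stationary occupancy is uniform.
    """
    if not 0 < stay < 1:
        raise ValueError("stay must be in (0, 1)")
    p = np.full((n_states, n_states), (1.0 - stay) / (n_states - 1))
    np.fill_diagonal(p, stay)
    return p


def boost_entries(p: np.ndarray, boosts: dict[int, float]) -> np.ndarray:
    """Scale off-diagonal entry probabilities into target states (0-based keys).

    Each row's diagonal is kept fixed and the off-diagonal mass renormalized,
    so drugs change how often a state is entered from elsewhere without
    changing persistence once entered.
    """
    p = validate_transition_matrix(p).copy()
    n = p.shape[0]
    for i in range(n):
        off = p[i].copy()
        off[i] = 0.0
        mass = off.sum()
        for j, f in boosts.items():
            if j != i:
                off[j] *= f
        if off.sum() > 0:
            off *= mass / off.sum()
        p[i] = off
        p[i, i] = 1.0 - mass
    return validate_transition_matrix(p, "boosted matrix")


def make_centroids(n_states: int, n_rois: int, seed: int) -> CentroidSet:
    """Mutually distinct unit-sd state maps (stand-ins for empirically derived CAPs).

    Rows are an orthonormal basis drawn from a seeded Gaussian ensemble and
    rescaled to unit standard deviation, so pairwise cosine similarity is ~0
    (well below 0.5) by construction and row means are ~0 for n_rois >> n_states.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    if n_states > n_rois:
        raise ValueError(f"n_states ({n_states}) cannot exceed n_rois ({n_rois})")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_rois, n_states))
    q, _ = np.linalg.qr(g)
    rows = q.T[:n_states]
    if n_rois > n_states:
        # center rows; orthogonality is only perturbed at O(1/n_rois)
        rows = rows - rows.mean(axis=1, keepdims=True)
    rows = rows / rows.std(axis=1, keepdims=True)
    return CentroidSet(rows)


def simulate_state_sequence(
    transition_matrix: np.ndarray, n_frames: int, seed: int
) -> StateLabelSequence:
    """Sample a label sequence from the chain, starting from its stationary law.

    Starting at stationarity makes the expected occupancy equal the
    stationary eigenvector from frame 1, so occupancy-recovery checks are
    exact in expectation.
    """
    p = validate_transition_matrix(transition_matrix)
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    n = p.shape[0]
    rng = np.random.default_rng(seed)
    cum = np.cumsum(p, axis=1)
    pi_cum = np.cumsum(stationary_distribution(p))
    u = rng.random(n_frames)
    labels = np.empty(n_frames, dtype=int)
    s = int(np.searchsorted(pi_cum, u[0], side="right"))
    labels[0] = s
    for t in range(1, n_frames):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        s = min(s, n - 1)
        labels[t] = s
    return StateLabelSequence(labels + 1, tr_seconds=2.0, n_states=n)


def simulate_subject_run(
    centroids: CentroidSet,
    labels: StateLabelSequence,
    noise_sd: float,
    seed: int,
    ar1: float = 0.0,
    tr_seconds: float | None = None,
) -> RoiTimeseries:
    """Frames = active-state centroid + Gaussian noise (optionally AR(1) in time)."""
    if labels.labels.max() > centroids.n_states:
        raise IndexError("label out of centroid range")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    signal = centroids.values[labels.labels - 1]
    eps = rng.standard_normal(signal.shape) * noise_sd
    if ar1:
        if not -1 < ar1 < 1:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        out = np.empty_like(eps)
        out[0] = eps[0]
        scale = np.sqrt(1.0 - ar1 ** 2)
        for t in range(1, eps.shape[0]):
            out[t] = ar1 * out[t - 1] + scale * eps[t]
        eps = out
    tr = labels.tr_seconds if tr_seconds is None else tr_seconds
    return RoiTimeseries(signal + eps, tuple(f"roi{i+1}" for i in range(centroids.n_rois)), tr)


def simulate_striatal_run(
    cortical_ts: RoiTimeseries,
    weight_profiles: np.ndarray,
    noise_sd: float,
    seed: int,
    coords: np.ndarray | None = None,
) -> VoxelTimeseries:
    """Voxel time courses as weighted mixtures of cortical ROI time courses."""
    w = np.asarray(weight_profiles, dtype=float)
    if w.ndim != 2:
        raise ValueError("weight_profiles must be voxels × ROIs")
    if not np.all(np.isfinite(w)):
        raise ValueError("weight_profiles must be finite")
    if w.shape[1] != cortical_ts.n_rois:
        raise ValueError(
            f"weights have {w.shape[1]} ROI columns, cortical series has {cortical_ts.n_rois}"
        )
    rng = np.random.default_rng(seed)
    values = cortical_ts.values @ w.T + rng.standard_normal(
        (cortical_ts.n_frames, w.shape[0])
    ) * noise_sd
    if coords is None:
        coords = striatal_grid(w.shape[0])
    return VoxelTimeseries(values, coords, cortical_ts.tr_seconds)


def striatal_grid(n_voxels: int) -> np.ndarray:
    """Deterministic compact 3-D block of voxel coordinates, (k, j, i) ascending.

    A near-cubic box is filled in scan order so that contiguity-based
    clustering of per-voxel maps behaves like a real mask.
    """
    side = int(np.ceil(n_voxels ** (1 / 3)))
    coords = []
    for k in range(side + 1):
        for j in range(side + 1):
            for i in range(side + 1):
                coords.append((i, j, k))
                if len(coords) == n_voxels:
                    return np.array(coords, dtype=int)
    raise RuntimeError("unreachable")


def make_weight_profiles(
    n_voxels: int, n_cortical_rois: int, seed: int, gain: float = 1.0
) -> np.ndarray:
    """Per-voxel cortical weight vectors: unit-norm Gaussian rows times ``gain``."""
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((n_voxels, n_cortical_rois))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    return w * gain


def permute_weight_profiles(
    base: np.ndarray, voxel_indices: np.ndarray, seed: int
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Apply an independent random permutation to each listed voxel's weights.

    Returns the permuted profile matrix and the per-voxel permutations (the
    planted rank rearrangement ground truth).
    """
    rng = np.random.default_rng(seed)
    out = base.copy()
    perms: dict[int, np.ndarray] = {}
    k = base.shape[1]
    for v in np.asarray(voxel_indices, dtype=int):
        perm = rng.permutation(k)
        out[v] = base[v, perm]
        perms[int(v)] = perm
    return out, perms


# ---------------------------------------------------------------------------
# cohort-level simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    n_subjects: int
    n_states: int = 8
    n_rois: int = 129
    n_cortical_rois: int = 53
    n_striatal_voxels: int = 300
    n_frames: int = 235
    tr_seconds: float = 2.0
    noise_sd: float = 0.5
    ar1: float = 0.0
    condition_transition_matrices: dict[str, np.ndarray] = field(default_factory=dict)
    condition_weight_profiles: dict[str, np.ndarray] = field(default_factory=dict)
    weight_permutations: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)
    subject_effect_scales: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cortical_rois > self.n_rois:
            raise ValueError("n_cortical_rois cannot exceed n_rois")
        if not self.condition_transition_matrices:
            raise ValueError("condition_transition_matrices must be provided")
        for cond, p in self.condition_transition_matrices.items():
            m = validate_transition_matrix(p, f"{cond} transition matrix")
            if m.shape[0] != self.n_states:
                raise ValueError(f"{cond} matrix is {m.shape[0]}-state, expected {self.n_states}")
        for cond, w in self.condition_weight_profiles.items():
            w = np.asarray(w)
            if w.shape != (self.n_striatal_voxels, self.n_cortical_rois):
                raise ValueError(f"{cond} weight profile has shape {w.shape}")
        if self.subject_effect_scales is not None:
            s = np.asarray(self.subject_effect_scales, dtype=float)
            if s.shape != (self.n_subjects,):
                raise ValueError("subject_effect_scales must have one entry per subject")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.condition_transition_matrices)


@dataclass
class GroundTruth:
    """Planted parameters recorded for recovery tests."""

    state_sequences: dict[tuple[str, str], np.ndarray]
    expected_dwell: dict[str, np.ndarray]
    weight_profiles: dict[str, np.ndarray]
    planted_rank_permutations: dict[str, dict[int, np.ndarray]]
    subject_effect_scales: np.ndarray | None = None


@dataclass
class CohortDataset:
    manifest: pd.DataFrame  # subject_id, condition, age, sex
    roi_timeseries: dict[tuple[str, str], RoiTimeseries]
    striatal_timeseries: dict[tuple[str, str], VoxelTimeseries]
    centroids: CentroidSet

    @property
    def subjects(self) -> list[str]:
        return sorted(self.manifest["subject_id"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.manifest["condition"].unique())


def study_config(
    n_subjects: int = 59,
    seed: int = 0,
    n_striatal_voxels: int = 300,
    permuted_fraction: float = 0.5,
    couple_subject_effects: bool = False,
    null: bool = False,
    **overrides,
) -> SimulationConfig:
    """The default study conditions: MPH boosts DMN/DAN entries and suppresses
    FPN entries and permutes the cortical weight ranking at half the striatal
    voxels; HAL boosts SM-DMN entries and leaves striatal weights alone.

    ``null=True`` plants no effects anywhere (all three conditions share the
    placebo parameters); ``couple_subject_effects=True`` scales each subject's
    drug effect (both dwell and weight permutation extent) by a common
    Uniform(0.2, 1) draw, planting a positive dynamics–reconfiguration
    coupling.
    """
    cfg = SimulationConfig(n_subjects=n_subjects, seed=seed,
                           n_striatal_voxels=n_striatal_voxels, **overrides)
    base = baseline_transition_matrix(cfg.n_states)
    from .timeseries_io import DEFAULT_STATE_NAMES

    if cfg.n_states == len(DEFAULT_STATE_NAMES):
        names = list(DEFAULT_STATE_NAMES)
    else:
        names = [f"state-{i+1}" for i in range(cfg.n_states)]

    def as_idx(boosts: dict[str, float]) -> dict[int, float]:
        return {names.index(k): v for k, v in boosts.items() if k in names}

    if null:
        mph = hal = base
    else:
        mph = boost_entries(base, as_idx(MPH_ENTRY_BOOSTS))
        hal = boost_entries(base, as_idx(HAL_ENTRY_BOOSTS))
    cfg.condition_transition_matrices = {"PBO": base, "MPH": mph, "HAL": hal}

    rng = np.random.default_rng(np.random.SeedSequence([seed, 91]))
    w0 = make_weight_profiles(cfg.n_striatal_voxels, cfg.n_cortical_rois,
                              seed=int(rng.integers(2 ** 31)))
    if null:
        w_mph, perms = w0, {}
    else:
        n_perm = int(round(permuted_fraction * cfg.n_striatal_voxels))
        voxels = rng.choice(cfg.n_striatal_voxels, size=n_perm, replace=False)
        w_mph, perms = permute_weight_profiles(w0, np.sort(voxels),
                                               seed=int(rng.integers(2 ** 31)))
    cfg.condition_weight_profiles = {"PBO": w0, "MPH": w_mph, "HAL": w0}
    cfg.weight_permutations = {"MPH": perms}

    if couple_subject_effects:
        cfg.subject_effect_scales = rng.uniform(0.2, 1.0, size=n_subjects)
    cfg.validate()
    return cfg


def _truncated_ages(rng: np.random.Generator, n: int) -> np.ndarray:
    ages = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(AGE_MEAN, AGE_SD, size=2 * n)
        ok = draw[(draw >= AGE_RANGE[0]) & (draw <= AGE_RANGE[1])]
        take = min(ok.size, n - filled)
        ages[filled:filled + take] = ok[:take]
        filled += take
    return np.round(ages, 1)


def simulate_cohort(
    config: SimulationConfig, include_striatal: bool = True
) -> tuple[CohortDataset, GroundTruth]:
    """Generate one run per subject per condition, plus the ground-truth ledger.

    All randomness flows from ``config.seed`` via a seed tree, so cohorts are
    bit-reproducible.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(4)
    rng_demo = np.random.default_rng(seeds[0])
    centroid_seed = int(np.random.default_rng(seeds[1]).integers(2 ** 31))
    centroids = make_centroids(config.n_states, config.n_rois, centroid_seed)
    run_rng = np.random.default_rng(seeds[2])

    ages = _truncated_ages(rng_demo, config.n_subjects)
    sexes = np.where(rng_demo.random(config.n_subjects) < P_MALE, "M", "F")
    subjects = [f"sub-{i+1:03d}" for i in range(config.n_subjects)]

    conditions = list(config.conditions)
    p_pbo = config.condition_transition_matrices.get("PBO")
    w_pbo = config.condition_weight_profiles.get("PBO")
    coords = striatal_grid(config.n_striatal_voxels)
    scales = config.subject_effect_scales

    rows = []
    roi_ts: dict[tuple[str, str], RoiTimeseries] = {}
    str_ts: dict[tuple[str, str], VoxelTimeseries] = {}
    sequences: dict[tuple[str, str], np.ndarray] = {}

    for si, subj in enumerate(subjects):
        for cond in conditions:
            p = config.condition_transition_matrices[cond]
            w = config.condition_weight_profiles.get(cond)
            if scales is not None and cond != "PBO" and p_pbo is not None:
                u = float(scales[si])
                p = (1.0 - u) * p_pbo + u * p
                perms = config.weight_permutations.get(cond, {})
                if perms and w_pbo is not None:
                    voxels = sorted(perms)
                    keep = voxels[: int(np.ceil(u * len(voxels)))]
                    w = w_pbo.copy()
                    for v in keep:
                        w[v] = w_pbo[v, perms[v]]
            seq = simulate_state_sequence(
                p, config.n_frames, seed=int(run_rng.integers(2 ** 31))
            )
            seq.tr_seconds = config.tr_seconds
            run = simulate_subject_run(
                centroids, seq, config.noise_sd,
                seed=int(run_rng.integers(2 ** 31)),
                ar1=config.ar1, tr_seconds=config.tr_seconds,
            )
            roi_ts[(subj, cond)] = run
            sequences[(subj, cond)] = seq.labels.copy()
            if include_striatal and w is not None:
                cortical = RoiTimeseries(
                    run.values[:, : config.n_cortical_rois],
                    run.roi_names[: config.n_cortical_rois],
                    config.tr_seconds,
                )
                str_ts[(subj, cond)] = simulate_striatal_run(
                    cortical, w, config.noise_sd,
                    seed=int(run_rng.integers(2 ** 31)), coords=coords,
                )
            rows.append({"subject_id": subj, "condition": cond,
                         "age": ages[si], "sex": sexes[si]})

    manifest = pd.DataFrame(rows)
    truth = GroundTruth(
        state_sequences=sequences,
        expected_dwell={
            c: stationary_distribution(p)
            for c, p in config.condition_transition_matrices.items()
        },
        weight_profiles=dict(config.condition_weight_profiles),
        planted_rank_permutations=dict(config.weight_permutations),
        subject_effect_scales=scales,
    )
    return CohortDataset(manifest, roi_ts, str_ts, centroids), truth


# ---------------------------------------------------------------------------
# on-disk cohort format
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortDataset, truth: GroundTruth, out_dir: str | Path) -> None:
    """Write a cohort as manifest.tsv + per-run TSVs + ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    from .timeseries_io import write_centroids
    write_centroids(cohort.centroids, out / "centroids.tsv")
    for (subj, cond), ts in cohort.roi_timeseries.items():
        write_roi_timeseries(ts, out / f"{subj}_{cond}_roi.tsv")
    for (subj, cond), ts in cohort.striatal_timeseries.items():
        write_voxel_timeseries(ts, out / f"{subj}_{cond}_striatal.tsv")
    gt = {
        "expected_dwell": {c: list(map(float, v)) for c, v in truth.expected_dwell.items()},
        "planted_rank_permutations": {
            c: {str(v): [int(x) for x in perm] for v, perm in perms.items()}
            for c, perms in truth.planted_rank_permutations.items()
        },
        "subject_effect_scales": (
            None if truth.subject_effect_scales is None
            else [float(x) for x in truth.subject_effect_scales]
        ),
        "state_sequences": {
            f"{s}|{c}": [int(x) for x in seq]
            for (s, c), seq in truth.state_sequences.items()
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(gt))


def load_cohort(in_dir: str | Path, tr_seconds: float = 2.0) -> CohortDataset:
    """Load a cohort directory written by :func:`write_cohort`."""
    from .timeseries_io import read_centroids

    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.tsv", sep="\t")
    centroids = read_centroids(src / "centroids.tsv")
    roi_ts, str_ts = {}, {}
    for _, row in manifest.iterrows():
        subj, cond = row["subject_id"], row["condition"]
        roi_ts[(subj, cond)] = read_roi_timeseries(
            src / f"{subj}_{cond}_roi.tsv", tr_seconds
        )
        vox_path = src / f"{subj}_{cond}_striatal.tsv"
        if vox_path.exists():
            str_ts[(subj, cond)] = read_voxel_timeseries(vox_path, tr_seconds)
    return CohortDataset(manifest, roi_ts, str_ts, centroids)
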