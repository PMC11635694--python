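"""Monte-Carlo recovery and calibration studies on the synthetic cohorts.

Each function repeats a scaled-down replica of one analysis across many
cohort seeds and reports a rate: statistical power against a planted effect,
separation of planted rank rearrangement from the split-half null, recovery
of a planted dynamics–reconfiguration coupling, or type-I error under a null
generator.  These are the package's own operating-characteristic checks;
problem sizes per seed are chosen small enough to repeat across 100 seeds
(see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from . import cap_dynamics as cd
from . import cscp as cp
from . import linkage as lk
from . import stats as st
from .pipeline import dwell_table, time_change_table
from .synthetic_data import simulate_cohort, study_config
from .timeseries_io import RoiTimeseries


def _seed_list(seed: int, n_seeds: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n_seeds)]


def _subject_ror_scores(cohort, n_cortical: int = 53):
    """Per-subject whole-striatum mean ROR for MPH−PBO and the split-half null."""
    drug, null = [], []
    for subj in cohort.subjects:
        prof = {}
        for cond in ("PBO", "MPH"):
            striatal = cohort.striatal_timeseries[(subj, cond)]
            roi = cohort.roi_timeseries[(subj, cond)]
            cortical = RoiTimeseries(roi.values[:, :n_cortical],
                                     roi.roi_names[:n_cortical], roi.tr_seconds)
            prof[cond] = cp.connectivity_profile(striatal, cortical, cond)
        drug.append(cp.subject_cscp_score(
            cp.rank_order_rearrangement(prof["MPH"], prof["PBO"])))
        striatal = cohort.striatal_timeseries[(subj, "PBO")]
        roi = cohort.roi_timeseries[(subj, "PBO")]
        cortical = RoiTimeseries(roi.values[:, :n_cortical],
                                 roi.roi_names[:n_cortical], roi.tr_seconds)
        h1, h2 = cp.split_half_profiles(striatal, cortical)
        null.append(cp.subject_cscp_score(cp.rank_order_rearrangement(h1, h2)))
    return np.array(drug), np.array(null)


def mph_dwell_power(
    n_seeds: int = 100, n_subjects: int = 59, alpha: float = 0.025, seed: int = 0
) -> float:
    """Power to detect the planted MPH increase in DMN total time.

    Per seed: simulate a cohort (full-strength planted effect, no striatal
    data needed), run frame assignment and dwell metrics, and test MPH vs
    PBO DMN total time with a paired t at ``alpha``.  Returns the rejection
    fraction.
    """
    rejections = 0
    for s in _seed_list(seed, n_seeds):
        cfg = study_config(n_subjects=n_subjects, seed=s, n_striatal_voxels=4)
        cohort, _ = simulate_cohort(cfg, include_striatal=False)
        dwell = dwell_table(cohort)
        piv = dwell[dwell["state"] == "DMN"].pivot(
            index="subject", columns="condition", values="total_time_s")
        res = st.paired_t(piv["MPH"].to_numpy(), piv["PBO"].to_numpy())
        if res.p < alpha and res.t > 0:
            rejections += 1
    return rejections / n_seeds


def ror_exceeds_null_rate(
    n_seeds: int = 100, n_subjects: int = 8, n_voxels: int = 48, seed: int = 0
) -> float:
    """How often planted weight permutations push drug-pair ROR above the null.

    Per seed: a small cohort with the default 50% of striatal voxels
    rank-permuted under MPH; compare the group mean MPH−PBO ROR against the
    group mean split-half placebo ROR.
    """
    wins = 0
    for s in _seed_list(seed, n_seeds):
        cfg = study_config(n_subjects=n_subjects, seed=s, n_striatal_voxels=n_voxels)
        cohort, _ = simulate_cohort(cfg)
        drug, null = _subject_ror_scores(cohort)
        if drug.mean() > null.mean():
            wins += 1
    return wins / n_seeds


def coupling_recovery_rate(
    n_seeds: int = 100, n_subjects: int = 59, n_voxels: int = 48, seed: int = 0
) -> float:
    """How often the planted dynamics–ROR coupling is recovered as r > 0.

    Cohorts are generated with per-subject effect scales driving both the
    dwell shift and the permutation extent; per seed the Pearson correlation
    between the absolute time-change score (all states) and the subject-wise
    MPH−PBO ROR is computed.
    """
    positive = 0
    for s in _seed_list(seed, n_seeds):
        cfg = study_config(n_subjects=n_subjects, seed=s,
                           n_striatal_voxels=n_voxels,
                           couple_subject_effects=True)
        cohort, _ = simulate_cohort(cfg)
        dwell = dwell_table(cohort)
        tchange = time_change_table(dwell, "MPH", "PBO",
                                    ["FPN", "DMN", "DAN"], normalize=True)
        drug, _ = _subject_ror_scores(cohort)
        r, _ = lk.dynamics_cscp_correlation(
            tchange.sort_index()["score_all"].to_numpy(), drug)
        if r > 0:
            positive += 1
    return positive / n_seeds


def null_calibration(
    n_seeds: int = 100, n_subjects: int = 59, n_voxels: int = 48,
    alpha: float = 0.05, seed: int = 0,
) -> tuple[float, float]:
    """Type-I error of the drug × state interaction and the linkage correlation.

    Cohorts with no planted effects anywhere; returns (interaction rejection
    rate, dynamics–ROR correlation rejection rate), both nominally ``alpha``.

    The correlation null pairs time-change scores with ROR scores from an
    *independently generated* null cohort.  Within a single cohort the two
    are mechanically coupled even without any drug effect: a subject whose
    two runs happened to realize different state occupancies shows both a
    larger dwell change and a larger apparent profile rearrangement, because
    state mix shapes the sampling distribution of the connectivity
    estimates.  That coupling is a property of finite scans, not of the
    statistics under test; see docs/methods.md.
    """
    rej_inter = rej_corr = 0
    for s in _seed_list(seed, n_seeds):
        cfg = study_config(n_subjects=n_subjects, seed=s,
                           n_striatal_voxels=n_voxels, null=True)
        cohort, _ = simulate_cohort(cfg)
        dwell = dwell_table(cohort)
        inter = [r for r in st.rm_anova(dwell, "total_time_s",
                                        ["condition", "state"])
                 if r.effect == "condition:state"][0]
        if inter.p < alpha:
            rej_inter += 1
        tchange = time_change_table(dwell, "MPH", "PBO",
                                    ["FPN", "DMN", "DAN"], normalize=True)
        cfg2 = study_config(n_subjects=n_subjects, seed=s + 2 ** 20,
                            n_striatal_voxels=n_voxels, null=True)
        cohort2, _ = simulate_cohort(cfg2)
        drug, _ = _subject_ror_scores(cohort2)
        _, p = lk.dynamics_cscp_correlation(
            tchange.sort_index()["score_all"].to_numpy(), drug)
        if p < alpha:
            rej_corr += 1
    return rej_inter / n_seeds, rej_corr / n_seeds
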