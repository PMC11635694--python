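"""End-to-end study pipeline on a cohort: dynamics → anticorrelation → CSCP → linkage.

Each stage is a thin cohort-level loop over the library primitives, returning
tidy tables; :func:`run_pipeline` chains them on a simulated cohort, writes
every stage's TSV plus a JSON manifest and a human-readable markdown report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cap_dynamics as cd
from . import cscp as cp
from . import linkage as lk
from . import stats as st
from .synthetic_data import CohortDataset, SimulationConfig, simulate_cohort, study_config
from .timeseries_io import RoiTimeseries, VoxelTimeseries

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs for a full synthetic-study run."""

    n_subjects: int = 59
    n_striatal_voxels: int = 300
    seed: int = 0
    noise_sd: float = 0.5
    alpha: float = 0.05
    n_states_family: int = 8  # Bonferroni family for per-state ANOVAs
    n_posthoc_family: int = 2  # MPH vs PBO and HAL vs PBO
    p_threshold: float = 0.001  # voxelwise one-sided threshold
    min_extent: int = 10  # cluster extent in voxels
    min_rank_shift: float = 5.0
    couple_subject_effects: bool = True
    null: bool = False
    normalize_time_change: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# stage tables
# ---------------------------------------------------------------------------

def dwell_table(cohort: CohortDataset) -> pd.DataFrame:
    """Assign frames and compute dwell metrics for every run.

    Long format: subject, condition, state, total_time_s, transitions,
    persistence_s.
    """
    rows = []
    names = cohort.centroids.state_names
    for (subj, cond), ts in cohort.roi_timeseries.items():
        seq = cd.assign_frames(ts, cohort.centroids)
        dm = cd.dwell_metrics(seq)
        for k in range(dm.n_states):
            rows.append({
                "subject": subj, "condition": cond, "state": names[k],
                "total_time_s": dm.total_time_s[k],
                "transitions": int(dm.transitions[k]),
                "persistence_s": dm.persistence_s[k],
            })
    return pd.DataFrame(rows).sort_values(
        ["subject", "condition", "state"]).reset_index(drop=True)


def anticorr_table(
    cohort: CohortDataset, network_a: str = "DMN", network_b: str = "DAN"
) -> pd.DataFrame:
    """Fisher-z network anticorrelation per run, from two separate beta series."""
    ia = cohort.centroids.state_names.index(network_a)
    ib = cohort.centroids.state_names.index(network_b)
    rows = []
    for (subj, cond), ts in cohort.roi_timeseries.items():
        beta_a = cd.network_beta_series(ts, cohort.centroids.values[ia])
        beta_b = cd.network_beta_series(ts, cohort.centroids.values[ib])
        rows.append({
            "subject": subj, "condition": cond,
            "anticorr_z": cd.anticorrelation_z(beta_a, beta_b),
        })
    return pd.DataFrame(rows).sort_values(["subject", "condition"]).reset_index(drop=True)


def _cortical_slice(ts: RoiTimeseries, n_cortical: int) -> RoiTimeseries:
    return RoiTimeseries(ts.values[:, :n_cortical], ts.roi_names[:n_cortical],
                         ts.tr_seconds)


def cscp_maps(
    cohort: CohortDataset,
    n_cortical_rois: int = 53,
    metrics: tuple[str, ...] = ("AD", "ROR", "ES"),
    drug_conditions: tuple[str, ...] = ("MPH", "HAL"),
    placebo: str = "PBO",
    equalize_null_length: bool = False,
) -> dict[str, dict[str, list[cp.CSCPMap]]]:
    """Per-subject divergence maps for each drug pair and the split-half null.

    Returns maps[metric][pair] = per-subject CSCPMap list, subjects sorted;
    pairs are ``"MPH-PBO"``-style plus ``"PBO-split"``.

    By default drug-pair profiles use full-length runs while the split-half
    null uses half-length runs (the study design's asymmetry);
    ``equalize_null_length=True`` computes drug and placebo profiles on
    first-half frames too, for calibration studies.
    """
    subjects = cohort.subjects
    out: dict[str, dict[str, list[cp.CSCPMap]]] = {
        m: {f"{d}-{placebo}": [] for d in drug_conditions} | {f"{placebo}-split": []}
        for m in metrics
    }
    for subj in subjects:
        profiles = {}
        for cond in (*drug_conditions, placebo):
            striatal = cohort.striatal_timeseries[(subj, cond)]
            cortical = _cortical_slice(cohort.roi_timeseries[(subj, cond)],
                                       n_cortical_rois)
            if equalize_null_length:
                half = striatal.n_frames // 2
                striatal = VoxelTimeseries(striatal.values[:half],
                                           striatal.voxel_coords,
                                           striatal.tr_seconds)
                cortical = RoiTimeseries(cortical.values[:half],
                                         cortical.roi_names,
                                         cortical.tr_seconds)
            profiles[cond] = cp.connectivity_profile(striatal, cortical, cond)
        pbo_striatal = cohort.striatal_timeseries[(subj, placebo)]
        pbo_cortical = _cortical_slice(cohort.roi_timeseries[(subj, placebo)],
                                       n_cortical_rois)
        half1, half2 = cp.split_half_profiles(pbo_striatal, pbo_cortical)
        for m in metrics:
            func = cp.METRIC_FUNCS[m]
            for d in drug_conditions:
                cmap = func(profiles[d], profiles[placebo])
                cmap.subject = subj
                out[m][f"{d}-{placebo}"].append(cmap)
            null_map = func(half1, half2)
            null_map.subject = subj
            null_map.condition_pair = f"{placebo}-split"
            out[m][f"{placebo}-split"].append(null_map)
    return out


def cscp_score_table(maps: dict[str, dict[str, list[cp.CSCPMap]]]) -> pd.DataFrame:
    """Subject-wise whole-striatum mean score per metric and condition pair."""
    rows = []
    for metric, pairs in maps.items():
        for pair, cmaps in pairs.items():
            for cmap in cmaps:
                rows.append({
                    "subject": cmap.subject, "metric": metric,
                    "condition_pair": pair,
                    "score": cp.subject_cscp_score(cmap),
                })
    return pd.DataFrame(rows)


def time_change_table(
    dwell: pd.DataFrame,
    drug: str,
    placebo: str,
    sig_states: list[str],
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-subject absolute time-change scores over all/sig/nonsig state subsets."""
    wide = dwell.pivot_table(index=["subject", "state"], columns="condition",
                             values="total_time_s")
    delta = (wide[drug] - wide[placebo]).abs().rename("abs_change").reset_index()
    all_states = sorted(dwell["state"].unique())
    nonsig = [s for s in all_states if s not in sig_states]
    rows = []
    for subj, grp in delta.groupby("subject"):
        by_state = grp.set_index("state")["abs_change"]

        def score(states: list[str]) -> float:
            v = float(by_state.loc[states].sum())
            return v / len(states) if normalize else v

        rows.append({
            "subject": subj,
            "score_all": score(all_states),
            "score_sig": score(sig_states),
            "score_nonsig": score(nonsig),
        })
    return pd.DataFrame(rows).set_index("subject").sort_index()


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Simulate a cohort under the study conditions and run every stage.

    Writes stage TSVs, ``results.json`` and ``report.md`` under ``out_dir``
    and returns the results manifest.  Deterministic given the config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = study_config(
        n_subjects=config.n_subjects, seed=config.seed,
        n_striatal_voxels=config.n_striatal_voxels,
        couple_subject_effects=config.couple_subject_effects,
        null=config.null, noise_sd=config.noise_sd,
    )
    cohort, truth = simulate_cohort(sim)
    results: dict = {"config": dataclasses.asdict(config)}

    # --- temporal dynamics ------------------------------------------------
    dwell = dwell_table(cohort)
    dwell.to_csv(out / "dwell.tsv", sep="\t", index=False)
    interaction = st.rm_anova(dwell, "total_time_s", ["condition", "state"])
    results["drug_x_state"] = [dataclasses.asdict(r) for r in interaction]

    per_state_alpha = st.bonferroni_alpha(config.alpha, config.n_states_family)
    per_state, sig_states = [], []
    for state, grp in dwell.groupby("state"):
        res = st.rm_anova(grp, "total_time_s", ["condition"])[0]
        per_state.append({"state": state, **dataclasses.asdict(res)})
        if res.p < per_state_alpha:
            sig_states.append(state)
    results["per_state_anova"] = per_state
    results["per_state_alpha"] = per_state_alpha
    results["significant_states"] = sig_states

    posthoc = []
    wide = dwell.pivot_table(index=["subject", "state"], columns="condition",
                             values="total_time_s").reset_index()
    for state in sig_states:
        sub = wide[wide["state"] == state]
        for drug in ("MPH", "HAL"):
            res = st.paired_t(sub[drug].to_numpy(), sub["PBO"].to_numpy(),
                              m_comparisons=config.n_posthoc_family)
            posthoc.append({"state": state, "contrast": f"{drug}-PBO",
                            **dataclasses.asdict(res)})
    results["posthoc_total_time"] = posthoc
    pd.DataFrame(posthoc).to_csv(out / "posthoc.tsv", sep="\t", index=False)

    # --- anticorrelation ---------------------------------------------------
    anti = anticorr_table(cohort)
    time_comb = (
        dwell[dwell["state"].isin(["DMN", "DAN"])]
        .groupby(["subject", "condition"])["total_time_s"].sum()
        .rename("time_in_state_s").reset_index()
    )
    anti = anti.merge(time_comb, on=["subject", "condition"])
    anti = anti.merge(cohort.manifest.rename(columns={"subject_id": "subject"}),
                      on=["subject", "condition"])
    anti.to_csv(out / "anticorr.tsv", sep="\t", index=False)
    anti_anova = st.rm_anova(anti, "anticorr_z", ["condition"])[0]
    results["anticorr_anova"] = dataclasses.asdict(anti_anova)
    lmm = st.lmm_anticorr(anti)
    results["anticorr_lmm"] = {
        "slope_time": float(lmm.fixed_effects["_time_c"]),
        "p_time": float(lmm.pvalues["_time_c"]),
        "r2_marginal": lmm.r2_marginal,
        "r2_conditional": lmm.r2_conditional,
    }

    # --- corticostriatal configuration ------------------------------------
    maps = cscp_maps(cohort, n_cortical_rois=sim.n_cortical_rois)
    scores = cscp_score_table(maps)
    scores.to_csv(out / "cscp_scores.tsv", sep="\t", index=False)
    cscp_anovas, sig_metrics = [], []
    for metric, grp in scores.groupby("metric"):
        tbl = grp.rename(columns={"condition_pair": "condition"})
        res = st.rm_anova(tbl, "score", ["condition"])[0]
        cscp_anovas.append({"metric": metric, **dataclasses.asdict(res)})
        if res.p < st.bonferroni_alpha(config.alpha, 3):
            sig_metrics.append(metric)
    results["cscp_anova"] = cscp_anovas
    results["significant_cscp_metrics"] = sig_metrics

    cscp_posthoc = []
    for metric in sig_metrics:
        piv = scores[scores["metric"] == metric].pivot(
            index="subject", columns="condition_pair", values="score")
        for a, b in (("MPH-PBO", "PBO-split"), ("HAL-PBO", "PBO-split"),
                     ("MPH-PBO", "HAL-PBO")):
            res = st.paired_t(piv[a].to_numpy(), piv[b].to_numpy(), m_comparisons=3)
            cscp_posthoc.append({"metric": metric, "contrast": f"{a} vs {b}",
                                 **dataclasses.asdict(res)})
    results["cscp_posthoc"] = cscp_posthoc

    # --- localization + linkage -------------------------------------------
    link_metric = "ROR" if "ROR" in (sig_metrics or ["ROR"]) else sig_metrics[0]
    nodes = cp.voxelwise_paired_test(
        maps[link_metric]["MPH-PBO"], maps[link_metric]["PBO-split"],
        p_threshold=config.p_threshold, min_extent=config.min_extent,
    )
    node_rows = [{
        "node": f"node-{i+1}", "size": nd.size, "peak_t": nd.peak_t,
        "peak_i": nd.peak_coord[0], "peak_j": nd.peak_coord[1],
        "peak_k": nd.peak_coord[2], "label": nd.label,
    } for i, nd in enumerate(nodes)]
    pd.DataFrame(node_rows).to_csv(out / "nodes.tsv", sep="\t", index=False)
    results["nodes"] = node_rows

    sig_for_linkage = sig_states or ["FPN", "DMN", "DAN"]
    tchange = time_change_table(dwell, "MPH", "PBO", sig_for_linkage,
                                normalize=config.normalize_time_change)
    ror = (scores.query("metric == @link_metric and condition_pair == 'MPH-PBO'")
           .set_index("subject")["score"].sort_index())
    tchange = tchange.loc[ror.index]
    r_all, p_all = lk.dynamics_cscp_correlation(tchange["score_all"].to_numpy(),
                                                ror.to_numpy())
    results["linkage_correlation"] = {"metric": link_metric, "r": r_all, "p": p_all}
    comp = lk.three_way_comparison(
        ror.to_numpy(), tchange["score_all"].to_numpy(),
        tchange["score_sig"].to_numpy(), tchange["score_nonsig"].to_numpy(),
    )
    results["correlation_comparison"] = {
        k: dataclasses.asdict(v) for k, v in comp.items()
    }

    if len(nodes) > 0 and sig_for_linkage:
        node_scores = pd.DataFrame({
            f"node-{i+1}": [
                cp.subject_cscp_score(m, nd.coords)
                for m in maps[link_metric]["MPH-PBO"]
            ]
            for i, nd in enumerate(nodes)
        }, index=[m.subject for m in maps[link_metric]["MPH-PBO"]]).sort_index()
        wide_t = dwell.pivot_table(index=["subject", "state"],
                                   columns="condition", values="total_time_s")
        delta = (wide_t["MPH"] - wide_t["PBO"]).rename("change").reset_index()
        state_changes = delta[delta["state"].isin(sig_for_linkage)].pivot(
            index="subject", columns="state", values="change").sort_index()
        node_level = lk.node_level_analysis(node_scores, state_changes)
        node_level.to_csv(out / "node_level.tsv", sep="\t", index=False)
        results["node_level"] = node_level.to_dict(orient="records")

    (out / "results.json").write_text(json.dumps(results, indent=2, default=float))
    _write_report(results, out / "report.md")
    return results


def _write_report(results: dict, path: Path) -> None:
    lines = ["# Synthetic study report", ""]
    inter = next(r for r in results["drug_x_state"]
                 if r["effect"] == "condition:state")
    lines += [
        "## Drug × state interaction on total time",
        f"F({inter['df1']},{inter['df2']}) = {inter['F']:.2f}, "
        f"p = {inter['p']:.2g}, partial eta^2 = {inter['eta_sq_partial']:.2f}",
        "",
        "## Per-state drug effects (Bonferroni alpha = "
        f"{results['per_state_alpha']:.5g})",
    ]
    for row in results["per_state_anova"]:
        flag = " *" if row["state"] in results["significant_states"] else ""
        lines.append(
            f"- {row['state']}: F({row['df1']},{row['df2']}) = {row['F']:.2f}, "
            f"p = {row['p']:.2g}{flag}"
        )
    lines += ["", "## Post hoc paired contrasts (total time)"]
    for row in results["posthoc_total_time"]:
        lines.append(
            f"- {row['state']} {row['contrast']}: t({row['df']}) = {row['t']:.2f}, "
            f"p_corr = {row['p_corrected']:.2g}, d = {row['cohen_d']:.2f}"
        )
    lmm = results["anticorr_lmm"]
    lines += [
        "", "## DMN–DAN anticorrelation",
        f"Time-in-state slope = {lmm['slope_time']:.3g} z/s, p = {lmm['p_time']:.2g}, "
        f"marginal R² = {lmm['r2_marginal']:.2f}, conditional R² = "
        f"{lmm['r2_conditional']:.2f}",
        "", "## CSCP metrics",
    ]
    for row in results["cscp_anova"]:
        flag = " *" if row["metric"] in results["significant_cscp_metrics"] else ""
        lines.append(
            f"- {row['metric']}: F({row['df1']},{row['df2']}) = {row['F']:.2f}, "
            f"p = {row['p']:.2g}{flag}"
        )
    link = results["linkage_correlation"]
    lines += [
        "", "## Dynamics–CSCP linkage",
        f"r({link['metric']}, |Δtime| all states) = {link['r']:.2f}, "
        f"p = {link['p']:.2g}",
        f"Striatal nodes surviving voxelwise test: {len(results['nodes'])}",
    ]
    path.write_text("\n".join(lines) + "\n")
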