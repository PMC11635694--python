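"""Linking drug-induced dwell-time change to corticostriatal reconfiguration.

The bridge quantity is the absolute time-change score: per subject, the sum
over a state subset of |total time under drug − total time under placebo|,
optionally divided by the number of states summed so subsets of different
size stay comparable.  Its correlation with subject-wise CSCP scores, the
Steiger comparison across state subsets, and the node × state exploratory
table live here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .cap_dynamics import DwellMetrics
from .stats import CorrelationComparison, steiger_z


@dataclass
class TimeChangeScore:
    subject: str
    condition_pair: str
    state_subset: str  # "all" | "significant" | "non-significant" | a state name
    value: float  # seconds (per state summed, when normalized)
    normalized: bool


def abs_time_change_score(
    dwell_drug: DwellMetrics,
    dwell_pbo: DwellMetrics,
    states: list[int] | None = None,
    normalize: bool = False,
) -> float:
    """Σ over the state subset of |Δ total time| (seconds), optionally per-state.

    ``states`` holds 1-based state indices; None means all states.
    """
    if dwell_drug.n_states != dwell_pbo.n_states:
        raise ValueError("dwell metrics must share the state space")
    if states is None:
        idx = np.arange(dwell_drug.n_states)
    else:
        idx = np.asarray(states, dtype=int) - 1
        if idx.size == 0:
            raise ValueError("state subset must be nonempty")
        if idx.min() < 0 or idx.max() >= dwell_drug.n_states:
            raise ValueError("state index out of range")
    total = float(np.abs(
        dwell_drug.total_time_s[idx] - dwell_pbo.total_time_s[idx]
    ).sum())
    return total / idx.size if normalize else total


def dynamics_cscp_correlation(
    scores: np.ndarray, cscp_scores: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between paired subject-wise scores."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(cscp_scores, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need >= 4 paired scores")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate input: zero variance")
    res = sstats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def three_way_comparison(
    cscp_scores: np.ndarray,
    score_all: np.ndarray,
    score_sig: np.ndarray,
    score_nonsig: np.ndarray,
    sided: str = "one",
) -> dict[str, CorrelationComparison]:
    """Compare r(x, all) against r(x, nonsig) and against r(x, sig).

    x is the CSCP score; the three y's are time-change scores over all
    states, the significantly modulated states, and the remainder.  Returns
    Steiger comparisons keyed ``"all_vs_nonsig"`` and ``"all_vs_sig"``.
    """
    x = np.asarray(cscp_scores, dtype=float)
    ys = {
        "all": np.asarray(score_all, dtype=float),
        "sig": np.asarray(score_sig, dtype=float),
        "nonsig": np.asarray(score_nonsig, dtype=float),
    }
    n = x.size
    for name, y in ys.items():
        if y.shape != x.shape:
            raise ValueError(f"score vector {name!r} not aligned with CSCP scores")

    def r(u, v):
        return float(sstats.pearsonr(u, v).statistic)

    r_all, r_sig, r_nonsig = (r(x, ys[k]) for k in ("all", "sig", "nonsig"))
    out = {
        "all_vs_nonsig": steiger_z(
            r_all, r_nonsig, r(ys["all"], ys["nonsig"]), n, sided=sided
        ),
        "all_vs_sig": steiger_z(
            r_all, r_sig, r(ys["all"], ys["sig"]), n, sided=sided
        ),
    }
    return out


def node_level_analysis(
    node_scores: pd.DataFrame,
    state_changes: pd.DataFrame,
) -> pd.DataFrame:
    """One Pearson test per (node, state), Bonferroni over the full table.

    ``node_scores``: subjects × nodes (per-subject mean CSCP metric in each
    significant striatal node).  ``state_changes``: subjects × states
    (per-subject change in time spent in each significantly modulated state).
    Corrected p = min(1, p × n_nodes × n_states), the joint family.
    """
    if node_scores.shape[1] == 0 or state_changes.shape[1] == 0:
        raise ValueError("node and state lists must be nonempty")
    if not node_scores.index.equals(state_changes.index):
        raise ValueError("subjects must align between node scores and state changes")
    m = node_scores.shape[1] * state_changes.shape[1]
    rows = []
    for node in node_scores.columns:
        for state in state_changes.columns:
            res = sstats.pearsonr(node_scores[node], state_changes[state])
            rows.append({
                "node": node,
                "state": state,
                "r": float(res.statistic),
                "p_uncorr": float(res.pvalue),
                "p_corr": float(min(1.0, res.pvalue * m)),
            })
    return pd.DataFrame(rows)
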