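"""Co-activation pattern (CAP) temporal dynamics.

Each fMRI frame is assigned to the transient network state whose spatial map
it most resembles; run-length accounting over the resulting label sequence
yields the three dwell metrics per state:

* **total time** — seconds spent in the state across the scan,
* **transitions** — number of entries into the state (a run touching the
  first frame counts as an entry),
* **persistence** — mean duration of a visit, in seconds.

By construction ``total_time = transitions × persistence`` exactly for every
visited state, and total times sum to the scan duration.  States never
visited carry NaN persistence (absence, not an instantaneous visit).

The module also provides the network "beta series" (per-frame amplitude of a
state map in the data) and the Fisher-z anticorrelation between two such
series, used for the DMN–DAN anticorrelation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .timeseries_io import CentroidSet, RoiTimeseries

log = logging.getLogger(__name__)


@dataclass
class StateLabelSequence:
    """Per-frame state labels, 1-based, with the sampling interval."""

    labels: np.ndarray
    tr_seconds: float
    n_states: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("labels must be a nonempty 1-D vector")
        if self.labels.min() < 1 or self.labels.max() > self.n_states:
            raise ValueError(
                f"labels must lie in 1..{self.n_states}; "
                f"found range {self.labels.min()}..{self.labels.max()}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.labels.size


@dataclass
class DwellMetrics:
    """Per-state dwell triplet.  Arrays indexed 0..n_states-1 for states 1..n."""

    total_time_s: np.ndarray
    transitions: np.ndarray
    persistence_s: np.ndarray  # NaN where the state was never visited
    tr_seconds: float
    n_frames: int

    @property
    def n_states(self) -> int:
        return self.total_time_s.size


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encode: list of (state, run_length_in_frames)."""
    out: list[tuple[int, int]] = []
    start = 0
    for t in range(1, labels.size + 1):
        if t == labels.size or labels[t] != labels[start]:
            out.append((int(labels[start]), t - start))
            start = t
    return out


def dwell_metrics(seq: StateLabelSequence) -> DwellMetrics:
    """Compute total time, entry counts and mean persistence per state."""
    k = seq.n_states
    frames_in = np.zeros(k, dtype=float)
    entries = np.zeros(k, dtype=int)
    for state, length in _runs(seq.labels):
        frames_in[state - 1] += length
        entries[state - 1] += 1
    total = frames_in * seq.tr_seconds
    with np.errstate(invalid="ignore", divide="ignore"):
        persistence = np.where(entries > 0, total / np.maximum(entries, 1), np.nan)
    return DwellMetrics(total, entries, persistence, seq.tr_seconds, seq.n_frames)


def assign_frames(
    ts: RoiTimeseries,
    centroids: CentroidSet,
    normalize: bool = True,
    metric: str = "correlation",
) -> StateLabelSequence:
    """Label every frame with its best-matching state.

    Similarity is the Pearson spatial correlation between the frame's ROI
    vector and each state map (``metric="euclidean"`` switches to negative
    Euclidean distance).  Each ROI column is z-scored across time first when
    ``normalize`` is set, mirroring common CAP practice.  Ties break toward
    the lowest state index; a frame with zero spatial variance is flagged with
    a warning and falls to state 1 by the same tie-break.
    """
    if ts.n_rois != centroids.n_rois:
        raise ValueError(
            f"time series has {ts.n_rois} ROIs but centroids have {centroids.n_rois}"
        )
    x = ts.values
    if normalize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd

    if metric == "euclidean":
        d = ((x[:, None, :] - centroids.values[None, :, :]) ** 2).sum(axis=2)
        sim = -d
    elif metric == "correlation":
        xc = x - x.mean(axis=1, keepdims=True)
        xn = np.linalg.norm(xc, axis=1)
        degenerate = xn == 0
        if degenerate.any():
            log.warning(
                "%d frame(s) with zero spatial variance; assigned by tie-break",
                int(degenerate.sum()),
            )
        xn[degenerate] = 1.0
        cc = centroids.values - centroids.values.mean(axis=1, keepdims=True)
        cn = np.linalg.norm(cc, axis=1)
        sim = (xc / xn[:, None]) @ (cc / cn[:, None]).T
        sim[degenerate] = 0.0
    else:
        raise ValueError(f"unknown metric {metric!r}")

    labels = np.argmax(sim, axis=1) + 1  # argmax takes the first max: lowest index
    return StateLabelSequence(labels, ts.tr_seconds, centroids.n_states)


def network_beta_series(ts: RoiTimeseries, state_map: np.ndarray) -> np.ndarray:
    """Per-frame OLS slope of the frame's ROI vector on one state map.

    One simple regression (with intercept) per frame; the slope series tracks
    how strongly the state's spatial pattern is expressed at each time point.
    """
    m = np.asarray(state_map, dtype=float).ravel()
    if m.size != ts.n_rois:
        raise ValueError(f"map has {m.size} ROIs, time series has {ts.n_rois}")
    var = m.var()
    if var == 0:
        raise ValueError("state map has zero variance")
    mc = m - m.mean()
    x = ts.values - ts.values.mean(axis=1, keepdims=True)
    return (x @ mc) / (mc @ mc)


def anticorrelation_z(beta_a: np.ndarray, beta_b: np.ndarray) -> float:
    """Fisher r-to-z of the Pearson correlation between two beta series.

    Negative z indicates anticorrelation between the two networks' time
    courses.
    """
    a = np.asarray(beta_a, dtype=float).ravel()
    b = np.asarray(beta_b, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise ValueError("series must share length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate input: a series has zero variance")
    r = float(sstats.pearsonr(a, b).statistic)
    if abs(r) >= 1.0 - 1e-12:
        raise ValueError("|r| = 1: degenerate (noise-free collinear) input")
    return float(np.arctanh(r))
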