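"""Time-series containers and I/O.

Everything downstream consumes one of three in-memory containers:

* :class:`RoiTimeseries` — frames × ROIs signal matrix (ROI means),
* :class:`VoxelTimeseries` — frames × voxels matrix with integer grid coordinates,
* :class:`CentroidSet` — state templates (one spatial map per transient network state).

Matrices travel as tab-separated text with a header row; volumes as NIfTI-1
via nibabel.  Voxel enumeration from a mask is fixed to (k, j, i) ascending so
downstream per-voxel maps are reproducible across runs and machines.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: Transient network state names used throughout: fronto-insular DMN,
#: frontoparietal, default mode, dorsal attention, salience 1, sensory-motor
#: occipital, sensory-motor DMN hybrid, salience 2.
DEFAULT_STATE_NAMES = (
    "FI-DMN", "FPN", "DMN", "DAN", "SN-1", "SMO", "SM-DMN", "SN-2",
)


class FormatError(ValueError):
    """Raised when a text matrix file violates the expected layout."""


def _check_matrix(values: np.ndarray, what: str, min_rows: int = 2) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"{what}: expected a 2-D matrix, got shape {values.shape}")
    if values.shape[0] < min_rows:
        raise ValueError(f"{what}: need at least {min_rows} frames, got {values.shape[0]}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what}: non-finite entries present")
    return values


@dataclass
class RoiTimeseries:
    """A frames × ROIs matrix of regional signal with its sampling interval."""

    values: np.ndarray
    roi_names: tuple[str, ...]
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = _check_matrix(self.values, "RoiTimeseries")
        self.roi_names = tuple(str(n) for n in self.roi_names)
        if len(self.roi_names) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.roi_names)} ROI names for {self.values.shape[1]} columns"
            )
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("ROI names must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class VoxelTimeseries:
    """A frames × voxels matrix; ``voxel_coords`` are (i, j, k) grid triplets."""

    values: np.ndarray
    voxel_coords: np.ndarray  # (n_voxels, 3) int
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = _check_matrix(self.values, "VoxelTimeseries")
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        if self.voxel_coords.ndim != 2 or self.voxel_coords.shape[1] != 3:
            raise ValueError("voxel_coords must be (n_voxels, 3)")
        if self.voxel_coords.shape[0] != self.values.shape[1]:
            raise ValueError("one coordinate triplet per voxel column required")
        uniq = {tuple(c) for c in self.voxel_coords}
        if len(uniq) != self.voxel_coords.shape[0]:
            raise ValueError("voxel_coords must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class CentroidSet:
    """State templates: one row (spatial map over ROIs) per transient network state."""

    values: np.ndarray
    state_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("centroids must be a 2-D (states × ROIs) matrix")
        if not self.state_names:
            n = self.values.shape[0]
            if n == len(DEFAULT_STATE_NAMES):
                self.state_names = DEFAULT_STATE_NAMES
            else:
                self.state_names = tuple(f"state-{i + 1}" for i in range(n))
        self.state_names = tuple(str(s) for s in self.state_names)
        if len(self.state_names) != self.values.shape[0]:
            raise ValueError("one name per centroid row required")
        if len(set(self.state_names)) != len(self.state_names):
            raise ValueError("state names must be unique")
        if np.any(self.values.std(axis=1) == 0):
            raise ValueError("every centroid row must have nonzero variance")

    @property
    def n_states(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def state_index(self, name: str) -> int:
        """1-based index of a named state."""
        return self.state_names.index(name) + 1


# ---------------------------------------------------------------------------
# tab-separated text matrices
# ---------------------------------------------------------------------------

def _read_tsv_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header row and at least one data row")
    header = lines[0].split("\t")
    ncol = len(header)
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != ncol:
            raise FormatError(
                f"{path}: line {lineno}: expected {ncol} columns, found {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    return header, np.array(rows, dtype=float)


def _write_tsv_matrix(path: str | Path, header: Sequence[str], values: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in np.asarray(values, dtype=float):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_roi_timeseries(
    path: str | Path, tr_seconds: float, discard_initial: int = 0
) -> RoiTimeseries:
    """Load a frames × ROIs TSV (header = ROI names, rows = frames in scan order).

    ``discard_initial`` drops that many leading frames after load, supporting
    the convention of discarding pre-steady-state volumes.
    """
    header, values = _read_tsv_matrix(path)
    if discard_initial:
        values = values[discard_initial:]
    if values.shape[0] < 2:
        raise FormatError(f"{path}: fewer than 2 frames after discarding")
    return RoiTimeseries(values, tuple(header), tr_seconds)


def write_roi_timeseries(ts: RoiTimeseries, path: str | Path) -> None:
    _write_tsv_matrix(path, ts.roi_names, ts.values)


def read_voxel_timeseries(
    path: str | Path, tr_seconds: float, discard_initial: int = 0
) -> VoxelTimeseries:
    """Load a frames × voxels TSV whose header encodes coordinates as ``i_j_k``."""
    header, values = _read_tsv_matrix(path)
    coords = []
    for col in header:
        parts = col.split("_")
        if len(parts) != 3:
            raise FormatError(f"{path}: voxel column name {col!r} is not 'i_j_k'")
        coords.append([int(p) for p in parts])
    if discard_initial:
        values = values[discard_initial:]
    return VoxelTimeseries(values, np.array(coords), tr_seconds)


def write_voxel_timeseries(ts: VoxelTimeseries, path: str | Path) -> None:
    header = [f"{i}_{j}_{k}" for i, j, k in ts.voxel_coords]
    _write_tsv_matrix(path, header, ts.values)


def read_centroids(path: str | Path) -> CentroidSet:
    """Load a states × ROIs TSV; first column holds state names."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header row and at least one state row")
    names, rows = [], []
    ncol = len(lines[0].split("\t"))
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != ncol:
            raise FormatError(f"{path}: line {lineno}: ragged row")
        names.append(cells[0])
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    return CentroidSet(np.array(rows), tuple(names))


def write_centroids(cs: CentroidSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("state\t" + "\t".join(f"roi{i + 1}" for i in range(cs.n_rois)) + "\n")
        for name, row in zip(cs.state_names, cs.values):
            fh.write(name + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# volumetric extraction
# ---------------------------------------------------------------------------

def extract_timeseries_from_nifti(
    image_path: str | Path,
    atlas_path: str | Path,
    mode: Literal["roi-mean", "voxelwise"] = "roi-mean",
    tr_seconds: float | Literal["from header"] = "from header",
    discard_initial: int = 0,
) -> RoiTimeseries | VoxelTimeseries:
    """Extract time series from a 4-D NIfTI using a label atlas or binary mask.

    roi-mean mode averages voxels per atlas label at each frame (labels sorted
    ascending; gaps in label numbering are fine).  voxelwise mode returns one
    column per nonzero mask voxel, ordered by (k, j, i) ascending.  The TR is
    read from the image header unless overridden; an explicit value wins over
    a conflicting header with a logged warning.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    atlas_img = nib.load(str(atlas_path))
    data = np.asarray(img.dataobj, dtype=float)
    atlas = np.asarray(atlas_img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D image, got shape {data.shape}")
    if atlas.shape != data.shape[:3]:
        raise ValueError(
            f"atlas grid {atlas.shape} does not match image grid {data.shape[:3]}"
        )

    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr_seconds == "from header":
        if header_tr <= 0:
            raise ValueError("no usable TR in header; pass tr_seconds explicitly")
        tr = header_tr
    else:
        tr = float(tr_seconds)
        if header_tr > 0 and abs(header_tr - tr) > 1e-6:
            log.warning(
                "TR mismatch: header says %.6g s, flag says %.6g s; using the flag",
                header_tr, tr,
            )

    n_frames = data.shape[3]
    if mode == "roi-mean":
        labels = np.unique(atlas)
        labels = labels[labels != 0]
        series, names = [], []
        for lab in labels:
            mask = atlas == lab
            if not mask.any():  # pragma: no cover - unique() guarantees presence
                log.warning("label %s covers no voxels; excluded", lab)
                continue
            series.append(data[mask].mean(axis=0))
            names.append(str(int(lab)) if float(lab).is_integer() else str(lab))
        values = np.column_stack(series)[discard_initial:]
        return RoiTimeseries(values, tuple(names), tr)
    if mode == "voxelwise":
        ii, jj, kk = np.nonzero(atlas)
        order = np.lexsort((ii, jj, kk))  # primary key k, then j, then i
        ii, jj, kk = ii[order], jj[order], kk[order]
        values = data[ii, jj, kk, :].T[discard_initial:]
        coords = np.column_stack([ii, jj, kk])
        return VoxelTimeseries(values, coords, tr)
    raise ValueError(f"unknown mode {mode!r}")
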