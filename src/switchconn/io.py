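"""File formats: BIDS-style events and confounds, delimited matrices, labels.

Conventions: tab-separated values throughout (comma-delimited inputs
are sniffed and accepted); lines starting with ``#`` are provenance
headers and ignored on read; ROI indices are 1-based in files and
0-based in memory; atlas coordinates are MNI millimetres.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import ConnectivityMatrix
from .design import REPEAT, SWITCH, Trial, TrialDesign
from .lss import CONFOUND_COLUMNS

EVENT_COLUMNS = ("onset", "duration", "trial_type", "task", "cue")


def provenance_header(seed=None, **extra) -> str:
    """Provenance comment block written at the top of every output file."""
    parts = [f"switchconn v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts.extend(f"{k}={v}" for k, v in sorted(extra.items()))
    return "# " + " ".join(parts) + "\n"


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def _read_table(path) -> pd.DataFrame:
    """Read a delimited table, sniffing tab vs comma, skipping # comments."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: no data rows")
    sep = "\t" if lines[0].count("\t") >= lines[0].count(",") else ","
    return pd.read_csv(
        _stdio.StringIO("\n".join(lines)), sep=sep, float_precision="round_trip"
    )


def _comment_metadata(path) -> dict:
    """Parse key=value pairs from # comment lines."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].split():
                if "=" in token:
                    key, _, value = token.partition("=")
                    meta[key] = value
    return meta


def write_events(design: TrialDesign, path, seed=None) -> None:
    """BIDS-style events TSV: onset, duration, trial_type, task, cue."""
    rows = [
        {
            "onset": trial.onset_s,
            "duration": 0.0,
            "trial_type": trial.condition,
            "task": trial.task,
            "cue": trial.cue,
        }
        for trial in design.trials
    ]
    frame = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, tr_s=design.tr_s, n_scans=design.n_scans))
        frame.to_csv(fh, sep="\t", index=False)


def read_events(path, tr_s: float | None = None, n_scans: int | None = None) -> TrialDesign:
    """Parse an events table back into a :class:`TrialDesign`.

    Requires onset, duration, and trial_type columns; task defaults to
    alternating with trial_type when absent, and switch/repeat is
    re-derived from the task sequence if only tasks are given.  ``tr_s``
    and ``n_scans`` fall back to the file's provenance header, then to
    TR 2 s with the run sized to fit the last onset plus 24 s.
    """
    frame = _read_table(path)
    missing = [c for c in ("onset", "duration", "trial_type") if c not in frame.columns]
    if missing and "task" not in frame.columns:
        raise ValueError(f"{path}: missing required columns: {', '.join(missing)}")
    meta = _comment_metadata(path)
    if tr_s is None:
        tr_s = float(meta.get("tr_s", 2.0))
    onsets = frame["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError(f"{path}: onsets must be strictly increasing")
    if "task" in frame.columns:
        tasks = [str(t) for t in frame["task"]]
    else:
        # Reconstruct a task sequence consistent with the switch/repeat labels.
        tasks = []
        current = 0
        for t, cond in enumerate(frame["trial_type"]):
            if t > 0 and str(cond) == SWITCH:
                current = 1 - current
            tasks.append(("shape", "color")[current])
    cues = [str(c) for c in frame["cue"]] if "cue" in frame.columns else ["full_word"] * len(tasks)
    conditions = [
        REPEAT if t == 0 else (SWITCH if tasks[t] != tasks[t - 1] else REPEAT)
        for t in range(len(tasks))
    ]
    if "trial_type" in frame.columns:
        stated = [str(c) for c in frame["trial_type"]]
        if stated != conditions:
            raise ValueError(
                f"{path}: trial_type labels inconsistent with the task sequence"
            )
    if n_scans is None:
        if "n_scans" in meta:
            n_scans = int(meta["n_scans"])
        else:
            n_scans = int(np.ceil((onsets[-1] + 24.0) / tr_s))
    trials = [
        Trial(float(onsets[t]), tasks[t], cues[t], conditions[t])
        for t in range(len(tasks))
    ]
    return TrialDesign(trials=trials, tr_s=tr_s, n_scans=n_scans)


def write_confounds(confounds: pd.DataFrame, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed))
        confounds.to_csv(fh, sep="\t", index=False)


def read_confounds(path) -> pd.DataFrame:
    frame = _read_table(path)
    missing = [c for c in CONFOUND_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing confound columns: {', '.join(missing)}")
    return frame[list(CONFOUND_COLUMNS)].astype(float)


def write_matrix(values: np.ndarray, path, labels: list[str] | None = None, seed=None, **meta) -> None:
    """Delimited numeric matrix with a one-line header of ROI labels."""
    values = np.asarray(values)
    if labels is None:
        labels = [f"roi_{i + 1}" for i in range(values.shape[1])]
    frame = pd.DataFrame(values, columns=labels)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, **meta))
        frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_matrix(path, expected_labels: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Read a labeled numeric matrix; exact decimal parse.

    Ragged or non-numeric cells raise with the offending row/column;
    ``expected_labels`` (e.g. from an atlas) validates the shape.
    """
    frame = _read_table(path)
    labels = [str(c) for c in frame.columns]
    for col in frame.columns:
        bad = pd.to_numeric(frame[col], errors="coerce")
        if bad.isna().any() and not frame[col].isna().any():
            row = int(np.flatnonzero(bad.isna())[0])
            raise ValueError(f"{path}: non-numeric cell at row {row + 1}, column {col!r}")
        if frame[col].isna().any():
            row = int(np.flatnonzero(frame[col].isna())[0])
            raise ValueError(f"{path}: missing value at row {row + 1}, column {col!r} (ragged row?)")
    values = frame.to_numpy(dtype=float)
    if expected_labels is not None and len(expected_labels) != len(labels):
        raise ValueError(
            f"{path}: matrix has {len(labels)} columns but {len(expected_labels)} "
            "ROI labels were expected"
        )
    return values, labels


def write_connectivity(matrix: ConnectivityMatrix, path, seed=None) -> None:
    write_matrix(
        matrix.values, path, labels=matrix.roi_labels, seed=seed,
        condition=matrix.condition,
    )


def read_connectivity(path) -> ConnectivityMatrix:
    values, labels = read_matrix(path)
    meta = _comment_metadata(path)
    condition = meta.get("condition")
    return ConnectivityMatrix(values=values, roi_labels=labels, condition=condition)


def write_labels(subject_ids: list[str], groups: list[str], path, seed=None) -> None:
    frame = pd.DataFrame({"subject_id": subject_ids, "group": groups})
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed))
        frame.to_csv(fh, sep="\t", index=False)


def read_labels(path) -> pd.DataFrame:
    frame = _read_table(path)
    missing = [c for c in ("subject_id", "group") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing label columns: {', '.join(missing)}")
    return frame[["subject_id", "group"]]


def read_atlas(path) -> pd.DataFrame:
    """Atlas table: roi_id, x, y, z (MNI mm), network."""
    frame = _read_table(path)
    missing = [c for c in ("roi_id", "x", "y", "z", "network") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing atlas columns: {', '.join(missing)}")
    return frame


def extract_roi_timeseries(img, coordinates_mm: np.ndarray, radius_mm: float = 6.0) -> np.ndarray:
    """Mean time series inside spheres around atlas coordinates.

    Optional utility for 4D NIfTI inputs (requires :mod:`nibabel`);
    ``img`` is a path or a loaded image, ``coordinates_mm`` an
    ``n_rois x 3`` array of MNI coordinates.  Returns
    ``n_scans x n_rois``.  Mean extraction commutes with the linear GLM,
    so running LSS on these averages matches averaging voxelwise betas.
    """
    import nibabel as nib

    if isinstance(img, (str, Path)):
        img = nib.load(str(img))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D image (x, y, z, time)")
    shape = data.shape[:3]
    grid = np.indices(shape).reshape(3, -1)
    world = img.affine[:3, :3] @ grid + img.affine[:3, 3:4]
    out = np.empty((data.shape[3], len(coordinates_mm)))
    flat = data.reshape(-1, data.shape[3])
    for r, center in enumerate(np.asarray(coordinates_mm, dtype=float)):
        mask = np.linalg.norm(world - center[:, None], axis=0) <= radius_mm
        if not mask.any():
            raise ValueError(f"no voxels within {radius_mm} mm of ROI {r + 1}")
        out[:, r] = flat[mask].mean(axis=0)
    return out
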