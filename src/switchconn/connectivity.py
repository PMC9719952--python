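"""Beta-series correlation connectivity and feature vectorization.

Functional connectivity between two regions is the Pearson correlation
of their single-trial amplitude series across the trials of one
condition.  The full matrix over ``n`` regions is symmetric with unit
diagonal; its upper triangle, flattened in row-major order, is the
``n(n-1)/2``-dimensional feature vector fed to classification
(24,531 features for the 222-region parcellation used here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BetaSeries:
    """Trial-by-region single-trial amplitude estimates.

    ``values`` is ``n_trials x n_rois``; ``condition_labels`` tags each
    trial (e.g. switch/repeat) so connectivity can be restricted to one
    condition.
    """

    values: np.ndarray
    condition_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("beta series must be a trials x ROIs matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("beta series contains non-finite values")
        if self.condition_labels is not None and len(self.condition_labels) != self.values.shape[0]:
            raise ValueError("one condition label per trial required")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def select(self, condition: str) -> np.ndarray:
        if self.condition_labels is None:
            raise ValueError("beta series carries no condition labels")
        mask = np.array([c == condition for c in self.condition_labels])
        if not mask.any():
            raise ValueError(f"no trials with condition {condition!r}")
        return self.values[mask]


@dataclass
class ConnectivityMatrix:
    """Symmetric region-by-region Pearson correlation matrix."""

    values: np.ndarray
    roi_labels: list[str]
    condition: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if len(self.roi_labels) != n:
            raise ValueError("one ROI label per row required")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureVector:
    """Upper-triangle FC features with their (i, j) region-pair map."""

    values: np.ndarray
    index_map: list[tuple[int, int]] = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.index_map) != self.values.size:
            raise ValueError("index_map must give one (i, j) pair per feature")


def n_pair_features(n_rois: int) -> int:
    """Number of distinct region pairs, n(n-1)/2."""
    return n_rois * (n_rois - 1) // 2


def beta_series_correlation(
    betas: BetaSeries | np.ndarray,
    condition: str | None = "switch",
    roi_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Pearson correlation of beta series between all region pairs.

    Correlations run across the trials of ``condition`` (pass ``None``
    to pool all trials).  Requires at least 3 trials and nonzero
    variance in every region; a flat region is an error naming the ROI.
    """
    if isinstance(betas, BetaSeries):
        data = betas.select(condition) if condition is not None else betas.values
    else:
        data = np.asarray(betas, dtype=float)
    n_trials, n_rois = data.shape
    if n_trials < 3:
        raise ValueError(
            f"need >= 3 trials to correlate; got {n_trials} for condition {condition!r}"
        )
    labels = roi_labels or [f"roi_{i + 1}" for i in range(n_rois)]
    sd = data.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"zero-variance beta series for ROI(s): {', '.join(labels[i] for i in flat)}"
        )
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, roi_labels=labels, condition=condition)


def upper_triangle_pairs(n: int) -> list[tuple[int, int]]:
    """Row-major (i, j), i < j ordering of region pairs."""
    iu, ju = np.triu_indices(n, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def vectorize_upper_triangle(
    matrix: ConnectivityMatrix | np.ndarray,
    fisher_z: bool = False,
) -> FeatureVector:
    """Flatten the strict upper triangle into a feature vector.

    Ordering is row-major over pairs (i, j), i < j, so position k of a
    ``n x n`` matrix maps deterministically back to a region pair.
    Asymmetry beyond 1e-10 is an error.  ``fisher_z`` applies the
    variance-stabilizing arctanh transform to the correlations (off by
    default: raw Pearson r is the analysis feature).
    """
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("input must be a square matrix")
    if np.abs(values - values.T).max(initial=0.0) > 1e-10:
        raise ValueError("matrix is not symmetric (tolerance 1e-10)")
    iu, ju = np.triu_indices(values.shape[0], k=1)
    vec = values[iu, ju]
    if fisher_z:
        vec = np.arctanh(np.clip(vec, -1 + 1e-15, 1 - 1e-15))
    return FeatureVector(values=vec, index_map=list(zip(iu.tolist(), ju.tolist())))


def devectorize_upper_triangle(vector: FeatureVector | np.ndarray, n_rois: int | None = None) -> np.ndarray:
    """Inverse of :func:`vectorize_upper_triangle`; unit diagonal."""
    vec = vector.values if isinstance(vector, FeatureVector) else np.asarray(vector, dtype=float)
    if n_rois is None:
        n_rois = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if n_pair_features(n_rois) != vec.size:
        raise ValueError(f"vector length {vec.size} does not fit {n_rois} ROIs")
    out = np.eye(n_rois)
    iu, ju = np.triu_indices(n_rois, k=1)
    out[iu, ju] = vec
    out[ju, iu] = vec
    return out


def group_mean_and_difference(
    patients: list[ConnectivityMatrix],
    controls: list[ConnectivityMatrix],
) -> tuple[ConnectivityMatrix, ConnectivityMatrix, ConnectivityMatrix]:
    """Entrywise group means and the control-minus-patient difference."""
    if not patients or not controls:
        raise ValueError("both groups must be nonempty")
    labels = patients[0].roi_labels
    for m in patients + controls:
        if m.roi_labels != labels:
            raise ValueError("all matrices must share the same ROI labels")
    mean_patient = np.mean([m.values for m in patients], axis=0)
    mean_control = np.mean([m.values for m in controls], axis=0)
    diff = mean_control - mean_patient
    cond = patients[0].condition
    return (
        ConnectivityMatrix(mean_patient, list(labels), cond),
        ConnectivityMatrix(mean_control, list(labels), cond),
        ConnectivityMatrix(diff, list(labels), cond),
    )
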