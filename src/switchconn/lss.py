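"""Single-trial response estimation by least-squares separate (LSS).

Each trial's amplitude is estimated from its own ordinary-least-squares
fit whose design holds exactly two task regressors — the trial of
interest and all remaining trials pooled — both built as zero-duration
stick functions at cue onset convolved with a canonical double-gamma
hemodynamic response, plus nuisance regressors (six rigid-body motion
parameters, mean white-matter and CSF signals) and an intercept.
Looping the fit over trials yields the beta series that downstream
connectivity analysis correlates.

Also provides head-motion screening of subjects by peak total
displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .design import TrialDesign

CONFOUND_COLUMNS = (
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
    "white_matter", "csf",
)

INCLUDE = "include"
EXCLUDE = "exclude"


@dataclass(frozen=True)
class HRFModel:
    """Canonical double-gamma hemodynamic response.

    The kernel is the difference of two gamma densities — a positive
    response peaking around ``peak_delay_s`` and an undershoot around
    ``undershoot_delay_s`` scaled down by ``peak_undershoot_ratio`` —
    sampled over ``duration_s`` seconds and normalized to peak 1.
    Defaults are the conventional canonical parameterization
    (peak delay 6 s, undershoot delay 16 s, unit dispersions, ratio 6,
    32 s support).
    """

    tr_s: float = 2.0
    duration_s: float = 32.0
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Unnormalized double-gamma response at times ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        peak = stats.gamma.pdf(
            t, self.peak_delay_s / self.peak_dispersion,
            scale=self.peak_dispersion,
        )
        under = stats.gamma.pdf(
            t, self.undershoot_delay_s / self.undershoot_dispersion,
            scale=self.undershoot_dispersion,
        )
        return peak - under / self.peak_undershoot_ratio


def sample_canonical_hrf(model: HRFModel | None = None, dt: float | None = None) -> np.ndarray:
    """Sample the canonical HRF on a regular grid, peak-normalized to 1.

    ``dt`` defaults to the model's TR; the kernel has
    ``floor(duration_s / dt) + 1`` samples.
    """
    model = model or HRFModel()
    dt = model.tr_s if dt is None else dt
    if dt <= 0 or model.duration_s <= 0:
        raise ValueError("dt and duration_s must be positive")
    n = int(np.floor(model.duration_s / dt)) + 1
    kernel = model.evaluate(np.arange(n) * dt)
    peak = kernel.max()
    if peak <= 0:
        raise ValueError("HRF kernel has non-positive peak")
    return kernel / peak


def single_trial_regressors(
    design: TrialDesign,
    hrf: HRFModel | None = None,
    oversample: int = 16,
) -> np.ndarray:
    """HRF-convolved stick regressor for every trial, one column each.

    Sticks are placed at cue onset (zero duration) on a grid of
    ``tr_s / oversample`` seconds, convolved at that resolution, and
    read out at scan times; returns an ``n_scans x n_trials`` matrix.
    """
    hrf = hrf or HRFModel(tr_s=design.tr_s)
    dt = design.tr_s / oversample
    kernel = sample_canonical_hrf(hrf, dt=dt)
    n_fine = design.n_scans * oversample
    out = np.zeros((design.n_scans, design.n_trials))
    for t, onset in enumerate(design.onsets):
        idx = int(round(onset / dt))
        if not 0 <= idx < n_fine:
            raise ValueError(f"trial {t} onset {onset}s falls outside the run")
        fine = np.zeros(n_fine)
        fine[idx] = 1.0
        conv = np.convolve(fine, kernel)[:n_fine]
        out[:, t] = conv[::oversample]
    return out


def _confound_matrix(confounds) -> tuple[np.ndarray, list[str]]:
    if confounds is None:
        return np.empty((0, 0)), []
    if isinstance(confounds, pd.DataFrame):
        return confounds.to_numpy(dtype=float), [str(c) for c in confounds.columns]
    arr = np.asarray(confounds, dtype=float)
    return arr, [f"confound_{i}" for i in range(arr.shape[1])]


def build_lss_design(
    design: TrialDesign,
    trial_index: int,
    confounds=None,
    n_scans: int | None = None,
    hrf: HRFModel | None = None,
    regressors: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for one trial's LSS fit.

    Columns: the trial of interest, all other trials pooled, the
    confound columns unmodified, and an intercept last.  ``trial_index``
    is 0-based.  ``regressors`` lets callers reuse the output of
    :func:`single_trial_regressors` across trials.
    """
    if not 0 <= trial_index < design.n_trials:
        raise IndexError(
            f"trial_index {trial_index} out of range for {design.n_trials} trials"
        )
    n_scans = design.n_scans if n_scans is None else n_scans
    if regressors is None:
        regressors = single_trial_regressors(design, hrf)
    if regressors.shape[0] != n_scans:
        raise ValueError("regressor rows do not match n_scans")
    this = regressors[:, trial_index]
    others = regressors.sum(axis=1) - this
    conf, conf_names = _confound_matrix(confounds)
    cols = [this, others]
    names = [f"trial_{trial_index}", "other_trials"]
    if conf_names:
        if conf.shape[0] != n_scans:
            raise ValueError("confound rows do not match n_scans")
        cols.extend(conf.T)
        names.extend(conf_names)
    cols.append(np.ones(n_scans))
    names.append("intercept")
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = sorted(names[j] for j in piv[rank:])
        raise np.linalg.LinAlgError(
            f"rank-deficient LSS design; collinear columns: {', '.join(bad)}"
        )


def estimate_beta_series(
    timeseries: np.ndarray,
    design: TrialDesign,
    confounds=None,
    hrf: HRFModel | None = None,
):
    """Estimate per-trial amplitudes for every ROI by LSS.

    For each trial a separate OLS fit of every ROI's time series on
    :func:`build_lss_design` is computed and the trial-of-interest
    coefficient kept, giving a ``n_trials x n_rois`` beta matrix.
    Deterministic; raises on non-finite data or a rank-deficient design
    (naming the collinear columns).
    """
    from .connectivity import BetaSeries

    Y = np.asarray(timeseries, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not np.all(np.isfinite(Y)):
        raise ValueError("timeseries contains non-finite values")
    if Y.shape[0] != design.n_scans:
        raise ValueError(
            f"timeseries has {Y.shape[0]} scans, design expects {design.n_scans}"
        )
    regressors = single_trial_regressors(design, hrf)
    betas = np.empty((design.n_trials, Y.shape[1]))
    for t in range(design.n_trials):
        X, names = build_lss_design(
            design, t, confounds=confounds, hrf=hrf, regressors=regressors
        )
        _check_full_rank(X, names)
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        betas[t] = coef[0]
    return BetaSeries(values=betas, condition_labels=list(design.conditions))


def screen_motion(motion: np.ndarray, threshold_mm: float = 3.0) -> str:
    """Head-motion screening by peak total displacement.

    ``motion`` is ``n_scans x 6`` (translations in mm, rotations in rad).
    Total displacement is the maximum over scans of the Euclidean norm of
    the three translations relative to the first (reference) scan;
    rotations are ignored.  Returns ``"exclude"`` iff it strictly
    exceeds ``threshold_mm``.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(
            f"motion must have 6 columns (3 translations, 3 rotations); "
            f"got shape {motion.shape}"
        )
    translations = motion[:, :3] - motion[0, :3]
    displacement = np.linalg.norm(translations, axis=1).max()
    return EXCLUDE if displacement > threshold_mm else INCLUDE
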