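"""Synthetic two-group cohorts for the task-switching connectivity pipeline.

Emulates the study conditions end to end without any imaging data: a
96-trial cued task-switching run, trial-wise responses for 222 regions
in two cohorts of 46 subjects, behavioral performance with a patient
deficit, realistic-scale head motion, and — for testing the single-trial
estimator — raw ROI time series built from HRF-convolved sticks plus
noise.

Trial-wise responses are drawn from a zero-mean multivariate normal
whose correlation follows a modular block structure: ``within_r``
between regions sharing a community, ``between_r`` otherwise, with the
patient group's blocks offset by ``group_delta_within`` /
``group_delta_between``.  This places the group difference in the
connectivity *pattern* — exactly the signal the downstream classifier
and network-efficiency analyses are meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TrialDesign, generate_task_design
from .lss import CONFOUND_COLUMNS, HRFModel, single_trial_regressors

CONTROL = "control"
PATIENT = "patient"


@dataclass
class SimulationConfig:
    """Cohort-level generating parameters.

    Defaults mirror the emulated study: two groups of 46 subjects, 222
    regions in 10 communities, a 96-trial run.  ``within_r`` /
    ``between_r`` set the control group's block correlations; the
    patient group's are offset by the ``group_delta_*`` terms.
    ``noise_sd`` scales response amplitudes (arbitrary units).
    Behavioral defaults give controls ~800 ms mean RT and ~94% accuracy
    with patients slower and less accurate, the qualitative deficit seen
    in cued task-switching.
    """

    n_per_group: int = 46
    n_rois: int = 222
    n_trials: int = 96
    n_modules: int = 10
    module_assignment: np.ndarray | None = None
    within_r: float = 0.5
    between_r: float = 0.1
    group_delta_within: float = 0.0
    group_delta_between: float = 0.0
    noise_sd: float = 1.0
    rt_control_mean_ms: float = 800.0
    rt_sd_ms: float = 100.0
    rt_patient_shift_ms: float = 120.0
    accuracy_control_mean: float = 0.94
    accuracy_patient_mean: float = 0.87
    accuracy_concentration: float = 50.0
    motion_step_mm: float = 0.01
    motion_step_rad: float = 0.0005
    seed: int | None = 0

    def __post_init__(self) -> None:
        for name in ("within_r", "between_r"):
            r = getattr(self, name)
            if not -1 < r < 1:
                raise ValueError(f"{name} must lie in (-1, 1); got {r}")
        for name, delta in (
            ("group_delta_within", self.group_delta_within),
            ("group_delta_between", self.group_delta_between),
        ):
            base = self.within_r if "within" in name else self.between_r
            if not -1 < base + delta < 1:
                raise ValueError(f"{name} pushes the target correlation outside (-1, 1)")
        if self.module_assignment is None:
            # small ROI counts cannot host the full default module count
            self.n_modules = min(self.n_modules, self.n_rois)
            self.module_assignment = default_module_assignment(self.n_rois, self.n_modules)
        else:
            self.module_assignment = np.asarray(self.module_assignment)
            if self.module_assignment.shape != (self.n_rois,):
                raise ValueError("module_assignment must give one label per ROI")


@dataclass
class SubjectRecord:
    """One simulated subject: betas, behavior, and motion traces."""

    subject_id: str
    group: str
    beta_series: np.ndarray
    mean_rt_ms: float
    accuracy_fraction: float
    motion: np.ndarray

    def __post_init__(self) -> None:
        if not 0 <= self.accuracy_fraction <= 1:
            raise ValueError("accuracy_fraction must lie in [0, 1]")


def default_module_assignment(n_rois: int, n_modules: int = 10) -> np.ndarray:
    """Contiguous, near-equal community blocks (module ids 0..n_modules-1)."""
    if not 1 <= n_modules <= n_rois:
        raise ValueError("need 1 <= n_modules <= n_rois")
    sizes = np.full(n_modules, n_rois // n_modules)
    sizes[: n_rois % n_modules] += 1
    return np.repeat(np.arange(n_modules), sizes)


def block_correlation_matrix(
    module_assignment: np.ndarray,
    within_r: float,
    between_r: float,
    clip_eps: float = 1e-10,
    psd_tol: float = 1e-8,
) -> np.ndarray:
    """Modular target correlation matrix, repaired to PSD if needed.

    Repair clips negative eigenvalues to ``clip_eps`` and renormalizes
    to unit diagonal; a matrix still indefinite beyond ``psd_tol`` after
    repair is an error.
    """
    modules = np.asarray(module_assignment)
    same = modules[:, None] == modules[None, :]
    corr = np.where(same, within_r, between_r).astype(float)
    np.fill_diagonal(corr, 1.0)
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < 0:
        w, v = np.linalg.eigh(corr)
        corr = (v * np.clip(w, clip_eps, None)) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        if np.linalg.eigvalsh(corr).min() < -psd_tol:
            raise ValueError("covariance repair failed to reach positive semidefiniteness")
    return corr


def _sample_betas(rng: np.random.Generator, corr: np.ndarray, n_trials: int, noise_sd: float) -> np.ndarray:
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    z = rng.standard_normal((n_trials, corr.shape[0]))
    return noise_sd * (z @ L.T)


def generate_group_beta_series(
    config: SimulationConfig,
    design: TrialDesign | None = None,
) -> list[SubjectRecord]:
    """Simulate both cohorts' trial-wise region responses and behavior.

    Controls are listed first, then patients.  Each subject's beta rows
    are i.i.d. draws from the group's block-structured multivariate
    normal; RT is Gaussian with a patient shift, accuracy
    Beta-distributed with a lower patient mean, and motion a small
    random walk.  Fully reproducible from ``config.seed``.
    """
    if design is None:
        design = generate_task_design(n_trials=config.n_trials, seed=config.seed)
    if design.n_trials != config.n_trials:
        raise ValueError(
            f"design has {design.n_trials} trials but config expects {config.n_trials}"
        )
    corr = {
        CONTROL: block_correlation_matrix(
            config.module_assignment, config.within_r, config.between_r
        ),
        PATIENT: block_correlation_matrix(
            config.module_assignment,
            config.within_r + config.group_delta_within,
            config.between_r + config.group_delta_between,
        ),
    }
    rng = np.random.default_rng(config.seed)
    records: list[SubjectRecord] = []
    for group, prefix in ((CONTROL, "C"), (PATIENT, "P")):
        rt_mean = config.rt_control_mean_ms + (
            config.rt_patient_shift_ms if group == PATIENT else 0.0
        )
        acc_mean = (
            config.accuracy_patient_mean if group == PATIENT else config.accuracy_control_mean
        )
        a = acc_mean * config.accuracy_concentration
        b = (1 - acc_mean) * config.accuracy_concentration
        for s in range(config.n_per_group):
            betas = _sample_betas(rng, corr[group], config.n_trials, config.noise_sd)
            rt = rng.normal(rt_mean, config.rt_sd_ms)
            acc = float(np.clip(rng.beta(a, b), 0.0, 1.0))
            steps = np.column_stack([
                rng.normal(0, config.motion_step_mm, size=(design.n_scans, 3)),
                rng.normal(0, config.motion_step_rad, size=(design.n_scans, 3)),
            ])
            motion = np.cumsum(steps, axis=0)
            motion -= motion[0]
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{prefix}{s + 1:02d}",
                    group=group,
                    beta_series=betas,
                    mean_rt_ms=float(rt),
                    accuracy_fraction=acc,
                    motion=motion,
                )
            )
    return records


def simulate_confounds(
    n_scans: int,
    seed: int | np.random.Generator | None = None,
    motion: np.ndarray | None = None,
    tr_s: float = 2.0,
) -> pd.DataFrame:
    """Nuisance table: 6 motion parameters plus WM/CSF mean signals.

    Motion defaults to a small random walk; WM and CSF are slow
    sinusoidal drifts plus white noise, standardized to unit variance.
    """
    rng = np.random.default_rng(seed)
    if motion is None:
        steps = np.column_stack([
            rng.normal(0, 0.01, size=(n_scans, 3)),
            rng.normal(0, 0.0005, size=(n_scans, 3)),
        ])
        motion = np.cumsum(steps, axis=0)
        motion -= motion[0]
    t = np.arange(n_scans) * tr_s
    tissue = []
    for period in (120.0, 90.0):
        drift = np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
        sig = drift + rng.normal(0, 0.5, size=n_scans)
        tissue.append((sig - sig.mean()) / sig.std())
    data = np.column_stack([motion, *[c[:, None] for c in tissue]])
    return pd.DataFrame(data, columns=list(CONFOUND_COLUMNS))


def generate_bold_timeseries(
    design: TrialDesign,
    true_amplitudes: np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator | None = None,
    hrf: HRFModel | None = None,
    confounds: pd.DataFrame | None = None,
    confound_leak: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Raw ROI time series from trial amplitudes.

    Each region's series is the sum over trials of its amplitude times
    the HRF-convolved stick at that trial's onset, plus optional leakage
    of the confound signals (coefficient ``confound_leak`` per column)
    and i.i.d. Gaussian noise of standard deviation ``noise_sd``.
    Returns the ``n_scans x n_rois`` series and the confound table.
    """
    amplitudes = np.atleast_2d(np.asarray(true_amplitudes, dtype=float))
    if amplitudes.shape[0] != design.n_trials:
        raise ValueError(
            f"true_amplitudes has {amplitudes.shape[0]} rows, design has "
            f"{design.n_trials} trials"
        )
    rng = np.random.default_rng(seed)
    regressors = single_trial_regressors(design, hrf)
    series = regressors @ amplitudes
    if confounds is None:
        confounds = simulate_confounds(design.n_scans, seed=rng, tr_s=design.tr_s)
    if confound_leak != 0.0:
        series = series + confound_leak * confounds.to_numpy().sum(axis=1, keepdims=True)
    if noise_sd > 0:
        series = series + rng.normal(0, noise_sd, size=series.shape)
    return series, confounds
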