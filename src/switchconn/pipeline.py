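"""End-to-end pipeline: simulate -> betas -> connectivity -> MVPA + graphs.

Runs the whole analysis on a synthetic two-group cohort: generate the
cued task-switching design and trial-wise region responses, optionally
push them through BOLD simulation and LSS re-estimation, build
switch-condition beta-series correlation matrices, classify groups from
the FC features with fold-wise F-score selection and a linear SVM
(LOOCV + permutation null), and compare weighted-network efficiency
AUCs between groups.  All randomness flows from one top-level seed via
named substreams, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import efficiency as eff
from . import io as scio
from . import mvpa
from .design import generate_task_design
from .lss import HRFModel, estimate_beta_series
from .simulate import (
    CONTROL,
    PATIENT,
    SimulationConfig,
    generate_bold_timeseries,
    generate_group_beta_series,
)

_SUBSTREAMS = ("design", "cohort", "bold", "permutation")


@dataclass
class PipelineConfig:
    """Everything needed for one deterministic end-to-end run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_switch: int = 24
    condition: str = "switch"
    via_bold: bool = False
    bold_noise_sd: float = 1.0
    grid_start: int = 20
    grid_step: int = 20
    feature_count: int | None = None
    n_permutations: int = 1000
    sparsity_min: float = 0.05
    sparsity_max: float = 0.50
    sparsity_step: float = 0.05
    fisher_z: bool = False
    seed: int = 0
    out_dir: str | Path | None = None
    write_matrices: bool = False

    def sparsities(self) -> np.ndarray:
        n = int(round((self.sparsity_max - self.sparsity_min) / self.sparsity_step)) + 1
        return np.round(self.sparsity_min + np.arange(n) * self.sparsity_step, 10)

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["simulation"]["module_assignment"] = None  # derived, not configuration
        out["out_dir"] = None  # where outputs land is not part of the analysis identity
        return out


@dataclass
class RunReport:
    """Summary of one pipeline run; every number is recomputable from
    the machine-readable outputs written next to it."""

    config: dict
    seed: int
    config_hash: str
    rt_comparison: eff.GroupComparison
    accuracy_comparison: eff.GroupComparison
    classification: mvpa.ClassificationResult
    permutation: mvpa.PermutationResult | None
    eg_comparison: eff.GroupComparison
    eloc_comparison: eff.GroupComparison

    def to_dict(self) -> dict:
        def comp(c: eff.GroupComparison) -> dict:
            return {
                "t": c.t_statistic, "df": c.degrees_of_freedom, "p": c.p_value,
                "mean_patient": c.mean_a, "mean_control": c.mean_b,
                "sd_patient": c.sd_a, "sd_control": c.sd_b,
            }

        cls = self.classification
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "behavior": {"rt_ms": comp(self.rt_comparison),
                         "accuracy": comp(self.accuracy_comparison)},
            "classification": {
                "selected_feature_count": cls.selected_feature_count,
                "accuracy_percent": cls.accuracy,
                "sensitivity_percent": cls.sensitivity,
                "specificity_percent": cls.specificity,
                "auc": cls.auc,
            },
            "permutation_p": None if self.permutation is None else self.permutation.p_value,
            "network": {"eg_auc": comp(self.eg_comparison),
                        "eloc_auc": comp(self.eloc_comparison)},
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            f"switchconn run (seed {self.seed}, config {self.config_hash})",
            "",
            "Behavior (patient vs control, pooled t):",
            f"  RT:       t({d['behavior']['rt_ms']['df']}) = "
            f"{d['behavior']['rt_ms']['t']:.2f}, p = {d['behavior']['rt_ms']['p']:.4g}",
            f"  Accuracy: t({d['behavior']['accuracy']['df']}) = "
            f"{d['behavior']['accuracy']['t']:.2f}, p = {d['behavior']['accuracy']['p']:.4g}",
            "",
            "Classification (LOOCV, linear SVM, F-score selection):",
            f"  selected features: {d['classification']['selected_feature_count']}",
            f"  accuracy = {d['classification']['accuracy_percent']:.2f}%  "
            f"sensitivity = {d['classification']['sensitivity_percent']:.2f}%  "
            f"specificity = {d['classification']['specificity_percent']:.2f}%  "
            f"AUC = {d['classification']['auc']:.4f}",
        ]
        if d["permutation_p"] is not None:
            lines.append(f"  permutation p = {d['permutation_p']:.4g}")
        net = d["network"]
        lines += [
            "",
            "Network efficiency AUC (patient vs control, pooled t):",
            f"  global: t({net['eg_auc']['df']}) = {net['eg_auc']['t']:.2f}, "
            f"p = {net['eg_auc']['p']:.4g}",
            f"  local:  t({net['eloc_auc']['df']}) = {net['eloc_auc']['t']:.2f}, "
            f"p = {net['eloc_auc']['p']:.4g}",
        ]
        return "\n".join(lines)


def _substreams(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return dict(zip(_SUBSTREAMS, children))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and (optionally) write all artifacts."""
    streams = _substreams(config.seed)
    sim = dataclasses.replace(
        config.simulation,
        seed=int(np.random.default_rng(streams["cohort"]).integers(2**31)),
    )
    design = generate_task_design(
        n_trials=sim.n_trials,
        n_switch=config.n_switch,
        seed=np.random.default_rng(streams["design"]),
    )
    cohort = generate_group_beta_series(sim, design)

    if config.via_bold:
        # Round-trip through raw time series and LSS re-estimation.
        bold_rng = np.random.default_rng(streams["bold"])
        hrf = HRFModel(tr_s=design.tr_s)
        for record in cohort:
            series, confounds = generate_bold_timeseries(
                design, record.beta_series, config.bold_noise_sd, seed=bold_rng, hrf=hrf
            )
            betas = estimate_beta_series(series, design, confounds=confounds, hrf=hrf)
            record.beta_series = betas.values

    matrices = {
        record.subject_id: conn.beta_series_correlation(
            conn.BetaSeries(record.beta_series, list(design.conditions)),
            condition=config.condition,
        )
        for record in cohort
    }
    features = np.vstack([
        conn.vectorize_upper_triangle(matrices[r.subject_id], fisher_z=config.fisher_z).values
        for r in cohort
    ])
    labels = np.array([r.group for r in cohort])

    patients = [r for r in cohort if r.group == PATIENT]
    controls = [r for r in cohort if r.group == CONTROL]
    rt_cmp = eff.compare_groups(
        [r.mean_rt_ms for r in patients], [r.mean_rt_ms for r in controls]
    )
    acc_cmp = eff.compare_groups(
        [r.accuracy_fraction for r in patients], [r.accuracy_fraction for r in controls]
    )

    if config.feature_count is not None:
        records = mvpa.loocv_classify(features, labels, config.feature_count)
        accuracy, sensitivity, specificity = mvpa.classification_metrics(records)
        _, auc = mvpa.roc_curve_auc(records)
        classification = mvpa.ClassificationResult(
            records=records,
            selected_feature_count=config.feature_count,
            accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
            auc=auc,
            feature_counts=np.array([config.feature_count]),
            accuracy_by_feature_count=np.array([accuracy]),
        )
    else:
        classification = mvpa.sweep_feature_counts(
            features, labels, grid_start=config.grid_start, grid_step=config.grid_step
        )

    permutation = None
    if config.n_permutations > 0:
        permutation = mvpa.permutation_test(
            features, labels,
            k_selected=classification.selected_feature_count,
            n_permutations=config.n_permutations,
            seed=int(np.random.default_rng(streams["permutation"]).integers(2**31)),
            observed_accuracy=classification.accuracy,
        )

    sparsities = config.sparsities()
    curves = {
        r.subject_id: eff.efficiency_curve(matrices[r.subject_id], sparsities)
        for r in cohort
    }
    eg_cmp = eff.compare_groups(
        [curves[r.subject_id].eg_auc for r in patients],
        [curves[r.subject_id].eg_auc for r in controls],
    )
    eloc_cmp = eff.compare_groups(
        [curves[r.subject_id].eloc_auc for r in patients],
        [curves[r.subject_id].eloc_auc for r in controls],
    )

    cfg_dict = config.as_dict()
    report = RunReport(
        config=cfg_dict,
        seed=config.seed,
        config_hash=scio.config_hash(cfg_dict),
        rt_comparison=rt_cmp,
        accuracy_comparison=acc_cmp,
        classification=classification,
        permutation=permutation,
        eg_comparison=eg_cmp,
        eloc_comparison=eloc_cmp,
    )

    if config.out_dir is not None:
        _write_outputs(config, design, cohort, matrices, classification,
                       permutation, curves, report)
    return report


def _write_outputs(config, design, cohort, matrices, classification,
                   permutation, curves, report) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    scio.write_events(design, out / "events.tsv", seed=seed)
    scio.write_labels(
        [r.subject_id for r in cohort], [r.group for r in cohort],
        out / "labels.tsv", seed=seed,
    )
    behavior = pd.DataFrame({
        "subject_id": [r.subject_id for r in cohort],
        "group": [r.group for r in cohort],
        "mean_rt_ms": [r.mean_rt_ms for r in cohort],
        "accuracy_fraction": [r.accuracy_fraction for r in cohort],
    })
    with open(out / "behavior.tsv", "w") as fh:
        fh.write(scio.provenance_header(seed=seed))
        behavior.to_csv(fh, sep="\t", index=False)

    if config.write_matrices:
        mdir = out / "connectivity"
        mdir.mkdir(exist_ok=True)
        for sid, matrix in matrices.items():
            scio.write_connectivity(matrix, mdir / f"{sid}.tsv", seed=seed)

    sweep = pd.DataFrame({
        "feature_count": classification.feature_counts,
        "accuracy_percent": classification.accuracy_by_feature_count,
    })
    with open(out / "sweep.tsv", "w") as fh:
        fh.write(scio.provenance_header(seed=seed))
        sweep.to_csv(fh, sep="\t", index=False)

    records = pd.DataFrame([
        {"subject_id": cohort[r.subject].subject_id, "true_label": r.true_label,
         "predicted_label": r.predicted_label, "decision_score": r.decision_score}
        for r in classification.records
    ])
    with open(out / "predictions.tsv", "w") as fh:
        fh.write(scio.provenance_header(
            seed=seed, selected_k=classification.selected_feature_count))
        records.to_csv(fh, sep="\t", index=False)

    points, _ = mvpa.roc_curve_auc(classification.records)
    roc = pd.DataFrame(points, columns=["fpr", "tpr"])
    with open(out / "roc.tsv", "w") as fh:
        fh.write(scio.provenance_header(seed=seed, auc=f"{classification.auc:.6f}"))
        roc.to_csv(fh, sep="\t", index=False)

    if permutation is not None:
        null = pd.DataFrame({"null_accuracy_percent": permutation.null_accuracies})
        with open(out / "null_accuracies.tsv", "w") as fh:
            fh.write(scio.provenance_header(
                seed=seed, observed=f"{permutation.observed_accuracy:.4f}",
                p=f"{permutation.p_value:.6f}"))
            null.to_csv(fh, sep="\t", index=False)

    rows = []
    for r in cohort:
        curve = curves[r.subject_id]
        for s, eg, el in zip(curve.sparsities, curve.eg_values, curve.eloc_values):
            rows.append({"subject_id": r.subject_id, "group": r.group,
                         "sparsity": s, "eg": eg, "eloc": el})
    with open(out / "efficiency_curves.tsv", "w") as fh:
        fh.write(scio.provenance_header(seed=seed))
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)

    auc_rows = pd.DataFrame({
        "subject_id": [r.subject_id for r in cohort],
        "group": [r.group for r in cohort],
        "eg_auc": [curves[r.subject_id].eg_auc for r in cohort],
        "eloc_auc": [curves[r.subject_id].eloc_auc for r in cohort],
    })
    with open(out / "efficiency_auc.tsv", "w") as fh:
        fh.write(scio.provenance_header(seed=seed))
        auc_rows.to_csv(fh, sep="\t", index=False)

    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    (out / "report.txt").write_text(report.summary() + "\n")
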