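# Methods

`switchconn` implements a task-based functional-connectivity analysis of
cued task-switching fMRI in two groups (schizophrenia patients vs.
healthy controls), from single-trial response estimation through
connectome classification and weighted-network efficiency. This note
documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic cohorts do and do not
establish.

## Task design

The paradigm is cued task-switching between a shape and a color
judgement: 96 trials, of which 24 are *switch* trials (cued task differs
from the previous trial) and 72 are *repeat* trials. The first trial has
no predecessor and is counted as a repeat, so the two condition counts
always partition the run exactly. The generator chooses which of the 95
transitions switch (uniformly at random without replacement given the
seed), derives the task sequence from a random starting task, and draws
each cue form (full word vs. single letter) independently.

Trial timing is not part of the emulated protocol's public description,
so the generator uses a jittered onset grid: mean inter-trial interval
6 s (uniform jitter ±1 s), first onset at 6 s, TR 2 s, and 24 s of rest
after the last onset. These are ordinary slow event-related values;
every one of them is a parameter of `generate_task_design`.

## Synthetic cohorts

`generate_group_beta_series` draws each subject's trial-by-region
response matrix i.i.d. across trials from a zero-mean multivariate
normal with a modular correlation structure: correlation `within_r`
(default 0.5) between regions in the same community, `between_r`
(default 0.1) otherwise, over 222 regions in 10 contiguous communities
(mirroring a 222-node, 10-network functional parcellation). The patient
group's blocks are offset by `group_delta_within` / `group_delta_between`,
placing the group difference in the *connectivity pattern* — the signal
the classifier and the efficiency analysis are designed to detect. If
the requested block matrix is not positive semidefinite, negative
eigenvalues are clipped to 1e-10 and the matrix renormalized to unit
diagonal; failure to reach PSD after repair is an error.

Behavioral performance is generated with a qualitative patient deficit:
mean RT Normal(800, 100) ms for controls, +120 ms for patients; accuracy
Beta-distributed with means 0.94 (controls) and 0.87 (patients) at
concentration 50. Motion traces are Gaussian random walks (0.01 mm /
0.0005 rad per scan), small enough that simulated subjects pass the
3 mm screening. These values are cohort-level conventions chosen once
to produce the qualitative group effects reported for this paradigm;
they are not fit to any dataset.

What the generator does *not* emulate: hemodynamic nonlinearity,
physiological and scanner noise spectra (1/f drift, spikes), spatial
autocorrelation between neighboring regions, trial-order effects
(switch cost dynamics), or heterogeneity across patients. Passing tests
on these cohorts therefore demonstrates the correctness and statistical
calibration of the *pipeline*, not expected performance on real data.

## Single-trial estimation (LSS)

Each trial's amplitude comes from its own OLS fit with two task
regressors — the trial of interest and all remaining trials pooled —
both zero-duration sticks at cue onset convolved with the canonical
double-gamma HRF (peak delay 6 s, undershoot delay 16 s, unit
dispersions, peak:undershoot ratio 6, 32 s support, peak-normalized),
plus six motion parameters, white-matter and CSF means, and an
intercept. Convolution is done on a 16× oversampled grid and read out
at scan times. The solver checks rank by pivoted QR and names the
collinear columns rather than silently pseudo-inverting.

A property worth knowing when interpreting recovery tests: the pooled
"all other trials" regressor represents heterogeneous other-trial
amplitudes by a single coefficient. When all trials share an identical
sampled kernel (onsets on the scan grid, kernels untruncated by the run
end) and do not overlap, the misfit is exactly absorbed and LSS equals
the one-regressor-per-trial GLM to machine precision. Onset jitter
(different subsample phases), kernel truncation, or extra nuisance
columns each break that exact absorption and leave a small bias even at
zero overlap — with overlapping trials (ITI below the 32 s kernel
support) the approximation error is the familiar LSS trade-off. The
exactness tests accordingly use grid-aligned, widely spaced, fully
contained trials; noisy-recovery tests report correlation with truth.

Motion screening follows a peak-displacement rule: a subject is
excluded when the maximum over scans of the Euclidean norm of the three
translations relative to the first scan strictly exceeds 3 mm.
Rotations are not converted to displacement.

## Connectivity features

Functional connectivity is the Pearson correlation of two regions'
beta series across the trials of one condition (default: the 24 switch
trials; pooling or the repeat condition are parameters). Correlations
are used raw — no Fisher z by default (`fisher_z=True` is available) —
and the strict upper triangle in row-major (i<j) order forms the
feature vector: 222 regions give (222·221)/2 = 24,531 features.
Degenerate inputs fail loudly: fewer than 3 trials, or a zero-variance
region (named in the error).

## Classification

A linear support-vector machine (hinge loss, C = 1) discriminates
patients (positive class) from controls under leave-one-out
cross-validation. Within each training fold, features are ranked by the
F-score

    F(i) = [(m_i+ − m_i)² + (m_i− − m_i)²] / (s²_i+ + s²_i−)

with class sample variances (n−1 denominators); ties rank by ascending
feature index, and a zero denominator with a positive numerator scores
+inf (a feature constant within each class but separated between them
is maximally discriminative). The held-out subject never contributes to
ranking or to the standardization (training-fold mean/SD; a flag
disables scaling). Internally the fold rankings are computed by
leave-one-out updates of per-class sums and sums of squares, which is
algebraically the training-fold F-score at O(features) per fold.

The feature count is selected by sweeping a grid (default 20 up to one
step below the dimension, step 20 — 1,226 values for 24,531 features)
and taking the *smallest* count attaining the maximum LOOCV accuracy.
Performance is summarized as accuracy, sensitivity, specificity (in
percent) and the ROC AUC computed from each subject's signed decision
score; the AUC equals the Mann–Whitney probability that a random
patient outscores a random control, ties counted ½.

Significance uses a label-permutation null: each permutation shuffles
group labels and reruns the full LOOCV procedure at the fixed selected
feature count; p is the fraction of permutations whose accuracy
*strictly* exceeds the observed one (no +1 correction, so p = 0 and
p = 1 are attainable boundary values by design). Re-running the entire
feature-count sweep inside every permutation is available behind the
pipeline's configuration but is not the default, which keeps 1,000
permutations tractable.

## Network efficiency

Each subject's FC matrix becomes a weighted undirected graph: diagonal
removed and negative correlations set to zero, since the efficiency
formulas require nonnegative weights (absolute-value handling is
available behind a flag). The graph is thresholded at sparsity levels
5–50% in 5% steps — sparsity being the proportion of strongest edges
retained among n(n−1)/2, with round-half-away-from-zero edge counts and
ties broken by ascending node-pair index. Edge length is 1/weight, the
standard convention for weighted efficiency.

Global efficiency is the mean inverse shortest path length over node
pairs (unreachable pairs contribute 0); a complete unit-weight graph
scores exactly 1. Local efficiency of node i sums
(w_ij · w_ih / d_jh(N_i))^{1/3} over neighbor pairs, normalized by
k_i(k_i−1), where d_jh(N_i) is the shortest path restricted to the
subgraph induced by i's neighbors — paths may not leave the neighbor
set — and nodes with fewer than two neighbors contribute 0. Shortest
paths use scipy's csgraph (Dijkstra for the full graph; Floyd–Warshall
on the many small dense neighbor subgraphs, where its per-call overhead
is lower). Both metrics are validated against independent
path-enumeration oracles on random graphs.

Each metric's curve over the sparsity sweep is summarized by its
trapezoidal area (units: metric × sparsity-width, axis 0.05–0.50), and
group AUCs are compared with a pooled-variance two-sample t-test
(df = n₁+n₂−2, so 46+46 subjects give df = 90). No correction is
applied across the two metrics. Behavioral RT and accuracy use the same
test.

## Pipeline and determinism

`run_pipeline` chains the stages — design, cohort, (optionally BOLD
simulation + LSS re-estimation), switch-condition connectivity,
classification with permutation test, efficiency comparison — and
writes every intermediate as headered TSV plus a JSON/text report. All
randomness derives from one seed through named `SeedSequence`
substreams; outputs carry a provenance header (package version, seed,
config hash) and contain no timestamps, so a rerun with the same
configuration is byte-identical. The default pipeline consumes the
generator's beta series directly; the BOLD+LSS round-trip is a
configuration flag because at 92 subjects × 96 trials it dominates run
time without changing the downstream analysis contract.

## Problem sizes used in the tests

The test suite exercises the full study geometry where the check needs
it (46+46 subjects, 222 regions, 24 switch trials for effect recovery;
1,226-point grid arithmetic) and smaller geometries elsewhere:
chance-level calibration uses 20+20 subjects × 500 noise features over
50 seeds with 99-permutation nulls; feature-count selection in the
effect-recovery test uses a coarse grid (step 4,000) with the
permutation null at the selected count (200 permutations); pipeline
calibration uses 8+8-subject null cohorts over 20 seeds. Monte-Carlo
recovery of generator correlations uses 500 trials (tolerance 0.05,
matching the sampling error at that size).

## Known limitations

- The LSS equivalence/exactness conditions above mean noiseless
  recovery is exact only for grid-aligned, non-overlapping, fully
  contained trials; realistic jittered designs estimate with small
  bias, as the method does in practice.
- Negative-correlation handling (zeroing) discards anticorrelation
  structure; the absolute-value flag changes the graphs materially.
- The permutation default (fixed selected k) is anti-conservative
  relative to permuting the whole selection sweep when the sweep
  overfits; the full-sweep variant is available but expensive.
- ROI extraction from volumes is a convenience utility (sphere means);
  it does no preprocessing of any kind.
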