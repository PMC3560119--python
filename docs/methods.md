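# Methods

## Problem setting

After an oral squamous cell carcinoma reaches remission, the clinical
question is whether — and roughly when — the disease will relapse within
the two-year follow-up. The package models this with two complementary
analyses over four data sources collected at the baseline visit (clinical
record, CT/MR-derived imaging features, tumor-tissue expression, blood
expression) plus blood expression repeated at three ordered visits
(baseline, follow-up #1, follow-up #2). Visits are treated as ordinal
slices only; no calendar spacing is modeled, because the follow-up design
fixes only their order.

## Baseline classification arm

**Cleaning.** A feature is dropped when its missing fraction strictly
exceeds 0.9; remaining gaps are imputed with the column mode (nominal) or
mean (numeric). Imputation precedes SMOTE because interpolation requires
complete numeric vectors. Missingness is assumed uninformative
(missing-completely-at-random), which is exactly what mode/mean imputation
can absorb — the synthetic generator injects missingness the same way.

**Probe QC.** Control probes, all but the first member of each duplicate
group, quality-flagged probes, and probes with more than 50% missing
intensities are removed. The 0.5 probe cutoff is a package default
(configurable): the >0.9 rule is specified for clinical features only, and
array probes warrant a stricter standard. Duplicate resolution keeps the
first occurrence — a deterministic rule; averaging is available as an
option at the call site by pre-aggregating.

**SMOTE.** The minority class is oversampled to a target minority:majority
ratio (default parity). Each synthetic sample interpolates a random
minority seed toward one of its k = 5 nearest minority neighbors —
Euclidean distance over standardized numeric features, nominal features
copied from the seed and excluded from the metric. k = 5 is the original
SMOTE convention; the mixed-metric choice is ours. Inside any
cross-validated evaluation SMOTE is refit on each training fold only;
applying it before the split would leak interpolated copies of test
patients into training.

**Gene ranking (SAM).** The moderated statistic uses the pooled standard
error plus an exchangeability constant s0, set to the median (configurable
quantile) of the per-gene standard errors rather than SAM's full
minimization grid — a documented simplification that preserves the
statistic's shape. Null distributions come from class-label permutations:
when the number of distinct relabelings C(n, n1) is within the requested
permutation budget the enumeration is exhaustive, otherwise relabelings are
sampled. P-values are computed against the null pooled over genes
(add-one smoothed) and made monotone by step-up adjustment. Fold change is
the linear-scale ratio of class means (values are log2 intensities), and
selection is two-sided: `max(r, 1/r) ≥ 1.8` by default, with `q ≤ 0.05`
(the q-cutoff companion to the 1.8 threshold is a package default, not a
literature value). The time-course variant first collapses each
patient × gene trajectory to its signed trapezoidal area (a least-squares
slope is available as an alternative summary), then compares groups with a
Wilcoxon rank-sum using midranks and the tie-corrected variance, with
q-values again by group-label permutation.

**Feature selection.** CFS scores a subset by
`k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)` where correlations are symmetrical
uncertainties over equal-frequency-discretized (4 bins) columns, and is
driven by a forward best-first search with a stall limit of 5 non-improving
expansions — the conventional toolkit defaults. The wrapper selector runs
the same search but scores subsets by 5-fold stratified CV accuracy of the
target learner; ties break toward smaller subsets, then lexicographic
order, so both selectors are column-order invariant.

**Learners and evaluation.** Naive Bayes (Laplace-smoothed nominal
likelihoods, Gaussian numeric likelihoods, empirical priors) and an
information-gain decision tree (binary splits: numeric midpoints,
one-category-vs-rest; min-leaf 2, max depth 10) are implemented natively as
reference learners. SVM/RF/ANN-style learners enter through a plugin
contract (`fit(table)` / `predict_scores(table)`) with a ready adapter for
sklearn estimators — the pipeline and fusion are the contribution here, not
the base learners. Evaluation is stratified 10-fold CV (per-fold metrics
averaged, dispersion reported as the between-fold standard deviation) or
leave-one-patient-out (pooled); folds refit SMOTE and feature selection.
Kappa is `(p_o − p_e)/(1 − p_e)` with the convention kappa = 1 when both
observed and chance agreement are exactly 1; AUC is the Mann–Whitney rank
form with midranks.

**Fusion.** Per-source binary votes are combined by weighted majority;
weights default to normalized per-source accuracy (the original study does
not publish its weights, so this is a reconstruction — uniform weighting is
retained for ablation). A patient missing from a source loses that
source's weight (renormalized). A fused tie goes to relapse: in
surveillance the false negative is the costly error.

## Temporal monitoring arm

**Personalized genetic signature.** For each patient the pre-treatment
(cancerous) and first-remission (cancer-free) profiles are differenced on
the log2 scale; genes with |d| ≥ 1 (one fold change of 2) form the
signature, each weighted by |d|/Σ|d|. The threshold default and the
opt-in top-k = 50 fallback (used when nothing passes) are package choices
— the source analysis quantifies neither. Follow-up visits are compared
against both references with Pearson correlation (undefined for constant
vectors: reported as missing, the distance still computed) and the weighted
Euclidean distance `sqrt(Σ w_g (x_g − ref_g)²)`. A distance tie is
assigned to the cancer-free side to avoid spurious alarms. Signatures are
strictly per patient and never pooled; signature genes are deliberately not
fed into the DBN.

**Discretization.** Gene expression is cut into 3 equal-frequency bins
(under/normal/over-expression) per gene, boundaries learned on training
patients pooled over visits and applied unchanged to held-out patients
(out-of-range values clamp to the end bins). Each quantile cut is snapped
to the midpoint between the adjacent observed values so no training value
sits exactly on a boundary — this makes the degenerate case of few distinct
values well defined. A constant gene collapses to a single bin with a
warning.

**Model and score.** The DBN is a stationary 2-TBN: one intra-slice DAG
plus inter-slice edges shared across both visit transitions — three visits
are too few to fit non-stationary dynamics. The relapse node is binary and
absorbing. Structures are scored decomposably per family: BDe (default,
equivalent sample size α = 1) or BIC; initial families use first-visit
observations, transition families pool both visit pairs. `max_parents`
defaults to 3, bounding CPT size at cohort scale. CPTs are fitted with
pseudocount 1 (rows without data fall back to uniform).

**Search.** Greedy hill climbing over single-edge moves
(add/delete/reverse intra, add/delete inter; intra-slice acyclicity and the
parent cap enforced per move). Restarts combine three kinds of starting
points: informed starts that give every child its exactly optimal
inter-parent set under a fixed intra pattern (transition families decouple
per child, so this is cheap and escapes pairwise parent-interaction traps
that single-edge moves cannot see), random structures, and perturbations of
the incumbent (iterated local search).
Simulated annealing proposes uniform random moves with Metropolis
acceptance under geometric cooling (T0 = 2, factor 0.9, 50 moves per
temperature, floor 1e-3), returns the best structure seen, and finishes
with one hill climb; it too supports best-of-n restarts with derived
seeds. Move enumeration is sorted so results are reproducible across
processes. On fully enumerable problems (4 variables, 2 slices) both
searches attain the global optimum computed by exhaustive enumeration of
all intra-slice DAGs with per-child optimal inter-parent sets.

**Inference.** Posteriors are exact: the 2-TBN is unrolled over the three
visits and queried by variable elimination with a greedy min-size order —
exactness, not the elimination flavor, is the contract, and an independent
vectorized enumeration of the full joint serves as the oracle in tests.
Impossible evidence raises an explicit inconsistency error. Relapse
forecasts threshold the posterior at 0.5 (configurable for
sensitivity-first operation).

**Evaluation.** Leave-one-patient-out: discretization, structure and CPTs
are refit on every fold (no leakage), the held-out patient is forecast at
two evidence horizons (baseline only → relapse at follow-up #1; baseline +
follow-up #1 → relapse at follow-up #2), and pooled Se/Sp/Acc are reported
per horizon. Because pooled and class-averaged accuracy can disagree on
small unbalanced cohorts, the balanced accuracy is reported alongside. A
fixed-structure mode evaluates a user-supplied topology without search.

## Synthetic cohorts: what they emulate and what they do not

The generator reproduces the study conditions as defaults: 86 patients
(26 relapsers), ~62 clinical and ~16 imaging features (≈60% nominal with
2–4 categories; informative features get class-dependent distributions),
45,015 probes of which 4,500 control + 4,500 duplicate + 2,524 low-quality
flags leave exactly 33,491 after QC, planted differentially expressed genes
shifted by log2(fold change) in relapsers on a log2-like intensity scale
(background Normal(8, 0.5)), designated features with >90% missingness, and
a 23-patient (11/12) three-visit time course sampled ancestrally from a
known ground-truth DBN with absorbing relapse and state-conditional
Gaussian emission (means 2 apart, sd 0.25).

Two ready-made ground truths drive the temporal experiments: a nine-gene +
relapse network (persistence and cross edges with copy-fidelity 0.85, one
relapse driver gene) mirroring the scale of the final reported model, and a
small deterministic network in which baseline over-expression of one gene
forces relapse — the noiseless ceiling at which leave-one-patient-out must
reach accuracy 1.

What passing these simulations does **not** show: real microarray data have
probe-level chemistry, batch and platform effects, informative missingness
and survival-time structure that the generator deliberately omits; the
synthetic fold changes and CPT fidelities are favorable by construction.
The simulations certify the correctness and calibration of the machinery,
not clinical performance.

## Numerical and experimental choices

- Problem sizes in the acceptance experiments — 200 random networks for the
  inference oracle, 100 datasets for the search oracle, 200 patients for
  recovery, 20 seeds for the shuffled-label control and the null
  calibration, 1000 draws for the metric and signature property checks —
  are the package's standard experiment sizes; all are driven by one seed.
- Parameter recovery is summarized by the observation-weighted mean
  total-variation distance between fitted and true transition-CPT rows over
  rows with at least 30 observations (the expected-TV metric used in
  structure-learning evaluations); the worst single row is also reported.
  At n = 200 patients a row observed ~130 times has TV sampling noise of
  about 0.03 even under a perfect estimator, so the per-row maximum is a
  noisy statistic and is reported rather than certified.
- Degenerate inputs: all-constant genes (single bin, warning), classes
  absent from a training fold (fold skipped with a warning), empty CFS
  subsets and all-missing columns (explicit errors naming the remedy),
  SMOTE with minority ≤ k (error suggesting smaller k).

## Known limitations

- The discrete DBN cannot represent continuous dynamics; information is
  lost at discretization, and 3 bins is a coarse default.
- With 23-patient cohorts the structure search is variance-dominated;
  the fixed-structure mode exists precisely to separate structure
  uncertainty from forecasting performance.
- The fusion weights are a reconstruction (normalized accuracy); any
  monotone reweighting that preserves the argmax yields identical calls.
- The wrapper selector's inner CV accuracy is an optimistically biased
  estimate for the selected subset; only the outer CV/LOPO numbers are
  reported as performance.
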