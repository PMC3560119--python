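# relapsekit

Decision support for oral squamous cell carcinoma (OSCC) surveillance after
remission. Between 25% and 48% of remittent OSCC patients suffer a
locoregional relapse during the two-year follow-up; `relapsekit` implements
a two-arm analysis that stratifies patients by relapse risk and monitors
disease evolution over the follow-up visits:

1. **Baseline multimodal classification.** Clinical, imaging,
   tissue-expression and blood-expression sources are each cleaned
   (sparse-feature removal, mode/mean imputation), rebalanced with SMOTE,
   reduced by SAM gene ranking with a fold-change filter or by CFS/wrapper
   feature selection, classified per source, and fused by weighted majority
   voting into a consensus relapse call.
2. **Temporal disease-evolution monitoring.** Blood expression measured at
   three visits (baseline, follow-up #1, follow-up #2) feeds a discrete
   dynamic Bayesian network (2-TBN) with intra- and inter-slice edges.
   Structure is learned by greedy hill climbing or simulated annealing over
   a decomposable BDe/BIC score; relapse probabilities at future visits are
   computed by exact inference on the unrolled network. A per-patient
   *personalized genetic signature* additionally tracks each follow-up
   visit's weighted distance and correlation against the patient's own
   cancerous and cancer-free reference profiles.

No public accession exists for cohorts of this shape, so the package ships
a first-class synthetic-data module (`relapsekit.synthgen`) emulating the
study conditions — an 86-patient cohort (26 relapsers / 60 controls) with
45,015 probes reducible to 33,491 after QC, and a 23-patient (11/12)
three-visit time course driven by a known ground-truth DBN — making every
stage testable end to end against known truth.

## The models in brief

**SAM ranking.** Per-gene moderated statistic
`d_i = (x̄_i1 − x̄_i0) / (s_i + s0)` with `s_i` the pooled standard error
and `s0` a quantile of the `s_i` distribution; q-values from a pooled
permutation null with step-up adjustment; selection by two-sided linear
fold change `max(r, 1/r) ≥ 1.8` and `q ≤ q_cutoff`.

**CFS merit.** For a subset of `k` features,
`merit = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)` with correlations measured as
symmetrical uncertainty after equal-frequency discretization; maximized by
forward best-first search.

**Metric panel.** Sensitivity, specificity, accuracy, Cohen's kappa
`(p_o − p_e)/(1 − p_e)` and the Mann–Whitney AUC with midranks, under
stratified 10-fold CV (per-fold mean ± sd) or leave-one-patient-out
(pooled).

**DBN score and inference.** Family scores are BDe (Dirichlet equivalent
sample size α, split uniformly over the `q·r` family cells) or BIC; the
structure score decomposes as the sum of initial-slice and pooled
transition family scores. Inference is exact variable elimination on the
unrolled three-slice network; the relapse state is absorbing.

## Worked example

```python
import numpy as np
from relapsekit.synthgen import deterministic_ground_truth, generate_timecourse
from relapsekit.dbn import ScoreConfig, lopo_evaluate

truth = deterministic_ground_truth()          # relapse driven by gene g1
cohort = generate_timecourse(truth, 14, 7, seed=5)
reports = lopo_evaluate(cohort.tensor, cohort.relapse_states, ScoreConfig(seed=0))
for horizon, rep in reports.items():
    print(f"{horizon}: Se {100*rep.sensitivity:.1f}% | "
          f"Sp {100*rep.specificity:.1f}% | Acc {100*rep.accuracy:.1f}%")
```

prints

```
baseline: Se 100.0% | Sp 100.0% | Acc 100.0%
baseline+fu1: Se 100.0% | Sp 100.0% | Acc 100.0%
```

i.e. with noiseless deterministic dynamics the leave-one-patient-out
forecaster recovers every relapse from baseline evidence alone, and again
when follow-up #1 is added — the sanity ceiling against which noisy
settings are judged. The same entry points run the noisy nine-gene ground
truth (`default_ground_truth()`), where structure search recovers the
planted inter-slice edges with precision/recall ≥ 0.8 at n = 200.

A command-line layer mirrors the library:

```bash
relapsekit simulate --out cohort/ --seed 1
relapsekit rank-genes --mode two-class --expression cohort/tissue_expression.tsv \
    --labels cohort/clinical.tsv --fc 1.8 --out ranking.tsv
relapsekit dbn lopo --timecourse cohort/timecourse.tsv --relapse cohort/relapse_states.tsv
```

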