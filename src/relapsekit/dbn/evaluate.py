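"""Leave-one-patient-out evaluation of the temporal relapse forecaster.

Each fold withholds one patient, learns the full temporal model on the rest
(discretization boundaries, structure, CPTs — nothing is shared with the
held-out patient), then forecasts the withheld patient's relapse state at
two evidence horizons:

* ``baseline`` — only first-visit observations are given; the relapse state
  at follow-up #1 is forecast.
* ``baseline+fu1`` — the first two visits are given; the relapse state at
  follow-up #2 is forecast.

Pooled sensitivity/specificity/accuracy are reported per horizon, alongside
a macro (balanced) accuracy, because pooled and class-averaged accuracy can
disagree on small unbalanced cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..containers import TimeCourseTensor, ValidationError
from .model import apply_discretization, fit_cpts, fit_discretization
from .scoring import ScoreConfig
from .search import AnnealSchedule, anneal_search, greedy_search
from .structure import DbnStructure
from .inference import predict_relapse

RELAPSE = "relapse"


@dataclass
class HorizonReport:
    """Pooled confusion-derived metrics for one evidence horizon."""

    horizon: str
    tp: int
    fn: int
    tn: int
    fp: int
    predictions: pd.DataFrame = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2


def _assemble_states(gene_states: np.ndarray, relapse: np.ndarray) -> np.ndarray:
    """Stack gene bins and the binary relapse row into one (p, v, s) array."""
    return np.concatenate([gene_states, relapse[:, None, :]], axis=1)


def learn_dbn(tc: TimeCourseTensor, relapse: np.ndarray, cfg: ScoreConfig,
              search: str = "greedy", sched: AnnealSchedule | None = None,
              n_bins: int = 3, pseudocount: float = 1.0,
              n_restarts: int = 2, structure: DbnStructure | None = None):
    """Learn discretization, structure and CPTs from a training cohort.

    ``structure=None`` triggers structure search; passing a fixed structure
    skips the search (useful for evaluating a known topology).
    """
    relapse = np.asarray(relapse, dtype=int)
    if relapse.shape != (tc.n_patients, tc.n_visits):
        raise ValidationError("relapse states must be (patients, visits)")
    boundaries = fit_discretization(tc, n_bins)
    gene_states = apply_discretization(tc, boundaries)
    states = _assemble_states(gene_states, relapse)
    variables = list(tc.gene_ids) + [RELAPSE]
    cards = {g: max(2, len(boundaries[g]) + 1) for g in tc.gene_ids}
    cards[RELAPSE] = 2
    if structure is None:
        if search == "greedy":
            structure = greedy_search(states, variables, cards, cfg,
                                      n_restarts=n_restarts)
        elif search == "anneal":
            structure = anneal_search(states, variables, cards, cfg, sched)
        else:
            raise ValidationError(f"unknown search {search!r} (greedy|anneal)")
    model = fit_cpts(structure, states, variables, cards,
                     pseudocount=pseudocount, boundaries=boundaries)
    return model


def _patient_evidence(model, tc: TimeCourseTensor, relapse: np.ndarray,
                      patient: int, upto_slice: int) -> dict:
    gene_states = apply_discretization(tc.subset_patients([patient]),
                                       model.boundaries)[0]
    evidence = {}
    for t in range(upto_slice + 1):
        for g, gene in enumerate(tc.gene_ids):
            evidence[(gene, t)] = int(gene_states[g, t])
        evidence[(RELAPSE, t)] = int(relapse[patient, t])
    return evidence


def lopo_evaluate(tc: TimeCourseTensor, relapse: np.ndarray,
                  cfg: ScoreConfig | None = None, search: str = "greedy",
                  sched: AnnealSchedule | None = None, n_bins: int = 3,
                  pseudocount: float = 1.0, threshold: float = 0.5,
                  n_restarts: int = 2,
                  structure: DbnStructure | None = None) -> dict[str, HorizonReport]:
    """Leave-one-patient-out relapse forecasting at both evidence horizons.

    Returns ``{"baseline": HorizonReport, "baseline+fu1": HorizonReport}``.
    Folds whose training cohort lacks a relapse class are skipped with a
    warning.
    """
    if cfg is None:
        cfg = ScoreConfig()
    relapse = np.asarray(relapse, dtype=int)
    if tc.n_visits < 3:
        raise ValidationError("need three visits (baseline, fu1, fu2)")
    final = relapse[:, -1]
    for label in (0, 1):
        if np.sum(final == label) < 1:
            raise ValidationError(f"cohort has no patients with final relapse "
                                  f"state {label}")
    horizons = {"baseline": 0, "baseline+fu1": 1}
    rows: dict[str, list] = {h: [] for h in horizons}
    for i in range(tc.n_patients):
        train = [j for j in range(tc.n_patients) if j != i]
        train_final = final[train]
        if len(np.unique(train_final)) < 2:
            warnings.warn(f"fold {i}: one relapse class absent from training "
                          "cohort; fold skipped")
            continue
        model = learn_dbn(tc.subset_patients(train), relapse[train], cfg,
                          search=search, sched=sched, n_bins=n_bins,
                          pseudocount=pseudocount, n_restarts=n_restarts,
                          structure=structure)
        for name, upto in horizons.items():
            evidence = _patient_evidence(model, tc, relapse, i, upto)
            forecast = predict_relapse(model, evidence, n_slices=tc.n_visits,
                                       threshold=threshold)
            target_slice = upto + 1
            prob, call = forecast[target_slice]
            rows[name].append((tc.patient_ids[i], int(relapse[i, target_slice]),
                               int(call), prob))
    reports = {}
    for name in horizons:
        df = pd.DataFrame(rows[name], columns=["patient_id", "truth",
                                               "predicted", "probability"])
        tp = int(((df.truth == 1) & (df.predicted == 1)).sum())
        fn = int(((df.truth == 1) & (df.predicted == 0)).sum())
        tn = int(((df.truth == 0) & (df.predicted == 0)).sum())
        fp = int(((df.truth == 0) & (df.predicted == 1)).sum())
        reports[name] = HorizonReport(name, tp, fn, tn, fp, df)
    return reports
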