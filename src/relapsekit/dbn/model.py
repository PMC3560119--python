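"""Parameterized DBN: conditional probability tables and discretization.

A :class:`DbnModel` bundles a :class:`~relapsekit.dbn.structure.DbnStructure`
with per-variable cardinalities, an initial CPT (first visit) and a
transition CPT (shared by all later visit pairs), plus the per-gene
discretization boundaries learned on training data.

CPTs are dense arrays of shape ``(n_parent_configs, r)``.  Parent
configurations are raveled in a canonical order: for transition families the
inter-slice parents (read at ``t``) come first, then the intra-slice parents
(read at ``t+1``); within each group parents follow the structure's variable
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..containers import TimeCourseTensor, ValidationError
from .scoring import family_counts
from .structure import DbnStructure


@dataclass
class DbnModel:
    structure: DbnStructure
    cardinalities: dict[str, int]
    initial_cpts: dict[str, np.ndarray]
    transition_cpts: dict[str, np.ndarray]
    boundaries: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.structure.variables:
            if v not in self.cardinalities:
                raise ValidationError(f"no cardinality for variable {v}")
            for cpts, parents in ((self.initial_cpts, self.initial_parents(v)),
                                  (self.transition_cpts, self.transition_parents(v))):
                table = np.asarray(cpts[v], dtype=float)
                q = int(np.prod([self.cardinalities[p] for p, _ in parents])) \
                    if parents else 1
                if table.shape != (q, self.cardinalities[v]):
                    raise ValidationError(
                        f"CPT for {v} has shape {table.shape}, expected "
                        f"({q}, {self.cardinalities[v]})")
                if not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
                    raise ValidationError(f"CPT rows for {v} do not sum to 1")
                cpts[v] = table

    @property
    def variables(self) -> tuple[str, ...]:
        return self.structure.variables

    def initial_parents(self, child: str) -> list[tuple[str, int]]:
        """Parents of ``child`` at the first visit, as (name, lag=0) pairs."""
        return [(p, 0) for p in self.structure.intra_parents(child)]

    def transition_parents(self, child: str) -> list[tuple[str, int]]:
        """Parents in the transition family; lag -1 = previous visit."""
        return ([(p, -1) for p in self.structure.inter_parents(child)]
                + [(p, 0) for p in self.structure.intra_parents(child)])

    def config_index(self, parents: list[tuple[str, int]],
                     states: dict[tuple[str, int], int]) -> int:
        if not parents:
            return 0
        cards = [self.cardinalities[p] for p, _ in parents]
        return int(np.ravel_multi_index([states[key] for key in parents], cards))


def fit_cpts(structure: DbnStructure, states: np.ndarray, variables: list[str],
             cardinalities: dict[str, int], pseudocount: float = 1.0,
             boundaries: dict[str, np.ndarray] | None = None) -> DbnModel:
    """Estimate CPTs by (optionally smoothed) relative frequencies.

    Rows are ``(counts + pseudocount) / (row_total + pseudocount * r)``;
    a row with no data and no smoothing falls back to uniform.
    """
    states = np.asarray(states, dtype=int)
    index = {v: i for i, v in enumerate(variables)}
    n_slices = states.shape[2]
    init_obs = states[:, :, 0]
    prev = np.concatenate([states[:, :, t] for t in range(n_slices - 1)])
    nxt = np.concatenate([states[:, :, t + 1] for t in range(n_slices - 1)])

    def estimate(child_states, parent_states, parent_cards, r):
        counts = family_counts(child_states, parent_states, parent_cards, r)
        counts += pseudocount
        totals = counts.sum(axis=1, keepdims=True)
        rows = np.divide(counts, totals, out=np.full_like(counts, 1.0 / r),
                         where=totals > 0)
        return rows

    initial, transition = {}, {}
    for v in variables:
        r = cardinalities[v]
        intra = structure.intra_parents(v)
        inter = structure.inter_parents(v)
        cols = [index[p] for p in intra]
        initial[v] = estimate(init_obs[:, index[v]], init_obs[:, cols],
                              tuple(cardinalities[p] for p in intra), r)
        parent_states = np.column_stack([prev[:, [index[p] for p in inter]],
                                         nxt[:, cols]])
        transition[v] = estimate(
            nxt[:, index[v]], parent_states,
            tuple(cardinalities[p] for p in inter)
            + tuple(cardinalities[p] for p in intra), r)
    return DbnModel(structure, dict(cardinalities), initial, transition,
                    dict(boundaries or {}))


# -- discretization ----------------------------------------------------------

def fit_discretization(tc: TimeCourseTensor, n_bins: int = 3) -> dict[str, np.ndarray]:
    """Equal-frequency bin boundaries per gene, pooled over patients × visits.

    Returns interior boundaries (strictly increasing, possibly fewer than
    ``n_bins - 1`` when quantiles coincide).  A constant gene yields no
    boundary (single bin) with a warning.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    boundaries = {}
    for g, gene in enumerate(tc.gene_ids):
        vals = np.unique(tc.values[:, g, :])
        cuts = []
        for q in np.quantile(tc.values[:, g, :], np.arange(1, n_bins) / n_bins):
            # snap the cut between adjacent observed values so no training
            # value ever sits exactly on a boundary
            below = vals[vals <= q]
            above = vals[vals > q]
            if below.size and above.size:
                cuts.append((below.max() + above.min()) / 2)
        cuts = np.unique(cuts)
        if cuts.size == 0 and vals.size <= 1:
            warnings.warn(f"gene {gene} is constant on training data; "
                          "falling back to a single bin")
        boundaries[gene] = cuts
    return boundaries


def apply_discretization(tc: TimeCourseTensor,
                         boundaries: dict[str, np.ndarray]) -> np.ndarray:
    """Map expression to bin indices; out-of-range values clamp to end bins."""
    states = np.empty(tc.values.shape, dtype=int)
    for g, gene in enumerate(tc.gene_ids):
        states[:, g, :] = np.searchsorted(boundaries[gene], tc.values[:, g, :],
                                          side="left")
    return states


def discretize(tc: TimeCourseTensor, n_bins: int = 3):
    """Fit and apply equal-frequency discretization; returns (states, map)."""
    boundaries = fit_discretization(tc, n_bins)
    return apply_discretization(tc, boundaries), boundaries
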