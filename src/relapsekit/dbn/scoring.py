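"""Decomposable family scores (BDe / BIC) for 2-TBN structure search.

The score of a structure is the sum over variables of two family scores:

* an *initial* family score fitted on the first-visit observations, with the
  variable's intra-slice parents, and
* a *transition* family score fitted on observations pooled over all
  consecutive visit pairs, with inter-slice parents read at ``t`` and
  intra-slice parents read at ``t+1``.

BDe is the log marginal likelihood under a Dirichlet prior with equivalent
sample size ``ess`` split uniformly over the ``q * r`` cells of the family
(``q`` parent configurations, ``r`` child states).  BIC is the maximized
log-likelihood penalized by ``0.5 * log(N) * (r - 1) * q``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from ..containers import ValidationError, check_fields
from .structure import DbnStructure


@dataclass
class ScoreConfig:
    score: str = "bde"
    ess: float = 1.0
    max_parents: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        check_fields(
            self,
            score=(lambda s: s in ("bde", "bic"), "must be 'bde' or 'bic'"),
            ess=(lambda a: a > 0, "equivalent sample size must be positive"),
            max_parents=(lambda m: m >= 0, "must be nonnegative"),
        )


def family_counts(child_states: np.ndarray, parent_states: np.ndarray,
                  parent_cards: tuple[int, ...], r: int) -> np.ndarray:
    """Contingency counts, shape (n parent configs, r)."""
    q = int(np.prod(parent_cards)) if parent_cards else 1
    if parent_cards:
        config = np.ravel_multi_index(tuple(parent_states.T), parent_cards)
    else:
        config = np.zeros(len(child_states), dtype=int)
    flat = np.bincount(config * r + child_states, minlength=q * r)
    return flat.reshape(q, r).astype(float)


def family_score(child_states: np.ndarray, parent_states: np.ndarray,
                 parent_cards: tuple[int, ...], r: int, cfg: ScoreConfig) -> float:
    """Score one family from discrete observations.

    ``parent_states`` has one column per parent (may be empty with shape
    ``(n, 0)``).  Deterministic in its inputs.
    """
    if len(parent_cards) > cfg.max_parents:
        raise ValidationError(
            f"family has {len(parent_cards)} parents, exceeding max_parents="
            f"{cfg.max_parents}")
    counts = family_counts(child_states, parent_states, parent_cards, r)
    q = counts.shape[0]
    if cfg.score == "bde":
        a_jk = cfg.ess / (q * r)
        a_j = cfg.ess / q
        row_tot = counts.sum(axis=1)
        return float(np.sum(gammaln(a_j) - gammaln(a_j + row_tot))
                     + np.sum(gammaln(a_jk + counts) - gammaln(a_jk)))
    # BIC
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = counts * (np.log(counts) - np.log(row_tot))
    ll = float(np.nansum(ll))
    n = len(child_states)
    penalty = 0.5 * math.log(n) * (r - 1) * q if n > 0 else 0.0
    return ll - penalty


class DbnScorer:
    """Caches family scores for a fixed discrete dataset.

    Parameters
    ----------
    states:
        Integer array, shape ``(n_patients, n_variables, n_slices)``.
    variables:
        Variable names matching axis 1.
    cardinalities:
        States per variable.
    """

    def __init__(self, states: np.ndarray, variables: list[str],
                 cardinalities: dict[str, int], cfg: ScoreConfig):
        states = np.asarray(states, dtype=int)
        if states.ndim != 3 or states.shape[1] != len(variables):
            raise ValidationError("states must be (patients, variables, slices)")
        if states.shape[2] < 2:
            raise ValidationError("need at least 2 slices of discrete data")
        self.states = states
        self.variables = list(variables)
        self.index = {v: i for i, v in enumerate(variables)}
        self.cards = dict(cardinalities)
        self.cfg = cfg
        n_p, _, n_s = states.shape
        # slice-0 view and pooled transition views (t and t+1 stacked)
        self._init_obs = states[:, :, 0]
        self._trans_prev = np.concatenate([states[:, :, t] for t in range(n_s - 1)])
        self._trans_next = np.concatenate([states[:, :, t + 1] for t in range(n_s - 1)])
        self._init_cache: dict = {}
        self._trans_cache: dict = {}

    def _cards_of(self, names) -> tuple[int, ...]:
        return tuple(self.cards[v] for v in names)

    def initial_family(self, child: str, intra_parents: tuple[str, ...]) -> float:
        key = (child, intra_parents)
        if key not in self._init_cache:
            cols = [self.index[p] for p in intra_parents]
            self._init_cache[key] = family_score(
                self._init_obs[:, self.index[child]],
                self._init_obs[:, cols],
                self._cards_of(intra_parents), self.cards[child], self.cfg)
        return self._init_cache[key]

    def transition_family(self, child: str, intra_parents: tuple[str, ...],
                          inter_parents: tuple[str, ...]) -> float:
        key = (child, intra_parents, inter_parents)
        if key not in self._trans_cache:
            inter_cols = [self.index[p] for p in inter_parents]
            intra_cols = [self.index[p] for p in intra_parents]
            parents = np.column_stack([self._trans_prev[:, inter_cols],
                                       self._trans_next[:, intra_cols]])
            self._trans_cache[key] = family_score(
                self._trans_next[:, self.index[child]], parents,
                self._cards_of(inter_parents) + self._cards_of(intra_parents),
                self.cards[child], self.cfg)
        return self._trans_cache[key]

    def child_score(self, structure: DbnStructure, child: str) -> float:
        intra = structure.intra_parents(child)
        inter = structure.inter_parents(child)
        return (self.initial_family(child, intra)
                + self.transition_family(child, intra, inter))

    def structure_score(self, structure: DbnStructure) -> float:
        return sum(self.child_score(structure, v) for v in structure.variables)
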