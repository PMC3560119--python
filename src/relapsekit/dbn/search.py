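"""Structure search over 2-TBNs: greedy hill climbing and simulated annealing.

Moves are single-edge operations: add/delete/reverse an intra-slice edge and
add/delete an inter-slice edge.  Intra-slice acyclicity and the per-child
parent cap are enforced on every move.  Because the score decomposes over
families, a move is evaluated by rescoring only the affected child (or the
two endpoints for a reversal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from ..containers import ValidationError, check_fields
from .scoring import DbnScorer, ScoreConfig
from .structure import DbnStructure

_EPS = 1e-12


@dataclass
class AnnealSchedule:
    """Geometric cooling schedule for simulated annealing."""

    t_initial: float = 2.0
    cooling: float = 0.9
    moves_per_temp: int = 50
    t_min: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        check_fields(
            self,
            t_initial=(lambda t: t > 0, "must be positive"),
            cooling=(lambda c: 0 < c < 1, "must be in (0, 1)"),
            moves_per_temp=(lambda m: m >= 1, "must be >= 1"),
            t_min=(lambda t: 0 < t <= self.t_initial,
                   "must be positive and <= t_initial"),
        )


# -- move enumeration --------------------------------------------------------

def _would_cycle(structure: DbnStructure, new_edge, removed=None) -> bool:
    # adding (p, c) creates a cycle iff p is reachable from c
    edges = set(structure.intra_edges)
    if removed is not None:
        edges.discard(removed)
    children: dict[str, list[str]] = {}
    for a, b in edges:
        children.setdefault(a, []).append(b)
    p, c = new_edge
    stack, seen = [c], {c}
    while stack:
        node = stack.pop()
        if node == p:
            return True
        for nxt in children.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def legal_moves(structure: DbnStructure, max_parents: int) -> list[tuple]:
    """All single-edge moves legal from ``structure``.

    Each move is ``(kind, parent, child)`` with kind one of
    ``add_intra | del_intra | rev_intra | add_inter | del_inter``.
    """
    moves = []
    variables = structure.variables
    intra, inter = structure.intra_edges, structure.inter_edges
    for p in variables:
        for c in variables:
            if p != c and (p, c) not in intra:
                if structure.n_parents(c) + 1 <= max_parents \
                        and not _would_cycle(structure, (p, c)):
                    moves.append(("add_intra", p, c))
            if (p, c) not in inter and structure.n_parents(c) + 1 <= max_parents:
                moves.append(("add_inter", p, c))
    # sorted iteration keeps the move order (and thus tie-breaking and RNG
    # consumption) independent of set iteration order across processes
    for p, c in sorted(intra):
        moves.append(("del_intra", p, c))
        if structure.n_parents(p) + 1 <= max_parents \
                and not _would_cycle(structure, (c, p), removed=(p, c)):
            moves.append(("rev_intra", p, c))
    for p, c in sorted(inter):
        moves.append(("del_inter", p, c))
    return moves


def apply_move(structure: DbnStructure, move: tuple) -> DbnStructure:
    kind, p, c = move
    intra, inter = set(structure.intra_edges), set(structure.inter_edges)
    if kind == "add_intra":
        intra.add((p, c))
    elif kind == "del_intra":
        intra.remove((p, c))
    elif kind == "rev_intra":
        intra.remove((p, c))
        intra.add((c, p))
    elif kind == "add_inter":
        inter.add((p, c))
    elif kind == "del_inter":
        inter.remove((p, c))
    else:  # pragma: no cover - guarded by legal_moves
        raise ValidationError(f"unknown move kind {kind}")
    return structure.with_edges(frozenset(intra), frozenset(inter))


def _affected_children(move: tuple) -> tuple[str, ...]:
    kind, p, c = move
    return (c, p) if kind == "rev_intra" else (c,)


def move_delta(scorer: DbnScorer, structure: DbnStructure, move: tuple) -> float:
    new = apply_move(structure, move)
    return sum(scorer.child_score(new, v) - scorer.child_score(structure, v)
               for v in _affected_children(move))


# -- greedy hill climbing ----------------------------------------------------

def _hill_climb(scorer: DbnScorer, start: DbnStructure, max_parents: int):
    structure = start
    score = scorer.structure_score(structure)
    while True:
        best_move, best_delta = None, _EPS
        for move in legal_moves(structure, max_parents):
            delta = move_delta(scorer, structure, move)
            if delta > best_delta:
                best_move, best_delta = move, delta
        if best_move is None:
            return structure, score
        structure = apply_move(structure, best_move)
        new_score = scorer.structure_score(structure)
        # decomposability: the incremental delta must equal the full rescore
        assert abs(new_score - (score + best_delta)) < 1e-6
        score = new_score


def _best_inter_sets(scorer: DbnScorer, structure: DbnStructure,
                     max_parents: int) -> DbnStructure:
    """Replace every child's inter parents by its exactly optimal set.

    Given fixed intra parents, the transition families decouple per child,
    so each child's best inter-parent set (within the parent budget) can be
    enumerated directly.  Used to build informed restart points that escape
    pairwise parent-interaction traps single-edge moves cannot see.
    """
    variables = structure.variables
    inter = set()
    for child in variables:
        intra_parents = structure.intra_parents(child)
        budget = max_parents - len(intra_parents)
        best_score, best_parents = -math.inf, ()
        for k in range(budget + 1):
            for parents in combinations(variables, k):
                s = scorer.transition_family(child, intra_parents, parents)
                if s > best_score:
                    best_score, best_parents = s, parents
        inter.update((p, child) for p in best_parents)
    return structure.with_edges(inter=frozenset(inter))


def _informed_starts(scorer: DbnScorer, variables, max_parents: int):
    """Restart structures with per-child optimal inter-parent sets."""
    empty = DbnStructure(tuple(variables))
    yield _best_inter_sets(scorer, empty, max_parents)
    if len(variables) <= 6:
        for p in variables:
            for c in variables:
                if p == c:
                    continue
                with_edge = empty.with_edges(intra=frozenset({(p, c)}))
                yield _best_inter_sets(scorer, with_edge, max_parents)


def _random_structure(variables, max_parents, rng) -> DbnStructure:
    structure = DbnStructure(tuple(variables))
    n_edges = rng.integers(0, 2 * len(variables) + 1)
    for _ in range(n_edges):
        moves = [m for m in legal_moves(structure, max_parents)
                 if m[0].startswith("add")]
        if not moves:
            break
        structure = apply_move(structure, moves[rng.integers(len(moves))])
    return structure


def greedy_search(states: np.ndarray, variables: list[str],
                  cardinalities: dict[str, int], cfg: ScoreConfig,
                  n_restarts: int = 3,
                  scorer: DbnScorer | None = None) -> DbnStructure:
    """Hill climbing with random restarts; returns the best structure found.

    The first climb always starts from the empty structure, so the returned
    score is never below the empty structure's score.
    """
    if scorer is None:
        scorer = DbnScorer(states, variables, cardinalities, cfg)
    rng = np.random.default_rng(cfg.seed)
    empty = DbnStructure(tuple(variables))
    best, best_score = _hill_climb(scorer, empty, cfg.max_parents)
    for start in _informed_starts(scorer, variables, cfg.max_parents):
        candidate, score = _hill_climb(scorer, start, cfg.max_parents)
        if score > best_score:
            best, best_score = candidate, score
    for restart in range(max(0, n_restarts - 1)):
        if restart % 2 == 0:
            # iterated local search: kick the incumbent with random moves
            start = best
            for _ in range(4):
                moves = legal_moves(start, cfg.max_parents)
                if not moves:
                    break
                start = apply_move(start, moves[rng.integers(len(moves))])
        else:
            start = _random_structure(variables, cfg.max_parents, rng)
        candidate, score = _hill_climb(scorer, start, cfg.max_parents)
        if score > best_score:
            best, best_score = candidate, score
    return best


# -- simulated annealing -----------------------------------------------------

def anneal_search(states: np.ndarray, variables: list[str],
                  cardinalities: dict[str, int], cfg: ScoreConfig,
                  sched: AnnealSchedule | None = None,
                  scorer: DbnScorer | None = None,
                  n_restarts: int = 1) -> DbnStructure:
    """Simulated annealing over single-edge moves.

    Proposals are uniform over the legal move set; a proposal with score
    change ``delta`` is accepted with probability ``min(1, exp(delta / T))``.
    The best structure seen anywhere along the trajectory is returned, then
    refined by one final hill climb so the result is at least a local
    optimum.  ``n_restarts > 1`` repeats the anneal with derived seeds and
    keeps the best result.
    """
    if sched is None:
        sched = AnnealSchedule(seed=cfg.seed)
    if scorer is None:
        scorer = DbnScorer(states, variables, cardinalities, cfg)
    if n_restarts > 1:
        results = []
        for k in range(n_restarts):
            run_sched = AnnealSchedule(sched.t_initial, sched.cooling,
                                       sched.moves_per_temp, sched.t_min,
                                       seed=sched.seed + 7919 * k)
            s = anneal_search(states, variables, cardinalities, cfg,
                              run_sched, scorer=scorer)
            results.append((scorer.structure_score(s), k, s))
        return max(results)[2]
    rng = np.random.default_rng(sched.seed)
    structure = DbnStructure(tuple(variables))
    score = scorer.structure_score(structure)
    best, best_score = structure, score
    temp = sched.t_initial
    while temp >= sched.t_min:
        for _ in range(sched.moves_per_temp):
            moves = legal_moves(structure, cfg.max_parents)
            if not moves:
                break
            move = moves[rng.integers(len(moves))]
            delta = move_delta(scorer, structure, move)
            if delta >= 0 or rng.random() < math.exp(delta / temp):
                structure = apply_move(structure, move)
                score += delta
                if score > best_score:
                    best, best_score = structure, score
        temp *= sched.cooling
    best, _ = _hill_climb(scorer, best, cfg.max_parents)
    return best


# -- exhaustive oracle (tiny problems) ---------------------------------------

def _all_intra_dags(variables, max_parents):
    pairs = [(p, c) for p in variables for c in variables if p != c]
    n = len(pairs)
    for mask in range(1 << n):
        edges = frozenset(pairs[i] for i in range(n) if mask >> i & 1)
        g = nx.DiGraph()
        g.add_nodes_from(variables)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            continue
        if any(sum(1 for _, c in edges if c == v) > max_parents for v in variables):
            continue
        yield edges


def exhaustive_optimum(states: np.ndarray, variables: list[str],
                       cardinalities: dict[str, int], cfg: ScoreConfig,
                       scorer: DbnScorer | None = None):
    """Globally optimal structure by full enumeration (<= 4 variables).

    Enumerates every acyclic intra-slice edge set; given intra parents, each
    child's inter-slice parent set is optimized independently (the score
    decomposes and inter edges impose no global constraint beyond the parent
    cap).  Returns ``(structure, score)``.
    """
    if len(variables) > 4:
        raise ValidationError("exhaustive enumeration is limited to 4 variables")
    if scorer is None:
        scorer = DbnScorer(states, variables, cardinalities, cfg)
    best_structure, best_score = None, -math.inf
    for intra in _all_intra_dags(variables, cfg.max_parents):
        total = 0.0
        inter_edges = set()
        trial = DbnStructure(tuple(variables), intra)
        for child in variables:
            intra_parents = trial.intra_parents(child)
            total += scorer.initial_family(child, intra_parents)
            budget = cfg.max_parents - len(intra_parents)
            child_best, child_parents = -math.inf, ()
            for k in range(budget + 1):
                for inter_parents in combinations(variables, k):
                    s = scorer.transition_family(child, intra_parents, inter_parents)
                    if s > child_best:
                        child_best, child_parents = s, inter_parents
            total += child_best
            inter_edges.update((p, child) for p in child_parents)
        if total > best_score:
            best_score = total
            best_structure = DbnStructure(tuple(variables), intra,
                                          frozenset(inter_edges))
    return best_structure, best_score
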