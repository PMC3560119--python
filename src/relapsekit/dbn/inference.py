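"""Exact inference on the unrolled DBN.

The network is unrolled over the requested number of visits into a static
Bayesian network whose nodes are ``(variable, slice)`` pairs; posteriors are
computed exactly by clique-style variable elimination (greedy min-size
elimination order).  A plain enumeration of the full joint is also provided
as an independent cross-check for small networks.
"""

from __future__ import annotations

import numpy as np

from ..containers import ValidationError
from .model import DbnModel

Node = tuple[str, int]


class InconsistentEvidenceError(ValueError):
    """Evidence has probability zero under the model."""


class Factor:
    """Nonnegative table over a tuple of nodes."""

    __slots__ = ("nodes", "table")

    def __init__(self, nodes: tuple[Node, ...], table: np.ndarray):
        self.nodes = tuple(nodes)
        self.table = np.asarray(table, dtype=float)
        if self.table.ndim != len(self.nodes):
            raise ValidationError("factor table rank != number of nodes")

    def multiply(self, other: "Factor") -> "Factor":
        nodes = self.nodes + tuple(n for n in other.nodes if n not in self.nodes)
        pos = {n: i for i, n in enumerate(nodes)}

        def expand(f: "Factor") -> np.ndarray:
            # permute axes into union order, then insert singleton axes
            order = sorted(range(len(f.nodes)), key=lambda i: pos[f.nodes[i]])
            table = np.transpose(f.table, order)
            shape = [1] * len(nodes)
            for axis, size in zip((pos[f.nodes[i]] for i in order), table.shape):
                shape[axis] = size
            return table.reshape(shape)

        return Factor(nodes, expand(self) * expand(other))

    def sum_out(self, node: Node) -> "Factor":
        axis = self.nodes.index(node)
        return Factor(self.nodes[:axis] + self.nodes[axis + 1:],
                      self.table.sum(axis=axis))

    def reduce(self, node: Node, state: int) -> "Factor":
        axis = self.nodes.index(node)
        return Factor(self.nodes[:axis] + self.nodes[axis + 1:],
                      np.take(self.table, state, axis=axis))


def unroll_factors(model: DbnModel, n_slices: int) -> list[Factor]:
    """CPT factors of the unrolled network over ``n_slices`` visits."""
    factors = []
    for v in model.variables:
        r = model.cardinalities[v]
        parents = model.initial_parents(v)
        nodes = tuple((p, 0) for p, _ in parents) + ((v, 0),)
        shape = tuple(model.cardinalities[p] for p, _ in parents) + (r,)
        factors.append(Factor(nodes, model.initial_cpts[v].reshape(shape)))
        for t in range(1, n_slices):
            parents = model.transition_parents(v)
            nodes = tuple((p, t + lag) for p, lag in parents) + ((v, t),)
            shape = tuple(model.cardinalities[p] for p, _ in parents) + (r,)
            factors.append(Factor(nodes, model.transition_cpts[v].reshape(shape)))
    return factors


def _validate_evidence(model: DbnModel, evidence: dict[Node, int],
                       n_slices: int) -> None:
    for (v, t), state in evidence.items():
        if v not in model.cardinalities:
            raise ValidationError(f"unknown variable {v} in evidence")
        if not 0 <= t < n_slices:
            raise ValidationError(f"evidence slice {t} outside 0..{n_slices - 1}")
        if not 0 <= state < model.cardinalities[v]:
            raise ValidationError(
                f"state {state} invalid for {v} (cardinality "
                f"{model.cardinalities[v]})")


def infer(model: DbnModel, evidence: dict[Node, int], query: Node,
          n_slices: int = 3) -> np.ndarray:
    """Exact posterior P(query | evidence) on the unrolled network.

    ``evidence`` maps ``(variable, slice)`` to an observed state.  Returns a
    distribution summing to 1; raises :class:`InconsistentEvidenceError` if
    the evidence has probability zero.
    """
    _validate_evidence(model, evidence, n_slices)
    qv, qt = query
    if not 0 <= qt < n_slices:
        raise ValidationError(f"query slice {qt} outside the unrolled window")
    if query in evidence:
        out = np.zeros(model.cardinalities[qv])
        out[evidence[query]] = 1.0
        return out
    factors = []
    for f in unroll_factors(model, n_slices):
        for node in f.nodes:
            if node in evidence:
                f = f.reduce(node, evidence[node])
        factors.append(f)
    hidden = {n for f in factors for n in f.nodes} - {query}
    while hidden:
        # greedy min-size: eliminate the node whose product factor is smallest
        best_node, best_cost = None, None
        for node in hidden:
            nodes = {n for f in factors if node in f.nodes for n in f.nodes}
            cost = int(np.prod([model.cardinalities[v] for v, _ in nodes]))
            if best_cost is None or cost < best_cost:
                best_node, best_cost = node, cost
        related = [f for f in factors if best_node in f.nodes]
        rest = [f for f in factors if best_node not in f.nodes]
        prod = related[0]
        for f in related[1:]:
            prod = prod.multiply(f)
        rest.append(prod.sum_out(best_node))
        factors = rest
        hidden.discard(best_node)
    result = factors[0]
    for f in factors[1:]:
        result = result.multiply(f)
    if result.nodes != (query,):
        result_table = result.table.reshape(-1)  # pragma: no cover
        raise ValidationError("elimination left unexpected nodes")
    total = result.table.sum()
    if total <= 0:
        raise InconsistentEvidenceError(
            f"evidence {evidence} has probability zero under the model")
    return result.table / total


def brute_force_marginal(model: DbnModel, evidence: dict[Node, int],
                         query: Node, n_slices: int = 3) -> np.ndarray:
    """Posterior by plain enumeration of the full unrolled joint.

    Independent of :func:`infer`'s elimination machinery: walks every joint
    assignment and multiplies CPT entries directly.  Exponential in the node
    count — use only on small networks.
    """
    _validate_evidence(model, evidence, n_slices)
    variables = model.variables
    nodes = [(v, t) for t in range(n_slices) for v in variables]
    cards = [model.cardinalities[v] for v, _ in nodes]
    col = {node: i for i, node in enumerate(nodes)}
    # all joint assignments, one row each (exponential in the node count)
    grids = np.meshgrid(*(np.arange(c) for c in cards), indexing="ij")
    assignments = np.stack([g.ravel() for g in grids], axis=1)
    prob = np.ones(len(assignments))
    for v in variables:
        parents = model.initial_parents(v)
        pcols = assignments[:, [col[(p, 0)] for p, _ in parents]]
        if parents:
            rows = np.ravel_multi_index(
                tuple(pcols.T), [model.cardinalities[p] for p, _ in parents])
        else:
            rows = np.zeros(len(assignments), dtype=int)
        prob *= model.initial_cpts[v][rows, assignments[:, col[(v, 0)]]]
        parents = model.transition_parents(v)
        for t in range(1, n_slices):
            pcols = assignments[:, [col[(p, t + lag)] for p, lag in parents]]
            if parents:
                rows = np.ravel_multi_index(
                    tuple(pcols.T),
                    [model.cardinalities[p] for p, _ in parents])
            else:
                rows = np.zeros(len(assignments), dtype=int)
            prob *= model.transition_cpts[v][rows, assignments[:, col[(v, t)]]]
    keep = np.ones(len(assignments), dtype=bool)
    for node, state in evidence.items():
        keep &= assignments[:, col[node]] == state
    qv, _ = query
    out = np.zeros(model.cardinalities[qv])
    np.add.at(out, assignments[keep, col[query]], prob[keep])
    total = out.sum()
    if total <= 0:
        raise InconsistentEvidenceError("evidence has probability zero")
    return out / total


def predict_relapse(model: DbnModel, evidence: dict[Node, int],
                    n_slices: int = 3, relapse_var: str = "relapse",
                    threshold: float = 0.5):
    """Relapse probability and binary call at every future visit.

    Evidence must cover at least the baseline visit; forecasts are produced
    for every slice after the last evidence slice.
    """
    if not evidence or min(t for _, t in evidence) > 0:
        raise ValidationError("evidence must cover at least the baseline slice")
    last = max(t for _, t in evidence)
    horizons = {}
    for s in range(last + 1, n_slices):
        posterior = infer(model, evidence, (relapse_var, s), n_slices)
        prob = float(posterior[1])
        horizons[s] = (prob, prob >= threshold)
    return horizons
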