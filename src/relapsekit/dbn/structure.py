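"""Structure of a two-slice temporal Bayesian network (2-TBN).

A dynamic Bayesian network over follow-up visits is specified by a set of
*intra-slice* edges (dependencies between variables measured at the same
visit) and *inter-slice* edges (dependencies from a variable at visit ``t``
to a variable at visit ``t+1``).  The transition model is stationary: the
same inter/intra pattern is shared by every consecutive visit pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from ..containers import ValidationError


@dataclass(frozen=True)
class DbnStructure:
    """Edge sets of a 2-TBN over named variables.

    Edges are ``(parent, child)`` pairs.  Intra-slice edges must form a DAG;
    inter-slice edges always point forward in time, so self-loops such as
    ``("g1", "g1")`` are legal there (persistence of a variable).
    """

    variables: tuple[str, ...]
    intra_edges: frozenset = field(default_factory=frozenset)
    inter_edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "intra_edges", frozenset(self.intra_edges))
        object.__setattr__(self, "inter_edges", frozenset(self.inter_edges))
        known = set(self.variables)
        for p, c in self.intra_edges | self.inter_edges:
            if p not in known or c not in known:
                raise ValidationError(f"edge ({p}, {c}) uses unknown variable")
        for p, c in self.intra_edges:
            if p == c:
                raise ValidationError(f"intra-slice self-loop on {p}")
        if not self.is_intra_acyclic():
            raise ValidationError("intra-slice edges contain a cycle")

    def is_intra_acyclic(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.intra_edges)
        return nx.is_directed_acyclic_graph(g)

    def _order(self, names) -> tuple[str, ...]:
        pos = {v: i for i, v in enumerate(self.variables)}
        return tuple(sorted(names, key=pos.__getitem__))

    def intra_parents(self, child: str) -> tuple[str, ...]:
        return self._order(p for p, c in self.intra_edges if c == child)

    def inter_parents(self, child: str) -> tuple[str, ...]:
        return self._order(p for p, c in self.inter_edges if c == child)

    def n_parents(self, child: str) -> int:
        return (sum(1 for _, c in self.intra_edges if c == child)
                + sum(1 for _, c in self.inter_edges if c == child))

    def topological_order(self) -> list[str]:
        """Variables ordered so every intra-slice parent precedes its child."""
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.intra_edges)
        pos = {v: i for i, v in enumerate(self.variables)}
        return list(nx.lexicographical_topological_sort(g, key=pos.__getitem__))

    def with_edges(self, intra=None, inter=None) -> "DbnStructure":
        return DbnStructure(self.variables,
                            self.intra_edges if intra is None else intra,
                            self.inter_edges if inter is None else inter)

    # -- plain-text serialization (one edge per line) ------------------------

    def to_lines(self) -> list[str]:
        lines = [f"{c}\t{p}\tintra" for p, c in sorted(self.intra_edges)]
        lines += [f"{c}\t{p}\tinter" for p, c in sorted(self.inter_edges)]
        return lines

    @classmethod
    def from_lines(cls, variables, lines) -> "DbnStructure":
        intra, inter = set(), set()
        for line in lines:
            line = line.strip()
            if not line:
                continue
            child, parent, kind = line.split("\t")
            {"intra": intra, "inter": inter}[kind].add((parent, child))
        return cls(tuple(variables), frozenset(intra), frozenset(inter))
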