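"""Directed multistate structures: states, transitions and their roles.

A multistate model is specified by a finite set of state labels and a set of
directed transitions between them.  Three roles follow from the edge set
alone: *initial* states (in-degree 0) are where a subject may start,
*absorbing* states (out-degree 0) are where the process ends, and every
other state is *transient*.  The graph must be acyclic: a subject can never
traverse the same transition twice, which is what makes per-transition event
and subject counts coincide and guarantees that path simulation terminates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = ["StateGraph", "build_graph", "remove_transition", "GraphError"]


class GraphError(ValueError):
    """Raised when a state/transition specification is structurally invalid."""


@dataclass(frozen=True)
class StateGraph:
    """Validated multistate structure.

    Parameters
    ----------
    states
        Ordered unique state labels; internal indices are 1-based positions
        in this list (declaration order, so outputs match user labels).
    transitions
        Ordered directed pairs ``(k, l)`` of state labels, indexed 1..M in
        declaration order.
    roles
        Map from state label to ``"initial"``, ``"transient"`` or
        ``"absorbing"``, derived purely from in/out degrees.
    """

    states: tuple[str, ...]
    transitions: tuple[tuple[str, str], ...]
    roles: dict[str, str] = field(compare=False)

    # -- convenience accessors -------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        """1-based index of a state in declaration order."""
        return self.states.index(label) + 1

    def transition_index(self, k: str, l: str) -> int:
        """1-based index of transition ``k -> l`` in declaration order."""
        return self.transitions.index((k, l)) + 1

    def successors(self, k: str) -> list[str]:
        return [b for (a, b) in self.transitions if a == k]

    def predecessors(self, l: str) -> list[str]:
        return [a for (a, b) in self.transitions if b == l]

    @property
    def initial_states(self) -> list[str]:
        return [s for s in self.states if self.roles[s] == "initial"]

    @property
    def transient_states(self) -> list[str]:
        return [s for s in self.states if self.roles[s] == "transient"]

    @property
    def absorbing_states(self) -> list[str]:
        return [s for s in self.states if self.roles[s] == "absorbing"]

    def topological_order(self) -> list[str]:
        """A topological order of the states (deterministic: ties broken by
        declaration index, never by label)."""
        g = self._nx()
        order = list(
            nx.lexicographical_topological_sort(g, key=lambda s: self.states.index(s))
        )
        return order

    def _nx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        g.add_edges_from(self.transitions)
        return g

    def to_dict(self) -> dict:
        return {"states": list(self.states), "transitions": [list(t) for t in self.transitions]}

    @classmethod
    def from_dict(cls, d: dict) -> "StateGraph":
        return build_graph(d["states"], [tuple(t) for t in d["transitions"]])


def _assign_roles(states, transitions) -> dict[str, str]:
    indeg = {s: 0 for s in states}
    outdeg = {s: 0 for s in states}
    for k, l in transitions:
        outdeg[k] += 1
        indeg[l] += 1
    roles = {}
    for s in states:
        if outdeg[s] == 0:
            roles[s] = "absorbing"
        elif indeg[s] == 0:
            roles[s] = "initial"
        else:
            roles[s] = "transient"
    return roles


def build_graph(states, transitions) -> StateGraph:
    """Build and validate a :class:`StateGraph`.

    Raises :class:`GraphError` on duplicate states, duplicate or self-loop
    transitions, endpoints not declared as states, cycles, isolated states
    (touching no transition), or absence of an absorbing state.
    """
    states = tuple(str(s) for s in states)
    if len(set(states)) != len(states):
        dupes = sorted({s for s in states if list(states).count(s) > 1})
        raise GraphError(f"duplicate state labels: {dupes}")
    transitions = tuple((str(k), str(l)) for k, l in transitions)
    seen = set()
    for k, l in transitions:
        if k == l:
            raise GraphError(f"self-transition {k} -> {l} is not allowed")
        if k not in states or l not in states:
            raise GraphError(f"transition {k} -> {l} references an undeclared state")
        if (k, l) in seen:
            raise GraphError(f"duplicate transition {k} -> {l}")
        seen.add((k, l))

    g = nx.DiGraph()
    g.add_nodes_from(states)
    g.add_edges_from(transitions)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        pretty = " -> ".join([cycle[0][0]] + [e[1] for e in cycle])
        raise GraphError(f"transition structure contains a cycle: {pretty}")

    touched = {s for t in transitions for s in t}
    isolated = [s for s in states if s not in touched]
    if isolated:
        raise GraphError(
            f"states {isolated} appear in no transition; a state cannot be "
            "both initial and absorbing"
        )

    roles = _assign_roles(states, transitions)
    if not any(r == "absorbing" for r in roles.values()):
        raise GraphError("at least one absorbing state is required")
    return StateGraph(states=states, transitions=transitions, roles=roles)


def remove_transition(graph: StateGraph, k: str, l: str) -> StateGraph:
    """Return a new graph without transition ``k -> l``.

    Roles are recomputed; a state left untouched by every remaining
    transition is dropped from the state set.
    """
    if (k, l) not in graph.transitions:
        raise GraphError(f"transition {k} -> {l} is not in the graph")
    remaining = tuple(t for t in graph.transitions if t != (k, l))
    touched = {s for t in remaining for s in t}
    states = tuple(s for s in graph.states if s in touched)
    return build_graph(states, remaining)
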