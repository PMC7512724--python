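"""Data model and validation for discrete Bayesian networks.

A :class:`DiscreteBayesNet` is a directed acyclic graph over categorical
nodes, each quantified by a conditional probability table (CPT) giving the
node's distribution for every joint state of its parents.  The joint
distribution of the network is the product of these conditional
distributions, which is what the inference module exploits.

Conventions fixed here and relied on everywhere else:

* CPT rows are keyed by parent joint-state tuples in declared parent order,
  enumerated canonically with the LAST parent varying fastest
  (:func:`itertools.product` order).
* State labels are case-sensitive exact strings; ``"Good"`` and ``"good"``
  are different states.
* Rows whose sum deviates from 1 by at most ``RENORM_TOL`` are renormalised
  with a warning at construction; larger deviations are left in place so
  that :func:`validate_network` can report them.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import InputError, StructureError

#: rows are considered normalised when |sum - 1| is below this
SUM_TOL = 1e-9
#: rows off by at most this much are silently repaired (elicitation rounding)
RENORM_TOL = 1e-6


@dataclass(frozen=True)
class StateSpace:
    """Ordered categorical state space of one node."""

    node: str
    states: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        if not self.node:
            raise InputError("node name must be a non-empty string")
        if len(self.states) < 2:
            raise InputError(f"node {self.node!r} needs >= 2 states, got {len(self.states)}")
        if any(not isinstance(s, str) or not s for s in self.states):
            raise InputError(f"node {self.node!r}: state labels must be non-empty strings")
        if len(set(self.states)) != len(self.states):
            raise InputError(f"node {self.node!r}: duplicate state labels in {self.states}")

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise InputError(
                f"state {state!r} not in node {self.node!r} (states: {list(self.states)})"
            ) from None

    def __len__(self) -> int:
        return len(self.states)


class CPT:
    """Conditional probability table P(child | parents).

    Parameters
    ----------
    child : str
        Name of the child node.
    child_states : sequence of str
        Ordered states of the child.
    parents : sequence of str
        Ordered parent names (may be empty).
    parent_states : sequence of sequence of str
        One state list per parent, same order as ``parents``.
    table : array-like or mapping
        Either a 2-D array of shape ``(n_rows, n_child_states)`` in
        canonical row order (last parent fastest), or a mapping from
        parent joint-state tuples to probability vectors.
    """

    __slots__ = ("child", "child_states", "parents", "parent_states", "table")

    def __init__(
        self,
        child: str,
        child_states: Sequence[str],
        parents: Sequence[str] = (),
        parent_states: Sequence[Sequence[str]] = (),
        table=None,
    ):
        self.child = child
        self.child_states = tuple(child_states)
        self.parents = tuple(parents)
        self.parent_states = tuple(tuple(s) for s in parent_states)
        if len(self.parents) != len(self.parent_states):
            raise InputError(
                f"CPT for {child!r}: {len(self.parents)} parents but "
                f"{len(self.parent_states)} parent state lists"
            )
        n_rows = self.n_rows
        if isinstance(table, Mapping):
            arr = np.full((n_rows, len(self.child_states)), np.nan)
            seen = set()
            for key, row in table.items():
                key = (key,) if isinstance(key, str) else tuple(key)
                idx = self.row_index(key)
                if idx in seen:
                    raise InputError(f"CPT for {child!r}: duplicate row for {key}")
                seen.add(idx)
                arr[idx] = np.asarray(row, dtype=float)
            if len(seen) != n_rows:
                missing = [
                    combo for i, combo in enumerate(self.parent_combinations()) if i not in seen
                ]
                raise InputError(f"CPT for {child!r}: missing rows for {missing[:3]}")
        else:
            arr = np.asarray(table, dtype=float)
            if arr.ndim == 1:
                arr = arr.reshape(1, -1) if not self.parents else arr.reshape(n_rows, -1)
            if arr.shape != (n_rows, len(self.child_states)):
                raise InputError(
                    f"CPT for {child!r}: table shape {arr.shape} != "
                    f"({n_rows}, {len(self.child_states)})"
                )
        arr = arr.copy()
        # repair benign elicitation rounding, keep real violations visible
        sums = arr.sum(axis=1)
        fixable = (np.abs(sums - 1.0) > SUM_TOL) & (np.abs(sums - 1.0) <= RENORM_TOL)
        if fixable.any():
            warnings.warn(
                f"CPT for {child!r}: renormalised {int(fixable.sum())} row(s) "
                f"with |sum-1| <= {RENORM_TOL:g}",
                stacklevel=2,
            )
            arr[fixable] /= sums[fixable, None]
        arr.flags.writeable = False
        self.table = arr

    # -- canonical row indexing -------------------------------------------

    @property
    def n_rows(self) -> int:
        return int(np.prod([len(s) for s in self.parent_states], dtype=np.int64)) if self.parents else 1

    def parent_combinations(self) -> Iterator[tuple[str, ...]]:
        """Canonical enumeration of parent joint states (last parent fastest)."""
        if not self.parents:
            yield ()
        else:
            yield from itertools.product(*self.parent_states)

    def row_index(self, parent_assignment: Sequence[str]) -> int:
        combo = tuple(parent_assignment)
        if len(combo) != len(self.parents):
            raise InputError(
                f"CPT for {self.child!r}: assignment {combo} does not match parents {self.parents}"
            )
        idx = 0
        for value, states, name in zip(combo, self.parent_states, self.parents):
            try:
                pos = states.index(value)
            except ValueError:
                raise InputError(
                    f"CPT for {self.child!r}: {value!r} is not a state of parent {name!r}"
                ) from None
            idx = idx * len(states) + pos
        return idx

    def row(self, parent_assignment: Sequence[str] = ()) -> np.ndarray:
        return self.table[self.row_index(parent_assignment)]

    def prob(self, child_state: str, parent_assignment: Sequence[str] = ()) -> float:
        try:
            j = self.child_states.index(child_state)
        except ValueError:
            raise InputError(
                f"{child_state!r} is not a state of node {self.child!r}"
            ) from None
        return float(self.row(parent_assignment)[j])

    # ---------------------------------------------------------------------

    def replace_table(self, table: np.ndarray) -> "CPT":
        return CPT(self.child, self.child_states, self.parents, self.parent_states, table)

    def __eq__(self, other):
        if not isinstance(other, CPT):
            return NotImplemented
        return (
            self.child == other.child
            and self.child_states == other.child_states
            and self.parents == other.parents
            and self.parent_states == other.parent_states
            and np.array_equal(self.table, other.table)
        )

    def allclose(self, other: "CPT", atol: float = 1e-9) -> bool:
        return (
            self.child == other.child
            and self.child_states == other.child_states
            and self.parents == other.parents
            and self.parent_states == other.parent_states
            and np.allclose(self.table, other.table, atol=atol, rtol=0.0)
        )

    def __repr__(self):
        return f"CPT({self.child!r} | {list(self.parents)}, {self.n_rows} rows)"


@dataclass(frozen=True)
class Evidence:
    """Clamped node states: each listed node is observed in one state."""

    assignments: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "assignments", dict(self.assignments))

    @classmethod
    def coerce(cls, value) -> "Evidence":
        if value is None:
            return cls({})
        if isinstance(value, Evidence):
            return value
        return cls(dict(value))

    def __contains__(self, node):
        return node in self.assignments

    def __len__(self):
        return len(self.assignments)

    def __iter__(self):
        return iter(self.assignments)

    def items(self):
        return self.assignments.items()

    def get(self, node, default=None):
        return self.assignments.get(node, default)

    def validate_against(self, net: "DiscreteBayesNet") -> None:
        for node, state in self.assignments.items():
            if node not in net.nodes:
                raise InputError(f"evidence node {node!r} not in network")
            net.nodes[node].index(state)  # raises on unknown state


class DiscreteBayesNet:
    """A DAG of categorical nodes with one CPT per node.

    ``nodes`` preserves insertion order, which fixes the serialisation
    order; graph semantics never depend on it.
    """

    def __init__(
        self,
        nodes: Mapping[str, StateSpace] | Iterable[StateSpace],
        edges: Iterable[tuple[str, str]] = (),
        cpts: Mapping[str, CPT] | Iterable[CPT] = (),
    ):
        if isinstance(nodes, Mapping):
            self.nodes: dict[str, StateSpace] = dict(nodes)
        else:
            self.nodes = {s.node: s for s in nodes}
        self.edges: set[tuple[str, str]] = {(p, c) for p, c in edges}
        if isinstance(cpts, Mapping):
            self.cpts: dict[str, CPT] = dict(cpts)
        else:
            self.cpts = {c.child: c for c in cpts}

    @classmethod
    def from_cpts(cls, cpts: Iterable[CPT]) -> "DiscreteBayesNet":
        """Build a network whose node set, states and edges are implied by the CPTs."""
        cpts = list(cpts)
        nodes = {c.child: StateSpace(c.child, c.child_states) for c in cpts}
        edges = {(p, c.child) for c in cpts for p in c.parents}
        return cls(nodes, edges, cpts)

    def parents_of(self, node: str) -> tuple[str, ...]:
        return self.cpts[node].parents if node in self.cpts else ()

    def copy_with_cpts(self, cpts: Mapping[str, CPT]) -> "DiscreteBayesNet":
        return DiscreteBayesNet(dict(self.nodes), set(self.edges), dict(cpts))

    def state_space_size(self) -> int:
        return int(np.prod([len(s) for s in self.nodes.values()], dtype=np.int64))

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def equal_within(self, other: "DiscreteBayesNet", atol: float = 1e-9) -> bool:
        if set(self.nodes) != set(other.nodes) or self.edges != other.edges:
            return False
        if any(self.nodes[n].states != other.nodes[n].states for n in self.nodes):
            return False
        return all(self.cpts[n].allclose(other.cpts[n], atol=atol) for n in self.nodes)

    def __repr__(self):
        return f"DiscreteBayesNet({len(self.nodes)} nodes, {len(self.edges)} edges)"


@dataclass(frozen=True)
class Violation:
    """One validation failure, attributable to a node and optionally a CPT row."""

    kind: str
    node: str | None
    detail: str

    def __str__(self):
        where = f" [{self.node}]" if self.node else ""
        return f"{self.kind}{where}: {self.detail}"


def validate_network(net: DiscreteBayesNet) -> list[Violation]:
    """Check every structural and numerical invariant; empty list means valid.

    Reported violations: non-DAG edge sets, edges touching unknown nodes,
    missing or surplus CPTs, CPT parents disagreeing with the in-edges,
    CPT state spaces disagreeing with the node declarations, rows not
    summing to one, entries outside [0, 1].
    """
    report: list[Violation] = []

    for p, c in sorted(net.edges):
        for end in (p, c):
            if end not in net.nodes:
                report.append(Violation("unknown-node", end, f"edge ({p}, {c}) references undeclared node"))

    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((p, c) for p, c in net.edges if p in net.nodes and c in net.nodes)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        report.append(
            Violation("cycle", cycle[0][0], "cycle detected: " + " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}")
        )

    for name in net.nodes:
        if name not in net.cpts:
            report.append(Violation("missing-cpt", name, "node has no CPT"))
    for name in net.cpts:
        if name not in net.nodes:
            report.append(Violation("surplus-cpt", name, "CPT for undeclared node"))

    for name, cpt in net.cpts.items():
        if name not in net.nodes:
            continue
        space = net.nodes[name]
        if cpt.child != name:
            report.append(Violation("cpt-child-mismatch", name, f"CPT child is {cpt.child!r}"))
            continue
        if cpt.child_states != space.states:
            report.append(
                Violation("state-mismatch", name, f"CPT states {list(cpt.child_states)} != declared {list(space.states)}")
            )
        in_edges = {p for p, c in net.edges if c == name}
        if set(cpt.parents) != in_edges:
            report.append(
                Violation("parent-mismatch", name, f"CPT parents {list(cpt.parents)} != in-edges {sorted(in_edges)}")
            )
        for parent, pstates in zip(cpt.parents, cpt.parent_states):
            if parent in net.nodes and net.nodes[parent].states != pstates:
                report.append(
                    Violation(
                        "parent-state-mismatch",
                        name,
                        f"parent {parent!r} states {list(pstates)} != declared {list(net.nodes[parent].states)}",
                    )
                )
        for i, combo in enumerate(cpt.parent_combinations()):
            row = cpt.table[i]
            s = float(row.sum())
            if not math.isclose(s, 1.0, abs_tol=SUM_TOL):
                report.append(
                    Violation("row-sum", name, f"row {combo or '()'} sum {s:.6g} != 1")
                )
            if (row < 0).any() or (row > 1).any():
                report.append(
                    Violation("row-range", name, f"row {combo or '()'} has entries outside [0, 1]")
                )
    return report


def require_valid(net: DiscreteBayesNet) -> None:
    """Raise :class:`NetworkValidationError` if the network is invalid."""
    from .errors import NetworkValidationError

    report = validate_network(net)
    if report:
        raise NetworkValidationError(
            f"invalid network: {len(report)} violation(s); first: {report[0]}", report
        )


def topological_order(net: DiscreteBayesNet) -> list[str]:
    """Parents-first node order, deterministic (lexicographic tie-break)."""
    g = net.to_digraph()
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        raise StructureError(
            f"graph has a cycle through edge {cycle[0][:2]}"
        ) from None
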