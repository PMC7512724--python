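"""Exact inference on discrete Bayesian networks.

:func:`marginal` computes P(target | evidence) by variable elimination:
each CPT becomes a factor (a multidimensional array indexed by its scope),
evidence slices the factors, and all remaining variables except the target
are summed out one at a time in a min-degree order on the moralised graph.
Conditioning normalises by P(evidence); evidence of probability zero is an
explicit error rather than a NaN, because the pooling layer must decide how
to treat an expert for whom the evidence is impossible.

:func:`enumerate_joint` is the brute-force oracle: the full joint table
obtained by multiplying CPT entries over every complete assignment.  It is
exponential in the number of nodes and capped accordingly; inference proper
never uses it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bn_core import SUM_TOL, DiscreteBayesNet, Evidence, topological_order
from .errors import ImpossibleEvidenceError, InputError

ENUMERATION_CAP = 2**20


@dataclass(frozen=True)
class MarginalDistribution:
    """P(node | evidence) as a vector aligned with the node's state order."""

    node: str
    states: tuple[str, ...]
    probabilities: np.ndarray
    evidence: Evidence = field(default_factory=Evidence)

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        p.flags.writeable = False
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "states", tuple(self.states))
        if p.shape != (len(self.states),):
            raise InputError(
                f"marginal for {self.node!r}: {p.shape[0]} probabilities for {len(self.states)} states"
            )
        if abs(float(p.sum()) - 1.0) > SUM_TOL or (p < -SUM_TOL).any():
            raise InputError(f"marginal for {self.node!r} is not a distribution: {p}")

    def prob(self, state: str) -> float:
        try:
            return float(self.probabilities[self.states.index(state)])
        except ValueError:
            raise InputError(f"{state!r} is not a state of {self.node!r}") from None

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(self.states, self.probabilities)}


class _Factor:
    """A nonnegative function over a tuple of variables, stored densely."""

    __slots__ = ("vars", "array")

    def __init__(self, variables: tuple[str, ...], array: np.ndarray):
        self.vars = variables
        self.array = array

    def reduce(self, var: str, index: int) -> "_Factor":
        axis = self.vars.index(var)
        sl = [slice(None)] * self.array.ndim
        sl[axis] = index
        return _Factor(self.vars[:axis] + self.vars[axis + 1 :], self.array[tuple(sl)])

    def sum_out(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(self.vars[:axis] + self.vars[axis + 1 :], self.array.sum(axis=axis))


def _multiply(factors: list[_Factor]) -> _Factor:
    scope: dict[str, None] = {}
    for f in factors:
        for v in f.vars:
            scope.setdefault(v)
    union = tuple(scope)
    out = None
    for f in factors:
        arr = f.array
        missing = tuple(v for v in union if v not in f.vars)
        arr = arr.reshape(arr.shape + (1,) * len(missing))
        order = f.vars + missing
        arr = arr.transpose([order.index(v) for v in union]) if union else arr
        out = arr if out is None else out * arr
    return _Factor(union, out if out is not None else np.array(1.0))


def _cpt_factor(net: DiscreteBayesNet, node: str) -> _Factor:
    cpt = net.cpts[node]
    shape = tuple(len(s) for s in cpt.parent_states) + (len(cpt.child_states),)
    # canonical row order (last parent fastest) is exactly row-major order
    return _Factor(cpt.parents + (node,), cpt.table.reshape(shape))


def _elimination_order(scopes: list[tuple[str, ...]], eliminate: set[str]) -> list[str]:
    """Min-degree order on the interaction graph, lexicographic tie-break."""
    neighbors: dict[str, set[str]] = {v: set() for v in eliminate}
    for scope in scopes:
        for a in scope:
            if a in neighbors:
                neighbors[a].update(b for b in scope if b != a)
    order = []
    remaining = set(eliminate)
    while remaining:
        v = min(remaining, key=lambda u: (len(neighbors[u] & remaining), u))
        order.append(v)
        remaining.discard(v)
        live = neighbors[v] & remaining
        for a in live:  # connect the clique left behind by eliminating v
            neighbors[a].update(b for b in live if b != a)
    return order


def marginal(net: DiscreteBayesNet, target: str, evidence=None) -> MarginalDistribution:
    """Exact P(target | evidence) by variable elimination.

    Raises
    ------
    InputError
        Unknown target/evidence node or state, or target clamped as evidence.
    ImpossibleEvidenceError
        The evidence has probability zero under the network.
    """
    ev = Evidence.coerce(evidence)
    if target not in net.nodes:
        raise InputError(f"target node {target!r} not in network")
    if target in ev:
        raise InputError(f"target {target!r} is clamped as evidence")
    ev.validate_against(net)

    factors = [_cpt_factor(net, node) for node in net.nodes]
    for node, state in ev.items():
        idx = net.nodes[node].index(state)
        factors = [f.reduce(node, idx) if node in f.vars else f for f in factors]

    to_eliminate = set(net.nodes) - set(ev.assignments) - {target}
    order = _elimination_order([f.vars for f in factors], to_eliminate)
    for var in order:
        touching = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        factors = rest + [_multiply(touching).sum_out(var)]

    result = _multiply(factors)
    vec = result.array if result.vars == (target,) else np.asarray(result.array).reshape(-1)
    norm = float(vec.sum())
    if norm <= 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {dict(ev.items())} has probability {norm:g}", probability=norm
        )
    return MarginalDistribution(target, net.nodes[target].states, vec / norm, ev)


def marginals(net: DiscreteBayesNet, targets: Sequence[str], evidence=None) -> dict[str, MarginalDistribution]:
    """Convenience map of :func:`marginal` over several targets, one evidence set."""
    return {t: marginal(net, t, evidence) for t in targets}


def joint_probability(net: DiscreteBayesNet, assignment: Mapping[str, str]) -> float:
    """P(assignment) as the product of the CPT entries it selects.

    ``assignment`` must cover every node with one of its legal states.
    """
    missing = set(net.nodes) - set(assignment)
    if missing:
        raise InputError(f"assignment misses node(s) {sorted(missing)}")
    extra = set(assignment) - set(net.nodes)
    if extra:
        raise InputError(f"assignment has unknown node(s) {sorted(extra)}")
    p = 1.0
    for node, space in net.nodes.items():
        space.index(assignment[node])  # state legality
        cpt = net.cpts[node]
        parent_combo = tuple(assignment[parent] for parent in cpt.parents)
        p *= cpt.prob(assignment[node], parent_combo)
    return p


@dataclass(frozen=True)
class JointTable:
    """Full joint distribution over all nodes; the brute-force oracle."""

    nodes: tuple[str, ...]
    states: tuple[tuple[str, ...], ...]
    probabilities: Mapping[tuple[str, ...], float]

    def marginal(self, target: str, evidence=None) -> np.ndarray:
        """Renormalised sum of consistent joint entries; oracle for :func:`marginal`."""
        ev = Evidence.coerce(evidence)
        t = self.nodes.index(target)
        target_states = self.states[t]
        clamp = {self.nodes.index(n): s for n, s in ev.items()}
        vec = np.zeros(len(target_states))
        for combo, p in self.probabilities.items():
            if all(combo[i] == s for i, s in clamp.items()):
                vec[target_states.index(combo[t])] += p
        total = vec.sum()
        if total <= 0.0:
            raise ImpossibleEvidenceError(
                f"evidence {dict(ev.items())} has probability {total:g}", probability=float(total)
            )
        return vec / total


def enumerate_joint(net: DiscreteBayesNet, cap: int = ENUMERATION_CAP) -> JointTable:
    """Tabulate :func:`joint_probability` over every complete assignment.

    Refuses when the state space exceeds ``cap`` (default 2**20) — this is
    a test oracle, not an inference method.
    """
    size = net.state_space_size()
    if size > cap:
        raise InputError(f"joint table would need {size} entries (cap {cap})")
    order = tuple(topological_order(net))
    spaces = tuple(net.nodes[n].states for n in order)
    table: dict[tuple[str, ...], float] = {}
    for combo in itertools.product(*spaces):
        table[combo] = joint_probability(net, dict(zip(order, combo)))
    total = sum(table.values())
    if abs(total - 1.0) > SUM_TOL:
        raise InputError(f"joint table sums to {total!r}; network invalid?")
    return JointTable(order, spaces, table)
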