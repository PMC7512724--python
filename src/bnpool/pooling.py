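"""Linear opinion pooling of expert Bayesian networks.

Two combination routes, both built on the linear opinion pool
P(X) = sum_i w_i P_i(X) with positive weights summing to one:

* **Prior Linear Pooling (PrLP)** pools the experts' probabilities within
  every CPT row first, producing one consensus network, and propagates
  that single network.  After pooling, each CPT row is an average of the
  experts' rows, so the conditional independence statements no longer
  reflect any individual's assessment.

* **Posterior Linear Pooling (PoLP)** builds one network per expert,
  propagates each individually, and pools the resulting marginals at the
  requested nodes.  Pooling happens per node, never jointly over several
  nodes.

With no evidence the PoLP marginal at a node equals the marginal of the
weighted mixture of the experts' joint distributions.  Under evidence the
two differ: PoLP averages the per-expert *posteriors* with the panel
weights unchanged, whereas the mixture posterior would reweight each
expert by how likely the evidence is under their network.  The unweighted
reading is what is implemented; see ``docs/methods.md``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn_core import CPT, SUM_TOL, DiscreteBayesNet, Evidence
from .errors import ImpossibleEvidenceError, InputError
from .inference import MarginalDistribution, marginal
from .panel import ExpertPanel, require_valid_panel

logger = logging.getLogger(__name__)

PRLP = "PrLP"
POLP = "PoLP"


@dataclass(frozen=True)
class PooledResult:
    """Pooled per-node marginals with their provenance."""

    method: str
    evidence: Evidence
    marginals: Mapping[str, MarginalDistribution]
    panel_label: str = "All"
    n_experts: int = 0

    def __post_init__(self):
        object.__setattr__(self, "marginals", dict(self.marginals))
        if self.method not in (PRLP, POLP):
            raise InputError(f"method must be {PRLP!r} or {POLP!r}, got {self.method!r}")

    def prob(self, node: str, state: str) -> float:
        return self.marginals[node].prob(state)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": self.method,
                "subgroup": self.panel_label,
                "node": node,
                "state": state,
                "value": float(p),
            }
            for node, m in self.marginals.items()
            for state, p in zip(m.states, m.probabilities)
        ]
        return pd.DataFrame(rows, columns=["method", "subgroup", "node", "state", "value"])


def linear_pool(distributions: Sequence[np.ndarray], weights: Sequence[float]) -> np.ndarray:
    """The linear opinion pool: componentwise sum of w_i * P_i.

    Every distribution must be normalised over the same state space and the
    weights must be positive and sum to one.  The output is renormalised to
    absorb float error (it is already normalised in exact arithmetic).
    """
    if len(distributions) == 0:
        raise InputError("need at least one distribution to pool")
    rows = [np.asarray(d, dtype=float) for d in distributions]
    if len({r.shape for r in rows}) != 1 or rows[0].ndim != 1:
        raise InputError("distributions have mismatched lengths")
    mat = np.asarray(rows)
    w = np.asarray(weights, dtype=float)
    if w.shape != (mat.shape[0],):
        raise InputError(f"{mat.shape[0]} distributions but {w.size} weights")
    if (w <= 0).any():
        raise InputError("weights must be strictly positive")
    if abs(float(w.sum()) - 1.0) > SUM_TOL:
        raise InputError(f"weights sum to {float(w.sum())!r}, not 1")
    sums = mat.sum(axis=1)
    if (np.abs(sums - 1.0) > 1e-6).any() or (mat < 0).any():
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise InputError(f"distribution {bad} is not normalised (sum {sums[bad]!r})")
    pooled = w @ mat
    return pooled / pooled.sum()


def prior_linear_pool(panel: ExpertPanel) -> DiscreteBayesNet:
    """Pool every CPT row across experts, returning one consensus network."""
    require_valid_panel(panel)
    w = panel.weight_vector()
    pooled: dict[str, CPT] = {}
    for node in panel.structure.nodes:
        template = panel.experts[0].cpts[node]
        stack = np.stack([e.cpts[node].table for e in panel.experts])  # (n, rows, states)
        table = np.einsum("i,irs->rs", w, stack)
        table /= table.sum(axis=1, keepdims=True)
        pooled[node] = template.replace_table(table)
    return panel.structure.copy_with_cpts(pooled)


def posterior_linear_pool(
    panel: ExpertPanel,
    targets: Sequence[str],
    evidence=None,
    drop_impossible: bool = False,
    panel_label: str = "All",
) -> PooledResult:
    """Propagate each expert's network, then pool the marginals per target.

    ``drop_impossible=True`` excludes experts for whom the evidence has
    probability zero and renormalises the remaining weights (with a logged
    warning); the default is to raise, naming the expert.
    """
    require_valid_panel(panel)
    ev = Evidence.coerce(evidence)
    overlap = set(targets) & set(ev.assignments)
    if overlap:
        raise InputError(f"target(s) {sorted(overlap)} are clamped as evidence")

    per_expert: dict[str, dict[str, MarginalDistribution]] = {}
    for eid, net in panel.expert_networks():
        try:
            per_expert[eid] = {t: marginal(net, t, ev) for t in targets}
        except ImpossibleEvidenceError:
            if not drop_impossible:
                raise ImpossibleEvidenceError(
                    f"evidence {dict(ev.items())} is impossible for expert {eid!r}; "
                    "pass drop_impossible=True to exclude such experts",
                ) from None
            logger.warning("dropping expert %r: evidence %s impossible", eid, dict(ev.items()))
    if not per_expert:
        raise ImpossibleEvidenceError(
            f"evidence {dict(ev.items())} is impossible for every expert"
        )

    kept = [eid for eid in panel.expert_ids if eid in per_expert]
    w = np.array([panel.weights[eid] for eid in kept])
    w = w / w.sum()

    marginals: dict[str, MarginalDistribution] = {}
    for t in targets:
        states = panel.structure.nodes[t].states
        pooled = linear_pool([per_expert[eid][t].probabilities for eid in kept], w)
        marginals[t] = MarginalDistribution(t, states, pooled, ev)
    return PooledResult(POLP, ev, marginals, panel_label=panel_label, n_experts=len(kept))


def prior_pool_marginals(
    panel: ExpertPanel,
    targets: Sequence[str],
    evidence=None,
    panel_label: str = "All",
) -> PooledResult:
    """PrLP end-to-end: pool the CPTs, then propagate the single network."""
    net = prior_linear_pool(panel)
    ev = Evidence.coerce(evidence)
    return PooledResult(
        PRLP,
        ev,
        {t: marginal(net, t, ev) for t in targets},
        panel_label=panel_label,
        n_experts=panel.n_experts,
    )


def compare_pooling(
    panel: ExpertPanel,
    targets: Sequence[str],
    evidence=None,
    drop_impossible: bool = False,
) -> pd.DataFrame:
    """Head-to-head PrLP vs PoLP table: (node, state, prlp, polp, abs_diff)."""
    prlp = prior_pool_marginals(panel, targets, evidence)
    polp = posterior_linear_pool(panel, targets, evidence, drop_impossible=drop_impossible)
    rows = []
    for t in targets:
        for state in panel.structure.nodes[t].states:
            a = prlp.prob(t, state)
            b = polp.prob(t, state)
            rows.append(
                {"node": t, "state": state, "prlp": a, "polp": b, "abs_diff": abs(a - b)}
            )
    return pd.DataFrame(rows, columns=["node", "state", "prlp", "polp", "abs_diff"])
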