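"""Scenario deltas, subgroup comparison tables and across-expert spread.

This module reproduces the analysis workflow of an elicitation case study:
clamp a node of interest to one state (diagnostic or predictive reasoning,
depending on arc direction), tabulate how the other nodes of interest move
relative to a baseline, split the respondent panel into covariate
subgroups and compare their pooled marginals against the full panel, and
describe the across-expert spread of individually propagated marginals
(PoLP exposes one value per expert before pooling, so means, standard
deviations and boxplot statistics are available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn_core import DiscreteBayesNet, Evidence
from .errors import ImpossibleEvidenceError, InputError
from .inference import MarginalDistribution, marginal
from .panel import ExpertPanel, filter_subgroup, subgroup_label
from .pooling import POLP, PRLP, PooledResult, posterior_linear_pool, prior_pool_marginals


def diagnostic_scenario(
    net: DiscreteBayesNet, clamp, report_nodes: Sequence[str]
) -> dict[str, MarginalDistribution]:
    """Clamp nodes to given states and report the updated marginals elsewhere.

    Conditioning against the arc direction is diagnostic reasoning, with it
    predictive; both are the same conditional-marginal computation.
    """
    ev = Evidence.coerce(clamp)
    overlap = set(report_nodes) & set(ev.assignments)
    if overlap:
        raise InputError(f"report node(s) {sorted(overlap)} are clamped")
    return {node: marginal(net, node, ev) for node in report_nodes}


def delta_table(
    baseline: Mapping[str, MarginalDistribution],
    scenarios: Sequence[tuple[str, Mapping[str, MarginalDistribution]]],
) -> pd.DataFrame:
    """Absolute differences of scenario marginals against a baseline.

    One row per (scenario label, node, state):
    ``(label, node, state, baseline, scenario, abs_diff)``.
    """
    rows = []
    for label, scenario in scenarios:
        missing = set(baseline) - set(scenario)
        if missing:
            raise InputError(f"scenario {label!r} misses node(s) {sorted(missing)}")
        for node, base in baseline.items():
            scen = scenario[node]
            if scen.states != base.states:
                raise InputError(
                    f"scenario {label!r}, node {node!r}: states {scen.states} != {base.states}"
                )
            for state, b, s in zip(base.states, base.probabilities, scen.probabilities):
                rows.append(
                    {
                        "label": label,
                        "node": node,
                        "state": state,
                        "baseline": float(b),
                        "scenario": float(s),
                        "abs_diff": abs(float(s) - float(b)),
                    }
                )
    return pd.DataFrame(
        rows, columns=["label", "node", "state", "baseline", "scenario", "abs_diff"]
    )


def per_expert_marginals(
    panel: ExpertPanel,
    node: str,
    state: str,
    evidence=None,
    drop_impossible: bool = False,
) -> np.ndarray:
    """P_i(node=state | evidence) for every expert i, in panel order.

    With ``drop_impossible=True`` experts for whom the evidence has zero
    probability contribute NaN instead of raising.
    """
    ev = Evidence.coerce(evidence)
    out = np.empty(panel.n_experts)
    for i, (eid, net) in enumerate(panel.expert_networks()):
        try:
            out[i] = marginal(net, node, ev).prob(state)
        except ImpossibleEvidenceError:
            if not drop_impossible:
                raise ImpossibleEvidenceError(
                    f"evidence {dict(ev.items())} is impossible for expert {eid!r}"
                ) from None
            out[i] = np.nan
    return out


@dataclass(frozen=True)
class ExpertSpread:
    """Descriptive statistics of per-expert probabilities for one node state."""

    node: str
    state: str
    subgroup: str
    values: np.ndarray
    mean: float
    sd: float
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    def five_number(self) -> tuple[float, float, float, float, float]:
        return (self.minimum, self.q1, self.median, self.q3, self.maximum)


def describe_spread(
    values: Sequence[float], node: str = "", state: str = "", subgroup: str = "All"
) -> ExpertSpread:
    """Mean, sample standard deviation and five-number summary of probabilities.

    The standard deviation uses the n-1 denominator (respondents are a
    sample) and is 0 for a single value; quantiles interpolate linearly
    between order statistics.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("cannot summarise an empty vector")
    if np.isnan(v).any() or (v < 0).any() or (v > 1).any():
        raise InputError("values must be probabilities in [0, 1]")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
    return ExpertSpread(
        node=node,
        state=state,
        subgroup=subgroup,
        values=v,
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        minimum=float(v.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(v.max()),
    )


def spread_report(
    panel: ExpertPanel,
    partitions: Sequence[Mapping[str, str]],
    nodes_states: Sequence[tuple[str, str]],
    evidence=None,
) -> list[ExpertSpread]:
    """Across-expert spread for each (node, state) within each subgroup.

    ``partitions`` is a list of covariate constraint maps; the empty map
    denotes the full panel.
    """
    out = []
    for constraints in partitions:
        sub = filter_subgroup(panel, constraints) if constraints else panel
        label = subgroup_label(constraints)
        for node, state in nodes_states:
            vals = per_expert_marginals(sub, node, state, evidence)
            out.append(describe_spread(vals, node=node, state=state, subgroup=label))
    return out


def _pool(panel, targets, evidence, method, label, drop_impossible=False) -> PooledResult:
    if method == PRLP:
        return prior_pool_marginals(panel, targets, evidence, panel_label=label)
    if method == POLP:
        return posterior_linear_pool(
            panel, targets, evidence, drop_impossible=drop_impossible, panel_label=label
        )
    raise InputError(f"method must be {PRLP!r} or {POLP!r}, got {method!r}")


def subgroup_report(
    panel: ExpertPanel,
    partitions: Sequence[Mapping[str, str]],
    targets: Sequence[str],
    evidence=None,
    method: str = POLP,
    mode: str = "filter",
    drop_impossible: bool = False,
) -> pd.DataFrame:
    """Pooled marginals per subgroup with absolute differences vs the full panel.

    Two subgroup semantics are supported:

    * ``mode="filter"`` — each constraint map selects the matching experts
      (covariate filtering) and the chosen pooling method runs on the
      sub-panel.  This is the natural route for PoLP, where each
      respondent's network exists individually.
    * ``mode="condition"`` — each constraint map is read as evidence
      ``node=state`` on subgroup nodes *inside* the network and combined
      with ``evidence``; the full panel is pooled once.  This is the
      natural route for PrLP when the network itself contains the
      subgroup variables.

    Returns a long-format table ``(method, subgroup, node, state, value,
    abs_diff)`` where ``abs_diff`` compares against the full-panel row
    (labelled ``All``).
    """
    if mode not in ("filter", "condition"):
        raise InputError(f"mode must be 'filter' or 'condition', got {mode!r}")
    ev = Evidence.coerce(evidence)

    results: list[PooledResult] = [
        _pool(panel, targets, ev, method, "All", drop_impossible)
    ]
    for constraints in partitions:
        if not constraints:
            continue
        label = subgroup_label(constraints)
        if mode == "filter":
            sub = filter_subgroup(panel, constraints)
            results.append(_pool(sub, targets, ev, method, label, drop_impossible))
        else:
            combined = Evidence({**dict(ev.items()), **dict(constraints)})
            results.append(_pool(panel, targets, combined, method, label, drop_impossible))

    baseline = results[0]
    rows = []
    for res in results:
        for node in targets:
            m = res.marginals[node]
            for state, p in zip(m.states, m.probabilities):
                rows.append(
                    {
                        "method": res.method,
                        "subgroup": res.panel_label,
                        "node": node,
                        "state": state,
                        "value": float(p),
                        "abs_diff": abs(float(p) - baseline.prob(node, state)),
                        "n_experts": res.n_experts,
                    }
                )
    return pd.DataFrame(
        rows, columns=["method", "subgroup", "node", "state", "value", "abs_diff", "n_experts"]
    )
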