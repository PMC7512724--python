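"""Expert panels: many CPT assessments over one shared network structure.

Each respondent ("expert") supplies a complete set of CPTs for the agreed
structure; the panel additionally carries per-expert categorical covariates
(for subgroup analysis) and positive pooling weights summing to one.  The
default weighting is equal, w_i = 1/n: every respondent's assessment counts
the same.

Subgroups are realised by filtering the panel on covariate categories and
renormalising the weights proportionally, so equal weights stay equal
within the subgroup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bn_core import CPT, SUM_TOL, DiscreteBayesNet, Violation, validate_network
from .errors import EmptySubgroupError, InputError, NetworkValidationError

#: covariate label used when an expert has no recorded value
MISSING = "missing"


@dataclass(frozen=True)
class ExpertAssessment:
    """One expert's complete CPT set over the shared structure."""

    expert_id: str
    cpts: Mapping[str, CPT]

    def __post_init__(self):
        object.__setattr__(self, "cpts", dict(self.cpts))


class ExpertPanel:
    """A panel of n experts sharing one network structure.

    Parameters
    ----------
    structure : DiscreteBayesNet
        The agreed skeleton (nodes, states, edges). Its CPT values, if any,
        are ignored by panel operations.
    experts : sequence of ExpertAssessment
        One assessment per expert; order is preserved and meaningful
        (per-expert outputs are reported in panel order).
    covariates : mapping expert_id -> {covariate: category}, optional
        Missing experts/values are treated as category ``"missing"``.
    weights : mapping expert_id -> float, optional
        Positive, summing to 1. Default: equal weights 1/n.
    """

    def __init__(
        self,
        structure: DiscreteBayesNet,
        experts: Sequence[ExpertAssessment],
        covariates: Mapping[str, Mapping[str, str]] | None = None,
        weights: Mapping[str, float] | None = None,
    ):
        self.structure = structure
        self.experts = list(experts)
        ids = [e.expert_id for e in self.experts]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate expert_id in panel")
        self.covariates = {eid: dict((covariates or {}).get(eid, {})) for eid in ids}
        if weights is None:
            n = len(self.experts)
            self.weights = {eid: 1.0 / n for eid in ids} if n else {}
        else:
            unknown = set(weights) - set(ids)
            if unknown:
                raise InputError(f"weights given for unknown expert(s) {sorted(unknown)}")
            self.weights = {eid: float(weights.get(eid, 0.0)) for eid in ids}

    @property
    def n_experts(self) -> int:
        return len(self.experts)

    @property
    def expert_ids(self) -> list[str]:
        return [e.expert_id for e in self.experts]

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights[e.expert_id] for e in self.experts])

    def covariate_names(self) -> list[str]:
        names: dict[str, None] = {}
        for row in self.covariates.values():
            for k in row:
                names.setdefault(k)
        return list(names)

    def covariate_of(self, expert_id: str, covariate: str) -> str:
        return self.covariates.get(expert_id, {}).get(covariate, MISSING)

    def expert_network(self, expert: str | int | ExpertAssessment) -> DiscreteBayesNet:
        """The BN formed from one expert's CPTs on the shared structure."""
        if isinstance(expert, int):
            expert = self.experts[expert]
        elif isinstance(expert, str):
            try:
                expert = next(e for e in self.experts if e.expert_id == expert)
            except StopIteration:
                raise InputError(f"no expert {expert!r} in panel") from None
        return self.structure.copy_with_cpts(dict(expert.cpts))

    def expert_networks(self):
        for e in self.experts:
            yield e.expert_id, self.structure.copy_with_cpts(dict(e.cpts))

    def __repr__(self):
        return f"ExpertPanel({self.n_experts} experts, {len(self.structure.nodes)} nodes)"


def validate_panel(panel: ExpertPanel) -> list[Violation]:
    """Report every violation of the shared-structure and weight invariants."""
    report: list[Violation] = []
    skeleton_report = [
        v for v in validate_network(panel.structure) if v.kind in ("cycle", "unknown-node")
    ]
    report.extend(skeleton_report)

    if panel.n_experts == 0:
        report.append(Violation("empty-panel", None, "panel has no experts"))
        return report

    w = panel.weight_vector()
    if (w <= 0).any():
        bad = [eid for eid, wi in zip(panel.expert_ids, w) if wi <= 0]
        report.append(Violation("weights", None, f"non-positive weight for expert(s) {bad}"))
    s = float(w.sum())
    if not math.isclose(s, 1.0, abs_tol=SUM_TOL):
        report.append(Violation("weights", None, f"weights sum {s:.6g} != 1"))

    structure = panel.structure
    for expert in panel.experts:
        eid = expert.expert_id
        for node in structure.nodes:
            if node not in expert.cpts:
                report.append(Violation("missing-cpt", node, f"expert {eid!r} has no CPT for node"))
                continue
            cpt = expert.cpts[node]
            if cpt.child != node:
                report.append(Violation("cpt-child-mismatch", node, f"expert {eid!r}: CPT child {cpt.child!r}"))
                continue
            if cpt.child_states != structure.nodes[node].states:
                report.append(
                    Violation("state-mismatch", node, f"expert {eid!r}: states {list(cpt.child_states)}")
                )
            declared = {p for p, c in structure.edges if c == node}
            if set(cpt.parents) != declared:
                report.append(
                    Violation(
                        "parent-mismatch", node,
                        f"expert {eid!r}: parents {list(cpt.parents)} != structure {sorted(declared)}",
                    )
                )
        extra = set(expert.cpts) - set(structure.nodes)
        for node in sorted(extra):
            report.append(Violation("surplus-cpt", node, f"expert {eid!r} assesses undeclared node"))
        # numerical validity of this expert's network
        net_report = validate_network(panel.expert_network(expert))
        for v in net_report:
            if v.kind in ("row-sum", "row-range"):
                report.append(Violation(v.kind, v.node, f"expert {eid!r}: {v.detail}"))
    return report


def require_valid_panel(panel: ExpertPanel) -> None:
    report = validate_panel(panel)
    if report:
        raise NetworkValidationError(
            f"invalid panel: {len(report)} violation(s); first: {report[0]}", report
        )


def filter_subgroup(panel: ExpertPanel, constraints: Mapping[str, str]) -> ExpertPanel:
    """Sub-panel of experts matching ALL covariate constraints.

    Weights are renormalised proportionally (w_i / sum over the subgroup),
    so equal weights stay equal.  The original panel is unchanged.  An
    empty result is an error: pooling over zero experts is undefined.
    """
    known = set(panel.covariate_names())
    unknown = set(constraints) - known
    if unknown:
        raise InputError(f"unknown covariate(s) {sorted(unknown)}; panel has {sorted(known)}")
    kept = [
        e
        for e in panel.experts
        if all(panel.covariate_of(e.expert_id, cov) == cat for cov, cat in constraints.items())
    ]
    if not kept:
        raise EmptySubgroupError(f"no experts match constraints {dict(constraints)}")
    total = sum(panel.weights[e.expert_id] for e in kept)
    weights = {e.expert_id: panel.weights[e.expert_id] / total for e in kept}
    covariates = {e.expert_id: dict(panel.covariates.get(e.expert_id, {})) for e in kept}
    return ExpertPanel(panel.structure, kept, covariates, weights)


def subgroup_label(constraints: Mapping[str, str]) -> str:
    """Human-readable label for a constraint map; 'All' for the empty map."""
    if not constraints:
        return "All"
    return ", ".join(f"{cat}" for cat in constraints.values())
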