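"""Seeded generators for networks and heterogeneous expert panels.

The generators emulate an elicitation survey: a consensus network is
perturbed per expert by drawing each CPT row from a Dirichlet distribution
centred on the (possibly subgroup-shifted) consensus row, with a shared
concentration kappa controlling how tightly experts scatter around the
consensus (the Dirichlet mean is the consensus row itself, so pooled CPTs
converge to the consensus as the panel grows).  Covariates are assigned
with exact category counts (largest-remainder apportionment of the stated
frequencies) and then shuffled, so subgroup sizes are deterministic.

:func:`wayfinding_fixture` builds the packaged six-node airport-wayfinding
schematic with a 99-respondent synthetic panel.  The network structure is
a schematic reading of the published node descriptions, and every CPT
value is synthetic: the original 49-node model's tables and raw survey
responses were never published.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bn_core import CPT, DiscreteBayesNet, StateSpace
from .errors import InputError
from .panel import ExpertAssessment, ExpertPanel

_EPS = 1e-6  # shifted probabilities are kept inside (0, 1) by this margin


@dataclass(frozen=True)
class SubgroupEffect:
    """A systematic CPT shift for experts in one covariate category.

    Before Dirichlet perturbation, ``delta`` is added to the probability of
    ``state`` in every row of ``node``'s CPT (clipped to stay inside (0, 1))
    and the remaining entries are rescaled so each row still sums to one.
    """

    covariate: str
    category: str
    node: str
    state: str
    delta: float


@dataclass(frozen=True)
class PanelRecipe:
    """Recipe for a synthetic expert panel around a consensus network."""

    n_experts: int
    concentration: float
    covariate_frequencies: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    subgroup_effects: tuple[SubgroupEffect, ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self,
            "covariate_frequencies",
            {k: dict(v) for k, v in dict(self.covariate_frequencies).items()},
        )
        object.__setattr__(self, "subgroup_effects", tuple(self.subgroup_effects))
        if self.n_experts < 1:
            raise InputError("n_experts must be >= 1")
        if not self.concentration > 0:
            raise InputError("concentration kappa must be > 0")
        for cov, freqs in self.covariate_frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise InputError(f"covariate {cov!r}: category proportions sum to {total!r}")
            if any(p < 0 for p in freqs.values()):
                raise InputError(f"covariate {cov!r}: negative proportion")


def random_network(n_nodes: int, max_parents: int, n_states: int = 2, seed: int = 0) -> DiscreteBayesNet:
    """A random valid network: random topological order, random parents,
    uniform-Dirichlet CPT rows.  Pure function of its arguments."""
    if n_nodes < 1 or max_parents < 0 or n_states < 2:
        raise InputError("need n_nodes >= 1, max_parents >= 0, n_states >= 2")
    rng = np.random.default_rng(seed)
    names = [f"X{i:02d}" for i in range(n_nodes)]
    order = list(rng.permutation(names))
    states = tuple(f"s{j}" for j in range(n_states))
    cpts = []
    for pos, name in enumerate(order):
        k = int(rng.integers(0, min(max_parents, pos) + 1))
        parents = sorted(rng.choice(order[:pos], size=k, replace=False)) if k else []
        n_rows = n_states ** len(parents)
        table = rng.dirichlet(np.ones(n_states), size=n_rows)
        cpts.append(CPT(name, states, parents, [states] * len(parents), table))
    nodes = {n: StateSpace(n, states) for n in names}  # declaration order = name order
    edges = {(p, c.child) for c in cpts for p in c.parents}
    return DiscreteBayesNet(nodes, edges, cpts)


def shift_row(row: np.ndarray, state_index: int, delta: float) -> np.ndarray:
    """Move probability mass onto one state, rescaling the rest; stays in (0, 1)."""
    row = np.asarray(row, dtype=float)
    target = float(np.clip(row[state_index] + delta, _EPS, 1.0 - _EPS))
    out = row.copy()
    others = row.sum() - row[state_index]
    if others <= 0:
        raise InputError("cannot shift a degenerate row with all mass on one state")
    out[state_index] = target
    mask = np.arange(row.size) != state_index
    out[mask] *= (1.0 - target) / others
    return out


def _shifted_consensus(
    consensus: DiscreteBayesNet, effects: Sequence[SubgroupEffect], covariates: Mapping[str, str]
) -> dict[str, np.ndarray]:
    """Per-node CPT tables after applying the effects active for one expert."""
    tables = {node: cpt.table.copy() for node, cpt in consensus.cpts.items()}
    for eff in effects:
        if covariates.get(eff.covariate) != eff.category:
            continue
        cpt = consensus.cpts[eff.node]
        j = cpt.child_states.index(eff.state)
        tables[eff.node] = np.vstack([shift_row(r, j, eff.delta) for r in tables[eff.node]])
    return tables


def _apportion(n: int, freqs: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n items to the stated proportions."""
    raw = {cat: n * p for cat, p in freqs.items()}
    counts = {cat: int(np.floor(x)) for cat, x in raw.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(raw, key=lambda c: (-(raw[c] - counts[c]), c))
    for cat in by_remainder[:short]:
        counts[cat] += 1
    return counts


def generate_panel(consensus: DiscreteBayesNet, recipe: PanelRecipe) -> ExpertPanel:
    """Draw a synthetic panel of experts around a consensus network.

    Each expert's CPT row for a node is ``Dirichlet(kappa * m)`` where ``m``
    is the consensus row after any subgroup shifts active for that expert.
    Covariates get exact largest-remainder counts, shuffled by the seed;
    weights are equal.
    """
    for eff in recipe.subgroup_effects:
        if eff.node not in consensus.nodes:
            raise InputError(f"effect targets unknown node {eff.node!r}")
        if eff.state not in consensus.nodes[eff.node].states:
            raise InputError(f"effect targets unknown state {eff.state!r} of {eff.node!r}")
        if eff.covariate not in recipe.covariate_frequencies:
            raise InputError(f"effect references covariate {eff.covariate!r} with no frequencies")

    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_experts
    ids = [f"E{i + 1:03d}" for i in range(n)]

    covariates: dict[str, dict[str, str]] = {eid: {} for eid in ids}
    for cov, freqs in recipe.covariate_frequencies.items():
        counts = _apportion(n, freqs)
        labels = [cat for cat in freqs for _ in range(counts[cat])]
        for eid, lab in zip(ids, rng.permutation(labels)):
            covariates[eid][cov] = str(lab)

    kappa = recipe.concentration
    experts = []
    for eid in ids:
        tables = _shifted_consensus(consensus, recipe.subgroup_effects, covariates[eid])
        cpts = {}
        for node, cpt in consensus.cpts.items():
            drawn = np.vstack(
                [rng.dirichlet(np.maximum(kappa * row, _EPS)) for row in tables[node]]
            )
            cpts[node] = cpt.replace_table(drawn)
        experts.append(ExpertAssessment(eid, cpts))
    return ExpertPanel(consensus, experts, covariates)


# ---------------------------------------------------------------------------
# Wayfinding schematic fixture
# ---------------------------------------------------------------------------

#: the six nodes of interest with their published state labels
WAYFINDING_STATES = {
    "Communication": ("Effective", "Ineffective"),
    "Environmental Factors": ("Good", "Bad"),
    "Human Factors": ("Good", "Bad"),
    "Navigation Pathway": ("Simple", "Complex"),
    "Visual Elements of Communication": ("Good", "Bad"),
    "Wayfinding": ("Effective", "Ineffective"),
}

WAYFINDING_SEED = 20180320

#: covariate frequencies matching the survey's subgroup counts out of 99
WAYFINDING_COVARIATES = {
    "Gender": {"Female": 46 / 99, "Male": 53 / 99},
    "Travel Purpose": {"Business": 32 / 99, "Personal": 67 / 99},
    "Travel Experience": {"Experienced": 85 / 99, "Inexperienced": 14 / 99},
}


def wayfinding_network() -> DiscreteBayesNet:
    """The six-node airport-wayfinding schematic with synthetic consensus CPTs.

    Structure (schematic reading of the published node descriptions):
    Visual Elements of Communication -> Communication;
    Navigation Pathway -> Environmental Factors;
    Human Factors, Environmental Factors, Communication -> Wayfinding.
    All CPT values below are synthetic placeholders chosen on the scale of
    the published pooled marginals; the real model's tables are unpublished.
    """
    s = WAYFINDING_STATES
    cpts = [
        CPT("Human Factors", s["Human Factors"], table=[[0.80, 0.20]]),
        CPT("Navigation Pathway", s["Navigation Pathway"], table=[[0.69, 0.31]]),
        CPT(
            "Visual Elements of Communication",
            s["Visual Elements of Communication"],
            table=[[0.71, 0.29]],
        ),
        CPT(
            "Communication",
            s["Communication"],
            parents=["Visual Elements of Communication"],
            parent_states=[s["Visual Elements of Communication"]],
            table=[[0.87, 0.13], [0.45, 0.55]],
        ),
        CPT(
            "Environmental Factors",
            s["Environmental Factors"],
            parents=["Navigation Pathway"],
            parent_states=[s["Navigation Pathway"]],
            table=[[0.86, 0.14], [0.55, 0.45]],
        ),
        CPT(
            "Wayfinding",
            s["Wayfinding"],
            parents=["Human Factors", "Environmental Factors", "Communication"],
            parent_states=[
                s["Human Factors"],
                s["Environmental Factors"],
                s["Communication"],
            ],
            # rows in canonical order, last parent (Communication) fastest
            table=[
                [0.95, 0.05],  # Good, Good, Effective
                [0.80, 0.20],  # Good, Good, Ineffective
                [0.78, 0.22],  # Good, Bad,  Effective
                [0.55, 0.45],  # Good, Bad,  Ineffective
                [0.60, 0.40],  # Bad,  Good, Effective
                [0.40, 0.60],  # Bad,  Good, Ineffective
                [0.35, 0.65],  # Bad,  Bad,  Effective
                [0.10, 0.90],  # Bad,  Bad,  Ineffective
            ],
        ),
    ]
    nodes = {name: StateSpace(name, states) for name, states in s.items()}
    edges = {(p, c.child) for c in cpts for p in c.parents}
    return DiscreteBayesNet(nodes, edges, cpts)


def wayfinding_recipe(seed: int = WAYFINDING_SEED) -> PanelRecipe:
    """The fixture's panel recipe: 99 respondents, kappa = 20, two injected
    subgroup effects mirroring the study's qualitative findings (lower
    effective-wayfinding assessments from inexperienced travellers, lower
    human-factors assessments from female travellers)."""
    return PanelRecipe(
        n_experts=99,
        concentration=20.0,
        covariate_frequencies=WAYFINDING_COVARIATES,
        subgroup_effects=(
            SubgroupEffect("Travel Experience", "Inexperienced", "Wayfinding", "Effective", -0.15),
            SubgroupEffect("Gender", "Female", "Human Factors", "Good", -0.10),
        ),
        seed=seed,
    )


def wayfinding_fixture(seed: int = WAYFINDING_SEED) -> tuple[DiscreteBayesNet, ExpertPanel]:
    """The packaged schematic network plus its deterministic 99-expert panel."""
    net = wayfinding_network()
    return net, generate_panel(net, wayfinding_recipe(seed))
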