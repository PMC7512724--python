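import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bnpool import (
    CPT,
    DiscreteBayesNet,
    ExpertAssessment,
    ExpertPanel,
    random_network,
    wayfinding_fixture,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_chain(p_a: float, p_b_given_at: float, p_b_given_af: float) -> DiscreteBayesNet:
    """A -> B over binary states (t, f)."""
    a = CPT("A", ("t", "f"), table=[[p_a, 1 - p_a]])
    b = CPT(
        "B",
        ("t", "f"),
        parents=["A"],
        parent_states=[("t", "f")],
        table=[[p_b_given_at, 1 - p_b_given_at], [p_b_given_af, 1 - p_b_given_af]],
    )
    return DiscreteBayesNet.from_cpts([a, b])


@pytest.fixture
def chain_expert1():
    return make_chain(0.8, 0.9, 0.2)


@pytest.fixture
def chain_expert2():
    return make_chain(0.2, 0.6, 0.3)


@pytest.fixture
def two_expert_chain(chain_expert1, chain_expert2):
    """The standing two-expert worked example (equal weights)."""
    return ExpertPanel(
        chain_expert1,
        [
            ExpertAssessment("expert1", dict(chain_expert1.cpts)),
            ExpertAssessment("expert2", dict(chain_expert2.cpts)),
        ],
    )


def homogeneous_panel(net: DiscreteBayesNet, n: int) -> ExpertPanel:
    experts = [ExpertAssessment(f"e{i}", dict(net.cpts)) for i in range(n)]
    return ExpertPanel(net, experts)


def random_panel(n_nodes: int, n_experts: int, seed: int) -> ExpertPanel:
    """Panel of independent random CPT sets over one random structure."""
    structure = random_network(n_nodes, max_parents=2, n_states=2, seed=seed)
    experts = []
    for i in range(n_experts):
        variant = random_network(n_nodes, max_parents=2, n_states=2, seed=seed)
        rng = np.random.default_rng((seed, i))
        cpts = {
            node: cpt.replace_table(rng.dirichlet(np.ones(len(cpt.child_states)), size=cpt.n_rows))
            for node, cpt in variant.cpts.items()
        }
        experts.append(ExpertAssessment(f"e{i}", cpts))
    return ExpertPanel(structure, experts)


def random_evidence(net: DiscreteBayesNet, rng: np.random.Generator, max_size: int = 2) -> dict:
    nodes = list(net.nodes)
    k = int(rng.integers(0, max_size + 1))
    chosen = rng.choice(nodes, size=min(k, len(nodes) - 1), replace=False)
    return {n: net.nodes[n].states[int(rng.integers(len(net.nodes[n].states)))] for n in chosen}


@pytest.fixture(scope="session")
def wayfinding():
    """(network, 99-expert panel) — deterministic packaged fixture."""
    return wayfinding_fixture()
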