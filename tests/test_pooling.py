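import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bnpool import (
    ExpertAssessment,
    ExpertPanel,
    ImpossibleEvidenceError,
    InputError,
    compare_pooling,
    enumerate_joint,
    linear_pool,
    marginal,
    posterior_linear_pool,
    prior_linear_pool,
    random_network,
)
from .conftest import homogeneous_panel, make_chain, random_evidence, random_panel


class TestLinearPool:
    def test_equal_weight_average(self):
        np.testing.assert_allclose(
            linear_pool([(0.6, 0.4), (0.8, 0.2)], (0.5, 0.5)), [0.7, 0.3]
        )

    def test_single_distribution_identity(self):
        np.testing.assert_allclose(linear_pool([(0.3, 0.7)], (1.0,)), [0.3, 0.7])

    def test_degenerate_components(self):
        np.testing.assert_allclose(
            linear_pool([(1.0, 0.0), (0.0, 1.0)], (0.25, 0.75)), [0.25, 0.75]
        )

    @pytest.mark.parametrize(
        "dists, weights, message",
        [
            ([(0.5, 0.5), (0.5, 0.3, 0.2)], (0.5, 0.5), "mismatched"),
            ([(0.5, 0.5)], (0.5, 0.5), "weights"),
            ([(0.5, 0.5), (0.5, 0.5)], (0.7, 0.5), "sum"),
            ([(0.5, 0.5), (0.5, 0.5)], (1.2, -0.2), "positive"),
            ([(0.6, 0.6)], (1.0,), "not normalised"),
            ([], (), "at least one"),
        ],
    )
    def test_input_errors(self, dists, weights, message):
        with pytest.raises(InputError, match=message):
            linear_pool(dists, weights)

    @given(
        st.lists(
            st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3), min_size=1, max_size=5
        )
    )
    def test_pool_stays_in_convex_hull(self, raw):
        dists = [np.asarray(r) / np.sum(r) for r in raw]
        w = np.full(len(dists), 1.0 / len(dists))
        pooled = linear_pool(dists, w)
        mat = np.asarray(dists)
        assert (pooled >= mat.min(axis=0) - 1e-12).all()
        assert (pooled <= mat.max(axis=0) + 1e-12).all()
        assert pooled.sum() == pytest.approx(1.0, abs=1e-9)


class TestPriorLinearPool:
    def test_worked_two_expert_chain_rows(self, two_expert_chain):
        pooled = prior_linear_pool(two_expert_chain)
        assert pooled.cpts["A"].prob("t") == pytest.approx(0.5, abs=1e-12)
        assert pooled.cpts["B"].prob("t", ("t",)) == pytest.approx(0.75, abs=1e-12)
        assert pooled.cpts["B"].prob("t", ("f",)) == pytest.approx(0.25, abs=1e-12)

    def test_homogeneous_panel_returns_the_shared_network(self, chain_expert1):
        pooled = prior_linear_pool(homogeneous_panel(chain_expert1, 5))
        assert pooled.equal_within(chain_expert1, atol=1e-12)

    def test_single_expert_panel_is_identity(self, chain_expert1):
        pooled = prior_linear_pool(homogeneous_panel(chain_expert1, 1))
        assert pooled.equal_within(chain_expert1, atol=0)

    def test_invalid_panel_refused_with_report(self, chain_expert1):
        panel = ExpertPanel(
            chain_expert1,
            [ExpertAssessment("e0", {"A": chain_expert1.cpts["A"]})],
        )
        from bnpool import NetworkValidationError

        with pytest.raises(NetworkValidationError) as exc:
            prior_linear_pool(panel)
        assert exc.value.report


class TestPosteriorLinearPool:
    def test_worked_two_expert_chain(self, two_expert_chain):
        res = posterior_linear_pool(two_expert_chain, ["B"])
        assert res.prob("B", "t") == pytest.approx(0.56, abs=1e-12)
        assert res.method == "PoLP"
        assert res.n_experts == 2

    def test_homogeneous_panel_equals_single_expert(self, chain_expert1):
        res = posterior_linear_pool(homogeneous_panel(chain_expert1, 4), ["B"], {"A": "t"})
        single = marginal(chain_expert1, "B", {"A": "t"})
        np.testing.assert_allclose(res.marginals["B"].probabilities, single.probabilities, atol=1e-12)

    def test_pooled_marginal_in_convex_hull_of_experts(self):
        panel = random_panel(5, 4, seed=17)
        target = list(panel.structure.nodes)[-1]
        res = posterior_linear_pool(panel, [target])
        per = np.array(
            [marginal(net, target).probabilities for _, net in panel.expert_networks()]
        )
        assert (res.marginals[target].probabilities >= per.min(axis=0) - 1e-12).all()
        assert (res.marginals[target].probabilities <= per.max(axis=0) + 1e-12).all()

    def test_target_clamped_as_evidence_rejected(self, two_expert_chain):
        with pytest.raises(InputError, match="clamped"):
            posterior_linear_pool(two_expert_chain, ["B"], {"B": "t"})

    def test_impossible_evidence_default_names_expert(self, chain_expert1):
        degenerate = make_chain(0.5, 0.0, 0.0)  # B=t impossible for this expert
        panel = ExpertPanel(
            chain_expert1,
            [
                ExpertAssessment("keeps", dict(chain_expert1.cpts)),
                ExpertAssessment("breaks", dict(degenerate.cpts)),
            ],
        )
        with pytest.raises(ImpossibleEvidenceError, match="breaks"):
            posterior_linear_pool(panel, ["A"], {"B": "t"})

    def test_drop_impossible_renormalizes_remaining_weights(self, chain_expert1):
        degenerate = make_chain(0.5, 0.0, 0.0)
        panel = ExpertPanel(
            chain_expert1,
            [
                ExpertAssessment("keeps", dict(chain_expert1.cpts)),
                ExpertAssessment("breaks", dict(degenerate.cpts)),
            ],
        )
        res = posterior_linear_pool(panel, ["A"], {"B": "t"}, drop_impossible=True)
        assert res.n_experts == 1
        np.testing.assert_allclose(
            res.marginals["A"].probabilities,
            marginal(chain_expert1, "A", {"B": "t"}).probabilities,
            atol=1e-12,
        )


class TestComparePooling:
    def test_worked_divergence(self, two_expert_chain):
        frame = compare_pooling(two_expert_chain, ["B"])
        row = frame[(frame.node == "B") & (frame.state == "t")].iloc[0]
        assert row.prlp == pytest.approx(0.50, abs=1e-12)
        assert row.polp == pytest.approx(0.56, abs=1e-12)
        assert row.abs_diff == pytest.approx(0.06, abs=1e-12)

    def test_homogeneous_panel_no_divergence(self, chain_expert1):
        frame = compare_pooling(homogeneous_panel(chain_expert1, 3), ["A", "B"])
        assert (frame.abs_diff < 1e-12).all()

    def test_root_node_no_evidence_never_diverges(self):
        # a root's marginal is its CPT row; averaging rows commutes with reading them
        panel = random_panel(5, 3, seed=23)
        roots = [n for n in panel.structure.nodes if not panel.experts[0].cpts[n].parents]
        frame = compare_pooling(panel, roots)
        assert (frame.abs_diff < 1e-12).all()


class TestMixtureIdentity:
    def test_no_evidence_polp_equals_mixture_of_joints(self):
        for seed in range(5):
            panel = random_panel(4, 3, seed=seed)
            target = list(panel.structure.nodes)[-1]
            res = posterior_linear_pool(panel, [target])
            w = panel.weight_vector()
            mix = sum(
                wi * enumerate_joint(net).marginal(target)
                for wi, (_, net) in zip(w, panel.expert_networks())
            )
            np.testing.assert_allclose(res.marginals[target].probabilities, mix, atol=1e-10)

    def test_with_evidence_polp_differs_from_mixture(self, two_expert_chain):
        """Equal-weight pooling of posteriors ignores each expert's evidence
        likelihood, so it is NOT the mixture posterior; frozen counterexample."""
        res = posterior_linear_pool(two_expert_chain, ["A"], {"B": "t"})
        polp = res.prob("A", "t")
        w = two_expert_chain.weight_vector()
        joints = [enumerate_joint(net) for _, net in two_expert_chain.expert_networks()]
        # mixture posterior: sum of unnormalised joint slices, then renormalise
        num = sum(wi * j.probabilities[("t", "t")] for wi, j in zip(w, joints))
        den = num + sum(wi * j.probabilities[("f", "t")] for wi, j in zip(w, joints))
        mixture = num / den
        assert polp == pytest.approx(0.72 / 0.76 / 2 + 0.12 / 0.36 / 2, abs=1e-12)
        assert mixture == pytest.approx(0.75, abs=1e-12)
        assert polp < mixture  # frozen sign of the divergence
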