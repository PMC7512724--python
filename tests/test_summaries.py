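import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bnpool import (
    CPT,
    DiscreteBayesNet,
    Evidence,
    InputError,
    MarginalDistribution,
    delta_table,
    describe_spread,
    diagnostic_scenario,
    filter_subgroup,
    marginal,
    per_expert_marginals,
    posterior_linear_pool,
    subgroup_report,
)
from .conftest import homogeneous_panel, make_chain


def md(node, p, states=("t", "f"), evidence=None):
    return MarginalDistribution(node, states, np.array([p, 1 - p]), Evidence.coerce(evidence))


class TestDiagnosticScenario:
    def test_clamping_effect_updates_cause(self, chain_expert1):
        out = diagnostic_scenario(chain_expert1, {"B": "t"}, ["A"])
        assert out["A"].prob("t") == pytest.approx(0.72 / 0.76, abs=1e-12)

    def test_disconnected_clamp_leaves_marginal_unchanged(self, chain_expert1):
        iso = CPT("Z", ("t", "f"), table=[[0.3, 0.7]])
        net = DiscreteBayesNet.from_cpts(list(chain_expert1.cpts.values()) + [iso])
        base = diagnostic_scenario(net, {}, ["B"])["B"]
        clamped = diagnostic_scenario(net, {"Z": "t"}, ["B"])["B"]
        np.testing.assert_allclose(base.probabilities, clamped.probabilities, atol=1e-12)

    def test_uninformative_clamp_with_prior_one(self):
        net = make_chain(1.0, 0.9, 0.2)
        base = diagnostic_scenario(net, {}, ["B"])["B"]
        clamped = diagnostic_scenario(net, {"A": "t"}, ["B"])["B"]
        np.testing.assert_allclose(base.probabilities, clamped.probabilities, atol=1e-12)

    def test_report_node_in_clamp_rejected(self, chain_expert1):
        with pytest.raises(InputError):
            diagnostic_scenario(chain_expert1, {"B": "t"}, ["B"])


class TestDeltaTable:
    def test_published_style_delta(self):
        # a 0.8033 baseline against a 0.7282 scenario differs by 0.0751
        frame = delta_table(
            {"H": md("H", 0.8033)}, [("Female, Inexperienced", {"H": md("H", 0.7282)})]
        )
        row = frame[(frame.node == "H") & (frame.state == "t")].iloc[0]
        assert row.abs_diff == pytest.approx(0.0751, abs=1e-12)

    def test_identical_scenario_all_zero(self):
        frame = delta_table({"H": md("H", 0.4)}, [("same", {"H": md("H", 0.4)})])
        assert (frame.abs_diff == 0).all()

    def test_half_half_vs_degenerate(self):
        frame = delta_table({"H": md("H", 0.5)}, [("s", {"H": md("H", 1.0)})])
        np.testing.assert_allclose(frame.abs_diff, [0.5, 0.5])

    def test_symmetric_under_swap(self):
        a, b = {"H": md("H", 0.3)}, {"H": md("H", 0.9)}
        fwd = delta_table(a, [("s", b)])
        rev = delta_table(b, [("s", a)])
        np.testing.assert_allclose(fwd.abs_diff.values, rev.abs_diff.values)

    def test_state_mismatch_rejected(self):
        base = {"H": md("H", 0.5)}
        bad = {"H": md("H", 0.5, states=("yes", "no"))}
        with pytest.raises(InputError, match="states"):
            delta_table(base, [("s", bad)])


class TestPerExpertMarginals:
    def test_worked_chain_vector(self, two_expert_chain):
        np.testing.assert_allclose(
            per_expert_marginals(two_expert_chain, "B", "t"), [0.76, 0.36], atol=1e-12
        )

    def test_homogeneous_panel_constant_vector(self, chain_expert1):
        vals = per_expert_marginals(homogeneous_panel(chain_expert1, 5), "B", "t")
        np.testing.assert_allclose(vals, vals[0])

    def test_weighted_mean_reproduces_polp(self, two_expert_chain):
        vals = per_expert_marginals(two_expert_chain, "B", "t")
        pooled = posterior_linear_pool(two_expert_chain, ["B"]).prob("B", "t")
        assert float(vals @ two_expert_chain.weight_vector()) == pooled


class TestDescribeSpread:
    def test_two_value_mean_and_sample_sd(self):
        s = describe_spread([0.76, 0.36])
        assert s.mean == pytest.approx(0.56)
        assert s.sd == pytest.approx(0.4 / np.sqrt(2), abs=1e-9)

    def test_constant_vector(self):
        s = describe_spread([0.5, 0.5, 0.5])
        assert (s.mean, s.sd, s.minimum, s.maximum) == (0.5, 0.0, 0.5, 0.5)

    def test_linear_interpolation_quartiles(self):
        s = describe_spread([0.2, 0.4, 0.6, 0.8])
        assert (s.q1, s.median, s.q3) == (
            pytest.approx(0.35),
            pytest.approx(0.5),
            pytest.approx(0.65),
        )

    def test_single_value_sd_zero(self):
        assert describe_spread([0.7]).sd == 0.0

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(InputError):
            describe_spread([])
        with pytest.raises(InputError):
            describe_spread([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_summary_statistics_lie_within_range(self, values):
        s = describe_spread(values)
        assert s.minimum <= s.q1 <= s.median <= s.q3 <= s.maximum
        assert s.minimum - 1e-12 <= s.mean <= s.maximum + 1e-12
        assert s.sd >= 0


class TestSubgroupReport:
    def test_injected_shift_shows_largest_delta_at_shifted_node(self, wayfinding):
        """The generator lowers Inexperienced travellers' effective-wayfinding
        rows, so that subgroup must show the largest absolute delta there."""
        net, panel = wayfinding
        partitions = [
            {"Travel Experience": "Experienced"},
            {"Travel Experience": "Inexperienced"},
        ]
        frame = subgroup_report(
            panel, partitions, ["Wayfinding"], method="PoLP", mode="filter"
        )
        eff = frame[(frame.state == "Effective") & (frame.subgroup != "All")]
        by_group = eff.set_index("subgroup").abs_diff
        assert by_group["Inexperienced"] > by_group["Experienced"]
        assert by_group["Inexperienced"] > 0.05

    def test_identical_covariates_give_zero_deltas(self, chain_expert1):
        panel = homogeneous_panel(chain_expert1, 4)
        panel.covariates.update({eid: {"G": "x"} for eid in panel.expert_ids})
        frame = subgroup_report(panel, [{"G": "x"}], ["B"], method="PoLP")
        assert (frame.abs_diff < 1e-12).all()

    def test_polp_linearity_over_partition(self, wayfinding):
        """Size-weighted average of complementary subgroup PoLP marginals
        equals the full-panel PoLP marginal exactly (linearity of the pool)."""
        net, panel = wayfinding
        full = posterior_linear_pool(panel, ["Wayfinding"]).prob("Wayfinding", "Effective")
        total = 0.0
        for cat in ("Female", "Male"):
            sub = filter_subgroup(panel, {"Gender": cat})
            part = posterior_linear_pool(sub, ["Wayfinding"]).prob("Wayfinding", "Effective")
            total += sub.n_experts / panel.n_experts * part
        assert total == pytest.approx(full, abs=1e-12)

    def test_condition_mode_uses_evidence_inside_network(self, chain_expert1):
        panel = homogeneous_panel(chain_expert1, 3)
        frame = subgroup_report(
            panel, [{"A": "t"}], ["B"], method="PrLP", mode="condition"
        )
        conditioned = frame[(frame.subgroup == "t") & (frame.state == "t")].iloc[0]
        assert conditioned.value == pytest.approx(
            marginal(chain_expert1, "B", {"A": "t"}).prob("t"), abs=1e-12
        )

    def test_unknown_mode_rejected(self, two_expert_chain):
        with pytest.raises(InputError, match="mode"):
            subgroup_report(two_expert_chain, [], ["B"], mode="both")
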