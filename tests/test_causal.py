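import numpy as np
import pytest

from mhecosim.basefunc import fit_exponential
from mhecosim.causal import (
    DEFAULT_POLICY,
    CausalNetwork,
    CausalNode,
    DistributionTable,
    Intervention,
    LAYER_T,
    LAYER_T1,
    LAYER_T2,
    Policy,
    apply_policy,
    build_default_network,
    propagate,
)
from mhecosim.ecosystem import generate_ecosystem, GeneratorParams
from mhecosim.pipeline import fit_models, propagation_models

# Adjacency implied by the three expert causal statements plus the
# population -> workforce structural link.
EXPECTED_EDGES = {
    ("population_adults", "total_professionals_fte"),
    ("population_adults", "frequentation_visits"),
    ("total_professionals_fte", "frequentation_visits"),
    ("availability_per_100k", "stay_days"),
    ("population_adults", "stay_days"),
    ("total_professionals_fte", "stay_days"),
    ("availability_per_100k", "discharges"),
    ("frequentation_visits", "discharges"),
    ("total_professionals_fte", "discharges"),
    ("availability_per_100k", "readmissions"),
    ("stay_days", "readmissions"),
    ("total_professionals_fte", "readmissions"),
}


class TestNetworkStructure:
    def test_frequentation_precedes_inpatient_consequences(self, network):
        order = network.topological_order()
        assert order.index("frequentation_visits") < order.index("stay_days")
        assert order.index("frequentation_visits") < order.index("discharges")

    def test_edge_set_matches_expert_adjacency(self, network):
        assert set(network.edges) == EXPECTED_EDGES

    def test_backward_time_edge_rejected(self, network):
        with pytest.raises(ValueError, match="layer"):
            network.add_edge("stay_days", "total_professionals_fte")

    def test_cycle_rejected(self):
        nodes = [CausalNode("a", LAYER_T1), CausalNode("b", LAYER_T1)]
        with pytest.raises(ValueError, match="acyclic"):
            CausalNetwork(nodes, [("a", "b"), ("b", "a")])

    def test_root_nodes_carry_no_model(self):
        z = np.arange(5.0)
        m = fit_exponential(z, np.exp(z))
        with pytest.raises(ValueError, match="no model"):
            CausalNode("total_professionals_fte", LAYER_T, m)

    def test_model_with_unknown_source_rejected(self, fitted_models):
        from mhecosim.basefunc import VariableTransform

        bad = fitted_models["frequentation"]
        models = dict(propagation_models(fitted_models))
        clone = type(bad).from_dict(bad.to_dict())
        clone.transform = VariableTransform(("not_a_variable",), (1.0,), "single")
        models["frequentation_visits"] = clone
        with pytest.raises(ValueError, match="not_a_variable"):
            build_default_network(models)

    def test_frequentation_model_required(self):
        with pytest.raises(ValueError, match="frequentation"):
            build_default_network({})


class TestPolicy:
    def test_default_policy_moves_headcounts(self, default_table):
        post = apply_policy(default_table, DEFAULT_POLICY)
        pre_f = default_table.to_frame().set_index("area_id")
        post_f = post.to_frame().set_index("area_id")
        delta = post_f["total_professionals_fte"] - pre_f["total_professionals_fte"]
        assert delta["Tolosa"] == pytest.approx(-0.5)
        assert delta["Azpeitia"] == pytest.approx(+0.5)
        assert delta["Andoain"] == pytest.approx(+1.0)
        untouched = delta.drop(["Tolosa", "Azpeitia", "Andoain"])
        assert (untouched == 0).all()

    def test_psychiatrist_delta_also_moves_psychiatrist_rate(self, default_table):
        post = apply_policy(default_table, DEFAULT_POLICY)
        pre = default_table.area("Andoain")
        after = post.area("Andoain")
        gained = (after.psychiatrists_per_100k - pre.psychiatrists_per_100k) * \
            pre.population_adults / 1e5
        assert gained == pytest.approx(1.0)

    def test_input_table_is_untouched(self, default_table):
        before = default_table.to_frame()
        apply_policy(default_table, DEFAULT_POLICY)
        assert default_table.to_frame().equals(before)

    def test_empty_policy_is_identity(self, default_table):
        post = apply_policy(default_table, Policy("noop", ()))
        assert post.to_frame().equals(default_table.to_frame())

    def test_sequential_half_deltas_equal_one_full(self, default_table):
        half = Policy("h", (Intervention("Amara", "psychiatrists", 0.5),))
        full = Policy("f", (Intervention("Amara", "psychiatrists", 1.0),))
        twice = apply_policy(apply_policy(default_table, half), half)
        once = apply_policy(default_table, full)
        assert twice.to_frame().drop(columns="area_id").round(12).equals(
            once.to_frame().drop(columns="area_id").round(12)
        )

    def test_pure_reassignment_conserves_ecosystem_headcount(self, default_table):
        policy = Policy(
            "swap",
            (
                Intervention("Tolosa", "psychiatrists", -0.5),
                Intervention("Azpeitia", "psychiatrists", +0.5),
            ),
        )
        assert policy.total_delta == 0
        post = apply_policy(default_table, policy)
        assert post.to_frame()["total_professionals_fte"].sum() == pytest.approx(
            default_table.to_frame()["total_professionals_fte"].sum()
        )

    def test_error_paths(self, default_table):
        with pytest.raises(ValueError, match="Atlantis"):
            apply_policy(
                default_table, Policy("p", (Intervention("Atlantis", "psychiatrists", 1.0),))
            )
        with pytest.raises(ValueError, match="negative"):
            apply_policy(
                default_table, Policy("p", (Intervention("Amara", "psychiatrists", -1e6),))
            )
        with pytest.raises(ValueError, match="decision"):
            Intervention("Amara", "frequentation_visits", 1.0)


class TestPropagation:
    def test_bounds_equal_prediction_intervals_bitwise(self, network, default_table, dist_pre):
        model = network.model("frequentation_visits")
        rec = default_table.area("Amara")
        x = model.transform.apply(
            {
                "population_adults": rec.population_adults,
                "total_professionals_fte": rec.total_professionals_fte,
            }
        )
        _, lo, hi = model.predict_interval(x, level=0.95)
        got_lo, got_hi = dist_pre.bounds("Amara", "frequentation_visits")
        assert got_lo == lo * model.response_divisor
        assert got_hi == hi * model.response_divisor

    def test_decision_variables_have_degenerate_bounds(self, default_table, dist_pre):
        rec = default_table.area("Eibar")
        for var, value in [
            ("total_professionals_fte", rec.total_professionals_fte),
            ("population_adults", rec.population_adults),
            ("psychiatrists_per_100k", rec.psychiatrists_per_100k),
        ]:
            lo, hi = dist_pre.bounds("Eibar", var)
            assert lo == hi == value

    def test_readmissions_bounds_are_relative_halfwidth(self, default_table, dist_pre):
        rec = default_table.area("Irun")
        lo, hi = dist_pre.bounds("Irun", "readmissions")
        assert lo == pytest.approx(rec.readmissions * 0.9)
        assert hi == pytest.approx(rec.readmissions * 1.1)

    def test_propagation_is_pure(self, network, default_table, dist_pre):
        with pytest.warns(UserWarning, match="positive exponent"):
            again = propagate(network, default_table)
        np.testing.assert_array_equal(again.lo, dist_pre.lo)
        np.testing.assert_array_equal(again.hi, dist_pre.hi)

    def test_zero_residual_models_propagate_degenerate_bounds(self):
        """A noise-free ecosystem yields exact fits and zero-width intervals."""
        params = GeneratorParams(seed=13, noise_sigma=0.0)
        table = generate_ecosystem(params)
        models = fit_models(table)
        network = build_default_network(propagation_models(models))
        with pytest.warns(UserWarning, match="positive exponent"):
            dist = propagate(network, table)
        for var in ("frequentation_visits", "stay_days", "discharges"):
            j = dist.variables.index(var)
            np.testing.assert_allclose(dist.lo[:, j], dist.hi[:, j], rtol=1e-9)
        j = dist.variables.index("frequentation_visits")
        pops = table.to_frame()["population_adults"].to_numpy()
        ftes = table.to_frame()["total_professionals_fte"].to_numpy()
        np.testing.assert_allclose(
            dist.lo[:, j], params.frequentation_formula(pops, ftes), rtol=1e-8
        )

    def test_monotone_frequentation_response_to_workforce(self, network, default_table):
        """More outpatient professionals never lower the frequentation midpoint."""
        grow = Policy("grow", (Intervention("Eguia", "total_professionals", +2.0),))
        post = apply_policy(default_table, grow)
        with pytest.warns(UserWarning):
            d_pre = propagate(network, default_table)
            d_post = propagate(network, post)
        mid_pre = d_pre.midpoints().loc["Eguia", "frequentation_visits"]
        mid_post = d_post.midpoints().loc["Eguia", "frequentation_visits"]
        assert network.model("frequentation_visits").betas[0] > 0
        assert mid_post > mid_pre

    def test_distribution_table_invariants(self):
        with pytest.raises(ValueError, match="lower bounds exceed"):
            DistributionTable(["a"], ["v"], np.array([[2.0]]), np.array([[1.0]]))
        with pytest.raises(ValueError, match=">= 0"):
            DistributionTable(["a"], ["v"], np.array([[-1.0]]), np.array([[1.0]]))

    def test_distribution_csv_round_trip(self, dist_pre, tmp_path):
        path = tmp_path / "dist.csv"
        dist_pre.to_csv(path)
        import pandas as pd

        back = DistributionTable.from_frame(pd.read_csv(path))
        for area in dist_pre.area_ids:
            for var in dist_pre.variables:
                assert back.bounds(area, var) == pytest.approx(dist_pre.bounds(area, var))
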