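"""Random-walk-with-restart propagation and the effect score."""

import numpy as np
import pytest

from netpharm.netio import WeightedNetwork
from netpharm.propagate import (
    SeedVector,
    disease_effect,
    drug_effect,
    effect_score,
    formula_effect,
    rwr,
    transition_matrix,
)
from netpharm.synthgen import SynthConfig, generate_bundle
from oracles import rwr_dense_solve


def net_from(edges):
    return WeightedNetwork.from_edges(edges)


class TestTransitionMatrix:
    def test_triangle_equal_weights(self):
        net = net_from([("A", "B", 0.5), ("B", "C", 0.5), ("A", "C", 0.5)])
        W = transition_matrix(net).toarray()
        off = W[W > 0]
        assert np.allclose(off, 0.5)

    def test_weights_normalised_per_column(self):
        net = net_from([("V", "U1", 0.9), ("V", "U2", 0.3), ("U1", "U2", 0.1)])
        W = transition_matrix(net).toarray()
        iv, iu1, iu2 = net.index["V"], net.index["U1"], net.index["U2"]
        assert W[iu1, iv] == pytest.approx(0.9 / 1.2)
        assert W[iu2, iv] == pytest.approx(0.3 / 1.2)

    def test_columns_sum_to_one(self, network):
        W = transition_matrix(network)
        assert np.allclose(np.asarray(W.sum(axis=0)).ravel(), 1.0, atol=1e-12)


class TestRwr:
    def test_restart_one_returns_seeds(self):
        net = net_from([("A", "B", 0.7)])
        seeds = SeedVector.from_symbols(net, ["A"], 1.0)
        res = rwr(net, seeds, r=1.0)
        assert res.scores["A"] == pytest.approx(1.0, abs=1e-12)
        assert res.scores["B"] == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_seed_strength(self, network):
        genes = list(network.node_order)[:4]
        a = rwr(network, SeedVector.from_symbols(network, genes, 1.0))
        b = rwr(network, SeedVector.from_symbols(network, genes, 0.25))
        for v in network.node_order:
            assert b.scores[v] == pytest.approx(0.25 * a.scores[v], abs=1e-9)

    def test_path_matches_dense_solve(self):
        net = net_from([("A", "B", 1.0), ("B", "C", 1.0)])
        seeds = SeedVector.from_symbols(net, ["A"], 1.0)
        res = rwr(net, seeds, r=0.3)
        x = res.to_array(net)
        expected = rwr_dense_solve(net, seeds.to_array(net), 0.3)
        assert np.abs(x - expected).max() < 1e-8

    def test_additivity_in_seeds(self, network):
        # rwr(a*x + b*y) = a*rwr(x) + b*rwr(y)
        nodes = list(network.node_order)
        x = rwr(network, SeedVector.from_symbols(network, nodes[:3], 1.0), tol=1e-12)
        y = rwr(network, SeedVector.from_symbols(network, nodes[3:6], 1.0), tol=1e-12)
        combined = SeedVector(
            {**{v: 2.0 for v in nodes[:3]}, **{v: 0.5 for v in nodes[3:6]}}
        )
        z = rwr(network, combined, tol=1e-12)
        for v in network.node_order:
            assert z.scores[v] == pytest.approx(
                2.0 * x.scores[v] + 0.5 * y.scores[v], abs=1e-8
            )

    def test_mass_conserved(self, network, disease_field):
        assert disease_field.total() == pytest.approx(
            disease_field.seeds.total(), abs=1e-8
        )

    def test_small_r_approaches_weighted_degree_stationary(self, network):
        seeds = SeedVector.from_symbols(network, list(network.node_order)[:3], 1.0)
        res = rwr(network, seeds, r=1e-4, tol=1e-12, max_iter=500_000)
        wdeg = np.array(
            [
                sum(d["weight"] for d in network.graph[v].values())
                for v in network.node_order
            ]
        )
        stationary = wdeg / wdeg.sum() * seeds.total()
        dist = np.abs(res.to_array(network) - stationary).sum()
        assert dist / seeds.total() < 1e-2

    def test_nonconvergence_raises(self, network):
        seeds = SeedVector.from_symbols(network, ["G00000"], 1.0)
        with pytest.raises(RuntimeError, match="converge"):
            rwr(network, seeds, max_iter=2)

    def test_invalid_restart_prob(self, network):
        seeds = SeedVector.from_symbols(network, ["G00000"], 1.0)
        with pytest.raises(ValueError):
            rwr(network, seeds, r=0.0)


class TestSeedVector:
    def test_off_network_seeds_dropped_and_recorded(self, network):
        sv = SeedVector.from_symbols(network, ["G00000", "NOTAGENE"], 1.0)
        assert sv.dropped == ("NOTAGENE",)
        assert set(sv.strengths) == {"G00000"}

    def test_all_off_network_errors(self, network):
        with pytest.raises(ValueError, match="none of"):
            SeedVector.from_symbols(network, ["NOPE"], 1.0)

    def test_zero_strength_rejected(self, network):
        with pytest.raises(ValueError):
            SeedVector.from_symbols(network, ["G00000"], 0.0)


class TestDiseaseEffect:
    def test_all_nodes_seeded_conserves_node_count(self, network):
        res = disease_effect(network, network.node_order)
        assert res.total() == pytest.approx(network.number_of_nodes(), abs=1e-7)

    def test_cycle_symmetry_about_seed(self):
        # on a 5-cycle seeded at A, nodes at equal graph distance tie
        edges = [("A", "B", 1.0), ("B", "C", 1.0), ("C", "D", 1.0),
                 ("D", "E", 1.0), ("E", "A", 1.0)]
        res = disease_effect(net_from(edges), ["A"])
        assert res.scores["B"] == pytest.approx(res.scores["E"], abs=1e-10)
        assert res.scores["C"] == pytest.approx(res.scores["D"], abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_module_members_score_above_background(self, seed):
        b = generate_bundle(SynthConfig(rng_seed=seed))
        res = disease_effect(b.network, b.disease_genes)
        inside = np.mean([res.scores[v] for v in b.disease_genes])
        outside = np.mean(
            [res.scores[v] for v in b.network.node_order
             if v not in b.disease_genes]
        )
        assert inside > outside


class TestDrugAndFormulaEffect:
    def test_component_strength_scales_linearly(self, network):
        targets = list(network.node_order)[:5]
        full = drug_effect(network, targets, strength=1.0, tol=1e-13)
        scaled = drug_effect(network, targets, strength=0.01, tol=1e-13)
        for v in network.node_order:
            assert scaled.scores[v] == pytest.approx(
                0.01 * full.scores[v], rel=1e-8, abs=1e-14
            )

    def test_formula_union_bounded_by_component_sum(self, network, bundle):
        comp_targets = {
            c: bundle.drugs.targets_of(c) for c in ("COMP_A", "COMP_B", "COMP_C")
        }
        union_run = formula_effect(network, comp_targets, strength=0.01, tol=1e-13)
        per_comp = [
            drug_effect(network, t, strength=0.01, tol=1e-13)
            for t in comp_targets.values()
        ]
        for v in network.node_order:
            bound = sum(p.scores[v] for p in per_comp)
            assert union_run.scores[v] <= bound + 1e-10

    def test_additive_mode_equals_component_sum(self, network, bundle):
        comp_targets = {
            c: bundle.drugs.targets_of(c) for c in ("COMP_A", "COMP_B", "COMP_C")
        }
        additive = formula_effect(
            network, comp_targets, strength=0.01, additive=True, tol=1e-13
        )
        per_comp = [
            drug_effect(network, t, strength=0.01, tol=1e-13)
            for t in comp_targets.values()
        ]
        for v in network.node_order:
            assert additive.scores[v] == pytest.approx(
                sum(p.scores[v] for p in per_comp), abs=1e-9
            )


class TestEffectScore:
    def test_disjoint_support_on_disconnected_components(self):
        net = net_from([("A", "B", 0.5), ("C", "D", 0.5)])
        dis = disease_effect(net, ["A"])
        drug = drug_effect(net, ["C"])
        assert effect_score(dis, drug).E == pytest.approx(0.0, abs=1e-12)

    def test_self_inner_product_is_squared_norm(self, network, disease_field):
        E = effect_score(disease_field, disease_field).E
        x = disease_field.to_array(network)
        assert E == pytest.approx(float(x @ x), rel=1e-12)

    def test_doubling_strength_doubles_E(self, network, disease_field):
        targets = list(network.node_order)[:5]
        e1 = effect_score(disease_field, drug_effect(network, targets, 1.0)).E
        e2 = effect_score(disease_field, drug_effect(network, targets, 2.0)).E
        assert e2 == pytest.approx(2.0 * e1, rel=1e-9)

    def test_node_set_mismatch_errors(self, network, disease_field):
        other = net_from([("A", "B", 0.5)])
        drug = drug_effect(other, ["A"])
        with pytest.raises(ValueError, match="node set"):
            effect_score(disease_field, drug)

    def test_effective_drug_outscores_random_drug(self):
        wins = 0
        for seed in range(10):
            b = generate_bundle(SynthConfig(rng_seed=seed))
            dis = disease_effect(b.network, b.disease_genes)
            e_eff = effect_score(
                dis, drug_effect(b.network, b.drugs.targets_of("DRUG_EFFECTIVE"))
            ).E
            e_rand = effect_score(
                dis, drug_effect(b.network, b.drugs.targets_of("DRUG_RANDOM"))
            ).E
            wins += e_eff > e_rand
        assert wins >= 9
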