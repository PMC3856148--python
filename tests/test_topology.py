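"""Subnetwork extraction and centralities against brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from netpharm.netio import DrugTargetTable, WeightedNetwork
from netpharm.propagate import PropagationResult, SeedVector, disease_effect
from netpharm.synthgen import SynthConfig, generate_bundle
from netpharm.topology import (
    annotate_targets,
    betweenness_centrality,
    degrees,
    extract_top_fraction,
    kcore_decomposition,
)
from oracles import brute_betweenness, brute_coreness


def fake_scores(network, mapping):
    seeds = SeedVector({next(iter(mapping)): 1.0})
    return PropagationResult(mapping, 0.3, 1, 0.0, seeds)


def path_graph(n):
    return nx.path_graph([chr(65 + i) for i in range(n)])


def star_graph(n_leaves):
    g = nx.Graph()
    for i in range(n_leaves):
        g.add_edge("HUB", f"L{i}")
    return g


class TestExtractTopFraction:
    def test_floor_selection(self, network):
        scores = fake_scores(
            network, {v: float(i) for i, v in enumerate(network.node_order)}
        )
        sub = extract_top_fraction(network, scores, 0.5)
        assert sub.number_of_nodes() == network.number_of_nodes() // 2

    def test_tie_break_lexicographic(self, network):
        scores = fake_scores(network, {v: 1.0 for v in network.node_order})
        sub = extract_top_fraction(network, scores, 0.05)
        k = math.floor(0.05 * network.number_of_nodes())
        assert sub.members == tuple(sorted(network.node_order)[:k])

    def test_induced_edges_only(self, network, disease_field):
        sub = extract_top_fraction(network, disease_field, 0.1)
        members = set(sub.members)
        for a, b in sub.graph.edges:
            assert a in members and b in members
            assert network.graph.has_edge(a, b)

    def test_idempotent_on_own_scores(self, network, disease_field):
        sub = extract_top_fraction(network, disease_field, 0.2)
        subnet = WeightedNetwork(sub.graph.subgraph(
            [v for v in sub.members if sub.graph.degree(v) > 0]
        ).copy())
        again = extract_top_fraction(
            subnet,
            PropagationResult(
                {v: disease_field.scores[v] for v in subnet.node_order},
                0.3, 1, 0.0, disease_field.seeds,
            ),
            0.999,
        )
        assert set(again.members) <= set(sub.members)
        assert len(again.members) == math.floor(0.999 * subnet.number_of_nodes())

    def test_disease_gene_coverage_reported(self, bundle, disease_field):
        sub = extract_top_fraction(
            bundle.network, disease_field, 0.2, disease_genes=bundle.disease_genes
        )
        assert sub.disease_genes_total == len(bundle.disease_genes)
        assert 0 <= sub.disease_genes_retained <= sub.disease_genes_total
        assert sub.disease_gene_coverage_pct == pytest.approx(
            100.0 * sub.disease_genes_retained / sub.disease_genes_total
        )

    def test_small_module_recovered_in_top_fraction(self):
        # when the module fits inside the top-3% budget, propagation puts
        # its members at the top of the ranking
        recovered = total = 0
        for seed in range(10):
            b = generate_bundle(SynthConfig(rng_seed=seed, disease_module_size=5))
            res = disease_effect(b.network, b.disease_genes)
            sub = extract_top_fraction(
                b.network, res, 0.03, disease_genes=b.disease_genes
            )
            recovered += sub.disease_genes_retained
            total += sub.disease_genes_total
        assert recovered / total >= 0.8

    def test_invalid_fraction_errors(self, network, disease_field):
        with pytest.raises(ValueError):
            extract_top_fraction(network, disease_field, 0.0)
        with pytest.raises(ValueError):
            extract_top_fraction(network, disease_field, 1.0)


class TestDegrees:
    def test_closed_forms(self):
        tri = nx.complete_graph(["A", "B", "C"])
        assert set(degrees(tri).values()) == {2}
        star = star_graph(4)
        d = degrees(star)
        assert d["HUB"] == 4
        assert all(d[f"L{i}"] == 1 for i in range(4))

    def test_handshake_lemma(self, network, disease_field):
        sub = extract_top_fraction(network, disease_field, 0.25)
        d = degrees(sub)
        assert sum(d.values()) == 2 * sub.number_of_edges()


class TestKCore:
    def test_closed_forms(self):
        assert set(kcore_decomposition(nx.complete_graph(3)).values()) == {2}
        assert set(kcore_decomposition(star_graph(5)).values()) == {1}

    def test_matches_recursive_deletion_oracle(self):
        g = nx.gnp_random_graph(50, 0.12, seed=7)
        assert kcore_decomposition(g) == brute_coreness(g)

    def test_coreness_bounded_by_degree(self, network, disease_field):
        sub = extract_top_fraction(network, disease_field, 0.25)
        d, c = degrees(sub), kcore_decomposition(sub)
        assert all(c[v] <= d[v] for v in d)


class TestBetweenness:
    def test_path_middle_node(self):
        g = path_graph(3)
        b_norm = betweenness_centrality(g)
        b_raw = betweenness_centrality(g, normalized=False)
        assert b_raw["B"] == pytest.approx(1.0)
        assert b_norm["B"] == pytest.approx(1.0)

    def test_star_center_and_leaves(self):
        n_leaves = 6
        g = star_graph(n_leaves)
        raw = betweenness_centrality(g, normalized=False)
        norm = betweenness_centrality(g)
        assert raw["HUB"] == pytest.approx(math.comb(n_leaves, 2))
        assert norm["HUB"] == pytest.approx(1.0)
        assert all(norm[f"L{i}"] == 0.0 for i in range(n_leaves))

    def test_cycle_symmetry(self):
        g = nx.cycle_graph(5)
        vals = list(betweenness_centrality(g).values())
        assert np.allclose(vals, vals[0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bfs_path_counting_oracle(self, seed):
        g = nx.gnp_random_graph(40, 0.1, seed=seed)
        ours = betweenness_centrality(g)
        brute = brute_betweenness(g)
        for v in g.nodes:
            assert ours[v] == pytest.approx(brute[v], abs=1e-10)

    def test_disconnected_pairs_contribute_zero(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("X", "Y")])
        raw = betweenness_centrality(g, normalized=False)
        assert raw["B"] == pytest.approx(1.0)  # only the A-C pair


class TestAnnotateTargets:
    def test_no_targets_summary_is_null(self, bundle, disease_field):
        sub = extract_top_fraction(bundle.network, disease_field, 0.05)
        empty = DrugTargetTable.from_rows([("d", "NSAID", "ZZZNOTINNET")])
        rep = annotate_targets(sub, bundle.disease_genes, empty)
        assert rep.summary["n_targets_on_subnetwork"] == 0
        assert rep.summary["frac_targets_degree_above_mean"] is None

    def test_hub_target_flagged_above_mean(self, bundle, disease_field):
        sub = extract_top_fraction(bundle.network, disease_field, 0.2)
        d = degrees(sub)
        hub = max(d, key=lambda v: (d[v], v))
        tab = DrugTargetTable.from_rows([("hubdrug", "DMARD", hub)])
        rep = annotate_targets(sub, bundle.disease_genes, tab)
        assert rep.summary["frac_targets_degree_above_mean"] == 1.0

    def test_table_columns_and_flags(self, bundle, disease_field):
        sub = extract_top_fraction(bundle.network, disease_field, 0.2)
        rep = annotate_targets(sub, bundle.disease_genes, bundle.drugs)
        assert list(rep.table.columns) == [
            "gene", "degree", "betweenness", "k_coreness",
            "is_disease_gene", "targeted_by",
        ]
        flagged = set(rep.table.loc[rep.table["is_disease_gene"], "gene"])
        assert flagged == bundle.disease_genes & set(sub.members)

    def test_effective_targets_sit_in_denser_core(self):
        # planted near-module targets should have higher mean coreness than
        # same-sized uniform node samples from the subnetwork
        import numpy as np

        wins = trials = 0
        for seed in range(10):
            b = generate_bundle(SynthConfig(rng_seed=seed))
            res = disease_effect(b.network, b.disease_genes)
            sub = extract_top_fraction(b.network, res, 0.25)
            core = kcore_decomposition(sub)
            on_sub = [
                t for t in b.drugs.targets_of("DRUG_EFFECTIVE") if t in core
            ]
            if not on_sub:
                continue
            target_core = np.mean([core[t] for t in on_sub])
            rng = np.random.default_rng(seed)
            members = list(sub.members)
            for _ in range(100):
                samp = rng.choice(members, len(on_sub), replace=False)
                trials += 1
                wins += target_core >= np.mean([core[v] for v in samp])
        assert wins / trials > 0.5
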