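import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metacna.isoenzyme import (
    build_edges,
    build_isoenzyme_groups,
    build_network,
    map_between_networks,
    network_stats,
)

from conftest import make_model


def groups_as_partition(groups):
    return sorted(tuple(sorted(g.genes)) for g in groups)


class TestGrouping:
    def test_identical_then_subset_merging(self):
        # A,B identical {r1,r2}; C={r1} nested; D={r2,r3} overlaps but is
        # not nested, so it stays separate
        model = make_model({
            "r1": (["a"], ["b"], ["A", "B", "C"]),
            "r2": (["b"], ["c"], ["A", "B", "D"]),
            "r3": (["c"], ["d"], ["D"]),
        })
        groups = build_isoenzyme_groups(model)
        partition = groups_as_partition(groups)
        assert partition == [("A", "B", "C"), ("D",)]
        by_genes = {tuple(sorted(g.genes)): g.reactions for g in groups}
        assert by_genes[("A", "B", "C")] == {"r1", "r2"}
        assert by_genes[("D",)] == {"r2", "r3"}

    def test_all_genes_one_reaction_single_group(self):
        model = make_model({"r1": (["a"], ["b"], ["A", "B", "C", "D"])})
        groups = build_isoenzyme_groups(model)
        assert len(groups) == 1
        assert groups[0].genes == {"A", "B", "C", "D"}

    def test_subset_chain_collapses_to_top(self):
        model = make_model({
            "r1": (["a"], ["b"], ["x", "y", "z"]),
            "r2": (["b"], ["c"], ["y", "z"]),
            "r3": (["c"], ["d"], ["z"]),
        })
        groups = build_isoenzyme_groups(model)
        assert groups_as_partition(groups) == [("x", "y", "z")]
        assert groups[0].reactions == {"r1", "r2", "r3"}

    def test_genes_without_reactions_excluded(self):
        model = make_model({"r1": (["a"], ["b"], ["A"])})
        model.genes.add("orphan")
        groups = build_isoenzyme_groups(model)
        assert groups_as_partition(groups) == [("A",)]

    def test_member_reactions_subset_of_group(self, small_dataset):
        _, (model, net, *_rest) = small_dataset
        gene_rxns = {}
        for r in model.reactions:
            for g in r.genes:
                gene_rxns.setdefault(g, set()).add(r.id)
        for grp in net.groups:
            for g in grp.genes:
                assert gene_rxns[g] <= set(grp.reactions)

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_partition_property_and_order_independence(self, data):
        # random small gene->reaction-set instances: the grouping is always
        # a partition of the genes, and equals the fixpoint of sequential
        # subset-merging no matter the processing order
        n_rxn = data.draw(st.integers(2, 5))
        genes = {}
        for gi in range(data.draw(st.integers(1, 8))):
            size = data.draw(st.integers(1, n_rxn))
            rset = frozenset(
                data.draw(
                    st.lists(
                        st.integers(0, n_rxn - 1),
                        min_size=size, max_size=size, unique=True,
                    )
                )
            )
            genes[f"g{gi}"] = rset
        reactions = {
            f"r{i}": ([f"m{i}"], [f"m{i+1}"],
                      [g for g, rs in genes.items() if i in rs])
            for i in range(n_rxn)
        }
        model = make_model(reactions)
        groups = build_isoenzyme_groups(model)
        # partition property
        seen = [g for grp in groups for g in grp.genes]
        assert sorted(seen) == sorted(genes)
        # independent oracle: genes end up in maximal reaction sets; a
        # sequential random-order merge must give the same *group reaction
        # sets* whenever each nested set has a unique maximal superset
        rsets = {frozenset(f"r{i}" for i in rs) for rs in genes.values()}
        maximal = {rs for rs in rsets if not any(rs < t for t in rsets)}
        assert {frozenset(g.reactions) for g in groups} == maximal


class TestEdges:
    def test_irreversible_gives_one_direction(self):
        model = make_model({
            "r1": (["a"], ["m"], ["u"]),
            "r2": (["m"], ["b"], ["v"]),
        })
        net = build_edges(build_isoenzyme_groups(model), model)
        gid = {next(iter(g.genes)): g.id for g in net.groups}
        assert net.graph.has_edge(gid["u"], gid["v"])
        assert not net.graph.has_edge(gid["v"], gid["u"])

    def test_no_shared_metabolite_no_edge(self):
        model = make_model({
            "r1": (["a"], ["b"], ["u"]),
            "r2": (["c"], ["d"], ["v"]),
        })
        net = build_edges(build_isoenzyme_groups(model), model)
        assert net.graph.number_of_edges() == 0

    def test_reversible_gives_both_directions(self):
        model = make_model(
            {
                "r1": (["a"], ["m"], ["u"]),
                "r2": (["m"], ["b"], ["v"]),
            },
            reversible={"r1", "r2"},
        )
        net = build_edges(build_isoenzyme_groups(model), model)
        gid = {next(iter(g.genes)): g.id for g in net.groups}
        assert net.graph.has_edge(gid["u"], gid["v"])
        assert net.graph.has_edge(gid["v"], gid["u"])

    def test_compartment_specific_metabolites_do_not_connect(self):
        model = make_model(
            {
                "r1": (["a_c"], ["m_c"], ["u"]),
                "r2": (["m_x"], ["b_x"], ["v"]),
            },
            metabolites={"a_c": "c", "m_c": "c", "m_x": "x", "b_x": "x"},
        )
        net = build_edges(build_isoenzyme_groups(model), model)
        assert net.graph.number_of_edges() == 0

    def test_no_self_loops(self, small_dataset):
        _, (_, net, *_rest) = small_dataset
        assert all(u != v for u, v in net.graph.edges())

    def test_removing_metabolite_never_adds_edge(self, rng):
        from metacna.simulate import SimulationConfig, generate_model
        from dataclasses import replace as drep

        model, _ = generate_model(
            SimulationConfig(seed=7, n_metabolites=30, n_reactions=40,
                             n_genes=30, n_groups=15, currency_fraction=0.0)
        )
        groups = build_isoenzyme_groups(model)
        full = build_edges(groups, model)
        victim = model.metabolites[5].id
        from metacna.model_io import MetabolicModel
        from dataclasses import replace

        reduced = MetabolicModel(
            id=model.id,
            metabolites=[m for m in model.metabolites if m.id != victim],
            reactions=[
                replace(r, reactants=r.reactants - {victim},
                        products=r.products - {victim})
                for r in model.reactions
            ],
        )
        sub = build_edges(groups, reduced)
        assert set(sub.graph.edges()) <= set(full.graph.edges())

    def test_unknown_reaction_raises(self):
        model = make_model({"r1": (["a"], ["b"], ["u"])})
        groups = build_isoenzyme_groups(model)
        object.__setattr__(groups[0], "reactions", frozenset({"nope"}))
        with pytest.raises(ValueError, match="unknown reaction"):
            build_edges(groups, model)


class TestNetworkStats:
    def test_directed_three_cycle(self):
        g = nx.DiGraph([(0, 1), (1, 2), (2, 0)])
        s = network_stats(g)
        assert s.density == pytest.approx(0.5)
        assert s.diameter == 2
        assert s.avg_shortest_path == pytest.approx(1.5)
        assert s.n_isolated == 0

    def test_density_integer_identity(self, small_dataset):
        _, (_, net, *_rest) = small_dataset
        s = network_stats(net)
        assert s.density * s.n_nodes * (s.n_nodes - 1) == pytest.approx(s.n_edges)

    def test_isolated_nodes_counted_and_excluded_from_paths(self):
        g = nx.DiGraph([(0, 1), (1, 0)])
        g.add_node(99)
        s = network_stats(g)
        assert s.n_isolated == 1
        assert s.diameter == 1
        assert s.avg_shortest_path == 1.0

    def test_single_node_density_flagged(self):
        g = nx.DiGraph()
        g.add_node(0)
        s = network_stats(g)
        assert s.density == 0.0
        assert not s.density_defined


class TestCrossNetworkOverlap:
    def test_identity_orthology_full_overlap(self, small_dataset):
        _, (_, net, *_rest) = small_dataset
        genes = [g for grp in net.groups for g in grp.genes]
        rep = map_between_networks(net, net, [(g, g) for g in genes])
        assert rep["fraction_a_in_b"] == 1.0
        assert rep["fraction_b_in_a"] == 1.0

    def test_partial_overlap_counts(self):
        model_a = make_model({
            "r1": (["a"], ["b"], ["g1"]),
            "r2": (["c"], ["d"], ["g2"]),
        })
        model_b = make_model({"r1": (["a"], ["b"], ["h1"])})
        net_a = build_edges(build_isoenzyme_groups(model_a), model_a)
        net_b = build_edges(build_isoenzyme_groups(model_b), model_b)
        rep = map_between_networks(net_a, net_b, [("g1", "h1")])
        assert rep["fraction_a_in_b"] == 0.5
        assert rep["fraction_b_in_a"] == 1.0

    def test_empty_orthology_warns_zero(self, small_dataset):
        _, (_, net, *_rest) = small_dataset
        with pytest.warns(UserWarning, match="empty orthology"):
            rep = map_between_networks(net, net, [])
        assert rep["fraction_a_in_b"] == 0.0


def test_graphml_roundtrip(tmp_path, small_dataset):
    _, (_, net, *_rest) = small_dataset
    path = str(tmp_path / "net.graphml")
    net.to_graphml(path)
    from metacna.isoenzyme import EnzymeOrthologyNetwork

    back = EnzymeOrthologyNetwork.from_graphml(path)
    assert set(back.graph.edges()) == set(net.graph.edges())
    assert {g.id: g.genes for g in back.groups} == {
        g.id: g.genes for g in net.groups
    }
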