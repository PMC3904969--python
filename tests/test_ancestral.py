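import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest

from metacna.ancestral import (
    Phylogeny,
    linear_parsimony_reconstruct,
    reconstruct_all,
    squared_parsimony_reconstruct,
)


def phylo(newick):
    return Phylogeny.from_newick(newick, is_path=False)


def brute_force_wagner(tree, tips, grid):
    """Exhaustive Sankoff over an integer grid; returns (cost, root states)."""
    internals = [n for n in tree.postorder if tree.children(n)]
    best = math.inf
    root_states = set()
    for assign in itertools.product(grid, repeat=len(internals)):
        val = dict(zip(internals, assign))
        val.update(tips)
        cost = sum(
            abs(val[c] - val[p])
            for p, c, _ in tree.branches()
            if c in val and p in val
        )
        if cost < best - 1e-12:
            best = cost
            root_states = {val[tree.root]}
        elif abs(cost - best) < 1e-12:
            root_states.add(val[tree.root])
    return best, root_states


def random_binary_newick(n, rng):
    labels = [f"T{i}" for i in range(n)]
    nodes = [f"{l}:1" for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(f"({a},{b}):1")
    return nodes[0][:-2] + ";", labels


class TestLinearParsimony:
    def test_constant_character_zero_cost(self):
        t = phylo("((A:1,B:1):1,(C:1,D:1):1);")
        res = linear_parsimony_reconstruct(t, {c: 7 for c in "ABCD"})
        assert res.cost == 0
        assert all(v == 7 for v in res.values.values())

    def test_three_taxon_example(self):
        t = phylo("((A:1,B:1)I:1,C:1)R;")
        res = linear_parsimony_reconstruct(t, {"A": 1, "B": 1, "C": 3})
        assert res.cost == 2
        assert res.values["I"] == 1
        assert res.root_interval == (1.0, 3.0)
        # the resolved root must itself be optimal
        assert 1.0 <= res.values["R"] <= 3.0

    def test_cherry_interval_and_midpoint_root(self):
        t = phylo("(A:1,B:1)R;")
        res = linear_parsimony_reconstruct(t, {"A": 0, "B": 2})
        assert res.cost == 2
        assert res.root_interval == (0.0, 2.0)
        assert res.values["R"] == 1.0  # midpoint resolution

    def test_four_taxon_split_interval(self):
        t = phylo("((A:1,B:1):1,(C:1,D:1):1)R;")
        res = linear_parsimony_reconstruct(t, {"A": 1, "B": 1, "C": 2, "D": 2})
        assert res.cost == 1
        assert res.root_interval == (1.0, 2.0)

    def test_missing_tips_impose_no_cost_and_are_imputed(self):
        t = phylo("((A:1,B:1):1,(C:1,D:1):1);")
        res = linear_parsimony_reconstruct(
            t, {"A": 5, "B": float("nan"), "C": 5, "D": 5}
        )
        assert res.cost == 0
        assert res.values["B"] == 5

    def test_fewer_than_two_informative_tips_raises(self):
        t = phylo("(A:1,B:1);")
        with pytest.raises(ValueError, match="non-missing"):
            linear_parsimony_reconstruct(t, {"A": 1, "B": float("nan")})

    def test_non_numeric_raises(self):
        t = phylo("(A:1,B:1);")
        with pytest.raises(TypeError):
            linear_parsimony_reconstruct(t, {"A": "x", "B": 2})

    def test_matches_exhaustive_sankoff_on_random_trees(self):
        rng = random.Random(99)
        for _ in range(60):
            n = rng.randint(2, 6)
            nwk, labels = random_binary_newick(n, rng)
            t = phylo(nwk)
            tips = {l: rng.randint(0, 5) for l in labels}
            res = linear_parsimony_reconstruct(t, tips)
            best, root_states = brute_force_wagner(t, tips, range(6))
            assert res.cost == pytest.approx(best)
            lo, hi = res.root_interval
            assert root_states == {
                v for v in range(6) if lo - 1e-9 <= v <= hi + 1e-9
            }
            # resolution achieves the optimal cost
            realized = sum(
                abs(res.values[c] - res.values[p]) for p, c, _ in t.branches()
            )
            assert realized == pytest.approx(best)

    def test_cost_invariant_to_tip_relabeling(self):
        t1 = phylo("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = phylo("((D:1,C:1):1,(B:1,A:1):1);")
        tips = {"A": 0, "B": 3, "C": 1, "D": 4}
        assert (
            linear_parsimony_reconstruct(t1, tips).cost
            == linear_parsimony_reconstruct(t2, tips).cost
        )

    def test_cost_lower_bound_and_path_tree_equality(self):
        # caterpillar with monotone tips: cost equals the tip range
        t = phylo("(((A:1,B:1):1,C:1):1,D:1);")
        tips = {"A": 0, "B": 1, "C": 2, "D": 5}
        res = linear_parsimony_reconstruct(t, tips)
        assert res.cost >= max(tips.values()) - min(tips.values())
        assert res.cost == pytest.approx(5)

    def test_inverse_length_weighting_moves_change_to_long_branch(self):
        # with cost |delta|/t, the long branch absorbs the change cheaply,
        # pulling the root to the short branch's tip value
        t = phylo("(A:1,B:10)R;")
        res = linear_parsimony_reconstruct(t, {"A": 0, "B": 2}, weighted=True)
        assert res.values["R"] == pytest.approx(0.0)
        unweighted = linear_parsimony_reconstruct(t, {"A": 0, "B": 2})
        assert unweighted.root_interval == (0.0, 2.0)

    def test_multifurcation_matches_brute_force(self):
        t = phylo("((A:1,B:1,C:1)I:1,D:1)R;")
        tips = {"A": 0, "B": 0, "C": 4, "D": 4}
        res = linear_parsimony_reconstruct(t, tips)
        best, root_states = brute_force_wagner(t, tips, range(5))
        assert res.cost == pytest.approx(best)


class TestSquaredParsimony:
    def test_cherry_takes_mean(self):
        t = phylo("(A:1,B:1)R;")
        res = squared_parsimony_reconstruct(t, {"A": 0, "B": 2})
        assert res.values["R"] == pytest.approx(1.0)
        assert res.cost == pytest.approx(2.0)  # (1-0)^2 + (2-1)^2

    def test_constant_zero_cost(self):
        t = phylo("((A:1,B:1):1,C:1);")
        res = squared_parsimony_reconstruct(t, {"A": 2, "B": 2, "C": 2})
        assert res.cost == pytest.approx(0.0)

    def test_matches_numeric_minimum(self):
        from scipy.optimize import minimize

        t = phylo("((A:1,B:1)I:1,C:1)R;")
        tips = {"A": 1.0, "B": 2.0, "C": 7.0}
        res = squared_parsimony_reconstruct(t, tips)

        def cost(x):
            val = {"I": x[0], "R": x[1], **tips}
            return sum(
                (val[c] - val[p]) ** 2 for p, c, _ in t.branches()
            )

        opt = minimize(cost, [0.0, 0.0])
        assert res.cost == pytest.approx(opt.fun, abs=1e-6)


class TestReconstructAll:
    def test_identical_tip_vectors_on_cherry(self):
        t = phylo("(A:1,B:1)R;")
        tips = pd.DataFrame({"g1": [2, 2], "g2": [0, 0]}, index=["A", "B"])
        out = reconstruct_all(t, tips)
        assert (out.states.loc["R"] == [2, 0]).all()
        assert (out.costs == 0).all()

    def test_four_taxon_split_per_group(self):
        t = phylo("((A:1,B:1):1,(C:1,D:1):1)R;")
        tips = pd.DataFrame({"g": [1, 1, 2, 2]}, index=list("ABCD"))
        out = reconstruct_all(t, tips)
        assert out.costs["g"] == pytest.approx(1.0)

    def test_unknown_tips_raise(self):
        t = phylo("(A:1,B:1);")
        tips = pd.DataFrame({"g": [1, 2, 3]}, index=["A", "B", "Z"])
        with pytest.raises(ValueError, match="Z"):
            reconstruct_all(t, tips)

    def test_low_rate_recovery_above_90_percent(self):
        # at a low event rate most internal nodes are recovered exactly
        from metacna.simulate import SimulationConfig, simulate_tree, simulate_copy_evolution

        fractions = []
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, n_taxa=16, gain_rate=0.001,
                                   loss_rate=0.001)
            tree = simulate_tree(cfg)
            groups = [f"G{i}" for i in range(30)]
            tips, truth = simulate_copy_evolution(tree, groups, cfg)
            out = reconstruct_all(tree, tips)
            ints = out.integer_states()
            internal = [n for n in tree.postorder if tree.children(n)]
            frac = (
                ints.loc[internal] == truth.node_states.loc[internal]
            ).to_numpy().mean()
            fractions.append(frac)
        assert np.mean(fractions) > 0.9

    def test_integer_rounding_halves_round_down(self):
        t = phylo("(A:1,B:1)R;")
        tips = pd.DataFrame({"g": [0, 3]}, index=["A", "B"])
        out = reconstruct_all(t, tips)
        assert out.states.at["R", "g"] == pytest.approx(1.5)
        assert out.integer_states().at["R", "g"] == 1


class TestPhylogeny:
    def test_newick_roundtrip_preserves_topology(self):
        t = phylo("((A:1,B:2)N1:3,C:4)root;")
        nwk = t.to_newick()
        t2 = phylo(nwk)
        assert sorted(t2.tips) == ["A", "B", "C"]
        assert t2.branch_length("B") == 2.0

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            phylo("(A:1,A:1);")

    def test_internal_labels_assigned_uniquely(self):
        t = phylo("((A:1,B:1):1,(C:1,D:1):1);")
        internals = [n for n in t.postorder if t.children(n)]
        assert len(internals) == len(set(internals)) == 3

    def test_branches_cover_all_nonroot_nodes(self):
        t = phylo("((A:1,B:1):2,C:3);")
        bs = t.branches()
        assert len(bs) == 4
        assert {c for _, c, _ in bs} == set(t.postorder) - {t.root}
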