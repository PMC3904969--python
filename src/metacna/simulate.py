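"""Synthetic data with known ground truth for every pipeline stage.

The generator emits all four pipeline inputs — an SBML metabolic model with
gene-protein-reaction strings, an ultrametric phylogeny, per-species
orthology tables, and a species x trait table — together with the ground
truth needed to score every stage: the planted isoenzyme-group partition,
the true copy-number vector at every tree node, the true per-branch events,
and the trait-generating coefficients.

Copy numbers evolve by a truncated Poisson birth-death process: along a
branch of length t (million years), gains ~ Poisson(gain_rate * t) and
losses ~ Poisson(loss_rate * t), with counts floored at zero.  Traits
follow a Brownian-like model on the same tree in which the change along a
branch is a linear function of that branch's true copy-number changes in a
few planted groups plus Gaussian noise with variance scaling with branch
length; unplanted traits are pure noise.

Default dimensions mirror a mammal-scale study (18 taxa, hundreds of
isoenzyme groups, 17 traits); tests use smaller configurations.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .ancestral import Phylogeny
from .model_io import CURRENCY_METABOLITES, MetabolicModel, Metabolite, Reaction

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree",
    "generate_model",
    "simulate_copy_evolution",
    "simulate_traits",
    "generate_dataset",
]


@dataclass
class SimulationConfig:
    seed: int = 0
    # model
    n_metabolites: int = 400
    n_reactions: int = 600
    n_genes: int = 800
    n_groups: int = 400
    n_compartments: int = 3
    reversible_fraction: float = 0.3
    currency_fraction: float = 0.05
    # phylogeny
    n_taxa: int = 18
    tree_depth_my: float = 160.0
    # copy-number evolution (per group, per million years)
    gain_rate: float = 0.002
    loss_rate: float = 0.002
    # traits
    n_traits: int = 17
    planted: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    trait_noise_var_per_my: float = 0.02
    missing_trait_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_groups > self.n_genes:
            raise ValueError("cannot plant more groups than genes")
        if min(self.gain_rate, self.loss_rate, self.trait_noise_var_per_my) < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class GroundTruth:
    planted_partition: dict[str, list[str]]  # group id -> gene ids
    node_states: pd.DataFrame | None = None  # node x group true counts
    branch_events: pd.DataFrame | None = None  # parent, child, gains, losses
    trait_coefficients: dict[str, list[tuple[str, float]]] = field(
        default_factory=dict
    )
    trait_node_values: pd.DataFrame | None = None


def simulate_tree(cfg: SimulationConfig) -> Phylogeny:
    """Ultrametric pure-birth tree rescaled to ``tree_depth_my``."""
    from dendropy.simulate import treesim

    rng = random.Random(cfg.seed)
    taxa = dendropy.TaxonNamespace(
        [f"sp{i:02d}" for i in range(cfg.n_taxa)]
    )
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=cfg.n_taxa,
        taxon_namespace=taxa,
        rng=rng,
    )
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth * cfg.tree_depth_my
    return Phylogeny(tree)


def generate_model(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[MetabolicModel, GroundTruth]:
    """Random compartmentalized reaction network with a planted grouping.

    Each planted group owns a private *anchor* reaction plus shared extras;
    every member gene's reaction set contains the anchor and is a subset of
    the group's set, at least one member carries the full set, and some
    members duplicate each other's sets exactly — so the two-step grouping
    provably recovers the planted partition.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.n_reactions < cfg.n_groups:
        raise ValueError("need at least one reaction per planted group")

    comps = [f"c{i}" for i in range(cfg.n_compartments)]
    currency_names = list(CURRENCY_METABOLITES)
    metabolites: list[Metabolite] = []
    n_currency = int(cfg.currency_fraction * cfg.n_metabolites)
    for i in range(cfg.n_metabolites):
        comp = comps[int(rng.integers(len(comps)))]
        if i < n_currency:
            base = currency_names[i % len(currency_names)]
            metabolites.append(
                Metabolite(
                    id=f"{base.lower().replace('+', '')}_{comp}_{i}",
                    name=base,
                    compartment=comp,
                )
            )
        else:
            metabolites.append(
                Metabolite(id=f"m{i:04d}_{comp}", name=f"met{i}", compartment=comp)
            )
    met_ids = [m.id for m in metabolites]

    reactions: list[Reaction] = []
    for i in range(cfg.n_reactions):
        k_r = int(rng.integers(1, 4))
        k_p = int(rng.integers(1, 4))
        chosen = rng.choice(len(met_ids), size=k_r + k_p, replace=False)
        reactions.append(
            Reaction(
                id=f"R{i:04d}",
                reversible=bool(rng.random() < cfg.reversible_fraction),
                reactants={met_ids[j] for j in chosen[:k_r]},
                products={met_ids[j] for j in chosen[k_r:]},
            )
        )

    # planted grouping over genes
    anchors = rng.choice(cfg.n_reactions, size=cfg.n_groups, replace=False)
    gene_names = [f"g{i:04d}" for i in range(cfg.n_genes)]
    # distribute genes: every group gets one, remainder at random
    owners = list(range(cfg.n_groups)) + list(
        rng.integers(0, cfg.n_groups, size=cfg.n_genes - cfg.n_groups)
    )
    partition: dict[str, list[str]] = {}
    non_anchor = [i for i in range(cfg.n_reactions) if i not in set(anchors)]
    group_rsets: list[list[int]] = []
    for gi in range(cfg.n_groups):
        extras = []
        if non_anchor and rng.random() < 0.7:
            n_extra = int(rng.integers(1, 3))
            extras = list(
                rng.choice(non_anchor, size=min(n_extra, len(non_anchor)), replace=False)
            )
        group_rsets.append([int(anchors[gi])] + [int(e) for e in extras])

    members: dict[int, list[str]] = {gi: [] for gi in range(cfg.n_groups)}
    for gene, gi in zip(gene_names, owners):
        members[gi].append(gene)
    for gi, genes in members.items():
        rset = group_rsets[gi]
        for j, gene in enumerate(genes):
            if j == 0 or len(rset) == 1 or rng.random() < 0.5:
                gene_rxns = list(rset)  # full set (first gene always)
            else:
                # proper subset containing the anchor
                k = int(rng.integers(1, len(rset)))
                extras = list(
                    rng.choice(rset[1:], size=k - 1, replace=False)
                ) if k > 1 else []
                gene_rxns = [rset[0]] + extras
            for ri in gene_rxns:
                reactions[ri].genes.add(gene)

    model = MetabolicModel(
        id=f"synthetic_model_seed{cfg.seed}",
        metabolites=metabolites,
        reactions=reactions,
    )
    truth = GroundTruth(
        planted_partition={
            f"planted{gi:04d}": sorted(genes) for gi, genes in members.items()
        }
    )
    return model, truth


def simulate_copy_evolution(
    tree: Phylogeny,
    group_ids: list[str],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    root_counts: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Evolve integer copy numbers along the tree.

    Returns the tip table (species x group) and ground truth holding the
    true counts at every node plus per-branch gain/loss events.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    states: dict[str, np.ndarray] = {}
    if root_counts is None:
        root = 1 + rng.poisson(1.0, size=len(group_ids))
    else:
        root = np.array([root_counts[g] for g in group_ids], dtype=int)
        if (root < 1).any():
            root = np.maximum(root, 1)
    states[tree.root] = root
    events = []
    for lab in reversed(tree.postorder):  # preorder: parents first
        if lab == tree.root:
            continue
        parent = states[tree.parent(lab)]
        t = tree.branch_length(lab)
        gains = rng.poisson(cfg.gain_rate * t, size=len(group_ids))
        losses = rng.poisson(cfg.loss_rate * t, size=len(group_ids))
        child = np.maximum(parent + gains - losses, 0)
        states[lab] = child
        applied_losses = parent + gains - child
        for gi, g in enumerate(group_ids):
            if gains[gi] or applied_losses[gi]:
                events.append(
                    (tree.parent(lab), lab, g, int(gains[gi]), int(applied_losses[gi]))
                )
    node_states = pd.DataFrame(
        {g: [states[lab][i] for lab in tree.postorder] for i, g in enumerate(group_ids)},
        index=tree.postorder,
        dtype=int,
    )
    truth = GroundTruth(
        planted_partition={},
        node_states=node_states,
        branch_events=pd.DataFrame(
            events, columns=["parent", "child", "group", "gains", "losses"]
        ),
    )
    tips = node_states.loc[tree.tips]
    return tips, truth


def simulate_traits(
    tree: Phylogeny,
    truth: GroundTruth,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Traits as linear functions of per-branch copy changes plus noise.

    Planted traits change along each branch by sum(beta_g * true copy delta
    of group g) plus Normal(0, trait_noise_var_per_my * t); unplanted traits
    are pure noise.  A ``missing_trait_fraction`` of tip values is masked.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    if truth.node_states is None:
        raise ValueError("run simulate_copy_evolution first")
    names = [f"trait{i:02d}" for i in range(cfg.n_traits)]
    planted = dict(cfg.planted)
    for t_name, spec in planted.items():
        for g, _ in spec:
            if g not in truth.node_states.columns:
                raise ValueError(f"planted group {g!r} not in simulated groups")

    node_vals: dict[str, dict[str, float]] = {n: {} for n in names}
    for name in names:
        node_vals[name][tree.root] = 0.0
    for lab in reversed(tree.postorder):
        if lab == tree.root:
            continue
        p = tree.parent(lab)
        t = tree.branch_length(lab)
        for name in names:
            delta = float(
                rng.normal(0.0, np.sqrt(cfg.trait_noise_var_per_my * t))
            )
            for g, beta in planted.get(name, []):
                dcopy = (
                    truth.node_states.at[lab, g] - truth.node_states.at[p, g]
                )
                delta += beta * float(dcopy)
            node_vals[name][lab] = node_vals[name][p] + delta

    trait_nodes = pd.DataFrame(
        {n: [node_vals[n][lab] for lab in tree.postorder] for n in names},
        index=tree.postorder,
    )
    tips = trait_nodes.loc[tree.tips].copy()
    mask = rng.random(tips.shape) < cfg.missing_trait_fraction
    tips = tips.mask(mask)
    truth.trait_coefficients = {n: planted.get(n, []) for n in names}
    truth.trait_node_values = trait_nodes
    return tips, truth


def generate_dataset(cfg: SimulationConfig, outdir: str | None = None):
    """Full bundle: model, network, tree, tip copy numbers, traits, truth.

    When ``outdir`` is given, everything is also written to disk in the
    pipeline's own file formats (SBML, Newick, CSV, TSV, JSON); outputs are
    byte-identical for identical configs.
    """
    from .isoenzyme import build_network
    from .model_io import strip_currency_metabolites, write_sbml_model

    rng = np.random.default_rng(cfg.seed)
    model, truth = generate_model(cfg, rng)
    net = build_network(model, strip_currency=True)
    tree = simulate_tree(cfg)
    root_counts = {
        grp.id: len(grp.genes) for grp in net.groups
    }
    tips, truth2 = simulate_copy_evolution(
        tree, net.node_ids, cfg, rng, root_counts=root_counts
    )
    truth2.planted_partition = truth.planted_partition
    traits, truth2 = simulate_traits(tree, truth2, cfg, rng)

    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_sbml_model(model, os.path.join(outdir, "model.xml"))
        with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
            fh.write(tree.to_newick() + "\n")
        tips.to_csv(os.path.join(outdir, "copy_numbers.csv"))
        traits.to_csv(os.path.join(outdir, "traits.csv"), na_rep="?")
        orth = _identity_orthology(net)
        orth.to_tsv(os.path.join(outdir, "orthology.tsv"))
        with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
            json.dump(
                {
                    "planted_partition": truth2.planted_partition,
                    "node_states": {
                        n: truth2.node_states.loc[n].to_dict()
                        for n in truth2.node_states.index
                    },
                    "trait_coefficients": {
                        k: [[g, b] for g, b in v]
                        for k, v in truth2.trait_coefficients.items()
                    },
                    "config": asdict(cfg),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
    return model, net, tree, tips, traits, truth2


def _identity_orthology(net):
    """Identity orthology table mapping the reference onto itself."""
    from .orthomap import OrthologyTable

    rows = []
    for grp in net.groups:
        for g in sorted(grp.genes):
            rows.append((g, g, "ortholog", f"fam_{grp.id}"))
    return OrthologyTable(
        pd.DataFrame(
            rows, columns=["reference_gene", "target_gene", "relation", "family"]
        )
    )
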