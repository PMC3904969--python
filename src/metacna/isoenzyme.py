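"""Isoenzyme groups and the enzyme orthology network.

Genes are collapsed into *isoenzyme groups* in two steps: (1) genes with
identical reaction sets are merged; (2) any group whose reaction set is a
subset of another group's is absorbed into it, repeated to a fixpoint.
Groups with overlapping but non-nested reaction sets stay distinct.  The
resulting groups are the nodes of a directed network in which an edge u -> v
exists whenever some reaction of u can produce a metabolite that some
reaction of v consumes (reversible reactions contribute both orientations,
handled independently).  Metabolite identity is compartment-specific, so
edges never cross compartments except through transport reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .model_io import MetabolicModel

__all__ = [
    "IsoenzymeGroup",
    "EnzymeOrthologyNetwork",
    "NetworkStats",
    "build_isoenzyme_groups",
    "build_edges",
    "build_network",
    "network_stats",
    "map_between_networks",
]


@dataclass
class IsoenzymeGroup:
    id: str
    genes: frozenset[str]
    reactions: frozenset[str]


@dataclass
class EnzymeOrthologyNetwork:
    """Directed shared-metabolite network over isoenzyme groups."""

    groups: list[IsoenzymeGroup]
    graph: nx.DiGraph
    #: compartments touched by each group's reactions
    compartments: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def node_ids(self) -> list[str]:
        return [g.id for g in self.groups]

    def group(self, node_id: str) -> IsoenzymeGroup:
        return self._by_id[node_id]

    @property
    def _by_id(self) -> dict[str, IsoenzymeGroup]:
        return {g.id: g for g in self.groups}

    def genes_per_group(self) -> dict[str, int]:
        return {g.id: len(g.genes) for g in self.groups}

    def to_graphml(self, path: str) -> None:
        g = self.graph.copy()
        for grp in self.groups:
            g.nodes[grp.id]["genes"] = ";".join(sorted(grp.genes))
            g.nodes[grp.id]["reactions"] = ";".join(sorted(grp.reactions))
            g.nodes[grp.id]["compartments"] = ";".join(
                sorted(self.compartments.get(grp.id, ()))
            )
        nx.write_graphml(g, path)

    @classmethod
    def from_graphml(cls, path: str) -> "EnzymeOrthologyNetwork":
        g = nx.read_graphml(path)
        groups = []
        comps: dict[str, frozenset[str]] = {}
        for nid, data in g.nodes(data=True):
            groups.append(
                IsoenzymeGroup(
                    id=nid,
                    genes=frozenset(
                        x for x in data.get("genes", "").split(";") if x
                    ),
                    reactions=frozenset(
                        x for x in data.get("reactions", "").split(";") if x
                    ),
                )
            )
            comps[nid] = frozenset(
                x for x in data.get("compartments", "").split(";") if x
            )
        graph = nx.DiGraph()
        graph.add_nodes_from(g.nodes())
        graph.add_edges_from(g.edges())
        return cls(groups=groups, graph=graph, compartments=comps)


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    n_isolated: int
    diameter: int
    avg_shortest_path: float
    density: float
    density_defined: bool = True


def build_isoenzyme_groups(model: MetabolicModel) -> list[IsoenzymeGroup]:
    """Collapse the model's genes into isoenzyme groups.

    Step 1 merges genes with identical reaction sets; step 2 repeatedly
    absorbs any group whose reaction set is a subset of another's, until no
    merge applies.  The fixpoint is independent of processing order (the
    subset relation is a partial order on the distinct reaction sets, and a
    set is always absorbed into a maximal superset); groups are processed by
    descending reaction-set size for determinism.  Genes associated with no
    reaction are excluded.
    """
    gene_reactions: dict[str, set[str]] = {}
    for r in model.reactions:
        for g in r.genes:
            gene_reactions.setdefault(g, set()).add(r.id)

    # step 1: one proto-group per distinct reaction set
    by_rset: dict[frozenset[str], set[str]] = {}
    for g, rset in gene_reactions.items():
        by_rset.setdefault(frozenset(rset), set()).add(g)

    # step 2: subset-merge to fixpoint.  Processing sets in descending size,
    # every non-maximal set is absorbed before any of its own subsets is
    # examined, so the fixpoint is: the surviving groups are exactly the
    # maximal reaction sets, and each nested set's genes go to one maximal
    # superset (the largest; exact ties broken lexicographically).
    sets = sorted(by_rset, key=lambda s: (-len(s), sorted(s)))
    maximal = [
        s for s in sets if not any(s < t for t in sets if len(t) > len(s))
    ]
    merged: dict[frozenset[str], set[str]] = {s: set() for s in maximal}
    for s in sets:
        if s in merged:
            merged[s] |= by_rset[s]
        else:
            target = min(
                (t for t in maximal if s < t),
                key=lambda t: (-len(t), sorted(t)),
            )
            merged[target] |= by_rset[s]

    groups = []
    ordered = sorted(merged.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0])))
    for i, (rset, genes) in enumerate(ordered):
        groups.append(
            IsoenzymeGroup(
                id=f"IG{i:04d}",
                genes=frozenset(genes),
                reactions=frozenset(rset),
            )
        )
    return groups


def build_edges(
    groups: list[IsoenzymeGroup], model: MetabolicModel
) -> EnzymeOrthologyNetwork:
    """Build the directed shared-metabolite network over isoenzyme groups.

    Assumes currency metabolites have already been stripped from ``model``.
    Edge u -> v iff, under some allowed orientation of their reactions, a
    product metabolite of u is a reactant metabolite of v (compartment
    specific), with u != v.
    """
    reactions = model.reactions_by_id()
    met_comp = {m.id: m.compartment for m in model.metabolites}

    produced: dict[str, set[str]] = {}  # group -> metabolites producible
    consumed: dict[str, set[str]] = {}  # group -> metabolites consumable
    comps: dict[str, frozenset[str]] = {}
    for grp in groups:
        prod: set[str] = set()
        cons: set[str] = set()
        touched: set[str] = set()
        for rid in grp.reactions:
            if rid not in reactions:
                raise ValueError(
                    f"group {grp.id} references unknown reaction {rid!r}"
                )
            r = reactions[rid]
            prod |= r.products
            cons |= r.reactants
            if r.reversible:  # both orientations allowed, independently
                prod |= r.reactants
                cons |= r.products
            touched |= {
                met_comp[m] for m in (r.reactants | r.products) if m in met_comp
            }
        produced[grp.id] = prod
        consumed[grp.id] = cons
        comps[grp.id] = frozenset(touched)

    graph = nx.DiGraph()
    graph.add_nodes_from(g.id for g in groups)
    ids = [g.id for g in groups]
    for u in ids:
        pu = produced[u]
        if not pu:
            continue
        for v in ids:
            if u != v and pu & consumed[v]:
                graph.add_edge(u, v)
    return EnzymeOrthologyNetwork(groups=groups, graph=graph, compartments=comps)


def build_network(
    model: MetabolicModel, strip_currency: bool = True
) -> EnzymeOrthologyNetwork:
    """Convenience: group genes and build edges in one call."""
    from .model_io import strip_currency_metabolites

    groups = build_isoenzyme_groups(model)
    if strip_currency:
        model = strip_currency_metabolites(model)
    return build_edges(groups, model)


def network_stats(net: EnzymeOrthologyNetwork | nx.DiGraph) -> NetworkStats:
    """Connectivity statistics of the enzyme orthology network.

    Density is n_edges / (n (n-1)) over directed pairs.  The diameter and
    average shortest path are computed over reachable ordered pairs of the
    largest weakly connected component, excluding self-pairs; isolated nodes
    (total degree zero) would otherwise make both undefined.
    """
    g = net.graph if isinstance(net, EnzymeOrthologyNetwork) else net
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    e = g.number_of_edges()
    density_defined = n >= 2
    density = e / (n * (n - 1)) if density_defined else 0.0
    isolated = sum(1 for v in g if g.in_degree(v) + g.out_degree(v) == 0)

    wcc = max(nx.weakly_connected_components(g), key=len)
    sub = g.subgraph(wcc)
    diameter = 0
    total = 0.0
    count = 0
    for src, lengths in nx.all_pairs_shortest_path_length(sub):
        for dst, d in lengths.items():
            if dst == src:
                continue
            total += d
            count += 1
            if d > diameter:
                diameter = d
    avg = total / count if count else 0.0
    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        n_isolated=isolated,
        diameter=diameter,
        avg_shortest_path=avg,
        density=density,
        density_defined=density_defined,
    )


def map_between_networks(
    net_a: EnzymeOrthologyNetwork,
    net_b: EnzymeOrthologyNetwork,
    gene_orthology: list[tuple[str, str]],
) -> dict:
    """Cross-network node overlap through gene orthology.

    A node of one network is *matched* if at least one of its genes has an
    ortholog inside some node of the other network.  Returns the matched
    fractions in both directions and the node-to-node correspondence used.
    """
    import warnings

    a_to_b: dict[str, set[str]] = {}
    b_to_a: dict[str, set[str]] = {}
    for ga, gb in gene_orthology:
        a_to_b.setdefault(ga, set()).add(gb)
        b_to_a.setdefault(gb, set()).add(ga)
    if not gene_orthology:
        warnings.warn("empty orthology table; overlap is zero by construction")

    gene_to_node_b = {
        g: grp.id for grp in net_b.groups for g in grp.genes
    }
    gene_to_node_a = {
        g: grp.id for grp in net_a.groups for g in grp.genes
    }

    def match(groups, fwd, gene_to_node):
        matched = {}
        for grp in groups:
            targets = {
                gene_to_node[h]
                for g in grp.genes
                for h in fwd.get(g, ())
                if h in gene_to_node
            }
            if targets:
                matched[grp.id] = sorted(targets)
        return matched

    corr_ab = match(net_a.groups, a_to_b, gene_to_node_b)
    corr_ba = match(net_b.groups, b_to_a, gene_to_node_a)
    return {
        "fraction_a_in_b": len(corr_ab) / len(net_a.groups) if net_a.groups else 0.0,
        "fraction_b_in_a": len(corr_ba) / len(net_b.groups) if net_b.groups else 0.0,
        "correspondence_a_to_b": corr_ab,
        "correspondence_b_to_a": corr_ba,
    }
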