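"""Copy-number alterations: calling, divergence, and the clustering test.

A CNA is an isoenzyme group whose (integer-resolved) gene count at a tree
node differs from the count at its direct ancestor.  Nodes carrying CNAs in
a given comparison tend to be adjacent in the enzyme orthology network; the
clustering test quantifies this by comparing the connected components formed
by CNA-carrying nodes against a null in which the same number of CNA
positions is placed uniformly at random (network topology is never
randomized, only CNA placement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr

from .ancestral import NodeStateMatrix, Phylogeny
from .isoenzyme import EnzymeOrthologyNetwork

__all__ = [
    "CNAEvent",
    "cna_events",
    "branch_event_counts",
    "network_distance",
    "divergence_pairs",
    "divergence_regression",
    "DivergenceFit",
    "cluster_test",
    "ClusterTestResult",
    "ancestor_at_depth",
]


@dataclass(frozen=True)
class CNAEvent:
    parent: str
    child: str
    group: str
    delta: int


def cna_events(
    states: NodeStateMatrix | pd.DataFrame, tree: Phylogeny
) -> list[CNAEvent]:
    """One event per (branch, group) whose integer count changed."""
    ints = (
        states.integer_states()
        if isinstance(states, NodeStateMatrix)
        else states
    )
    events: list[CNAEvent] = []
    for parent, child, _ in tree.branches():
        pv = ints.loc[parent]
        cv = ints.loc[child]
        delta = cv - pv
        for group in delta.index[delta != 0]:
            events.append(
                CNAEvent(parent, child, group, int(delta[group]))
            )
    return events


def branch_event_counts(
    events: list[CNAEvent], tree: Phylogeny
) -> pd.Series:
    counts = {(p, c): 0 for p, c, _ in tree.branches()}
    for e in events:
        counts[(e.parent, e.child)] += 1
    return pd.Series(counts)


def events_to_frame(events: list[CNAEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.parent, e.child, e.group, e.delta) for e in events],
        columns=["parent", "child", "group", "delta"],
    )


# --------------------------------------------------------------------------
# network divergence vs. time


def network_distance(va: pd.Series, vb: pd.Series) -> float:
    """Euclidean distance between two copy-number vectors."""
    if set(va.index) != set(vb.index):
        raise ValueError("copy-number vectors cover different group sets")
    diff = va - vb.reindex(va.index)
    return float(np.sqrt((diff.astype(float) ** 2).sum()))


def divergence_pairs(
    tree: Phylogeny, states: NodeStateMatrix
) -> pd.DataFrame:
    """(time, distance) per branch: branch length in My vs. the Euclidean
    distance between the copy-number vectors at its two end points."""
    ints = states.integer_states()
    rows = []
    for parent, child, length in tree.branches():
        d = network_distance(ints.loc[parent], ints.loc[child])
        rows.append((parent, child, length, d))
    return pd.DataFrame(rows, columns=["parent", "child", "time", "distance"])


@dataclass
class DivergenceFit:
    coefficient: float  # a in y = a x^b
    exponent: float  # b
    r: float  # Pearson correlation on the log-log scale
    n_used: int


def divergence_regression(pairs) -> DivergenceFit:
    """Power-law fit y = a x^b by least squares of log y on log x.

    ``pairs`` is an iterable of (time, distance); non-positive values are
    excluded with a warning.
    """
    arr = np.asarray(
        pairs[["time", "distance"]] if isinstance(pairs, pd.DataFrame) else pairs,
        dtype=float,
    )
    ok = (arr[:, 0] > 0) & (arr[:, 1] > 0)
    if (~ok).any():
        warnings.warn(
            f"excluded {int((~ok).sum())} non-positive (time, distance) pairs"
        )
    arr = arr[ok]
    if len(arr) < 2:
        raise ValueError("need at least 2 positive pairs")
    lx, ly = np.log10(arr[:, 0]), np.log10(arr[:, 1])
    b, loga = np.polyfit(lx, ly, 1)
    if len(arr) == 2 or np.allclose(lx, lx[0]):
        r = 1.0
    else:
        r = float(pearsonr(lx, ly)[0])
    return DivergenceFit(
        coefficient=float(10**loga), exponent=float(b), r=r, n_used=len(arr)
    )


# --------------------------------------------------------------------------
# clustering permutation test


@dataclass
class ClusterTestResult:
    observed: dict[str, float]
    p_greater: dict[str, float]  # P(null >= observed), "bigger than chance"
    p_less: dict[str, float]
    n_permutations: int
    seed: int | None
    degenerate: bool = False
    classification: dict[str, str] = field(default_factory=dict)

    def classify(self, alpha: float = 0.05) -> dict[str, str]:
        out = {}
        for k in self.observed:
            if self.degenerate:
                out[k] = "n.s."
            elif self.p_greater[k] <= alpha:
                out[k] = "bigger"
            elif self.p_less[k] <= alpha:
                out[k] = "smaller"
            else:
                out[k] = "n.s."
        return out


_STATS = (
    "n_components",
    "max_component_size",
    "mean_component_size",
    "mean_in_degree",
    "mean_out_degree",
)


def _component_stats(indptr, indices, node_idx, n_nodes):
    """Weak-component stats of the subgraph induced on ``node_idx``."""
    mask = np.zeros(n_nodes, dtype=bool)
    mask[node_idx] = True
    # edges with both endpoints selected
    rows = np.repeat(node_idx, np.diff(indptr)[node_idx])
    cols_all = [indices[indptr[i]: indptr[i + 1]] for i in node_idx]
    cols = np.concatenate(cols_all) if cols_all else np.empty(0, dtype=int)
    keep = mask[cols] if len(cols) else np.empty(0, dtype=bool)
    rows, cols = rows[keep], cols[keep]
    # relabel to compact indices
    remap = -np.ones(n_nodes, dtype=int)
    remap[node_idx] = np.arange(len(node_idx))
    k = len(node_idx)
    sub = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (remap[rows], remap[cols])),
        shape=(k, k),
    )
    ncomp, labels = connected_components(sub, directed=True, connection="weak")
    sizes = np.bincount(labels, minlength=ncomp)
    return ncomp, int(sizes.max()), float(sizes.mean())


def cluster_test(
    net: EnzymeOrthologyNetwork | nx.DiGraph,
    cna_nodes,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> ClusterTestResult:
    """Permutation test for clustering of CNA-carrying nodes.

    Observed statistics: number, maximum size and mean size of the weak
    components of the subgraph induced on ``cna_nodes``, plus the mean in-
    and out-degree of those nodes in the full network.  The null places the
    same number of CNA nodes uniformly at random (without replacement),
    ``n_perm`` times; empirical p-values use the +1 correction,
    ``p = (1 + #{null >= obs}) / (1 + n_perm)`` and the mirrored version.

    When ``exhaustive`` is true (or None and the number of placements is at
    most ``n_perm``), every placement is enumerated instead of sampled and
    p-values are exact fractions over all placements.
    """
    g = net.graph if isinstance(net, EnzymeOrthologyNetwork) else net
    nodes = list(g.nodes())
    cna_nodes = set(cna_nodes)
    unknown = cna_nodes - set(nodes)
    if unknown:
        raise ValueError(f"CNA nodes not in network: {sorted(unknown)}")

    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr")
    indptr, indices = adj.indptr, adj.indices
    in_deg = np.asarray(adj.sum(axis=0)).ravel()
    out_deg = np.asarray(adj.sum(axis=1)).ravel()

    k = len(cna_nodes)
    degenerate = k == 0 or k == n
    obs_idx = np.array(sorted(index[v] for v in cna_nodes), dtype=int)

    if k == 0:
        observed = {s: 0.0 for s in _STATS}
        return ClusterTestResult(
            observed, {s: 1.0 for s in _STATS}, {s: 1.0 for s in _STATS},
            n_perm, seed, degenerate=True,
        )

    ncomp, mx, mean = _component_stats(indptr, indices, obs_idx, n)
    observed = {
        "n_components": float(ncomp),
        "max_component_size": float(mx),
        "mean_component_size": mean,
        "mean_in_degree": float(in_deg[obs_idx].mean()),
        "mean_out_degree": float(out_deg[obs_idx].mean()),
    }
    if degenerate:
        return ClusterTestResult(
            observed, {s: 1.0 for s in _STATS}, {s: 1.0 for s in _STATS},
            n_perm, seed, degenerate=True,
        )

    from math import comb

    if exhaustive is None:
        exhaustive = comb(n, k) <= n_perm
    if exhaustive:
        from itertools import combinations

        draws = [np.array(c, dtype=int) for c in combinations(range(n), k)]
    else:
        rng = np.random.default_rng(seed)
        draws = [
            rng.choice(n, size=k, replace=False) for _ in range(n_perm)
        ]

    null = np.empty((len(draws), 5))
    for i, idx in enumerate(draws):
        nc, m2, me = _component_stats(indptr, indices, idx, n)
        null[i] = (nc, m2, me, in_deg[idx].mean(), out_deg[idx].mean())

    p_ge, p_le = {}, {}
    for j, s in enumerate(_STATS):
        ge = int((null[:, j] >= observed[s] - 1e-12).sum())
        le = int((null[:, j] <= observed[s] + 1e-12).sum())
        if exhaustive:
            p_ge[s] = ge / len(draws)
            p_le[s] = le / len(draws)
        else:
            p_ge[s] = (1 + ge) / (1 + len(draws))
            p_le[s] = (1 + le) / (1 + len(draws))
    res = ClusterTestResult(
        observed, p_ge, p_le, len(draws), seed, degenerate=False
    )
    res.classification = res.classify()
    return res


def ancestor_at_depth(tree: Phylogeny, tip: str, depth: int) -> str | None:
    """The ancestor ``depth`` nodes above a tip (1 = direct ancestor)."""
    node = tip
    for _ in range(depth):
        node = tree.parent(node)
        if node is None:
            return None
    return node
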