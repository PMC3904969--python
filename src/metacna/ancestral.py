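"""Ancestral reconstruction of continuous characters by linear parsimony.

Linear (Wagner) parsimony minimizes the sum over branches of |child - parent|
for a character observed at the tips of a fixed rooted tree.  The exact
optimum is computed by dynamic programming over convex piecewise-linear cost
functions: for each node v, ``f_v(x)`` is the minimal subtree cost given that
v takes value x.  For a tip, ``f = |x - observed|`` (or identically zero when
the tip is missing, which therefore contributes no cost).  For an internal
node, ``f_v = sum_c  min_y [ f_c(y) + w |x - y| ]``; the inner minimization
("smoothing") simply clips the slopes of ``f_c`` to ``[-w, w]``.  The branch
weight w is 1 by default (unweighted parsimony; branch lengths do not enter
the cost).

Each optimal node value forms an interval.  A single resolution is chosen on
the down-pass: the root takes the midpoint of its optimal interval and every
other node takes the point of its conditionally-optimal interval closest to
its resolved parent.  Copy-number-alteration calling rounds the resolved
values to integers (half-integers round down); the raw reals are retained.

Squared-change parsimony (minimizing sum of squared changes) is available as
an alternative; it uses the standard quadratic-recursion dynamic program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "linear_parsimony_reconstruct",
    "squared_parsimony_reconstruct",
    "reconstruct_all",
    "NodeStateMatrix",
]


# --------------------------------------------------------------------------
# phylogeny container


class Phylogeny:
    """A rooted tree with named nodes and branch lengths in million years.

    Wraps a dendropy tree; unnamed internal nodes are assigned stable labels
    ``N0, N1, ...`` in preorder (root first).  Tip labels must be unique.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        counter = 0
        used = {
            lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon
        }
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("unlabeled tip in tree")
                nd._mc_label = nd.taxon.label
            else:
                label = nd.label or (nd.taxon.label if nd.taxon else None)
                while not label or label in used:
                    label = f"N{counter}"
                    counter += 1
                used.add(label)
                nd._mc_label = label
        labels = [lf._mc_label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels")

        # index nodes in postorder for the reconstruction sweeps
        self.postorder: list[str] = []
        self._children: dict[str, list[str]] = {}
        self._parent: dict[str, str | None] = {}
        self._length: dict[str, float] = {}  # branch above each node
        for nd in tree.postorder_node_iter():
            lab = nd._mc_label
            self.postorder.append(lab)
            self._children[lab] = [c._mc_label for c in nd.child_nodes()]
            self._parent[lab] = (
                nd.parent_node._mc_label if nd.parent_node else None
            )
            self._length[lab] = (
                float(nd.edge.length) if nd.edge.length is not None else 0.0
            )
        self.root: str = self.postorder[-1]
        self.tips: list[str] = [lab for lab in self.postorder if not self._children[lab]]

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str, is_path: bool | None = None) -> "Phylogeny":
        """Read a rooted tree from a Newick string or file path."""
        if is_path is None:
            is_path = "(" not in source
        kwargs = dict(
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        try:
            if is_path:
                tree = dendropy.Tree.get(path=source, **kwargs)
            else:
                tree = dendropy.Tree.get(data=source, **kwargs)
        except dendropy.utility.error.DataParseError as exc:
            if "uplicate" in str(exc):
                raise ValueError(f"duplicate tip labels in tree: {exc}") from exc
            raise
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    # -- topology accessors ------------------------------------------------
    def children(self, label: str) -> list[str]:
        return self._children[label]

    def parent(self, label: str) -> str | None:
        return self._parent[label]

    def branch_length(self, child_label: str) -> float:
        return self._length[child_label]

    @property
    def node_labels(self) -> list[str]:
        return list(self.postorder)

    def branches(self) -> list[tuple[str, str, float]]:
        """All (parent, child, length) triples, postorder by child."""
        return [
            (self._parent[c], c, self._length[c])
            for c in self.postorder
            if self._parent[c] is not None
        ]

    def terminal_branch(self, tip: str) -> tuple[str, str]:
        return (self._parent[tip], tip)


# --------------------------------------------------------------------------
# convex piecewise-linear functions: (breakpoints xs, slopes ss, value y0 at
# xs[0]).  len(ss) == len(xs) + 1; slopes are nondecreasing.  A function with
# no breakpoints is the constant y0 (only the all-missing case).

_PLF = tuple[list[float], list[float], float]


def _plf_tip(v: float) -> _PLF:
    return ([v], [-1.0, 1.0], 0.0)


def _plf_const_zero() -> _PLF:
    return ([], [0.0], 0.0)


def _plf_eval(f: _PLF, x: float) -> float:
    xs, ss, y0 = f
    if not xs:
        return y0
    y = y0
    if x <= xs[0]:
        return y0 + ss[0] * (x - xs[0])
    for j in range(1, len(xs)):
        if x <= xs[j]:
            return y + ss[j] * (x - xs[j - 1])
        y += ss[j] * (xs[j] - xs[j - 1])
    return y + ss[-1] * (x - xs[-1])


def _plf_add(f: _PLF, g: _PLF) -> _PLF:
    fx, fs, _ = f
    gx, gs, _ = g
    if not fx:
        return (list(gx), [s + fs[0] for s in gs], _plf_eval(g, gx[0]) + f[2]) if gx else ([], [fs[0] + gs[0]], f[2] + g[2])
    if not gx:
        return (list(fx), [s + gs[0] for s in fs], f[2] + g[2])
    xs = sorted(set(fx) | set(gx))
    i = j = 0
    ss = []
    for k in range(len(xs) + 1):
        # slope on segment k (left of xs[k], or right of last)
        ss.append(fs[i] + gs[j])
        if k < len(xs):
            if i < len(fx) and fx[i] == xs[k]:
                i += 1
            if j < len(gx) and gx[j] == xs[k]:
                j += 1
    y0 = _plf_eval(f, xs[0]) + _plf_eval(g, xs[0])
    return (xs, ss, y0)


def _plf_clip(f: _PLF, w: float) -> _PLF:
    """min_y f(y) + w|x - y|  ==  f with slopes clipped to [-w, w]."""
    xs, ss, y0 = f
    if not xs:
        return f
    # cumulative values at breakpoints
    vals = [y0]
    for j in range(1, len(xs)):
        vals.append(vals[-1] + ss[j] * (xs[j] - xs[j - 1]))
    cs = [min(max(s, -w), w) for s in ss]
    nxs, nss, nvals = [], [cs[0]], []
    for j, x in enumerate(xs):
        if cs[j] != cs[j + 1]:
            nxs.append(x)
            nvals.append(vals[j])
            nss.append(cs[j + 1])
    if not nxs:  # clipped flat: constant at the minimum of f
        return ([], [0.0], min(vals))
    return (nxs, nss, nvals[0])


def _plf_min(f: _PLF) -> tuple[float, float, float]:
    """(min value, argmin lower, argmin upper); infinities when unbounded."""
    xs, ss, y0 = f
    if not xs:
        return (y0, -math.inf, math.inf)
    vals = [y0]
    for j in range(1, len(xs)):
        vals.append(vals[-1] + ss[j] * (xs[j] - xs[j - 1]))
    lo = -math.inf if ss[0] >= 0 else None
    hi = math.inf if ss[-1] <= 0 else None
    best = min(vals)
    if lo is None:
        # leftmost breakpoint whose right slope is >= 0
        for j, x in enumerate(xs):
            if ss[j + 1] >= 0:
                lo = x
                break
        if lo is None:
            lo = xs[-1]
    if hi is None:
        # rightmost breakpoint whose left slope is <= 0
        for j in range(len(xs) - 1, -1, -1):
            if ss[j] <= 0:
                hi = xs[j]
                break
        if hi is None:
            hi = xs[0]
    return (best, lo, hi)


def _plf_conditional_interval(f: _PLF, w: float) -> tuple[float, float]:
    """Interval [A, B] such that argmin_x f(x) + w|x - p| = clamp(p, A, B)."""
    xs, ss, _ = f
    if not xs:
        return (-math.inf, math.inf)
    a = -math.inf
    if ss[0] < -w:
        for j, x in enumerate(xs):
            if ss[j + 1] >= -w:
                a = x
                break
        else:
            a = xs[-1]
    b = math.inf
    if ss[-1] > w:
        for j in range(len(xs) - 1, -1, -1):
            if ss[j] <= w:
                b = xs[j]
                break
        else:
            b = xs[0]
    return (a, b)


# --------------------------------------------------------------------------
# integer-indexed topology for repeated sweeps (the association pipeline
# reconstructs thousands of single characters on one fixed tree)


class _TreeIndex:
    def __init__(self, tree: "Phylogeny"):
        labels = tree.postorder
        self.labels = labels
        self.pos = {lab: i for i, lab in enumerate(labels)}
        self.children = [
            [self.pos[c] for c in tree.children(lab)] for lab in labels
        ]
        self.parent = [
            self.pos[tree.parent(lab)] if tree.parent(lab) is not None else -1
            for lab in labels
        ]
        self.root = self.pos[tree.root]
        self.tip_pos = [self.pos[t] for t in tree.tips]
        self.weights = [1.0] * len(labels)  # unweighted parsimony


def _wagner_indexed(
    ti: _TreeIndex, tipvals: np.ndarray
) -> tuple[np.ndarray, float, tuple[float, float], list[tuple[float, float]]]:
    """Wagner parsimony sweep over an indexed tree.

    ``tipvals`` has one entry per node (postorder); non-tip and missing-tip
    entries are NaN.  Returns resolved values for every node, the minimal
    cost, the optimal root interval, and each node's conditional-optimal
    interval [a, b]: given the resolved parent value p, every value in
    clamp(p, a, b) extends the reconstruction at minimal cost.
    """
    n = len(ti.labels)
    funcs: list[_PLF] = [None] * n  # type: ignore[list-item]
    for i in range(n):
        kids = ti.children[i]
        if not kids:
            v = tipvals[i]
            funcs[i] = _plf_tip(float(v)) if v == v else _plf_const_zero()
        else:
            acc = None
            for c in kids:
                fc = _plf_clip(funcs[c], ti.weights[c])
                acc = fc if acc is None else _plf_add(acc, fc)
            funcs[i] = acc
    cost, lo, hi = _plf_min(funcs[ti.root])
    if math.isinf(lo) or math.isinf(hi):
        lo = hi = 0.0 if math.isinf(lo) and math.isinf(hi) else (lo if not math.isinf(lo) else hi)
    values = np.empty(n)
    values[ti.root] = (lo + hi) / 2.0
    cond: list[tuple[float, float]] = [(lo, hi)] * n
    for i in range(n - 1, -1, -1):
        if i == ti.root:
            continue
        p = values[ti.parent[i]]
        if not ti.children[i] and tipvals[i] == tipvals[i]:
            values[i] = tipvals[i]
            cond[i] = (tipvals[i], tipvals[i])
            continue
        a, b = _plf_conditional_interval(funcs[i], ti.weights[i])
        cond[i] = (a, b)
        values[i] = min(max(p, a), b)
    return values, cost, (lo, hi), cond


# --------------------------------------------------------------------------


@dataclass
class ReconstructionResult:
    values: dict[str, float]  # every node label -> resolved value
    cost: float
    root_interval: tuple[float, float]


def _branch_weight(weighted: bool, length: float) -> float:
    if not weighted:
        return 1.0
    # weighted variant: cost per unit change is inversely proportional to
    # branch duration, so long branches absorb change more cheaply
    return 1.0 / max(length, 1e-9)


def linear_parsimony_reconstruct(
    tree: Phylogeny,
    tip_values: dict[str, float],
    weighted: bool = False,
) -> ReconstructionResult:
    """Exact linear (Wagner) parsimony for one continuous character.

    ``tip_values`` maps tip labels to observed values; tips may be omitted or
    mapped to NaN, in which case they are treated as missing: they impose no
    cost and receive imputed values on the down-pass.

    Returns the resolved value at every node, the exact minimal total cost,
    and the optimal root interval.
    """
    observed = {}
    for t in tree.tips:
        v = tip_values.get(t)
        if v is None:
            continue
        if isinstance(v, str):
            raise TypeError(f"non-numeric tip value for {t!r}: {v!r}")
        v = float(v)
        if not math.isnan(v):
            observed[t] = v
    if len(observed) < 2:
        raise ValueError(
            f"need at least 2 non-missing tips, got {len(observed)}"
        )

    if weighted:
        ti = _TreeIndex(tree)
        ti.weights = [
            _branch_weight(True, tree.branch_length(lab))
            for lab in tree.postorder
        ]
    else:
        ti = getattr(tree, "_cached_index", None)
        if ti is None:
            ti = _TreeIndex(tree)
            tree._cached_index = ti
    tipvals = np.full(len(ti.labels), np.nan)
    for t, v in observed.items():
        tipvals[ti.pos[t]] = v
    vals, cost, (lo, hi), _ = _wagner_indexed(ti, tipvals)
    values = {lab: float(vals[i]) for i, lab in enumerate(ti.labels)}
    return ReconstructionResult(values=values, cost=cost, root_interval=(lo, hi))


def squared_parsimony_reconstruct(
    tree: Phylogeny, tip_values: dict[str, float]
) -> ReconstructionResult:
    """Squared-change parsimony (sum of squared changes), unweighted.

    Dynamic program over quadratics ``f(x) = a (x - m)^2 + k``; smoothing
    across a branch maps (a, m, k) to (a/(a+1), m, k).
    """
    observed = {
        t: float(v)
        for t, v in tip_values.items()
        if v is not None and not math.isnan(float(v))
    }
    if len(observed) < 2:
        raise ValueError("need at least 2 non-missing tips")

    quad: dict[str, tuple[float, float, float] | None] = {}
    for lab in tree.postorder:
        kids = tree.children(lab)
        if not kids:
            quad[lab] = (math.inf, observed[lab], 0.0) if lab in observed else None
        else:
            terms = []
            for c in kids:
                q = quad[c]
                if q is None:
                    continue
                a, m, k = q
                a2 = 1.0 if math.isinf(a) else a / (a + 1.0)
                terms.append((a2, m, k))
            if not terms:
                quad[lab] = None
            else:
                asum = sum(t[0] for t in terms)
                m = sum(t[0] * t[1] for t in terms) / asum
                k = sum(
                    t[2] + t[0] * (t[1] - m) ** 2 for t in terms
                )
                quad[lab] = (asum, m, k)

    a, m, k = quad[tree.root]
    values = {tree.root: m}
    for lab in reversed(tree.postorder):
        if lab == tree.root:
            continue
        p = values[tree.parent(lab)]
        q = quad[lab]
        if not tree.children(lab):
            values[lab] = observed.get(lab, p)
            continue
        if q is None:
            values[lab] = p
            continue
        a, m, kk = q
        values[lab] = (a * m + p) / (a + 1.0)
    return ReconstructionResult(values=values, cost=k, root_interval=(m, m))


# --------------------------------------------------------------------------


@dataclass
class NodeStateMatrix:
    """Real-valued reconstructed states for every node and character."""

    states: pd.DataFrame  # index: node labels (postorder); columns: characters
    costs: pd.Series  # per-character minimal parsimony cost
    tip_missing: pd.DataFrame | None = None

    def integer_states(self) -> pd.DataFrame:
        """Resolved states rounded to integers (half-integers round down)."""
        return np.ceil(self.states - 0.5).astype(int)


def reconstruct_all(
    tree: Phylogeny,
    tip_states: pd.DataFrame,
    method: str = "linear",
    weighted: bool = False,
) -> NodeStateMatrix:
    """Reconstruct every character (column) independently on the tree.

    ``tip_states`` is a species x character table; its index must cover all
    tips with a common column set (NaN = missing).
    """
    missing_tips = set(tree.tips) - set(tip_states.index)
    extra = set(tip_states.index) - set(tree.tips)
    if extra:
        raise ValueError(
            f"tip table rows not in tree: {sorted(extra)}"
        )
    if method not in {"linear", "squared"}:
        raise ValueError(f"unknown method {method!r}")

    recon = (
        linear_parsimony_reconstruct
        if method == "linear"
        else squared_parsimony_reconstruct
    )
    cols = {}
    costs = {}
    for char in tip_states.columns:
        tips = {
            t: tip_states.at[t, char]
            for t in tip_states.index
        }
        if method == "linear":
            res = recon(tree, tips, weighted=weighted)
        else:
            res = recon(tree, tips)
        cols[char] = [res.values[lab] for lab in tree.postorder]
        costs[char] = res.cost
    states = pd.DataFrame(cols, index=tree.postorder)
    missing = tip_states.isna() if not missing_tips else None
    return NodeStateMatrix(
        states=states, costs=pd.Series(costs), tip_missing=missing
    )
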