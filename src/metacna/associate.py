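"""Associating branch-wise copy-number changes with branch-wise trait changes.

The unit of analysis is a tree branch: predictors are the per-branch changes
in gene copy number of each isoenzyme group (from the parsimony
reconstruction of the tip copy-number vectors), and the response is the
per-branch change in a trait (from an independent parsimony reconstruction
of the tip trait values).  Working on branch-wise changes makes the rows
phylogenetically independent contrasts rather than correlated species
values.

For each trait the pipeline is: CFS feature selection -> least median of
squares regression -> leave-one-species-out prediction.  A held-out species'
trait is predicted from the trait value reconstructed for the root *without*
that species plus the regression-predicted changes accumulated along the
root-to-tip path, with every branch of that lineage excluded from the
training rows; the quality measure is the Pearson correlation r between
these predictions and the observed values.  Significance is assessed by
re-running the entire pipeline on datasets in which trait values are
reshuffled among the tip species (empirical one-tailed p with +1
correction), and Benjamini-Hochberg FDR is applied across traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .ancestral import (
    NodeStateMatrix,
    Phylogeny,
    _wagner_indexed,
)
from .estimators import (
    CFSSelector,
    LeastMedianSquaresRegressor,
    _cfs_search,
    _lms_fit_indexed,
)

__all__ = [
    "AssociationResult",
    "branch_change_matrix",
    "cfs_select",
    "lms_regress",
    "loo_species_predict",
    "permutation_significance",
    "associate_traits",
    "bh_fdr",
    "anosim",
    "pca_summary",
]


MISSING_MARKER = "?"


def read_trait_table(path: str) -> pd.DataFrame:
    """Species x trait CSV with '?' marking missing values."""
    df = pd.read_csv(path, index_col=0, na_values=[MISSING_MARKER])
    return df.apply(pd.to_numeric, errors="coerce")


@dataclass
class AssociationResult:
    trait: str
    selected_groups: list[str]
    predictions: pd.Series  # per species LOO predictions
    observed: pd.Series
    r: float
    p: float | None = None
    n_permutations: int = 0
    fdr_significant: bool | None = None


# --------------------------------------------------------------------------


def branch_change_matrix(
    tree: Phylogeny,
    group_states: NodeStateMatrix,
    trait_states: pd.DataFrame | None = None,
    mode: str = "delta",
) -> pd.DataFrame:
    """Branch x (group [, trait]) table of per-branch changes.

    ``mode="delta"`` (default) gives signed child-minus-parent changes in
    integer copy number; ``mode="absolute"`` gives the child's absolute
    copy number instead.  If ``trait_states`` (node x trait, real-valued
    reconstructed states) is given, one delta column per trait is appended.
    """
    if mode not in {"delta", "absolute"}:
        raise ValueError(f"unknown mode {mode!r}")
    ints = group_states.integer_states()
    branches = [(p, c) for p, c, _ in tree.branches()]
    idx = pd.MultiIndex.from_tuples(branches, names=["parent", "child"])
    if mode == "delta":
        feats = pd.DataFrame(
            [ints.loc[c] - ints.loc[p] for p, c in branches], index=idx
        )
    else:
        feats = pd.DataFrame([ints.loc[c] for p, c in branches], index=idx)
    if trait_states is not None:
        tr = pd.DataFrame(
            [trait_states.loc[c] - trait_states.loc[p] for p, c in branches],
            index=idx,
        )
        feats = pd.concat([feats, tr], axis=1)
    return feats


def cfs_select(features: pd.DataFrame, target: pd.Series) -> list[str]:
    """CFS subset selection; returns the selected column names."""
    sel = CFSSelector().fit(features.to_numpy(dtype=float), target.to_numpy(dtype=float))
    return [features.columns[i] for i in sel.selected_indices_]


def lms_regress(
    X, y, n_subsamples: int = 2000, seed: int | None = None
) -> LeastMedianSquaresRegressor:
    """Fit least-median-of-squares regression; returns the fitted estimator."""
    return LeastMedianSquaresRegressor(
        n_subsamples=n_subsamples, random_state=seed
    ).fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))


# --------------------------------------------------------------------------
# fast single-trait engine


class _AssociationEngine:
    """Precomputed state for repeated LOO runs of one feature matrix.

    The feature matrix (copy-number deltas per branch) is fixed; only the
    trait tip values change between calls (observed vs. permuted).  Tree
    indexing, per-fold feature blocks (centered columns, norms,
    feature-feature correlations) and the LMS subsample index sets are
    therefore set up once, so each permutation costs one parsimony sweep
    plus a few small matrix products per fold.
    """

    def __init__(
        self,
        tree: Phylogeny,
        features: pd.DataFrame,
        n_subsamples: int = 200,
        stall_limit: int = 2,
        seed: int | None = None,
        prediction: str = "path",
    ):
        from .ancestral import _TreeIndex

        if prediction not in {"path", "parent"}:
            raise ValueError(f"unknown prediction mode {prediction!r}")
        self.prediction = prediction
        self.tree = tree
        self.ti = _TreeIndex(tree)
        self.feature_names = list(features.columns)
        self.F = features.to_numpy(dtype=float)
        self.branches = list(features.index)  # (parent, child)
        self.row_of_branch = {b: i for i, b in enumerate(self.branches)}
        self.bparent = np.array([self.ti.pos[p] for p, _ in self.branches])
        self.bchild = np.array([self.ti.pos[c] for _, c in self.branches])
        self.n_subsamples = n_subsamples
        self.stall_limit = stall_limit
        self._idx_rng = np.random.default_rng(
            seed if seed is not None else 0
        )
        self._idx_cache: dict[tuple[int, int], np.ndarray] = {}
        self._folds: dict[str, dict] = {}

    def _subsample_idx(self, n: int, q: int) -> np.ndarray:
        key = (n, q)
        if key not in self._idx_cache:
            from .estimators import _subsample_indices

            self._idx_cache[key] = _subsample_indices(
                n, q, self.n_subsamples, self._idx_rng
            )
        return self._idx_cache[key]

    def _fold(self, s: str) -> dict:
        if s in self._folds:
            return self._folds[s]
        parent, child = self.tree.terminal_branch(s)
        term_row = self.row_of_branch[(parent, child)]
        # branch rows on the root-to-tip path, terminal branch last
        path_rows = []
        node = s
        while self.tree.parent(node) is not None:
            path_rows.append(self.row_of_branch[(self.tree.parent(node), node)])
            node = self.tree.parent(node)
        path_rows = path_rows[::-1]
        mask = np.ones(len(self.branches), dtype=bool)
        if self.prediction == "path":
            # the regression predicts every branch of s's lineage, so none
            # of them may appear in its training rows: training on ancestral
            # branches lets the subsample fits memorize the lineage's trait
            # changes, which leaks phylogenetic signal into the null
            mask[path_rows] = False
        else:
            mask[term_row] = False
        X = self.F[mask]
        sx_all = X.std(axis=0)
        live = np.flatnonzero(sx_all > 0)
        Xl = X[:, live]
        mean = Xl.mean(axis=0)
        Xc = Xl - mean
        sx = np.sqrt((Xc**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            rff = np.abs(np.nan_to_num((Xc.T @ Xc) / np.outer(sx, sx)))
        fold = {
            "parent_pos": self.ti.pos[parent],
            "mask": mask,
            "live": live,
            "Xc": Xc,
            "mean": mean,
            "sx": sx,
            "rff": rff,
            "x_new": self.F[term_row, live],
            "x_path": self.F[np.array(path_rows)][:, live],
        }
        self._folds[s] = fold
        return fold

    def loo_predictions(
        self, trait: dict[str, float]
    ) -> tuple[dict[str, float], dict[str, list[int]]]:
        """Leave-one-species-out predictions for one trait.

        ``trait`` maps tip -> value (missing tips absent).  Returns
        predictions per held-out species and the per-fold selected feature
        indices (into the full feature matrix).
        """
        ti = self.ti
        preds: dict[str, float] = {}
        folds: dict[str, list[int]] = {}
        species = [t for t in self.tree.tips if t in trait]
        base = np.full(len(ti.labels), np.nan)
        for t in species:
            base[ti.pos[t]] = trait[t]
        for s in species:
            if len(species) - 1 < 2:
                continue
            fold = self._fold(s)
            tipvals = base.copy()
            tipvals[ti.pos[s]] = np.nan
            vals, _, _, _ = _wagner_indexed(ti, tipvals)
            y = (vals[self.bchild] - vals[self.bparent])[fold["mask"]]
            ymean = y.mean()
            yc = y - ymean
            sy = float(np.sqrt((yc**2).sum()))
            if sy > 0:
                rcf = np.abs(fold["Xc"].T @ yc) / (fold["sx"] * sy)
                sel_local = _cfs_search(rcf, fold["rff"], self.stall_limit)
            else:
                sel_local = []
            sel = [int(fold["live"][i]) for i in sel_local]
            folds[s] = sel
            if not sel:
                # no informative predictor: fall back to the phylogenetic
                # expectation (parent value plus the mean branch change)
                preds[s] = float(vals[fold["parent_pos"]] + ymean)
                continue
            Xs = fold["Xc"][:, sel_local]
            A = np.column_stack([np.ones(len(Xs)), Xs])
            idx = self._subsample_idx(len(Xs), len(sel_local) + 1)
            beta, _ = _lms_fit_indexed(A, yc, idx)
            mean_sel = fold["mean"][sel_local]
            if self.prediction == "parent":
                x_new = fold["x_new"][sel_local] - mean_sel
                delta_hat = float(ymean + beta[0] + x_new @ beta[1:])
                preds[s] = float(vals[fold["parent_pos"]]) + delta_hat
            else:
                # anchor at the reconstructed root value and accumulate the
                # regression-predicted changes along the root-to-tip path
                xp = fold["x_path"][:, sel_local] - mean_sel
                deltas = ymean + beta[0] + xp @ beta[1:]
                preds[s] = float(vals[self.ti.root] + deltas.sum())
        return preds, folds

    def loo_r(
        self, trait: dict[str, float]
    ) -> tuple[float, dict[str, float], dict[str, list[int]]]:
        preds, folds = self.loo_predictions(trait)
        obs = np.array([trait[s] for s in preds])
        hat = np.array([preds[s] for s in preds])
        if len(obs) < 3 or np.std(hat) == 0 or np.std(obs) == 0:
            return float("nan"), preds, folds
        return float(pearsonr(hat, obs)[0]), preds, folds


def _trait_dict(values: pd.Series) -> dict[str, float]:
    return {
        k: float(v) for k, v in values.items() if pd.notna(v)
    }


def loo_species_predict(
    tree: Phylogeny,
    group_states: NodeStateMatrix,
    trait_values: pd.Series,
    mode: str = "delta",
    n_subsamples: int = 200,
    stall_limit: int = 2,
    seed: int | None = None,
    prediction: str = "path",
) -> AssociationResult:
    """Leave-one-species-out association of one trait with CNA changes.

    Requires at least 4 species with an observed trait value.  Species with
    a missing trait are skipped (they still shape the CNA reconstruction,
    which uses genome data only).
    """
    trait = _trait_dict(trait_values)
    if len(trait) < 4:
        raise ValueError(
            f"trait {trait_values.name!r}: need >= 4 observed species, got {len(trait)}"
        )
    features = branch_change_matrix(tree, group_states, mode=mode)
    engine = _AssociationEngine(
        tree, features, n_subsamples, stall_limit, seed=seed, prediction=prediction
    )
    r, preds, folds = engine.loo_r(trait)
    selected = sorted({i for sel in folds.values() for i in sel})
    return AssociationResult(
        trait=str(trait_values.name),
        selected_groups=[engine.feature_names[i] for i in selected],
        predictions=pd.Series(preds),
        observed=pd.Series({s: trait[s] for s in preds}),
        r=r,
    )


def permutation_significance(
    tree: Phylogeny,
    group_states: NodeStateMatrix,
    trait_values: pd.Series,
    n_perm: int = 1000,
    mode: str = "delta",
    n_subsamples: int = 200,
    stall_limit: int = 2,
    seed: int | None = None,
    prediction: str = "path",
) -> AssociationResult:
    """LOO association plus its empirical permutation p-value.

    Trait values are reshuffled among the observed tip species and the whole
    pipeline (trait reconstruction, per-fold selection, LMS, LOO r) is
    re-run per permutation; ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)``.
    """
    trait = _trait_dict(trait_values)
    if len(trait) < 4:
        raise ValueError("need >= 4 observed species")
    features = branch_change_matrix(tree, group_states, mode=mode)
    engine = _AssociationEngine(
        tree, features, n_subsamples, stall_limit, seed=seed, prediction=prediction
    )
    rng = np.random.default_rng(seed)
    r_obs, preds, folds = engine.loo_r(trait)

    tips = list(trait)
    values = np.array([trait[t] for t in tips])
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        r_perm, _, _ = engine.loo_r(dict(zip(tips, perm)))
        if not np.isnan(r_perm) and r_perm >= r_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    selected = sorted({i for sel in folds.values() for i in sel})
    return AssociationResult(
        trait=str(trait_values.name),
        selected_groups=[engine.feature_names[i] for i in selected],
        predictions=pd.Series(preds),
        observed=pd.Series({s: trait[s] for s in preds}),
        r=r_obs,
        p=p,
        n_permutations=n_perm,
    )


def associate_traits(
    tree: Phylogeny,
    group_states: NodeStateMatrix,
    traits: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    mode: str = "delta",
    n_subsamples: int = 200,
    seed: int | None = None,
    prediction: str = "path",
) -> tuple[pd.DataFrame, list[AssociationResult]]:
    """Run the full association pipeline for every trait column.

    Returns a summary table (trait, r, p, FDR flag, selected groups) and the
    per-trait result objects.
    """
    ss = np.random.SeedSequence(seed)
    results = []
    for trait_name, child_seed in zip(
        traits.columns, ss.spawn(len(traits.columns))
    ):
        try:
            res = permutation_significance(
                tree,
                group_states,
                traits[trait_name],
                n_perm=n_perm,
                mode=mode,
                n_subsamples=n_subsamples,
                prediction=prediction,
                seed=int(child_seed.generate_state(1)[0] % (2**31)),
            )
        except ValueError as exc:
            warnings.warn(f"trait {trait_name!r} skipped: {exc}")
            continue
        results.append(res)
    flags = bh_fdr([r.p for r in results], alpha=alpha)
    for res, flag in zip(results, flags):
        res.fdr_significant = bool(flag)
    table = pd.DataFrame(
        {
            "trait": [r.trait for r in results],
            "r": [r.r for r in results],
            "p": [r.p for r in results],
            "fdr_significant": [r.fdr_significant for r in results],
            "selected_groups": [";".join(r.selected_groups) for r in results],
        }
    ).set_index("trait")
    return table, results


# --------------------------------------------------------------------------
# supporting statistics


def bh_fdr(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level alpha."""
    pvalues = np.asarray(list(pvalues), dtype=float)
    if len(pvalues) == 0:
        return np.zeros(0, dtype=bool)
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return reject


def anosim(
    distances: pd.DataFrame | np.ndarray,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with M
    the number of pairs; p by label permutation.  Groups of size 1 are
    excluded with a warning.
    """
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import anosim as _sk_anosim

    if isinstance(distances, pd.DataFrame):
        ids = list(distances.index)
        mat = distances.to_numpy(dtype=float)
    else:
        mat = np.asarray(distances, dtype=float)
        ids = [str(i) for i in range(len(mat))]
    grouping = pd.Series(list(grouping), index=ids)
    sizes = grouping.value_counts()
    singletons = sizes[sizes < 2].index
    if len(singletons):
        warnings.warn(f"excluding singleton groups: {sorted(singletons)}")
        keep = [i for i in ids if grouping[i] not in set(singletons)]
        sub = pd.DataFrame(mat, index=ids, columns=ids).loc[keep, keep]
        mat, ids, grouping = sub.to_numpy(), keep, grouping[keep]
    if grouping.nunique() < 2:
        raise ValueError("need at least 2 groups of size >= 2")
    dm = DistanceMatrix(mat, ids)
    res = _sk_anosim(
        dm, grouping.to_numpy(), permutations=n_perm,
        seed=seed if seed is not None else 0,
    )
    return float(res["test statistic"]), float(res["p-value"])


def pca_summary(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Variance fraction per principal component (covariance-matrix PCA).

    Returns the non-increasing fractions, which sum to 1; all zeros (with a
    warning) for a constant matrix.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix")
    cov = np.cov(X, rowvar=False)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0, None)
    total = eig.sum()
    if total == 0:
        warnings.warn("constant matrix: no variance to decompose")
        return np.zeros(len(eig))
    return eig / total
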