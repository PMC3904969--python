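# metacna

Copy-number evolution of isoenzyme groups in mammalian metabolic networks,
and its association with phenotypic traits.

Genome-scale metabolic models assign many distinct genes to the same
reaction — isoenzymes, often born by gene duplication. `metacna` implements
a phylogenetically-aware comparative pipeline around this observation, for
researchers in systems biology and molecular evolution:

1. **Model I/O** — read an SBML metabolic model (legacy note-field or fbc
   gene associations), flatten gene-protein-reaction strings to gene sets,
   and strip the thirteen ubiquitous currency metabolites (H+, H2O, ATP,
   ADP, Pi, PPi, Na+, CoA, O2, NAD+, NADH, NADP+, NADPH) in every
   compartment.
2. **Enzyme orthology network** — collapse genes into *isoenzyme groups*
   (identical reaction sets merged, then nested subsets absorbed to a
   fixpoint) and connect group u → v when a product of one of u's reactions
   is a reactant of one of v's (reversible reactions contribute both
   orientations); network statistics and cross-network overlap through gene
   orthology.
3. **Genome projection** — map a target genome onto the network by the
   three-step orthology/orphan-homolog/gene-family assignment, yielding one
   gene-count vector *v* per species (element *v<sub>i</sub>* = gene count
   of group *i*).
4. **Ancestral reconstruction** — exact linear (Wagner) parsimony for every
   group and trait on a fixed dated phylogeny, by dynamic programming over
   convex piecewise-linear cost functions (missing trait values allowed);
   squared-change parsimony as an alternative. A *copy-number alteration*
   (CNA) is any group whose count differs between a node and its direct
   ancestor.
5. **CNA analysis** — per-branch CNA events; Euclidean network divergence
   and its power-law regression against divergence time
   (y = a·x^b fit on log-log scale); a permutation test asking whether
   CNA-carrying nodes cluster in the network (induced weak components vs.
   uniformly re-placed CNAs, never randomizing topology).
6. **Trait association** — per-branch trait changes regressed on per-branch
   copy-number changes: CFS feature selection
   (merit k·r̄_cf / √(k + k(k−1)·r̄_ff)), least-median-of-squares
   regression, leave-one-species-out prediction correlation r, empirical
   significance from 1,000 trait reshuffles, Benjamini–Hochberg FDR across
   traits; ANOSIM and covariance-PCA summaries.
7. **Synthetic data** — a generator for every input (SBML model with a
   planted grouping, dated tree, birth–death copy evolution, traits driven
   by planted groups) with full ground truth, so each stage is testable.

The regression and selection steps are scikit-learn estimators
(`LeastMedianSquaresRegressor`, `CFSSelector`) and compose with sklearn
pipelines.

## Worked example

```python
from metacna import (SimulationConfig, generate_dataset, reconstruct_all,
                     network_stats, cna_events, permutation_significance)

cfg = SimulationConfig(
    seed=1, n_metabolites=60, n_reactions=80, n_genes=80, n_groups=40,
    n_taxa=16, gain_rate=0.08, loss_rate=0.08, n_traits=2,
    planted={"trait00": [("IG0000", 8.0)]},
    trait_noise_var_per_my=0.001, missing_trait_fraction=0.0,
)
model, net, tree, tips, traits, truth = generate_dataset(cfg)
stats = network_stats(net)
print(f"{stats.n_nodes} groups, {stats.n_edges} edges, "
      f"density {stats.density:.3f}")

states = reconstruct_all(tree, tips)          # Wagner parsimony per group
print(f"{len(cna_events(states, tree))} CNA events on {len(tree.branches())} branches")

res = permutation_significance(tree, states, traits["trait00"],
                               n_perm=1000, seed=1)
print(f"trait00: LOO r = {res.r:.3f}, p = {res.p:.4g}, "
      f"selected {res.selected_groups}")
```

Output:

```
40 groups, 488 edges, density 0.313
412 CNA events on 30 branches
trait00: LOO r = 0.968, p = 0.000999, selected ['IG0000']
```

The planted group `IG0000` (true effect β = 8 per gene copy) is the only
group selected across the leave-one-out folds; the prediction correlation
0.968 beats all 1,000 trait reshuffles, giving the smallest attainable
empirical p of 1/1001.

A `metacna` command-line tool wraps the same functions
(`metacna simulate`, `model-summary`, `build-network`, `map-genome`,
`ancestral`, `cluster-test`, `associate`); run `metacna --help`.

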