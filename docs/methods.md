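# Methods

This note documents the models, algorithms and numerical choices behind
`metacna`, in the order the pipeline runs them.

## Metabolic model reduction

A genome-scale metabolic model is reduced to the data the comparative
analysis needs: metabolites with compartments, reactions with reversibility
and side membership, and the set of genes attached to each reaction.
Boolean gene-protein-reaction structure (AND/OR complexes) is flattened to
gene membership because the downstream unit of analysis is the *count* of
genes per isoenzyme group; complex stoichiometry never enters. Both legacy
`GENE_ASSOCIATION` note fields and fbc gene products are read, with the
dialect auto-detected.

Thirteen currency metabolites — H+, H2O, ATP, ADP, Pi, PPi, Na+, CoA, O2,
NAD+, NADH, NADP+, NADPH — are removed in every compartment before edge
construction; left in place they would connect most of the network through
cofactor recycling rather than carbon flow. Matching is by
compartment-stripped base name against a configurable synonym table
(case-insensitive), since SBML dialects suffix compartments differently
(`M_atp_c`, `atp[c]`, ...). Reactions whose two sides are emptied by the
removal are kept but flagged, so reaction counts are stable; they simply
contribute no edges.

## Isoenzyme groups and the enzyme orthology network

Grouping is two-step: genes with identical reaction sets merge, then any
group whose reaction set is nested inside another's is absorbed, repeated
to a fixpoint. Processing nested sets in descending size order makes the
fixpoint a closed form: the surviving groups are exactly the *maximal*
reaction sets, and each nested set's genes join one maximal superset (the
largest; exact ties resolved lexicographically). Groups with overlapping
but non-nested reaction sets are never merged. Genes with no reaction are
excluded.

Edges are directed: u → v when, under some allowed orientation of their
reactions, a product of u is a reactant of v. Reversible reactions
contribute both orientations independently. Metabolite identity is
(species, compartment), so edges cross compartments only through transport
reactions that share a species.

Network statistics: density is e/(n(n−1)) over ordered pairs. Diameter and
average shortest path are computed over reachable ordered pairs of the
largest weakly connected component, self-pairs excluded — isolated groups
would otherwise make both undefined; this component-restricted convention
is a package choice, recorded here rather than asserted as the only one.

## Genome projection

A target genome is projected onto the reference network in three steps:
orthologs are counted in their counterpart's group (a gene whose orthologs
span several groups goes to the plurality group; exact ties to the
lexicographically smallest id, with a warning — a rule, not a claim about
biology); orphan genes homologous to members of exactly one group join it;
remaining families of ≥ 2 members (configurable) whose annotated reference
members all sit in one group are assigned there. An audit records the step
that placed each gene; genes absent from the orthology table are silently
ignored, since most of a genome is non-metabolic.

## Ancestral reconstruction

Copy numbers and traits are reconstructed on a fixed, dated phylogeny by
linear (Wagner) parsimony: minimize the sum over branches of
|child − parent|. The optimum is computed exactly by dynamic programming
over convex piecewise-linear functions f_v(x) = minimal subtree cost given
node value x; crossing a branch clips slopes to [−w, w] (w = 1,
unweighted: branch lengths do not enter the cost; an inverse-length
weighted variant exists but is off by default). This handles real-valued
traits, integer counts, multifurcations and missing tips (cost-free,
imputed on the down-pass) in one framework, and matches exhaustive Sankoff
enumeration on every topology up to six tips (tested).

Optimal node values form intervals. The resolution rule matters for CNA
calling and is therefore explicit: the root takes its interval midpoint;
every other node takes the value in its conditionally-optimal interval
closest to its resolved parent. Resolved values are kept as reals;
CNA calling rounds to integers with half-integers rounded *down* (the
conservative direction for a midpoint-resolved root). Linear parsimony was
chosen over squared-change because states are integer gene counts and
linear parsimony preserves integer optima; squared-change (exact quadratic
recursion) is available as `method="squared"`.

A CNA event is any (branch, group) with a nonzero integer delta. Network
divergence between two nodes is the Euclidean distance between their count
vectors; its relation to time is summarized by a log-log least squares fit
y = a·x^b with Pearson r on the log scale (non-positive pairs excluded
with a warning).

## Clustering permutation test

Remove all nodes without CNAs; compute the weak components of the induced
subgraph (direction is ignored for connectivity — the question is
adjacency, not reachability). Statistics: number of components, maximum
and mean component size, and the mean in/out degree of the CNA nodes in
the full network. The null re-places the same number of CNA positions
uniformly at random, topology fixed; p-values are empirical with the +1
correction, one per tail, and the placement null is enumerated completely
whenever the number of placements is no larger than the permutation
budget (making small-network p-values exact fractions). Classification at
α = 0.05 into bigger / smaller / n.s. covers both tails.

A calibration note: empirical p-values of heavily discrete statistics
(max component size takes a handful of values on small networks) are
conservative by construction, so type-I calibration checks use the
fine-grained mean-degree statistic; the discrete statistics are instead
validated exactly against complete enumeration.

## Trait association

The unit of analysis is the branch: predictors are per-branch integer
copy-number deltas (signed; an absolute-copy-number mode exists), the
response is the per-branch trait delta from the trait's own parsimony
reconstruction. Branch-wise changes are phylogenetically independent
contrasts, so shared ancestry does not masquerade as association.

**CFS selection.** Greedy best-first forward search over the merit
k·r̄_cf / √(k + k(k−1)·r̄_ff), where r̄_cf is the mean absolute
feature-target Pearson correlation of the k selected features and r̄_ff
their mean absolute pairwise correlation; the search stops after two
consecutive additions that fail to improve the best merit seen, and
returns the best subset.

**Least median of squares.** Candidate fits are exact interpolations of
(p+1)-row subsamples (all of them when few enough, otherwise uniformly
sampled), plus two non-elemental candidates judged by the same median
loss: the full-data OLS fit (so the returned fit is never worse than OLS
on the median loss) and a reweighted refit (OLS on the inliers of the best
elemental fit at the usual 2.5σ robust cut), which keeps the elemental
search's robustness with far stabler coefficients. Ties at the minimal
median — common, because any fit through a zero-variance majority of rows
attains a zero median — are broken by the mean of the smallest 75% of
squared residuals, preferring the fit that also explains rows beyond the
median. Missing predictor values are imputed with column medians and the
data re-centered before fitting. A structural consequence of the median
loss worth knowing: an association carried by a minority of branches is
invisible to it, so detectable signals must move the trait on roughly half
the branches or more.

**Leave-one-species-out.** For each species s with an observed trait: the
trait is re-reconstructed without s; selection and regression are re-run on
training rows that exclude *every branch of s's root-to-tip lineage*; s's
value is predicted as the reconstructed root value plus the sum of
regression-predicted deltas along that lineage. Two aspects of this design
carry the statistical weight:

- *Path anchoring.* With s removed, its parent becomes a degree-2 node
  whose parsimony interval collapses toward the grandparent, so a
  parent-anchored prediction systematically loses the trait change on the
  parent's own branch — a noiseless planted signal then cannot reach
  r = 1, whereas the path-anchored prediction recovers it.
- *Lineage exclusion.* The regression predicts every branch of the
  lineage, so none of them may appear in its training rows. Training on
  ancestral branches lets the interpolating subsample fits memorize the
  lineage's reconstructed trait changes; a heritable (Brownian) trait then
  beats its own tip-permutations even with no copy-number association,
  making the permutation p anticonservative. With lineage exclusion the
  null p-values are indistinguishable from uniform in calibration runs,
  while planted-signal recovery is unchanged. (The parent-anchored,
  terminal-exclusion form remains available as `prediction="parent"`; its
  null is markedly anticonservative, which is the reason it is not the
  default.)

Copy-number reconstructions are not recomputed per fold: genome data is
never missing in this design. The quality measure is the Pearson
correlation r between predictions and observations across species.

**Significance and multiplicity.** Trait values are reshuffled among the
observed tip species; the entire pipeline (trait reconstruction, per-fold
selection, regression, LOO r) is re-run per reshuffle; the one-tailed
empirical p is (1 + #{r_perm ≥ r_obs})/(1 + n) with n = 1,000 by default.
Benjamini-Hochberg at α = 0.05 is applied across traits. ANOSIM (rank
permutation on a distance matrix, groups of one excluded) and PCA on the
covariance matrix (variance fractions only) provide the descriptive
companion summaries.

For repeated permutation runs the engine precomputes per-fold feature
blocks and LMS subsample index sets once; the subsample sets are drawn
from the run's seed and shared across permutations, which is both faster
and removes needless Monte-Carlo variation between permutations.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with full ground truth:

- **Model**: a random compartmentalized reaction-metabolite graph (3
  compartments by default) with currency metabolites injected at a
  configurable rate. Gene-reaction assignments are planted group by group:
  each group owns a private anchor reaction plus shared extras; every
  member's reaction set contains the anchor and at least one member
  carries the full set. This guarantees (provably, and tested) that the
  two-step grouping recovers the planted partition exactly.
- **Copy evolution**: along each branch of length t (My), gains ~
  Poisson(λ_g t) and losses ~ Poisson(λ_l t), counts floored at zero; root
  counts equal the reference model's group sizes. True states and events
  are recorded at every node and branch.
- **Traits**: per branch, delta = Σ_g β_g·Δcopy_g + N(0, σ²t); unplanted
  traits are pure Brownian noise; a configurable fraction of tip values is
  masked (written as `?`).

Default dimensions mirror a mammal-scale study: 18 taxa on a Yule tree
rescaled to 160 My depth, ~400 groups from 800 genes, 17 traits, event
rate 0.002 per group per My. What the generator does *not* emulate:
realistic chemistry, gene-family sequence evolution, correlated gains
across groups, non-Brownian trait evolution, or orthology-inference error
(identity tables are emitted). Passing tests therefore validate the
machinery and its statistical calibration, not the biological conclusions
one would draw from real genomes.

## Verification scenario sizes

Tests and the acceptance script scale the study down so every stage can be
recomputed from scratch: 16 taxa, 40 groups (80 genes, 80 reactions, 60
metabolites). The planted-association scenario uses a deliberately strong,
dense signal — gain = loss = 0.08 per group per My (one to two events per
branch, the density the median-based regression loss structurally needs),
one planted group with β = 8 trait units per gene copy, trait noise
variance 0.001 per My — so that recovery failures indicate implementation
error rather than weak signal. Type-I and FDR calibrations use 500 and 200
replicates respectively; parsimony is verified against exhaustive
enumeration on all 1,069 rooted binary topologies of up to six tips with
integer states on 0..5.

## Known limitations

- Parsimony reconstructions are point resolutions from optimal intervals;
  CNA calls on long branches inherit that ambiguity, and the residual
  failure mode of the association pipeline is an event parsimony places on
  a neighboring branch of the true one, mis-anchoring the prediction.
- The LMS loss cannot see minority-branch associations (above).
- The clustering test conditions on the observed number of CNA nodes; it
  does not model uncertainty in the CNA calls themselves.
- Cross-network overlap depends entirely on the supplied orthology table;
  no orthology inference is performed.
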