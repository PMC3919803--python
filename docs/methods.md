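# Methods

This note documents the models, conventions and design choices behind the
package, roughly in pipeline order. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Supermatrix and coverage semantics

A supermatrix is a taxon × column character matrix with a gene →
`[start, end)` partition map (0-based half-open internally; the emitted
partition files use the 1-based inclusive `MODEL, name = first-last`
dialect, with conversion centralized in one pair of functions). Coverage
is tracked in a separate boolean presence mask — a taxon is present in a
gene iff it contributed at least one non-gap residue — rather than derived
from gap counts, so writing and re-reading a matrix preserves coverage
exactly and later column pruning cannot silently change what "covered"
means. An all-gap row within a gene file is treated as an absent taxon at
parse time.

All dataset-reduction rules read only the presence mask and the
ribosomal-protein (RP) flags, never column content. They are therefore
order-preserving, idempotent, and commute pairwise (property-tested), and
`mintax` thresholds compose by maximum:

- `filter_min_taxa(t)`: keep genes present in ≥ t taxa. A taxon that would
  lose its last gene makes the call fail rather than silently dropping the
  taxon, because a downstream tree leaf without data is an error anyway.
- `filter_group_coverage`: keep genes with ≥ 1 present taxon in every
  group of a user-supplied taxon grouping (the "most purposive subset").
- `exclude_flagged`: delete RP-flagged genes (`noRPs` variants).
- `select_representatives`: within each focal group keep the single taxon
  with the most covered amino-acid positions (sum of gene lengths over
  present genes). Positions, not gene counts, are used as the finer of the
  two natural coverage measures; exact ties break to the lexicographically
  smaller taxon id for determinism.

The quartet-based information-content weighting some matrix-reduction
tools add on top of coverage thresholds is deliberately not implemented;
reduction here is whole-gene only.

## Singleton/dingleton (-DS) pruning

Columns are classified from a residue tally that ignores gaps and the
ambiguity code "X" (an ambiguous state is not evidence of a private
character). A column with at most one distinct residue is *constant*.
Otherwise it is *singleton* if some residue has tally exactly 1 and
*dingleton* if some residue has tally exactly 2; `-DS` pruning removes
every singleton or dingleton column. Two readings of "a pair sharing a
state different from all other sequences" are possible; the default takes
it as "a residue occurring in exactly two sequences, whatever the rest
carry", because the strict alternative (remainder monomorphic) is nearly
inert at realistic taxon counts and could not produce the strong
alignment shortening this filter is used for. The strict reading is
available behind a `strict=True` switch for sensitivity analysis. A
consequence of the tally rule worth noting: a column with exactly two
non-gap residues that differ is two singletons and is removed.

Pruning preserves the gene set unless a gene loses every column, in which
case the gene is dropped with a logged warning. Idempotence, preservation
of monomorphic columns, and the branch-length-shortening effect (total
re-estimated tree length after pruning ≤ before, on genes simulated with
site-rate heterogeneity) are covered by tests.

## Likelihood machinery

`Q = S·diag(π)` with the diagonal filled to zero row sums and the matrix
scaled so the equilibrium rate `−Σ π_i Q_ii` is 1; branch lengths are then
expected substitutions per site for a variable site at relative rate 1.
Spectral decomposition of the symmetrized form `diag(√π)·Q·diag(1/√π)`
gives `P(t) = R·diag(e^{λt})·L` with rows clipped to [0, 1] and
renormalized (errors ≤ 1e-12).

Rate variation is the standard two-component mixture: invariant with
probability `p_inv`, else one of K = 4 equal-weight discrete-gamma
categories. Category rates are the mean over each quantile bin of the
mean-1 gamma density (computed via the incomplete-gamma identity and
renormalized to mean exactly 1) — the mean-of-bin convention, not the
median. Rates are *not* rescaled by `1/(1 − p_inv)`; the mixture's total
mean rate is absorbed by the branch lengths. This matters when comparing
absolute branch lengths across tools.

Felsenstein pruning runs over deduplicated site patterns with per-site
rescaling of partial likelihoods (each internal node's partials are
divided by their per-site maximum, with the logs accumulated), so
underflow cannot occur even on long trees. Gaps and "X" contribute a flat
partial over all 20 residues; the invariant-site term for a pattern is
`Σ π_r` over the residues compatible with every sequence (zero when the
non-gap residues conflict).

### Branch-length optimization

Coordinate-wise ascent: each branch is optimized by bounded Brent search
holding the others fixed, sweeping the tree depth-first until the lnL gain
per sweep falls below a tolerance (default 1e-4). Within a sweep, subtree
("down") and rest-of-tree ("out") partials are kept current as the
traversal proceeds, so every 1-D search maximizes the exact joint
likelihood; the ascent is monotone by construction (a proposed move is
rejected if it does not improve the exact objective). For one branch the
site likelihood is `Σ_m (o·R)_m (L·d)_m e^{λ_m r_k t}` in the eigenbasis,
so a line-search step costs a single (sites × 20K) matrix-vector product
after two one-off basis transforms. Brent uses a trust region
`[0, max(0.5, 5t)]` that grows across sweeps if the optimum hits the
ceiling; lengths are capped at 20 substitutions/site.

`compare_topologies` optimizes branch lengths per candidate with the
partitions sharing one set of branch lengths (each partition keeps its own
matrix, frequencies, `p_inv` and gamma shape) and reports candidates
sorted by total lnL with ΔlnL to the best. Its default convergence
tolerance is 0.5 lnL units with a coarser line-search tolerance: the
quantity of interest is a ΔlnL ranking whose relevant differences are
tens to hundreds of units, and measured residual under-convergence at
this setting is about one unit. Statistical topology tests (AU/SH,
bootstrap) are out of scope; the ranking reports raw ΔlnL only.

### Start topologies for per-gene fits

Where a per-gene tree is needed (gene-rate proxy, model selection) the
topology comes from neighbor joining on maximum-likelihood pairwise
distances under the same +I+G+F model (sites with an ambiguous member are
skipped pairwise; negative NJ branch lengths are clamped to zero) and only
branch lengths are then optimized. This replaces a full ML tree search:
the downstream quantities — a tree-length sum and a between-model lnL
difference on a common tree — are robust to fine topology details at
these scales, and the approximation is validated by the rate-recovery and
model-recovery tests rather than assumed.

## Gene-rate filter

A gene's evolutionary rate is proxied by the total branch length of its
primer-taxon tree under LG+I+G+F (primer taxa default to the seven
core-set reference species and are configurable). With `n` rateable genes
the exclusion threshold is the `floor(q·n)`-th smallest tree length and
exceedance is strict — the unique simple convention under which 410
distinct rates at q = 0.75 retain exactly 307 genes, matching the
dataset ledger this reproduces. Genes with fewer than two primer taxa
cannot be rated; they are retained (the filter acts only on measured
rates) and logged prominently.

## Model selection and partitions

Every gene is scored under the eight empirical matrices with +I+G+F on a
single shared tree (NJ-started, branch lengths optimized under LG). The
+F frequencies are the gene's observed residue counts with add-one
smoothing — identical across candidates by definition of +F — and `p_inv`
and the gamma shape are profiled once (two alternating bounded searches)
under LG and reused. Every candidate therefore has the same parameter
count k = 21 (p_inv + shape + 19 free frequencies), and the AIC ranking
`2k − 2 lnL` reduces to lnL ranking with a deterministic model-name
tie-break (Blosum62 < cpREV < Dayhoff < JTT < LG < rtREV < VT < WAG).
This is one step beyond the usual shared-tree shortcut (which re-profiles
rate parameters per candidate); the JTT-recovery test shows the cheaper
convention still identifies the generating matrix. AICc and BIC are not
implemented. Partition assignment sends each gene to its best available
model's partition, falling back to the second-best when a model is
excluded (the 7-partition scheme used when LG is unavailable to a
downstream program); per-partition `p_inv`/shape are the means over the
member genes' fits, and partition frequencies are recomputed from the
partition's own columns.

## Synthetic data

The generator's defaults are the study conditions: 19 taxa in five groups
of sizes 3/1/2/2/11; 410 genes with lognormal lengths around 187 columns
(ledger scale: 76,652 positions / 410 genes); per-gene matrices drawn
from the eight empirical models with an LG/JTT/WAG-heavy mix; lognormal
gene-rate multipliers (mean 1, σ = 0.5); `p_inv` = 0.1 and gamma shape
0.8; an RP flag on a deterministic round(410·51/410) = 51 genes (a seeded
permutation, not Bernoulli draws, so flag-count arithmetic is exact); and
per-taxon presence probabilities from 0.95 (primer taxa) down to 0.087
(the single gastrotrich), mimicking the strongly unequal EST coverage the
real data show. The default tree carries the Seisonidea+Acanthocephala
resolution with the contested internal branch at 0.05 substitutions/site
— long enough to be recoverable, short enough not to be trivial. Species
names are synthetic stand-ins for the study's taxa.

Simulation is the standard Markov walk: root states from π, per-site
rates (invariant or a gamma category), child states via
`P(t · rate · multiplier)`. Everything is deterministic given
(seed, gene index). Limitations, deliberately accepted: missingness is
taxon-wise i.i.d. across genes (no phylogenetic autocorrelation of
coverage, no within-gene partial fragments); no alignment error, paralogy
or contamination; no compositional heterogeneity across lineages. Passing
tests therefore demonstrate correctness of the pipeline's computations
under the stated generative model, not robustness to those real-data
pathologies.

## Problem sizes used in the checks

The topology-recovery suite uses 20 replicates of 40 genes × 300 sites on
19 taxa — a deliberate scale-down of the 410-gene study matrix that keeps
ΔlnL separations large (tens to hundreds of units) while the whole suite
re-simulates and re-analyzes every fixture from scratch. Candidates there
are evaluated under a single LG+I+G+F partition, as the original
reduced-dataset analyses did; with per-gene generating matrices mixed
into the data this is mild, candidate-neutral model misspecification.
Likelihood correctness is checked against exhaustive ancestral-state
enumeration (via independent `expm`) on quartets, and re-rooting
invariance on a six-taxon tree; branch-length recovery at 5,000 sites;
the discrete gamma against adaptive quadrature.

## Numerical conventions and degenerate inputs

- Branch lengths live in [0, 20]; optimizers may return lengths of order
  1e-6 instead of exactly 0 for identical sequences (line-search
  tolerance).
- All-gap columns classify as constant and carry likelihood 1 (they
  contribute 0 to lnL).
- Pairs with no comparable sites get the ceiling ML distance.
- `exclude_fast_genes` with a single rateable record uses k = max(1,
  floor(q·n)), i.e. the record itself is the threshold and is retained.
- Empirical frequency vectors are add-one smoothed, so no frequency is
  exactly zero even for residues unobserved in a gene.
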