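# Methods

## Model

The pipeline treats a plant's recorded metabolite content as a noisy,
heavily censored sample of its true metabolome. Its central assumption
is that structurally similar metabolites tend to arise from the same or
adjacent biosynthetic pathways, so presence of *any* member of a group
of structurally similar metabolites is evidence that the pathway — and
hence, probably, the other members — is present. All downstream
similarity is therefore computed over binary plant × metabolite-group
vectors rather than plant × metabolite vectors, which makes the
comparison robust to which particular compound happened to be recorded.

## Stages, parameters, defaults

**Fingerprints.** Structures are parsed with RDKit; the default scheme
is topological atom pairs hashed to 166 bits (configurable length), with
MACCS structural keys as an alternative. Downstream mathematics consumes
only binary vectors, so the scheme is deliberately pluggable, and
fingerprints can be supplied directly as `id<TAB>bitstring` TSV without
any chemistry I/O. A pair of all-zero fingerprints has an undefined
Tanimoto value and raises instead of returning 0 — a silent zero would
be indistinguishable from genuine dissimilarity. Inside network
construction, all-zero fingerprints are kept as isolated nodes (they can
never clear a positive threshold) and logged.

**Similarity network.** Edge iff Tanimoto strictly exceeds the threshold
(default 0.85, the conventional bioactive-similarity cut-off); ties at
exactly the threshold are excluded. All n(n−1)/2 pairs are evaluated via
one integer matrix product. Isolated nodes are retained so singleton
accounting downstream is exact.

**DPClus.** The density–periphery algorithm is specified loosely in the
literature, so this package fixes a deterministic normative variant:
edges are weighted by common-neighbour counts and nodes by summed
incident edge weights; clusters are seeded at the highest-weight node
(ties: higher degree, then smallest id) and grown greedily, admitting
the best-ranked neighbour whose addition keeps cluster density ≥ d
(default 0.9) and whose cluster property cp ≥ 0.5; in overlapping mode
each finished cluster is extended once more over the original graph (so
nodes already claimed by earlier clusters may join); the cluster's nodes
are then removed from the working graph and the process repeats while
edges remain. Candidate ranking is (E_nk, attachment, degree, id), where
*attachment* is the summed common-neighbour weight of the candidate's
edges into the cluster. The attachment term matters only when raw edge
counts tie — in particular at the first growth step from a lone seed,
where every neighbour has E_nk = 1: without it, a high-degree bridge
endpoint would be preferred over a clique mate and a spurious
bridge-pair cluster emitted. Boundary equality is accepted (≥, not >),
which keeps size-2 seed edges (density 1) admissible. A lone seed has no
defined density, so its first neighbour is admitted on the E_nk ranking
alone (any first pair has density 1). Overlap extension runs exactly
once per cluster; unbounded re-extension could merge everything.
Metabolites in no cluster become singleton groups, so groups always
cover the input exactly.

**Plant matrix.** Plants with fewer than `min_metabolites` (default 30)
distinct metabolites are dropped before matrix construction; sparsely
recorded plants carry too little signal to place. Singleton groups are
retained as columns — Simpson/Jaccard pair counts are defined over the
complete group set, and dropping singletons would change them. A
metabolite in several overlapping groups sets every corresponding
column.

**Plant clustering.** Simpson (`a/min(a+b, a+c)`) is the primary
coefficient: it normalises by the smaller profile, so a thoroughly
studied plant and a sparsely recorded relative still score high, and it
equals 1 for nested profiles. Jaccard is provided for comparison.
Distances are `d = 1 − s`. Ward clustering exposes both classic
dialects: `ward.D` (default) applies the Lance–Williams Ward update
directly to the supplied distances, `ward.D2` to squared distances. Both
are computed through SciPy's Ward linkage, which squares its input
internally: running it on √d and squaring the reported heights is
algebraically identical to the Lance–Williams recurrence on raw d. The
choice of dialect is config surface because historical hierarchical
clustering code was ambiguous on this point; merge order often agrees,
heights do not. Tree cutting supports a global k and per-subtree height
thresholds (a mapping from internal-node id to threshold, inherited down
the subtree), which makes the common manual practice of cutting
different parts of a dendrogram at different heights explicit and
reproducible rather than an undocumented judgement call.

**Baker's Gamma.** For each unordered leaf pair, each tree assigns the
lowest number of clusters k at which the pair first co-clusters under
k-cuts (equivalently n minus the merge stage uniting them); the
coefficient is the Spearman correlation, with average ranks on ties,
between the two pair vectors. This value is invariant under strictly
monotone transformations of merge heights (they preserve merge order)
but *not* under arbitrary height changes on a fixed topology, since
reordering merge heights reorders k-cuts; the property tests assert the
monotone-transform invariance, which is the defensible form. Newick
trees (possibly non-binary) are supported by ranking internal nodes
bottom-up by height and using the most recent common ancestor's rank;
rank correlation makes this consistent with the linkage-based levels.
Two star trees compare as 1 by convention (all pair levels equal on
both sides leaves the correlation undefined; identical structures are
maximally concordant).

**Prediction.** Plant sets are formed genus-first (the finer, safer
rank); plants not covered by a genus-level set of size ≥ 2 may still
form family-level sets within their cluster. Candidate groups have at
most 8 members — small groups are the ones plausibly tracking a single
pathway — and at least 2 supporting plants in the set. Only plants
already associated with a group (≥ 1 recorded member) receive its
missing members: a plant with no member of the group provides no
evidence that the pathway is active in it. Isomer handling is a
user-supplied exclusion list; a helper flags same-molecular-formula
group members for review but never auto-excludes, because constitutional
isomers can genuinely arise from different pathways and no structural
test distinguishes the cases reliably.

**Usage classification.** Features are the binary group-membership
vectors; labels E/M collapse to M and W plants are excluded. The
classifier is an RBF-kernel soft-margin SVM at library defaults. The
default evaluation is resubstitution (predict the training set), which
is what a near-perfect majority-class row in a default-parameter SVM
confusion matrix implies; stratified k-fold cross-validation is offered
as the honest generalisation estimate and clearly labelled as a
different protocol. Rates are reported raw and rounded half-up to one
decimal; note that half-up rounding of 8/14 gives 57.1, so published
tables rounded differently by 0.1 may disagree at the last digit.

## Synthetic data

The generator plants exactly the structure the pipeline assumes: each
metabolite group is a random 166-bit base pattern with 40 set bits;
members are copies with independent 1 % per-bit flips; base patterns are
redrawn until pairwise Hamming distance ≥ 50; the resulting within-group
Tanimoto (≈ 0.92 in expectation) and cross-group Tanimoto (≈ 0.15) are
*verified empirically* against the 0.85 threshold by an exhaustive scan,
with the group redrawn on violation and a hard failure after 100
redraws. Taxa own disjoint sets of 8 groups; each of the 6 plants per
taxon receives every metabolite of its taxon's groups; each relation is
then deleted independently with probability q (default 0.2); usage
labels are constant within a taxon. Defaults (5 taxa × 6 plants ≈ 200
metabolites) keep a full pipeline run under a few seconds while leaving
every stage real work.

What the generator does not emulate: the heavy-tailed plant-degree and
group-size distributions of real species–metabolite databases, chemical
realism of fingerprints (bit patterns are abstract), taxa sharing
pathways (taxon profiles are disjoint), and correlated missingness
(deletions are independent, whereas real censoring concentrates on
under-studied species). Passing recovery tests therefore show the
machinery is correct under its own assumptions — clean separation, block
structure, independent censoring — not that real data will cluster this
cleanly; on real inputs the similarity threshold, group sizes, and cut
heights all interact with much messier geometry.

`score_recovery` re-derives the set of recoverable masked relations with
an independent brute-force loop (rather than reusing the prediction
code), so recall-on-recoverable = 1.0 is a genuine cross-check of the
prediction implementation, and shuffled-prediction controls give the
random precision baseline.

## Numerical choices and degenerate inputs

- Tanimoto/Simpson/Jaccard raise on undefined 0/0 denominators rather
  than returning 0.
- Network thresholds are strict (>); DPClus density and cp thresholds
  are inclusive (≥).
- All tie-breaks (DPClus seeding and growth, group ordering, partition
  labelling) resolve by lexicographic id last, making every output a
  deterministic function of the input data and configuration.
- Ward input validation requires a symmetric, non-negative,
  zero-diagonal matrix; one item is an error, two items produce a single
  merge at their distance.
- Plant-group ids are assigned by first appearance in sorted-leaf order,
  so partitions are stable across runs.
- Synthetic generation, SVM cross-validation, and the acceptance script
  consume explicit seeds; reruns are byte-identical (covered by tests).

## Problem sizes

Tests and the reproduction script run the full pipeline at 5 taxa × 6
plants (≈ 200 metabolites, ≈ 500 network edges) and the operation-level
oracles at ≤ 1000 random vectors, ≤ 200-node graphs, and ≤ 20-leaf
trees — sizes chosen so the whole suite completes in seconds while the
brute-force oracles remain tractable.

## Known limitations

- DPClus variants differ across the literature; this package's fixed
  variant reproduces the documented parameters and behaviour but is not
  a byte-for-byte port of any historical binary.
- Resubstitution accuracy overstates generalisation by construction; use
  k-fold mode for honest estimates.
- Baker's Gamma significance is not assessed (no permutation test).
- Power-law fitting of degree/size distributions is out of scope; the
  raw histograms are emitted for external analysis.
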