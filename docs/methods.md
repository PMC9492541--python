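# Methods

## Scope and model

The package operates downstream of gene tree–species tree reconciliation.
Its inputs are expectations, not observations: a reconciliation program
averaging over sampled gene-tree histories reports, per orthogroup and per
species-tree node, an expected copy number and expected counts of
originations, duplications, transfers-in and losses. All accounting here is
therefore defined on non-negative reals and no stage rounds to integers.

Two notions of "gain" coexist deliberately. Category-level gains and losses
follow a **content-difference** definition — the category-weighted content
of a node minus that of its immediate ancestor — while the mechanism
profiles follow **event counts** (origination + duplication + transfer).
Per orthogroup the two are tied by the bookkeeping identity
`copies(child) − copies(parent) = orig + dup + trans − loss`, which the
simulator satisfies exactly and the tests assert; per category they can
differ because profiles spread fractional mass over letters.

Fusion-mediated originations are a subset of originations: the mechanism
table reports the fusion percentage alongside the other three, which alone
sum to 100 on nodes with any gains.

## Functional profiles

Each annotated sequence distributes one unit of weight uniformly over its
category letters (1/k each); a cluster profile is the average of these unit
vectors. The average runs over annotated members only (default), so
annotation coverage does not dilute profiles; dividing by all members is
available via `include_unannotated=True`. The printed two-member example
(one {K} member, one {B, K} member → 0.75 K + 0.25 B) cannot discriminate
between the two denominators, so the choice is a package decision, recorded
in the profile TSV header. The "unknown function" category S is removed
after averaging, with renormalization; removing it before averaging would
differ only for sequences where S co-occurs with informative letters, and
that ordering is switchable.

## External-homologue incorporation

Three filters in order: (1) any hit with query or target coverage strictly
below the threshold (default 75%) is discarded — at-threshold passes; (2) an
external sequence is dropped unless the orthogroup of its best-scoring
internal target (reverse direction) matches the orthogroup of the internal
sequence that best hit it in the forward direction; an external with no
surviving forward hit cannot satisfy this and is dropped; (3) each internal
sequence contributes at most its single best-scoring external query, and
per-orthogroup results are deduplicated. Score ties break deterministically
(higher score, then lexicographically smaller id). Note that relaxing the
coverage threshold is *not* guaranteed to enlarge the result: a newly
admitted forward hit can flip an external's best forward cluster and revoke
its reciprocity, so monotonicity is asserted only on fixtures whose score
structure rules that out.

## Correspondence analysis

Relative category compositions are compositional data (row-sum-constrained),
so the multivariate step uses correspondence analysis rather than PCA:
with correspondence matrix `P = X / n`, row masses `r`, column masses `c`,
the SVD of `D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}` yields principal row coordinates
`D_r^{-1/2}UΣ`, standard column coordinates `D_c^{-1/2}V`, and total inertia
`Σσ²_k = χ²/n` (asserted against scipy's chi-square statistic). Before CA
the table drops the S column and is column-normalized (division by column
*sums*; a max-based variant would be CA-equivalent but changes classifier
features) and then row-normalized. This doubly-normalized table is computed
once over **all** nodes; the CA is fitted on its terminal rows and every
other node is projected as a supplementary point via the transition formula
(row profile × standard column coordinates), so training rows reproduce
their own coordinates and ancestral nodes live in the same feature space
the classifiers were trained in.

Category grouping takes the sign of the mean dimension-1 row coordinate of
the in-group terminals as the positive orientation and assigns each letter
by the sign of its dimension-1 coordinate; the result is invariant to the
SVD's global sign indeterminacy. Letters exactly at zero go to "other" with
a warning; an exactly-zero orientation raises instead of guessing.

## Classifier ensemble

Features are the leading CA dimensions covering ≥ 90% of inertia
(configurable). The default roster is a nearest-neighbour classifier, a
margin classifier with probability calibration, a random forest and a small
feed-forward network; a logistic model is deliberately not included.
Hyperparameters come from stratified cross-validated grid search (requested
5 folds, capped at the minority-class count for small terminal sets), after
which each model is refit on all terminals. Weights are computed over the
full scored node set (terminals + ancestors): per node the across-model mean
probability, per model the mean squared deviation from those means, and the
weight is the inverse of the model's *relative* variance (variance divided
by the summed variances), renormalized to 1. A variance floor of 1e−12
keeps the rule defined for constant models; when all models agree the floor
makes the weights exactly equal by symmetry. The alternative reading of the
weight rule (reciprocal of the variance share without renormalization)
differs only by the common normalizing constant and yields identical
weights after the final normalization.

## Fusion calls

A family is composite when strictly more than 50% of its members are
composite sequences. A composite is a bona fide fusion only when every
component family originated at a **proper ancestor** (lineage ancestry) of
the composite's origination node: same-node co-origination is rejected as a
documented false-negative class, and non-ancestral components (fission
signatures, sibling-clade families) are rejected as false positives.
Ancestry is lineage-based because content is inherited along lineages in
the reconciliation model; a node-depth ordering that also admits
transfer-mediated acquisition is available (`ancestry="depth"`). Families
with a single sequence are never accepted as components. A family with
originations recorded at several nodes resolves to the one closest to the
root (preorder tie-break); families present at the root with no recorded
origination ("pre-root") resolve to the root.

## Mann–Whitney U

One-tailed, exact by full enumeration of all `C(n, n_a)` group assignments
for pooled sizes ≤ 12 (ties contribute 1/2 to U and are handled exactly by
the enumeration); larger samples use the normal approximation with the
standard tie correction and a continuity correction of 1/2. U is reported
for the first sample.

## Simulator

The generator performs a discrete branch walk in preorder; on each branch
events resolve in the order losses → duplications → transfers →
originations, which conserves the bookkeeping identity exactly. Per branch
of length ℓ: each parent copy is lost with probability `1 − e^{−λℓ}`, each
surviving copy duplicates `Poisson(δℓ)` times, `Poisson(τℓ)` transfers-in
draw donor families uniformly among families whose origination node is
strictly shallower than the receiving node (a rank-based stand-in for
contemporaneity; exact time calibration is out of scope), and `Poisson(σℓ)`
new families are born with categories drawn from the baseline distribution
tilted by the receiving clade's multipliers.

Default study conditions (chosen a priori as a desk-scale emulation of a
genome-scale dataset, where ancestors carry thousands of families and
reconciliations infer hundreds of originations per branch): 9-tip two-clade
pectinate tree (4 + 5 tips, unit branch lengths), 1000 root families,
origination σ = 150 per branch, per-copy duplication δ = 0.02, transfer
τ = 5 per branch, per-copy loss λ = 0.03, a 10-letter category alphabet
(C, E, G, K, O, P, T, U, W, Z) with uniform baseline, and clade-A
multipliers of 2.0 on {K, T, W} when a bias is planted. With these rates a
back-of-envelope power calculation puts the per-branch expected shift at
2.5–3.5 standard deviations above zero, which is what makes the planted
bias recoverable in ≥ 95 of 100 replicates without being trivially strong.

Annotations are emitted for extant (tip) copies only — families extinct at
every tip leave nothing to annotate, so `SimTruth.observable_composition()`
(truth restricted to families with surviving members) is the matrix a
noise-free reconstruction recovers exactly, while the full true composition
includes mass no annotation-based method can see. Optional noise adds a
second category letter with probability `p_multi` and blanks annotations
with probability `p_unannotated`. Composites plant true fusions (two
ancestrally originated components) and decoys (a same-node or non-ancestral
component) in equal numbers; `floor(member_fraction · n)` member sequences
per family carry the composite flag, so a fraction of exactly 0.5 fails the
strict majority rule. Hit tables plant four scenarios per external
sequence: clean reciprocal (incorporated), coverage 74.9 (discarded),
reciprocity conflict (discarded) and coverage exactly 75.0 (incorporated).

What the simulator does **not** emulate: sequence evolution (no alignments
or domain architectures — composites are planted, not detected), gene-tree
uncertainty (event expectations are integer counts, whereas real
reconciliations emit fractional posteriors), correlated annotation errors,
and lineage-specific rate variation beyond the planted clade multipliers.
Passing recovery tests therefore shows the *accounting and inference
chain* is correct under the assumed generative structure, not that the
upstream reconciliation or annotation tools are accurate on real data.

All randomness flows from one mandatory master seed; each stage uses a
substream seed derived as the first four bytes of
`sha256("{seed}:{stage}")` (mod 2³¹), so stages can be regenerated
independently and fixtures are byte-identical across runs.

## Numerical and interface choices

* Relative compositions: all-zero rows stay zero and are flagged rather
  than renormalized; shift and scoring operations refuse flagged nodes.
* CA keeps singular values > 1e−12; identical row profiles give a
  zero-dimension model with total inertia 0.
* Percent outputs are computed on the 0–100 scale; decompositions carry an
  explicit residual so the parts always sum to 100.
* Path-cumulative changes exclude the group root's own row (the branch into
  the group root belongs to the root's change, not to the within-group
  path), so sums telescope to tip content minus group-root content.
* The estimator layer (`CorrespondenceAnalysis`,
  `VarianceWeightedEnsemble`) follows the scikit-learn protocol
  (`fit`/`transform`/`predict_proba`, `get_params`, trailing-underscore
  fitted attributes) and composes with sklearn model selection; the
  accounting stages are plain functions over pandas objects.

## Limitations

* The recovery guarantees are statements about the simulator's generative
  model at the default conditions; weaker biases, smaller repertoires or
  heavier annotation noise will lower the recovery rates.
* Mechanism fractions inherit any bias in the upstream reconciliation
  (e.g. transfer/duplication confusion); the package only accounts.
* The lineage-ancestry fusion rule misses fusions whose parts arose in the
  same node, and misclassifies transfer-acquired components as
  non-ancestral unless the depth rule is chosen.
* Classifier probabilities are not calibrated beyond what the base models
  provide; they are comparative scores, not posterior probabilities.
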