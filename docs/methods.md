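# Methods

This note documents the models and procedures implemented in `cofunmir`,
the assumptions behind them, the tunable parameters, and the design choices
made where the design was genuinely open.

## Similarity measures

### Disease semantic similarity (Resnik)

Semantic similarity between ontology terms uses Resnik's
most-informative-common-ancestor definition. Because no annotation corpus is
shipped with the package, information content is computed *structurally*:
p(t) is the fraction of all ontology terms that are descendants of t
(t included), and IC(t) = −log p(t). The similarity of two terms is the
maximal IC over their common ancestors, divided by the maximal attainable IC
(that of a leaf, log N for an N-term ontology), which bounds values in
[0, 1] so they can be mixed with functional similarity on a commensurate
scale. The root has IC 0, so terms whose only common ancestor is the root
get similarity 0. Only `is_a` edges are read from OBO input; other
relationship types are ignored.

### Gene-set functional similarity

Functional similarity between two entities annotated with gene sets defaults
to the Jaccard index of the sets. When a gene–gene similarity matrix is
available, a best-match-average is used instead: for each gene of one set
take the maximum similarity against the other set, average within each
direction, then average the two directions. The Jaccard default was chosen
because it is reproducible from association tables alone and requires no
additional gene-level similarity resource; the best-match-average variant is
pluggable for users who have one.

### Sequence similarity

Each mature miRNA sequence is encoded as a (4+λ)-dimensional
pseudo-nucleotide-composition vector: the four nucleotide frequencies plus λ
sequence-order correlation terms

    θ_t = (1/(L−t)) Σ_{i=1}^{L−t} (M_{r_i} − M_{r_{i+t}})²,  t = 1..λ,

where M is the molecular weight of the nucleotide (A 135.1270, G 151.1261,
C 111.1020, U 112.0868 daltons) standardized to zero mean and unit
population SD over the four nucleotides. All 4+λ entries share the
denominator Σf + w·Σθ, so the vector sums to 1. Defaults λ=5 and w=0.05 give
9-dimensional vectors. Sequences must be at least λ+2 long so every order
term averages at least two position pairs; DNA-alphabet input (T) is read as
U since FASTA sources vary.

Pairwise Euclidean distances between vectors are min–max rescaled over the
off-diagonal pairs and inverted: the closest pair in the set scores 1, the
farthest 0, and the diagonal is fixed at 1. The rescaling is relative to the
analysed set — adding or removing sequences changes the normalization. When
all pairwise distances coincide (including any two-sequence input) the
normalization is degenerate and all similarities are set to 1 with a logged
warning.

### Combination

Disease similarity is DisSim = α·FunSim + (1−α)·SemSim and miRNA similarity
is MiRSim = α·funSim + (1−α)·SeqSim, with the same α (default 0.8) in both.
The self-similarity of every entity is set to 1 after combination: kernel
diagonals require a well-defined self-similarity, and neither component
defines one consistently (structural Resnik gives IC(t)/maxIC on the
diagonal).

## Pair kernel and classifier

A training sample is a labeled (disease, miRNA) pair. Three
similarity-of-pairs modes are provided:

- `average`: (DisSim + MiRSim)/2,
- `sqrt`: √(DisSim·MiRSim) — the default, bounded in [0, 1] when the inputs
  are,
- `centre`: the Euclidean distance of (DisSim, MiRSim) from the grand means
  (AvgDisSim, AvgMiRSim). As written this is a *distance* — larger values
  mean less typical, not more similar — and the implementation keeps the
  formula verbatim but logs a semantics warning when the mode is selected.

AvgDisSim/AvgMiRSim are the means over all off-diagonal entity pairs of the
*full* similarity matrices, not only over entities occurring in the training
set, so they do not depend on the sampled negatives.

The kernels are supplied to a libSVM-backed support vector classifier as
precomputed kernels. These matrices are not guaranteed positive
semi-definite; libSVM tolerates indefinite precomputed kernels, and no
spectral correction is applied. Probabilities come from libSVM's internal
Platt-style calibration; the regularization constant C defaults to 1 (the
method is not sensitive to it on the planted benchmark) and label metrics
use a 0.5 probability cutoff. Ranked outputs break probability ties by
disease id then miRNA id, so rankings are reproducible.

## Negative-sample selection

For each case/control expression study the per-miRNA fold change is
log2((mean case + ε)/(mean control + ε)) with pseudocount ε = 1e-8. A
(disease, miRNA) pair is nominated negative when |log2 FC| < 0.05. The
threshold is interpreted on the log2 scale: a *linear* fold change below
0.05 would mean 20-fold down-regulation, the opposite of "not differentially
expressed". Nominated pairs overlapping the positive set are discarded, and
a final refinement keeps only diseases with at least one known positive
miRNA and miRNAs with at least one known positive disease, mirroring how
curated negative sets are restricted to entities the positive data can vouch
for.

## Evaluation

Cross-validation (leave-one-out or stratified k-fold) pools held-out
probabilities across folds; AUC is computed over the pooled scores and
specificity/sensitivity/precision/accuracy at the 0.5 cutoff. The full
sample-by-sample kernel is computed once and sliced per fold — kernel
entries do not depend on the fitted model, so this is exactly equivalent to
recomputing per fold. The permutation test permutes labels n_perm times,
re-runs the evaluation, and reports the plus-one empirical p-value
(1 + #{null ≥ observed})/(n_perm + 1). The default scheme inside the
permutation loop is 5-fold CV: the null being sampled is the same as under
LOOCV but each draw costs k fits instead of n.

The ensemble trains n models (default 100), each on all positives plus an
independently drawn balanced negative subset. A candidate is *strongly
associated* only when every model predicts it positive; the reported
probability is the across-model average and the output ranking uses it.

## Co-functional pair scoring

On the tripartite network, psg is the Jaccard index of the two target sets,
rd the Jaccard index of the two disease sets multiplied by the shared-disease
fraction of all network diseases |V_d|, and psgc the fraction of shared
targets that are disease genes of at least one *shared* disease (the union
in psgc runs over the shared diseases only; the scoring rationale is about
the diseases the pair has in common). With no shared targets psgc is defined
as 0 — the 0/0 case — making cfScore 0, consistent with target sharing being
a requirement for co-function. |V_d| is the disease set of the network under
analysis, so disjoint disease families (e.g. cancers vs non-cancers) should
be scored as separate networks. Pairs are unordered, self-pairs rejected,
and the ranking keeps pairs with cfScore > 0 sharing at least `min_diseases`
diseases (default 10 — a pragmatic cut for "multi-disease" given that pairs
co-functioning across many diseases are rarely documented).

Reconstruction adds the top-n ranked predicted disease–miRNA edges (default
3000 at full scale; proportionally fewer on small networks) with
`predicted(probability)` provenance; known edges are never overwritten, and
predicted edges count identically to known ones in D₁/D₂ during scoring —
provenance is retained for reporting only.

Co-functional target probabilities p(g) = (shared diseases linked to
g)/(shared diseases) are reported per shared target, sorted descending; when
the pair shares no disease, p is 0 for every shared target.

## Synthetic fixtures

The generator plants the structure the method is designed to detect, so
every stage is testable without external downloads:

- **Modules.** Each of `n_modules` (default 3) modules is a miRNA pair
  sharing `module_overlap` (default 0.8) of `module_n_genes` (default 8)
  module genes, associated with `module_n_diseases` (default 12, clearing
  the 10-shared-disease ranking threshold) diseases that are each linked to
  all module genes.
- **Background.** Remaining miRNAs/diseases get sparse random annotations
  (5 targets / 5 genes each). Every background miRNA also receives one known
  association to a background disease, because the negative-selection
  refinement only admits miRNAs with at least one known positive — as is
  true of real negative sets.
- **Expression.** One study per module disease with 5 case and 5 control
  samples; log2 expression is N(5, noise_sd²) with noise_sd = 0.05, and the
  module's miRNA pair is shifted by ±`effect_size` (default 1.0, i.e.
  2-fold) in cases. The small noise default reflects the regime in which a
  0.05 log2-FC flatness cutoff is meaningful: averaged, well-measured
  expression. Real single-study miRNA data are noisier; passing tests on
  this fixture show the selection logic is correct, not that the 0.05 cutoff
  is robust to noisy studies.
- **Sequences.** Planted pair members differ by 2 point mutations on a
  random 20–25 nt sequence; background sequences are uniform random. This
  makes sequence similarity correlate with planted co-function so the
  α-mixing is exercised.
- **Ontology.** A three-level tree: root, one branch per module plus a
  background branch, diseases as leaves — deep enough for non-trivial Resnik
  values, shallow enough to enumerate by hand.

Everything derives from one `numpy` generator seeded by the spec, so equal
seeds give byte-identical fixture files. The fixture does not emulate
platform effects, missing values, precursor/mature id ambiguity, or
literature-validation labels.

## Problem sizes and numerical choices

The default benchmark (3 modules × 12 diseases × 2 miRNAs = 72 positives,
balanced to 144 samples) keeps leave-one-out evaluation and a 50-permutation
null in the seconds range on one CPU; the full-scale analyses the method
targets (thousands of associations, hundreds of entities) use the same code
paths with larger inputs. Matrix symmetry is validated to 1e-12; composition
vectors sum to 1 within 1e-9; degenerate cases (zero-variance weights,
all-equal sequence distances, single-class training sets, empty shared
target sets) raise typed errors or return documented fallbacks rather than
NaN.

## Known limitations

- Structural IC is a proxy for corpus-based IC; ontologies whose term
  density does not reflect disease specificity will distort SemSim.
- Min–max sequence-similarity normalization is set-relative; similarities
  from different miRNA sets are not comparable.
- The `centre` kernel mode is kept verbatim for completeness despite its
  inverted semantics; use `sqrt` (default) or `average` for prediction.
- Indefinite kernels mean the SVM optimisation is not convex in general;
  results are deterministic per seed but global optimality is not
  guaranteed.
- Co-functional groups larger than two miRNAs are out of scope.
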