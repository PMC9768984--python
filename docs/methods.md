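# Methods

## Ontology model

The ontology is a directed acyclic graph of terms with typed edges
pointing child → parent. Only `is_a` and `part_of` edges carry
semantics in the Wang family of measures, so every other OBO relation
(`regulates`, `occurs_in`, …) is dropped at load time with a log line,
as are obsolete terms; `alt_id` entries resolve to their canonical id.
Analysis is restricted to a single namespace (biological process by
default), and after filtering each namespace must have **exactly one
root**: a multi-root namespace is a hard error rather than being
patched with a virtual root, because the annotation probability of the
root anchors the information-content scale (`Pro(root) = 1`).

## Information content

`Pro(t)` is the number of terms whose ancestor closure contains `t` —
**including `t` itself** — divided by the namespace size, and
`IC(t) = −ln Pro(t)` (natural log; the base only rescales Resnik and
cancels in Relevance). Counting the term itself is a deliberate
reading of the "occurrence of the term in the corpus": a literal
direct-children count would give every leaf `Pro = 0` and infinite IC,
breaking the Resnik and Relevance formulas. Under this definition
leaves have the maximal IC `ln N` and the root has IC 0.

MICA ties (two common ancestors with equal IC) are broken by
lexicographically smallest term id for determinism. Raw Resnik is
unbounded above, so before gene-level aggregation it is divided by the
namespace's maximum IC (configurable off), keeping all gene
similarities on a [0, 1] scale.

## S-values and the HGS weight

For a focus term `X`, each term `t` in `X`'s ancestor sub-DAG receives
`S_X(t)`: the maximal product of edge weights along a rootward path
from `X` to `t`, computed by dynamic programming in topological order
(children before parents). Weights:

| scheme | `is_a` | `part_of` |
|---|---|---|
| Wang (fixed) | 0.8 | 0.6 |
| HGS | `1/(0.67 + n_children(parent)) + 0.4` | `1/(0.67 + n_children(parent)) + 0.3` |

The HGS functional form is this package's single largest modelling
choice: the measure is specified by its constants (`d = 0.4`/`0.3`,
`c = 0.67`) and by the requirement that the parent's child count
replaces information content. The adopted form is the simplest one
that (a) decreases as the parent's child count grows, matching the
negative child-count/IC relationship the measure is built on, and
(b) stays strictly below 1 for every child count ≥ 1, so S-values
decay along paths. The child count is taken in the full namespace
graph, not the sub-DAG, and the weight is applied uniformly to every
edge. With child counts pinned at 1 and `d` chosen so that
`1/(c+1) + d` equals 0.8/0.6, HGS reduces exactly to Wang — a limit the
tests exercise.

Note that S-values are *not* monotone along every child→parent edge of
a DAG: an ancestor reachable by a short heavy path can out-score a
child that sits on a long path. What does hold — and is tested — is
that every ancestor's S-value is strictly below the best S-value among
its sub-DAG children, making the focus term the unique maximum.

## Gene similarity

Genes are compared through their annotation term sets (terms are used
as directly annotated; no up-propagation, since each term's ancestor
sub-DAG already encodes its ancestry at similarity time). The
term-pair matrix is collapsed by best-match-average
(`(Σᵢ maxⱼ + Σⱼ maxᵢ) / (rows + cols)`), or optionally the global
maximum. The gene matrix is symmetric, computed once per unordered
pair, and its **diagonal is set to 1.0 by convention** for every
measure: Relevance and normalized Resnik self-similarities are
intrinsically below 1 (`1 − Pro(t)` and `IC(t)/IC_max`), so forcing the
diagonal keeps the feature scale consistent across measures; a
`zero_diagonal` flag removes self-similarity from the features
entirely. Row *i* of the matrix — gene *i*'s similarity to every gene
in the cohort — is its classifier feature vector. Evidence codes are
carried through the GAF reader but not weighted.

## Boosting

**AdaBoost-M1.** Stumps minimize weighted 0/1 error over all
(feature, midpoint threshold, polarity) candidates; ties break toward
the lowest feature index, lowest threshold, negative-class-left.
Weights start uniform (`1/n`), and each round multiplies by
`exp(−α·y·h(x))` and renormalizes. A perfect stump (`ε = 0`) receives
α computed at `ε = 10⁻¹⁰` (≈ 11.5) instead of infinity and training
stops, honouring the zero-error stop rule; `ε ≥ 0.5` in the first
round aborts with a diagnostic (the weak-learning condition failed),
and in later rounds stops training with the offending stump discarded.

**Regularized gradient boosting.** The ensemble starts from the
log-odds of the positive rate, then repeatedly fits a depth-limited
regression tree to `g = p − y`, `h = p(1−p)` maximizing the
second-order gain `½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − G²/(H+λ)]` with
leaf values `−G/(H+λ)`; λ penalizes leaf values only (no split-gain
γ, no row/column subsampling, no minimum child weight). Splits with
non-positive gain become leaves, so λ → ∞ collapses every tree to a
zero leaf and predictions to the prior. Defaults: 500 trees, learning
rate 0.1, depth 3, λ = 5. Both learners are deterministic given the
data — no internal randomness — so matrices, models and metrics are
bit-reproducible.

Probabilities are clipped to `[10⁻¹⁵, 1−10⁻¹⁵]` inside the log loss.
Baseline classifiers (GaussianNB, linear/RBF SVC, KNN, random forest)
come from scikit-learn behind the same `fit`/`predict`/`predict_score`
contract and serve purely as comparison points.

## Evaluation protocol

Random undersampling keeps every minority sample and a uniform random
subset of the majority of equal size, reporting the pre-sampling ratio
`positives/negatives × 100`. By default undersampling happens **inside
each training fold**, leaving test folds untouched (no leakage of the
balancing step); a `global` mode undersamples once before splitting
for pipelines that balance first. Stratified k-fold (default k = 5)
shuffles within class and deals round-robin, so per-fold class counts
deviate from proportionality by at most one. Degenerate metric
denominators (e.g. no predicted positives) yield 0 with an explicit
`degenerate` flag instead of raising. AUC-ROC is the rank
(Mann–Whitney) statistic with ties counting ½ — identical to the
trapezoidal area under the empirical ROC. All randomness flows from
one top-level seed, recorded with the derived sub-seeds in the run log.

## Synthetic data

The generator emulates the structure the pipeline needs to be tested
against: a single-rooted DAG whose branches are disjoint subtrees
(each new term attaches to an earlier branch term below the depth cap,
occasionally gaining a second parent; edges are `part_of` with a
configurable fraction, 0.2 by default, matching the `is_a`-dominated
character of biological-process ontologies), and two gene classes
whose 2–15 annotation terms are drawn from their own branch with
probability `branch_purity` and uniformly otherwise. Purity must
exceed 0.5 — at 0.5 the classes are unlearnable by construction.
Defaults (2 branches × 30 terms, depth 5, 100+100 genes, purity 0.9)
give a cohort whose similarity matrix has planted block structure.

What it does **not** emulate: real GO's scale (tens of thousands of
terms) and fan-in, annotation-count skew across genes, evidence-code
noise, shallow-annotation genes, or biologically correlated branches.
Passing tests therefore demonstrate that the machinery is correct and
that the pipeline recovers planted structure — not that any particular
accuracy carries over to live SFARI + GO + GOA snapshots, whose
version drift is exactly why the acceptance quantities are computed on
synthetic cohorts.

## Problem sizes

The test suite runs the full pipeline on cohorts of 30–200 genes over
ontologies of 31–241 terms, and the boosted-model checks use the
standard 500-tree configuration on the 200-gene planted cohort; the
acceptance script evaluates gradient boosting, AdaBoost and random
forest at 200 genes across purities 1.0/0.8/0.6. These sizes were
chosen so the whole suite completes in about a minute on one CPU while
still exercising every code path at the standard hyperparameters.

## Known limitations

- Only `is_a`/`part_of` semantics; no `regulates` chains, GO slims, or
  cross-namespace similarity.
- No annotation-corpus-frequency IC variants (Resnik IC is structural).
- No multiclass boosting, validation-based early stopping, or feature
  importances.
- The SFARI reader takes a column-name mapping rather than tracking
  every release dialect; negative genes are supplied as a plain list.
- Genes without surviving annotations are dropped (and counted) rather
  than imputed.
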