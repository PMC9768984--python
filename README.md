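# hecasd

Gene Ontology–based functional similarity between genes and boosted
ensemble classification of candidate disease genes.

## The problem

Complex disorders such as autism spectrum disorder have many candidate
risk genes but few confirmed ones. A standard strategy is to score how
functionally similar each candidate is to known disease genes — using
the Gene Ontology (GO) rather than noisy protein-interaction or
regulatory networks — and to train a binary classifier (disease /
non-disease) on the resulting gene–gene similarity matrix. This package
implements that pipeline end to end for researchers who have an
ontology (OBO), gene→term annotations (GAF or TSV), a SFARI-style
scored gene table for positives, and a negative gene list.

## The model

**Term similarity.** GO is a DAG of terms linked by `is_a` and
`part_of` edges. With `Pro(t)` the fraction of namespace terms at or
below `t` and `IC(t) = −ln Pro(t)`:

- *Resnik*: `sim(t₁,t₂) = IC(MICA)`, the information content of the
  most informative common ancestor (optionally divided by the
  namespace's maximum IC).
- *Relevance*: `2·IC(MICA)·(1−Pro(MICA)) / (IC(t₁)+IC(t₂))`.
- *Wang*: every term `t` in the focus term's ancestor sub-DAG gets an
  S-value `S_X(t)`, the maximal product of edge weights (0.8 `is_a`,
  0.6 `part_of`) along a rootward path from `X`; then
  `sim(X,Y) = Σ_{t∈T_X∩T_Y} (S_X(t)+S_Y(t)) / (SV(X)+SV(Y))`.
- *HGS* (hybrid gene similarity): Wang's aggregation with the fixed
  constants replaced by a child-count-driven weight
  `w = 1/(c + n_children(parent)) + d`, with `d = 0.4` (`is_a`),
  `d = 0.3` (`part_of`) and `c = 0.67` — busy parent terms pass less
  semantic value to each child, mirroring the negative relation between
  a term's child count and its IC.

**Gene similarity.** A gene pair's term-pair matrix is collapsed by
best-match-average (BMA; max is also available); doing so for all pairs
yields a symmetric gene×gene matrix whose rows double as classifier
feature vectors.

**Classification.** Two boosting learners are implemented natively:
AdaBoost-M1 over decision stumps (`α = ½ ln((1−ε)/ε)`, exponential
reweighting, zero-error early stop) and regularized gradient boosting
(depth-limited trees on log-loss gradients/hessians, L2-penalized leaf
values `−Σg/(Σh+λ)`, defaults 500 trees, learning rate 0.1, depth 3,
λ = 5). Naive Bayes, linear/RBF SVM, KNN and random-forest baselines
are wrapped from scikit-learn. Evaluation balances classes by random
undersampling and uses stratified 5-fold cross-validation (precision,
recall, F-measure, accuracy, specificity, AUC-ROC).

## Worked example

```python
from hecasd import (OntologyGraph, RelationType, WeightScheme, build_ic_table,
                    graph_term_sim, resnik_sim, SyntheticConfig, generate_synthetic,
                    ExperimentConfig, run_experiment)

edges = [("A", "R", RelationType.IS_A), ("B", "R", RelationType.IS_A),
         ("C", "A", RelationType.IS_A), ("C", "B", RelationType.PART_OF),
         ("D", "C", RelationType.IS_A)]
graph = OntologyGraph(["R", "A", "B", "C", "D"], edges)
ic = build_ic_table(graph)
print(f"IC(B)            = {ic.ic['B']:.4f}")
print(f"Resnik(C, B)     = {resnik_sim(graph, ic, 'C', 'B'):.4f}")
print(f"Wang(C, D)       = {graph_term_sim(graph, 'C', 'D', WeightScheme.wang()):.4f}")
print(f"HGS(C, D)        = {graph_term_sim(graph, 'C', 'D', WeightScheme.hgs()):.4f}")

cfg = SyntheticConfig(branch_purity=0.9, n_pos_genes=30, n_neg_genes=30, seed=7)
g, ann, labels = generate_synthetic(cfg)
result = run_experiment(g, ann, labels,
                        ExperimentConfig(measure="hgs", classifier="gbm",
                                         classifier_params={"n_trees": 100}, seed=7))
r = result.report
print(f"5-fold CV: accuracy={r.accuracy:.3f} precision={r.precision:.3f} "
      f"recall={r.recall:.3f} F={r.f_measure:.3f} AUC={r.auc_roc:.3f}")
```

Output:

```
IC(B)            = 0.5108
Resnik(C, B)     = 0.5108
Wang(C, D)       = 0.8455
HGS(C, D)        = 0.8801
5-fold CV: accuracy=0.967 precision=0.971 recall=0.967 F=0.966 AUC=0.997
```

On the five-term toy ontology, C and D share most of their ancestry, so
both graph-based measures score the pair high; HGS scores it slightly
higher because the toy graph's parents have few children, which raises
the HGS edge weights. The cross-validated metrics show the classifier
recovering the two planted annotation branches of the synthetic cohort
almost perfectly at 90 % branch purity.

A `hecasd` command-line tool mirrors the library:
`hecasd simulate`, `hecasd stats`, `hecasd termsim`,
`hecasd build-matrix`, `hecasd train`, and `hecasd run` (full
experiment from a JSON config). See `hecasd --help`.

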