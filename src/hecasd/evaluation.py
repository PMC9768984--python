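"""Class balancing, stratified cross-validation, metrics, and the runner.

The labeled gene sets are heavily imbalanced (a few dozen positives
against ~1200 negatives), so the majority class is randomly
undersampled to parity before training.  By default the undersampling
happens inside each training fold, keeping test folds untouched; a
``global`` mode undersamples once before splitting, mirroring a
pipeline in which balancing precedes cross-validation.

Point metrics (precision, recall, F-measure, accuracy, specificity)
are computed from the confusion counts; AUC-ROC uses the rank
(Mann-Whitney) formulation with ties counting one half.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from . import boosting
from .dataset import LabeledGeneSet
from .gene_similarity import AnnotationSet, GeneSimilarityMatrix, build_gene_matrix
from .ontology import OntologyGraph, OntologyError
from .term_similarity import WeightScheme

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "FoldSplit",
    "UndersampleResult",
    "ExperimentConfig",
    "ExperimentResult",
    "random_undersample",
    "stratified_kfold",
    "confusion",
    "metrics",
    "auc_roc",
    "run_experiment",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f_measure: float
    accuracy: float
    specificity: float
    auc_roc: float | None = None
    log_loss: float | None = None
    degenerate: tuple[str, ...] = ()
    per_fold: list["MetricsReport"] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        out = {
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "auc_roc": self.auc_roc,
            "log_loss": self.log_loss,
            "degenerate": list(self.degenerate),
        }
        if self.per_fold:
            out["per_fold"] = [f.to_dict() for f in self.per_fold]
        return out


@dataclass(frozen=True)
class UndersampleResult:
    """Retained sample indices plus the pre-sampling imbalance ratio."""

    indices: np.ndarray
    prec_under: float  # positives / negatives * 100, before sampling


@dataclass(frozen=True)
class FoldSplit:
    folds: tuple[np.ndarray, ...]
    k: int
    seed: int

    def iter_folds(self):
        """Yield (train_indices, test_indices) per fold."""
        all_idx = np.concatenate(self.folds)
        for i, test in enumerate(self.folds):
            train = np.setdiff1d(all_idx, test)
            yield train, test


def random_undersample(labels: Sequence[int], seed: int = 0) -> UndersampleResult:
    """Balance classes by randomly dropping majority samples.

    All minority samples are kept; a uniform random subset of the
    majority class of equal size is retained.  Already balanced input is
    returned unchanged.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise OntologyError(f"undersampling needs two classes, got {classes.tolist()}")
    n_pos = int((y == classes.max()).sum())
    n_neg = int((y == classes.min()).sum())
    prec_under = n_pos / n_neg * 100.0
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    if counts[0] == counts[1]:
        return UndersampleResult(indices=np.arange(len(y)), prec_under=prec_under)
    keep_min = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    rng = np.random.default_rng(seed)
    keep_maj = rng.choice(maj_idx, size=len(keep_min), replace=False)
    retained = np.sort(np.concatenate([keep_min, keep_maj]))
    return UndersampleResult(indices=retained, prec_under=prec_under)


def stratified_kfold(labels: Sequence[int], k: int = 5, seed: int = 0) -> FoldSplit:
    """Shuffle within class, deal round-robin into ``k`` folds.

    Per-fold class counts differ from exact proportionality by at most
    one sample per class.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise OntologyError(
                f"class {cls!r} has {len(idx)} samples, fewer than k={k}"
            )
        idx = rng.permutation(idx)
        for i, sample in enumerate(idx):
            folds[i % k].append(int(sample))
    return FoldSplit(
        folds=tuple(np.sort(np.array(f, dtype=int)) for f in folds), k=k, seed=seed
    )


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise OntologyError(f"length mismatch: {yt.shape} vs {yp.shape}")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def _safe_ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Point metrics from confusion counts; degenerate ratios become 0."""
    flags: list[str] = []
    precision = _safe_ratio(c.tp, c.tp + c.fp, "precision", flags)
    recall = _safe_ratio(c.tp, c.tp + c.fn, "recall", flags)
    f_measure = _safe_ratio(2 * precision * recall, precision + recall, "f_measure", flags)
    accuracy = _safe_ratio(c.tp + c.tn, c.total, "accuracy", flags)
    specificity = _safe_ratio(c.tn, c.tn + c.fp, "specificity", flags)
    return MetricsReport(
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        accuracy=accuracy,
        specificity=specificity,
        degenerate=tuple(flags),
    )


def auc_roc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute one half."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise OntologyError("AUC needs both classes present")
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))


# ---------------------------------------------------------------------------
# experiment runner


@dataclass
class ExperimentConfig:
    """Everything one end-to-end run needs, with one top-level seed."""

    measure: str = "hgs"
    combine: str = "bma"
    classifier: str = "gbm"
    classifier_params: dict[str, Any] = field(default_factory=dict)
    k: int = 5
    seed: int = 0
    undersample_mode: str = "per_fold"  # or "global"
    zero_diagonal: bool = False
    scheme: WeightScheme | None = None

    def __post_init__(self) -> None:
        if self.undersample_mode not in ("per_fold", "global"):
            raise OntologyError(
                f"undersample_mode must be per_fold or global, got {self.undersample_mode!r}"
            )


@dataclass
class ExperimentResult:
    report: MetricsReport
    matrix: GeneSimilarityMatrix
    labels: np.ndarray
    genes: tuple[str, ...]
    dropped_genes: tuple[str, ...]
    prec_under: float | None
    config: ExperimentConfig
    fold_seed: int

    def metrics_json(self) -> str:
        payload = {
            "measure": self.config.measure,
            "combine": self.config.combine,
            "classifier": self.config.classifier,
            "k": self.config.k,
            "seed": self.config.seed,
            "undersample_mode": self.config.undersample_mode,
            "n_genes": len(self.genes),
            "n_dropped": len(self.dropped_genes),
            "prec_under": self.prec_under,
            "metrics": self.report.to_dict(),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _make_classifier(name: str, params: dict[str, Any], seed: int):
    name = name.lower()
    if name == "adaboost":
        return boosting.AdaBoostM1(**params)
    if name == "gbm":
        return boosting.RegularizedGradientBoosting(**params)
    return boosting.make_baseline(name, seed=seed, **params)


def _mean_report(per_fold: list[MetricsReport]) -> MetricsReport:
    def mean(attr: str) -> float:
        values = [getattr(f, attr) for f in per_fold]
        values = [v for v in values if v is not None]
        return float(np.mean(values)) if values else 0.0

    degenerate = tuple(sorted({flag for f in per_fold for flag in f.degenerate}))
    return MetricsReport(
        precision=mean("precision"),
        recall=mean("recall"),
        f_measure=mean("f_measure"),
        accuracy=mean("accuracy"),
        specificity=mean("specificity"),
        auc_roc=mean("auc_roc"),
        log_loss=mean("log_loss"),
        degenerate=degenerate,
        per_fold=per_fold,
    )


def run_experiment(
    graph: OntologyGraph,
    annotations: AnnotationSet,
    labeled: LabeledGeneSet,
    config: ExperimentConfig | None = None,
    *,
    matrix: GeneSimilarityMatrix | None = None,
    out_dir: str | None = None,
) -> ExperimentResult:
    """Gene matrix -> undersampling -> stratified k-fold CV -> metrics.

    All randomness (undersampling, fold shuffling, any stochastic
    classifier) derives from ``config.seed``.  When ``out_dir`` is
    given, the similarity matrix (TSV), the metrics (JSON) and a plain
    run log are written there.
    """
    config = config or ExperimentConfig()
    annotated = [g for g in labeled.genes if g in annotations]
    dropped = tuple(g for g in labeled.genes if g not in annotations)
    if dropped:
        logger.info("%d labeled genes lack annotations and are dropped", len(dropped))
    working = labeled.restrict(annotated)
    if matrix is None:
        matrix = build_gene_matrix(
            working.genes,
            annotations,
            graph,
            measure=config.measure,
            scheme=config.scheme,
            combine=config.combine,
        )
    X = matrix.feature_matrix(zero_diagonal=config.zero_diagonal)
    y = working.labels
    genes = np.array(working.genes)

    rng = np.random.default_rng(config.seed)
    under_seed = int(rng.integers(2**31 - 1))
    fold_seed = int(rng.integers(2**31 - 1))
    clf_seed = int(rng.integers(2**31 - 1))

    prec_under: float | None = None
    if config.undersample_mode == "global":
        under = random_undersample(y, seed=under_seed)
        prec_under = under.prec_under
        X, y, genes = X[under.indices], y[under.indices], genes[under.indices]

    split = stratified_kfold(y, k=config.k, seed=fold_seed)
    per_fold: list[MetricsReport] = []
    started = time.time()
    for fold_no, (train, test) in enumerate(split.iter_folds()):
        if config.undersample_mode == "per_fold":
            under = random_undersample(y[train], seed=under_seed + fold_no)
            if prec_under is None:
                prec_under = under.prec_under
            train = train[under.indices]
        model = _make_classifier(config.classifier, config.classifier_params, clf_seed)
        model.fit(X[train], y[train])
        labels_pred, scores = boosting.predict(model, X[test])
        report = metrics(confusion(y[test], labels_pred))
        if np.unique(y[test]).size == 2:
            report.auc_roc = auc_roc(y[test], scores)
        if scores.min() >= 0.0 and scores.max() <= 1.0:
            report.log_loss = boosting.log_loss(y[test], np.clip(scores, 1e-15, 1 - 1e-15))
        per_fold.append(report)
    elapsed = time.time() - started

    result = ExperimentResult(
        report=_mean_report(per_fold),
        matrix=matrix,
        labels=y,
        genes=tuple(genes),
        dropped_genes=dropped,
        prec_under=prec_under,
        config=config,
        fold_seed=fold_seed,
    )
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        matrix.to_tsv(os.path.join(out_dir, "gene_matrix.tsv"))
        with open(os.path.join(out_dir, "metrics.json"), "wt", encoding="utf-8") as fh:
            fh.write(result.metrics_json())
        with open(os.path.join(out_dir, "run.log"), "wt", encoding="utf-8") as fh:
            fh.write(
                "\n".join(
                    [
                        f"seed={config.seed}",
                        f"undersample_seed={under_seed}",
                        f"fold_seed={fold_seed}",
                        f"classifier_seed={clf_seed}",
                        f"measure={config.measure}",
                        f"combine={config.combine}",
                        f"classifier={config.classifier}",
                        f"classifier_params={json.dumps(config.classifier_params, sort_keys=True)}",
                        f"undersample_mode={config.undersample_mode}",
                        f"n_genes={len(result.genes)}",
                        f"n_dropped={len(dropped)}",
                        f"cv_seconds={elapsed:.2f}",
                    ]
                )
                + "\n"
            )
    return result
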