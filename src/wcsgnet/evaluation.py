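"""Cross-validation protocol and performance metrics.

The 5-fold protocol is leak-free by construction: the split happens before
any network is built, highly variable genes are selected on the training
fold only, training networks use the training pool only, each test cell is
inserted into the pool individually for its own network, and up-sampling
touches training folds only — metrics are always computed on unduplicated
test cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifier import WCSGNetClassifier
from .datasets import ExpressionDataset
from .preprocess import cpm_normalize, log_transform, select_hvgs, EPS_FEATURES
from .wcsn import CellNetwork


@dataclass
class FoldSplit:
    fold_id: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int


@dataclass
class MetricReport:
    accuracy: float
    mean_f1: float
    per_class_f1: dict
    rare_type_mean_f1: float  # nan when no rare type exists
    confusion: np.ndarray
    classes: list


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Deterministic stratified k-fold; per-class fold sizes differ by <= 1."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} cells, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        FoldSplit(fold_id=i, train_indices=tr, test_indices=te, seed=seed)
        for i, (tr, te) in enumerate(skf.split(np.zeros(labels.size), labels))
    ]


def confusion_matrix(true_labels, predicted_labels, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    C = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        C[idx[t], idx[p]] += 1
    return C


def accuracy(true_labels, predicted_labels) -> float:
    """Fraction of predictions equal to the truth."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.size == 0:
        raise ValueError("accuracy of an empty prediction set is undefined")
    if t.size != p.size:
        raise ValueError("label vectors differ in length")
    return float((t == p).mean())


def mean_f1(true_labels, predicted_labels, class_list=None):
    """Macro F1: unweighted mean of per-class F1 over the given classes.

    Per class k, precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their
    harmonic mean with the 0/0 convention F1 = 0.  Returns (macro mean,
    per-class dict).
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if class_list is None:
        class_list = sorted(set(t.tolist()))
    class_list = list(class_list)
    if not class_list:
        raise ValueError("class_list must be non-empty")
    per_class = {}
    for c in class_list:
        tp = int(np.sum((t == c) & (p == c)))
        fp = int(np.sum((t != c) & (p == c)))
        fn = int(np.sum((t == c) & (p != c)))
        if tp == 0:
            per_class[c] = 0.0
        else:
            prec = tp / (tp + fp)
            rec = tp / (tp + fn)
            per_class[c] = 2 * prec * rec / (prec + rec)
    return float(np.mean([per_class[c] for c in class_list])), per_class


def rare_type_mean_f1(
    true_labels,
    predicted_labels,
    fraction_threshold: float = 0.03,
    dataset_labels=None,
) -> float:
    """Macro F1 over rare classes (< threshold share of the full dataset).

    ``dataset_labels`` gives the population the shares are measured on
    (default: the truth vector itself).  Returns nan when no class is rare.
    """
    if not 0 < fraction_threshold < 1:
        raise ValueError("fraction_threshold must lie in (0, 1)")
    t = np.asarray(true_labels)
    pop = t if dataset_labels is None else np.asarray(dataset_labels)
    classes, counts = np.unique(pop, return_counts=True)
    rare = [c for c, n in zip(classes, counts) if n / pop.size < fraction_threshold]
    rare = [c for c in rare if c in set(t.tolist())]
    if not rare:
        return float("nan")
    m, _ = mean_f1(t, predicted_labels, class_list=rare)
    return m


def sparsity(counts) -> float:
    """Proportion of zero entries in the count matrix."""
    X = np.asarray(counts)
    if X.size == 0:
        raise ValueError("sparsity of an empty matrix is undefined")
    return float((X == 0).mean())


def _report(true_labels, predicted_labels, dataset_labels, rare_threshold=0.03):
    classes = sorted(set(np.asarray(true_labels).tolist()))
    acc = accuracy(true_labels, predicted_labels)
    mf1, per_class = mean_f1(true_labels, predicted_labels, classes)
    rare = rare_type_mean_f1(
        true_labels, predicted_labels, rare_threshold, dataset_labels
    )
    return MetricReport(
        accuracy=acc,
        mean_f1=mf1,
        per_class_f1=per_class,
        rare_type_mean_f1=rare,
        confusion=confusion_matrix(true_labels, predicted_labels, classes),
        classes=classes,
    )


@dataclass
class CrossvalResult:
    fold_reports: list[MetricReport]
    pooled: MetricReport
    splits: list[FoldSplit]
    predictions: np.ndarray  # pooled, aligned with dataset order
    hvg_ids_per_fold: list[list[str]]
    test_networks_per_fold: list[list[CellNetwork]] = field(default_factory=list)


def run_crossval(
    ds: ExpressionDataset,
    k: int = 5,
    seed: int = 0,
    n_hvgs: int = 2000,
    rare_threshold: float = 0.03,
    collect_networks: bool = False,
    clf_params: dict | None = None,
    splits: list[FoldSplit] | None = None,
) -> CrossvalResult:
    """Full stratified k-fold protocol on a preprocessed dataset.

    Per fold: HVG selection on training cells only -> training networks from
    the training pool -> up-sampled training -> model fit -> per-test-cell
    leak-free network -> prediction; metrics on unduplicated test cells.
    An externally defined partition (e.g. a published fixed split) can be
    injected via ``splits``; it must cover every cell exactly once.
    """
    labels = ds.labels
    if splits is None:
        splits = stratified_kfold(labels, k=k, seed=seed)
    else:
        covered = np.concatenate([s.test_indices for s in splits])
        if sorted(covered.tolist()) != list(range(ds.n)):
            raise ValueError("injected splits must partition all cells")
    E = cpm_normalize(ds)
    col = {g: j for j, g in enumerate(ds.gene_ids)}

    predictions = np.empty(ds.n, dtype=object)
    fold_reports = []
    hvg_lists = []
    networks_per_fold = []
    for split in splits:
        tr, te = split.train_indices, split.test_indices
        E_prime_train = log_transform(E[tr], EPS_FEATURES)
        hvgs = select_hvgs(E_prime_train, ds.gene_ids, p=n_hvgs)
        hvg_lists.append(hvgs)
        idx = np.array([col[g] for g in hvgs])

        clf = WCSGNetClassifier(random_state=seed + split.fold_id, **(clf_params or {}))
        clf.fit(E[np.ix_(tr, idx)], labels[tr])
        pred = clf.predict(E[np.ix_(te, idx)])
        predictions[te] = pred
        fold_reports.append(_report(labels[te], pred, labels, rare_threshold))
        if collect_networks:
            networks_per_fold.append(clf._test_networks(E[np.ix_(te, idx)]))

    pooled = _report(labels, predictions, labels, rare_threshold)
    return CrossvalResult(
        fold_reports=fold_reports,
        pooled=pooled,
        splits=splits,
        predictions=predictions,
        hvg_ids_per_fold=hvg_lists,
        test_networks_per_fold=networks_per_fold,
    )
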