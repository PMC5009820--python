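"""Cluster-label prediction with leakage-free cross-validation.

Patients are labeled with their discovered cluster and a classifier is
evaluated by stratified 10-fold cross-validation. Inside every fold,
genes are ranked on the training patients only by information gain under
supervised entropy-minimization (MDL) discretization, the top genes are
kept, and the classifier is fit and scored on the held-out fold. Pooled
confusion-matrix metrics, one-vs-rest ROC/AUC, and a label-shuffling
permutation null for the accuracy are reported.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

ClassifierFactory = Callable[[int], "object"]


@dataclass
class LabeledDataset:
    """Patients x genes feature matrix with one cluster label per patient."""

    X: pd.DataFrame  # rows patients, columns genes
    y: pd.Series  # patient -> cluster id

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            self.y = self.y.reindex(self.X.index)
        if self.y.isna().any():
            raise ValueError("every patient needs a label")
        if self.y.nunique() < 2:
            raise ValueError("at least 2 classes are required")

    @property
    def classes(self) -> list:
        return sorted(self.y.unique())


# ---------------------------------------------------------------------------
# Information gain with Fayyad-Irani MDL discretization
# ---------------------------------------------------------------------------


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _mdl_cuts(sorted_labels: np.ndarray, cum: np.ndarray, lo: int, hi: int, boundaries: np.ndarray, cuts: list[int]) -> None:
    """Recursive entropy-minimization splitting with the MDL stopping rule.

    ``cum`` holds cumulative class counts over the feature-sorted sample
    order; ``boundaries`` are candidate cut indices (positions where the
    sorted feature value changes). Accepted cut indices are appended to
    ``cuts``.
    """
    n = hi - lo
    cand = boundaries[(boundaries > lo) & (boundaries < hi)]
    if n < 2 or cand.size == 0:
        return
    total = cum[hi] - cum[lo]
    h_s = _entropy_from_counts(total)
    if h_s == 0.0:
        return

    left = cum[cand] - cum[lo]  # (n_cand, n_classes)
    right = total - left
    n_left = left.sum(axis=1)
    n_right = right.sum(axis=1)

    def _ent_rows(c: np.ndarray, tot: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = c / tot[:, None]
            term = np.where(c > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return term.sum(axis=1)

    h_left = _ent_rows(left, n_left)
    h_right = _ent_rows(right, n_right)
    weighted = (n_left * h_left + n_right * h_right) / n
    best = int(np.argmin(weighted))
    gain = h_s - weighted[best]

    c_all = int((total > 0).sum())
    c_left = int((left[best] > 0).sum())
    c_right = int((right[best] > 0).sum())
    delta = math.log2(3**c_all - 2) - (c_all * h_s - c_left * h_left[best] - c_right * h_right[best])
    threshold = (math.log2(n - 1) + delta) / n
    if gain <= threshold:
        return
    cut = int(cand[best])
    cuts.append(cut)
    _mdl_cuts(sorted_labels, cum, lo, cut, boundaries, cuts)
    _mdl_cuts(sorted_labels, cum, cut, hi, boundaries, cuts)


def information_gain(feature: Sequence[float], labels: Sequence) -> float:
    """Information gain (bits) of a numeric feature about class labels.

    The feature is discretized by recursive supervised entropy
    minimization with the Fayyad-Irani MDL stopping criterion; features
    the rule leaves unsplit carry zero gain. IG = H(labels) - sum over
    bins of (|bin|/n) H(labels | bin).
    """
    values = np.asarray(feature, dtype=float)
    y, classes = pd.factorize(np.asarray(labels))
    if classes.size < 2:
        raise ValueError("labels must contain at least 2 classes")
    if values.shape[0] != y.shape[0]:
        raise ValueError("feature and labels differ in length")

    order = np.argsort(values, kind="mergesort")
    v_sorted = values[order]
    y_sorted = y[order]
    n = values.shape[0]
    one_hot = np.zeros((n, classes.size))
    one_hot[np.arange(n), y_sorted] = 1.0
    cum = np.vstack([np.zeros(classes.size), np.cumsum(one_hot, axis=0)])
    boundaries = np.flatnonzero(np.diff(v_sorted) != 0) + 1

    cuts: list[int] = []
    _mdl_cuts(y_sorted, cum, 0, n, boundaries, cuts)
    if not cuts:
        return 0.0
    edges = [0] + sorted(cuts) + [n]
    h_total = _entropy_from_counts(cum[n] - cum[0])
    h_cond = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        counts = cum[b] - cum[a]
        h_cond += (b - a) / n * _entropy_from_counts(counts)
    return max(0.0, h_total - h_cond)


def select_by_information_gain(X: pd.DataFrame, y: pd.Series, k_top: int) -> list[str]:
    """Top ``k_top`` genes by information gain, computed on these rows only.

    Called per fold on the training split so feature selection never sees
    the held-out patients. Ties (including the common all-zero-gain
    case) break lexicographically by gene symbol.
    """
    if k_top > X.shape[1]:
        raise ValueError(f"k_top={k_top} exceeds {X.shape[1]} genes")
    labels = y.loc[X.index].to_numpy()
    gains = np.array([information_gain(X[g].to_numpy(), labels) for g in X.columns])
    ranking = (
        pd.DataFrame({"gene": X.columns, "gain": gains})
        .sort_values(["gain", "gene"], ascending=[False, True], kind="mergesort")
    )
    return ranking["gene"].head(k_top).tolist()


# ---------------------------------------------------------------------------
# Cross-validation, metrics, permutation null
# ---------------------------------------------------------------------------


def default_classifier_factory(n_estimators: int = 100) -> ClassifierFactory:
    """Random-forest factory meeting the fit/predict_proba contract."""

    def factory(seed: int):
        return RandomForestClassifier(n_estimators=n_estimators, random_state=seed)

    return factory


@dataclass
class PerformanceReport:
    """Pooled multiclass evaluation of a cross-validated classifier."""

    confusion: pd.DataFrame  # rows true class, columns predicted
    accuracy: float
    per_class: pd.DataFrame  # tpr, fpr, tnr, fnr, precision, f1, auc per class
    macro: dict[str, float]
    roc_curves: dict  # class -> (fpr array, tpr array)
    fold_accuracies: list[float]
    fold_sizes: list[int]
    fold_genes: list[list[str]]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion.to_dict(),
            "per_class": self.per_class.to_dict(orient="index"),
            "macro": self.macro,
            "fold_accuracies": self.fold_accuracies,
            "fold_sizes": self.fold_sizes,
        }


def _metrics_from_confusion(confusion: pd.DataFrame) -> pd.DataFrame:
    """One-vs-rest TPR/FPR/TNR/FNR/precision/F1 per class from a pooled
    confusion matrix (rows = true class, columns = predicted class)."""
    cm = confusion.to_numpy(dtype=float)
    total = cm.sum()
    rows = {}
    for idx, cls in enumerate(confusion.index):
        tp = cm[idx, idx]
        fn = cm[idx].sum() - tp
        fp = cm[:, idx].sum() - tp
        tn = total - tp - fn - fp
        tpr = tp / (tp + fn) if tp + fn else 0.0
        fpr = fp / (fp + tn) if fp + tn else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * precision * tpr / (precision + tpr) if precision + tpr else 0.0
        rows[cls] = {
            "tpr": tpr,
            "fpr": fpr,
            "tnr": 1.0 - fpr,
            "fnr": 1.0 - tpr,
            "precision": precision,
            "f1": f1,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def cross_validate(
    dataset: LabeledDataset,
    classifier_factory: ClassifierFactory | None = None,
    folds: int = 10,
    k_top: int = 500,
    seed: int = 0,
) -> PerformanceReport:
    """Stratified k-fold cross-validation with per-fold feature selection.

    Each fold selects its own top genes by information gain on the
    training patients, fits a fresh classifier, and predicts the held-out
    patients. The confusion matrix is pooled over folds; per-class
    metrics and one-vs-rest ROC/AUC come from the pooled predictions and
    class scores. When a class has fewer members than ``folds`` the fold
    count is reduced (best effort) with a warning.
    """
    if classifier_factory is None:
        classifier_factory = default_classifier_factory()
    X, y = dataset.X, dataset.y
    classes = dataset.classes
    k_top = min(k_top, X.shape[1])

    min_class = int(y.value_counts().min())
    folds_eff = folds
    if min_class < folds:
        folds_eff = max(2, min_class)
        warnings.warn(
            f"smallest class has {min_class} members; reducing folds {folds} -> {folds_eff}",
            stacklevel=2,
        )
    if len(y) < folds_eff:
        raise ValueError("fewer patients than folds")

    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed % (2**32))
    y_true_all: list = []
    y_pred_all: list = []
    scores_all: list[np.ndarray] = []
    fold_accuracies: list[float] = []
    fold_sizes: list[int] = []
    fold_genes: list[list[str]] = []

    ss = np.random.SeedSequence([seed, 0xC5])
    fold_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(folds_eff)]

    for fold_id, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        X_train, y_train = X.iloc[train_idx], y.iloc[train_idx]
        X_test, y_test = X.iloc[test_idx], y.iloc[test_idx]
        genes = select_by_information_gain(X_train, y_train, k_top)
        fold_genes.append(genes)
        clf = classifier_factory(fold_seeds[fold_id])
        try:
            clf.fit(X_train[genes].to_numpy(), y_train.to_numpy())
        except Exception as exc:  # surface which fold broke
            raise RuntimeError(f"classifier failed to fit in fold {fold_id}: {exc}") from exc
        pred = clf.predict(X_test[genes].to_numpy())
        proba = clf.predict_proba(X_test[genes].to_numpy())
        # align score columns to the global class order
        aligned = np.zeros((len(test_idx), len(classes)))
        for j, cls in enumerate(clf.classes_):
            aligned[:, classes.index(cls)] = proba[:, j]
        y_true_all.extend(y_test.tolist())
        y_pred_all.extend(list(pred))
        scores_all.append(aligned)
        fold_accuracies.append(float(np.mean(pred == y_test.to_numpy())))
        fold_sizes.append(len(test_idx))

    scores = np.vstack(scores_all)
    cm = sk_confusion(y_true_all, y_pred_all, labels=classes)
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    accuracy = float(np.trace(cm) / cm.sum())
    per_class = _metrics_from_confusion(confusion)

    roc_curves: dict = {}
    aucs = {}
    y_true_arr = np.asarray(y_true_all)
    for j, cls in enumerate(classes):
        binary = (y_true_arr == cls).astype(int)
        if binary.min() == binary.max():  # class absent or exhaustive in pooled test
            roc_curves[cls] = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
            aucs[cls] = float("nan")
            continue
        fpr, tpr, _ = roc_curve(binary, scores[:, j])
        roc_curves[cls] = (fpr, tpr)
        aucs[cls] = float(sk_auc(fpr, tpr))
    per_class["auc"] = pd.Series(aucs)

    macro = {c: float(per_class[c].mean()) for c in ("tpr", "fpr", "tnr", "fnr", "precision", "f1")}
    macro["auc"] = float(np.nanmean(per_class["auc"]))
    macro["accuracy"] = accuracy

    return PerformanceReport(
        confusion=confusion,
        accuracy=accuracy,
        per_class=per_class,
        macro=macro,
        roc_curves=roc_curves,
        fold_accuracies=fold_accuracies,
        fold_sizes=fold_sizes,
        fold_genes=fold_genes,
    )


@dataclass
class PermutationResult:
    """Label-shuffling null for the cross-validated accuracy."""

    observed_accuracy: float
    permutation_accuracies: list[float]
    count_better: int
    n_permutations: int
    seed: int
    p_value: float = field(init=False)

    def __post_init__(self) -> None:
        self.p_value = self.count_better / self.n_permutations

    @property
    def p_label(self) -> str:
        """The reported p-value: an upper bound when no permutation wins."""
        if self.count_better == 0:
            return f"< {1.0 / self.n_permutations:g}"
        return f"{self.p_value:g}"


def permutation_test(
    dataset: LabeledDataset,
    classifier_factory: ClassifierFactory | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
    folds: int = 10,
    k_top: int = 500,
) -> PermutationResult:
    """Empirical accuracy null built by shuffling patient labels.

    Each of ``n_permutations`` shuffles permutes the labels uniformly at
    random (class sizes fixed by construction) and reruns the FULL
    cross-validation, including per-fold information-gain selection. The
    p-value is the fraction of permutations with strictly greater
    accuracy than observed; a zero count is reported as the bound
    ``< 1/N``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = cross_validate(dataset, classifier_factory, folds=folds, k_top=k_top, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E3]))
    perm_acc: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fold-reduction warnings repeat identically per shuffle
        for p in range(n_permutations):
            y_perm = pd.Series(rng.permutation(dataset.y.to_numpy()), index=dataset.y.index)
            shuffled = LabeledDataset(X=dataset.X, y=y_perm)
            report = cross_validate(
                shuffled, classifier_factory, folds=folds, k_top=k_top,
                seed=int(rng.integers(2**31)),
            )
            perm_acc.append(report.accuracy)
    count_better = int(sum(a > observed.accuracy for a in perm_acc))
    return PermutationResult(
        observed_accuracy=observed.accuracy,
        permutation_accuracies=perm_acc,
        count_better=count_better,
        n_permutations=n_permutations,
        seed=seed,
    )
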