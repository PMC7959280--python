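"""Imbalance-aware gesture classification and its statistical evaluation.

The protocol: stratified 10-fold cross-validation where, strictly inside
each training fold, minority classes are oversampled to the majority count
with SMOTE (synthetic samples interpolated toward k=5 same-class nearest
neighbors) and features are ranked by ANOVA F-score, the top n are kept,
and one of four classifiers is fitted — k-nearest neighbors (5, uniform
weights) or a 350-tree Gini ensemble (bagged trees, random forest, or
extra trees). Test folds never touch the oversampler or the F statistics.
Reported metrics are overall accuracy, macro (and weighted) precision and
sensitivity, and a row-normalized confusion matrix; classifier pairs are
compared with a paired t-test over per-fold accuracies with Bonferroni
correction.

SMOTE is implemented here (convex combinations x + u (x_nn - x), u ~
U(0,1)) with a seeded generator, so the whole protocol is deterministic
given the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (BaggingClassifier, ExtraTreesClassifier,
                              RandomForestClassifier)
from sklearn.feature_selection import f_classif
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

from .netfeatures import META_COLUMNS, feature_names

CLASSIFIER_NAMES = ("KNN", "BAG", "RF", "ET")


@dataclass
class ClassifierSpec:
    """One of the four study classifiers with its fixed hyperparameters."""

    name: str
    n_neighbors: int = 5
    n_trees: int = 350
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}")
        if self.n_trees < 1:
            raise ValueError("tree count must be >= 1")

    def make(self):
        tree_kw = dict(criterion="gini", min_samples_split=2, min_samples_leaf=1)
        if self.name == "KNN":
            return KNeighborsClassifier(n_neighbors=self.n_neighbors,
                                        weights="uniform")
        if self.name == "BAG":
            # bootstrap replicas of unpruned trees, all features per split
            return BaggingClassifier(
                estimator=DecisionTreeClassifier(**tree_kw),
                n_estimators=self.n_trees, random_state=self.seed)
        if self.name == "RF":
            return RandomForestClassifier(n_estimators=self.n_trees,
                                          random_state=self.seed, **tree_kw)
        # ET: whole sample (no bootstrap), random split points
        return ExtraTreesClassifier(n_estimators=self.n_trees, bootstrap=False,
                                    random_state=self.seed, **tree_kw)


@dataclass
class CVReport:
    classifier: str
    n_selected: int
    fold_accuracies: list[float]
    accuracy: float
    precision_macro: float
    sensitivity_macro: float
    precision_weighted: float
    sensitivity_weighted: float
    confusion: pd.DataFrame          # row-normalized, true x predicted
    selected_features: list[list[str]]
    labels: list[str]
    seed: int

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "n_selected": self.n_selected,
            "fold_accuracies": self.fold_accuracies,
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "sensitivity_macro": self.sensitivity_macro,
            "precision_weighted": self.precision_weighted,
            "sensitivity_weighted": self.sensitivity_weighted,
            "confusion": self.confusion.to_dict(),
            "selected_features": self.selected_features,
            "labels": self.labels,
            "seed": self.seed,
        }


@dataclass
class ComparisonResult:
    comparison: str
    improvement: float               # mean paired accuracy difference, % points
    ci_low: float
    ci_high: float
    p_value: float
    p_adjusted: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# SMOTE

def smote_oversample(x: np.ndarray, y: np.ndarray, k: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Balance all classes to the majority count by SMOTE interpolation.

    Synthetic rows are x + u (x_nn - x) with u ~ U(0, 1) and x_nn one of
    the k nearest same-class neighbors; original rows are kept unchanged.
    k is reduced (with a warning) for classes of size <= k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("SMOTE needs >= 2 samples per class")
    target = counts.max()
    rng = np.random.default_rng(seed)
    xs, ys = [x], [y]
    for cls, cnt in zip(classes, counts):
        need = target - cnt
        if need == 0:
            continue
        xc = x[y == cls]
        k_eff = min(k, cnt - 1)
        if k_eff < k:
            import warnings
            warnings.warn(f"class {cls!r} has {cnt} samples; "
                          f"SMOTE neighbors reduced to {k_eff}")
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(xc)
        _, nbrs = nn.kneighbors(xc)          # column 0 is the point itself
        base = rng.integers(0, cnt, size=need)
        pick = rng.integers(1, k_eff + 1, size=need)
        u = rng.uniform(0, 1, size=need)
        x_new = xc[base] + u[:, None] * (xc[nbrs[base, pick]] - xc[base])
        xs.append(x_new)
        ys.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(xs), np.concatenate(ys)


# ---------------------------------------------------------------------------
# Feature scoring

def anova_f_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature one-way ANOVA F values (between- over within-class MS).

    Zero within-class variance with a between-class effect gives F = +inf
    (ranks first); a feature constant everywhere scores 0.
    """
    import warnings

    x = np.asarray(x, dtype=float)
    with warnings.catch_warnings():
        # constant features divide 0/0 inside f_classif; scored 0 below
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.filterwarnings("ignore", message=".*constant.*",
                                category=UserWarning)
        f, _ = f_classif(x, y)
    f = np.asarray(f, dtype=float)
    const = np.ptp(x, axis=0) == 0
    f[const] = 0.0
    f[np.isnan(f)] = 0.0
    return f


def select_top_k(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k highest-F features (stable order for ties)."""
    scores = anova_f_scores(x, y)
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# Cross-validation

def _split_xy(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = [c for c in feature_names() if c in features.columns]
    if not cols:
        cols = [c for c in features.columns if c not in META_COLUMNS]
    return features[cols].to_numpy(dtype=float), \
        features["label"].to_numpy(), cols


def cross_validate(features: pd.DataFrame, spec: ClassifierSpec,
                   n_selected: int | None = None, seed: int = 0,
                   n_folds: int = 10, smote_k: int = 5,
                   group_by_subject: bool = False) -> CVReport:
    """Stratified k-fold evaluation with in-fold SMOTE and F-selection.

    Everything fitted — the oversampler, the F statistics, the classifier —
    sees only the training fold; the test fold is evaluated untouched.
    ``group_by_subject`` switches to subject-grouped folds (no subject in
    both train and test), trading stratification for leakage control.
    """
    x, y, cols = _split_xy(features)
    n_selected = len(cols) if n_selected is None else int(n_selected)
    if not 1 <= n_selected <= len(cols):
        raise ValueError(f"n_selected must be in [1, {len(cols)}]")
    labels = sorted(np.unique(y).tolist())
    lab_idx = {l: i for i, l in enumerate(labels)}
    if group_by_subject:
        groups = features["subject"].to_numpy()
        n_folds = min(n_folds, len(np.unique(groups)))
        splits = GroupKFold(n_splits=n_folds).split(x, y, groups)
    else:
        splits = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                 random_state=seed).split(x, y)
    fold_acc: list[float] = []
    selected_names: list[list[str]] = []
    conf = np.zeros((len(labels), len(labels)))
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    for fold, (tr, te) in enumerate(splits):
        x_tr, y_tr = smote_oversample(x[tr], y[tr], k=smote_k,
                                      seed=seed * 1009 + fold)
        keep = select_top_k(x_tr, y_tr, n_selected)
        selected_names.append([cols[i] for i in keep])
        clf_spec = ClassifierSpec(name=spec.name, n_neighbors=spec.n_neighbors,
                                  n_trees=spec.n_trees,
                                  seed=seed * 1013 + fold)
        clf = clf_spec.make()
        clf.fit(x_tr[:, keep], y_tr)
        pred = clf.predict(x[te][:, keep])
        fold_acc.append(float((pred == y[te]).mean()))
        for t, p in zip(y[te], pred):
            conf[lab_idx[t], lab_idx[p]] += 1
        y_true_all.append(y[te])
        y_pred_all.append(pred)

    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    prec_m, sens_m, prec_w, sens_w = _precision_sensitivity(
        y_true, y_pred, labels)
    row_sum = conf.sum(axis=1, keepdims=True)
    conf_norm = np.divide(conf, row_sum, out=np.zeros_like(conf),
                          where=row_sum > 0)
    return CVReport(
        classifier=spec.name, n_selected=n_selected,
        fold_accuracies=fold_acc,
        accuracy=float((y_pred == y_true).mean()),
        precision_macro=prec_m, sensitivity_macro=sens_m,
        precision_weighted=prec_w, sensitivity_weighted=sens_w,
        confusion=pd.DataFrame(conf_norm, index=labels, columns=labels),
        selected_features=selected_names, labels=labels, seed=seed)


def _precision_sensitivity(y_true: np.ndarray, y_pred: np.ndarray,
                           labels: list[str]) -> tuple[float, float, float, float]:
    """Per-class Tp/(Tp+Fp) and Tp/(Tp+Fn), macro- and support-weighted."""
    prec, sens, support = [], [], []
    for lab in labels:
        tp = np.sum((y_pred == lab) & (y_true == lab))
        fp = np.sum((y_pred == lab) & (y_true != lab))
        fn = np.sum((y_pred != lab) & (y_true == lab))
        prec.append(tp / (tp + fp) if tp + fp else 0.0)
        sens.append(tp / (tp + fn) if tp + fn else 0.0)
        support.append(np.sum(y_true == lab))
    w = np.asarray(support) / max(sum(support), 1)
    return (float(np.mean(prec)), float(np.mean(sens)),
            float(np.asarray(prec) @ w), float(np.asarray(sens) @ w))


# ---------------------------------------------------------------------------
# Statistical comparison

def compare_accuracies(acc_a: np.ndarray, acc_b: np.ndarray,
                       comparison: str = "A versus B",
                       n_comparisons: int = 6,
                       alpha: float = 0.05) -> ComparisonResult:
    """Paired t-test on matched accuracy vectors (fractions in [0, 1]).

    Improvement and its (1-alpha) confidence interval are reported in
    percentage points of A over B; the p-value is Bonferroni-adjusted for
    the configured number of comparisons.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("accuracy vectors must be paired (equal length)")
    diff = (a - b) * 100.0
    mean = float(diff.mean())
    df = len(diff) - 1
    sd = diff.std(ddof=1)
    if sd == 0:
        return ComparisonResult(comparison=comparison, improvement=mean,
                                ci_low=mean, ci_high=mean,
                                p_value=0.0 if mean != 0 else 1.0,
                                p_adjusted=0.0 if mean != 0 else 1.0,
                                degenerate=True)
    se = sd / np.sqrt(len(diff))
    t_stat, p = stats.ttest_rel(a, b)
    crit = stats.t.ppf(1 - alpha / 2, df)
    return ComparisonResult(
        comparison=comparison, improvement=mean,
        ci_low=mean - crit * se, ci_high=mean + crit * se,
        p_value=float(p), p_adjusted=min(1.0, n_comparisons * float(p)))


def compare_classifiers(report_a: CVReport, report_b: CVReport,
                        n_comparisons: int = 6) -> ComparisonResult:
    """Paired t-test between the per-fold accuracies of two CV reports."""
    return compare_accuracies(
        np.asarray(report_a.fold_accuracies),
        np.asarray(report_b.fold_accuracies),
        comparison=f"{report_a.classifier} versus {report_b.classifier}",
        n_comparisons=n_comparisons)


def tree_count_sweep(features: pd.DataFrame, name: str = "ET",
                     grid: range | list[int] = range(100, 1001, 20),
                     n_selected: int | None = None, seed: int = 0,
                     n_folds: int = 10) -> pd.DataFrame:
    """Mean CV accuracy per ensemble size (utility, not default protocol)."""
    rows = []
    for n_trees in grid:
        rep = cross_validate(features,
                             ClassifierSpec(name=name, n_trees=n_trees),
                             n_selected=n_selected, seed=seed,
                             n_folds=n_folds)
        rows.append({"n_trees": n_trees, "accuracy": rep.accuracy})
    return pd.DataFrame(rows)


def accuracy_vs_nfeatures(features: pd.DataFrame, specs: list[ClassifierSpec],
                          grid: list[int], seed: int = 0, n_folds: int = 10
                          ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Mean CV accuracy (+/- standard error) per (classifier, n_selected).

    Also returns, per classifier, the concatenated per-(fold, n_selected)
    accuracy vector used for paired classifier comparisons.
    """
    rows = []
    acc_vectors: dict[str, list[float]] = {s.name: [] for s in specs}
    for spec in specs:
        for n_sel in grid:
            rep = cross_validate(features, spec, n_selected=n_sel,
                                 seed=seed, n_folds=n_folds)
            acc = np.asarray(rep.fold_accuracies)
            rows.append({"classifier": spec.name, "n_selected": n_sel,
                         "accuracy": acc.mean(),
                         "se": acc.std(ddof=1) / np.sqrt(len(acc))})
            acc_vectors[spec.name].extend(rep.fold_accuracies)
    return pd.DataFrame(rows), {k: np.asarray(v)
                                for k, v in acc_vectors.items()}
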