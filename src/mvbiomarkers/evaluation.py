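"""Evaluation harness: repeated stratified CV, metric panel, comparisons.

Implements the experimental protocol around the biomarker pipeline:
repeated stratified 10-fold cross-validation (20 repeats by default)
with three classifier families (decision tree, RBF-kernel SVM, linear
SVM), the ACC/SEN/SPE/AUC panel with out-of-fold predictions pooled
per repeat, paired t-tests on per-repeat accuracies, grid search over
the hyperparameter ranges, the auxiliary-vs-self projection-learning
comparison, and the auxiliary-sample-size sweep.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .biomarkers import biomarkers_from_model
from .projection import HyperParams, fit_model

CLASSIFIERS = ("decision-tree", "svm-rbf", "svm-linear")


@dataclasses.dataclass
class LabeledViews:
    """Two aligned d x n feature blocks with one class label per subject."""

    X_CT: np.ndarray
    X_CV: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.X_CT = np.asarray(self.X_CT, dtype=float)
        self.X_CV = np.asarray(self.X_CV, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X_CT.shape != self.X_CV.shape:
            raise ValueError("views must share shape")
        if self.labels.shape[0] != self.X_CT.shape[1]:
            raise ValueError("one label per subject (column) required")

    @property
    def n(self) -> int:
        return self.X_CT.shape[1]

    def subset(self, idx: np.ndarray) -> "LabeledViews":
        return LabeledViews(self.X_CT[:, idx], self.X_CV[:, idx], self.labels[idx])

    def class_order(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab), None)
        return tuple(seen)


def as_labeled_views(obj) -> LabeledViews:
    """Coerce a SyntheticCohort or (X_CT, X_CV, labels) tuple."""
    if isinstance(obj, LabeledViews):
        return obj
    if hasattr(obj, "group_labels"):
        return LabeledViews(obj.X_CT, obj.X_CV, obj.group_labels)
    X_CT, X_CV, labels = obj
    return LabeledViews(X_CT, X_CV, labels)


@dataclasses.dataclass
class CVConfig:
    """Cross-validation and classifier configuration."""

    n_folds: int = 10
    n_repeats: int = 20
    base_seed: int = 0
    stratified: bool = True
    classifier: str = "svm-linear"
    classifier_params: dict = dataclasses.field(default_factory=dict)
    positive_class: str = "pMCI"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}, got {self.classifier!r}")

    def replace(self, **kw) -> "CVConfig":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class MetricSet:
    """ACC/SEN/SPE/AUC panel; an undefined metric is NaN, never silently 0."""

    acc: float
    sen: float
    spe: float
    auc: float = float("nan")


@dataclasses.dataclass
class RunResult:
    per_repeat: list[MetricSet]
    mean: MetricSet
    protocol: str
    seeds: list[int]
    fold_assignments: list[np.ndarray]
    p_value: float | None = None

    def accuracies(self) -> np.ndarray:
        return np.array([m.acc for m in self.per_repeat])


def confusion_metrics(y_true: Sequence, y_pred: Sequence, positive_class) -> MetricSet:
    """ACC, SEN (true-positive rate), SPE (true-negative rate).

    SEN is NaN when no positive samples exist, SPE when no negatives.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and nonempty")
    pos = y_true == positive_class
    pred_pos = y_pred == positive_class
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    acc = (tp + tn) / (tp + tn + fp + fn)
    sen = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spe = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return MetricSet(acc=acc, sen=sen, spe=spe)


def auc_score(y_true: Sequence, scores: Sequence, positive_class) -> float:
    """Rank (Mann-Whitney) AUC: P(random positive outscores random negative),
    ties counted one half. NaN when only one class is present."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must be equal-length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    pos = y_true == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _repeat_seed(base_seed: int, repeat_index: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(repeat_index), int(salt)])
    return int(ss.generate_state(1)[0] % (2**31))


def make_folds(labels: Sequence, cfg: CVConfig, repeat_index: int) -> np.ndarray:
    """Assign every sample to one of n_folds folds.

    Stratified mode shuffles each class and deals it round-robin with a
    random fold offset, so per-fold class counts differ by at most one;
    a class smaller than n_folds leaves some folds without it (warned).
    Deterministic in (base_seed, repeat_index).
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n < cfg.n_folds:
        raise ValueError(f"need n >= n_folds, got n={n}, n_folds={cfg.n_folds}")
    rng = np.random.default_rng(_repeat_seed(cfg.base_seed, repeat_index))
    folds = np.empty(n, dtype=int)
    if cfg.stratified:
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            if idx.size < cfg.n_folds:
                warnings.warn(
                    f"class {cls!r} has {idx.size} < {cfg.n_folds} samples; "
                    "some folds will lack it",
                    stacklevel=2,
                )
            rng.shuffle(idx)
            offset = int(rng.integers(cfg.n_folds))
            folds[idx] = (np.arange(idx.size) + offset) % cfg.n_folds
    else:
        idx = rng.permutation(n)
        for f, part in enumerate(np.array_split(idx, cfg.n_folds)):
            folds[part] = f
    return folds


def _make_classifier(name: str, seed: int, params: Mapping):
    if name == "decision-tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "svm-rbf":
        return SVC(kernel="rbf", **params)
    if name == "svm-linear":
        return SVC(kernel="linear", **params)
    raise ValueError(f"unknown classifier {name!r}")


def _decision_scores(clf, X: np.ndarray, positive_class) -> np.ndarray:
    """Score oriented so larger means more positive-class."""
    if hasattr(clf, "decision_function"):
        s = clf.decision_function(X)
        # binary decision_function is positive for classes_[1]
        return s if clf.classes_[1] == positive_class else -s
    proba = clf.predict_proba(X)
    j = int(np.flatnonzero(clf.classes_ == positive_class)[0])
    return proba[:, j]


def _cv_repeat(
    bio_fn,
    labels: np.ndarray,
    cfg: CVConfig,
    repeat_index: int,
) -> tuple[MetricSet, np.ndarray]:
    """One CV repeat; bio_fn(train_idx, test_idx) -> (B_train, B_test).

    Out-of-fold predictions and scores are pooled over folds before
    computing the metric panel.
    """
    folds = make_folds(labels, cfg, repeat_index)
    n = labels.shape[0]
    y_pred = np.empty(n, dtype=labels.dtype)
    scores = np.empty(n, dtype=float)
    clf_seed = _repeat_seed(cfg.base_seed, repeat_index, salt=7)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        if np.unique(labels[train]).size < 2:
            warnings.warn(f"degenerate fold {f}: single-class training set", stacklevel=2)
        B_train, B_test = bio_fn(np.flatnonzero(train), np.flatnonzero(test))
        clf = _make_classifier(cfg.classifier, clf_seed, cfg.classifier_params)
        clf.fit(B_train, labels[train])
        y_pred[test] = clf.predict(B_test)
        scores[test] = _decision_scores(clf, B_test, cfg.positive_class)
    m = confusion_metrics(labels, y_pred, cfg.positive_class)
    m.auc = auc_score(labels, scores, cfg.positive_class)
    return m, folds


def run_protocol(
    aux,
    target,
    hp: HyperParams,
    cfg: CVConfig,
    protocol: str = "auxiliary",
    standardize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> RunResult:
    """Full biomarker evaluation under one of two learning protocols.

    protocol="auxiliary"
        Projections (and standardization) are learned once on the full
        auxiliary set; biomarkers are computed for every target
        subject, and cross-validation trains/tests only the classifier.
    protocol="self"
        Within each repeat and fold, projections are learned on the
        target training folds only; train- and test-fold biomarkers
        come from that fold's model, so no test-fold information enters
        model fitting.
    """
    target = as_labeled_views(target)
    if np.unique(target.labels).size < 2:
        raise ValueError("target set must contain both classes")
    if protocol == "auxiliary":
        aux = as_labeled_views(aux)
        if aux.n == 0:
            raise ValueError("auxiliary set must be nonempty under protocol='auxiliary'")
        model = fit_model(
            aux.X_CT, aux.X_CV, aux.labels, aux.class_order(), hp,
            standardize=standardize, tol=tol, max_iter=max_iter,
        )
        bio = biomarkers_from_model(model, target.X_CT, target.X_CV)

        def bio_fn(train_idx, test_idx):
            return bio[train_idx], bio[test_idx]

    elif protocol == "self":
        def bio_fn(train_idx, test_idx, _target=target):
            fold_model = fit_self_model(
                _target, train_idx, hp, standardize=standardize, tol=tol, max_iter=max_iter
            )
            B_train = biomarkers_from_model(
                fold_model, _target.X_CT[:, train_idx], _target.X_CV[:, train_idx]
            )
            B_test = biomarkers_from_model(
                fold_model, _target.X_CT[:, test_idx], _target.X_CV[:, test_idx]
            )
            return B_train, B_test

    else:
        raise ValueError(f"protocol must be 'auxiliary' or 'self', got {protocol!r}")

    per_repeat: list[MetricSet] = []
    assignments: list[np.ndarray] = []
    seeds = [_repeat_seed(cfg.base_seed, r) for r in range(cfg.n_repeats)]
    for r in range(cfg.n_repeats):
        m, folds = _cv_repeat(bio_fn, target.labels, cfg, r)
        per_repeat.append(m)
        assignments.append(folds)
    mean = MetricSet(
        acc=float(np.mean([m.acc for m in per_repeat])),
        sen=float(np.mean([m.sen for m in per_repeat])),
        spe=float(np.mean([m.spe for m in per_repeat])),
        auc=float(np.mean([m.auc for m in per_repeat])),
    )
    return RunResult(
        per_repeat=per_repeat, mean=mean, protocol=protocol,
        seeds=seeds, fold_assignments=assignments,
    )


def fit_self_model(
    target: LabeledViews,
    train_idx: np.ndarray,
    hp: HyperParams,
    standardize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 200,
):
    """Fit projections on the training-fold subjects only.

    Slices the training columns before any statistic is computed, so
    the fitted model provably cannot depend on test-fold features; the
    leakage audit perturbs held-out columns and checks the fit is
    unchanged.
    """
    sub = target.subset(np.asarray(train_idx))
    return fit_model(
        sub.X_CT, sub.X_CV, sub.labels, sub.class_order(), hp,
        standardize=standardize, tol=tol, max_iter=max_iter,
    )


def paired_accuracy_ttest(acc_a: Sequence[float], acc_b: Sequence[float]) -> float:
    """Two-sided paired t-test p-value on per-repeat accuracy differences.

    Zero-variance differences: p = 1 when the mean difference is zero
    (no evidence of any difference), else p = 0.0 as a below-machine-
    precision flag.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 paired values")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
    return float(scipy.stats.ttest_rel(a, b).pvalue)


def default_grids() -> dict[str, list]:
    """The hyperparameter ranges used in the reference evaluation."""
    return {
        "lam": [round(0.1 * i, 1) for i in range(1, 10)],
        "alpha": [10.0**i for i in range(-3, 2)],
        "beta": [10.0**j for j in range(-1, 2)],
        "k_ct": [3, 5, 7, 9, 11, 13, 15],
        "k_cv": [3, 5, 7, 9, 11, 13, 15],
        "eta": [q * 10.0**-2 for q in range(1, 10)] + [q * 10.0**-1 for q in range(1, 10)],
    }


def grid_size(grids: Mapping[str, Sequence] | None = None) -> int:
    """Number of hyperparameter combinations enumerated by a grid."""
    grids = default_grids() if grids is None else grids
    size = 1
    for values in grids.values():
        size *= len(values)
    return size


def grid_search(
    aux,
    target,
    grids: Mapping[str, Sequence] | None,
    cfg: CVConfig,
    protocol: str = "auxiliary",
    screening_repeats: int = 5,
    standardize: bool = True,
) -> pd.DataFrame:
    """Evaluate run_protocol over every grid combination.

    Uses a reduced repeat count (default 5) for screening; final
    reporting of a chosen combination should rerun at full repeats.
    Rows are sorted by mean accuracy (desc), ties broken by AUC (desc)
    then lexicographically by parameters. Note the top row is selected
    on evaluation performance and is therefore an optimistic estimate.
    """
    grids = default_grids() if grids is None else dict(grids)
    if any(len(v) == 0 for v in grids.values()) or len(grids) == 0:
        raise ValueError("grids must be nonempty")
    names = sorted(grids)
    screen_cfg = cfg.replace(n_repeats=min(screening_repeats, cfg.n_repeats))
    rows = []
    for combo in itertools.product(*(grids[k] for k in names)):
        hp = HyperParams(**dict(zip(names, combo)))
        res = run_protocol(aux, target, hp, screen_cfg, protocol=protocol, standardize=standardize)
        row = dict(zip(names, combo))
        row.update(
            mean_acc=res.mean.acc, mean_sen=res.mean.sen,
            mean_spe=res.mean.spe, mean_auc=res.mean.auc,
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["mean_acc", "mean_auc", *names],
        ascending=[False, False] + [True] * len(names),
        kind="stable",
    ).reset_index(drop=True)
    return df


def auxiliary_size_sweep(
    aux,
    target,
    hp: HyperParams,
    cfg: CVConfig,
    sizes: Sequence[int] = (50, 100, 150, 200, 250),
    n_resamples: int = 10,
    standardize: bool = True,
) -> pd.DataFrame:
    """Mean accuracy as a function of auxiliary-set size.

    For each size, draws class-balanced (1:1) auxiliary subsets without
    replacement and evaluates protocol="auxiliary"; accuracy is
    averaged over the resamples. Deterministic given cfg.base_seed.
    """
    aux = as_labeled_views(aux)
    classes = aux.class_order()
    if len(classes) != 2:
        raise ValueError("auxiliary set must contain exactly two classes")
    idx_by_class = {c: np.flatnonzero(aux.labels == c) for c in classes}
    for size in sizes:
        half = size // 2
        if size % 2 != 0:
            raise ValueError(f"size {size} is not even; 1:1 balance requires an even size")
        for c in classes:
            if half > idx_by_class[c].size:
                raise ValueError(
                    f"size {size} needs {half} subjects of class {c!r}, "
                    f"only {idx_by_class[c].size} available"
                )
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.base_seed), 977]))
    rows = []
    for size in sizes:
        half = size // 2
        accs = []
        for j in range(n_resamples):
            chosen = np.concatenate(
                [rng.choice(idx_by_class[c], size=half, replace=False) for c in classes]
            )
            sub = aux.subset(np.sort(chosen))
            res = run_protocol(sub, target, hp, cfg, protocol="auxiliary", standardize=standardize)
            accs.append(res.mean.acc)
        rows.append(
            {
                "size": size,
                "mean_acc": float(np.mean(accs)),
                "sd_acc": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                "n_resamples": n_resamples,
            }
        )
    return pd.DataFrame(rows)
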