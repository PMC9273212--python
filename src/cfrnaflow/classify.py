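"""Bootstrap evaluation protocol for cfRNA-based cancer classification.

The protocol estimates out-of-sample performance without a fixed train/test
split, which matters for cohorts of a few hundred plasma samples:

* Each replicate draws a training multiset of cohort size with replacement;
  samples never drawn form the holdout ("out-of-bag") set.
* Feature selection runs only on the training multiset: in each of 10
  rounds, a stratified 75% subsample is drawn and every feature is scored
  with a rank-sum test between classes (all unordered class pairs in the
  multiclass task); the 50 smallest-p features per comparison are recorded
  and the union over rounds/pairs is kept.  Repeated subsampling damps
  within-class heterogeneity.
* A balanced random forest — each tree trained on a per-class bootstrap of
  minority-class size — is fitted at a maximum tree depth chosen by
  stratified cross-validation, then scored on the holdout samples.
* Across replicates the protocol reports the holdout AUROC distribution, an
  out-of-bag ROC built from each sample's median held-out probability, the
  averaged row-normalized confusion matrix, per-class top-1/top-2 recall,
  and a recurrence table of feature importances.

Per-replicate RNG streams are derived from the master seed and the replicate
index (``default_rng([seed, replicate])``), so results do not depend on
execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from cfrnaflow.differential import _vectorized_ranksum_p, ranksum_test


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class BootstrapSpec:
    """Protocol parameters.

    ``depth_grid`` entries are maximum tree depths; ``None`` means unbounded.
    ``subsample_fraction`` controls the per-round feature-selection subsets,
    and ``top_k_features`` the number of features recorded per comparison.
    """

    n_replicates: int = 100
    subsample_fraction: float = 0.75
    n_subsample_rounds: int = 10
    top_k_features: int = 50
    n_trees: int = 100
    depth_grid: tuple[int | None, ...] = (3, 5, 7, 10, None)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ClassificationError("subsample_fraction must be in (0, 1]")
        if self.top_k_features < 1:
            raise ClassificationError("top_k_features must be >= 1")
        if self.n_replicates < 1:
            raise ClassificationError("n_replicates must be >= 1")
        if self.n_trees < 1:
            raise ClassificationError("n_trees must be >= 1")
        if not self.depth_grid:
            raise ClassificationError("depth_grid must be non-empty")


@dataclass
class ReplicateResult:
    """Everything recorded for one bootstrap replicate."""

    train_ids: list[str]
    holdout_ids: list[str]
    selected_features: list[str]
    depth: int | None
    holdout_proba: pd.DataFrame        # holdout samples x classes
    auroc: float | None = None         # binary task only
    confusion: np.ndarray | None = None  # multiclass: raw counts, true x pred
    top1_recall: dict[str, float] | None = None
    top2_recall: dict[str, float] | None = None
    importance_ranks: dict[str, int] = field(default_factory=dict)


@dataclass
class EvaluationReport:
    """Aggregate result of a bootstrap evaluation run."""

    task: str
    class_order: list[str]
    spec: BootstrapSpec
    replicates: list[ReplicateResult]
    auroc_distribution: list[float] | None = None
    oob_probabilities: pd.Series | None = None
    oob_roc: pd.DataFrame | None = None
    oob_auroc: float | None = None
    confusion_matrix: pd.DataFrame | None = None
    top1_recall: pd.DataFrame | None = None
    top2_recall: pd.DataFrame | None = None

    @property
    def average_recall(self) -> float | None:
        """Unweighted mean over classes of the mean per-class top-1 recall."""
        if self.top1_recall is None:
            return None
        return float(self.top1_recall.mean(axis=0).mean())

    @property
    def average_top2_recall(self) -> float | None:
        if self.top2_recall is None:
            return None
        return float(self.top2_recall.mean(axis=0).mean())

    def to_json_dict(self) -> dict:
        out: dict = {
            "task": self.task,
            "class_order": self.class_order,
            "n_replicates": len(self.replicates),
            "seed": self.spec.seed,
        }
        if self.auroc_distribution is not None:
            out["auroc_distribution"] = [round(a, 10) for a in
                                         self.auroc_distribution]
            out["mean_auroc"] = round(float(np.mean(self.auroc_distribution)), 10)
        if self.oob_auroc is not None:
            out["oob_auroc"] = round(self.oob_auroc, 10)
        if self.confusion_matrix is not None:
            out["confusion_matrix"] = {
                c: [round(v, 10) for v in row]
                for c, row in self.confusion_matrix.iterrows()
            }
        if self.top1_recall is not None:
            out["mean_top1_recall"] = {
                c: round(float(v), 10)
                for c, v in self.top1_recall.mean(axis=0).items()
            }
            out["average_recall"] = round(self.average_recall, 10)
        if self.top2_recall is not None:
            out["mean_top2_recall"] = {
                c: round(float(v), 10)
                for c, v in self.top2_recall.mean(axis=0).items()
            }
            out["average_top2_recall"] = round(self.average_top2_recall, 10)
        return out


def draw_bootstrap(
    sample_ids: Sequence[str],
    rng: np.random.Generator,
    labels: pd.Series | None = None,
    max_redraws: int = 100,
) -> tuple[list[str], list[str]]:
    """Draw one bootstrap training multiset and its holdout complement.

    Sampling is with replacement until the training multiset reaches cohort
    size; the holdout set contains every sample never drawn.  When ``labels``
    is given the draw is repeated (bounded) until both the training multiset
    and the holdout contain at least one sample of every class — holdout
    metrics are undefined otherwise.
    """
    ids = list(sample_ids)
    n = len(ids)
    if n < 2:
        raise ClassificationError("bootstrap requires at least 2 samples")
    classes = None
    if labels is not None:
        classes = sorted(set(labels.loc[ids]))
    for _ in range(max_redraws):
        draw = rng.integers(0, n, size=n)
        train = [ids[i] for i in draw]
        drawn = set(draw)
        holdout = [ids[i] for i in range(n) if i not in drawn]
        if classes is None:
            return train, holdout
        train_classes = set(labels.loc[train])
        holdout_classes = set(labels.loc[holdout]) if holdout else set()
        missing = [c for c in classes
                   if c not in train_classes or c not in holdout_classes]
        if not missing:
            return train, holdout
    raise ClassificationError(
        f"could not draw a bootstrap with class(es) {missing} present in both "
        f"train and holdout after {max_redraws} attempts"
    )


def _stratified_subsample(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a per-class ceil(fraction * n_c) subsample, no replacement."""
    parts = []
    for c in sorted(set(y)):
        idx = np.flatnonzero(y == c)
        take = int(np.ceil(fraction * idx.size))
        parts.append(rng.choice(idx, size=take, replace=False))
    return np.concatenate(parts)


def select_features_multiclass(
    expr: pd.DataFrame,
    labels: Sequence[str],
    spec: BootstrapSpec,
    rng: np.random.Generator,
) -> list[str]:
    """Union of per-round, per-class-pair top rank-sum features.

    ``expr`` is a feature x training-sample matrix (columns may repeat for
    bootstrap multisets) and ``labels`` the matching class labels.  Each
    round draws a stratified ``subsample_fraction`` subset, scores every
    feature with a rank-sum test for every unordered class pair, and records
    the ``top_k_features`` smallest p-values per pair (ties broken by stable
    feature order).  Returns the union over pairs and rounds, in feature
    order.
    """
    y = np.asarray(labels)
    if len(y) != expr.shape[1]:
        raise ClassificationError("labels length must match sample count")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ClassificationError("feature selection needs >= 2 classes")
    x = expr.to_numpy(dtype=float)
    selected = np.zeros(x.shape[0], dtype=bool)
    for _ in range(spec.n_subsample_rounds):
        sub = _stratified_subsample(y, spec.subsample_fraction, rng)
        x_sub, y_sub = x[:, sub], y[sub]
        for ca, cb in combinations(classes, 2):
            p = _vectorized_ranksum_p(x_sub[:, y_sub == ca],
                                      x_sub[:, y_sub == cb])
            top = np.argsort(p, kind="stable")[: spec.top_k_features]
            selected[top] = True
    return list(expr.index[selected])


def select_features_binary(
    expr: pd.DataFrame,
    labels: Sequence[str],
    spec: BootstrapSpec,
    rng: np.random.Generator,
) -> list[str]:
    """Two-class special case of :func:`select_features_multiclass`."""
    if len(set(labels)) != 2:
        raise ClassificationError("binary feature selection needs exactly "
                                  "2 classes")
    return select_features_multiclass(expr, labels, spec, rng)


class BalancedRandomForest:
    """Random forest over class-balanced per-tree bootstraps.

    Each of ``n_trees`` CART trees (Gini impurity, sqrt(n_features)
    candidate features per split, the given maximum depth) is trained on a
    bootstrap that draws, for every class, minority-class-size instances
    with replacement; predicted probabilities are the mean of the per-tree
    class-probability votes.  This counteracts class imbalance without
    reweighting.
    """

    def __init__(self, n_trees: int = 100, max_depth: int | None = None):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.trees_: list[DecisionTreeClassifier] = []
        self.tree_sample_indices_: list[np.ndarray] = []
        self.classes_: np.ndarray | None = None

    def fit(self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ClassificationError("balanced forest needs >= 2 classes")
        class_idx = [np.flatnonzero(y == c) for c in self.classes_]
        minority = min(idx.size for idx in class_idx)
        if minority == 0:  # pragma: no cover - unique() precludes this
            raise ClassificationError("a class has no training instances")
        self.trees_ = []
        self.tree_sample_indices_ = []
        for _ in range(self.n_trees):
            idx = np.concatenate([
                rng.choice(ci, size=minority, replace=True) for ci in class_idx
            ])
            tree = DecisionTreeClassifier(
                criterion="gini",
                max_features="sqrt",
                max_depth=self.max_depth,
                random_state=int(rng.integers(2 ** 31)),
            )
            tree.fit(x[idx], y[idx])
            self.trees_.append(tree)
            self.tree_sample_indices_.append(idx)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if not self.trees_:
            raise ClassificationError("forest is not fitted")
        out = np.zeros((x.shape[0], self.classes_.size))
        for tree in self.trees_:
            proba = tree.predict_proba(x)
            # every class is present in every balanced bootstrap, so the
            # per-tree class order equals self.classes_
            out += proba
        return out / len(self.trees_)

    @property
    def feature_importances_(self) -> np.ndarray:
        """Mean impurity decrease per feature across trees."""
        if not self.trees_:
            raise ClassificationError("forest is not fitted")
        return np.mean([t.feature_importances_ for t in self.trees_], axis=0)


def fit_balanced_random_forest(
    x: np.ndarray,
    y: Sequence[str],
    depth: int | None,
    n_trees: int,
    rng: np.random.Generator,
) -> BalancedRandomForest:
    return BalancedRandomForest(n_trees=n_trees, max_depth=depth).fit(
        x, np.asarray(y), rng
    )


def auroc(scores: Sequence[float], binary_labels: Sequence[bool]) -> float:
    """Area under the ROC curve; ties between scores count one half.

    Equals the probability that a uniformly chosen positive outscores a
    uniformly chosen negative (the Mann-Whitney identity).
    """
    y = np.asarray(binary_labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ClassificationError("AUROC needs both classes present")
    return float(roc_auc_score(y, s))


def _sorted_depth_grid(grid: tuple[int | None, ...]) -> list[int | None]:
    finite = sorted(d for d in grid if d is not None)
    return finite + ([None] if None in grid else [])


def tune_depth(
    x: np.ndarray,
    y: Sequence[str],
    spec: BootstrapSpec,
    rng: np.random.Generator,
) -> int | None:
    """Pick a maximum tree depth by stratified cross-validation.

    The score is holdout-fold AUROC for two classes and macro-averaged
    top-1 recall for three or more; ties prefer the smallest depth
    (``None`` = unbounded counts as the largest).  Folds are reduced with a
    warning when the smallest class has fewer members than ``cv_folds``.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ClassificationError("depth tuning needs >= 2 classes")
    grid = _sorted_depth_grid(spec.depth_grid)
    if len(grid) == 1:
        return grid[0]
    min_count = min(int((y == c).sum()) for c in classes)
    folds = min(spec.cv_folds, min_count)
    if folds < spec.cv_folds:
        warnings.warn(
            f"smallest class has {min_count} members; reducing CV folds "
            f"from {spec.cv_folds} to {folds}", stacklevel=2)
    if folds < 2:
        warnings.warn("cross-validation impossible (a class has a single "
                      "member); falling back to the smallest depth",
                      stacklevel=2)
        return grid[0]
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    splits = list(skf.split(x, y))
    scores = []
    for depth in grid:
        fold_scores = []
        for tr, te in splits:
            model = BalancedRandomForest(spec.n_trees, depth).fit(
                x[tr], y[tr], rng)
            proba = model.predict_proba(x[te])
            if classes.size == 2:
                fold_scores.append(
                    roc_auc_score(y[te] == classes[1], proba[:, 1]))
            else:
                pred = model.classes_[np.argmax(proba, axis=1)]
                recalls = [np.mean(pred[y[te] == c] == c)
                           for c in classes if (y[te] == c).any()]
                fold_scores.append(float(np.mean(recalls)))
        scores.append(float(np.mean(fold_scores)))
    return grid[int(np.argmax(scores))]


def _importance_ranks(model: BalancedRandomForest,
                      features: list[str]) -> dict[str, int]:
    imp = model.feature_importances_
    order = np.argsort(-imp, kind="stable")
    return {features[j]: rank + 1 for rank, j in enumerate(order)}


def _run_replicate(
    expr: pd.DataFrame,
    labels: pd.Series,
    spec: BootstrapSpec,
    replicate: int,
    hook: Callable[[str, dict], None] | None,
) -> ReplicateResult:
    rng = np.random.default_rng([spec.seed, replicate])
    sample_ids = list(expr.columns)
    train_ids, holdout_ids = draw_bootstrap(sample_ids, rng, labels=labels)

    # everything before prediction sees only the training multiset
    train_expr = expr.loc[:, train_ids]
    y_train = labels.loc[train_ids].to_numpy()
    if hook:
        hook("train_extracted", {"replicate": replicate,
                                 "train_ids": list(train_ids),
                                 "holdout_ids": list(holdout_ids)})
    selected = select_features_multiclass(train_expr, y_train, spec, rng)
    if hook:
        hook("features_selected", {"replicate": replicate,
                                   "features": list(selected)})
    x_train = train_expr.loc[selected].to_numpy(dtype=float).T
    depth = tune_depth(x_train, y_train, spec, rng)
    model = fit_balanced_random_forest(x_train, y_train, depth,
                                       spec.n_trees, rng)
    if hook:
        hook("model_fitted", {"replicate": replicate, "depth": depth})

    x_holdout = expr.loc[selected, holdout_ids].to_numpy(dtype=float).T
    if hook:
        hook("holdout_read", {"replicate": replicate,
                              "holdout_ids": list(holdout_ids)})
    proba = model.predict_proba(x_holdout)
    proba_df = pd.DataFrame(proba, index=holdout_ids,
                            columns=list(model.classes_))
    return ReplicateResult(
        train_ids=train_ids,
        holdout_ids=holdout_ids,
        selected_features=selected,
        depth=depth,
        holdout_proba=proba_df,
        importance_ranks=_importance_ranks(model, selected),
    )


def evaluate_binary(
    expr: pd.DataFrame,
    labels: pd.Series,
    spec: BootstrapSpec,
    positive_label: str,
    hook: Callable[[str, dict], None] | None = None,
) -> EvaluationReport:
    """Bootstrap evaluation of the two-class (cancer vs healthy) task.

    ``expr`` is the normalized feature x sample matrix for the full cohort;
    normalization is assumed to have been computed once on the full cohort
    before bootstrapping.  Returns the per-replicate holdout AUROC
    distribution and the out-of-bag ROC built from each sample's median
    held-out positive-class probability.
    """
    classes = sorted(set(labels.loc[expr.columns]))
    if len(classes) != 2:
        raise ClassificationError(f"binary task needs 2 classes, got {classes}")
    if positive_label not in classes:
        raise ClassificationError(f"positive label {positive_label!r} not in "
                                  f"{classes}")

    replicates = []
    aurocs = []
    oob: dict[str, list[float]] = {s: [] for s in expr.columns}
    for r in range(spec.n_replicates):
        rep = _run_replicate(expr, labels, spec, r, hook)
        p_pos = rep.holdout_proba[positive_label]
        y_holdout = labels.loc[rep.holdout_ids] == positive_label
        rep.auroc = auroc(p_pos.to_numpy(), y_holdout.to_numpy())
        aurocs.append(rep.auroc)
        for sid, p in p_pos.items():
            oob[sid].append(float(p))
        replicates.append(rep)

    never_held_out = [s for s, v in oob.items() if not v]
    if never_held_out:
        warnings.warn(f"{len(never_held_out)} sample(s) never appeared in a "
                      "holdout set; excluded from the OOB ROC", stacklevel=2)
    oob_median = pd.Series({s: float(np.median(v)) for s, v in oob.items() if v},
                           name="median_holdout_probability")
    y_oob = (labels.loc[oob_median.index] == positive_label).to_numpy()
    fpr, tpr, thresholds = roc_curve(y_oob, oob_median.to_numpy())
    report = EvaluationReport(
        task="binary",
        class_order=classes,
        spec=spec,
        replicates=replicates,
        auroc_distribution=aurocs,
        oob_probabilities=oob_median,
        oob_roc=pd.DataFrame({"fpr": fpr, "tpr": tpr,
                              "threshold": thresholds}),
        oob_auroc=float(roc_auc_score(y_oob, oob_median.to_numpy())),
    )
    return report


def _top2_hits(proba: pd.DataFrame, class_order: list[str]) -> pd.Series:
    """Whether each sample's true class placeholder is needed by caller;
    returns per-sample top-2 class tuples with deterministic tie-breaks."""
    cols = list(proba.columns)
    p = proba.to_numpy()
    # ties broken by fixed class order: lexsort on (class index, -p)
    idx = np.lexsort((np.arange(len(cols))[None, :].repeat(len(p), 0),
                      -p), axis=1)[:, :2]
    return pd.Series([tuple(cols[j] for j in row) for row in idx],
                     index=proba.index)


def evaluate_multiclass(
    expr: pd.DataFrame,
    labels: pd.Series,
    spec: BootstrapSpec,
    hook: Callable[[str, dict], None] | None = None,
) -> EvaluationReport:
    """Bootstrap evaluation of the tumor-site (multiclass) task.

    Per replicate the holdout confusion counts are row-normalized; the
    report averages these matrices over replicates and records per-class
    top-1 (diagonal) and top-2 recall (true class among the two highest
    predicted probabilities, probability ties broken by fixed class order).
    """
    classes = sorted(set(labels.loc[expr.columns]))
    if len(classes) < 3:
        raise ClassificationError("multiclass task needs >= 3 classes")
    k = len(classes)
    cindex = {c: i for i, c in enumerate(classes)}

    replicates = []
    confusions = []
    top1_rows = []
    top2_rows = []
    for r in range(spec.n_replicates):
        rep = _run_replicate(expr, labels, spec, r, hook)
        proba = rep.holdout_proba[classes]
        y_true = labels.loc[rep.holdout_ids]
        pred = proba.columns[np.argmax(proba.to_numpy(), axis=1)]
        conf = np.zeros((k, k))
        for t, p in zip(y_true, pred):
            conf[cindex[t], cindex[p]] += 1
        rep.confusion = conf
        row_norm = conf / conf.sum(axis=1, keepdims=True)
        confusions.append(row_norm)
        top2 = _top2_hits(proba, classes)
        rep.top1_recall = {c: float(row_norm[cindex[c], cindex[c]])
                           for c in classes}
        rep.top2_recall = {
            c: float(np.mean([t in pair for t, pair in
                              zip(y_true, top2) if t == c]))
            for c in classes
        }
        top1_rows.append(rep.top1_recall)
        top2_rows.append(rep.top2_recall)
        replicates.append(rep)

    return EvaluationReport(
        task="multiclass",
        class_order=classes,
        spec=spec,
        replicates=replicates,
        confusion_matrix=pd.DataFrame(np.mean(confusions, axis=0),
                                      index=classes, columns=classes),
        top1_recall=pd.DataFrame(top1_rows),
        top2_recall=pd.DataFrame(top2_rows),
    )


def aggregate_feature_importance(
    replicates: list[ReplicateResult],
    rank_cutoff: int = 50,
    min_frequency: int = 40,
    fold_changes: pd.Series | None = None,
) -> pd.DataFrame:
    """Recurrently important features across bootstrap replicates.

    A feature's frequency counts the replicates where its importance rank
    (1 = most important, mean impurity decrease) is within ``rank_cutoff``;
    features reaching ``min_frequency`` are returned with their mean
    importance rank over the replicates that selected them and, when
    ``fold_changes`` is supplied, the log2 fold change vs the comparator
    group.  Sorted by descending frequency, then mean rank.
    """
    if not replicates:
        raise ClassificationError("no replicates to aggregate")
    freq: dict[str, int] = {}
    ranks: dict[str, list[int]] = {}
    for rep in replicates:
        for feat, rank in rep.importance_ranks.items():
            ranks.setdefault(feat, []).append(rank)
            if rank <= rank_cutoff:
                freq[feat] = freq.get(feat, 0) + 1
    rows = []
    for feat, count in freq.items():
        if count >= min_frequency:
            row = {
                "feature": feat,
                "frequency": count,
                "mean_importance_rank": float(np.mean(ranks[feat])),
            }
            if fold_changes is not None:
                row["log2_fold_change"] = float(fold_changes.get(feat, np.nan))
            rows.append(row)
    out = pd.DataFrame(rows, columns=["feature", "frequency",
                                      "mean_importance_rank"]
                       + (["log2_fold_change"] if fold_changes is not None
                          else []))
    if len(out):
        out = out.sort_values(["frequency", "mean_importance_rank"],
                              ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    return out


def compare_feature_sets(metric_a: Sequence[float],
                         metric_b: Sequence[float]) -> float:
    """One-tailed Mann-Whitney p-value for 'A performs better than B'.

    Used to compare per-replicate performance distributions of two feature
    sets (e.g. human+microbe vs human-only recall).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ClassificationError("both metric vectors must be non-empty")
    _, p = ranksum_test(a, b, alternative="greater")
    return p
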