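"""Imbalance-aware ensemble staging and its evaluation protocols.

The classifier is a bagged ensemble of 130 decision trees in which each
tree's bootstrap draw is re-balanced by random under-sampling to the
minority-class count, countering the dominance of stage-2 sleep among
clips.  Under-sampling is re-drawn independently per tree so the ensemble
sees diverse majority-class subsets.  The per-class score is the fraction
of trees voting for that class; one-vs-rest ROC curves and AUROC are
computed from these vote fractions.

Evaluation protocols: leave-one-subject-out cross-validation (population
model), stratified 20-fold cross-validation within one subject (personal
model), sensor-subset ablation, learning curves over training-cohort size,
and a weighted-epoch actigraphy baseline standing in for a wrist device's
proprietary sleep/wake scorer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix, SensorSubset, build_feature_matrix, ProcessedRecording
from .io_model import (
    ChannelSeries,
    Recording,
    StageLabel,
    ValidationError,
    map_stage_resolution,
    resolution_classes,
)

__all__ = [
    "BaggingConfig",
    "BalancedBaggingModel",
    "FoldResult",
    "EvaluationReport",
    "train_balanced_bagging",
    "predict_scores",
    "predict_labels",
    "loso_evaluate",
    "personal_evaluate",
    "permutation_null_auroc",
    "subset_ablation",
    "learning_curve",
    "actigraphy_baseline",
]


@dataclass(frozen=True)
class BaggingConfig:
    """Ensemble hyperparameters."""

    n_trees: int = 130
    undersample: bool = True
    max_depth: Optional[int] = None
    min_samples_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be at least 1")


@dataclass
class BalancedBaggingModel:
    """A fitted ensemble: trees, class order, and the training schema."""

    trees: list[DecisionTreeClassifier]
    classes: tuple[str, ...]  # canonical order (ties break toward earlier)
    feature_names: tuple[str, ...]
    config: BaggingConfig
    per_tree_class_counts: list[dict[str, int]] = field(default_factory=list)


def _ordered_classes(labels: np.ndarray, resolution: Optional[int]) -> tuple[str, ...]:
    present = set(labels)
    if resolution is not None:
        order = [c for c in resolution_classes(resolution) if c in present]
        extra = sorted(present - set(order))
        return tuple(order + extra)
    return tuple(sorted(present))


def train_balanced_bagging(
    features: FeatureMatrix | pd.DataFrame,
    labels: Sequence[str],
    config: BaggingConfig = BaggingConfig(),
    *,
    resolution: Optional[int] = None,
) -> BalancedBaggingModel:
    """Fit the under-sampled bagging ensemble.

    Each tree sees a bootstrap draw re-balanced by random under-sampling to
    the minority-class count (sampling with replacement within each class);
    with ``undersample`` off it sees a plain bootstrap of the full set.
    Deterministic under ``config.seed``.
    """
    X = features.df if isinstance(features, FeatureMatrix) else features
    y = np.asarray(list(labels), dtype=object)
    if len(X) != len(y):
        raise ValidationError("features and labels differ in length")
    classes = _ordered_classes(y, resolution)
    if len(classes) < 2:
        raise ValidationError("training requires at least 2 classes")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < 5:
        raise ValidationError(
            f"every class needs at least 5 rows, got {counts}"
        )

    Xv = X.to_numpy(dtype=float)
    class_idx = {c: np.nonzero(y == c)[0] for c in classes}
    minority = min(counts.values())
    n = len(y)

    trees = []
    per_tree_counts = []
    for t in range(config.n_trees):
        rng = np.random.default_rng([int(config.seed) % (2**31), 17, t])
        if config.undersample:
            idx = np.concatenate(
                [rng.choice(class_idx[c], size=minority, replace=True) for c in classes]
            )
        else:
            idx = rng.choice(n, size=n, replace=True)
        tree = DecisionTreeClassifier(
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(Xv[idx], y[idx])
        trees.append(tree)
        per_tree_counts.append({c: int(np.sum(y[idx] == c)) for c in classes})
    return BalancedBaggingModel(
        trees=trees,
        classes=classes,
        feature_names=tuple(X.columns),
        config=config,
        per_tree_class_counts=per_tree_counts,
    )


def _check_schema(model: BalancedBaggingModel, X: pd.DataFrame) -> np.ndarray:
    if set(X.columns) != set(model.feature_names):
        raise ValidationError("feature columns do not match the training schema")
    return X[list(model.feature_names)].to_numpy(dtype=float)


def predict_scores(
    model: BalancedBaggingModel, features: FeatureMatrix | pd.DataFrame
) -> pd.DataFrame:
    """Per-class vote fractions; rows sum to 1, columns in canonical order."""
    X = features.df if isinstance(features, FeatureMatrix) else features
    Xv = _check_schema(model, X)
    votes = np.zeros((len(Xv), len(model.classes)))
    col = {c: j for j, c in enumerate(model.classes)}
    for tree in model.trees:
        pred = tree.predict(Xv)
        for j, c in enumerate(model.classes):
            votes[pred == c, j] += 1
    votes /= len(model.trees)
    return pd.DataFrame(votes, columns=list(model.classes))


def predict_labels(
    model: BalancedBaggingModel, features: FeatureMatrix | pd.DataFrame
) -> np.ndarray:
    """Argmax of vote fractions; ties break toward the earlier class."""
    scores = predict_scores(model, features)
    idx = np.argmax(scores.to_numpy(), axis=1)  # first max wins the tie
    return np.asarray([model.classes[i] for i in idx], dtype=object)


@dataclass
class FoldResult:
    """Metrics of a single cross-validation fold."""

    held_out: str
    classes: tuple[str, ...]
    confusion: pd.DataFrame  # rows: true class counts
    recall: dict[str, float]
    roc: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (fpr, tpr)
    auroc: dict[str, float]


@dataclass
class EvaluationReport:
    """Aggregate of fold metrics at one staging resolution."""

    resolution: int
    classes: tuple[str, ...]
    folds: list[FoldResult]
    recall_mean: dict[str, float]
    recall_sd: dict[str, float]
    auroc_mean: dict[str, float]
    auroc_sd: dict[str, float]
    pooled_confusion: pd.DataFrame  # row-normalized over pooled clips
    mean_confusion: pd.DataFrame  # mean of per-fold row-normalized matrices


def _coarse_labels(fm: FeatureMatrix, resolution: int) -> np.ndarray:
    return np.asarray(
        [map_stage_resolution(StageLabel(s), resolution) for s in fm.labels],
        dtype=object,
    )


def _evaluate_fold(
    model: BalancedBaggingModel,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    held_out: str,
) -> FoldResult:
    classes = model.classes
    scores = predict_scores(model, X_test)
    pred = np.asarray(
        [classes[i] for i in np.argmax(scores.to_numpy(), axis=1)], dtype=object
    )
    conf = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for t, p in zip(y_test, pred):
        conf.loc[t, p] += 1
    recall = {}
    roc = {}
    auroc = {}
    for c in classes:
        n_c = int(np.sum(y_test == c))
        recall[c] = float(conf.loc[c, c] / n_c) if n_c else float("nan")
        pos = (y_test == c).astype(int)
        if 0 < pos.sum() < len(pos):
            fpr, tpr, _ = roc_curve(pos, scores[c].to_numpy())
            roc[c] = (fpr, tpr)
            auroc[c] = float(roc_auc_score(pos, scores[c].to_numpy()))
        else:
            roc[c] = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
            auroc[c] = float("nan")
    return FoldResult(
        held_out=held_out,
        classes=classes,
        confusion=conf,
        recall=recall,
        roc=roc,
        auroc=auroc,
    )


def _aggregate(folds: list[FoldResult], resolution: int) -> EvaluationReport:
    classes = folds[0].classes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN class slices
        recall_mean = {
            c: float(np.nanmean([f.recall[c] for f in folds])) for c in classes
        }
        recall_sd = {
            c: float(np.nanstd([f.recall[c] for f in folds])) for c in classes
        }
        auroc_mean = {
            c: float(np.nanmean([f.auroc[c] for f in folds])) for c in classes
        }
        auroc_sd = {c: float(np.nanstd([f.auroc[c] for f in folds])) for c in classes}
    pooled = sum(f.confusion for f in folds)
    pooled_norm = pooled.div(pooled.sum(axis=1).replace(0, np.nan), axis=0)
    per_fold_norm = [
        f.confusion.div(f.confusion.sum(axis=1).replace(0, np.nan), axis=0)
        for f in folds
    ]
    mean_conf = sum(df.fillna(0.0) for df in per_fold_norm) / len(folds)
    return EvaluationReport(
        resolution=resolution,
        classes=classes,
        folds=folds,
        recall_mean=recall_mean,
        recall_sd=recall_sd,
        auroc_mean=auroc_mean,
        auroc_sd=auroc_sd,
        pooled_confusion=pooled_norm,
        mean_confusion=mean_conf,
    )


def loso_evaluate(
    fm: FeatureMatrix,
    resolution: int,
    config: BaggingConfig = BaggingConfig(),
) -> EvaluationReport:
    """Leave-one-subject-out evaluation: one fold per subject.

    Training rows never share a subject with test rows; per-fold recall,
    confusion, one-vs-rest ROC, and AUROC are aggregated as mean and SD
    across folds.
    """
    subjects = list(dict.fromkeys(fm.subjects))
    if len(subjects) < 2:
        raise ValidationError(
            "leave-one-subject-out needs at least 2 subjects; "
            "use personal_evaluate for a single subject"
        )
    y = _coarse_labels(fm, resolution)
    folds = []
    for held in subjects:
        test_rows = fm.rows_for_subject(held)
        model = train_balanced_bagging(
            fm.df.loc[~test_rows], y[~test_rows], config, resolution=resolution
        )
        folds.append(
            _evaluate_fold(model, fm.df.loc[test_rows], y[test_rows], held)
        )
    return _aggregate(folds, resolution)


def personal_evaluate(
    fm: FeatureMatrix,
    resolution: int,
    k: int = 20,
    config: BaggingConfig = BaggingConfig(),
) -> EvaluationReport:
    """Stratified k-fold evaluation within a single subject's rows.

    Classes with fewer than 2 rows are merged out (dropped) with a warning.
    Fold test sets partition the rows; per-class rows are dealt round-robin
    so every training split retains each class.
    """
    subjects = set(fm.subjects)
    if len(subjects) != 1:
        raise ValidationError("personal_evaluate expects a single subject's rows")
    if fm.n_clips < k:
        raise ValidationError(f"subject has {fm.n_clips} rows, fewer than {k} folds")
    y = _coarse_labels(fm, resolution)

    keep = np.ones(len(y), dtype=bool)
    for c in set(y):
        if np.sum(y == c) < 2:
            warnings.warn(f"class {c} has < 2 rows; dropped from personal model")
            keep &= y != c
    Xd = fm.df.loc[keep].reset_index(drop=True)
    y = y[keep]

    rng = np.random.default_rng([int(config.seed) % (2**31), 23])
    fold_of = np.empty(len(y), dtype=int)
    next_fold = 0
    for c in sorted(set(y)):
        idx = np.nonzero(y == c)[0]
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            fold_of[i] = (next_fold + j) % k
        next_fold = (next_fold + len(idx)) % k

    folds = []
    for f in range(k):
        test_rows = fold_of == f
        if not test_rows.any():
            continue
        model = train_balanced_bagging(
            Xd.loc[~test_rows],
            y[~test_rows],
            replace(config, seed=config.seed + 1000 + f),
            resolution=resolution,
        )
        folds.append(_evaluate_fold(model, Xd.loc[test_rows], y[test_rows], f"fold{f}"))
    return _aggregate(folds, resolution)


def permutation_null_auroc(
    fm: FeatureMatrix,
    resolution: int,
    config: BaggingConfig = BaggingConfig(),
    repeats: int = 20,
) -> pd.DataFrame:
    """Per-class mean LOSO AUROC after within-subject label permutation.

    Returns one row per repeat with a column per class — the chance-level
    reference distribution against which real AUROCs are judged.
    """
    out = []
    labels = fm.labels.to_numpy().copy()
    for r in range(repeats):
        rng = np.random.default_rng([int(config.seed) % (2**31), 29, r])
        perm = labels.copy()
        for s in set(fm.subjects):
            rows = np.nonzero(fm.rows_for_subject(s))[0]
            perm[rows] = perm[rng.permutation(rows)]
        fm_perm = FeatureMatrix(
            df=fm.df,
            labels=pd.Series(perm, name="stage"),
            subjects=fm.subjects,
            clip_starts=fm.clip_starts,
        )
        try:
            rep = loso_evaluate(fm_perm, resolution, replace(config, seed=config.seed + r))
        except ValidationError:
            continue
        out.append(rep.auroc_mean)
    return pd.DataFrame(out)


def subset_ablation(
    cohort: Sequence[Recording] | Sequence[ProcessedRecording],
    subsets: dict[str, SensorSubset],
    resolution: int,
    config: BaggingConfig = BaggingConfig(),
    **build_kw,
) -> pd.DataFrame:
    """Mean (SD) AUROC per class for each sensor subset.

    Features are rebuilt per subset from the same processed cohort and
    evaluated by leave-one-subject-out cross-validation.
    """
    from .features import process_recording

    processed = [
        r if isinstance(r, ProcessedRecording) else process_recording(r, **build_kw)
        for r in cohort
    ]
    rows = []
    for name, subset in subsets.items():
        fm = build_feature_matrix(processed, subset)
        rep = loso_evaluate(fm, resolution, config)
        row: dict[str, object] = {"subset": name, "n_features": fm.df.shape[1]}
        for c in rep.classes:
            row[f"auroc_{c}"] = rep.auroc_mean[c]
            row[f"auroc_sd_{c}"] = rep.auroc_sd[c]
        rows.append(row)
    return pd.DataFrame(rows)


def learning_curve(
    fm: FeatureMatrix,
    resolution: int,
    repeats: int = 10,
    config: BaggingConfig = BaggingConfig(),
) -> pd.DataFrame:
    """AUROC versus number of training subjects.

    For each n from 2 to N-1, draws ``repeats`` random n-subject training
    sets, each evaluated on one subject held out from the remainder, and
    records the mean and SD AUROC per class.
    """
    subjects = list(dict.fromkeys(fm.subjects))
    if len(subjects) < 3:
        raise ValidationError("learning curve needs at least 3 subjects")
    y = _coarse_labels(fm, resolution)
    classes = resolution_classes(resolution)
    rows = []
    for n in range(2, len(subjects)):
        per_class: dict[str, list[float]] = {c: [] for c in classes}
        for r in range(repeats):
            rng = np.random.default_rng([int(config.seed) % (2**31), 31, n, r])
            pick = rng.choice(len(subjects), size=n + 1, replace=False)
            train_subj = {subjects[i] for i in pick[:n]}
            held = subjects[pick[n]]
            train_rows = fm.subjects.isin(train_subj).to_numpy()
            test_rows = fm.rows_for_subject(held)
            try:
                model = train_balanced_bagging(
                    fm.df.loc[train_rows],
                    y[train_rows],
                    replace(config, seed=config.seed + 100 * n + r),
                    resolution=resolution,
                )
            except ValidationError:
                continue
            fold = _evaluate_fold(model, fm.df.loc[test_rows], y[test_rows], held)
            for c in classes:
                if np.isfinite(fold.auroc.get(c, float("nan"))):
                    per_class[c].append(fold.auroc[c])
        row: dict[str, object] = {"n_subjects": n}
        for c in classes:
            vals = per_class[c]
            row[f"auroc_{c}"] = float(np.mean(vals)) if vals else float("nan")
            row[f"auroc_sd_{c}"] = float(np.std(vals)) if vals else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


#: Weighted-epoch window of the classic wrist-actigraphy scorer.
_ACTI_WEIGHTS = (0.04, 0.2, 1.0, 0.2, 0.04)


def actigraphy_baseline(
    counts: ChannelSeries | np.ndarray, threshold: float = 40.0
) -> np.ndarray:
    """Sleep/wake per epoch from activity counts, weighted-window scored.

    s_k = 0.04 c_{k-2} + 0.2 c_{k-1} + c_k + 0.2 c_{k+1} + 0.04 c_{k+2}
    (edges zero-padded); epoch k is wake iff s_k strictly exceeds the
    threshold.  This re-implements the published weighted-epoch algorithm as
    a documented stand-in for the wrist device's proprietary scorer.
    """
    c = counts.values if isinstance(counts, ChannelSeries) else np.asarray(counts)
    c = np.asarray(c, dtype=float)
    padded = np.pad(c, 2)
    s = sum(w * padded[i : i + len(c)] for i, w in enumerate(_ACTI_WEIGHTS))
    return np.where(s > threshold, "Wake", "Sleep").astype(object)
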