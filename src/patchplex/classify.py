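"""Stratified cross-validation with nested random-forest feature selection.

Each of the (by default 1,000) rounds: (i) balance the two classes by
undersampling the majority class; (ii) split each class 80/20 into
training and validation; (iii) on the training set only, fit a first
random forest and select the features whose out-of-bag permutation
importance (mean decrease in accuracy) strictly exceeds the third quartile
of the importance distribution; (iv) train a second forest on the selected
features; (v) score the validation set.  Selection and training are nested
inside the round and never see validation rows (no double dipping).
Metrics are averaged over rounds, with a Wilson score interval on the mean
accuracy; per-feature selection counts feed the stability assessment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import _generate_unsampled_indices, _get_n_samples_bootstrap
from sklearn.metrics import roc_auc_score

from .defaults import CV_ROUNDS, IMPORTANCE_QUANTILE, N_TREES, TRAIN_FRACTION
from .features import FeatureMatrix

log = logging.getLogger(__name__)

__all__ = ["CVConfig", "RoundResult", "CVSummary", "stratify_round", "oob_importance",
           "select_important", "train_and_eval", "run_cv", "wilson_interval"]

METRICS = ("accuracy", "specificity", "sensitivity", "auc")


@dataclass(frozen=True)
class CVConfig:
    rounds: int = CV_ROUNDS
    train_fraction: float = TRAIN_FRACTION
    n_trees: int = N_TREES
    importance_quantile: float = IMPORTANCE_QUANTILE
    seed: int = 0
    positive_class: int = 1  # the seizure-affected/case label

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class RoundResult:
    round_index: int
    selected_features: list[str]
    accuracy: float
    specificity: float
    sensitivity: float
    auc: float
    validation_ids: list[int]


@dataclass
class CVSummary:
    config: CVConfig
    metrics_mean: dict[str, float]
    metrics_sd: dict[str, float]
    wilson_ci: tuple[float, float]
    selection_counts: pd.Series          # per feature, over rounds
    n_validation_total: int              # pooled validation classifications
    rounds: list[RoundResult] = field(default_factory=list)


def stratify_round(labels: np.ndarray, rng: np.random.Generator,
                   train_fraction: float = TRAIN_FRACTION) -> tuple[np.ndarray, np.ndarray]:
    """Balanced train/validation split for one round.

    The majority class is undersampled without replacement to the minority
    size, then each class is split ``train_fraction`` / rest (counts
    rounded to nearest, at least one validation subject per class).
    Returns disjoint arrays of subject indices.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    n_min = min(int((labels == c).sum()) for c in classes)
    if n_min < 2:
        raise ValueError("class too small for a nonempty validation set")
    n_train = int(round(train_fraction * n_min))
    n_train = min(max(n_train, 1), n_min - 1)
    train, val = [], []
    for c in classes:
        idx = rng.permutation(np.flatnonzero(labels == c))[:n_min]
        train.append(idx[:n_train])
        val.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(val))


def _tree_predict(tree, X32: np.ndarray, classes: np.ndarray) -> np.ndarray:
    # bypass per-call input validation; X32 must be C-contiguous float32
    proba = tree.tree_.predict(X32)
    if proba.ndim == 3:  # (n_samples, n_outputs, n_classes)
        proba = proba[:, 0, :]
    return classes[np.argmax(proba, axis=1)]


def oob_importance(forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Out-of-bag permutation importance (mean decrease in accuracy).

    For each tree, its out-of-bag rows are scored before and after
    permuting one feature at a time; decreases are averaged over all
    trees.  Only features a tree actually splits on are permuted — the
    others leave its predictions unchanged, contributing an exact zero.
    """
    n, p = X.shape
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)
    imp = np.zeros(p)
    for tree in forest.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if oob.size == 0:
            continue
        Xo = X32[oob]
        yo = y[oob]
        base = float(np.mean(_tree_predict(tree, Xo, forest.classes_) == yo))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        perm = rng.permutation(len(oob))
        for f in used:
            Xp = Xo.copy()
            Xp[:, f] = Xp[perm, f]
            acc = float(np.mean(_tree_predict(tree, Xp, forest.classes_) == yo))
            imp[f] += base - acc
    return imp / len(forest.estimators_)


def select_above_quantile(importances: np.ndarray, names: list[str],
                          quantile: float = IMPORTANCE_QUANTILE) -> list[str]:
    """Features strictly above the given quantile (linear interpolation) of
    the importance distribution; if none exceed it (all equal, or the top
    quarter ties the quantile), fall back to all features with a warning."""
    q = float(np.quantile(importances, quantile))
    sel = [nm for nm, v in zip(names, importances) if v > q]
    if not sel:
        log.warning("importance distribution is degenerate; keeping all %d features this round", len(names))
        return list(names)
    return sel


def select_important(X_train: np.ndarray, y_train: np.ndarray, names: list[str],
                     config: CVConfig, seed: int, rng: np.random.Generator) -> list[str]:
    """Nested-forest feature selection on the training set only."""
    if X_train.shape[1] < 2:
        raise ValueError("at least 2 features required for selection")
    rf = RandomForestClassifier(
        n_estimators=config.n_trees, max_features="sqrt", bootstrap=True,
        random_state=seed, n_jobs=1,
    ).fit(X_train, y_train)
    imp = oob_importance(rf, X_train, y_train, rng)
    return select_above_quantile(imp, names, config.importance_quantile)


def train_and_eval(X_train: np.ndarray, y_train: np.ndarray,
                   X_val: np.ndarray, y_val: np.ndarray,
                   selected_idx: np.ndarray, config: CVConfig, seed: int,
                   round_index: int, validation_ids: list[int]) -> RoundResult:
    """Fit the second forest on the selected features and score validation."""
    if selected_idx.size == 0:
        raise ValueError("selected feature set is empty")
    pos = config.positive_class
    rf = RandomForestClassifier(
        n_estimators=config.n_trees, max_features="sqrt", bootstrap=True,
        random_state=seed, n_jobs=1,
    ).fit(X_train[:, selected_idx], y_train)
    proba = rf.predict_proba(X_val[:, selected_idx])[:, list(rf.classes_).index(pos)]
    pred = np.where(proba >= 0.5, pos, 1 - pos)
    is_pos = y_val == pos
    if is_pos.all() or (~is_pos).all():
        raise ValueError("validation set contains a single class")
    return RoundResult(
        round_index=round_index,
        selected_features=[],  # filled by caller (names)
        accuracy=float(np.mean(pred == y_val)),
        sensitivity=float(np.mean(pred[is_pos] == y_val[is_pos])),
        specificity=float(np.mean(pred[~is_pos] == y_val[~is_pos])),
        auc=float(roc_auc_score(is_pos.astype(int), proba)),
        validation_ids=list(validation_ids),
    )


def run_round(X: np.ndarray, y: np.ndarray, names: list[str], config: CVConfig,
              round_index: int) -> RoundResult:
    """One fully nested CV round, reproducible from (config.seed, round_index).

    Every input the selection and training stages see is sliced from the
    training rows before they run, so validation rows cannot leak.
    """
    ss = np.random.SeedSequence((config.seed, round_index))
    rng = np.random.default_rng(ss)
    rf_seed1, rf_seed2 = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    train_ids, val_ids = stratify_round(y, rng, config.train_fraction)
    X_train, y_train = X[train_ids], y[train_ids]
    selected = select_important(X_train, y_train, names, config, rf_seed1, rng)
    sel_idx = np.array([names.index(nm) for nm in selected])
    res = train_and_eval(X_train, y_train, X[val_ids], y[val_ids],
                         sel_idx, config, rf_seed2, round_index, list(map(int, val_ids)))
    res.selected_features = selected
    return res


def wilson_interval(p_hat: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p_hat <= 1:
        raise ValueError("p_hat must be in [0, 1]")
    z = float(norm.ppf(1 - (1 - conf) / 2))
    denom = 1 + z**2 / n
    center = (p_hat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2)) / denom
    lo = 0.0 if p_hat == 0 else max(center - half, 0.0)  # collapses exactly at the boundary
    hi = 1.0 if p_hat == 1 else min(center + half, 1.0)
    return (lo, hi)


def run_cv(fm: FeatureMatrix, labels: np.ndarray, config: CVConfig) -> CVSummary:
    """Full cross-validation over ``config.rounds`` rounds."""
    X = fm.values.to_numpy(dtype=float)
    names = fm.feature_names
    y = np.asarray(labels)
    results = [run_round(X, y, names, config, r) for r in range(config.rounds)]

    per_metric = {m: np.array([getattr(r, m) for r in results]) for m in METRICS}
    counts = pd.Series(0, index=pd.Index(names, name="feature"), dtype=int)
    for r in results:
        counts[r.selected_features] += 1
    n_val_total = sum(len(r.validation_ids) for r in results)
    return CVSummary(
        config=config,
        metrics_mean={m: float(v.mean()) for m, v in per_metric.items()},
        metrics_sd={m: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for m, v in per_metric.items()},
        wilson_ci=wilson_interval(float(per_metric["accuracy"].mean()), n_val_total),
        selection_counts=counts,
        n_validation_total=n_val_total,
        rounds=results,
    )
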