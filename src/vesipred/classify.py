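"""Standardization, gradient-boosted classification, metrics and CV protocol.

The classifier is XGBoost with the configuration selected for the
vesicular-transport benchmark: learning_rate 0.1, 1,000 trees of depth 8,
min_child_weight 1, gamma 0, row/column subsampling 0.8, binary-logistic
objective and scale_pos_weight 0.6 (the training set stays mildly
imbalanced after ENN cleaning, so positives are down-weighted slightly
below parity).

Two areas deserve care and are handled explicitly here:

* **Metric suite.**  Besides accuracy, sensitivity, specificity, precision
  and MCC, the benchmark's printed "AUC" formula is (Sens + Spec)/2 —
  balanced accuracy at the operating threshold, not the area under the ROC
  curve.  Both are computed and reported under distinct names
  (``balanced_auc`` and ``roc_auc``, the latter the trapezoidal area from the
  continuous scores).  Rates whose denominator class is empty are reported
  as NaN rather than silently zero; MCC follows the standard convention of
  0 when any factor of its denominator vanishes.
* **Leakage.**  ``run_cv`` resamples, standardizes and (optionally)
  selects features inside each training split only, and
  ``evaluate_holdout`` audits train/test id disjointness before fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from xgboost import XGBClassifier

from .imbalance import Resampler, make_resampled_folds
from .tables import FeatureTable

#: A feature selector is fitted on (z-scored) training data and returns the
#: column indices to keep, in order.
Selector = Callable[[FeatureTable], np.ndarray]


# ---------------------------------------------------------------------------
# Z-score standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizerState:
    """Per-feature means and standard deviations fitted on training data."""

    means: np.ndarray
    sds: np.ndarray


def zscore_fit(table: FeatureTable) -> StandardizerState:
    """Fit population-sd z-score parameters; constant features get sd 1."""
    if table.n_samples < 1:
        raise ValueError("cannot standardize an empty table")
    means = table.X.mean(axis=0)
    sds = table.X.std(axis=0)  # population sd (ddof=0)
    sds = np.where(sds == 0.0, 1.0, sds)
    return StandardizerState(means=means, sds=sds)


def zscore_apply(state: StandardizerState, table: FeatureTable) -> FeatureTable:
    """Apply stored standardization unchanged to any table."""
    if len(state.means) != table.n_features:
        raise ValueError("standardizer dimensionality does not match table")
    X = (table.X - state.means) / state.sds
    return FeatureTable(table.ids, X, table.y, table.feature_names)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    """XGBoost configuration; defaults are the benchmark's selected values."""

    learning_rate: float = 0.1
    n_estimators: int = 1000
    max_depth: int = 8
    min_child_weight: float = 1.0
    gamma: float = 0.0
    subsample: float = 0.8
    colsample_bytree: float = 0.8
    objective: str = "binary:logistic"
    n_threads: int = 1
    scale_pos_weight: float = 0.6
    seed: int = 0


@dataclass
class TrainedClassifier:
    """A fitted booster bound to its feature-name contract."""

    booster: XGBClassifier
    feature_names: tuple[str, ...]
    config: ClassifierConfig

    def _check(self, table: FeatureTable) -> None:
        if table.feature_names != self.feature_names:
            raise ValueError(
                "feature columns do not match the columns the model was "
                f"trained on ({table.n_features} vs {len(self.feature_names)})"
            )

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        """Probability of the positive (vesicular) class per sample."""
        self._check(table)
        return self.booster.predict_proba(table.X)[:, 1]

    def predict(self, table: FeatureTable, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(table) >= threshold).astype(int)


def train_classifier(
    table: FeatureTable, config: ClassifierConfig | None = None
) -> TrainedClassifier:
    """Fit the gradient-boosted classifier on a feature table.

    Deterministic given the config seed and single-threaded mode.  Inputs
    must be finite and both classes present.
    """
    config = config or ClassifierConfig()
    if len(np.unique(table.y)) < 2:
        raise ValueError("training requires both classes")
    if not np.isfinite(table.X).all():
        raise ValueError("training features contain NaN or infinite values")
    booster = XGBClassifier(
        learning_rate=config.learning_rate,
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        min_child_weight=config.min_child_weight,
        gamma=config.gamma,
        subsample=config.subsample,
        colsample_bytree=config.colsample_bytree,
        objective=config.objective,
        n_jobs=config.n_threads,
        scale_pos_weight=config.scale_pos_weight,
        random_state=config.seed,
        tree_method="hist",
        eval_metric="logloss",
    )
    booster.fit(table.X, table.y)
    return TrainedClassifier(booster=booster, feature_names=table.feature_names, config=config)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion(labels: Sequence[int], predictions: Sequence[int]) -> tuple[int, int, int, int]:
    """Confusion counts (tp, fp, tn, fn) with positive = vesicular = 1."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary 0/1")
    tp = int(((y == 1) & (p == 1)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    return tp, fp, tn, fn


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts plus the benchmark metric suite.

    Undefined rates (empty denominator class) are NaN, never silently 0;
    ``balanced_auc`` is (Sens + Spec)/2, balanced accuracy at the threshold,
    while ``roc_auc`` is the trapezoidal area under the score-based ROC.
    """

    tp: float
    fp: float
    tn: float
    fn: float
    acc: float
    sens: float
    spec: float
    precision: float
    mcc: float
    balanced_auc: float
    roc_auc: float
    threshold: float = 0.5

    _METRICS = ("acc", "sens", "spec", "precision", "mcc", "balanced_auc", "roc_auc")

    def to_dict(self) -> dict:
        return {
            k: float(getattr(self, k))
            for k in ("tp", "fp", "tn", "fn", *self._METRICS, "threshold")
        }

    def summary(self) -> str:
        lines = [
            f"n = {self.tp + self.fp + self.tn + self.fn:.0f}  "
            f"(TP {self.tp:.1f} | FP {self.fp:.1f} | TN {self.tn:.1f} | FN {self.fn:.1f})"
        ]
        for k in self._METRICS:
            lines.append(f"{k:>10}: {getattr(self, k):.4f}")
        return "\n".join(lines)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metric_suite(
    tp: float,
    fp: float,
    tn: float,
    fn: float,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    threshold: float = 0.5,
) -> EvalReport:
    """Compute the full metric suite from confusion counts.

    When continuous ``scores`` and ``labels`` are given, ``roc_auc`` is the
    trapezoidal area under their empirical ROC curve; otherwise NaN.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + fp + tn + fn
    if n < 1:
        raise ValueError("empty confusion table")
    acc = (tp + tn) / n
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, fp + tn)
    precision = _safe_div(tp, tp + fp)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    balanced_auc = (sens + spec) / 2.0
    roc_auc = float("nan")
    if scores is not None and labels is not None:
        labels = np.asarray(labels)
        if len(np.unique(labels)) == 2:
            roc_auc = float(roc_auc_score(labels, np.asarray(scores)))
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        acc=acc, sens=sens, spec=spec, precision=precision,
        mcc=mcc, balanced_auc=balanced_auc, roc_auc=roc_auc, threshold=threshold,
    )


def evaluate_scores(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """Threshold continuous scores and compute the full report."""
    preds = (np.asarray(scores) >= threshold).astype(int)
    tp, fp, tn, fn = confusion(labels, preds)
    return metric_suite(tp, fp, tn, fn, scores=scores, labels=labels, threshold=threshold)


def mean_report(reports: Sequence[EvalReport]) -> EvalReport:
    """Average per-fold reports metric-wise (NaN-aware), counts included."""
    if not reports:
        raise ValueError("no reports to average")
    fields = ("tp", "fp", "tn", "fn", *EvalReport._METRICS)
    vals = {
        f: float(np.nanmean([getattr(r, f) for r in reports])) for f in fields
    }
    return EvalReport(threshold=reports[0].threshold, **vals)


def roc_points(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(fpr, tpr, threshold) points of the empirical ROC, for export/plots."""
    fpr, tpr, thr = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr, thr])


# ---------------------------------------------------------------------------
# Cross-validation and holdout protocol
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold reports plus their average, for k-fold x repeats runs."""

    fold_reports: list[list[EvalReport]]  # [repeat][fold]
    report: EvalReport
    k: int
    repeats: int
    seed: int

    def repeat_means(self) -> list[EvalReport]:
        return [mean_report(folds) for folds in self.fold_reports]


def _fit_fold(
    train: FeatureTable,
    config: ClassifierConfig,
    selector: Selector | None,
) -> tuple[StandardizerState, np.ndarray | None, TrainedClassifier]:
    state = zscore_fit(train)
    train_z = zscore_apply(state, train)
    cols = None
    if selector is not None:
        cols = np.asarray(selector(train_z), dtype=int)
        train_z = train_z.select_features(cols)
    model = train_classifier(train_z, config)
    return state, cols, model


def _score_fold(
    state: StandardizerState,
    cols: np.ndarray | None,
    model: TrainedClassifier,
    table: FeatureTable,
    threshold: float,
) -> EvalReport:
    table_z = zscore_apply(state, table)
    if cols is not None:
        table_z = table_z.select_features(cols)
    scores = model.predict_proba(table_z)
    return evaluate_scores(table_z.y, scores, threshold=threshold)


def run_cv(
    table: FeatureTable,
    k: int = 5,
    config: ClassifierConfig | None = None,
    resampler: Resampler | None = None,
    repeats: int = 3,
    seed: int = 0,
    selector: Selector | None = None,
    threshold: float = 0.5,
) -> CVResult:
    """Repeated stratified k-fold CV with a leakage-free pipeline.

    Within each split: resample the training folds, fit z-scoring on the
    (resampled) training data, optionally fit the feature selector on the
    standardized training data, train the classifier, and score the
    untouched validation fold.  Repeats r = 0..repeats-1 reuse the protocol
    with seeds ``seed + r``.  Returns all per-fold reports and their mean.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    config = config or ClassifierConfig()
    all_reports: list[list[EvalReport]] = []
    for r in range(repeats):
        rep_seed = seed + r
        folds = make_resampled_folds(table, k, resampler, seed=rep_seed)
        fold_reports = []
        for train, val in folds:
            state, cols, model = _fit_fold(
                train, replace(config, seed=rep_seed), selector
            )
            fold_reports.append(_score_fold(state, cols, model, val, threshold))
        all_reports.append(fold_reports)
    flat = [rep for folds in all_reports for rep in folds]
    return CVResult(
        fold_reports=all_reports,
        report=mean_report(flat),
        k=k,
        repeats=repeats,
        seed=seed,
    )


@dataclass(frozen=True)
class PipelineSpec:
    """Train-side pipeline for holdout evaluation: resample -> z-score ->
    select -> train, all fitted on training data only."""

    resampler: Resampler | None = None
    selector: Selector | None = None
    threshold: float = 0.5


def evaluate_holdout(
    train_table: FeatureTable,
    test_table: FeatureTable,
    config: ClassifierConfig | None = None,
    pipeline: PipelineSpec | None = None,
) -> EvalReport:
    """Fit the full pipeline on the training table, report on the test table.

    Train and test ids must be disjoint (audited); the test table is never
    touched by resampling, standardization fitting or selection.
    """
    pipeline = pipeline or PipelineSpec()
    overlap = set(train_table.ids) & set(test_table.ids)
    if overlap:
        raise ValueError(
            f"train/test ids overlap ({len(overlap)} shared, e.g. "
            f"{sorted(overlap)[:3]}); holdout evaluation would leak"
        )
    train = pipeline.resampler(train_table) if pipeline.resampler else train_table
    state, cols, model = _fit_fold(train, config or ClassifierConfig(), pipeline.selector)
    return _score_fold(state, cols, model, test_table, pipeline.threshold)
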