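"""High-level Model/Results interface for the vesicular-transport classifier.

:class:`VesicleTransportModel` bundles the whole study pipeline — feature
encoding from PSSM profiles, ENN imbalance cleaning, MRMD feature
selection, z-score standardization and the gradient-boosted classifier —
behind a statsmodels-like surface: construct the model from data, call
``fit()``, and receive a :class:`VTPResults` object carrying the fitted
pipeline, cross-validation diagnostics and a ``summary()`` table.

Example
-------
>>> from vesipred import SyntheticDatasetSpec, simulate_profiles
>>> from vesipred.model import VesicleTransportModel
>>> profiles, labels = simulate_profiles(SyntheticDatasetSpec(60, 120, seed=7))
>>> model = VesicleTransportModel.from_profiles(profiles, labels)
>>> results = model.fit(k=5, repeats=1, seed=7)
>>> print(results.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import classify, imbalance, mrmd
from .profile_io import PSSMProfile
from .tables import FeatureTable, extract_features


def mrmd_selector(method: str = "score_sum", k: int | None = None) -> classify.Selector:
    """Build a training-data-only feature selector from an MRMD ranking.

    Returns a callable for :func:`vesipred.classify.run_cv`: given a
    training table it ranks features with the requested MRMD method and
    keeps the top ``k`` (all, ranked, when k is None).
    """

    def _select(train: FeatureTable) -> np.ndarray:
        ranking = mrmd.rank_features(train, method=method)
        keep = train.n_features if k is None else min(k, train.n_features)
        return ranking.top(keep)

    return _select


class VesicleTransportModel:
    """Gradient-boosted identification of vesicular transport proteins.

    Parameters
    ----------
    table
        Labeled feature table (1 = vesicular transport protein).
    config
        Classifier configuration; defaults to the benchmark's selection.
    resampler
        Training-fold resampler; defaults to ENN cleaning.  Pass
        ``imbalance.identity_resampler`` to disable.
    select_method, select_k
        MRMD ranking method and prefix size fitted inside each training
        split; ``select_k=None`` disables selection.
    """

    def __init__(
        self,
        table: FeatureTable,
        config: classify.ClassifierConfig | None = None,
        resampler: imbalance.Resampler | None = imbalance.enn_undersample,
        select_method: str = "hits_h",
        select_k: int | None = None,
    ) -> None:
        self.table = table
        self.config = config or classify.ClassifierConfig()
        self.resampler = resampler
        self.select_method = select_method
        self.select_k = select_k

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_profiles(
        cls,
        profiles: Iterable[PSSMProfile],
        labels: Sequence[int] | np.ndarray,
        encoder: str = "both",
        **kwargs,
    ) -> "VesicleTransportModel":
        """Build the model from PSSM profiles via the feature encoders."""
        return cls(extract_features(profiles, labels, encoder=encoder), **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        id_col: str = "id",
        label_col: str = "label",
        **kwargs,
    ) -> "VesicleTransportModel":
        return cls(FeatureTable.from_dataframe(df, id_col, label_col), **kwargs)

    # -- fitting ----------------------------------------------------------

    def _selector(self) -> classify.Selector | None:
        if self.select_k is None:
            return None
        return mrmd_selector(self.select_method, self.select_k)

    def fit(self, k: int = 5, repeats: int = 1, seed: int = 0) -> "VTPResults":
        """Cross-validate for diagnostics, then fit the final pipeline on
        all data.  Returns a results object; the model itself is unchanged."""
        selector = self._selector()
        cv = classify.run_cv(
            self.table,
            k=k,
            config=self.config,
            resampler=self.resampler,
            repeats=repeats,
            seed=seed,
            selector=selector,
        )
        train = self.resampler(self.table) if self.resampler else self.table
        state, cols, model = classify._fit_fold(
            train, replace(self.config, seed=seed), selector
        )
        return VTPResults(model_spec=self, cv=cv, standardizer=state,
                          selected_columns=cols, classifier=model, seed=seed)


@dataclass
class VTPResults:
    """Fitted pipeline plus cross-validation diagnostics."""

    model_spec: VesicleTransportModel
    cv: classify.CVResult
    standardizer: classify.StandardizerState
    selected_columns: np.ndarray | None
    classifier: classify.TrainedClassifier
    seed: int

    @property
    def report(self) -> classify.EvalReport:
        """Mean cross-validation report (average of per-fold metrics)."""
        return self.cv.report

    @property
    def selected_features(self) -> tuple[str, ...]:
        if self.selected_columns is None:
            return self.model_spec.table.feature_names
        return tuple(
            self.model_spec.table.feature_names[c] for c in self.selected_columns
        )

    # -- prediction -------------------------------------------------------

    def _transform(self, table: FeatureTable) -> FeatureTable:
        table = classify.zscore_apply(self.standardizer, table)
        if self.selected_columns is not None:
            table = table.select_features(self.selected_columns)
        return table

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        return self.classifier.predict_proba(self._transform(table))

    def predict(self, table: FeatureTable, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(table) >= threshold).astype(int)

    def predict_profiles(self, profiles: Iterable[PSSMProfile]) -> np.ndarray:
        """Probability of the vesicular class for raw profiles."""
        table = extract_features(profiles, encoder="both")
        return self.predict_proba(table)

    def evaluate(self, test_table: FeatureTable, threshold: float = 0.5) -> classify.EvalReport:
        """Score an untouched holdout table with the fitted pipeline."""
        overlap = set(self.model_spec.table.ids) & set(test_table.ids)
        if overlap:
            raise ValueError(f"holdout shares {len(overlap)} ids with training data")
        scores = self.predict_proba(test_table)
        return classify.evaluate_scores(test_table.y, scores, threshold=threshold)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Human-readable account of the fitted pipeline and CV metrics."""
        spec = self.model_spec
        resampler = spec.resampler.__name__ if spec.resampler else "none"
        n_sel = (
            len(self.selected_columns)
            if self.selected_columns is not None
            else spec.table.n_features
        )
        rep = self.report
        lines = [
            "Vesicular transport protein classifier",
            "=" * 48,
            f"samples:            {spec.table.n_samples} "
            f"({int(spec.table.y.sum())} positive)",
            f"features:           {spec.table.n_features} -> {n_sel} used",
            f"resampler:          {resampler}",
            f"selection:          {spec.select_method} "
            f"(k={spec.select_k if spec.select_k is not None else 'off'})",
            f"classifier:         XGBoost ({spec.config.n_estimators} trees, "
            f"depth {spec.config.max_depth}, eta {spec.config.learning_rate}, "
            f"scale_pos_weight {spec.config.scale_pos_weight})",
            f"cross-validation:   {self.cv.k}-fold x {self.cv.repeats} "
            f"(seed {self.seed})",
            "-" * 48,
            "mean cross-validation metrics",
            rep.summary(),
        ]
        return "\n".join(lines)

    def roc_points(self) -> np.ndarray:
        """Pooled out-of-fold ROC points from a fresh CV pass (fpr, tpr, thr)."""
        spec = self.model_spec
        folds = imbalance.make_resampled_folds(
            spec.table, self.cv.k, spec.resampler, seed=self.seed
        )
        labels, scores = [], []
        for train, val in folds:
            state, cols, model = classify._fit_fold(
                train, replace(spec.config, seed=self.seed), spec._selector()
            )
            val_z = classify.zscore_apply(state, val)
            if cols is not None:
                val_z = val_z.select_features(cols)
            labels.append(val_z.y)
            scores.append(model.predict_proba(val_z))
        return classify.roc_points(np.concatenate(labels), np.concatenate(scores))

    def plot_roc(self, ax=None):
        """Plot the pooled out-of-fold ROC curve (matplotlib Axes)."""
        import matplotlib.pyplot as plt

        pts = self.roc_points()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(pts[:, 0], pts[:, 1], label=f"ROC (AUC={self.report.roc_auc:.3f})")
        ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Versioned on-disk serialization (booster JSON + pipeline state)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        # persist the core booster (robust across sklearn-wrapper versions)
        self.classifier.booster.get_booster().save_model(directory / "booster.json")
        meta = {
            "format_version": 1,
            "seed": self.seed,
            "feature_names": list(self.model_spec.table.feature_names),
            "selected_columns": (
                self.selected_columns.tolist()
                if self.selected_columns is not None
                else None
            ),
            "standardizer": {
                "means": self.standardizer.means.tolist(),
                "sds": self.standardizer.sds.tolist(),
            },
            "config": self.classifier.config.__dict__,
            "select_method": self.model_spec.select_method,
            "select_k": self.model_spec.select_k,
        }
        (directory / "pipeline.json").write_text(json.dumps(meta))


def load_pipeline(directory: str | Path) -> "LoadedPipeline":
    """Load a pipeline saved by :meth:`VTPResults.save` for prediction."""
    import xgboost as xgb

    directory = Path(directory)
    meta = json.loads((directory / "pipeline.json").read_text())
    if meta.get("format_version") != 1:
        raise ValueError("unsupported pipeline format version")
    booster = xgb.Booster()
    booster.load_model(str(directory / "booster.json"))
    feature_names = tuple(meta["feature_names"])
    cols = meta["selected_columns"]
    selected = None if cols is None else np.asarray(cols, dtype=int)
    state = classify.StandardizerState(
        means=np.asarray(meta["standardizer"]["means"]),
        sds=np.asarray(meta["standardizer"]["sds"]),
    )
    return LoadedPipeline(
        standardizer=state, selected_columns=selected, booster=booster,
        feature_names=feature_names,
        config=classify.ClassifierConfig(**meta["config"]),
    )


@dataclass
class LoadedPipeline:
    """Prediction-only pipeline restored from disk."""

    standardizer: classify.StandardizerState
    selected_columns: np.ndarray | None
    booster: "object"  # xgboost.Booster
    feature_names: tuple[str, ...]
    config: classify.ClassifierConfig

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        import xgboost as xgb

        if table.feature_names != self.feature_names:
            raise ValueError("feature columns do not match the saved pipeline")
        table = classify.zscore_apply(self.standardizer, table)
        if self.selected_columns is not None:
            table = table.select_features(self.selected_columns)
        return np.asarray(self.booster.predict(xgb.DMatrix(table.X)), dtype=float)

    def predict(self, table: FeatureTable, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(table) >= threshold).astype(int)
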