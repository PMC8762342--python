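"""Class-imbalance resampling and leakage-free cross-validation folds.

The benchmark problem is heavily imbalanced (few vesicular transport
proteins among many non-vesicular ones).  This module implements the three
resamplers the pipeline actually uses:

* **Edited nearest neighbours (ENN)** — a cleaning undersampler that
  removes majority-class samples whose neighbourhood disagrees with their
  label.  It only deletes; the resulting class ratio is a data outcome, not
  a parameter.
* **Random undersampling** — majority rows subsampled without replacement
  to a target minority:majority ratio.
* **SMOTE** — synthetic minority oversampling by uniform interpolation
  between a minority sample and one of its k minority-class nearest
  neighbours.

Because oversamplers synthesize rows, naive k-fold cross-validation leaks:
a synthetic point interpolated from a validation sample carries its
information into training.  :func:`make_resampled_folds` therefore applies
the resampler to the k-1 training folds only, keeping every validation fold
untouched original data.

Neighbour queries are computed on z-scored features (population sd), since
Euclidean neighbourhoods are scale-sensitive and the downstream pipeline
standardizes features anyway.
"""

from __future__ import annotations

from typing import Callable, Iterator, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .tables import FeatureTable

#: A resampler maps a training FeatureTable to a resampled FeatureTable.
Resampler = Callable[[FeatureTable], FeatureTable]


def _check_two_classes(table: FeatureTable) -> None:
    if len(np.unique(table.y)) < 2:
        raise ValueError("resampling requires both classes to be present")


def _majority_label(y: np.ndarray) -> int:
    """Label with more samples; the negative class on ties (it is the
    majority in the motivating benchmark)."""
    n_pos = int((y == 1).sum())
    n_neg = len(y) - n_pos
    return 1 if n_pos > n_neg else 0


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd


def _neighbor_labels(X: np.ndarray, y: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Labels of each point's n nearest neighbours, excluding the point itself."""
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    # drop self; with exact duplicates self may not be first, so remove by index
    out = np.empty((len(y), n_neighbors), dtype=int)
    for i, row in enumerate(idx):
        row = row[row != i][:n_neighbors]
        if len(row) < n_neighbors:  # all-duplicate corner: self appeared twice
            row = idx[i][1 : n_neighbors + 1]
        out[i] = y[row]
    return out


def enn_undersample(
    table: FeatureTable, n_neighbors: int = 3, kind: str = "all"
) -> FeatureTable:
    """Edited-nearest-neighbours cleaning of the majority class.

    A majority-class sample is removed when its ``n_neighbors`` nearest
    neighbours (Euclidean on z-scored features, excluding itself) fail the
    agreement rule: with ``kind='all'`` any neighbour of a different class
    triggers removal; with ``kind='mode'`` removal requires the neighbour
    majority to differ.  Minority samples are never touched and no sample
    is ever synthesized.
    """
    _check_two_classes(table)
    if kind not in ("all", "mode"):
        raise ValueError("kind must be 'all' or 'mode'")
    n = table.n_samples
    if not 1 <= n_neighbors < n:
        raise ValueError(f"n_neighbors must be in [1, {n - 1}]")
    maj = _majority_label(table.y)
    nb_labels = _neighbor_labels(_zscore(table.X), table.y, n_neighbors)
    if kind == "all":
        agrees = (nb_labels == table.y[:, None]).all(axis=1)
    else:
        modes = stats.mode(nb_labels, axis=1, keepdims=False).mode
        agrees = modes == table.y
    keep = (table.y != maj) | agrees
    return table.take(np.flatnonzero(keep))


def random_undersample(
    table: FeatureTable, target_ratio: float = 1.0, seed: int = 0
) -> FeatureTable:
    """Subsample majority rows without replacement to a minority:majority ratio.

    ``target_ratio`` is the desired (minority count) / (majority count);
    1.0 balances the classes.  Deletion-only: the requested ratio must not
    exceed what removal can reach, and no row is ever altered.
    """
    _check_two_classes(table)
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    maj = _majority_label(table.y)
    maj_idx = np.flatnonzero(table.y == maj)
    min_idx = np.flatnonzero(table.y != maj)
    n_keep = int(round(len(min_idx) / target_ratio))
    if n_keep > len(maj_idx) or n_keep < 1:
        raise ValueError(
            f"target ratio {target_ratio} unreachable by deletion alone "
            f"({len(min_idx)} minority vs {len(maj_idx)} majority)"
        )
    rng = np.random.default_rng(seed)
    kept = rng.choice(maj_idx, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([min_idx, kept]))
    return table.take(keep)


def smote_oversample(
    table: FeatureTable, n_new: int, k_neighbors: int = 5, seed: int = 0
) -> FeatureTable:
    """SMOTE: synthesize minority samples by neighbour interpolation.

    Each of the ``n_new`` synthetic rows lies uniformly on the segment
    between a random minority sample and one of its ``k_neighbors`` nearest
    minority-class neighbours (Euclidean on z-scored features).  Originals
    are retained; synthetic rows get ids ``smote_<i>`` and the minority
    label.
    """
    _check_two_classes(table)
    if n_new < 1:
        raise ValueError("n_new must be >= 1")
    maj = _majority_label(table.y)
    min_idx = np.flatnonzero(table.y != maj)
    if len(min_idx) <= k_neighbors:
        raise ValueError(
            f"minority class has {len(min_idx)} samples; needs more than "
            f"k_neighbors={k_neighbors}"
        )
    minority_label = int(table.y[min_idx[0]])
    Xmin = table.X[min_idx]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(_zscore(table.X)[min_idx])
    _, nb = nn.kneighbors()
    nb = nb[:, :k_neighbors]
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(min_idx), size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    gap = rng.random(size=n_new)
    neighbors = nb[base, pick]
    X_new = Xmin[base] + gap[:, None] * (Xmin[neighbors] - Xmin[base])
    ids_new = np.array([f"smote_{i}" for i in range(n_new)], dtype=object)
    return FeatureTable(
        ids=np.concatenate([table.ids, ids_new]),
        X=np.vstack([table.X, X_new]),
        y=np.concatenate([table.y, np.full(n_new, minority_label)]),
        feature_names=table.feature_names,
    )


def identity_resampler(table: FeatureTable) -> FeatureTable:
    """No-op resampler; reduces make_resampled_folds to plain stratified CV."""
    return table


def make_resampled_folds(
    table: FeatureTable,
    k: int,
    resampler: Resampler | None = None,
    seed: int = 0,
) -> list[tuple[FeatureTable, FeatureTable]]:
    """Stratified k-fold splits with resampling confined to training folds.

    For each of the k iterations the resampler is applied to the union of
    the k-1 training folds ONLY; the validation fold is the untouched
    original data.  Over one pass the validation folds partition the input
    exactly, so no synthetic or removed-row artifact can ever reach a
    validation fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(table.y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"k={k} exceeds the smaller class size {counts.min()}; "
            "stratified folds would be empty"
        )
    resampler = resampler or identity_resampler
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_rows, val_rows in splitter.split(table.X, table.y):
        folds.append((resampler(table.take(train_rows)), table.take(val_rows)))
    return folds


def _not_implemented(name: str) -> Resampler:
    def _raise(table: FeatureTable) -> FeatureTable:
        raise NotImplementedError(
            f"{name} is declared for interface completeness but not "
            "implemented; the pipeline's selected resampler is ENN"
        )

    return _raise


#: Interface hooks for the resamplers the benchmark compared but did not
#: select; calling any of them raises NotImplementedError.
cluster_centroids = _not_implemented("ClusterCentroids")
near_miss = _not_implemented("NearMiss")
smote_enn = _not_implemented("SMOTEENN")
smote_tomek = _not_implemented("SMOTETomek")
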