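"""Labeled feature tables and profile-to-feature extraction.

A :class:`FeatureTable` bundles sample ids, an n x d feature matrix, binary
labels (1 = vesicular transport protein) and feature names, and reads/writes
the package's CSV convention: an ``id`` column, a ``label`` column, then one
column per feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aatp import AATP_NAMES, aatp as _encode_aatp
from .csp import CSP_NAMES, csp_segpsep_segacp as _encode_csp
from .profile_io import PSSMProfile, normalize_pssm

#: Recognized encoder names for extract_features.
ENCODERS = ("aatp", "csp", "both")


@dataclass
class FeatureTable:
    """n samples x d features with ids, binary labels and feature names."""

    ids: np.ndarray
    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, d = self.X.shape
        if len(self.ids) != n or len(self.y) != n:
            raise ValueError(
                f"row counts disagree: ids={len(self.ids)}, X={n}, y={len(self.y)}"
            )
        self.feature_names = tuple(self.feature_names)
        if len(self.feature_names) != d:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {d} columns"
            )
        if d < 1:
            raise ValueError("at least one feature is required")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def take(self, rows: Sequence[int] | np.ndarray) -> "FeatureTable":
        rows = np.asarray(rows)
        return FeatureTable(self.ids[rows], self.X[rows], self.y[rows], self.feature_names)

    def select_features(self, cols: Sequence[int] | np.ndarray) -> "FeatureTable":
        cols = np.asarray(cols, dtype=int)
        names = tuple(self.feature_names[c] for c in cols)
        return FeatureTable(self.ids, self.X[:, cols], self.y, names)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "label", self.y)
        df.insert(0, "id", self.ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, id_col: str = "id", label_col: str = "label"
    ) -> "FeatureTable":
        feature_cols = [c for c in df.columns if c not in (id_col, label_col)]
        return cls(
            ids=df[id_col].astype(str).to_numpy(dtype=object),
            X=df[feature_cols].to_numpy(dtype=float),
            y=df[label_col].to_numpy(dtype=int),
            feature_names=tuple(feature_cols),
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureTable":
        return cls.from_dataframe(pd.read_csv(path))


def extract_features(
    profiles: Iterable[PSSMProfile],
    labels: Sequence[int] | np.ndarray | None = None,
    encoder: str = "both",
) -> FeatureTable:
    """Encode profiles into a feature table.

    ``encoder`` is one of ``aatp`` (420 features), ``csp`` (700) or ``both``
    (1,120; AATP columns first).  Raw profiles are logistic-normalized on
    the fly; labels default to all zeros when not supplied (prediction-time
    tables).
    """
    if encoder not in ENCODERS:
        raise ValueError(f"unknown encoder {encoder!r}; expected one of {ENCODERS}")
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to encode")
    names: tuple[str, ...] = ()
    if encoder in ("aatp", "both"):
        names += AATP_NAMES
    if encoder in ("csp", "both"):
        names += CSP_NAMES
    rows = np.empty((len(profiles), len(names)))
    ids = []
    for k, prof in enumerate(profiles):
        if not prof.normalized:
            prof = normalize_pssm(prof)
        parts = []
        if encoder in ("aatp", "both"):
            parts.append(_encode_aatp(prof).values)
        if encoder in ("csp", "both"):
            parts.append(_encode_csp(prof).values)
        rows[k] = np.concatenate(parts)
        ids.append(prof.id)
    y = np.zeros(len(profiles), dtype=int) if labels is None else np.asarray(labels)
    return FeatureTable(ids=np.array(ids, dtype=object), X=rows, y=y, feature_names=names)
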