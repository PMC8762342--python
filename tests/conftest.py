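from __future__ import annotations

import numpy as np
import pytest

from vesipred import PSSMProfile, SyntheticDatasetSpec, normalize_pssm, simulate_profiles
from vesipred.tables import FeatureTable


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def make_profile(rng):
    """Factory for random normalized profiles of a given length."""

    def _make(L: int = 15, seed: int | None = None) -> PSSMProfile:
        gen = np.random.default_rng(seed) if seed is not None else rng
        raw = PSSMProfile(
            id=f"rand_L{L}",
            scores=np.clip(np.rint(gen.normal(0, 3, size=(L, 20))), -10, 13),
        )
        return normalize_pssm(raw)

    return _make


@pytest.fixture
def make_blob_table():
    """Factory for two-Gaussian-blob feature tables (for resampling tests)."""

    def _make(
        n_pos: int = 40,
        n_neg: int = 80,
        d: int = 5,
        separation: float = 6.0,
        seed: int = 0,
    ) -> FeatureTable:
        gen = np.random.default_rng(seed)
        X_pos = gen.normal(loc=separation, size=(n_pos, d))
        X_neg = gen.normal(loc=0.0, size=(n_neg, d))
        X = np.vstack([X_pos, X_neg])
        y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
        ids = np.array([f"s{i}" for i in range(n_pos + n_neg)], dtype=object)
        names = tuple(f"f{j}" for j in range(d))
        return FeatureTable(ids=ids, X=X, y=y, feature_names=names)

    return _make


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset shared by the slower pipeline tests."""
    spec = SyntheticDatasetSpec(
        n_positive=40, n_negative=60, length_range=(20, 40), seed=5
    )
    return simulate_profiles(spec)
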