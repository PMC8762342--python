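"""AATP encoding: amino-acid composition plus transition probability composition.

From a normalized L x 20 profile P this module extracts the classic
420-dimensional AATP vector:

* **AAC** (20 values): the per-column mean ``x_j = (1/L) sum_i P[i, j]``,
  the average propensity of positions to mutate into residue type *j*.
* **TPC** (400 values): from the transition probability matrix whose (i, j)
  entry accumulates products of consecutive-position scores,
  ``T[i, j] = sum_{k=1..L-1} P[k, i] * P[k+1, j]``, each source-residue row
  *i* normalized by its total so the 20 entries with fixed *i* sum to 1.
  TPC captures the local order structure that plain composition discards.

The TPC matrix is flattened row-major with the source residue *i* outer:
``X_11 ... X_1,20, X_21, ..., X_20,20``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profile_io import AA_ORDER, PSSMProfile

#: Stable names for the 420 AATP features, AAC block first.
AAC_NAMES = tuple(f"AAC_{a}" for a in AA_ORDER)
TPC_NAMES = tuple(f"TPC_{a}_{b}" for a in AA_ORDER for b in AA_ORDER)
AATP_NAMES = AAC_NAMES + TPC_NAMES


def _require_normalized(profile: PSSMProfile) -> np.ndarray:
    if not profile.normalized:
        raise ValueError(
            f"profile {profile.id!r} must be normalized before feature "
            "extraction (see normalize_pssm)"
        )
    return profile.scores


@dataclass(frozen=True)
class AATPVector:
    """The 420-dimensional AATP feature vector of one profile."""

    aac: np.ndarray  # 20
    tpc: np.ndarray  # 400, row-major over (source, target) pairs
    names: tuple[str, ...] = AATP_NAMES

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.aac, self.tpc])


def aac(profile: PSSMProfile) -> np.ndarray:
    """Per-column mean of the normalized profile (20 values)."""
    return _require_normalized(profile).mean(axis=0)


def tpc(profile: PSSMProfile) -> np.ndarray:
    """Row-normalized transition probabilities between consecutive rows.

    Returns 400 values flattened with the source residue outer.  A source
    row whose normalizer is zero (impossible for logistic-normalized input,
    kept defensive) yields 20 zeros.
    """
    P = _require_normalized(profile)
    if P.shape[0] < 2:
        raise ValueError(
            f"profile {profile.id!r}: TPC needs at least 2 rows, got {P.shape[0]}"
        )
    # T[i, j] = sum_k P[k, i] * P[k+1, j]
    T = P[:-1].T @ P[1:]
    denom = T.sum(axis=1, keepdims=True)
    out = np.divide(T, denom, out=np.zeros_like(T), where=denom != 0.0)
    return out.ravel()


def aatp(profile: PSSMProfile) -> AATPVector:
    """Concatenated [AAC | TPC] encoding, 20 + 400 = 420 features."""
    return AATPVector(aac=aac(profile), tpc=tpc(profile))
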