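"""Segmented pseudo-PSSM, autocovariance and consensus-sequence features.

The 700-dimensional encoding fuses three views of a normalized L x 20
profile P:

* **Segmented pseudo-PSSM** (380 values).  The profile is split into two
  segments (boundary at L1 = floor(L/2)) and, separately, three segments
  (L1 = floor(L/3); the remainder is absorbed by the last segment).  For
  each segment and column j the lag-0 statistic is the segment mean; for
  lag lambda > 0 it is the mean squared difference between entries lambda
  rows apart, ``mean_i (P[i, j] - P[i+lambda, j])^2`` over the lag-shortened
  window.  Two segments use lambda in 0..4 (2 x 20 x 5 = 200 values);
  three segments use lambda in 0..2 (3 x 20 x 3 = 180 values).
* **Segmented autocovariance transformation** (280 values).  For the same
  segmentations, the lag-lg autocovariance of each column around its
  segment mean m: ``mean_i (P[i, j] - m)(P[i+lg, j] - m)``.  Two segments
  use lg in 1..4 (160 values), three segments lg in 1..2 (120 values).
* **Consensus sequence features** (40 values).  The consensus sequence is
  the per-row argmax column; its composition (CSAAC, counts / L) and its
  composition moment (CSCM, sum of 1-based match positions divided by
  L*(L-1)) give 20 + 20 values.

Output ordering within each block is segment outer, lag middle, column
inner.  All blocks require L >= 10 so every lag window is non-empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aatp import _require_normalized
from .profile_io import AA_ORDER, PSSMProfile

PSE2_NAMES = tuple(
    f"PSE2_s{s}_lam{lam}_{a}" for s in (1, 2) for lam in range(5) for a in AA_ORDER
)
PSE3_NAMES = tuple(
    f"PSE3_s{s}_lam{lam}_{a}" for s in (1, 2, 3) for lam in range(3) for a in AA_ORDER
)
ACT2_NAMES = tuple(
    f"ACT2_s{s}_lg{lg}_{a}" for s in (1, 2) for lg in (1, 2, 3, 4) for a in AA_ORDER
)
ACT3_NAMES = tuple(
    f"ACT3_s{s}_lg{lg}_{a}" for s in (1, 2, 3) for lg in (1, 2) for a in AA_ORDER
)
CS_NAMES = tuple(f"CSAAC_{a}" for a in AA_ORDER) + tuple(f"CSCM_{a}" for a in AA_ORDER)
CSP_NAMES = PSE2_NAMES + PSE3_NAMES + ACT2_NAMES + ACT3_NAMES + CS_NAMES


@dataclass(frozen=True)
class ConsensusSequence:
    """Per-row argmax column of a profile (0-based indices into AA_ORDER)."""

    indices: np.ndarray

    @property
    def residues(self) -> str:
        return "".join(AA_ORDER[i] for i in self.indices)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class CSPVector:
    """The 700-dimensional fused segmented-profile feature vector."""

    psepssm2: np.ndarray  # 200
    psepssm3: np.ndarray  # 180
    act: np.ndarray  # 280 (two-segment 160 then three-segment 120)
    cs: np.ndarray  # 40
    names: tuple[str, ...] = CSP_NAMES

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.psepssm2, self.psepssm3, self.act, self.cs])


def _segment_bounds(L: int, n_segments: int) -> list[tuple[int, int]]:
    # remainder rows are absorbed by the last segment
    L1 = L // n_segments
    bounds = [(s * L1, (s + 1) * L1) for s in range(n_segments - 1)]
    bounds.append(((n_segments - 1) * L1, L))
    return bounds


def _check_segmentable(profile: PSSMProfile, n_segments: int) -> np.ndarray:
    P = _require_normalized(profile)
    if n_segments not in (2, 3):
        raise ValueError("n_segments must be 2 or 3")
    if P.shape[0] < 10:
        raise ValueError(
            f"profile {profile.id!r}: segmented encoders need L >= 10 "
            f"(got {P.shape[0]}) so every lag window is non-empty"
        )
    return P


def pse_pssm_segments(profile: PSSMProfile, n_segments: int) -> np.ndarray:
    """Segment-wise means and mean squared lag differences.

    200 values for two segments (lambda 0..4), 180 for three (lambda 0..2).
    """
    P = _check_segmentable(profile, n_segments)
    max_lam = 4 if n_segments == 2 else 2
    out: list[np.ndarray] = []
    for start, end in _segment_bounds(P.shape[0], n_segments):
        seg = P[start:end]
        out.append(seg.mean(axis=0))
        for lam in range(1, max_lam + 1):
            diff = seg[:-lam] - seg[lam:]
            out.append((diff * diff).mean(axis=0))
    return np.concatenate(out)


def act_segments(profile: PSSMProfile, n_segments: int) -> np.ndarray:
    """Per-segment, per-column autocovariance around the segment mean.

    160 values for two segments (lg 1..4), 120 for three (lg 1..2).
    """
    P = _check_segmentable(profile, n_segments)
    max_lg = 4 if n_segments == 2 else 2
    out: list[np.ndarray] = []
    for start, end in _segment_bounds(P.shape[0], n_segments):
        seg = P[start:end]
        m = seg.mean(axis=0)
        centered = seg - m
        for lg in range(1, max_lg + 1):
            out.append((centered[:-lg] * centered[lg:]).mean(axis=0))
    return np.concatenate(out)


def consensus_sequence(profile: PSSMProfile) -> ConsensusSequence:
    """Per-row argmax column; ties broken by the lowest column index.

    Valid for raw or normalized profiles: the logistic normalization is
    strictly monotone, so the argmax is identical either way.
    """
    return ConsensusSequence(indices=np.argmax(profile.scores, axis=1))


def cs_features(profile: PSSMProfile) -> np.ndarray:
    """Composition and composition moment of the consensus sequence (40).

    CSAAC_j is the fraction of consensus positions assigned to residue j;
    CSCM_j is the sum of the 1-based positions where the consensus equals j,
    divided by L*(L-1), weighting residues by where they occur.
    """
    L = profile.length
    if L < 2:
        raise ValueError(
            f"profile {profile.id!r}: consensus moment needs L >= 2 (got {L})"
        )
    idx = consensus_sequence(profile).indices
    csaac = np.bincount(idx, minlength=20) / L
    positions = np.arange(1, L + 1)
    cscm = np.bincount(idx, weights=positions, minlength=20) / (L * (L - 1))
    return np.concatenate([csaac, cscm])


def csp_segpsep_segacp(profile: PSSMProfile) -> CSPVector:
    """Fused 700-dimensional encoding: 200 + 180 + 280 + 40 values."""
    act2 = act_segments(profile, 2)
    act3 = act_segments(profile, 3)
    return CSPVector(
        psepssm2=pse_pssm_segments(profile, 2),
        psepssm3=pse_pssm_segments(profile, 3),
        act=np.concatenate([act2, act3]),
        cs=cs_features(profile),
    )
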