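"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain Python loops directly from the defining
formulas, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Feature encoders
# ---------------------------------------------------------------------------

def aac_ref(P: np.ndarray) -> np.ndarray:
    L = P.shape[0]
    out = np.zeros(20)
    for j in range(20):
        s = 0.0
        for i in range(L):
            s += P[i, j]
        out[j] = s / L
    return out


def tpc_ref(P: np.ndarray) -> np.ndarray:
    L = P.shape[0]
    out = np.zeros((20, 20))
    for i in range(20):
        denom = 0.0
        for jp in range(20):
            for k in range(L - 1):
                denom += P[k + 1, jp] * P[k, i]
        for j in range(20):
            num = 0.0
            for k in range(L - 1):
                num += P[k, i] * P[k + 1, j]
            out[i, j] = num / denom if denom != 0.0 else 0.0
    return out.ravel()


def _seg_bounds(L: int, n_seg: int) -> list[tuple[int, int]]:
    L1 = L // n_seg
    bounds = [(s * L1, (s + 1) * L1) for s in range(n_seg - 1)]
    bounds.append(((n_seg - 1) * L1, L))
    return bounds


def pse_pssm_ref(P: np.ndarray, n_seg: int) -> np.ndarray:
    max_lam = 4 if n_seg == 2 else 2
    out = []
    for start, end in _seg_bounds(P.shape[0], n_seg):
        for lam in range(max_lam + 1):
            for j in range(20):
                if lam == 0:
                    s = 0.0
                    for i in range(start, end):
                        s += P[i, j]
                    out.append(s / (end - start))
                else:
                    s = 0.0
                    for i in range(start, end - lam):
                        s += (P[i, j] - P[i + lam, j]) ** 2
                    out.append(s / (end - start - lam))
    return np.array(out)


def act_ref(P: np.ndarray, n_seg: int) -> np.ndarray:
    max_lg = 4 if n_seg == 2 else 2
    out = []
    for start, end in _seg_bounds(P.shape[0], n_seg):
        for lg in range(1, max_lg + 1):
            for j in range(20):
                m = 0.0
                for i in range(start, end):
                    m += P[i, j]
                m /= end - start
                s = 0.0
                for i in range(start, end - lg):
                    s += (P[i, j] - m) * (P[i + lg, j] - m)
                out.append(s / (end - start - lg))
    return np.array(out)


def cs_ref(P: np.ndarray) -> np.ndarray:
    L = P.shape[0]
    consensus = []
    for i in range(L):
        best, best_v = 0, P[i, 0]
        for j in range(1, 20):
            if P[i, j] > best_v:
                best, best_v = j, P[i, j]
        consensus.append(best)
    csaac = [consensus.count(j) / L for j in range(20)]
    cscm = []
    for j in range(20):
        s = sum(i + 1 for i, c in enumerate(consensus) if c == j)
        cscm.append(s / (L * (L - 1)))
    return np.array(csaac + cscm)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def metrics_ref(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Direct evaluation of the printed metric formulas."""
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
    spec = tn / (fp + tn) if fp + tn > 0 else float("nan")
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    auc = 0.5 * (sens + spec)
    return {
        "acc": acc, "sens": sens, "spec": spec,
        "precision": precision, "mcc": mcc, "balanced_auc": auc,
    }


# ---------------------------------------------------------------------------
# ENN
# ---------------------------------------------------------------------------

def enn_keep_ref(X: np.ndarray, y: np.ndarray, n_neighbors: int, kind: str) -> np.ndarray:
    """Per-point k-NN agreement check on z-scored features (boolean keep mask)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n = len(y)
    n_pos = int((y == 1).sum())
    majority = 1 if n_pos > n - n_pos else 0
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if y[i] != majority:
            continue
        dists = [(np.linalg.norm(Z[i] - Z[j]), j) for j in range(n) if j != i]
        dists.sort()
        nb = [y[j] for _, j in dists[:n_neighbors]]
        if kind == "all":
            agrees = all(l == y[i] for l in nb)
        else:
            counts = {0: nb.count(0), 1: nb.count(1)}
            mode = max(counts, key=lambda l: (counts[l], -l))
            # tie -> smaller label wins like scipy.stats.mode
            mode = 0 if counts[0] >= counts[1] else 1
            agrees = mode == y[i]
        keep[i] = agrees
    return keep
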