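"""Max-Relevance-Max-Distance (MRMD) feature ranking and subset selection.

MRMD scores each feature by two ingredients:

* **relevance** — the absolute Pearson correlation between the feature
  column and the binary label, in [0, 1];
* **distance** — the mean Euclidean distance between the (z-scored)
  feature column and every other feature column, rescaled to [0, 1] by the
  maximum.  Duplicated features contribute zero mutual distance, so a high
  distance score marks a feature as non-redundant.

``score_sum`` ranks features directly by relevance + distance.  The five
link-analysis methods aggregate three base orderings (relevance-only,
distance-only, and their sum) through a directed preference graph: an edge
u -> v exists when v outranks u on at least one base ordering, weighted by
the total score margin between the two features (see
:func:`_preference_weights`).  Nodes are then scored by the corresponding
centrality:

* ``pagerank`` — damped random walk (alpha 0.85); mass flows toward
  features that beat many others.
* ``trustrank`` — personalized PageRank restarted at trust seeds, the top
  decile of features by relevance.
* ``leaderrank`` — PageRank on the graph augmented with a ground node
  bidirectionally linked to every feature, which removes dangling-node
  pathologies.
* ``hits_a`` — HITS authority score, descending: authorities are features
  endorsed (outranked-against) by many others.
* ``hits_h`` — HITS hub score, ascending: a feature's hub score aggregates
  the authority of the features that beat it, so a small hub score marks a
  feature that is rarely beaten, and rarely by anything strong.

All centralities are deterministic power iterations (tolerance 1e-9, at
most 200 iterations); ties are broken by relevance, then feature index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .tables import FeatureTable

RANKING_METHODS = (
    "score_sum",
    "hits_a",
    "hits_h",
    "pagerank",
    "trustrank",
    "leaderrank",
)

_DAMPING = 0.85
_TOL = 1e-9
_MAX_ITER = 200


@dataclass(frozen=True)
class FeatureRanking:
    """An ordered permutation of feature indices with its ingredient scores."""

    order: np.ndarray
    relevance: np.ndarray
    distance: np.ndarray
    method: str

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "order": self.order.tolist(),
            "relevance": self.relevance.tolist(),
            "distance": self.distance.tolist(),
        }


@dataclass(frozen=True)
class SubsetSearchResult:
    """Best prefix size along a ranking, with the full CV score curve."""

    selected: np.ndarray
    k: int
    score_curve: tuple[tuple[int, float], ...]
    metric_name: str

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "selected": self.selected.tolist(),
            "metric_name": self.metric_name,
            "score_curve": [[k, float(s)] for k, s in self.score_curve],
        }


def relevance_scores(table: FeatureTable) -> np.ndarray:
    """|Pearson r| between each feature and the label; constant features -> 0."""
    if table.n_samples < 3:
        raise ValueError("relevance needs at least 3 samples")
    y = table.y.astype(float)
    if y.std() == 0.0:
        raise ValueError("labels are constant; relevance is undefined")
    Xc = table.X - table.X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    sy = np.sqrt((yc * yc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[sx == 0.0] = 0.0
    return np.abs(np.clip(r, -1.0, 1.0))


def distance_scores(table: FeatureTable) -> np.ndarray:
    """Mean Euclidean distance of each z-scored column to all others, in [0,1].

    The raw mean distances are rescaled by their maximum; a score near zero
    marks a feature that duplicates much of the rest of the table.
    """
    d = table.n_features
    if d < 2:
        raise ValueError("distance scores need at least 2 features")
    X = table.X
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd == 0.0, 1.0, sd)
    D = squareform(pdist(Z.T, metric="euclidean"))
    mean_dist = D.sum(axis=1) / (d - 1)
    top = mean_dist.max()
    return mean_dist / top if top > 0 else np.zeros(d)


def _base_orderings(rel: np.ndarray, dist: np.ndarray) -> list[np.ndarray]:
    idx = np.arange(len(rel))
    orders = []
    for score in (rel, dist, rel + dist):
        # descending score, ties by relevance then index
        orders.append(np.lexsort((idx, -rel, -score)))
    return orders


def _preference_weights(rel: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Margin-weighted preference graph: W[u, v] = total score margin by
    which v beats u over the three base score vectors.

    An edge u -> v exists exactly when v outranks u on at least one base
    ordering; its weight sums ``max(0, s_v - s_u)`` over the relevance,
    distance and sum score vectors.  Margins (rather than win counts) keep
    the centralities faithful to the effect sizes: a feature that beats
    another by a hair on one ordering contributes almost nothing, so the
    eigenvector methods cannot be captured by large blocks of
    near-indistinguishable features.
    """
    W = np.zeros((len(rel), len(rel)))
    for s in (rel, dist, rel + dist):
        W += np.maximum(s[None, :] - s[:, None], 0.0)
    return W


def _order_by(scores: np.ndarray, rel: np.ndarray, descending: bool = True) -> np.ndarray:
    idx = np.arange(len(scores))
    key = -scores if descending else scores
    return np.lexsort((idx, -rel, key))


def rank_features(table: FeatureTable, method: str = "score_sum") -> FeatureRanking:
    """Rank all features by an MRMD aggregation method.

    See the module docstring for the semantics of each method.  The output
    order is always a permutation of ``range(d)``.
    """
    if method not in RANKING_METHODS:
        raise ValueError(f"unknown ranking method {method!r}; expected one of {RANKING_METHODS}")
    rel = relevance_scores(table)
    dist = distance_scores(table)
    if method == "score_sum":
        order = _order_by(rel + dist, rel)
        return FeatureRanking(order=order, relevance=rel, distance=dist, method=method)

    d = table.n_features
    W = _preference_weights(rel, dist)
    G = nx.from_numpy_array(W, create_using=nx.DiGraph)

    if method in ("hits_a", "hits_h"):
        hubs, auths = nx.hits(G, max_iter=_MAX_ITER, tol=_TOL, normalized=True)
        if method == "hits_a":
            scores = np.array([auths[i] for i in range(d)])
            order = _order_by(scores, rel, descending=True)
        else:
            scores = np.array([hubs[i] for i in range(d)])
            order = _order_by(scores, rel, descending=False)
    elif method == "pagerank":
        pr = nx.pagerank(G, alpha=_DAMPING, tol=_TOL, max_iter=_MAX_ITER, weight="weight")
        order = _order_by(np.array([pr[i] for i in range(d)]), rel)
    elif method == "trustrank":
        n_seeds = max(1, d // 10)
        seeds = _order_by(rel, rel)[:n_seeds]
        personalization = {i: (1.0 if i in set(seeds.tolist()) else 0.0) for i in range(d)}
        pr = nx.pagerank(
            G,
            alpha=_DAMPING,
            personalization=personalization,
            tol=_TOL,
            max_iter=_MAX_ITER,
            weight="weight",
        )
        order = _order_by(np.array([pr[i] for i in range(d)]), rel)
    else:  # leaderrank
        ground = d
        G2 = G.copy()
        for i in range(d):
            G2.add_edge(ground, i, weight=1.0)
            G2.add_edge(i, ground, weight=1.0)
        pr = nx.pagerank(G2, alpha=_DAMPING, tol=_TOL, max_iter=_MAX_ITER, weight="weight")
        order = _order_by(np.array([pr[i] for i in range(d)]), rel)

    return FeatureRanking(order=order, relevance=rel, distance=dist, method=method)


def select_subset(
    table: FeatureTable,
    ranking: FeatureRanking,
    evaluator: Callable[[FeatureTable], float],
    k_grid: Sequence[int] | None = None,
    metric_name: str = "score",
) -> SubsetSearchResult:
    """Pick the best top-k prefix of a ranking by an evaluator callback.

    ``evaluator`` receives the table restricted to the top-k features and
    returns a scalar to maximize (typically a cross-validated metric).
    Ties prefer the smaller k.  The default grid is every 10th dimension
    from 20 up to d.
    """
    d = table.n_features
    if k_grid is None:
        k_grid = list(range(min(20, d), d + 1, 10))
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid is empty")
    if any(k < 1 or k > d for k in k_grid):
        raise ValueError(f"k_grid values must lie in [1, {d}]")
    curve: list[tuple[int, float]] = []
    for k in k_grid:
        sub = table.select_features(ranking.top(k))
        try:
            score = float(evaluator(sub))
        except Exception as exc:
            raise RuntimeError(f"evaluator failed at k={k}: {exc}") from exc
        curve.append((k, score))
    best_k, _ = max(curve, key=lambda ks: (ks[1], -ks[0]))
    return SubsetSearchResult(
        selected=ranking.top(best_k),
        k=best_k,
        score_curve=tuple(curve),
        metric_name=metric_name,
    )
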