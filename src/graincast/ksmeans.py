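"""Temporally weighted k-means grading (K-Smeans).

Each sample to be graded is a spatiotemporal feature matrix

    G_t = [x_{t-P}, ..., x_t, xhat_{t+1}, ..., xhat_{t+F}]  in R^{(P+F+1) x 3}

stacking P past standardized observations of the three quality
indicators, the current observation, and F forecaster outputs. Before
clustering, row tau is scaled by the sigmoid time-decay weight

    w(tau) = 2 / (1 + exp(lambda * |tau - t|))

(w = 1 at the anchor, decaying symmetrically with lag), and the weighted
matrix is flattened row-major (time-major). lambda = 0 reproduces plain
k-means on the unweighted window; large lambda collapses the feature to
the current observation alone.

Clustering is Lloyd's algorithm with deterministic maximin (farthest
point) initialization: the first center is the point nearest the global
mean, each next center the point with the greatest minimum distance to
the centers already chosen. The number of grades is selected by majority
vote of three validity indices (silhouette max, Davies-Bouldin min, Dunn
max); clusters are then ordered into grades by descending germination at
the anchor, and each grade is summarized by the min/max range of each
indicator over its members in original units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    InfeasibleKError,
    NotFittedError,
    ShapeError,
)
from .metrics import davies_bouldin, dunn, silhouette

__all__ = [
    "decay_weight", "decay_weights", "build_feature", "apply_weights",
    "init_centers_maximin", "KSmeans", "select_k", "grade_clusters",
    "assign_grade", "GradeTable",
]


def decay_weight(tau, t, lam: float):
    """Sigmoid time-decay weight ``2 / (1 + exp(lam * |tau - t|))``."""
    if lam < 0:
        raise ValueError("decay factor lambda must be >= 0")
    lag = np.abs(np.asarray(tau, dtype=float) - t)
    out = 2.0 / (1.0 + np.exp(lam * lag))
    return float(out) if out.ndim == 0 else out


def decay_weights(P: int, F: int, lam: float) -> np.ndarray:
    """Weights for the window rows tau = t-P .. t+F (length P+F+1)."""
    taus = np.arange(-P, F + 1, dtype=float)
    return decay_weight(taus, 0.0, lam)


def build_feature(history, forecasts, P: int, F: int) -> np.ndarray:
    """Assemble G_t from the last P+1 history rows and F forecast rows.

    ``history`` holds standardized observations up to and including the
    anchor (time-ascending, last row = x_t); ``forecasts`` holds the F
    forecast rows. Missing history is an error, never silent padding.
    """
    hist = np.atleast_2d(np.asarray(history, dtype=float))
    fc = np.asarray(forecasts, dtype=float)
    if F == 0:
        fc = fc.reshape(0, hist.shape[1])
    else:
        fc = np.atleast_2d(fc)
    if hist.shape[0] < P + 1:
        raise ShapeError(
            f"need {P + 1} history rows (P={P} past + current), got {hist.shape[0]}"
        )
    if fc.shape[0] != F:
        raise ShapeError(f"need exactly F={F} forecast rows, got {fc.shape[0]}")
    if F > 0 and fc.shape[1] != hist.shape[1]:
        raise ShapeError("history and forecasts disagree in indicator count")
    return np.vstack([hist[-(P + 1):], fc])


def apply_weights(feature: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scale row tau of G_t by w(tau), then flatten row-major."""
    G = np.atleast_2d(np.asarray(feature, dtype=float))
    w = np.asarray(weights, dtype=float)
    if len(w) != G.shape[0]:
        raise ShapeError(f"{len(w)} weights for {G.shape[0]} feature rows")
    return (G * w[:, None]).ravel()


def init_centers_maximin(vectors: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Deterministic farthest-point seeding.

    First center: the point nearest the global mean. Each subsequent
    center: the point maximizing the minimum distance to all chosen
    centers. The seed only breaks exact ties.
    """
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    distinct = np.unique(X, axis=0)
    if k > len(distinct):
        raise InfeasibleKError(f"k={k} exceeds {len(distinct)} distinct points")
    rng = np.random.default_rng(seed)

    def _pick(score):  # argmin with seeded tie-break
        best = np.flatnonzero(score == score.min())
        return best[0] if len(best) == 1 else rng.choice(best)

    center_idx = [_pick(np.linalg.norm(X - X.mean(axis=0), axis=1))]
    min_dist = np.linalg.norm(X - X[center_idx[0]], axis=1)
    for _ in range(1, k):
        nxt = _pick(-min_dist)
        center_idx.append(nxt)
        min_dist = np.minimum(min_dist, np.linalg.norm(X - X[nxt], axis=1))
    return X[center_idx].copy()


def _assign(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
    return d2.argmin(axis=1)  # argmin ties go to the lower cluster index


@dataclass
class KSmeans:
    """Lloyd's algorithm on decay-weighted window features."""

    k: int
    lam: float = 0.5
    max_iter: int = 300
    tol: float = 1e-6
    seed: int = 0

    centers_: np.ndarray | None = field(default=None, repr=False)
    labels_: np.ndarray | None = field(default=None, repr=False)
    wcss_history_: list = field(default_factory=list, repr=False)
    n_iter_: int = 0
    converged_: bool = False

    def fit(self, weighted_vectors: np.ndarray) -> "KSmeans":
        X = np.atleast_2d(np.asarray(weighted_vectors, dtype=float))
        if not np.isfinite(X).all():
            raise ValueError("features must be finite")
        if self.k < 1:
            raise InfeasibleKError("k must be >= 1")
        centers = init_centers_maximin(X, self.k, self.seed)
        self.wcss_history_ = []
        for it in range(1, self.max_iter + 1):
            labels = _assign(X, centers)
            # repair empty clusters with the point farthest from its center
            for c in range(self.k):
                if not (labels == c).any():
                    far = np.linalg.norm(X - centers[labels], axis=1).argmax()
                    centers[c] = X[far]
                    labels = _assign(X, centers)
            new_centers = np.array(
                [X[labels == c].mean(axis=0) for c in range(self.k)]
            )
            self.wcss_history_.append(
                float(((X - new_centers[labels]) ** 2).sum())
            )
            shift = np.linalg.norm(new_centers - centers, axis=1).max()
            centers = new_centers
            if shift < self.tol:
                self.converged_ = True
                break
        self.n_iter_ = it
        self.centers_ = centers
        self.labels_ = _assign(X, centers)
        return self

    def predict(self, weighted_vectors: np.ndarray) -> np.ndarray:
        if self.centers_ is None:
            raise NotFittedError("call fit() first")
        X = np.atleast_2d(np.asarray(weighted_vectors, dtype=float))
        if X.shape[1] != self.centers_.shape[1]:
            raise ShapeError("feature width differs from the fitted centers")
        return _assign(X, self.centers_)


def fit_ksmeans(features, k, lam=0.5, P=None, F=None, **kw) -> KSmeans:
    """Weight raw G_t matrices and fit; ``features`` is (n, P+F+1, 3) or flat."""
    feats = np.asarray(features, dtype=float)
    if feats.ndim == 3:
        P = feats.shape[1] - 1 - (F or 0) if P is None else P
        F = feats.shape[1] - 1 - P if F is None else F
        w = decay_weights(P, F, lam)
        feats = np.array([apply_weights(G, w) for G in feats])
    model = KSmeans(k=k, lam=lam, **kw)
    return model.fit(feats)


def select_k(weighted_vectors: np.ndarray, k_range, lam=0.5, seed=0,
             **kw) -> tuple[pd.DataFrame, int]:
    """Score every k by the three validity indices and vote.

    Returns (table, recommended_k). Vote: argmax silhouette, argmin
    Davies-Bouldin, argmax Dunn; majority wins, silhouette breaks ties.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k range")
    X = np.atleast_2d(np.asarray(weighted_vectors, dtype=float))
    rows = []
    for k in k_range:
        model = KSmeans(k=k, lam=lam, seed=seed, **kw).fit(X)
        rows.append(
            {
                "k": k,
                "silhouette": silhouette(X, model.labels_),
                "davies_bouldin": davies_bouldin(X, model.labels_),
                "dunn": dunn(X, model.labels_),
            }
        )
    table = pd.DataFrame(rows)
    votes = [
        int(table.loc[table["silhouette"].idxmax(), "k"]),
        int(table.loc[table["davies_bouldin"].idxmin(), "k"]),
        int(table.loc[table["dunn"].idxmax(), "k"]),
    ]
    counts = {k: votes.count(k) for k in set(votes)}
    best = max(counts.values())
    winners = [k for k, c in counts.items() if c == best]
    recommended = votes[0] if votes[0] in winners else winners[0]
    table.attrs["votes"] = {
        "silhouette": votes[0], "davies_bouldin": votes[1], "dunn": votes[2],
        "recommended": recommended,
    }
    return table, recommended


@dataclass
class GradeTable:
    """Per-grade indicator ranges plus member counts.

    ``ranges`` columns: level, then min/max per indicator (original
    units); ``counts`` columns: cluster, level, count. ``cluster_to_level``
    maps raw cluster index -> ordinal grade (0 = highest germination).
    """

    ranges: pd.DataFrame
    counts: pd.DataFrame
    cluster_to_level: dict


def grade_clusters(model: KSmeans, current_obs: np.ndarray,
                   indicator_names, germination_col: int = 0) -> GradeTable:
    """Summarize fitted clusters into an ordered grade table.

    ``current_obs`` is the (n, 3) matrix of the members' anchor-time
    observations in original units, aligned with the fitted samples.
    Grades are ordered by descending mean germination.
    """
    if model.labels_ is None:
        raise NotFittedError("model is not fitted")
    obs = np.atleast_2d(np.asarray(current_obs, dtype=float))
    labels = model.labels_
    if len(obs) != len(labels):
        raise ShapeError("current_obs and fitted labels disagree in length")
    germ_means = {
        c: obs[labels == c, germination_col].mean() for c in range(model.k)
    }
    order = sorted(germ_means, key=lambda c: -germ_means[c])
    cluster_to_level = {c: lvl for lvl, c in enumerate(order)}
    rows, count_rows = [], []
    for lvl, c in enumerate(order):
        members = obs[labels == c]
        row = {"level": lvl}
        for j, name in enumerate(indicator_names):
            row[f"{name}_min"] = members[:, j].min()
            row[f"{name}_max"] = members[:, j].max()
        rows.append(row)
        count_rows.append({"cluster": c, "level": lvl, "count": int((labels == c).sum())})
    return GradeTable(pd.DataFrame(rows), pd.DataFrame(count_rows), cluster_to_level)


def assign_grade(weighted_vector: np.ndarray, model: KSmeans,
                 grade_table: GradeTable) -> int:
    """Grade of the nearest center (ties break to the lower cluster index)."""
    label = int(model.predict(np.atleast_2d(weighted_vector))[0])
    return grade_table.cluster_to_level[label]
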