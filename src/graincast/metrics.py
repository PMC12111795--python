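"""Regression error metrics and internal clustering validity indices.

Regression metrics follow the standard printed forms:

* ``MSE = mean((yhat - y)^2)``, ``RMSE = sqrt(MSE)``, ``MAE = mean|yhat - y|``
* ``MAPE = 100%/n * sum |yhat - y| / |y|`` — terms with ``y = 0`` are
  excluded (the count is reported) rather than epsilon-padded
* ``SMAPE = 200%/n * sum |yhat - y| / (|yhat| + |y|)`` with 0/0 terms
  contributing 0
* ``MSPE = mean(((yhat - y)/y)^2)`` — the mean squared relative error;
  this companion of MAPE is implementation-defined here (conventions for
  it vary) and is flagged as such in reports

Clustering indices (Euclidean distances throughout):

* silhouette ``s(i) = (b(i) - a(i)) / max(a(i), b(i))`` averaged over
  samples; singleton-cluster points contribute 0
* Davies-Bouldin ``DB = (1/k) sum_i max_{j!=i} (S_i + S_j)/d(c_i, c_j)``
  with ``S_i`` the mean member-to-centroid distance
* Dunn ``DI = min pairwise single-linkage cluster distance / max cluster
  diameter``; all-singleton clusterings have zero diameter and return
  +inf with a warning
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import ShapeError, UndefinedMetricError

__all__ = [
    "mse", "rmse", "mae", "mape", "smape", "mspe",
    "regression_report", "silhouette", "davies_bouldin", "dunn",
]


def _check(y_true, y_pred):
    y = np.asarray(y_true, dtype=float).ravel()
    yh = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != yh.shape:
        raise ShapeError(f"length mismatch: {y.shape} vs {yh.shape}")
    if y.size == 0:
        raise UndefinedMetricError("empty input")
    return y, yh


def mse(y_true, y_pred) -> float:
    y, yh = _check(y_true, y_pred)
    return float(np.mean((yh - y) ** 2))


def rmse(y_true, y_pred) -> float:
    return float(np.sqrt(mse(y_true, y_pred)))


def mae(y_true, y_pred) -> float:
    y, yh = _check(y_true, y_pred)
    return float(np.mean(np.abs(yh - y)))


def mape(y_true, y_pred) -> float:
    """Mean absolute percentage error (%), zero-truth terms excluded."""
    y, yh = _check(y_true, y_pred)
    keep = y != 0
    if not keep.any():
        raise UndefinedMetricError("MAPE undefined: every true value is zero")
    return float(100.0 * np.mean(np.abs(yh[keep] - y[keep]) / np.abs(y[keep])))


def smape(y_true, y_pred) -> float:
    """Symmetric MAPE (%), in [0, 200]; 0/0 terms contribute 0."""
    y, yh = _check(y_true, y_pred)
    denom = np.abs(yh) + np.abs(y)
    terms = np.zeros_like(denom)
    nz = denom != 0
    terms[nz] = np.abs(yh[nz] - y[nz]) / denom[nz]
    return float(200.0 * np.mean(terms))


def mspe(y_true, y_pred) -> float:
    """Mean squared percentage (relative) error, zero-truth terms excluded."""
    y, yh = _check(y_true, y_pred)
    keep = y != 0
    if not keep.any():
        raise UndefinedMetricError("MSPE undefined: every true value is zero")
    return float(np.mean(((yh[keep] - y[keep]) / y[keep]) ** 2))


def regression_report(y_true, y_pred) -> dict:
    """All six regression metrics plus the comparison count n."""
    y, yh = _check(y_true, y_pred)
    report = {
        "mse": mse(y, yh),
        "rmse": rmse(y, yh),
        "mae": mae(y, yh),
        "smape": smape(y, yh),
        "n": int(y.size),
    }
    for name, fn in (("mape", mape), ("mspe", mspe)):
        try:
            report[name] = fn(y, yh)
        except UndefinedMetricError:
            report[name] = float("nan")
    return report


# -- clustering validity ------------------------------------------------------

def _pairwise(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _check_labels(points, labels):
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    lab = np.asarray(labels)
    if len(lab) != len(X):
        raise ShapeError("labels and points disagree in length")
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise UndefinedMetricError("validity indices need >= 2 clusters")
    return X, lab, uniq


def silhouette(points, labels) -> float:
    X, lab, uniq = _check_labels(points, labels)
    D = _pairwise(X)
    s = np.zeros(len(X))
    for i in range(len(X)):
        own = lab == lab[i]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton convention: s(i) = 0
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, lab == c].mean() for c in uniq if c != lab[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


def davies_bouldin(points, labels) -> float:
    X, lab, uniq = _check_labels(points, labels)
    cents = np.array([X[lab == c].mean(axis=0) for c in uniq])
    scatter = np.array(
        [np.linalg.norm(X[lab == c] - cents[i], axis=1).mean()
         for i, c in enumerate(uniq)]
    )
    k = len(uniq)
    ratios = np.zeros(k)
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if j == i:
                continue
            d = np.linalg.norm(cents[i] - cents[j])
            if d == 0:
                warnings.warn("coincident cluster centroids; DB index is +inf",
                              stacklevel=2)
                worst = np.inf
                break
            worst = max(worst, (scatter[i] + scatter[j]) / d)
        ratios[i] = worst
    return float(ratios.mean())


def dunn(points, labels) -> float:
    X, lab, uniq = _check_labels(points, labels)
    D = _pairwise(X)
    max_diam = 0.0
    for c in uniq:
        members = np.flatnonzero(lab == c)
        if len(members) > 1:
            max_diam = max(max_diam, D[np.ix_(members, members)].max())
    d_min = np.inf
    for i, ci in enumerate(uniq):
        for cj in uniq[i + 1:]:
            d_min = min(d_min, D[np.ix_(lab == ci, lab == cj)].min())
    if max_diam == 0:
        warnings.warn("all clusters are singletons; Dunn index is +inf",
                      stacklevel=2)
        return float("inf")
    return float(d_min / max_diam)
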