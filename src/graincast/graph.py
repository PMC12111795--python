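"""Correlation graph over series variables and graph-convolution primitives.

Every series variable (temperature, moisture, the three quality
indicators) is a node; the graph is fully connected with signed Pearson
correlations as edge weights, so any pair of variables can exchange
information directly. For message passing the adjacency gets unit
self-loops and symmetric degree normalization ``D^{-1/2} (A + I) D^{-1/2}``
with degrees taken on absolute weights (signed edges are kept — e.g. the
inhibitory coupling between germination and fatty acid — while the
normalization stays well defined).

A GCN layer propagates ``relu(A_norm H W + b)`` and then concatenates the
initial embedding ``h0`` back onto the output (a jump connection, so the
raw token survives arbitrarily deep stacks); the stack's per-layer outputs
are finally concatenated per node and linearly mixed back to model width.

The functions here are written against the dispatching ops in
:mod:`graincast.autodiff`, so they run identically on numpy arrays
(inference, inspection) and on autodiff tensors (training).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import autodiff as ad
from .exceptions import DegenerateSeriesError, ShapeError

__all__ = [
    "edge_weight",
    "correlation_adjacency",
    "normalize_adjacency",
    "VariableGraph",
    "build_graph",
    "gcn_layer",
    "aggregate_layers",
    "association_features",
]


def edge_weight(series_a, series_b) -> float:
    """Pearson correlation cov(a, b)/(sd_a sd_b) between two equal-length series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ShapeError("edge_weight needs two equal-length 1-D series, n >= 2")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateSeriesError("zero-variance series has no defined edge weight")
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    return float(np.clip(cov / (a.std() * b.std()), -1.0, 1.0))


def correlation_adjacency(samples: np.ndarray) -> np.ndarray:
    """Pairwise signed correlations of the columns of ``samples`` (zero diagonal).

    Zero-variance columns get weight 0 to every other node (a constant
    environmental setting in a single-condition panel is a valid input).
    """
    X = np.asarray(samples, dtype=float)
    n_vars = X.shape[1]
    adj = np.zeros((n_vars, n_vars))
    sd = X.std(axis=0)
    for i in range(n_vars):
        for j in range(i + 1, n_vars):
            if sd[i] == 0 or sd[j] == 0:
                continue
            adj[i, j] = adj[j, i] = edge_weight(X[:, i], X[:, j])
    return adj


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Add unit self-loops and apply symmetric degree normalization.

    Degrees are computed on absolute weights so signed edges cannot
    produce negative or zero degrees.
    """
    A = np.asarray(adjacency, dtype=float)
    A_loop = A.copy()
    np.fill_diagonal(A_loop, 1.0)
    deg = np.abs(A_loop).sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return d_inv_sqrt[:, None] * A_loop * d_inv_sqrt[None, :]


@dataclass
class VariableGraph:
    """Fully connected variable graph with correlation edge weights."""

    node_names: list
    adjacency: np.ndarray  # signed correlations, zero diagonal
    normalized_adjacency: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def with_extra_node(self, name: str, weight: float = 1.0) -> "VariableGraph":
        """Append a node connected to every existing node with ``weight``."""
        n = self.n_nodes
        adj = np.zeros((n + 1, n + 1))
        adj[:n, :n] = self.adjacency
        adj[n, :n] = adj[:n, n] = weight
        return VariableGraph(
            list(self.node_names) + [name], adj, normalize_adjacency(adj)
        )

    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            {"node_a": self.node_names[i], "node_b": self.node_names[j],
             "weight": self.adjacency[i, j]}
            for i in range(self.n_nodes)
            for j in range(i + 1, self.n_nodes)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    @classmethod
    def from_edge_list(cls, edges: pd.DataFrame) -> "VariableGraph":
        names = sorted(set(edges["node_a"]) | set(edges["node_b"]))
        idx = {n: i for i, n in enumerate(names)}
        adj = np.zeros((len(names), len(names)))
        for _, row in edges.iterrows():
            i, j = idx[row["node_a"]], idx[row["node_b"]]
            adj[i, j] = adj[j, i] = row["weight"]
        return cls(names, adj, normalize_adjacency(adj))


def build_graph(samples, node_names=None) -> VariableGraph:
    """Build the variable graph from a samples x variables matrix.

    ``samples`` may be a DataFrame (column names become node names) or a
    2-D array plus explicit ``node_names``. Edge weights should be fitted
    on the training split only; callers pass the training rows.
    """
    if isinstance(samples, pd.DataFrame):
        node_names = list(samples.columns)
        X = samples.to_numpy(dtype=float)
    else:
        X = np.asarray(samples, dtype=float)
        node_names = list(node_names or range(X.shape[1]))
    if X.shape[0] < 2:
        raise ShapeError("need >= 2 samples per variable to build the graph")
    adj = correlation_adjacency(X)
    return VariableGraph(node_names, adj, normalize_adjacency(adj))


def gcn_layer(a_norm, h, weight, bias, h0):
    """One propagation step: ``relu(A_norm H W + b)`` then jump-concat ``h0``.

    Shapes: ``a_norm`` (N, N); ``h`` (..., N, width_in); ``weight``
    (width_in, width_out); ``h0`` (..., N, D). Output width is
    width_out + D.
    """
    msg = ad.matmul(ad.matmul(a_norm, h), weight) + bias
    return ad.concat([ad.relu(msg), h0], axis=-1)


def aggregate_layers(layer_outputs, w_g):
    """Concatenate per-node outputs of all layers column-wise and mix by ``w_g``."""
    stacked = ad.concat(list(layer_outputs), axis=-1)
    return ad.matmul(stacked, w_g)


def association_features(env_tokens, proj_params, pool_query, n_heads: int = 1):
    """Condense environmental-variable tokens into one association row.

    ``env_tokens`` is (..., E, D): the embedded tokens of the designated
    environmental variables (temperature, moisture). Each token is run
    through its own multi-head self-attention (``proj_params`` is a list
    of ``(w_q, w_k, w_v)`` per variable; with a single token per call the
    attention reduces to that token's value projection), the outputs are
    stacked and pooled by an attention-weighted mean: scores come from
    the learned query ``pool_query`` (D,), softmaxed over the E rows.
    Returns (..., D), the feature row of the association node.
    """
    from .layers import scaled_dot_attention

    n_env = env_tokens.shape[-2]
    if n_env != len(proj_params):
        raise ShapeError(
            f"{n_env} environmental tokens but {len(proj_params)} projection sets"
        )
    attended = ad.concat(
        [
            scaled_dot_attention(
                env_tokens[(Ellipsis, slice(i, i + 1), slice(None))],
                *proj_params[i], n_heads=n_heads,
            )
            for i in range(n_env)
        ],
        axis=-2,
    )  # (..., E, D)
    scores = ad.matmul(attended, pool_query.reshape(-1, 1))  # (..., E, 1)
    weights = ad.softmax(scores.swapaxes(-1, -2), axis=-1)  # (..., 1, E)
    pooled = ad.matmul(weights, attended)  # (..., 1, D)
    return pooled.reshape(*pooled.shape[:-2], pooled.shape[-1])
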