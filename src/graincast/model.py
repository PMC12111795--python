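"""The SGCNiFormer forecaster: variable-token attention + graph branch + gate.

The model reads a lookback window ``X`` (T time steps x N variables; here
temperature, moisture, germination, fatty acid, bulk density), embeds each
variable's full series as one token, and runs two branches:

* an attention branch — multi-head self-attention across variable tokens
  with residual connections and layer normalization, then a feed-forward
  sublayer (the inverted-transformer arrangement);
* a graph branch — the correlation graph over variables, extended with one
  association node pooled from the environmental tokens, propagated
  through a stack of GCN layers with jump connections, then aggregated
  across layers back to model width.

A dynamic gate fuses the branches per dimension
(``K = gamma * H + (1 - gamma) * S``), and a shared per-variable linear
head maps the fused token to the forecast horizon. Ablation switches
reproduce the reduced models: ``use_gcn=False, use_dgm=False`` is the pure
token-attention forecaster (Model 1); ``use_gcn=True, use_dgm=False``
fuses the branches by their elementwise mean (Model 2).

Training is Adam on MSE over standardized values, chronological
70/15/15 window split, everything seeded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .exceptions import ConfigError, DataSizeError
from .graph import (
    VariableGraph,
    aggregate_layers,
    association_features,
    build_graph,
    gcn_layer,
)
from .layers import (
    dynamic_gate,
    embed_series,
    ffn,
    forecast_head,
    layer_norm,
    scaled_dot_attention,
)
from .metrics import regression_report
from .panel import INDICATORS, MODEL_VARIABLES, QualityPanel, TIME_COL, standardize

ASSOC_NODE = "_association"


@dataclass
class ModelConfig:
    """Hyperparameters of the forecaster.

    Defaults follow the training protocol used throughout this package:
    batch size 32, learning rate 1e-4, 3 GCN layers, 20 epochs, Adam.
    """

    variables: tuple = MODEL_VARIABLES
    env_variables: tuple = ("temperature_c", "moisture_pct")
    lookback: int = 4
    horizon: int = 2
    d_model: int = 32
    n_heads: int = 4
    d_ff: int = 64
    gcn_layers: int = 3
    lr: float = 1e-4
    batch_size: int = 32
    epochs: int = 20
    seed: int = 0
    use_gcn: bool = True
    use_dgm: bool = True
    gate_concat: bool = False
    learn_adjacency: bool = False

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ConfigError("d_model must be divisible by n_heads")
        if self.horizon < 1:
            raise ConfigError("horizon must be >= 1")
        if self.use_gcn and self.gcn_layers < 1:
            raise ConfigError("need >= 1 GCN layer when the graph branch is on")
        missing = set(self.env_variables) - set(self.variables)
        if missing:
            raise ConfigError(f"environmental variables not in variables: {missing}")


class SGCNiFormer:
    """Forecaster over variable tokens with a gated graph branch."""

    def __init__(self, config: ModelConfig, graph: VariableGraph):
        if list(graph.node_names) != list(config.variables):
            raise ConfigError("graph nodes must match config.variables in order")
        self.config = config
        self.graph = graph
        self.graph_ext = graph.with_extra_node(ASSOC_NODE, weight=1.0)
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(config.seed))

    # -- parameters -----------------------------------------------------------
    def _init_params(self, rng):
        cfg = self.config
        d, t, f = cfg.d_model, cfg.lookback, cfg.horizon

        def p(name, *shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
            self.params[name] = Tensor(
                rng.normal(0.0, scale, shape), requires_grad=True
            )

        def zeros(name, *shape):
            self.params[name] = Tensor(np.zeros(shape), requires_grad=True)

        def ones(name, *shape):
            self.params[name] = Tensor(np.ones(shape), requires_grad=True)

        p("embed_w", t, d)
        zeros("embed_b", d)
        for w in ("att_wq", "att_wk", "att_wv"):
            p(w, d, d)
        ones("ln1_gamma", d), zeros("ln1_beta", d)
        p("ffn_w1", d, cfg.d_ff), zeros("ffn_b1", cfg.d_ff)
        p("ffn_w2", cfg.d_ff, d), zeros("ffn_b2", d)
        ones("ln2_gamma", d), zeros("ln2_beta", d)
        if cfg.use_gcn:
            for i in range(len(cfg.env_variables)):
                for w in ("wq", "wk", "wv"):
                    p(f"assoc_{w}_{i}", d, d)
            p("assoc_pool_q", d, scale=1.0 / np.sqrt(d))
            for layer in range(cfg.gcn_layers):
                w_in = d if layer == 0 else 2 * d
                p(f"gcn_w{layer}", w_in, d)
                zeros(f"gcn_b{layer}", d)
            p("agg_wg", d + cfg.gcn_layers * 2 * d, d)
            if cfg.learn_adjacency:
                zeros("adj_delta", self.graph_ext.n_nodes, self.graph_ext.n_nodes)
        if cfg.use_dgm:
            # neutral start: zero gate parameters give gamma = 0.5 exactly,
            # so the fused model begins at the ungated mean of the branches
            # and learns to deviate from it
            gate_in = 2 * d if cfg.gate_concat else d
            zeros("gate_w", gate_in, d)
            zeros("gate_b", d)
        p("head_w", d, f)
        zeros("head_b", f)

    def _params_for(self, training: bool):
        if training:
            return self.params
        return {k: v.data for k, v in self.params.items()}

    # -- forward --------------------------------------------------------------
    def forward(self, x, params=None):
        """Map windows (..., T, N) to forecasts (..., horizon, N)."""
        cfg = self.config
        p = self.params if params is None else params
        h0 = embed_series(x, p["embed_w"], p["embed_b"])  # (..., N, D)
        att = scaled_dot_attention(
            h0, p["att_wq"], p["att_wk"], p["att_wv"], n_heads=cfg.n_heads
        )
        h = layer_norm(h0 + att, p["ln1_gamma"], p["ln1_beta"])
        h = layer_norm(
            h + ffn(h, p["ffn_w1"], p["ffn_b1"], p["ffn_w2"], p["ffn_b2"]),
            p["ln2_gamma"], p["ln2_beta"],
        )
        if cfg.use_gcn:
            s = self._graph_branch(h0, p)
            if cfg.use_dgm:
                _, k = dynamic_gate(
                    h, s, p["gate_w"], p["gate_b"], concat_input=cfg.gate_concat
                )
            else:
                k = (h + s) * 0.5  # Model 2: ungated mean of the branches
        else:
            k = h  # Model 1: attention branch only
        return forecast_head(k, p["head_w"], p["head_b"])

    def _graph_branch(self, h0, p):
        cfg = self.config
        n = len(cfg.variables)
        env_idx = [list(cfg.variables).index(v) for v in cfg.env_variables]
        env_tokens = ad.concat(
            [h0[(Ellipsis, slice(i, i + 1), slice(None))] for i in env_idx],
            axis=-2,
        )
        proj = [
            (p[f"assoc_wq_{i}"], p[f"assoc_wk_{i}"], p[f"assoc_wv_{i}"])
            for i in range(len(env_idx))
        ]
        assoc = association_features(
            env_tokens, proj, p["assoc_pool_q"], n_heads=cfg.n_heads
        )
        assoc_row = assoc.reshape(*assoc.shape[:-1], 1, assoc.shape[-1])
        g0 = ad.concat([h0, assoc_row], axis=-2)  # (..., N+1, D)
        a_norm = self.graph_ext.normalized_adjacency
        if cfg.learn_adjacency:
            a_norm = p["adj_delta"] + a_norm
        h_l = g0
        outputs = [g0]
        for layer in range(cfg.gcn_layers):
            h_l = gcn_layer(
                a_norm, h_l, p[f"gcn_w{layer}"], p[f"gcn_b{layer}"], g0
            )
            outputs.append(h_l)
        s_full = aggregate_layers(outputs, p["agg_wg"])  # (..., N+1, D)
        return s_full[(Ellipsis, slice(0, n), slice(None))]

    # -- training / inference -------------------------------------------------
    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(x, dtype=float), self._params_for(False))

    def fit(self, x_train: np.ndarray, y_train: np.ndarray) -> list[float]:
        """Adam/MSE training loop; returns the per-epoch loss history."""
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        opt = Adam(self.params.values(), lr=cfg.lr)
        n = len(x_train)
        history = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                pred = self.forward(Tensor(x_train[idx]))
                err = pred - Tensor(y_train[idx])
                loss = (err * err).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
        return history

    def snapshot(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def save(self, path) -> None:
        blob = {k: v.data.tolist() for k, v in self.params.items()}
        payload = {
            "config": asdict(self.config),
            "params": blob,
            "graph_nodes": list(self.graph.node_names),
            "graph_adjacency": self.graph.adjacency.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "SGCNiFormer":
        with open(path) as fh:
            payload = json.load(fh)
        cfg_dict = payload["config"]
        cfg_dict["variables"] = tuple(cfg_dict["variables"])
        cfg_dict["env_variables"] = tuple(cfg_dict["env_variables"])
        cfg = ModelConfig(**cfg_dict)
        from .graph import normalize_adjacency

        adj = np.asarray(payload["graph_adjacency"])
        graph = VariableGraph(
            payload["graph_nodes"], adj, normalize_adjacency(adj)
        )
        model = cls(cfg, graph)
        for k, v in payload["params"].items():
            model.params[k] = Tensor(np.asarray(v), requires_grad=True)
        return model


# -- windows, splits, end-to-end training -------------------------------------

def make_windows(panel: QualityPanel, config: ModelConfig):
    """Sliding (lookback, horizon) windows per (condition, replicate) series.

    Returns ``(X, Y, starts)`` with X (n, T, N), Y (n, horizon, N), and the
    window start times used for the chronological split. Windows are
    ordered by start time, then series key.
    """
    t_look, t_hor = config.lookback, config.horizon
    entries = []
    for key in panel.series_keys():
        series = panel.series(key)
        vals = series[list(config.variables)].to_numpy(dtype=float)
        times = series[TIME_COL].to_numpy()
        n_steps = len(series)
        for start in range(n_steps - t_look - t_hor + 1):
            entries.append(
                (
                    times[start],
                    key,
                    vals[start:start + t_look],
                    vals[start + t_look:start + t_look + t_hor],
                )
            )
    if not entries:
        raise DataSizeError(
            f"series too short for lookback={t_look} + horizon={t_hor}"
        )
    entries.sort(key=lambda e: (e[0], e[1]))
    x = np.stack([e[2] for e in entries])
    y = np.stack([e[3] for e in entries])
    starts = np.array([e[0] for e in entries])
    return x, y, starts


def chronological_split(n: int, train_frac=0.7, val_frac=0.15):
    """Index arrays for a leakage-free 70/15/15 split over time-ordered windows."""
    i_train = int(np.floor(train_frac * n))
    i_val = int(np.floor((train_frac + val_frac) * n))
    idx = np.arange(n)
    return idx[:i_train], idx[i_train:i_val], idx[i_val:]


@dataclass
class TrainedForecaster:
    model: SGCNiFormer
    panel_std: QualityPanel
    history: list
    splits: tuple
    windows: tuple  # (X, Y, starts)

    def forecast_after(self, history_window: np.ndarray) -> np.ndarray:
        """Standardized forecasts (horizon, N) following one lookback window."""
        return np.asarray(self.model.predict(history_window[None])[0])


def train_forecaster(panel: QualityPanel, config: ModelConfig) -> TrainedForecaster:
    """Standardize, build the training-split graph, train, and package up."""
    need = [v for v in config.variables if v not in panel.scaler]
    panel_std = standardize(panel, "zscore", columns=need) if need else panel
    x, y, starts = make_windows(panel_std, config)
    tr, va, te = chronological_split(len(x))
    train_end = starts[tr[-1]] if len(tr) else starts[0]
    horizon_span = (
        panel_std.df[TIME_COL].sort_values().unique()
    )
    # graph edges come from records the training windows could have seen
    step = horizon_span[1] - horizon_span[0] if len(horizon_span) > 1 else 1
    cutoff = train_end + (config.lookback + config.horizon - 1) * step
    train_rows = panel_std.df[panel_std.df[TIME_COL] <= cutoff]
    graph = build_graph(train_rows[list(config.variables)])
    model = SGCNiFormer(config, graph)
    history = model.fit(x[tr], y[tr])
    return TrainedForecaster(model, panel_std, history, (tr, va, te), (x, y, starts))


def persistence_forecast(x: np.ndarray, horizon: int) -> np.ndarray:
    """Repeat the last observed row of each window across the horizon."""
    return np.repeat(x[:, -1:, :], horizon, axis=1)


def evaluate_forecaster(tf: TrainedForecaster, split: str = "test") -> dict:
    """Per-variable and pooled metric reports (standardized space).

    Includes the persistence baseline under ``"persistence"``. The pooled
    scope covers the three quality indicators.
    """
    x, y, _ = tf.windows
    idx = {"train": tf.splits[0], "val": tf.splits[1], "test": tf.splits[2]}[split]
    if len(idx) == 0:
        raise DataSizeError(f"empty {split!r} split")
    pred = np.asarray(tf.model.predict(x[idx]))
    base = persistence_forecast(x[idx], tf.model.config.horizon)
    truth = y[idx]
    variables = list(tf.model.config.variables)
    ind_cols = [variables.index(v) for v in INDICATORS if v in variables]
    report = {"model": {}, "persistence": {}}
    for name, yhat in (("model", pred), ("persistence", base)):
        per_var = {
            v: regression_report(truth[..., j], yhat[..., j])
            for j, v in enumerate(variables)
        }
        per_var["pooled_indicators"] = regression_report(
            truth[..., ind_cols], yhat[..., ind_cols]
        )
        report[name] = per_var
    return report


def ablation_configs(config: ModelConfig) -> dict[str, ModelConfig]:
    """The full model plus the two reduced models used in ablation studies."""
    return {
        "full": replace(config, use_gcn=True, use_dgm=True),
        "model2": replace(config, use_gcn=True, use_dgm=False),
        "model1": replace(config, use_gcn=False, use_dgm=False),
    }
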