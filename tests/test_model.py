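"""Forecaster components, training loop contracts and ablation switches."""

import dataclasses

import numpy as np
import pytest

from graincast.autodiff import sigmoid
from graincast.exceptions import ConfigError, DataSizeError, ShapeError
from graincast.graph import build_graph
from graincast.layers import (
    dynamic_gate,
    embed_series,
    ffn,
    forecast_head,
    layer_norm,
    scaled_dot_attention,
)
from graincast.metrics import regression_report
from graincast.model import (
    ModelConfig,
    SGCNiFormer,
    chronological_split,
    evaluate_forecaster,
    make_windows,
    persistence_forecast,
    train_forecaster,
)
from graincast.panel import MODEL_VARIABLES, standardize


class TestEmbedding:
    def test_zero_window_zero_tokens(self, rng):
        w = rng.normal(size=(6, 4))
        out = embed_series(np.zeros((6, 3)), w, np.zeros(4))
        np.testing.assert_array_equal(out, np.zeros((3, 4)))

    def test_identical_variables_identical_tokens(self, rng):
        x = rng.normal(size=6)
        window = np.column_stack([x, x, rng.normal(size=6)])
        out = embed_series(window, rng.normal(size=(6, 4)), rng.normal(size=4))
        np.testing.assert_array_equal(out[0], out[1])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_per_variable_dot_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t, n, d = 5, 3, 4
        x = rng.normal(size=(t, n))
        w, b = rng.normal(size=(t, d)), rng.normal(size=d)
        got = embed_series(x, w, b)
        for var in range(n):
            np.testing.assert_allclose(got[var], x[:, var] @ w + b, atol=1e-6)

    def test_wrong_length_raises(self, rng):
        with pytest.raises(ShapeError):
            embed_series(np.zeros((5, 3)), rng.normal(size=(6, 4)),
                         np.zeros(4))


class TestAttention:
    def test_single_token_is_value_projection(self, rng):
        d = 4
        h = rng.normal(size=(1, d))
        wv = rng.normal(size=(d, d))
        out = scaled_dot_attention(h, rng.normal(size=(d, d)),
                                   rng.normal(size=(d, d)), wv, n_heads=2)
        np.testing.assert_allclose(out, h @ wv, atol=1e-12)

    def test_zero_query_uniform_weights(self, rng):
        d, n = 4, 5
        h = rng.normal(size=(n, d))
        wv = rng.normal(size=(d, d))
        out = scaled_dot_attention(h, np.zeros((d, d)),
                                   rng.normal(size=(d, d)), wv, n_heads=1)
        np.testing.assert_allclose(out, np.tile((h @ wv).mean(axis=0), (n, 1)),
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_manual_softmax_sum(self, seed):
        rng = np.random.default_rng(seed)
        n, d = 3, 2
        h = rng.normal(size=(n, d))
        wq, wk, wv = (rng.normal(size=(d, d)) for _ in range(3))
        got = scaled_dot_attention(h, wq, wk, wv, n_heads=1)
        q, k, v = h @ wq, h @ wk, h @ wv
        for i in range(n):
            logits = q[i] @ k.T / np.sqrt(d)
            w = np.exp(logits - logits.max())
            w /= w.sum()
            np.testing.assert_allclose(got[i], w @ v, atol=1e-6)

    def test_head_divisibility(self, rng):
        with pytest.raises(ConfigError):
            scaled_dot_attention(rng.normal(size=(2, 5)), np.eye(5), np.eye(5),
                                 np.eye(5), n_heads=2)


class TestFfn:
    def test_identity_on_nonnegative(self):
        h = np.array([[0.5, 2.0]])
        out = ffn(h, np.eye(2), np.zeros(2), np.eye(2), np.zeros(2))
        np.testing.assert_allclose(out, h)

    def test_relu_kill_leaves_second_bias(self, rng):
        h = np.array([[1.0, 1.0]])
        b2 = rng.normal(size=2)
        out = ffn(h, -10.0 * np.eye(2), np.zeros(2), np.eye(2), b2)
        np.testing.assert_allclose(out[0], b2)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d, dff = 3, 5
        h = rng.normal(size=(4, d))
        w1, b1 = rng.normal(size=(d, dff)), rng.normal(size=dff)
        w2, b2 = rng.normal(size=(dff, d)), rng.normal(size=d)
        got = ffn(h, w1, b1, w2, b2)
        for row in range(4):
            hidden = np.maximum(h[row] @ w1 + b1, 0.0)
            np.testing.assert_allclose(got[row], hidden @ w2 + b2, atol=1e-6)


class TestDynamicGate:
    def test_saturated_bias_selects_branches(self, rng):
        d = 4
        h, s = rng.normal(size=(3, d)), rng.normal(size=(3, d))
        gamma, k = dynamic_gate(h, s, np.zeros((d, d)), np.full(d, 50.0))
        np.testing.assert_allclose(gamma, 1.0, atol=1e-9)
        np.testing.assert_allclose(k, h, atol=1e-7)
        gamma, k = dynamic_gate(h, s, np.zeros((d, d)), np.full(d, -50.0))
        np.testing.assert_allclose(gamma, 0.0, atol=1e-9)
        np.testing.assert_allclose(k, s, atol=1e-7)

    def test_zero_parameters_give_exact_mean(self, rng):
        d = 4
        h, s = rng.normal(size=(3, d)), rng.normal(size=(3, d))
        gamma, k = dynamic_gate(h, s, np.zeros((d, d)), np.zeros(d))
        np.testing.assert_array_equal(gamma, np.full((3, d), 0.5))
        np.testing.assert_array_equal(k, (h + s) / 2.0)

    def test_equal_branches_fixed_point(self, rng):
        d = 4
        h = rng.normal(size=(3, d))
        _, k = dynamic_gate(h, h, rng.normal(size=(d, d)),
                            rng.normal(size=d))
        np.testing.assert_allclose(k, h, atol=1e-12)

    def test_gate_in_unit_interval_and_convex(self, rng):
        d = 4
        h, s = rng.normal(size=(5, d)), rng.normal(size=(5, d))
        gamma, k = dynamic_gate(h, s, rng.normal(size=(d, d)),
                                rng.normal(size=d))
        assert ((gamma > 0) & (gamma < 1)).all()
        lo, hi = np.minimum(h, s), np.maximum(h, s)
        assert ((k >= lo - 1e-12) & (k <= hi + 1e-12)).all()

    def test_concat_variant_matches_manual(self, rng):
        d = 3
        h, s = rng.normal(size=(2, d)), rng.normal(size=(2, d))
        w = rng.normal(size=(2 * d, d))
        b = rng.normal(size=d)
        gamma, _ = dynamic_gate(h, s, w, b, concat_input=True)
        manual = sigmoid(np.concatenate([h, s], axis=-1) @ w + b)
        np.testing.assert_allclose(gamma, manual, atol=1e-12)


class TestForecastHead:
    def test_zero_input_zero_bias(self):
        out = forecast_head(np.zeros((3, 4)), np.zeros((4, 2)), np.zeros(2))
        np.testing.assert_array_equal(out, np.zeros((2, 3)))

    def test_constant_bias_head(self, rng):
        k = rng.normal(size=(3, 4))
        out = forecast_head(k, np.zeros((4, 2)), np.array([1.5, -2.0]))
        np.testing.assert_allclose(out, [[1.5] * 3, [-2.0] * 3])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, d, f = 3, 4, 2
        k = rng.normal(size=(n, d))
        w, b = rng.normal(size=(d, f)), rng.normal(size=f)
        got = forecast_head(k, w, b)
        for var in range(n):
            np.testing.assert_allclose(got[:, var], k[var] @ w + b, atol=1e-6)


# ------------------------------------------------------------ whole model


def _tiny_trained(panel, config):
    return train_forecaster(panel, config)


def test_variable_permutation_equivariance(dense_clean_panel, rng):
    """Permuting input variables permutes forecasts identically."""
    cfg = ModelConfig(d_model=8, n_heads=2, gcn_layers=2, epochs=1, seed=0)
    panel_std = standardize(dense_clean_panel, columns=list(MODEL_VARIABLES))
    x, _, _ = make_windows(panel_std, cfg)
    graph = build_graph(panel_std.df[list(cfg.variables)])
    model = SGCNiFormer(cfg, graph)
    perm = rng.permutation(len(cfg.variables))
    vars_p = tuple(np.array(cfg.variables)[perm])
    cfg_p = dataclasses.replace(cfg, variables=vars_p)
    graph_p = build_graph(panel_std.df[list(vars_p)])
    model_p = SGCNiFormer(cfg_p, graph_p)
    model_p.params = {k: v for k, v in model.params.items()}
    base = model.predict(x[:4])
    permuted = model_p.predict(x[:4][..., perm])
    np.testing.assert_allclose(permuted, base[..., perm], atol=1e-8)


def test_zero_lr_leaves_parameters(dense_clean_panel):
    cfg = ModelConfig(d_model=8, n_heads=2, gcn_layers=1, epochs=3, lr=0.0,
                      seed=1)
    tf = _tiny_trained(dense_clean_panel, cfg)
    fresh = SGCNiFormer(cfg, tf.model.graph)
    for k, v in fresh.params.items():
        np.testing.assert_array_equal(tf.model.params[k].data, v.data)


def test_single_window_overfit():
    """Capacity sanity: one window memorized at high learning rate."""
    rng = np.random.default_rng(0)
    cfg = ModelConfig(d_model=8, n_heads=2, gcn_layers=1, epochs=500,
                      lr=1e-2, seed=0, lookback=4, horizon=2)
    x = rng.normal(size=(1, 4, 5))
    y = rng.normal(size=(1, 2, 5))
    graph = build_graph(rng.normal(size=(20, 5)), list(cfg.variables))
    model = SGCNiFormer(cfg, graph)
    history = model.fit(x, y)
    assert history[-1] < 1e-3


def test_seed_reproducibility(dense_clean_panel):
    cfg = ModelConfig(d_model=8, n_heads=2, gcn_layers=1, epochs=2, seed=3)
    a = _tiny_trained(dense_clean_panel, cfg)
    b = _tiny_trained(dense_clean_panel, cfg)
    assert a.history == b.history
    assert len(a.history) == cfg.epochs


def test_ablation_switches_change_architecture(dense_clean_panel):
    cfg = ModelConfig(d_model=8, n_heads=2, gcn_layers=1, epochs=1, seed=0)
    m1 = dataclasses.replace(cfg, use_gcn=False, use_dgm=False)
    m2 = dataclasses.replace(cfg, use_gcn=True, use_dgm=False)
    tf1 = _tiny_trained(dense_clean_panel, m1)
    tf2 = _tiny_trained(dense_clean_panel, m2)
    assert "gcn_w0" not in tf1.model.params
    assert "gate_w" not in tf2.model.params and "gcn_w0" in tf2.model.params


def test_too_short_series_raises(small_panel):
    cfg = ModelConfig(lookback=6, horizon=2)
    with pytest.raises(DataSizeError):
        make_windows(standardize(small_panel, columns=list(MODEL_VARIABLES)),
                     cfg)


def test_chronological_split_ordering():
    tr, va, te = chronological_split(100)
    assert len(tr) == 70 and len(va) == 15 and len(te) == 15
    assert tr.max() < va.min() <= va.max() < te.min()


def test_evaluate_reports_match_metrics_module(dense_clean_panel):
    cfg = ModelConfig(d_model=8, n_heads=2, gcn_layers=1, epochs=2, seed=0)
    tf = _tiny_trained(dense_clean_panel, cfg)
    report = evaluate_forecaster(tf, "test")
    x, y, _ = tf.windows
    te = tf.splits[2]
    pred = np.asarray(tf.model.predict(x[te]))
    j = list(cfg.variables).index("germination_pct")
    manual = regression_report(y[te][..., j], pred[..., j])
    for key, val in manual.items():
        got = report["model"]["germination_pct"][key]
        assert got == pytest.approx(val, nan_ok=True)


def test_perfect_model_scores_zero(dense_clean_panel):
    cfg = ModelConfig(d_model=8, n_heads=2, gcn_layers=1, epochs=1, seed=0)
    tf = _tiny_trained(dense_clean_panel, cfg)
    x, y, _ = tf.windows
    base = persistence_forecast(x, cfg.horizon)
    assert base.shape == y.shape
    rep = regression_report(y, y)
    assert rep["mse"] == rep["mae"] == 0.0


def test_checkpoint_round_trip(tmp_path, dense_clean_panel):
    cfg = ModelConfig(d_model=8, n_heads=2, gcn_layers=1, epochs=1, seed=0)
    tf = _tiny_trained(dense_clean_panel, cfg)
    path = tmp_path / "model.json"
    tf.model.save(path)
    back = SGCNiFormer.load(path)
    x, _, _ = tf.windows
    np.testing.assert_allclose(back.predict(x[:3]), tf.model.predict(x[:3]),
                               atol=1e-12)
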