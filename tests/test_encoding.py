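"""Encoding models: gradient descent, early stopping, bootstrap, prediction."""

import numpy as np
import pytest

from visenc import (
    AlignmentError,
    DataError,
    DesignMatrix,
    EncodingModel,
    ResponseMatrix,
    TrainConfig,
    fit_region,
    fit_voxel,
    predict,
)


def _design(rng, p, q, prefix="c"):
    return DesignMatrix(
        rng.standard_normal((p, q)),
        [f"{prefix}{j}" for j in range(q)],
        [f"s{i}" for i in range(p)],
    )


def test_constant_response_returns_degenerate_model():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((200, 50))
    kernel, constant, diag = fit_voxel(X, np.full(200, 3.7), TrainConfig(seed=0))
    assert np.max(np.abs(kernel)) < 0.05
    assert constant == pytest.approx(3.7, abs=0.05)
    assert diag["degenerate"]


def test_noiseless_kernel_matches_least_squares_oracle():
    """On noiseless dense data the early-stopped kernel points where OLS points."""
    rng = np.random.default_rng(1)
    p, q = 500, 50
    X = rng.standard_normal((p, q))
    h = rng.standard_normal(q)
    y = X @ h + 1.3
    kernel, constant, _ = fit_voxel(X, y, TrainConfig(seed=0))
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = np.column_stack([(X - mu) / sd, np.ones(p)])
    ols = np.linalg.lstsq(Z, y, rcond=None)[0]
    assert np.corrcoef(kernel, ols[:q])[0, 1] > 0.99
    assert constant == pytest.approx(ols[q], rel=0.05)


def test_snr1_heldout_prediction():
    rng = np.random.default_rng(2)
    p, q = 500, 50
    X = rng.standard_normal((p, q))
    h = rng.standard_normal(q)
    signal = X @ h
    y = signal + signal.std() * rng.standard_normal(p)
    kernel, constant, _ = fit_voxel(X, y, TrainConfig(seed=0))
    mu, sd = X.mean(axis=0), X.std(axis=0)
    X_new = rng.standard_normal((100, q))
    pred = ((X_new - mu) / sd) @ kernel + constant
    assert np.corrcoef(pred, X_new @ h)[0, 1] > 0.5


def test_closed_form_limit():
    """Without standardization/bootstrap, small steps run long converge to the
    least-squares solution on the estimation rows."""
    rng = np.random.default_rng(3)
    p, q = 200, 20
    X = rng.standard_normal((p, q))
    h = rng.standard_normal(q)
    y = X @ h + 0.7
    cfg = TrainConfig(
        seed=0, n_bootstrap=1, standardize_channels=False,
        learning_rate=1e-4, max_iters=50_000, patience=10_000, min_rel_improvement=1e-12,
    )
    kernel, constant, diag = fit_voxel(X, y, cfg)
    stop_rng = np.random.default_rng([0, 0, 0])
    stop_idx = np.sort(stop_rng.choice(p, size=40, replace=False))
    est = np.setdiff1d(np.arange(p), stop_idx)
    A = np.column_stack([X[est], np.ones(est.size)])
    ols = np.linalg.lstsq(A, y[est], rcond=None)[0]
    assert np.linalg.norm(kernel - ols[:q]) / np.linalg.norm(ols[:q]) < 1e-3
    assert constant == pytest.approx(ols[q], abs=1e-3)


def test_early_stopping_regularizes():
    """At the interpolation threshold of the estimation subsample, stopping on
    held-out error beats running the same descent to max_iters (10 seeds)."""
    p, q = 200, 160
    es, full = [], []
    for s in range(10):
        rng = np.random.default_rng([999, s])
        X = rng.standard_normal((p, q))
        h = rng.standard_normal(q)
        signal = X @ h
        y = signal + signal.std() * rng.standard_normal(p)
        X_new = rng.standard_normal((200, q))
        truth = X_new @ h
        mu, sd = X.mean(axis=0), X.std(axis=0)
        Zn = (X_new - mu) / sd
        k1, c1, _ = fit_voxel(X, y, TrainConfig(seed=s, n_bootstrap=1))
        k2, c2, _ = fit_voxel(X, y, TrainConfig(seed=s, n_bootstrap=1, early_stopping=False))
        es.append(np.corrcoef(Zn @ k1 + c1, truth)[0, 1])
        full.append(np.corrcoef(Zn @ k2 + c2, truth)[0, 1])
    assert np.mean(es) > np.mean(full)


def test_bootstrap_averaging_reduces_kernel_variance():
    """Variance of kernel estimates across data seeds with 10 bootstrap rounds
    never exceeds the single-fit variance."""
    p, q = 150, 40
    h = np.arange(q) / q
    kernels = {1: [], 10: []}
    for s in range(10):
        rng = np.random.default_rng([555, s])
        X = rng.standard_normal((p, q))
        signal = X @ h
        y = signal + signal.std() * rng.standard_normal(p)
        for nb in (1, 10):
            k, _, _ = fit_voxel(X, y, TrainConfig(seed=s, n_bootstrap=nb))
            kernels[nb].append(k)
    var1 = np.var(np.array(kernels[1]), axis=0).mean()
    var10 = np.var(np.array(kernels[10]), axis=0).mean()
    assert var10 <= var1


def test_fit_region_matches_per_voxel_fits():
    rng = np.random.default_rng(5)
    X = _design(rng, 80, 10)
    Y = ResponseMatrix(
        rng.standard_normal((80, 3)), ["v0", "v1", "v2"], list(X.stimulus_ids)
    )
    cfg = TrainConfig(seed=4, n_bootstrap=2, max_iters=500)
    model = fit_region(X, Y, cfg)
    assert model.kernels.shape == (10, 3)
    for v in range(3):
        kernel, constant, _ = fit_voxel(X, Y.values[:, v], cfg, voxel_index=v)
        assert np.array_equal(model.kernels[:, v], kernel)
        assert model.constants[v] == constant


def test_fit_region_is_deterministic():
    rng = np.random.default_rng(6)
    X = _design(rng, 60, 8)
    Y = ResponseMatrix(rng.standard_normal((60, 2)), ["a", "b"], list(X.stimulus_ids))
    cfg = TrainConfig(seed=9, max_iters=300)
    m1 = fit_region(X, Y, cfg)
    m2 = fit_region(X, Y, cfg)
    assert np.array_equal(m1.kernels, m2.kernels)
    assert np.array_equal(m1.constants, m2.constants)


def test_fit_region_stimulus_mismatch_raises():
    rng = np.random.default_rng(7)
    X = _design(rng, 20, 4)
    Y = ResponseMatrix(rng.standard_normal((20, 2)), ["a", "b"],
                       [f"other{i}" for i in range(20)])
    with pytest.raises(AlignmentError):
        fit_region(X, Y, TrainConfig(seed=0))


def test_region_to_region_design_uses_same_machinery():
    """A ResponseMatrix used as the design obeys the same contracts — no code
    path distinguishes feature channels from source-region voxels."""
    rng = np.random.default_rng(8)
    source = ResponseMatrix(
        rng.standard_normal((80, 6)), [f"src{j}" for j in range(6)],
        [f"s{i}" for i in range(80)],
    )
    target = ResponseMatrix(
        source.values @ rng.standard_normal((6, 3)) + 0.1 * rng.standard_normal((80, 3)),
        ["t0", "t1", "t2"], list(source.stimulus_ids),
    )
    model = fit_region(source.as_design(), target, TrainConfig(seed=1, max_iters=2000))
    pred = predict(model, source.as_design())
    for v in range(3):
        assert np.corrcoef(pred.values[:, v], target.values[:, v])[0, 1] > 0.9


def test_predict_zero_kernels_returns_constants():
    model = EncodingModel(
        np.zeros((4, 3)), np.full(3, 5.0), [f"c{j}" for j in range(4)],
        ["v0", "v1", "v2"], None, None, TrainConfig(),
    )
    X = DesignMatrix(np.random.default_rng(0).standard_normal((6, 4)),
                     [f"c{j}" for j in range(4)], [f"s{i}" for i in range(6)])
    pred = predict(model, X)
    assert np.all(pred.values == 5.0)
    assert pred.stimulus_ids == X.stimulus_ids and pred.voxel_ids == model.voxel_ids


def test_predict_reproduces_noiseless_generator():
    rng = np.random.default_rng(9)
    p, q, v = 40, 6, 3
    X = _design(rng, p, q)
    H = rng.standard_normal((q, v))
    c = rng.standard_normal(v)
    Y = X.values @ H + c
    model = EncodingModel(H, c, list(X.channel_ids), [f"v{i}" for i in range(v)],
                          None, None, TrainConfig())
    pred = predict(model, X)
    assert np.max(np.abs(pred.values - Y)) < 1e-8


def test_predict_commutes_with_roi_restriction():
    rng = np.random.default_rng(10)
    X = _design(rng, 30, 5)
    model = EncodingModel(
        rng.standard_normal((5, 4)), rng.standard_normal(4),
        list(X.channel_ids), ["v0", "v1", "v2", "v3"],
        None, None, TrainConfig(),
    )
    roi = ["v3", "v1"]
    a = predict(model, X).restrict(roi)
    b = predict(model.restrict(roi), X)
    assert np.array_equal(a.values, b.values)
    assert a.voxel_ids == b.voxel_ids == roi


def test_predict_channel_mismatch_raises():
    rng = np.random.default_rng(11)
    model = EncodingModel(np.zeros((3, 1)), np.zeros(1), ["a", "b", "c"], ["v"],
                          None, None, TrainConfig())
    X = DesignMatrix(rng.standard_normal((5, 3)), ["a", "b", "WRONG"],
                     [f"s{i}" for i in range(5)])
    with pytest.raises(AlignmentError):
        predict(model, X)


def test_nonfinite_inputs_rejected():
    rng = np.random.default_rng(12)
    X = rng.standard_normal((30, 4))
    y = rng.standard_normal(30)
    y[3] = np.inf
    with pytest.raises(DataError):
        fit_voxel(X, y, TrainConfig(seed=0))
    bad = X.copy()
    bad[0, 0] = np.nan
    with pytest.raises(DataError):
        DesignMatrix(bad, list("abcd"), [f"s{i}" for i in range(30)])
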