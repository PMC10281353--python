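import dataclasses

import numpy as np
import pytest

from neurothresh.cnn import (
    CNNConfig,
    CNNError,
    load_estimator,
    plan_architecture,
    predict,
    random_search,
    save_estimator,
    to_device_intensity,
    train,
)
from neurothresh.dataset import ThresholdDataset, enumerate_samples
from neurothresh.geometry import GridSpec


def _toy_dataset(n, seed, spec=None, weights=None, noise=0.0, channels="cartesian"):
    """Labels are an exact linear function of the flattened tensor."""
    spec = spec or GridSpec(3, 1.5)
    rng = np.random.default_rng(seed)
    C = 3 if channels == "cartesian" else 4
    X = rng.normal(size=(n, spec.N, spec.N, spec.N, C))
    c = spec.N // 2
    X[:, c, c, c, :3] /= np.linalg.norm(X[:, c, c, c, :3], axis=-1, keepdims=True)
    flat = X.reshape(n, -1)
    if weights is None:
        # linear teacher supported on the centre voxel (an exact linear
        # function of the flattened tensor, realizable by shared-weight convs)
        w_rng = np.random.default_rng(7)
        weights = np.zeros(flat.shape[1])
        center_flat = (c * spec.N * spec.N + c * spec.N + c) * C
        weights[center_flat:center_flat + C] = w_rng.normal(size=C)
    y = 100.0 + 10.0 * (flat @ weights) + noise * rng.standard_normal(n)
    y = np.maximum(y, 1.0)
    keys = enumerate_samples(n, ("P-A",), 1)
    return ThresholdDataset(X, y, np.ones(n), keys[:n], spec, channels)


SMALL = CNNConfig(filters_1=8, dense_units_1=16, learning_rate=3e-3,
                  max_epochs=60, early_stop_patience=15, lr_plateau_patience=6,
                  batch_size=32)


class TestArchitecturePlan:
    def test_best_plan_edges_and_widths(self):
        plan = plan_architecture(CNNConfig(), 9, 3, "variable")
        assert plan.conv_edges == [7, 5, 3, 1]
        conv_f = [l.out_shape[-1] for l in plan.layers if l.kind == "conv"]
        dense_u = [l.out_shape[0] for l in plan.layers if l.kind == "dense"]
        assert conv_f == [115, 92, 74, 59]
        assert dense_u == [57, 46, 36]

    def test_param_count_matches_closed_form(self):
        plan = plan_architecture(CNNConfig(), 9, 3, "variable")
        # independent closed-form count
        f = [3, 115, 92, 74, 59]
        expected = sum(27 * f[i] * f[i + 1] + f[i + 1] for i in range(4))
        d = [59, 57, 46, 36, 1]  # flatten edge is 1³×59
        expected += sum(d[i] * d[i + 1] + d[i + 1] for i in range(4))
        assert plan.n_params == expected

    @pytest.mark.parametrize("N,edges", [(3, [2, 1]), (5, [4, 3, 2, 1]), (7, [6, 5, 4, 3])])
    def test_variable_adaptation_smaller_grids(self, N, edges):
        plan = plan_architecture(CNNConfig(), N, 3, "variable")
        assert plan.conv_edges == edges
        kernels = {l.kernel for l in plan.layers if l.kind == "conv"}
        assert kernels == {2}

    def test_constant_adaptation_matches_n9_plan(self):
        p9 = plan_architecture(CNNConfig(), 9, 3, "variable")
        p3 = plan_architecture(CNNConfig(), 3, 3, "constant")
        assert p3.layers == p9.layers
        assert p3.input_shape == (9, 9, 9, 3)

    def test_shrink_rounding_half_up(self):
        cfg = CNNConfig()
        assert cfg.conv_filters() == [115, 92, 74, 59]
        assert cfg.dense_units() == [57, 46, 36]

    def test_spatial_collapse_rejected(self):
        with pytest.raises(CNNError):
            plan_architecture(CNNConfig(n_conv_layers=6), 9, 3, "variable")


class TestTraining:
    def test_linear_teacher_converges(self):
        """Labels exactly linear in the input: val MSE < 1% of label variance."""
        tr = _toy_dataset(1500, 1)
        va = _toy_dataset(300, 2)
        cfg = dataclasses.replace(SMALL, filters_1=16, dense_units_1=32,
                                  learning_rate=1e-2, max_epochs=100,
                                  early_stop_patience=25, lr_plateau_patience=10)
        est = train(tr, va, cfg, seed=0)
        # final_val_loss is on the internally standardized label scale
        y_std = (va.thresholds - np.mean(tr.thresholds)) / np.std(tr.thresholds)
        assert est.final_val_loss < 1e-2 * np.var(y_std)

    def test_constant_labels_learn_bias(self):
        tr = _toy_dataset(200, 3)
        va = _toy_dataset(60, 4)
        tr = dataclasses.replace(tr, thresholds=np.full(len(tr), 123.0))
        va = dataclasses.replace(va, thresholds=np.full(len(va), 123.0))
        cfg = dataclasses.replace(SMALL, max_epochs=30)
        est = train(tr, va, cfg, seed=0)
        pred = predict(est, va)
        assert np.allclose(pred, 123.0, rtol=0.01)

    def test_history_monotone_epochs_and_final_val_consistency(self):
        tr = _toy_dataset(200, 5)
        va = _toy_dataset(60, 6)
        cfg = dataclasses.replace(SMALL, max_epochs=12)
        est = train(tr, va, cfg, seed=1)
        assert est.history["epoch"] == sorted(est.history["epoch"])
        # recorded final val loss equals re-evaluation of the served weights
        from neurothresh.cnn import _forward, _prepare_inputs, _transform_labels

        X = _prepare_inputs(va, est.plan)
        y = _transform_labels(va.thresholds, est.label_transform)[:, None]
        y = (y - est.label_mean) / est.label_std
        reval = float(np.mean((_forward(est.plan, est.weights, X) - y) ** 2))
        assert est.final_val_loss == pytest.approx(reval, rel=1e-6)

    def test_lr_trace_shows_factor_5_reductions(self):
        tr = _toy_dataset(200, 7)
        va = _toy_dataset(60, 8)
        cfg = dataclasses.replace(SMALL, max_epochs=25, lr_plateau_patience=2)
        est = train(tr, va, cfg, seed=2)
        lrs = sorted(set(est.history["lr"]), reverse=True)
        for a, b in zip(lrs, lrs[1:]):
            assert a / b == pytest.approx(5.0)

    def test_seed_reproducibility(self):
        tr = _toy_dataset(150, 9)
        va = _toy_dataset(50, 10)
        cfg = dataclasses.replace(SMALL, max_epochs=5)
        e1 = train(tr, va, cfg, seed=3)
        e2 = train(tr, va, cfg, seed=3)
        for k in e1.weights:
            assert np.array_equal(e1.weights[k], e2.weights[k])

    def test_shape_mismatch_is_error(self):
        tr = _toy_dataset(100, 11)
        va = _toy_dataset(30, 12, spec=GridSpec(5, 1.5))
        with pytest.raises(CNNError):
            train(tr, va, SMALL, seed=0)


@pytest.fixture(scope="module")
def fitted():
    tr = _toy_dataset(300, 13)
    va = _toy_dataset(80, 14)
    cfg = dataclasses.replace(SMALL, max_epochs=20)
    return train(tr, va, cfg, seed=4), va


class TestPrediction:
    def test_batch_permutation_invariance(self, fitted):
        est, va = fitted
        perm = np.random.default_rng(0).permutation(len(va))
        p_all = predict(est, va.tensors)
        p_perm = predict(est, va.tensors[perm])
        assert np.allclose(p_perm, p_all[perm], atol=1e-5)

    def test_duplicate_rows_identical_outputs(self, fitted):
        est, va = fitted
        X = np.repeat(va.tensors[:1], 4, axis=0)
        p = predict(est, X)
        assert np.all(p == p[0])

    def test_convention_mismatch_raises(self, fitted):
        est, _ = fitted
        bad = _toy_dataset(10, 15, channels="spherical")
        with pytest.raises(CNNError, match="spherical"):
            predict(est, bad)

    def test_save_load_round_trip(self, fitted, tmp_path):
        est, va = fitted
        save_estimator(est, tmp_path / "est")
        back = load_estimator(tmp_path / "est")
        assert np.allclose(predict(back, va.tensors), predict(est, va.tensors))
        assert back.history["val_loss"] == est.history["val_loss"]


class TestDeviceIntensity:
    def test_simple_division(self):
        assert to_device_intensity(100.0, 2.0) == pytest.approx(50.0)
        assert to_device_intensity(57.0, 57.0) == pytest.approx(1.0)

    def test_vectorized_matches_elementwise(self, rng):
        thr = rng.uniform(50, 500, size=20)
        mag = rng.uniform(0.5, 3.0, size=20)
        out = to_device_intensity(thr, mag)
        for i in range(20):
            assert out[i] == pytest.approx(thr[i] / mag[i], rel=1e-15)

    def test_zero_magnitude_rejected(self):
        with pytest.raises(CNNError):
            to_device_intensity(100.0, 0.0)


class TestRandomSearch:
    def test_trial_count_and_ranking(self):
        tr = _toy_dataset(120, 16)
        va = _toy_dataset(40, 17)
        res = random_search(tr, va, n_trials=3, budget_epochs=2, seed=5)
        assert len(res) == 3
        assert [r["val_mse"] for r in res] == sorted(r["val_mse"] for r in res)

    def test_seeded_configs_reproducible(self):
        tr = _toy_dataset(120, 18)
        va = _toy_dataset(40, 19)
        r1 = random_search(tr, va, n_trials=2, budget_epochs=1, seed=6)
        r2 = random_search(tr, va, n_trials=2, budget_epochs=1, seed=6)
        assert [r["config"] for r in r1] == [r["config"] for r in r2]

    def test_degenerate_ranges_single_point(self):
        tr = _toy_dataset(100, 20)
        va = _toy_dataset(30, 21)
        point = {
            "n_conv_layers": (2, 2), "kernel": (2, 2), "filters_1": (8, 8),
            "n_dense_layers": (1, 1), "dense_units_1": (16, 16),
            "shrink_rate": (0.8, 0.8), "batch_size": (32, 32),
            "learning_rate": (1e-3, 1e-3),
        }
        res = random_search(tr, va, n_trials=2, budget_epochs=1, seed=7, ranges=point)
        c0, c1 = res[0]["config"], res[1]["config"]
        assert (c0.n_conv_layers, c0.kernel, c0.filters_1) == (2, 2, 8)
        assert (c1.n_conv_layers, c1.kernel, c1.filters_1) == (2, 2, 8)
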