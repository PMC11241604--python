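"""PResNet classifier: p-ReLU, backprop correctness, training, persistence,
and the risk screen."""

import numpy as np
import pytest

from lungscreen.classify import (
    Prediction,
    PresnetConfig,
    build_presnet,
    load_model,
    predict,
    predict_batch,
    prelu,
    risk_screen,
    save_model,
    train,
)
from lungscreen.features import feature_names


def two_gaussians(n=400, d=10, sep=4.0, seed=42):
    rng = np.random.default_rng(seed)
    x = np.vstack([rng.normal(0, 1, (n // 2, d)), rng.normal(sep, 1, (n // 2, d))])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    perm = rng.permutation(n)
    return x[perm], y[perm]


class TestPrelu:
    def test_positive_branch(self):
        assert prelu(5.0, 0.7) == 5.0

    def test_negative_branch(self):
        assert prelu(-2.0, 0.25) == -0.5

    def test_limit_cases_relu_and_identity(self, rng):
        x = rng.normal(size=100)
        assert np.array_equal(prelu(x, 0.0), np.maximum(x, 0.0))
        assert np.array_equal(prelu(x, 1.0), x)

    def test_monotone_and_continuous(self):
        grid = np.linspace(-5, 5, 1001)
        for j in (0.0, 0.25, 0.9):
            y = prelu(grid, j)
            assert np.all(np.diff(y) >= 0)
            assert abs(prelu(1e-12, j) - prelu(-1e-12, j)) < 1e-10

    def test_nonfinite_slope_rejected(self):
        with pytest.raises(ValueError):
            prelu(1.0, float("nan"))


class TestBuildPresnet:
    def test_forward_on_zero_input_is_finite(self):
        model = build_presnet(PresnetConfig(), input_dim=12)
        logits = model.forward(np.zeros((3, 12)))
        assert np.all(np.isfinite(logits)) and logits.shape == (3, 2)

    def test_seeded_init_reproducible(self):
        a = build_presnet(PresnetConfig(seed=5), 10)
        b = build_presnet(PresnetConfig(seed=5), 10)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_skip_connections_are_live(self, rng):
        cfg = PresnetConfig(n_blocks=2, width=8, seed=1)
        model = build_presnet(cfg, 10)
        x = rng.normal(size=(4, 10))
        base = model.forward(x)
        # zeroing the residual branch must change the output iff the branch
        # is live; the skip keeps the forward pass well-defined either way
        for i in range(cfg.n_blocks):
            saved = model.params[f"w_b{i}"].copy()
            model.params[f"w_b{i}"] = np.zeros_like(saved)
            ablated = model.forward(x)
            assert not np.allclose(ablated, base)
            model.params[f"w_b{i}"] = saved

    def test_input_smaller_than_pooling_rejected(self):
        with pytest.raises(ValueError):
            build_presnet(PresnetConfig(kappa=4), input_dim=3)

    def test_image_mode_not_available(self):
        with pytest.raises(NotImplementedError):
            PresnetConfig(mode="image")

    def test_gradients_match_finite_differences(self, rng):
        cfg = PresnetConfig(n_blocks=1, width=3, seed=7)
        model = build_presnet(cfg, 6)
        x = rng.normal(size=(4, 6))
        y = np.array([0, 1, 1, 0])
        _, grads = model.loss_and_grads(x, y)
        for key in ("w_stem", "w_a0", "w_b0", "w_fc", "j_stem", "j_block0", "b_fc"):
            p = np.atleast_1d(model.params[key])
            g = np.atleast_1d(grads[key])
            idx = tuple(0 for _ in p.shape)
            eps = 1e-6
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = model.loss_and_grads(x, y)
            p[idx] = orig - eps
            lm, _ = model.loss_and_grads(x, y)
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestTrain:
    def test_separable_benchmark_accuracy(self):
        x, y = two_gaussians()
        cfg = PresnetConfig(epochs=50, seed=1)
        model = build_presnet(cfg, x.shape[1])
        model, history = train(model, x[:320], y[:320], cfg)
        preds = predict_batch(model, x[320:])
        acc = np.mean(
            [(p.class_label == "Abnormal") == bool(t) for p, t in zip(preds, y[320:])]
        )
        assert acc >= 0.95
        assert history["loss"][-1] < history["loss"][0]

    def test_same_seed_identical_parameters(self):
        x, y = two_gaussians(n=80)
        cfg = PresnetConfig(epochs=5, seed=3, width=8, n_blocks=1)
        m1, _ = train(build_presnet(cfg, x.shape[1]), x, y, cfg)
        m2, _ = train(build_presnet(cfg, x.shape[1]), x, y, cfg)
        assert all(np.array_equal(m1.params[k], m2.params[k]) for k in m1.params)

    def test_single_class_rejected(self):
        cfg = PresnetConfig(epochs=1)
        model = build_presnet(cfg, 4)
        with pytest.raises(ValueError):
            train(model, np.zeros((6, 4)), np.zeros(6, dtype=int), cfg)

    def test_warm_start_continues_from_checkpoint(self, tmp_path):
        x, y = two_gaussians(n=80)
        cfg = PresnetConfig(epochs=3, seed=3, width=8, n_blocks=1)
        model, _ = train(build_presnet(cfg, x.shape[1]), x, y, cfg)
        save_model(model, tmp_path / "warm.npz")
        warm = load_model(tmp_path / "warm.npz")
        warm, history = train(warm, x, y, cfg)
        assert len(history["loss"]) == cfg.epochs  # trained further, no error


@pytest.fixture(scope="module")
def trained():
    x, y = two_gaussians(n=120, d=8)
    cfg = PresnetConfig(epochs=10, seed=2, width=8, n_blocks=1)
    model, _ = train(build_presnet(cfg, 8), x, y, cfg)
    return model, x


class TestPredict:

    def test_scores_are_probabilities(self, trained):
        model, x = trained
        p = predict(model, x[0])
        assert 0.0 <= p.abnormal_score <= 1.0
        assert p.class_label in ("Normal", "Abnormal")

    def test_argmax_consistency(self, trained):
        model, x = trained
        for row in x[:20]:
            p = predict(model, row)
            assert (p.class_label == "Abnormal") == (p.abnormal_score > 0.5)

    def test_batch_equals_per_sample(self, trained):
        model, x = trained
        batch = predict_batch(model, x[:20])
        singles = [predict(model, row) for row in x[:20]]
        for a, b in zip(batch, singles):
            assert a.class_label == b.class_label
            assert a.abnormal_score == pytest.approx(b.abnormal_score, abs=1e-12)

    def test_shape_mismatch_rejected(self, trained):
        model, _ = trained
        with pytest.raises(ValueError):
            predict(model, np.zeros(5))

    def test_save_reload_bit_reproduces_predictions(self, trained, tmp_path):
        model, x = trained
        save_model(model, tmp_path / "m.npz")
        reloaded = load_model(tmp_path / "m.npz")
        assert np.array_equal(model.forward(x), reloaded.forward(x))


class TestRiskScreen:
    def _vector(self, flags, radii):
        names = tuple(feature_names())
        v = np.zeros(len(names))
        for i, (f, r) in enumerate(zip(flags, radii)):
            v[names.index(f"q{i}_on_rib_flag")] = f
            v[names.index(f"q{i}_nodule_blob_radius")] = r
        return v

    def test_normal_prediction_keeps_none(self):
        p = Prediction("Normal", 0.1, "none")
        out = risk_screen(p, self._vector([1, 1, 1, 1], [9, 9, 9, 9]))
        assert out.risk_label == "none"

    def test_on_rib_flag_in_salient_quadrant_gives_high(self):
        p = Prediction("Abnormal", 0.9, "low")
        out = risk_screen(p, self._vector([0, 1, 0, 0], [1, 7, 1, 1]))
        assert out.risk_label == "high"

    def test_large_blob_gives_high(self):
        p = Prediction("Abnormal", 0.9, "low")
        out = risk_screen(p, self._vector([0, 0, 0, 0], [1, 1, 9, 1]))
        assert out.risk_label == "high"

    def test_small_free_nodule_is_low(self):
        p = Prediction("Abnormal", 0.8, "low")
        out = risk_screen(p, self._vector([0, 0, 0, 0], [1, 4, 1, 1]))
        assert out.risk_label == "low"

    def test_missing_on_rib_block_rejected(self):
        p = Prediction("Abnormal", 0.9, "low")
        with pytest.raises(ValueError, match="on-rib block"):
            risk_screen(p, np.zeros(4), names=("a", "b", "c", "d"))

    def test_label_invariant_enforced(self):
        with pytest.raises(ValueError):
            Prediction("Normal", 0.2, "high")
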