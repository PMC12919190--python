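"""CORAL distribution identities, disagreement loss, and training behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinescore.consensus import RatingSummary
from kinescore.kinematics import FeatureVector, Signal
from kinescore.ordinal import (ModelConfig, build_model, disagreement_loss,
                               disagreement_loss_terms, expand_distribution,
                               predict_batch, train, _batch_loss_and_grad)

SMALL_CFG = ModelConfig(input_length=64, cnn_blocks=((4, 5, 2), (8, 3, 2)),
                        mlp_widths=(8,), epochs=5, batch_size=8, seed=0)


def toy_dataset(n, seed=0, sev_to_freq=True):
    """Signals whose frequency/amplitude fall with target severity."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        sev = float(rng.integers(0, 5))
        t = np.arange(200) / 50.0
        freq = 3.0 - 0.5 * sev if sev_to_freq else 2.0
        amp = 1.0 - 0.15 * sev
        x = amp * np.sin(2 * np.pi * freq * t) + rng.normal(0, 0.05, t.size)
        sig = Signal(x, 50.0)
        feats = FeatureVector(*np.concatenate([[amp, freq], rng.normal(0, 1, 10)]))
        out.append((sig, feats, RatingSummary(sev + rng.normal(0, 0.1), 0.4, 3)))
    return out


class TestBuildModel:
    def test_k_minus_one_logits(self):
        model = build_model(ModelConfig(num_classes=5, input_length=64,
                                        cnn_blocks=((4, 3, 2),), mlp_widths=(4,)),
                            n_features=12)
        logits = model.forward(np.zeros((3, 64)), np.zeros((3, 12)))
        assert logits.shape == (3, 4)

    def test_different_seeds_different_weights_same_shapes(self):
        cfgs = [ModelConfig(seed=s, input_length=64,
                            cnn_blocks=((4, 3, 2),), mlp_widths=(4,))
                for s in (0, 1)]
        m0, m1 = (build_model(c, 12) for c in cfgs)
        w0 = m0.cnn.layers[0].params["w"]
        w1 = m1.cnn.layers[0].params["w"]
        assert w0.shape == w1.shape
        assert not np.allclose(w0, w1)

    def test_thresholds_strictly_increasing(self):
        model = build_model(SMALL_CFG, 12)
        b = model.thresholds()
        assert (np.diff(b) > 0).all()


class TestExpandDistribution:
    def test_degenerate_top_class(self):
        p = expand_distribution(np.ones(4))
        np.testing.assert_allclose(p.class_probs, [0, 0, 0, 0, 1])
        assert p.mean == 4.0 and p.variance == 0.0

    def test_worked_cumulative_example(self):
        p = expand_distribution(np.array([0.9, 0.5, 0.2, 0.05]))
        np.testing.assert_allclose(p.class_probs, [0.1, 0.4, 0.3, 0.15, 0.05])
        assert p.mean == pytest.approx(1.65)

    def test_degenerate_bottom_class(self):
        p = expand_distribution(np.zeros(4))
        assert p.mean == 0.0 and p.variance == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expand_distribution(np.array([1.2, 0.5, 0.1, 0.0]))

    def test_non_monotone_input_monotonized(self):
        p = expand_distribution(np.array([0.3, 0.6, 0.1, 0.0]))
        assert (np.diff(p.cumulative) <= 1e-12).all()
        assert p.class_probs.min() >= 0

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=6))
    @settings(deadline=None, max_examples=60)
    def test_reaccumulation_identity(self, cum):
        """P(y > k) recomputed from the class distribution matches."""
        p = expand_distribution(np.array(cum))
        back = 1.0 - np.cumsum(p.class_probs)[:-1]
        np.testing.assert_allclose(back, p.cumulative, atol=1e-9)
        assert p.class_probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert p.variance >= -1e-12


class TestDisagreementLoss:
    def test_perfect_confident_prediction_costs_nothing(self):
        p = expand_distribution(np.array([1.0, 1.0, 0.0, 0.0]))
        assert p.mean == 2.0 and p.variance == 0.0
        assert disagreement_loss(p, 2.0, lambda_weight=1.0) == 0.0

    def test_huber_quadratic_zone(self):
        p = expand_distribution(np.array([1.0, 0.5, 0.0, 0.0]))  # mean 1.5
        loss = disagreement_loss(p, 2.0, lambda_weight=0.0, huber_delta=1.0)
        assert loss == pytest.approx(0.125)

    def test_pure_variance_penalty(self):
        p = expand_distribution(np.array([0.9, 0.5, 0.2, 0.05]))
        h, v = disagreement_loss_terms(p, p.mean, lambda_weight=1.0)
        assert h == 0.0
        assert disagreement_loss(p, p.mean, 1.0) == pytest.approx(p.variance)

    def test_negative_lambda_rejected(self):
        p = expand_distribution(np.array([0.5, 0.2, 0.1, 0.0]))
        with pytest.raises(ValueError):
            disagreement_loss(p, 1.0, lambda_weight=-0.1)

    def test_huber_linear_zone_slope(self):
        p = expand_distribution(np.array([1.0, 1.0, 1.0, 1.0]))  # mean 4
        loss = disagreement_loss(p, 0.0, lambda_weight=0.0, huber_delta=1.0)
        assert loss == pytest.approx(1.0 * (4.0 - 0.5))


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        """Closed-form dL/dlogits agrees with numerical differentiation."""
        model = build_model(SMALL_CFG, 12)
        rng = np.random.default_rng(0)
        logits = rng.normal(0, 1, (4, 4))
        targets = rng.uniform(0, 4, 4)
        _, _, grad = _batch_loss_and_grad(model, logits, targets)

        eps = 1e-6
        for i in range(4):
            for k in range(4):
                up, down = logits.copy(), logits.copy()
                up[i, k] += eps
                down[i, k] -= eps
                lu, _, _ = _batch_loss_and_grad(model, up, targets)
                ld, _, _ = _batch_loss_and_grad(model, down, targets)
                num = (lu - ld) / (2 * eps)
                assert grad[i, k] == pytest.approx(num, abs=1e-5)

    def test_network_backward_matches_finite_differences(self):
        """End-to-end backprop through conv/bn/pool/linear layers."""
        cfg = ModelConfig(input_length=16, cnn_blocks=((3, 3, 2),),
                          mlp_widths=(4,), seed=1)
        model = build_model(cfg, 5)
        model.set_training(True)
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (3, 16))
        F = rng.normal(0, 1, (3, 5))
        t = rng.uniform(0, 4, 3)

        def loss_value():
            logits = model.forward(X, F)
            loss, _, _ = _batch_loss_and_grad(model, logits, t)
            return loss

        logits = model.forward(X, F)
        _, _, dlog = _batch_loss_and_grad(model, logits, t)
        model.backward(dlog)

        # probe a few parameters in each component
        probes = [(model.cnn.layers[0], "w", (0, 0, 1)),
                  (model.cnn.layers[1], "gamma", (1,)),
                  (model.mlp.layers[0], "w", (2, 3)),
                  (model.head, "w", (0, 0))]
        eps = 1e-6
        for layer, name, idx in probes:
            analytic = layer.grads[name][idx]
            orig = layer.params[name][idx]
            layer.params[name][idx] = orig + eps
            lu = loss_value()
            layer.params[name][idx] = orig - eps
            ld = loss_value()
            layer.params[name][idx] = orig
            assert analytic == pytest.approx((lu - ld) / (2 * eps), abs=2e-4), \
                f"gradient mismatch at {name}{idx}"
        # threshold parameters
        _ = loss_value()
        model.backward(_batch_loss_and_grad(model, model.forward(X, F), t)[2])
        for i in range(model.theta.size):
            analytic = model.theta_grad[i]
            model.theta[i] += eps
            lu = loss_value()
            model.theta[i] -= 2 * eps
            ld = loss_value()
            model.theta[i] += eps
            assert analytic == pytest.approx((lu - ld) / (2 * eps), abs=2e-4)


class TestTraining:
    def test_seeded_training_is_deterministic(self):
        data = toy_dataset(6)
        cfg = ModelConfig(input_length=64, cnn_blocks=((4, 3, 2),),
                          mlp_widths=(4,), epochs=5, batch_size=4, seed=7)
        _, h1 = train(data, cfg)
        _, h2 = train(data, cfg)
        assert h1["loss"] == h2["loss"]

    def test_loss_decreases_on_learnable_data(self):
        data = toy_dataset(50, seed=1)
        cfg = ModelConfig(input_length=64, cnn_blocks=((4, 5, 2), (8, 3, 2)),
                          mlp_widths=(8,), epochs=30, batch_size=16, seed=0)
        _, history = train(data, cfg)
        assert history["loss"][-1] < history["loss"][0]

    def test_lambda_zero_reduces_to_pure_huber(self):
        data = toy_dataset(12)
        cfg = ModelConfig(input_length=64, cnn_blocks=((4, 3, 2),),
                          mlp_widths=(4,), epochs=3, batch_size=4, seed=3,
                          lambda_weight=0.0)
        _, history = train(data, cfg)
        np.testing.assert_allclose(history["loss"], history["huber"])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], SMALL_CFG)


@pytest.fixture(scope="module")
def trained():
    data = toy_dataset(80, seed=4)
    cfg = ModelConfig(input_length=64, cnn_blocks=((4, 5, 2), (8, 3, 2)),
                      mlp_widths=(8,), epochs=40, batch_size=16, seed=0)
    model, _ = train(data, cfg)
    return model


class TestPredict:
    def test_moments_within_distribution_support(self, trained):
        test = toy_dataset(20, seed=9)
        preds = predict_batch(trained, [d[0] for d in test],
                              [d[1] for d in test])
        for p in preds:
            assert 0.0 <= p.mean <= 4.0
            assert 0.0 <= p.variance <= 4.0
            assert (np.diff(p.cumulative) <= 1e-12).all()

    def test_inference_is_deterministic(self, trained):
        test = toy_dataset(3, seed=9)
        p1 = predict_batch(trained, [d[0] for d in test], [d[1] for d in test])
        p2 = predict_batch(trained, [d[0] for d in test], [d[1] for d in test])
        for a, b in zip(p1, p2):
            assert a.mean == b.mean and a.variance == b.variance

    def test_severe_scores_above_normal(self, trained):
        """Mean prediction at true severity 4 exceeds severity 0."""
        rng = np.random.default_rng(11)
        mus = {0: [], 4: []}
        for sev in (0, 4):
            for _ in range(10):
                t = np.arange(200) / 50.0
                freq, amp = 3.0 - 0.5 * sev, 1.0 - 0.15 * sev
                x = amp * np.sin(2 * np.pi * freq * t) + rng.normal(0, 0.05, t.size)
                feats = FeatureVector(*np.concatenate([[amp, freq],
                                                       rng.normal(0, 1, 10)]))
                p = predict_batch(trained, [Signal(x, 50.0)], [feats])[0]
                mus[sev].append(p.mean)
        assert np.mean(mus[4]) > np.mean(mus[0])

    def test_checkpoint_round_trip(self, trained, tmp_path):
        from kinescore.ordinal import OrdinalScorer
        path = tmp_path / "model.npz"
        trained.save(path)
        loaded = OrdinalScorer.load(path)
        test = toy_dataset(4, seed=2)
        p1 = predict_batch(trained, [d[0] for d in test], [d[1] for d in test])
        p2 = predict_batch(loaded, [d[0] for d in test], [d[1] for d in test])
        for a, b in zip(p1, p2):
            assert a.mean == pytest.approx(b.mean, abs=1e-12)
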