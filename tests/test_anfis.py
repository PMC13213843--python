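"""ANFIS layers, gradients, training behaviour and serialization."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from anfiskit import anfis
from anfiskit.errors import InvalidParameterError, StratificationError

from .conftest import tiny_model

unit = st.floats(0, 1, allow_nan=False)


def unrolled_forward(x, model):
    """Layer-by-layer scalar reference forward pass (plain Python loops)."""
    firing = []
    for rule in model.rules:
        w = 1.0
        for f, mf_index in enumerate(rule.antecedent):
            c = model.centers[f, mf_index]
            s = model.widths[f, mf_index]
            mu = math.exp(-((x[f] - c) ** 2) / (2 * s * s))
            w *= max(mu, model.epsilon)
        firing.append(w)
    total = sum(firing)
    z = 0.0
    for w, rule in zip(firing, model.rules):
        consequent = rule.intercept + sum(
            p * xi for p, xi in zip(rule.coefficients, x)
        )
        z += (w / total) * consequent
    return 1.0 / (1.0 + math.exp(-z))


class TestMembership:
    def test_peak_at_center(self):
        mf = anfis.MembershipFunction(0.5, 0.25)
        assert anfis.gaussian_membership(0.5, mf) == 1.0

    def test_closed_form_value(self):
        mf = anfis.MembershipFunction(0.5, 0.25)
        assert anfis.gaussian_membership(0.0, mf) == pytest.approx(math.exp(-2))

    @given(d=st.floats(0, 2, allow_nan=False))
    def test_symmetry_about_center(self, d):
        mf = anfis.MembershipFunction(0.3, 0.2)
        left = anfis.gaussian_membership(0.3 - d, mf)
        right = anfis.gaussian_membership(0.3 + d, mf)
        assert left == pytest.approx(right, rel=1e-12)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            anfis.MembershipFunction(0.5, 0.0)


class TestFiring:
    def test_input_at_rule_centers_fires_fully(self):
        model = tiny_model(seed=1)
        rule = 0
        x = model.centers[np.arange(model.n_features), model.antecedents[rule]]
        w = anfis.rule_firing(x, model)
        assert w[rule] == pytest.approx(1.0)

    def test_single_factor_product(self):
        model = tiny_model(seed=2)
        rule = 1
        idx = model.antecedents[rule]
        x = model.centers[np.arange(model.n_features), idx].copy()
        # displace one coordinate so its membership is exactly 0.5
        f = 0
        sigma = model.widths[f, idx[f]]
        x[f] += sigma * math.sqrt(2 * math.log(2))
        w = anfis.rule_firing(x, model)
        assert w[rule] == pytest.approx(0.5, rel=1e-9)

    def test_eleven_way_product_avoids_underflow(self):
        n_features = 11
        centers = np.tile([0.0, 0.5, 1.0], (n_features, 1))
        widths = np.full((n_features, 3), 0.25)
        model = anfis.ANFISModel(
            centers=centers,
            widths=widths,
            antecedents=np.ones((1, n_features), dtype=int),
            coefficients=np.zeros((1, n_features)),
            intercepts=np.zeros(1),
            feature_names=tuple(f"f{i}" for i in range(n_features)),
        )
        x = np.full(n_features, 0.0)  # membership e^-2 under the Medium MF each
        w = anfis.rule_firing(x, model)
        assert w[0] == pytest.approx(math.exp(-22), rel=1e-9)

    def test_normalize_proportionality_and_sum(self):
        w = np.array([2.0, 2.0, 0, 0, 0, 0, 0, 0])
        normalized = anfis.normalize_firing(w)
        assert normalized[:2] == pytest.approx([0.5, 0.5])
        assert normalized.sum() == pytest.approx(1.0)
        assert anfis.normalize_firing(np.ones(8)) == pytest.approx([0.125] * 8)

    @given(scale=st.floats(1e-6, 1e6, allow_nan=False))
    def test_normalize_scale_invariance(self, scale):
        w = np.array([0.2, 0.5, 0.1, 0.9])
        assert anfis.normalize_firing(w * scale) == pytest.approx(
            anfis.normalize_firing(w)
        )

    def test_all_zero_firing_rejected(self):
        with pytest.raises(InvalidParameterError):
            anfis.normalize_firing(np.zeros(8))


class TestForward:
    def test_zero_consequents_give_half(self):
        model = tiny_model(seed=3)
        model.coefficients[:] = 0.0
        model.intercepts[:] = 0.0
        assert anfis.forward(np.array([0.2, 0.4, 0.9]), model) == pytest.approx(0.5)

    def test_constant_consequents_pass_through_sigmoid(self):
        model = tiny_model(seed=4)
        model.coefficients[:] = 0.0
        model.intercepts[:] = 1.7
        expected = 1.0 / (1.0 + math.exp(-1.7))
        for x in (np.array([0.1, 0.1, 0.1]), np.array([0.9, 0.2, 0.6])):
            assert anfis.forward(x, model) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_unrolled_oracle(self, seed):
        model = tiny_model(n_features=2 + seed % 3, n_rules=2 + seed, seed=seed)
        rng = np.random.default_rng(seed + 100)
        for x in rng.random((10, model.n_features)):
            assert anfis.forward(x, model) == pytest.approx(
                unrolled_forward(x, model), abs=1e-10
            )

    @given(data=st.data())
    def test_layer_contracts_on_random_inputs(self, data):
        model = tiny_model(seed=6)
        x = np.array(
            [data.draw(unit) for _ in range(model.n_features)]
        )
        w = anfis.rule_firing(x, model)
        assert np.all(w > 0) and np.all(w <= 1.0 + 1e-12)
        normalized = anfis.normalize_firing(w)
        assert normalized.sum() == pytest.approx(1.0)
        y = anfis.forward(x, model)
        assert 0.0 < y < 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_rule_permutation_equivariance(self, seed):
        model = tiny_model(n_features=4, n_rules=6, seed=seed)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(model.n_rules)
        permuted = model.copy()
        permuted.antecedents = model.antecedents[perm]
        permuted.coefficients = model.coefficients[perm]
        permuted.intercepts = model.intercepts[perm]
        for x in rng.random((5, 4)):
            assert anfis.forward(x, permuted) == pytest.approx(
                anfis.forward(x, model), rel=1e-12
            )


def numeric_gradients(model, X, t, h=1e-6):
    grads = {}
    for key in ("centers", "widths", "coefficients", "intercepts"):
        arr = getattr(model, key)
        grad = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = arr[i]
            arr[i] = orig + h
            up, _ = anfis.loss_and_gradients(model, X, t)
            arr[i] = orig - h
            down, _ = anfis.loss_and_gradients(model, X, t)
            arr[i] = orig
            grad[i] = (up - down) / (2 * h)
        grads[key] = grad
    return grads


class TestGradients:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_analytic_matches_finite_difference(self, seed):
        model = tiny_model(n_features=3, n_rules=4, seed=seed)
        rng = np.random.default_rng(seed + 50)
        X = rng.random((8, 3))
        t = rng.integers(0, 2, 8).astype(float)
        _, analytic = anfis.loss_and_gradients(model, X, t)
        numeric = numeric_gradients(model, X, t)
        for key, grad in numeric.items():
            scale = np.maximum(np.abs(grad), 1e-4)
            assert np.max(np.abs(analytic[key] - grad) / scale) < 1e-4, key


def _separable_toy(n=80, seed=0):
    rng = np.random.default_rng(seed)
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    X = np.c_[
        np.where(y == 1, rng.uniform(0.7, 1.0, n), rng.uniform(0.0, 0.3, n)),
        rng.random(n),
    ]
    return X, y


class TestTraining:
    def test_separable_toy_reaches_full_accuracy(self):
        X, y = _separable_toy()
        config = anfis.TrainingConfig(seed=1, max_epochs=100)
        model, history = anfis.train(X, y, config)
        probs = anfis.predict_proba(model, X)
        assert np.mean((probs > 0.5) == y) == 1.0

    def test_uninformative_labels_track_majority_rate(self):
        rng = np.random.default_rng(3)
        X = rng.random((400, 3))
        y = (rng.random(400) < 0.25).astype(float)  # independent of X
        config = anfis.TrainingConfig(seed=3, max_epochs=25)
        _, history = anfis.train(X, y, config)
        majority = 0.75
        assert abs(history.val_acc[history.best_epoch] - majority) < 0.15

    def test_deterministic_histories(self):
        X, y = _separable_toy(seed=5)
        config = anfis.TrainingConfig(seed=9, max_epochs=12)
        _, first = anfis.train(X, y, config)
        _, second = anfis.train(X, y, config)
        assert first.train_loss == second.train_loss
        assert first.val_loss == second.val_loss
        assert first.best_epoch == second.best_epoch

    def test_early_stopping_restores_best_epoch(self):
        X, y = _separable_toy(seed=6)
        config = anfis.TrainingConfig(seed=2, max_epochs=40, early_stopping_patience=5)
        model, history = anfis.train(X, y, config)
        best = history.val_loss[history.best_epoch]
        assert best <= min(history.val_loss) + 1e-12
        assert history.n_epochs <= 40

    def test_single_class_labels_rejected(self):
        X = np.random.default_rng(0).random((20, 2))
        with pytest.raises(StratificationError):
            anfis.train(X, np.ones(20))

    def test_kmeans_antecedents_are_unique(self):
        rng = np.random.default_rng(4)
        X = rng.random((100, 5))
        model = anfis.initialize_model(X, tuple("abcde"), n_rules=8, seed=0)
        antecedents = {tuple(row) for row in model.antecedents}
        assert len(antecedents) == 8


class TestModelObjects:
    def test_classifier_from_dataframe_and_summary(self, small_fit):
        results, data = small_fit
        text = results.summary()
        assert "rules: 8" in text
        assert "features: 11" in text
        assert results.history.n_epochs >= 1

    def test_serialization_roundtrip_bit_for_bit(self, small_fit, tmp_path):
        results, data = small_fit
        path = tmp_path / "model.json"
        results.save(path)
        loaded = anfis.ANFISResults.load(path)
        X = data.X_test.to_numpy()[:50]
        assert np.array_equal(results.predict_proba(X), loaded.predict_proba(X))
        assert loaded.scaler == results.scaler
        assert loaded.history.best_epoch == results.history.best_epoch

    def test_predict_threshold_is_strict(self):
        model = tiny_model(seed=7)
        model.coefficients[:] = 0.0
        model.intercepts[:] = 0.0  # forward output exactly 0.5
        results = anfis.ANFISResults(None, model, None)
        assert results.predict(np.array([[0.2, 0.4, 0.6]]))[0] == 0
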