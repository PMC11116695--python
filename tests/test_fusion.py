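import numpy as np
import pytest

from cmifuse.fusion import (
    Ae2Model,
    FusionConfig,
    FusionDivergenceError,
    MinMaxScaler,
    ViewSet,
    _h_grad,
    _init_model,
    _param_and_h_grads,
    ae2_objective,
    degradation_forward,
    first_ae_forward,
    fused_features,
    infer_latent,
    objective_terms,
    train_ae2,
)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@pytest.fixture
def two_views():
    rng = np.random.default_rng(0)
    return ViewSet(X=[rng.random((20, 50)), rng.random((15, 50))])


class TestViewSet:
    def test_sample_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sample count"):
            ViewSet(X=[np.zeros((3, 4)), np.zeros((3, 5))])

    def test_unscaled_input_rejected(self):
        with pytest.raises(ValueError, match="scaled"):
            ViewSet(X=[np.full((2, 3), 5.0)])

    def test_nonfinite_rejected(self):
        bad = np.zeros((2, 3))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ViewSet(X=[bad])


class TestMinMaxScaler:
    def test_maps_training_data_to_unit_interval(self):
        X = np.random.default_rng(1).normal(0, 5, (4, 30))
        s = MinMaxScaler().fit(X)
        t = s.transform(X)
        assert t.min() >= 0 and t.max() <= 1

    def test_clips_new_data_and_handles_constant_rows(self):
        X = np.vstack([np.arange(10.0), np.full(10, 3.0)])
        s = MinMaxScaler().fit(X)
        t = s.transform(np.array([[100.0], [9.0]]))
        assert t[0, 0] == 1.0  # clipped
        assert t[1, 0] == 0.5  # constant coordinate


class TestForwardPasses:
    def zero_model(self, dims, cfg):
        model = _init_model(cfg, dims)
        for k in model.params:
            model.params[k][:] = 0.0
        return model

    def test_zero_parameters_give_half_everywhere(self):
        cfg = FusionConfig(k=2, C=2, S=1, epochs=1)
        model = self.zero_model([3], cfg)
        z_mid, z_c = first_ae_forward(model, 0, np.random.default_rng(0).random((3, 4)))
        assert np.all(z_mid == 0.5) and np.all(z_c == 0.5)
        g = degradation_forward(model, 0, np.zeros((2, 4)))
        assert np.all(g == 0.5)

    def test_single_sample_shapes_preserved(self):
        cfg = FusionConfig(k=2, C=4, S=2, epochs=1)
        model = _init_model(cfg, [5])
        z_mid, z_c = first_ae_forward(model, 0, np.random.default_rng(0).random((5, 1)))
        assert z_mid.shape == (2, 1) and z_c.shape == (5, 1)

    def test_two_layer_forward_matches_manual_arithmetic(self):
        cfg = FusionConfig(k=1, C=2, S=1, epochs=1)
        model = _init_model(cfg, [2])
        W0 = np.array([[0.5, -0.25]])
        b0 = np.array([0.1])
        W1 = np.array([[2.0], [-1.0]])
        b1 = np.array([0.0, 0.3])
        model.params["ae.0.0.W"], model.params["ae.0.0.b"] = W0, b0
        model.params["ae.0.1.W"], model.params["ae.0.1.b"] = W1, b1
        x = np.array([[0.2], [0.8]])
        z_mid, z_c = first_ae_forward(model, 0, x)
        h1 = sigmoid(W0 @ x + b0[:, None])
        h2 = sigmoid(W1 @ h1 + b1[:, None])
        assert np.allclose(z_mid, h1, atol=1e-12)
        assert np.allclose(z_c, h2, atol=1e-12)

    def test_single_degradation_layer_is_affine_plus_sigmoid(self):
        cfg = FusionConfig(k=2, C=2, S=1, epochs=1)
        model = _init_model(cfg, [3])
        H = np.random.default_rng(2).normal(0, 1, (2, 5))
        W = model.params["dr.0.0.W"]
        b = model.params["dr.0.0.b"]
        assert np.allclose(
            degradation_forward(model, 0, H), sigmoid(W @ H + b[:, None]), atol=1e-12
        )

    def test_shape_mismatch_rejected(self):
        cfg = FusionConfig(k=2, C=2, S=1, epochs=1)
        model = _init_model(cfg, [3])
        with pytest.raises(ValueError, match="features"):
            first_ae_forward(model, 0, np.zeros((4, 2)))


class TestObjective:
    def test_lambda_zero_reduces_to_reconstruction(self, two_views):
        cfg = FusionConfig(k=4, lam=0.0, epochs=1, seed=0)
        model = _init_model(cfg, two_views.dims)
        model.H = np.zeros((4, two_views.n))
        recon, _ = objective_terms(model, two_views)
        assert ae2_objective(model, two_views) == pytest.approx(recon, abs=1e-10)

    def test_direct_formula_agrees_with_tracked_terms(self, two_views):
        cfg = FusionConfig(k=4, lam=2.5, epochs=1, seed=1)
        model = _init_model(cfg, two_views.dims)
        H = np.random.default_rng(0).normal(0, 1, (4, two_views.n))
        recon, deg = objective_terms(model, two_views, H)
        direct = 0.0
        for v, X in enumerate(two_views.X):
            z_mid, z_c = first_ae_forward(model, v, X)
            g = degradation_forward(model, v, H)
            direct += ((X - z_c) ** 2).sum() + 2.5 * ((z_mid - g) ** 2).sum()
        assert recon + 2.5 * deg == pytest.approx(direct, abs=1e-10)

    def test_nonnegative(self, two_views):
        cfg = FusionConfig(k=4, epochs=1, seed=2)
        model = _init_model(cfg, two_views.dims)
        model.H = np.zeros((4, two_views.n))
        assert ae2_objective(model, two_views) >= 0


def test_fusion_gradients_match_central_differences():
    """Backprop for weights, biases and H vs numerical differentiation."""
    rng = np.random.default_rng(0)
    views = ViewSet(X=[rng.random((3, 4)), rng.random((2, 4))])
    cfg = FusionConfig(k=2, C=2, S=1, lam=0.7, epochs=1, seed=1)
    model = _init_model(cfg, views.dims)
    H = rng.normal(0, 0.5, (2, 4))
    grads, dH, _ = _param_and_h_grads(model, views, H)
    h = 1e-6

    def loss():
        return _param_and_h_grads(model, views, H)[2]

    for name, arr in model.params.items():
        flat = arr.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + h
            lp = loss()
            flat[i] = orig - h
            lm = loss()
            flat[i] = orig
            num = (lp - lm) / (2 * h)
            ana = grads[name].ravel()[i]
            assert abs(num - ana) < 1e-4 * max(1.0, abs(num)), name
    flat = H.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + h
        lp = loss()
        flat[i] = orig - h
        lm = loss()
        flat[i] = orig
        num = (lp - lm) / (2 * h)
        assert abs(num - dH.ravel()[i]) < 1e-4 * max(1.0, abs(num))


class TestTraining:
    def test_loss_descends_on_random_two_view_data(self, two_views):
        model = train_ae2(two_views, FusionConfig(k=8, epochs=100, seed=0))
        assert model.loss_history[-1] < model.loss_history[0]
        assert all(np.isfinite(model.loss_history))

    def test_single_view_lambda_zero_is_plain_autoencoder(self):
        rng = np.random.default_rng(3)
        views = ViewSet(X=[rng.random((10, 40))])
        model = train_ae2(views, FusionConfig(k=4, lam=0.0, epochs=80, seed=0))
        assert model.loss_history[-1] < model.loss_history[0]

    def test_deterministic_latents(self, two_views):
        cfg = FusionConfig(k=6, epochs=40, infer_steps=100, seed=5)
        a = train_ae2(two_views, cfg)
        b = train_ae2(two_views, cfg)
        assert np.array_equal(a.H, b.H)

    def test_too_few_samples_rejected(self):
        views = ViewSet(X=[np.random.default_rng(0).random((3, 1))])
        with pytest.raises(ValueError, match="2 samples"):
            train_ae2(views, FusionConfig(k=2, epochs=1))

    def test_degradation_term_nonincreasing_in_lambda(self, two_views):
        degs = []
        for lam in (0.1, 1.0, 10.0):
            cfg = FusionConfig(k=8, lam=lam, epochs=80, infer_steps=200, seed=0)
            model = train_ae2(two_views, cfg)
            degs.append(objective_terms(model, two_views)[1])
        assert degs[0] >= degs[1] >= degs[2]


class TestInferLatent:
    @pytest.fixture(scope="class")
    def trained(self):
        rng = np.random.default_rng(4)
        views = ViewSet(X=[rng.random((12, 40)), rng.random((9, 40))])
        model = train_ae2(views, FusionConfig(k=5, epochs=100, infer_steps=300, seed=0))
        return model, views

    def test_training_columns_recover_stored_latents(self, trained):
        model, views = trained
        H = infer_latent(model, views)
        rmse = np.sqrt(((H - model.H) ** 2).mean())
        assert rmse < 1e-2

    def test_single_new_sample(self, trained):
        model, views = trained
        one = ViewSet(X=[x[:, :1] for x in views.X])
        assert infer_latent(model, one).shape == (5, 1)

    def test_duplicated_column_gives_duplicated_latent(self, trained):
        model, views = trained
        dup = ViewSet(X=[np.hstack([x[:, :1], x[:, :1]]) for x in views.X])
        H = infer_latent(model, dup)
        assert np.array_equal(H[:, 0], H[:, 1])

    def test_dimension_mismatch_rejected(self, trained):
        model, _ = trained
        with pytest.raises(ValueError, match="view 0"):
            infer_latent(model, ViewSet(X=[np.zeros((3, 2)), np.zeros((9, 2))]))


class TestFusedFeatures:
    def test_shape_and_alignment(self, two_views):
        model = train_ae2(two_views, FusionConfig(k=8, epochs=30, infer_steps=100, seed=0))
        F = fused_features(model)
        assert F.shape == (50, 8)
        assert np.array_equal(F, model.H.T)
        assert np.all(np.isfinite(F))

    def test_latent_separates_planted_clusters(self):
        rng = np.random.default_rng(6)
        n = 60
        labels = np.repeat([0, 1], n // 2)
        centers = rng.random((2, 10, 2))  # two views, 10 features, 2 clusters
        X = [
            np.clip(centers[v][:, labels] + rng.normal(0, 0.08, (10, n)), 0, 1)
            for v in range(2)
        ]
        model = train_ae2(ViewSet(X=X), FusionConfig(k=4, epochs=150, seed=0))
        F = fused_features(model)
        # linear separator on the latent does far better than chance
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression().fit(F, labels)
        assert clf.score(F, labels) > 0.8
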