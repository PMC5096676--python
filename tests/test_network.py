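import numpy as np
import pytest

from cellsegnet.data import PatchDataset
from cellsegnet.network import (
    ConvRound,
    NetworkSpec,
    PatchClassifier,
    FULL_FAMILY,
    TEST_FAMILY,
    TrainConfig,
    cost,
    load_checkpoint,
    receptive_field,
    softmax,
    train_ensemble,
)
from cellsegnet.network import Network, _cost_grad, _MaxPool, _ReLU


def _toy_dataset(rf=9, n_per_class=120, seed=0, noise=0.3):
    """Linearly separable bright-vs-dark patches as a 2-class dataset."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    images = []
    rows = np.full(n, rf // 2)
    cols = np.full(n, rf // 2)
    labels = np.repeat([0, 1], n_per_class).astype(np.int64)
    for lab in labels:
        base = -1.0 if lab == 0 else 1.0
        images.append(base + noise * rng.normal(size=(1, rf, rf)))
    idx = np.arange(n)
    rng.shuffle(idx)
    images = [images[i] for i in idx]
    labels = labels[idx]
    is_val = np.zeros(n, dtype=bool)
    is_val[:: 10] = True
    return PatchDataset(
        images=images, patch_size=rf,
        image_index=np.arange(n), rows=rows, cols=cols, labels=labels,
        is_validation=is_val, n_classes=2, seed=seed,
    )


TOY_SPEC = NetworkSpec(conv_rounds=(ConvRound(4, 4, True), ConvRound(3, 4)),
                       fc_widths=(8,), n_classes=2)


class TestReceptiveField:
    def test_single_conv_three(self):
        spec = NetworkSpec(conv_rounds=(ConvRound(3, 2),), fc_widths=(4,))
        assert receptive_field(spec) == 3

    def test_two_convs_with_pool_between(self):
        spec = NetworkSpec(conv_rounds=(ConvRound(3, 2, True), ConvRound(3, 2)),
                          fc_widths=(4,))
        assert receptive_field(spec) == 8

    def test_default_families_match_imaging_regimes(self):
        assert receptive_field(TEST_FAMILY[31]) == 31
        assert receptive_field(FULL_FAMILY[31]) == 31
        assert receptive_field(FULL_FAMILY[61]) == 61

    def test_gradient_support_probe(self):
        # a single-pixel perturbation must influence exactly the dense
        # outputs within an rf x rf window (nonzero-footprint oracle)
        spec = TEST_FAMILY[9]
        rf = receptive_field(spec)
        net = Network(spec, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        img = rng.normal(size=(1, rf + 10, rf + 10))
        base = net.dense_scores(img)
        img2 = img.copy()
        pr = pc = rf // 2 + 5  # a pixel with full context on all sides
        img2[0, pr, pc] += 10.0
        diff = np.abs(net.dense_scores(img2) - base).sum(axis=0)
        touched = np.argwhere(diff > 1e-9)
        # dense output (i, j) corresponds to the patch centered at
        # (i + rf//2, j + rf//2) in image coordinates
        half = rf // 2
        centers = touched + half
        assert np.abs(centers - [pr, pc]).max() <= half
        rspan = centers[:, 0].max() - centers[:, 0].min() + 1
        cspan = centers[:, 1].max() - centers[:, 1].min() + 1
        assert rspan == rf and cspan == rf

    def test_filter_size_outside_family_rejected(self):
        with pytest.raises(ValueError, match="3-5"):
            NetworkSpec(conv_rounds=(ConvRound(7, 2),), fc_widths=(4,))


class TestForward:
    def test_relu_definition(self):
        relu = _ReLU()
        out = relu.forward(np.array([-2.0, 0.0, 3.0]), train=False)
        np.testing.assert_array_equal(out, [0.0, 0.0, 3.0])

    def test_maxpool_window(self):
        pool = _MaxPool()
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
        assert pool.forward(x, train=False)[0, 0, 0, 0] == 4.0

    def test_zero_weights_give_zero_scores(self):
        spec = TEST_FAMILY[9]
        net = Network(spec, np.random.default_rng(0))
        for layer in net.layers:
            for name, _ in layer.params():
                getattr(layer, name)[...] = 0.0
        patch = np.random.default_rng(1).normal(size=(1, 9, 9))
        np.testing.assert_allclose(net.forward(patch), 0.0)

    def test_shape_mismatch_rejected(self):
        net = Network(TEST_FAMILY[9], np.random.default_rng(0))
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 7, 7)))

    def test_softmax_is_probability_vector(self):
        scores = np.random.default_rng(2).normal(scale=20, size=(40, 3))
        p = softmax(scores)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestCost:
    def test_perfect_confidence_costs_nothing(self):
        scores = np.array([[100.0, 0.0, 0.0]])
        assert cost(scores, np.array([0])) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_scores_cost_log_nclasses(self):
        scores = np.zeros((1, 3))
        assert cost(scores, np.array([1])) == pytest.approx(np.log(3))

    def test_l2_term_counts_conv_filter_weights_only(self):
        net = Network(TEST_FAMILY[9], np.random.default_rng(0))
        scores = np.zeros((1, 3))
        lam = 0.01
        expected = np.log(3) + lam * net.filter_weight_sq_sum()
        assert cost(scores, np.array([0]), net, lam) == pytest.approx(expected)


class TestGradients:
    @pytest.mark.parametrize("batch_norm,dropout", [(True, 0.0), (False, 0.0)])
    def test_analytic_gradients_match_finite_differences(self, batch_norm, dropout):
        """Central-difference check across conv, relu, maxpool, fully
        connected and batch-norm layers."""
        spec = NetworkSpec(conv_rounds=(ConvRound(3, 3, True), ConvRound(3, 2)),
                           fc_widths=(5,), n_classes=3, batch_norm=batch_norm,
                           dropout_fc=dropout)
        rf = receptive_field(spec)
        net = Network(spec, np.random.default_rng(1))
        nudger = np.random.default_rng(7)
        for layer in net.layers:  # move off exact relu kinks
            for name, _ in layer.params():
                getattr(layer, name)[...] += nudger.normal(0, 0.05,
                                                           getattr(layer, name).shape)
        X = np.random.default_rng(2).normal(size=(4, 1, rf, rf))
        y = np.array([0, 1, 2, 1])
        lam = 1e-3

        def total_cost():
            return cost(net.forward(X, train=True), y, net, lam)

        scores = net.forward(X, train=True)
        net.backward(_cost_grad(scores, y))
        checker = np.random.default_rng(3)
        for layer in net.layers:
            for name, is_filter in layer.params():
                P = getattr(layer, name)
                G = getattr(layer, "d" + name).copy()
                if is_filter:
                    G = G + 2 * lam * P
                flat = P.ravel()
                for k in checker.choice(P.size, size=min(6, P.size),
                                        replace=False):
                    eps, old = 1e-5, flat[k]
                    flat[k] = old + eps
                    cp = total_cost()
                    flat[k] = old - eps
                    cm = total_cost()
                    flat[k] = old
                    num = (cp - cm) / (2 * eps)
                    ana = G.ravel()[k]
                    rel = abs(num - ana) / max(abs(num), abs(ana), 1e-6)
                    assert rel < 1e-4, (layer.kind, name, rel)


class TestTraining:
    def test_separable_problem_reaches_low_validation_error(self):
        ds = _toy_dataset()
        model = PatchClassifier(ds, TOY_SPEC)
        res = model.fit(TrainConfig(epochs=5, seed=0, batch_size=32))
        assert res.final_validation_error < 0.01

    def test_cost_decreases_over_epochs(self):
        ds = _toy_dataset()
        drops = []
        for seed in range(3):
            res = PatchClassifier(ds, TOY_SPEC).fit(
                TrainConfig(epochs=4, seed=seed, batch_size=32))
            hist = res.history_frame()
            drops.append(hist.cost.iloc[-1] < hist.cost.iloc[0])
        assert np.mean(drops) == 1.0

    def test_fixed_seed_reproduces_weights(self):
        ds = _toy_dataset()
        cfg = TrainConfig(epochs=2, seed=5, batch_size=32)
        a = PatchClassifier(ds, TOY_SPEC).fit(cfg)
        b = PatchClassifier(ds, TOY_SPEC).fit(cfg)
        for key, arr in a.network.state_arrays().items():
            np.testing.assert_array_equal(arr, b.network.state_arrays()[key])

    def test_strong_regularization_shrinks_filter_norm(self):
        ds = _toy_dataset()
        free = PatchClassifier(ds, TOY_SPEC).fit(
            TrainConfig(epochs=3, seed=1, batch_size=32, l2_lambda=0.0))
        reg = PatchClassifier(ds, TOY_SPEC).fit(
            TrainConfig(epochs=3, seed=1, batch_size=32, l2_lambda=1e3,
                        learning_rate=1e-4))
        assert (reg.network.filter_weight_sq_sum()
                < free.network.filter_weight_sq_sum())

    def test_ensemble_members_have_distinct_weights(self):
        ds = _toy_dataset()
        members = train_ensemble(ds, TOY_SPEC,
                                 TrainConfig(epochs=1, seed=0, batch_size=32),
                                 n_models=2)
        w0 = members[0].network.conv_filter_weights()[0]
        w1 = members[1].network.conv_filter_weights()[0]
        assert not np.array_equal(w0, w1)

    def test_checkpoint_round_trips_bit_exactly(self, tmp_path):
        ds = _toy_dataset()
        res = PatchClassifier(ds, TOY_SPEC).fit(
            TrainConfig(epochs=1, seed=0, batch_size=32))
        path = tmp_path / "model.npz"
        res.save(path)
        loaded = load_checkpoint(path)
        for key, arr in res.network.state_arrays().items():
            np.testing.assert_array_equal(arr, loaded.network.state_arrays()[key])
        patch = np.random.default_rng(0).normal(size=(1, 9, 9))
        np.testing.assert_array_equal(res.network.forward(patch),
                                      loaded.network.forward(patch))

    def test_patch_size_must_match_receptive_field(self):
        ds = _toy_dataset(rf=13)
        with pytest.raises(ValueError, match="receptive field"):
            PatchClassifier(ds, TOY_SPEC)

    def test_summary_reports_final_errors(self):
        ds = _toy_dataset()
        res = PatchClassifier(ds, TOY_SPEC).fit(
            TrainConfig(epochs=1, seed=0, batch_size=32))
        text = res.summary()
        assert "receptive field" in text and "validation" in text
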