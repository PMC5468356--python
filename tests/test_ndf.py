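import numpy as np
import pytest

from ki67score.ndf import (
    Conv2D,
    ForestState,
    MaxPool2D,
    Network,
    NetworkConfig,
    ReLU,
    decision_layer_forward,
    decision_routing,
    forest_predict,
    sigmoid,
    softmax_cross_entropy,
)
from ki67score.ndf.forest import DecisionLayer
from ki67score.ndf.network import LayerSpec


class TestConv:
    def test_table_output_sizes(self, rng):
        conv1 = Conv2D(3, 90, 2, rng)
        out = conv1.forward(np.zeros((1, 3, 71, 71)))
        assert out.shape == (1, 90, 70, 70)
        conv2 = Conv2D(90, 180, 4, rng)
        assert conv2.forward(np.zeros((1, 90, 35, 35))).shape == (1, 180, 32, 32)

    def test_identity_kernel(self):
        rng = np.random.default_rng(0)
        conv = Conv2D(1, 1, 1, rng)
        conv.params["W"][:] = 1.0
        conv.params["b"][:] = 0.0
        x = rng.normal(size=(1, 1, 3, 3))
        assert np.allclose(conv.forward(x), x)

    def test_oversized_filter_names_layer(self, rng):
        conv = Conv2D(1, 1, 5, rng, name="conv-test")
        with pytest.raises(ValueError, match="conv-test"):
            conv.forward(np.zeros((1, 1, 3, 3)))


class TestMaxPool:
    def test_nonoverlapping_halving(self):
        out = MaxPool2D(2).forward(np.zeros((1, 90, 70, 70)))
        assert out.shape == (1, 90, 35, 35)

    def test_constant_input_constant_output(self):
        out = MaxPool2D(2).forward(np.full((1, 1, 6, 6), 3.5))
        assert np.all(out == 3.5)

    def test_distinct_block_maxima(self):
        x = np.arange(1, 17, dtype=float).reshape(1, 1, 4, 4)
        out = MaxPool2D(2).forward(x)
        assert np.array_equal(out[0, 0], [[6, 8], [14, 16]])

    def test_odd_side_floor_drops_trailing(self):
        out = MaxPool2D(2).forward(np.zeros((1, 720, 7, 7)))
        assert out.shape == (1, 720, 3, 3)


class TestReLU:
    def test_clamps_and_preserves(self):
        x = np.array([[-3.0, 5.0, 0.0]])
        assert np.array_equal(ReLU().forward(x), [[0.0, 5.0, 0.0]])


class TestRouting:
    def test_zero_functionals_uniform_leaves(self):
        f = ForestState(n_trees=1, depth=2,
                        decision_weights=np.zeros((1, 3, 4)),
                        decision_biases=np.zeros((1, 3)))
        mu = decision_routing(np.ones(4), f)
        assert np.allclose(mu, 0.25)

    def test_saturated_routing_single_leaf(self):
        f = ForestState(n_trees=1, depth=3,
                        decision_weights=np.zeros((1, 7, 2)),
                        decision_biases=np.full((1, 7), 50.0))
        mu = decision_routing(np.zeros(2), f)
        assert mu[0] == pytest.approx(1.0, abs=1e-12)
        assert mu[1:].max() < 1e-12

    def test_matches_brute_force_path_products_depth3(self, rng):
        in_dim = 6
        f = ForestState.init_random(2, 3, in_dim, rng, scale=1.0)
        x = rng.normal(size=in_dim)
        for t in range(2):
            mu = decision_routing(x, f, tree=t)
            d = sigmoid(f.decision_weights[t] @ x + f.decision_biases[t])
            expected = np.empty(8)
            for leaf in range(8):
                prob, node = 1.0, 0
                for bit in (leaf >> 2 & 1, leaf >> 1 & 1, leaf & 1):
                    prob *= d[node] if bit == 0 else 1.0 - d[node]
                    node = 2 * node + 1 + bit
                expected[leaf] = prob
            assert np.allclose(mu, expected, atol=1e-12)
            assert mu.sum() == pytest.approx(1.0, abs=1e-12)

    def test_sums_to_one_over_many_random_draws(self, rng):
        f = ForestState.init_random(5, 4, 8, rng, scale=3.0)
        X = rng.normal(size=(2000, 8))
        from ki67score.ndf.forest import _routing_forward
        mu, _ = _routing_forward(X, f)
        assert np.allclose(mu.sum(axis=2), 1.0, atol=1e-9)


class TestForestPredict:
    def test_uniform_leaves_give_uniform_output(self, rng):
        f = ForestState.init_random(3, 2, 5, rng)  # leaf logits zero -> uniform pi
        out = forest_predict(rng.normal(size=5), f)
        assert np.allclose(out, 0.5)

    def test_depth_zero_tree_returns_leaf_distribution(self):
        pi = np.array([[[0.3, 0.7]]])
        f = ForestState.from_leaf_distributions(
            np.zeros((1, 0, 4)), np.zeros((1, 0)), pi)
        out = forest_predict(np.ones(4), f)
        assert np.allclose(out, [0.3, 0.7])

    def test_two_trees_depth_one_hand_computed(self):
        w = np.zeros((2, 1, 1))
        b = np.array([[0.0], [np.log(3.0)]])  # d = 0.5 and 0.75 at x=0
        pi = np.array([[[0.9, 0.1], [0.2, 0.8]],
                       [[0.6, 0.4], [0.5, 0.5]]])
        f = ForestState.from_leaf_distributions(w, b, pi)
        out = forest_predict(np.zeros(1), f)
        t1 = 0.5 * pi[0, 0] + 0.5 * pi[0, 1]
        t2 = 0.75 * pi[1, 0] + 0.25 * pi[1, 1]
        assert np.allclose(out, (t1 + t2) / 2, atol=1e-12)
        assert out.sum() == pytest.approx(1.0)

    def test_probability_outputs_are_distributions(self, rng):
        f = ForestState.init_random(4, 3, 6, rng, scale=2.0)
        f.leaf_logits = rng.normal(size=f.leaf_logits.shape)
        out = forest_predict(rng.normal(size=(50, 6)), f)
        assert np.all(out >= 0) and np.allclose(out.sum(axis=1), 1.0)


class TestDecisionLayer:
    def test_default_embedding_width_720(self, rng):
        f = ForestState.init_random(45, 4, 5760, rng)
        out = decision_layer_forward(rng.normal(size=5760), f)
        assert out.shape == (720,)

    def test_zero_functionals_give_uniform_sixteenths(self):
        f = ForestState(n_trees=45, depth=4,
                        decision_weights=np.zeros((45, 15, 10)),
                        decision_biases=np.zeros((45, 15)))
        out = decision_layer_forward(np.ones(10), f)
        assert np.allclose(out, 1.0 / 16.0)

    def test_each_tree_slice_sums_to_one(self, rng):
        f = ForestState.init_random(6, 4, 12, rng, scale=2.0)
        out = decision_layer_forward(rng.normal(size=12), f)
        assert np.allclose(out.reshape(6, 16).sum(axis=1), 1.0, atol=1e-9)

    def test_probability_mode_concatenates_tree_posteriors(self, rng):
        f = ForestState.init_random(3, 2, 7, rng, scale=1.0)
        out = decision_layer_forward(rng.normal(size=7), f, mode="probability")
        assert out.shape == (6,)
        assert np.allclose(out.reshape(3, 2).sum(axis=1), 1.0)

    def test_dimension_mismatch_raises(self, rng):
        f = ForestState.init_random(2, 2, 10, rng)
        with pytest.raises(ValueError, match="features"):
            decision_layer_forward(np.ones(9), f)

    def test_gradient_check_embedding_mode(self, rng):
        """Backpropagated decision-layer gradients agree with central
        finite differences to < 1e-4 relative error (depth-2, 2 trees)."""
        f = ForestState.init_random(2, 2, 5, rng, scale=1.0)
        layer = DecisionLayer(f)
        X = rng.normal(size=(3, 5))
        C = rng.normal(size=(3, layer.forest.embedding_width))  # random loss weights

        def loss():
            return float((layer.forward(X) * C).sum())

        base = loss()
        layer.backward(C)
        eps = 1e-6
        for pname in ("W", "b"):
            p, g = layer.params[pname], layer.grads[pname]
            for ix in np.ndindex(p.shape):
                old = p[ix]
                p[ix] = old + eps
                lp = loss()
                p[ix] = old - eps
                lm = loss()
                p[ix] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[ix]) <= 1e-4 * max(abs(num), abs(g[ix]), 1e-6)


class TestNetwork:
    def test_full_architecture_spatial_chain(self):
        net = Network(NetworkConfig.full(), rng_seed=0)
        sides = net.shape_chain()
        spatial = [s for s, l in zip(sides, net.layers)
                   if l.name.startswith(("conv", "maxpool"))]
        assert spatial == [70, 35, 32, 16, 14, 7, 6, 3, 2]
        decision = [s for s, l in zip(sides, net.layers) if l.name.startswith("decision")]
        assert decision == [720]
        assert sides[-1] == 2

    def test_forward_scores_length_two_and_deterministic(self, rng):
        net = Network(NetworkConfig.small(), rng_seed=1)
        x = rng.random((2, 3, 71, 71))
        s1 = net.forward(x)
        s2 = net.forward(x)
        assert s1.shape == (2, 2)
        assert np.array_equal(s1, s2)  # dropout off outside training

    def test_whole_net_gradients_match_finite_differences(self, rng):
        cfg = NetworkConfig(n_classes=2, dropout_ratio=0.0, input_shape=(2, 8, 8))
        cfg.layers = [
            LayerSpec("conv", maps=3, filter=2), LayerSpec("relu"),
            LayerSpec("maxpool", filter=2),
            LayerSpec("decision", n_trees=2, depth=2),
            LayerSpec("fc", maps=4), LayerSpec("relu"),
            LayerSpec("fc", maps=2),
        ]
        net = Network(cfg, rng_seed=3)
        X = rng.random((4, 2, 8, 8))
        y = np.array([0, 1, 0, 1])

        def loss():
            return softmax_cross_entropy(net.forward(X), y)[0]

        l0, ds = softmax_cross_entropy(net.forward(X), y)
        net.backward(ds)
        eps = 1e-6
        for layer, name, p in net.parameters():
            g = layer.grads[name]
            flat = list(np.ndindex(p.shape))
            for ix in flat[:: max(1, len(flat) // 10)]:
                old = p[ix]
                p[ix] = old + eps
                lp = loss()
                p[ix] = old - eps
                lm = loss()
                p[ix] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[ix]) <= 1e-4 * max(abs(num), abs(g[ix]), 1e-6), \
                    f"{layer.name}.{name}[{ix}]"
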