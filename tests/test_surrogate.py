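import numpy as np
import pytest

import pinndesign as P
from pinndesign.geometry import ParameterError
from pinndesign.surrogate import SurrogateModel, _leaky


def tiny_model(rng, f=6, s=7, depth=2, stats=True):
    m = SurrogateModel(
        K0=rng.standard_normal((s, f)),
        hidden=[rng.standard_normal((s, s)) * 0.3 for _ in range(depth)],
        Kout=rng.standard_normal((2, s)),
    )
    if stats:
        m.norm_stats = P.NormStats(mean=np.array([1.0, -2.0]), std=np.array([1.5, 0.5]))
    return m


def random_laplacian(rng, n):
    a = np.abs(rng.standard_normal((n, n)))
    a = a + a.T
    np.fill_diagonal(a, 0)
    return P.graph_laplacian(a).matrix


class TestForward:
    def test_zero_weights_give_zero_output(self, rng):
        m = SurrogateModel(
            K0=np.zeros((4, 6)), hidden=[np.zeros((4, 4))], Kout=np.zeros((2, 4))
        )
        out = P.forward(m, rng.standard_normal((6, 5)), random_laplacian(rng, 5))
        assert np.all(out == 0)

    def test_no_hidden_layers_is_linear(self, rng):
        m = SurrogateModel(
            K0=rng.standard_normal((4, 6)), hidden=[], Kout=rng.standard_normal((2, 4))
        )
        X = rng.standard_normal((6, 5))
        out = P.forward(m, X, random_laplacian(rng, 5))
        assert np.allclose(out, m.Kout @ m.K0 @ X, atol=1e-12)

    def test_matches_hand_unrolled_loop(self, rng):
        m = tiny_model(rng, f=6, s=7, depth=3, stats=False)
        X = rng.standard_normal((6, 5))
        L = random_laplacian(rng, 5)
        # independent unrolled computation
        Y = m.K0 @ X
        for K in m.hidden:
            Y = Y + _leaky(K @ Y @ L, m.slope)
        expected = m.Kout @ Y
        assert np.allclose(P.forward(m, X, L), expected, atol=1e-12)

    def test_shape_errors_name_operand(self, rng):
        m = tiny_model(rng)
        with pytest.raises(ValueError, match="rows"):
            P.forward(m, rng.standard_normal((5, 5)), random_laplacian(rng, 5))
        with pytest.raises(ValueError, match="Laplacian"):
            P.forward(m, rng.standard_normal((6, 5)), random_laplacian(rng, 4))

    def test_node_permutation_equivariance(self, rng):
        m = tiny_model(rng, stats=False)
        X = rng.standard_normal((6, 8))
        L = random_laplacian(rng, 8)
        perm = rng.permutation(8)
        out = P.forward(m, X, L)
        out_p = P.forward(m, X[:, perm], L[np.ix_(perm, perm)])
        assert np.allclose(out_p, out[:, perm], atol=1e-10)


class TestCountParameters:
    def test_hand_counted_minimal_model(self):
        m = SurrogateModel(K0=np.zeros((1, 4)), hidden=[np.zeros((1, 1))], Kout=np.zeros((2, 1)))
        assert P.count_parameters(m) == 7

    def test_matches_flattened_weight_list(self, rng):
        m = tiny_model(rng, f=9, s=11, depth=4)
        flat = np.concatenate([w.ravel() for w in m.weights()])
        assert P.count_parameters(m) == flat.size

    def test_formula_and_monotone_in_width(self):
        for s, k, depth in [(8, 20, 5), (16, 20, 5), (64, 20, 3)]:
            m = P.init_model(k + 3, s, depth)
            assert P.count_parameters(m) == s * (k + 3) + depth * s**2 + 2 * s
        small = P.count_parameters(P.init_model(23, 32, 5))
        large = P.count_parameters(P.init_model(23, 64, 5))
        assert large > small


def make_examples(rng, n_ex=6, n=5, f=6):
    L = random_laplacian(rng, n)
    lap = P.GraphLaplacian(matrix=L, kernel_scale=8.0)
    return [
        P.LabeledExample(
            features=rng.standard_normal((f, n)),
            laplacian=lap,
            targets=rng.standard_normal((2, n)),
        )
        for _ in range(n_ex)
    ]


class TestStandardizeTargets:
    def test_pooled_zero_mean_unit_sd_and_round_trip(self, rng):
        examples = make_examples(rng)
        std, stats = P.standardize_targets(examples)
        pooled = np.concatenate([e.targets for e in std], axis=1)
        assert np.allclose(pooled.mean(axis=1), 0.0, atol=1e-8)
        assert np.allclose(pooled.std(axis=1), 1.0, atol=1e-8)
        back = stats.inverse(std[0].targets)
        assert np.allclose(back, examples[0].targets, atol=1e-10)

    def test_constant_channel_rejected(self, rng):
        examples = make_examples(rng, n_ex=3)
        for e in examples:
            e.targets[0] = 4.2
        with pytest.raises(ParameterError):
            P.standardize_targets(examples)


class TestTrain:
    def test_recovers_realizable_linear_target(self, rng):
        # targets are a fixed linear readout of the features: the network
        # contains this function exactly, so validation error must collapse
        n, f = 6, 8
        L = random_laplacian(rng, n)
        lap = P.GraphLaplacian(matrix=L, kernel_scale=8.0)
        true_map = rng.standard_normal((2, f))
        examples = []
        for _ in range(40):
            X = rng.standard_normal((f, n))
            examples.append(
                P.LabeledExample(features=X, laplacian=lap, targets=true_map @ X)
            )
        std, stats = P.standardize_targets(examples)
        model = P.init_model(f, width=16, depth=2, seed=0)
        model.norm_stats = stats
        cfg = P.TrainConfig(epochs=200, batch_size=8, learning_rate=5e-3, seed=0)
        model, history = P.train(model, std, cfg)
        rel = P.validation_relative_error(model, std)
        assert np.all(rel < 0.05)

    def test_overfits_tiny_dataset(self, rng):
        examples = make_examples(rng, n_ex=4, n=4, f=5)
        std, stats = P.standardize_targets(examples)
        model = P.init_model(5, width=24, depth=2, seed=1)
        model.norm_stats = stats
        cfg = P.TrainConfig(
            epochs=600, batch_size=0, learning_rate=1e-2, seed=1,
            validation_fraction=0.25, ema_decay=0.0, channel_weights=(1.0, 1.0),
        )
        model, history = P.train(model, std, cfg)
        assert history.train_loss[-1] < 1e-3

    def test_same_seed_is_bit_reproducible(self, rng):
        examples = make_examples(rng, n_ex=8)
        std, stats = P.standardize_targets(examples)
        runs = []
        for _ in range(2):
            model = P.init_model(6, width=8, depth=2, seed=3)
            model.norm_stats = stats
            m, h = P.train(model, std, P.TrainConfig(epochs=30, seed=3))
            runs.append((h.train_loss[-1], h.val_loss[-1], m.K0.copy()))
        assert runs[0][0] == runs[1][0]
        assert runs[0][1] == runs[1][1]
        assert np.array_equal(runs[0][2], runs[1][2])

    def test_divergence_aborts(self, rng):
        examples = make_examples(rng, n_ex=4)
        std, stats = P.standardize_targets(examples)
        model = P.init_model(6, width=8, depth=2, seed=0)
        model.norm_stats = stats
        model.K0 *= 1e200  # force overflow
        with pytest.raises(FloatingPointError):
            P.train(model, std, P.TrainConfig(epochs=3, seed=0))


class TestPredictDesignMetrics:
    def test_zero_weight_model_returns_channel_means(self, rng):
        m = SurrogateModel(
            K0=np.zeros((4, 23)), hidden=[np.zeros((4, 4))], Kout=np.zeros((2, 4))
        )
        m.norm_stats = P.NormStats(mean=np.array([3.0, 0.8]), std=np.array([2.0, 0.2]))
        n = 6
        S = P.one_hot("ACDEFG")
        e, r, per = P.predict_design_metrics(
            m, S, np.zeros((3, n)), random_laplacian(rng, n)
        )
        assert e == pytest.approx(3.0 * n)
        assert r == pytest.approx(0.8)
        assert np.allclose(per[0], 3.0) and np.allclose(per[1], 0.8)

    def test_permutation_equivariance_of_outputs(self, rng):
        m = tiny_model(rng, f=23, s=9, depth=2)
        n = 7
        S = P.project_feasible(rng.standard_normal((20, n)))
        geo = rng.standard_normal((3, n))
        L = random_laplacian(rng, n)
        perm = rng.permutation(n)
        _, _, per = P.predict_design_metrics(m, S, geo, L)
        _, _, per_p = P.predict_design_metrics(
            m, S[:, perm], geo[:, perm], L[np.ix_(perm, perm)]
        )
        assert np.allclose(per_p, per[:, perm], atol=1e-10)

    def test_out_of_range_matrix_warns(self, rng):
        m = tiny_model(rng, f=23, s=5, depth=1)
        S = np.full((20, 5), 2.0)
        with pytest.warns(UserWarning):
            P.predict_design_metrics(m, S, np.zeros((3, 5)), random_laplacian(rng, 5))

    def test_memorizes_overfit_training_example(self, rng):
        # an overfit model must reproduce a training example's targets when
        # queried with that example's one-hot sequence
        n = 5
        seqs = ["ACDEF", "GHIKL", "MNPQR", "STVWY"]
        L = random_laplacian(rng, n)
        lap = P.GraphLaplacian(matrix=L, kernel_scale=8.0)
        geo = rng.standard_normal((3, n))
        examples = [
            P.LabeledExample(
                features=np.vstack([P.one_hot(s), geo]),
                laplacian=lap,
                targets=rng.standard_normal((2, n)),
            )
            for s in seqs
        ]
        raw_targets = [e.targets.copy() for e in examples]
        std, stats = P.standardize_targets(examples)
        model = P.init_model(23, width=32, depth=2, seed=5)
        model.norm_stats = stats
        cfg = P.TrainConfig(
            epochs=800, batch_size=0, learning_rate=1e-2, seed=5,
            validation_fraction=0.25, ema_decay=0.0, channel_weights=(1.0, 1.0),
        )
        model, history = P.train(model, std, cfg)
        # check an example from the training split (index from the seeded split)
        order = np.random.default_rng(5).permutation(4)
        i = order[-1]
        _, _, per = P.predict_design_metrics(model, P.one_hot(seqs[i]), geo, L)
        train_rmse = np.sqrt(history.train_loss[-1])
        assert np.abs(
            (per - raw_targets[i]) / stats.std[:, None]
        ).max() < max(10 * train_rmse, 0.1)


class TestSequenceGradient:
    def test_matches_central_differences(self, rng):
        m = tiny_model(rng, f=13, s=7, depth=3)
        n, k = 5, 10
        geo = rng.standard_normal((3, n))
        L = random_laplacian(rng, n)
        S = P.project_feasible(rng.standard_normal((k, n)))
        _, g = P.objective_value_and_grad(m, S, geo, L, 2.0, 0.1)
        h = 1e-6
        num = np.zeros_like(S)
        for i in range(k):
            for j in range(n):
                Sp, Sm = S.copy(), S.copy()
                Sp[i, j] += h
                Sm[i, j] -= h
                fp, _ = P.objective_value_and_grad(m, Sp, geo, L, 2.0, 0.1)
                fm, _ = P.objective_value_and_grad(m, Sm, geo, L, 2.0, 0.1)
                num[i, j] = (fp - fm) / (2 * h)
        assert np.abs(g - num).max() / np.abs(num).max() < 1e-4

    def test_zero_readout_gives_zero_gradient(self, rng):
        m = tiny_model(rng, f=13, s=6, depth=2)
        m.Kout = np.zeros_like(m.Kout)
        S = P.project_feasible(rng.standard_normal((10, 5)))
        _, g = P.objective_value_and_grad(
            m, S, rng.standard_normal((3, 5)), random_laplacian(rng, 5)
        )
        assert np.all(g == 0)

    def test_no_penalty_ignores_deviation_head(self, rng):
        m = tiny_model(rng, f=13, s=6, depth=2)
        S = P.project_feasible(rng.standard_normal((10, 5)))
        geo = rng.standard_normal((3, 5))
        L = random_laplacian(rng, 5)
        _, g0 = P.objective_value_and_grad(m, S, geo, L, stability_weight=0.0)
        m2 = m.copy()
        m2.Kout[1] = rng.standard_normal(6)  # change only the deviation head
        _, g1 = P.objective_value_and_grad(m2, S, geo, L, stability_weight=0.0)
        assert np.allclose(g0, g1, atol=1e-12)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        m = tiny_model(rng, f=23, s=5, depth=2)
        path = tmp_path / "model.ckpt.npz"
        m.save(path)
        m2 = SurrogateModel.load(path)
        for a, b in zip(m.weights(), m2.weights()):
            assert np.array_equal(a, b)
        assert np.array_equal(m.norm_stats.mean, m2.norm_stats.mean)
        X = rng.standard_normal((23, 6))
        L = random_laplacian(rng, 6)
        assert np.array_equal(P.forward(m, X, L), P.forward(m2, X, L))
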