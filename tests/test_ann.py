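"""Network forward pass, backprop gradients, training and ensembles."""

import numpy as np
import pandas as pd
import pytest

from sensipod import ANNConfig, ANNEnsemble, benchmark
from sensipod.ann import (ANNModel, ScalingParams, derive_run_seeds,
                          endpoint_array, gradients, train,
                          validate_training_table, _logistic)
from sensipod.errors import InvalidInputError, SchemaError


def toy_table(n=12, seed=0, with_imax=True):
    rng = np.random.default_rng(seed)
    log_ec3 = rng.uniform(-2, 1, size=n)
    d = {
        "chemical": [f"T{i}" for i in range(n)],
        "avg_lys_cys": 100 / (1 + 10 ** (0.5 * log_ec3)),
        "mit_ug_ml": 10 ** (0.5 * log_ec3 + 1),
        "ec3_pct": 10 ** log_ec3,
        "split": ["train"] * n,
    }
    if with_imax:
        d["imax"] = 1 + 3 * (1 - log_ec3 / 1.3)
    return pd.DataFrame(d)


class TestScaling:
    def test_extremes_map_to_margins(self):
        vals = np.array([[1.0], [10.0], [100.0]])
        sp = ScalingParams.fit(vals, margin=0.05)
        scaled = sp.transform(vals)[:, 0]
        assert scaled[0] == pytest.approx(0.05)
        assert scaled[1] == pytest.approx(0.5)
        assert scaled[2] == pytest.approx(0.95)

    def test_round_trip_identity(self, rng):
        vals = 10 ** rng.uniform(-3, 3, size=(50, 3))
        sp = ScalingParams.fit(vals, margin=0.05)
        back = sp.inverse(sp.transform(vals))
        assert np.allclose(back, vals, rtol=1e-12)

    def test_nonpositive_inputs_rejected(self):
        sp = ScalingParams.fit(np.array([[1.0], [10.0]]), margin=0.05)
        with pytest.raises(InvalidInputError):
            sp.transform(np.array([[0.0]]))


class TestForward:
    def zero_model(self, n_in=2):
        sizes = (n_in, 5, 2, 1)
        weights = [np.zeros((sizes[i], sizes[i + 1])) for i in range(3)]
        biases = [np.zeros(sizes[i + 1]) for i in range(3)]
        sp = ScalingParams(np.zeros(n_in), np.ones(n_in), 0.05)
        spy = ScalingParams(np.zeros(1), np.ones(1), 0.05)
        return ANNModel(weights, biases, sp, spy, ANNConfig(variant="D_hC"))

    def test_all_zero_parameters_output_half(self):
        m = self.zero_model()
        assert m.forward(np.array([[0.3, 0.9]]))[0] == pytest.approx(0.5)

    def test_hand_computed_single_path(self):
        # 2 -> 1 -> 1 -> 1 effective path embedded in the 5/2 topology
        m = self.zero_model()
        m.weights[0][:, 0] = [1.0, -2.0]
        m.biases[0][0] = 0.5
        m.weights[1][0, 0] = 2.0
        m.weights[2][0, 0] = -1.5
        x = np.array([[0.4, 0.1]])
        h1 = 1 / (1 + np.exp(-(0.4 * 1.0 + 0.1 * -2.0 + 0.5)))
        h1_rest = 0.5  # four untouched hidden-1 units
        h2a = 1 / (1 + np.exp(-(2.0 * h1)))
        h2b = 0.5
        out = 1 / (1 + np.exp(-(-1.5 * h2a)))
        assert m.forward(x)[0] == pytest.approx(out, abs=1e-6)
        assert h1_rest == h2b  # documents the untouched-unit values used above

    def test_output_bounded_for_any_weights(self, rng):
        m = self.zero_model()
        for _ in range(10):
            m.weights = [rng.normal(0, 10, size=w.shape) for w in m.weights]
            m.biases = [rng.normal(0, 10, size=b.shape) for b in m.biases]
            out = m.forward(rng.uniform(0, 1, size=(20, 2)))
            assert np.all((out > 0) & (out < 1))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            self.zero_model().forward(np.ones((1, 3)))


class TestGradients:
    def test_backprop_matches_central_finite_differences(self, rng):
        """Analytic gradients agree with central differences to 1e-6 relative."""
        sizes = (3, 5, 2, 1)
        weights = [rng.normal(0, 0.7, size=(sizes[i], sizes[i + 1]))
                   for i in range(3)]
        biases = [rng.normal(0, 0.7, size=sizes[i + 1]) for i in range(3)]
        x = rng.uniform(0, 1, size=(7, 3))
        y = rng.uniform(0.1, 0.9, size=7)

        def loss(ws, bs):
            a = x
            for W, b in zip(ws, bs):
                a = _logistic(a @ W + b)
            return np.mean((a[:, 0] - y) ** 2)

        gw, gb = gradients(weights, biases, x, y)
        eps = 1e-6
        for k in range(3):
            for idx in np.ndindex(weights[k].shape):
                w_plus = [w.copy() for w in weights]
                w_minus = [w.copy() for w in weights]
                w_plus[k][idx] += eps
                w_minus[k][idx] -= eps
                num = (loss(w_plus, biases) - loss(w_minus, biases)) / (2 * eps)
                assert gw[k][idx] == pytest.approx(num, rel=1e-6, abs=1e-9)
            for i in range(biases[k].size):
                b_plus = [b.copy() for b in biases]
                b_minus = [b.copy() for b in biases]
                b_plus[k][i] += eps
                b_minus[k][i] -= eps
                num = (loss(weights, b_plus) - loss(weights, b_minus)) / (2 * eps)
                assert gb[k][i] == pytest.approx(num, rel=1e-6, abs=1e-9)


class TestTraining:
    def test_converges_on_noiseless_toy_target(self):
        table = toy_table(n=12)
        cfg = ANNConfig(variant="D_hC", iterations=10_000, seed=3)
        model = train(table, cfg)
        Xs = model.x_scaling.transform(
            table[["avg_lys_cys", "mit_ug_ml"]].to_numpy())
        ys = model.y_scaling.transform(
            table["ec3_pct"].to_numpy().reshape(-1, 1))[:, 0]
        rmse_scaled = np.sqrt(np.mean((model.forward(Xs) - ys) ** 2))
        assert rmse_scaled < 0.05

    def test_same_seed_bit_identical_weights(self):
        table = toy_table()
        cfg = ANNConfig(variant="D_hC", iterations=50, seed=11)
        m1, m2 = train(table, cfg), train(table, cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)

    def test_different_seeds_differ(self):
        table = toy_table()
        m1 = train(table, ANNConfig(variant="D_hC", iterations=50, seed=1))
        m2 = train(table, ANNConfig(variant="D_hC", iterations=50, seed=2))
        assert not np.allclose(m1.weights[0], m2.weights[0])

    def test_predictions_positive_and_deterministic(self):
        table = toy_table()
        model = train(table, ANNConfig(variant="D_hC", iterations=200, seed=5))
        vec = {"avg_lys_cys": 40.0, "mit_ug_ml": 5.0}
        p1, p2 = model.predict_ec3(vec), model.predict_ec3(vec)
        assert p1 == p2 and p1 > 0

    def test_near_interpolating_model_close_to_training_rows(self):
        table = toy_table(n=12)
        model = train(table, ANNConfig(variant="D_hC", iterations=10_000, seed=3))
        for _, row in table.iterrows():
            pred = model.predict_ec3(
                {"avg_lys_cys": row.avg_lys_cys, "mit_ug_ml": row.mit_ug_ml})
            assert pred / row.ec3_pct < 2 and row.ec3_pct / pred < 2

    def test_missing_endpoint_rejected(self):
        table = toy_table()
        model = train(table, ANNConfig(variant="D_hC", iterations=10, seed=5))
        with pytest.raises(InvalidInputError):
            model.predict_ec3({"avg_lys_cys": 40.0, "mit_ug_ml": None})

    def test_duplicate_chemicals_rejected(self):
        table = toy_table()
        table.loc[1, "chemical"] = table.loc[0, "chemical"]
        with pytest.raises(SchemaError):
            validate_training_table(table, "D_hC")


@pytest.fixture(scope="module")
def ensemble():
    cfg = ANNConfig(variant="D_hC", iterations=400, seed=42)
    return ANNEnsemble.fit(toy_table(n=16), cfg, n_runs=12)


class TestEnsemble:
    def test_run_count_and_ci_ordering(self, ensemble):
        pred = ensemble.predict({"avg_lys_cys": 45.0, "mit_ug_ml": 6.0})
        assert pred.n_runs == 12
        assert 0 <= pred.ci_low <= pred.mean_ec3 <= pred.ci_high
        assert all(v > 0 for v in pred.per_run_ec3)

    def test_seed_reproducibility(self):
        cfg = ANNConfig(variant="D_hC", iterations=100, seed=9)
        p1 = ANNEnsemble.fit(toy_table(), cfg, n_runs=5).predict(
            {"avg_lys_cys": 45.0, "mit_ug_ml": 6.0})
        p2 = ANNEnsemble.fit(toy_table(), cfg, n_runs=5).predict(
            {"avg_lys_cys": 45.0, "mit_ug_ml": 6.0})
        assert p1.per_run_ec3 == p2.per_run_ec3
        assert p1.mean_ec3 == p2.mean_ec3

    def test_mean_invariant_under_run_permutation(self, ensemble, rng):
        pred = ensemble.predict({"avg_lys_cys": 45.0, "mit_ug_ml": 6.0})
        shuffled = rng.permutation(pred.per_run_ec3)
        assert np.mean(shuffled) == pytest.approx(pred.mean_ec3, abs=1e-9)

    def test_run_seeds_deterministic_and_distinct(self):
        s1 = derive_run_seeds(123, 100)
        s2 = derive_run_seeds(123, 100)
        assert np.array_equal(s1, s2)
        assert len(np.unique(s1)) == 100
        assert s1.max() < 2 ** 31


class TestBenchmark:
    def test_perfect_and_constant_predictors(self):
        table = toy_table(n=8)

        class Fake:
            config = ANNConfig(variant="D_hC")

            def __init__(self, values):
                self.values = list(values)

            def predict_ec3(self, x):
                return self.values.pop(0)

        perfect = benchmark(Fake(table.ec3_pct.tolist()), table, "train")
        assert perfect.r_squared == pytest.approx(1.0)
        assert perfect.rmse_log10 == pytest.approx(0.0)

        gm = 10 ** np.mean(np.log10(table.ec3_pct))
        const = benchmark(Fake([gm] * 8), table, "train")
        assert const.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_three_points(self):
        table = toy_table(n=8).iloc[:3].copy()
        table["ec3_pct"] = [0.1, 1.0, 10.0]

        class Fake:
            config = ANNConfig(variant="D_hC")
            vals = [0.2, 1.0, 5.0]

            def predict_ec3(self, x):
                return Fake.vals.pop(0)

        res = benchmark(Fake(), table, "train")
        obs = np.log10([0.1, 1.0, 10.0])
        pred = np.log10([0.2, 1.0, 5.0])
        ss_res = np.sum((pred - obs) ** 2)
        ss_tot = np.sum((obs - obs.mean()) ** 2)
        assert res.r_squared == pytest.approx(1 - ss_res / ss_tot)
        assert res.rmse_log10 == pytest.approx(np.sqrt(ss_res / 3))
        assert res.n == 3

    def test_empty_split_errors(self):
        with pytest.raises(SchemaError):
            benchmark(train(toy_table(), ANNConfig(variant="D_hC", iterations=10)),
                      toy_table(), "test")


class TestEndpointArray:
    def test_variant_feature_selection(self):
        x = endpoint_array({"avg_lys_cys": 50, "mit_ug_ml": 2, "imax": 3}, "D_hC")
        assert x.tolist() == [50, 2]
        x = endpoint_array([50, 2, 3], "D_hC_KS")
        assert x.tolist() == [50, 2, 3]

    def test_missing_or_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            endpoint_array({"avg_lys_cys": 50}, "D_hC")
        with pytest.raises(InvalidInputError):
            endpoint_array([50, -1], "D_hC")
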