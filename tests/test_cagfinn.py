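import numpy as np
import pytest

from msitvc import (AsymmetricMF, CAGFINNRegressor, FuzzyPartition,
                    generate_tsk_dataset, membership, tsk_forward)
from msitvc.cagfinn import _forward, premise_gradients


def make_model(rng, c=4, q=3):
    return CAGFINNRegressor.from_parameters(
        centers=rng.normal(size=(c, q)),
        sigma_left=rng.uniform(0.3, 1.0, (c, q)),
        sigma_right=rng.uniform(0.3, 1.0, (c, q)),
        consequents=rng.normal(size=(c, q + 1)),
    )


class TestMembership:
    def test_peak_exactly_one_at_center(self):
        mf = AsymmetricMF(center=2.0, sigma_left=0.5, sigma_right=1.5)
        assert membership(mf, 2.0) == 1.0

    def test_symmetric_spreads_reduce_to_wide_gaussian(self):
        s = 0.7
        mf = AsymmetricMF(center=1.0, sigma_left=s, sigma_right=s)
        for x in (-1.0, 0.5, 1.0, 2.3):
            expected = np.exp(-((x - 1.0) ** 2) / (2 * (2 * s) ** 2))
            assert membership(mf, x) == pytest.approx(expected, abs=1e-15)

    def test_one_total_spread_from_center(self):
        mf = AsymmetricMF(center=0.0, sigma_left=0.4, sigma_right=0.6)
        val = membership(mf, mf.sigma_total)
        assert val == pytest.approx(np.exp(-0.5), abs=1e-12)
        assert mf.side_index == "right"
        membership(mf, -0.1)
        assert mf.side_index == "left"

    def test_non_finite_input_rejected(self):
        mf = AsymmetricMF(center=0.0, sigma_left=1.0, sigma_right=1.0)
        with pytest.raises(ValueError):
            membership(mf, np.nan)

    def test_non_positive_spreads_rejected(self):
        with pytest.raises(ValueError):
            AsymmetricMF(center=0.0, sigma_left=0.0, sigma_right=1.0)


class TestFireRules:
    def test_single_rule_normalizes_to_one(self):
        rng = np.random.default_rng(0)
        model = make_model(rng, c=1)
        _, rbar = model.fire_rules(rng.normal(size=3))
        np.testing.assert_allclose(rbar, [1.0])

    def test_input_at_rule_center_fires_fully(self):
        rng = np.random.default_rng(1)
        model = make_model(rng)
        R, _ = model.fire_rules(model.centers_[2])
        assert R[2] == pytest.approx(1.0, abs=1e-15)

    def test_matches_brute_force_product_normalize_oracle(self):
        rng = np.random.default_rng(2)
        model = make_model(rng, c=4, q=3)
        for _ in range(20):
            x = rng.normal(size=3)
            R, rbar = model.fire_rules(x)
            b = model.sigma_left_ + model.sigma_right_
            R_oracle = np.array([
                np.prod([np.exp(-((x[j] - model.centers_[i, j]) ** 2)
                                / (2 * b[i, j] ** 2)) for j in range(3)])
                for i in range(4)
            ])
            np.testing.assert_allclose(R, R_oracle, atol=1e-12)
            np.testing.assert_allclose(rbar, R_oracle / R_oracle.sum(), atol=1e-12)

    def test_normalized_strengths_sum_to_one_everywhere(self):
        rng = np.random.default_rng(3)
        model = make_model(rng, c=6, q=2)
        for _ in range(200):
            _, rbar = model.fire_rules(rng.normal(scale=3.0, size=2))
            assert rbar.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_rules_underflow_falls_back_to_uniform(self):
        model = CAGFINNRegressor.from_parameters(
            centers=[[0.0], [1.0]], sigma_left=[[1e-3], [1e-3]],
            sigma_right=[[1e-3], [1e-3]], consequents=[[0.0, 1.0], [0.0, 3.0]],
        )
        _, rbar = model.fire_rules([1e6])
        np.testing.assert_allclose(rbar, [0.5, 0.5])
        assert model.predict([[1e6]])[0] == pytest.approx(2.0)

    def test_dimension_mismatch_rejected(self):
        model = make_model(np.random.default_rng(4))
        with pytest.raises(ValueError, match="dimension"):
            model.fire_rules([1.0, 2.0])


class TestPredict:
    def test_equal_biases_give_constant_output(self):
        rng = np.random.default_rng(5)
        consequents = np.zeros((3, 4))
        consequents[:, -1] = 7.5
        model = CAGFINNRegressor.from_parameters(
            centers=rng.normal(size=(3, 3)),
            sigma_left=np.full((3, 3), 0.5), sigma_right=np.full((3, 3), 0.5),
            consequents=consequents,
        )
        preds = model.predict(rng.normal(size=(30, 3)))
        np.testing.assert_allclose(preds, 7.5, atol=1e-12)

    def test_single_rule_affine_evaluation(self):
        model = CAGFINNRegressor.from_parameters(
            centers=[[0.0]], sigma_left=[[0.5]], sigma_right=[[0.5]],
            consequents=[[2.0, 1.0]],
        )
        assert model.predict([[3.0]])[0] == pytest.approx(7.0)

    def test_matches_ground_truth_tsk_generator(self, tsk_system):
        X, y = generate_tsk_dataset(60, tsk_system, noise_sd=0.0, seed=1)
        model = CAGFINNRegressor.from_parameters(
            centers=[r[0] for r in tsk_system],
            sigma_left=[r[1] / 2 for r in tsk_system],
            sigma_right=[r[1] / 2 for r in tsk_system],
            consequents=[r[2] for r in tsk_system],
        )
        assert np.abs(model.predict(X) - y).max() < 1e-10

    def test_symmetric_limit_equals_standard_gaussian_tsk(self):
        # frozen symmetric spreads: CAGFINN == classic Gaussian TSK with b=2s
        rng = np.random.default_rng(6)
        c, q = 3, 2
        centers = rng.normal(size=(c, q))
        s = rng.uniform(0.3, 0.8, (c, q))
        W = rng.normal(size=(c, q + 1))
        model = CAGFINNRegressor.from_parameters(centers, s, s, W)
        rules = [(centers[i], 2 * s[i], W[i]) for i in range(c)]
        X = rng.normal(size=(50, q))
        np.testing.assert_allclose(model.predict(X), tsk_forward(X, rules),
                                   atol=1e-10)


class TestTraining:
    def test_consequent_only_training_equals_batch_least_squares(self, tsk_system):
        X, y = generate_tsk_dataset(50, tsk_system, noise_sd=0.1, seed=2)
        init = FuzzyPartition(
            centers=[r[0] for r in tsk_system],
            U=np.full((4, 50), 0.25),
            sigma_init=[r[1] for r in tsk_system],
        )
        est = CAGFINNRegressor(learning_rate=0.0, max_epochs=15, tol=0.0,
                               standardize=False)
        est.fit(X, y, init=init)
        b = est.sigma_left_ + est.sigma_right_
        _, rbar, _, _, _ = _forward(X, est.centers_, b, est.consequents_)
        Phi = (rbar[:, :, None]
               * np.hstack([X, np.ones((50, 1))])[:, None, :]).reshape(50, -1)
        w_ls = np.linalg.lstsq(Phi, y, rcond=None)[0]
        assert np.abs(est.consequents_.ravel() - w_ls).max() < 1e-6

    def test_premise_gradients_match_finite_differences(self):
        rng = np.random.default_rng(7)
        centers = np.array([[0.0, 0.0], [1.0, 1.0]])
        b = np.array([[0.8, 1.0], [1.2, 0.9]])
        W = rng.normal(size=(2, 3))
        x = np.array([0.3, -0.2])
        y = 0.7
        gc, gb = premise_gradients(x, y, centers, b, W)

        def loss(cc, bb):
            _, _, _, O, _ = _forward(x[None], cc, bb, W)
            return 0.5 * (O[0] - y) ** 2

        h = 1e-6
        for i in range(2):
            for j in range(2):
                cc = centers.copy()
                cc[i, j] += h
                up = loss(cc, b)
                cc[i, j] -= 2 * h
                fd = (up - loss(cc, b)) / (2 * h)
                assert abs(gc[i, j] - fd) / max(abs(fd), 1e-10) < 1e-4
                bb = b.copy()
                bb[i, j] += h
                up = loss(centers, bb)
                bb[i, j] -= 2 * h
                fd = (up - loss(centers, bb)) / (2 * h)
                assert abs(gb[i, j] - fd) / max(abs(fd), 1e-10) < 1e-4

    def test_parameter_recovery_from_noiseless_tsk_data(self, tsk_system):
        X, y = generate_tsk_dataset(200, tsk_system, noise_sd=0.0, seed=3)
        Xt, yt = generate_tsk_dataset(100, tsk_system, noise_sd=0.0, seed=4)
        init = FuzzyPartition(
            centers=[r[0] for r in tsk_system], U=np.full((4, 200), 0.25),
            sigma_init=[r[1] for r in tsk_system],
        )
        est = CAGFINNRegressor(learning_rate=0.001, max_epochs=100, tol=1e-9,
                               standardize=False)
        est.fit(X, y, init=init)
        rmse = float(np.sqrt(np.mean((est.predict(Xt) - yt) ** 2)))
        assert rmse < 1e-3

    def test_training_error_never_ends_above_first_epoch(self, tsk_system):
        X, y = generate_tsk_dataset(120, tsk_system, noise_sd=0.2, seed=5)
        est = CAGFINNRegressor(max_epochs=40, seed=0).fit(X, y)
        assert est.training_log_[-1] <= est.training_log_[0] + 1e-12

    def test_rule_count_fixed_during_training(self, tsk_system):
        X, y = generate_tsk_dataset(80, tsk_system, noise_sd=0.1, seed=6)
        est = CAGFINNRegressor(max_epochs=10, seed=0).fit(X, y)
        assert est.centers_.shape[0] == est.n_rules_
        assert est.consequents_.shape == (est.n_rules_, X.shape[1] + 1)

    def test_spreads_stay_above_floor(self, tsk_system):
        X, y = generate_tsk_dataset(80, tsk_system, noise_sd=0.1, seed=8)
        est = CAGFINNRegressor(max_epochs=20, learning_rate=0.05, seed=0).fit(X, y)
        assert np.all(est.sigma_left_ > 0)
        assert np.all(est.sigma_right_ > 0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            CAGFINNRegressor().fit(np.zeros((5, 2)), np.zeros(4))

    def test_json_round_trip_preserves_predictions(self, tsk_system, tmp_path):
        X, y = generate_tsk_dataset(60, tsk_system, noise_sd=0.1, seed=7)
        est = CAGFINNRegressor(max_epochs=10, seed=0).fit(X, y)
        path = tmp_path / "model.json"
        est.to_json(path)
        loaded = CAGFINNRegressor.from_json(path)
        np.testing.assert_allclose(loaded.predict(X), est.predict(X), atol=1e-12)
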