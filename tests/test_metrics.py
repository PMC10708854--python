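import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msitvc import compute_metrics, holdout_split, loocv
from msitvc.metrics import MetricsReport


def loop_oracle(y, yp):
    """Independent straight-loop implementation of every metric."""
    n = len(y)
    se = sum((y[i] - yp[i]) ** 2 for i in range(n))
    rmse = math.sqrt(se / n)
    mae = sum(abs(y[i] - yp[i]) for i in range(n)) / n
    log_ratios = [math.log10(yp[i] / y[i]) for i in range(n)]
    bf = 10 ** (sum(log_ratios) / n)
    af = 10 ** (sum(abs(r) for r in log_ratios) / n)
    mape = 100.0 / n * sum(abs(y[i] - yp[i]) / y[i] for i in range(n))
    ape = sum(100.0 * abs(y[i] - yp[i]) / y[i] for i in range(n))
    ybar = sum(y) / n
    sep = 100.0 * rmse / ybar
    sd_y = math.sqrt(sum((v - ybar) ** 2 for v in y) / (n - 1))
    rpd = sd_y / rmse
    rer = (max(y) - min(y)) / rmse
    q1, q3 = np.percentile(y, [25, 75])
    rpiq = (q3 - q1) / rmse
    pbar = sum(yp) / n
    theta = (ybar - pbar) / sd_y
    sd_p = math.sqrt(sum((v - pbar) ** 2 for v in yp) / (n - 1))
    pooled = math.sqrt(((n - 1) * sd_y**2 + (n - 1) * sd_p**2) / (2 * n - 2))
    d = (ybar - pbar) / pooled
    r = np.corrcoef(y, yp)[0, 1]
    return dict(rmse=rmse, mae=mae, bf=bf, af=af, mape_pct=mape, ape=ape,
                sep_pct=sep, rpd=rpd, rer=rer, rpiq=rpiq, theta=theta,
                cohens_d=d, r_squared=r**2)


class TestComputeMetrics:
    def test_perfect_agreement_bf_af_one(self):
        y = np.linspace(3.0, 9.9, 10)
        rep = compute_metrics(y, y)
        assert rep.bf == 1.0
        assert rep.af == 1.0
        assert rep.zero_rmse

    def test_tenfold_overprediction(self):
        y = np.array([1.0, 2.0, 5.0, 8.0])
        rep = compute_metrics(y, 10 * y)
        assert rep.bf == pytest.approx(10.0, abs=1e-12)
        assert rep.af == pytest.approx(10.0, abs=1e-12)

    def test_hand_arithmetic_example(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rep = compute_metrics(y, y + 1.0)
        sd_y = np.std(y, ddof=1)
        assert rep.rmse == 1.0
        assert rep.rer == 3.0
        assert rep.theta == pytest.approx((2.5 - 3.5) / sd_y)
        assert rep.mae == 1.0

    def test_zero_rmse_reports_infinite_ratios_with_flag(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rep = compute_metrics(y, y)
        assert rep.zero_rmse
        assert math.isinf(rep.rpd) and math.isinf(rep.rer) and math.isinf(rep.rpiq)

    def test_every_metric_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(2, 40))
            y = rng.uniform(1.0, 10.0, n)
            yp = y + rng.normal(0, 0.5, n)
            yp = np.clip(yp, 0.1, None)
            rep = compute_metrics(y, yp)
            for key, val in loop_oracle(list(y), list(yp)).items():
                assert getattr(rep, key) == pytest.approx(val, abs=1e-10), key

    def test_nonpositive_observation_flags_log_metrics(self):
        rep = compute_metrics(np.array([-1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert not rep.log_ratio_defined
        assert math.isnan(rep.bf) and math.isnan(rep.af)
        assert np.isfinite(rep.rmse)

    def test_r2_definitions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yp = np.array([1.1, 1.9, 3.2, 3.8])
        corr = compute_metrics(y, yp).r_squared
        expl = compute_metrics(y, yp, r2_definition="explained").r_squared
        assert corr == pytest.approx(np.corrcoef(y, yp)[0, 1] ** 2)
        assert expl == pytest.approx(1 - np.sum((y - yp) ** 2) / np.sum((y - 2.5) ** 2))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([1.0]), np.array([1.0]))


class TestMetricIdentities:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_report_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        y = rng.uniform(1.0, 10.0, n)
        yp = np.clip(y + rng.normal(0, 1.0, n), 0.1, None)
        rep = compute_metrics(y, yp)
        assert rep.af >= 1.0 - 1e-12
        assert rep.af >= rep.bf - 1e-12 if rep.bf >= 1 else rep.af >= 1 / rep.bf - 1e-12
        if not rep.zero_rmse:
            q1, q3 = np.percentile(y, [25, 75])
            assert rep.rpiq * rep.rmse == pytest.approx(q3 - q1, abs=1e-9)
            assert rep.rer >= rep.rpiq - 1e-12
        assert 0.0 <= rep.r_squared <= 1.0 + 1e-12

    def test_af_symmetric_bf_inverts_under_swap(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(1, 10, 20)
        yp = np.clip(y + rng.normal(0, 1, 20), 0.1, None)
        fwd = compute_metrics(y, yp)
        rev = compute_metrics(yp, y)
        assert fwd.af == pytest.approx(rev.af, abs=1e-12)
        assert fwd.bf == pytest.approx(1.0 / rev.bf, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(1, 10, 25)
        yp = np.clip(y + rng.normal(0, 0.5, 25), 0.1, None)
        a = compute_metrics(y, yp)
        b = compute_metrics(3.7 * y, 3.7 * yp)
        for name in ("bf", "af", "mape_pct", "sep_pct", "rpd", "rer", "rpiq",
                     "r_squared", "theta", "cohens_d"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-9)
        assert b.rmse == pytest.approx(3.7 * a.rmse, rel=1e-12)
        assert b.mae == pytest.approx(3.7 * a.mae, rel=1e-12)


class TestProtocols:
    def test_loocv_constant_target_perfect(self):
        from sklearn.linear_model import LinearRegression
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 2))
        y = np.full(10, 6.0)
        preds, rep, failures = loocv(X, y, LinearRegression)
        np.testing.assert_allclose(preds, 6.0, atol=1e-9)
        assert rep.bf == pytest.approx(1.0, abs=1e-9)
        assert rep.af == pytest.approx(1.0, abs=1e-9)
        assert failures == []

    def test_loocv_matches_hat_matrix_oracle(self):
        from sklearn.linear_model import LinearRegression
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        preds, _, _ = loocv(X, y, LinearRegression)
        A = np.hstack([np.ones((5, 1)), X])
        H = A @ np.linalg.inv(A.T @ A) @ A.T
        fit = H @ y
        closed_form = y - (y - fit) / (1 - np.diag(H))
        np.testing.assert_allclose(preds, closed_form, atol=1e-10)

    def test_loocv_deterministic(self):
        from sklearn.linear_model import Ridge
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        a, _, _ = loocv(X, y, Ridge, seed=9)
        b, _, _ = loocv(X, y, Ridge, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_holdout_84_samples_gives_8_test(self, spoilage_dataset):
        ds84 = spoilage_dataset.select(np.arange(84))
        train, test = holdout_split(ds84, test_frac=0.1, seed=0)
        assert test.n_samples == 8
        assert train.n_samples == 76

    def test_holdout_disjoint_exhaustive_stratified(self, spoilage_dataset):
        train, test = holdout_split(spoilage_dataset, test_frac=0.2, seed=1)
        ids_train = set(train.frame["sample_id"])
        ids_test = set(test.frame["sample_id"])
        assert not ids_train & ids_test
        assert len(ids_train | ids_test) == spoilage_dataset.n_samples
        # every temperature keeps a presence in the training set
        assert set(train.frame["temperature_C"]) == set(
            spoilage_dataset.frame["temperature_C"])

    def test_holdout_reproducible_under_seed(self, spoilage_dataset):
        a = holdout_split(spoilage_dataset, 0.1, seed=7)[1]
        b = holdout_split(spoilage_dataset, 0.1, seed=7)[1]
        assert list(a.frame["sample_id"]) == list(b.frame["sample_id"])

    @pytest.mark.parametrize("frac", [0.0, 1.0])
    def test_degenerate_fraction_rejected(self, spoilage_dataset, frac):
        with pytest.raises(ValueError):
            holdout_split(spoilage_dataset, test_frac=frac)

    def test_split_leaving_no_training_data_rejected(self, spoilage_dataset):
        tiny = spoilage_dataset.select(np.arange(1))
        with pytest.raises(ValueError, match="training"):
            holdout_split(tiny, test_frac=0.5)
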