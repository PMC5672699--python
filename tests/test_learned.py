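"""Quadratic regression and the backprop network."""

import dataclasses

import numpy as np
import pytest

from lvvol.errors import (
    BorderValidationError,
    ConfigurationError,
    SingularFitError,
)
from lvvol.function import CycleSeries, FrameRecord
from lvvol.learned import (
    BPNetConfig,
    BPNetModel,
    QuadraticModel,
    SplitPlan,
    bpnet_loss_and_gradients,
    fit_bpnet,
    fit_quadratic,
    hidden_layer_sweep,
    predict_bpnet,
    predict_quadratic,
    split_cohort,
)
from lvvol.learned import _init_layers  # noqa: PLC2701 - gradient check needs raw nets


def dummy_cohort(n_cases, n_frames):
    return [
        CycleSeries(case_id=f"c{i}", frames=[
            FrameRecord(frame_id=str(j), volume_ml=1.0 + 0.01 * j)
            for j in range(n_frames)
        ])
        for i in range(n_cases)
    ]


class TestQuadratic:
    def test_constant_target(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(2, 9, size=(60, 16))
        m = fit_quadratic(x, np.full(60, 5.0))
        assert m.c == pytest.approx(5.0, abs=1e-8)
        assert np.allclose(m.a, 0.0, atol=1e-8)
        assert np.allclose(m.b, 0.0, atol=1e-8)

    def test_noiseless_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(3, 10, size=(200, 16))
        a = rng.normal(scale=0.05, size=16)
        b = rng.normal(scale=0.3, size=16)
        c = 1.2
        y = c + (x**2) @ a + x @ b
        m = fit_quadratic(x, y)
        assert np.allclose(m.a, a, rtol=1e-6)
        assert np.allclose(m.b, b, rtol=1e-6)
        assert m.c == pytest.approx(c, rel=1e-6)

    def test_underdetermined_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(SingularFitError):
            fit_quadratic(rng.uniform(1, 2, size=(30, 16)), rng.normal(size=30))

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(3, 10, size=(100, 16))
        x[:, 15] = x[:, 14]  # collinear pair
        with pytest.raises(SingularFitError, match="d16"):
            fit_quadratic(x, rng.normal(size=100))

    @pytest.mark.parametrize("a1,b1,c,d1,expected", [
        (0.0, 0.0, 2.5, 3.0, 2.5),
        (0.0, 1.0, 0.0, 7.0, 7.0),
        (2.0, 3.0, 1.0, 2.0, 15.0),
    ])
    def test_hand_evaluations(self, a1, b1, c, d1, expected):
        a = np.zeros(16)
        b = np.zeros(16)
        a[0], b[0] = a1, b1
        d = np.full(16, 1e-9)
        d[0] = d1
        m = QuadraticModel(a=a, b=b, c=c)
        assert predict_quadratic(m, d) == pytest.approx(expected)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(2, 8, size=(120, 16))
        y = rng.normal(size=120)
        design = np.hstack([x**2, x, np.ones((120, 1))])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        m = fit_quadratic(x, y)
        fit = np.concatenate([m.a, m.b, [m.c]])
        assert np.allclose(fit, beta, rtol=1e-8)


class TestBPNet:
    @pytest.mark.parametrize("depth", range(1, 9))
    def test_gradients_match_finite_differences(self, depth):
        rng = np.random.default_rng(depth)
        w, b = _init_layers([16] + [4] * depth + [1], rng)
        x = rng.normal(size=(3, 16))
        y = rng.normal(size=3)
        _, gw, gb = bpnet_loss_and_gradients(w, b, x, y)
        eps = 1e-6
        worst = 0.0
        for arrs, grads in ((w, gw), (b, gb)):
            for arr, grad in zip(arrs, grads):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    i = it.multi_index
                    orig = arr[i]
                    arr[i] = orig + eps
                    lp, _, _ = bpnet_loss_and_gradients(w, b, x, y)
                    arr[i] = orig - eps
                    lm, _, _ = bpnet_loss_and_gradients(w, b, x, y)
                    arr[i] = orig
                    worst = max(worst, abs((lp - lm) / (2 * eps) - grad[i]))
        assert worst < 1e-6

    def test_constant_target_learned(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(3, 9, size=(120, 16))
        cfg = BPNetConfig(max_epochs=2000, seed=0)
        model, report = fit_bpnet(x[:80], np.full(80, 3.0), cfg)
        pred = predict_bpnet(model, x[80:])
        assert np.all(np.abs(pred - 3.0) < 0.01)

    def test_loss_non_increasing_at_small_step(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(60, 16))
        y = x.sum(axis=1) * 0.1
        cfg = BPNetConfig(learning_rate=0.01, momentum=0.0, max_epochs=500,
                          seed=1)
        _, report = fit_bpnet(x, y, cfg)
        assert np.all(np.diff(report.losses) <= 1e-12)

    def test_divergence_reported(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 16))
        y = rng.normal(size=60) * 10
        from lvvol.errors import DivergenceError

        with pytest.raises(DivergenceError):
            fit_bpnet(x, y, BPNetConfig(learning_rate=500.0, momentum=0.9,
                                        max_epochs=5000, seed=2))

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        x = rng.uniform(2, 8, size=(80, 16))
        y = x.mean(axis=1)
        model, _ = fit_bpnet(x, y, BPNetConfig(max_epochs=200, seed=3))
        path = tmp_path / "net.json"
        model.save(path)
        clone = BPNetModel.load(path)
        probe = rng.uniform(2, 8, size=(20, 16))
        assert np.array_equal(predict_bpnet(model, probe),
                              predict_bpnet(clone, probe))

    def test_wrong_feature_length_rejected(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(2, 8, size=(60, 16))
        model, _ = fit_bpnet(x, x.mean(axis=1),
                             BPNetConfig(max_epochs=50, seed=4))
        with pytest.raises(BorderValidationError):
            predict_bpnet(model, np.ones(15))

    def test_dead_network_outputs_bias(self):
        cfg = BPNetConfig(n_hidden_layers=2, units_per_layer=4)
        weights = [np.zeros((16, 4)), np.zeros((4, 4)), np.zeros((4, 1))]
        biases = [np.zeros(4), np.zeros(4), np.array([4.2])]
        model = BPNetModel(weights=weights, biases=biases,
                           x_mean=np.zeros(16), x_std=np.ones(16), config=cfg)
        assert predict_bpnet(model, np.ones(16) * 7) == pytest.approx(4.2)

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ConfigurationError):
            fit_bpnet(rng.normal(size=(30, 16)), rng.normal(size=30))

    def test_internal_split_reports_holdout(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(2, 8, size=(140, 16))
        y = x.mean(axis=1)
        _, report = fit_bpnet(x, y, BPNetConfig(max_epochs=100, seed=6),
                              split=SplitPlan(fraction_train=0.5, seed=0))
        assert report.n_train == 70
        assert report.holdout_mse is not None

    def test_depth_out_of_range(self):
        with pytest.raises(ConfigurationError):
            BPNetConfig(n_hidden_layers=9)


class TestSplitCohort:
    def test_half_split_arithmetic_50x40(self):
        cohort = dummy_cohort(50, 40)
        train, test = split_cohort(cohort, SplitPlan(seed=0))
        assert len(train) == 1000
        assert len(test) == 1000
        assert set(train).isdisjoint(test)
        assert len(set(train) | set(test)) == 2000

    def test_case_level_two_cases(self):
        cohort = dummy_cohort(2, 10)
        train, test = split_cohort(cohort, SplitPlan(mode="case", seed=1))
        train_cases = {i for i, _ in train}
        test_cases = {i for i, _ in test}
        assert len(train_cases) == len(test_cases) == 1
        assert train_cases.isdisjoint(test_cases)
        assert len(train) == len(test) == 10

    def test_deterministic(self):
        cohort = dummy_cohort(5, 8)
        plan = SplitPlan(seed=42)
        assert split_cohort(cohort, plan) == split_cohort(cohort, plan)

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            SplitPlan(fraction_train=0.0)
        cohort = dummy_cohort(1, 2)
        with pytest.raises(ConfigurationError):
            split_cohort(cohort, SplitPlan(fraction_train=0.01))


class TestSweep:
    def test_single_depth_single_row(self):
        from lvvol.synthetic import CohortSpec, make_cohort

        cohort, _ = make_cohort(CohortSpec(n_cases=4, seed=9))
        df = hidden_layer_sweep(cohort, [4],
                                BPNetConfig(max_epochs=300, seed=0),
                                SplitPlan(seed=0))
        assert len(df) == 1
        assert set(df.columns) >= {"n_hidden_layers", "ccc_train", "ccc_test",
                                   "icc_train", "icc_test"}

    def test_depth_nine_rejected(self):
        cohort = dummy_cohort(2, 4)
        with pytest.raises(ConfigurationError):
            hidden_layer_sweep(cohort, [9], BPNetConfig(), SplitPlan())
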