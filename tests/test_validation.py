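"""Validation metrics: Q2 (LOO), external R2, VIF, mean effect, benchmark gate."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qsarkit.core import ActivitySeries, DescriptorTable, DomainError
from qsarkit.mlr import anova, fit_ols
from qsarkit.validation import (
    benchmark_gate,
    descriptor_diagnostics,
    mean_effect,
    q2_loo,
    r2_external,
    vif,
)
from tests.conftest import random_problem


class TestQ2Loo:
    def test_noise_free_data_gives_one(self):
        ids = [f"c{i}" for i in range(8)]
        X = DescriptorTable.from_arrays(
            ids, ["x"], np.linspace(0, 1, 8)[:, None] + np.arange(8)[:, None] * 0.01
        )
        y = ActivitySeries.from_values(ids, 2.0 * X.values[:, 0] + 1.0)
        assert q2_loo(X, y) == pytest.approx(1.0, abs=1e-12)

    def test_hat_shortcut_equals_explicit_refit_loop(self, make_problem):
        X, y, *_ = make_problem(n=15, p=3, noise=0.5)
        shortcut = q2_loo(X, y)
        # oracle: n explicit refits, each predicting the held-out compound
        press = 0.0
        ids = X.compound_ids
        for left_out in ids:
            keep = [i for i in ids if i != left_out]
            model = fit_ols(X.subset(keep), y.reindex(keep))
            pred = model.predict(X.subset([left_out])).values[0]
            press += (y.reindex([left_out]).values[0] - pred) ** 2
        yv = y.values
        explicit = 1.0 - press / np.sum((yv - yv.mean()) ** 2)
        assert shortcut == pytest.approx(explicit, abs=1e-9)

    def test_constant_response_rejected(self, rng):
        ids = [f"c{i}" for i in range(10)]
        X = DescriptorTable.from_arrays(ids, ["x"], rng.standard_normal((10, 1)))
        y = ActivitySeries.from_values(ids, np.full(10, 5.0))
        with pytest.raises(DomainError):
            q2_loo(X, y)

    def test_never_exceeds_r2_on_training_data(self, rng):
        for seed in range(10):
            X, y, *_ = random_problem(np.random.default_rng(seed), n=20, p=4, noise=0.8)
            model = fit_ols(X, y)
            assert q2_loo(X, y) <= anova(model, X, y).r2 + 1e-12


class TestR2External:
    def test_perfect_predictions(self):
        assert r2_external([5.0, 4.5], [5.0, 4.5], 4.4) == pytest.approx(1.0)

    def test_training_mean_prediction_scores_zero(self):
        assert r2_external([5.0, 4.5, 4.0], [4.4, 4.4, 4.4], 4.4) == pytest.approx(0.0)

    def test_three_point_hand_example(self):
        # numerator 3 * 0.1^2 = 0.03; denominator 0.6^2 + 0.1^2 + 0.4^2 = 0.53
        got = r2_external([5.0, 4.5, 4.0], [4.9, 4.6, 4.1], 4.4)
        assert got == pytest.approx(1 - 0.03 / 0.53, abs=1e-9)

    def test_empty_test_set_rejected(self):
        with pytest.raises(DomainError):
            r2_external([], [], 4.4)

    def test_zero_denominator_rejected(self):
        with pytest.raises(DomainError):
            r2_external([4.4, 4.4], [4.0, 5.0], 4.4)


class TestVif:
    def test_orthogonal_columns_all_one(self):
        X = DescriptorTable.from_arrays(
            ["a", "b", "c", "d"],
            ["u", "v"],
            [[1, 1], [1, -1], [-1, 1], [-1, -1]],
        )
        assert vif(X).to_numpy() == pytest.approx([1.0, 1.0])

    def test_two_columns_with_r_07_closed_form(self, rng):
        n = 2000
        z = rng.standard_normal((n, 2))
        x1 = z[:, 0]
        x2 = 0.7 * z[:, 0] + np.sqrt(1 - 0.49) * z[:, 1]
        # force exact sample correlation via orthogonalization
        x1c = (x1 - x1.mean()) / np.linalg.norm(x1 - x1.mean())
        e = z[:, 1] - (z[:, 1] @ x1c) * x1c
        e = (e - e.mean()) / np.linalg.norm(e - e.mean())
        x2 = 0.7 * x1c + np.sqrt(1 - 0.49) * e
        ids = [f"c{i}" for i in range(n)]
        X = DescriptorTable.from_arrays(ids, ["a", "b"], np.column_stack([x1c, x2]))
        assert vif(X).to_numpy() == pytest.approx([1 / 0.51, 1 / 0.51], rel=1e-9)

    def test_matches_auxiliary_regression_oracle(self, rng):
        n, p = 20, 4
        values = rng.standard_normal((n, p))
        values[:, 3] += 0.8 * values[:, 0]
        ids = [f"c{i}" for i in range(n)]
        names = [f"x{j}" for j in range(p)]
        X = DescriptorTable.from_arrays(ids, names, values)
        got = vif(X)
        # oracle: VIF_j = 1 / (1 - R2 of column j regressed on the others)
        for j, name in enumerate(names):
            others = [k for k in range(p) if k != j]
            A = np.column_stack([np.ones(n), values[:, others]])
            beta, *_ = np.linalg.lstsq(A, values[:, j], rcond=None)
            resid = values[:, j] - A @ beta
            r2_j = 1 - resid @ resid / np.sum((values[:, j] - values[:, j].mean()) ** 2)
            assert got[name] == pytest.approx(1 / (1 - r2_j), rel=1e-8)

    @given(st.floats(min_value=0.1, max_value=10), st.floats(min_value=-5, max_value=5))
    def test_invariant_under_affine_column_rescaling(self, scale, shift):
        rng = np.random.default_rng(7)
        values = rng.standard_normal((15, 3))
        ids = [f"c{i}" for i in range(15)]
        base = vif(DescriptorTable.from_arrays(ids, list("abc"), values))
        values2 = values.copy()
        values2[:, 1] = scale * values2[:, 1] + shift
        again = vif(DescriptorTable.from_arrays(ids, list("abc"), values2))
        assert again.to_numpy() == pytest.approx(base.to_numpy(), rel=1e-8)

    def test_all_at_least_one(self, rng):
        values = rng.standard_normal((25, 5))
        X = DescriptorTable.from_arrays(
            [f"c{i}" for i in range(25)], [f"x{j}" for j in range(5)], values
        )
        assert np.all(vif(X).to_numpy() >= 1.0 - 1e-12)


class TestMeanEffect:
    def make_model(self, names, coefs, intercept=0.0):
        from qsarkit.core import LinearModel

        return LinearModel(tuple(names), tuple(coefs), intercept)

    def test_single_descriptor_is_one(self, rng):
        X = DescriptorTable.from_arrays(["a", "b"], ["x"], [[1.0], [2.0]])
        me = mean_effect(self.make_model(["x"], [0.7]), X)
        assert me.to_numpy() == pytest.approx([1.0])

    def test_symmetric_pair_splits_evenly(self):
        X = DescriptorTable.from_arrays(["a", "b"], ["u", "v"], [[1.0, 2.0], [3.0, 2.0]])
        me = mean_effect(self.make_model(["u", "v"], [0.5, 0.5]), X)
        assert me.to_numpy() == pytest.approx([0.5, 0.5])

    def test_three_descriptor_hand_example(self):
        # beta = (1, 2, -1), column sums (4, 1, 2) -> (4, 2, -2)/4
        X = DescriptorTable.from_arrays(
            ["a", "b"], ["u", "v", "w"], [[1.0, 0.5, 1.5], [3.0, 0.5, 0.5]]
        )
        me = mean_effect(self.make_model(["u", "v", "w"], [1.0, 2.0, -1.0]), X)
        assert me.to_numpy() == pytest.approx([1.0, 0.5, -0.5])

    def test_sums_to_one_on_fitted_models(self, make_problem):
        X, y, *_ = make_problem(n=20, p=4, noise=0.5)
        model = fit_ols(X, y)
        assert mean_effect(model, X).sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_rejected(self):
        X = DescriptorTable.from_arrays(["a", "b"], ["u"], [[1.0], [-1.0]])
        with pytest.raises(DomainError):
            mean_effect(self.make_model(["u"], [1.0]), X)


class TestBenchmarkGate:
    def test_study_metrics_pass(self):
        verdict = benchmark_gate(0.7397, 0.6712, 0.5547, 0.7202)
        assert verdict.passed
        assert all(c.passed for c in verdict.criteria)

    def test_low_r2_fails_named_criterion(self):
        verdict = benchmark_gate(0.5, 0.5, 0.5, 0.5)
        failed = {c.name for c in verdict.criteria if not c.passed}
        assert "r2" in failed
        assert not verdict.passed

    def test_boundary_values_pass_inclusively(self):
        assert benchmark_gate(0.6, 0.6, 0.5, 0.6).passed


class TestDescriptorDiagnostics:
    def test_frame_shape_and_columns(self, make_problem):
        X, y, *_ = make_problem(n=25, p=5, noise=0.5)
        model = fit_ols(X, y)
        diag = descriptor_diagnostics(model, X, y)
        assert list(diag.columns) == ["coefficient", "ME", "VIF", "t_stat", "p_value", "SE"]
        assert list(diag.index) == list(model.descriptor_names)
        assert diag["ME"].sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(diag["VIF"].to_numpy() >= 1.0 - 1e-12)
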