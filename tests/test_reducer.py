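import numpy as np
import pandas as pd
import pytest

from shortform import (
    predict,
    refit_union,
    select_items_lasso,
    sum_scores,
    union_included,
)
from shortform.reducer import ReducedModel
from shortform.targets import TargetScores

from .oracles import cd_lasso, null_threshold


def standardized(X):
    return (X - X.mean(axis=0)) / X.std(axis=0)


def random_instance(rng, n, p):
    X = rng.integers(1, 5, size=(n, p)).astype(float)
    while np.any(X.std(axis=0) == 0):
        X = rng.integers(1, 5, size=(n, p)).astype(float)
    w = rng.normal(size=p)
    y = X @ w + rng.normal(scale=0.5, size=n)
    items = [f"item_{i + 1:02d}" for i in range(p)]
    return pd.DataFrame(X, columns=items), pd.Series(y, name="y")


class TestSelectItemsLasso:
    def test_matches_coordinate_descent_oracle_small_instances(self):
        """Solutions agree with a from-scratch cyclic coordinate-descent
        solver to 1e-6 on tiny instances across an alpha grid."""
        rng = np.random.default_rng(0)
        for trial in range(6):
            resp, y = random_instance(rng, n=rng.integers(4, 13), p=rng.integers(2, 6))
            Z = standardized(resp.to_numpy())
            yz = (y - y.mean()) / y.std(ddof=0)
            for alpha in [0.01, 0.05, 0.1, 0.3, 0.6, 1.0]:
                sel = select_items_lasso(resp, y, alpha)
                w_ref, _ = cd_lasso(Z, yz.to_numpy(), alpha)
                np.testing.assert_allclose(
                    sel.coefficients.to_numpy(), w_ref, atol=1e-6,
                    err_msg=f"trial {trial}, alpha {alpha}",
                )

    def test_included_matches_nonzero_pattern(self, toy_responses):
        y = sum_scores(toy_responses).values["total"]
        sel = select_items_lasso(toy_responses, y, alpha=0.2)
        nonzero = [c for c, w in sel.coefficients.items() if w != 0.0]
        assert sel.included_items == nonzero

    def test_null_threshold_empties_selection(self, toy_responses):
        """Above the closed-form threshold max|z_j . y_z|/n the L1 solution
        is identically zero."""
        y = sum_scores(toy_responses).values["total"]
        Z = standardized(toy_responses.to_numpy(float))
        yz = (y - y.mean()) / y.std(ddof=0)
        amax = null_threshold(Z, yz.to_numpy())
        assert select_items_lasso(toy_responses, y, amax * 1.001).included_items == []
        assert select_items_lasso(toy_responses, y, amax * 0.98).included_items != []

    def test_alpha_zero_is_ols_and_reproduces_sum_targets(self, toy_responses):
        y = sum_scores(toy_responses).values["total"]
        sel = select_items_lasso(toy_responses, y, alpha=0.0)
        assert sel.included_items == list(toy_responses.columns)
        assert sel.training_r2 == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_item_gets_zero_weight(self, toy_responses, caplog):
        resp = toy_responses.copy()
        resp["item_07"] = 2
        y = sum_scores(toy_responses).values["total"]
        with caplog.at_level("WARNING", logger="shortform.reducer"):
            sel = select_items_lasso(resp, y, alpha=0.05)
        assert sel.coefficients["item_07"] == 0.0
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_preconditions(self, toy_responses):
        y = sum_scores(toy_responses).values["total"]
        with pytest.raises(ValueError, match="non-negative"):
            select_items_lasso(toy_responses, y, alpha=-1.0)
        with pytest.raises(ValueError, match="2 participants"):
            select_items_lasso(toy_responses.iloc[:1], y.iloc[:1], alpha=0.1)


class TestUnionIncluded:
    def _selection(self, items, universe):
        coef = pd.Series(0.0, index=universe)
        coef[items] = 1.0
        from shortform.reducer import LassoSelection

        return LassoSelection(
            dimension="d", alpha=0.1, coefficients=coef,
            included_items=list(items), training_r2=0.5,
        )

    def test_union_in_original_order(self):
        universe = ["i1", "i2", "i3", "i4", "i5"]
        sels = [self._selection(["i1", "i3"], universe), self._selection(["i3", "i5"], universe)]
        assert union_included(sels) == ["i1", "i3", "i5"]

    def test_single_dimension_passthrough(self):
        universe = ["i1", "i2", "i3"]
        sel = self._selection(["i2"], universe)
        assert union_included([sel]) == ["i2"]

    def test_all_empty(self):
        universe = ["i1", "i2"]
        assert union_included([self._selection([], universe)] * 2) == []


class TestRefitUnion:
    def test_full_item_sum_identity(self, toy_responses):
        """All items + sum targets: unit weights, zero intercept, zero error."""
        targets = sum_scores(toy_responses)
        model = refit_union(toy_responses, targets, list(toy_responses.columns))
        np.testing.assert_allclose(model.weights["total"], 1.0, atol=1e-9)
        assert model.intercepts["total"] == pytest.approx(0.0, abs=1e-8)
        pred = predict(model, toy_responses)
        np.testing.assert_allclose(
            pred.values["total"], targets.values["total"], atol=1e-8
        )

    def test_recovers_generating_weights(self):
        rng = np.random.default_rng(1)
        X = rng.integers(1, 5, size=(50, 3)).astype(float)
        resp = pd.DataFrame(X, columns=["a", "b", "c"])
        y = 2.0 * X[:, 0] - 1.5 * X[:, 2] + 0.7
        targets = TargetScores(pd.DataFrame({"dim": y}), kind="sum")
        model = refit_union(resp, targets, ["a", "c"])
        np.testing.assert_allclose(model.weights["dim"], [2.0, -1.5], atol=1e-8)
        assert model.intercepts["dim"] == pytest.approx(0.7, abs=1e-8)

    def test_matches_normal_equations_oracle(self, toy_responses):
        targets = sum_scores(toy_responses)
        included = ["item_01", "item_03", "item_05"]
        model = refit_union(toy_responses, targets, included)
        A = np.column_stack([np.ones(len(toy_responses)), toy_responses[included]])
        beta = np.linalg.solve(A.T @ A, A.T @ targets.values["total"])
        np.testing.assert_allclose(model.intercepts["total"], beta[0], atol=1e-9)
        np.testing.assert_allclose(model.weights["total"], beta[1:], atol=1e-9)

    def test_duplicated_dimension_gives_identical_columns(self, toy_responses):
        y = sum_scores(toy_responses).values["total"]
        targets = TargetScores(pd.DataFrame({"d1": y, "d2": y}), kind="subscale")
        model = refit_union(toy_responses, targets, ["item_01", "item_02"])
        np.testing.assert_allclose(model.weights["d1"], model.weights["d2"])

    def test_refit_dominates_lasso_training_r2(self):
        """OLS on the (superset) union can only improve training R² over the
        step-1 penalized fit, for every dimension: 100 random instances."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            resp, _ = random_instance(rng, n=30, p=5)
            Y = pd.DataFrame(
                {
                    "d1": resp.to_numpy() @ rng.normal(size=5) + rng.normal(size=30),
                    "d2": resp.to_numpy() @ rng.normal(size=5) + rng.normal(size=30),
                }
            )
            targets = TargetScores(Y, kind="subscale")
            alphas = rng.uniform(0.01, 0.5, size=2)
            sels = [
                select_items_lasso(resp, Y[d], a, dimension=d)
                for d, a in zip(Y, alphas)
            ]
            included = union_included(sels, item_order=list(resp.columns))
            if not included:
                continue
            model = refit_union(resp, targets, included)
            for d, sel in zip(Y, sels):
                assert model.training_r2[d] >= sel.training_r2 - 1e-10

    def test_empty_included_rejected(self, toy_responses):
        with pytest.raises(ValueError, match="lower alpha"):
            refit_union(toy_responses, sum_scores(toy_responses), [])


class TestPredict:
    def _model(self, items, weights, intercept, n_total=6, dim="total"):
        return ReducedModel(
            included_items=items,
            weights=pd.DataFrame({dim: weights}, index=items),
            intercepts=pd.Series({dim: intercept}),
            alphas_used=pd.Series({dim: np.nan}),
            n_items_total=n_total,
        )

    def test_hand_arithmetic(self):
        model = self._model(["a", "b"], [2.0, -1.0], 0.5)
        resp = pd.DataFrame({"a": [3], "b": [4]})
        assert predict(model, resp).values["total"].iloc[0] == pytest.approx(2.5)

    def test_zero_weights_predict_intercept(self):
        model = self._model(["a"], [0.0], 7.25)
        resp = pd.DataFrame({"a": [1, 2, 3]})
        np.testing.assert_allclose(predict(model, resp).values["total"], 7.25)

    def test_excluded_columns_are_ignored(self, toy_responses):
        """Sparsity consistency: adding excluded-item columns with arbitrary
        values leaves predictions unchanged."""
        targets = sum_scores(toy_responses)
        model = refit_union(toy_responses, targets, ["item_01", "item_04"])
        base = predict(model, toy_responses)
        noisy = toy_responses.copy()
        noisy["item_03"] = 999
        noisy["extra"] = -1
        pd.testing.assert_frame_equal(base.values, predict(model, noisy).values)

    def test_missing_included_column_named_in_error(self):
        model = self._model(["a", "zz"], [1.0, 1.0], 0.0)
        with pytest.raises(KeyError, match="zz"):
            predict(model, pd.DataFrame({"a": [1]}))


class TestModelJson:
    def test_round_trip(self, toy_responses):
        targets = sum_scores(toy_responses)
        model = refit_union(toy_responses, targets, ["item_02", "item_05"])
        clone = ReducedModel.from_json(model.to_json())
        assert clone.included_items == model.included_items
        np.testing.assert_allclose(clone.weights, model.weights)
        np.testing.assert_allclose(clone.intercepts, model.intercepts)
        assert clone.n_items_total == model.n_items_total
        pd.testing.assert_frame_equal(
            predict(clone, toy_responses).values, predict(model, toy_responses).values
        )
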