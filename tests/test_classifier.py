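import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

import ramanpheno as rp
from ramanpheno.classifier import (
    FittedModel,
    encode_labels,
    evaluate,
    select_lambda_cv,
)
from ramanpheno.errors import ConvergenceError
from ramanpheno.spectra_io import BandAssignmentTable
import pandas as pd


def nll(params, X, y):
    b, w = params[0], params[1:]
    s = b + X @ w
    return np.mean(np.log1p(np.exp(-np.where(y == 1, s, -s))))


def brute_force_fit(X, y, lambda_=0.0):
    """Independent oracle: coarse grid restart + Nelder-Mead refinement."""

    def obj(p):
        return nll(p, X, y) + lambda_ * np.abs(p[1:]).sum()

    best = None
    for b0 in (-1, 0, 1):
        for w0 in (-2, -0.5, 0, 0.5, 2):
            for w1 in (-2, -0.5, 0, 0.5, 2):
                r = minimize(
                    obj, np.array([b0, w0, w1], dtype=float),
                    method="Nelder-Mead",
                    options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 20000},
                )
                if best is None or r.fun < best.fun:
                    best = r
    return best.x, best.fun


class TestStratifiedSplit:
    def test_counts(self):
        labels = ["Tconv"] * 100 + ["Treg"] * 50
        train, test = rp.stratified_split(labels, 0.2, seed=0)
        lab = np.asarray(labels)
        assert (lab[test] == "Tconv").sum() == 20
        assert (lab[test] == "Treg").sum() == 10
        assert len(set(train) & set(test)) == 0
        assert len(train) + len(test) == 150

    def test_seed_deterministic(self):
        labels = ["Tconv"] * 40 + ["Treg"] * 20
        a = rp.stratified_split(labels, 0.25, seed=3)
        b = rp.stratified_split(labels, 0.25, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rp.stratified_split(["Tconv"] * 10, 0.2, seed=0)

    def test_bad_fraction_rejected(self):
        labels = ["Tconv"] * 4 + ["Treg"] * 4
        for frac in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                rp.stratified_split(labels, frac, seed=0)


class TestFitLassoLogistic:
    def test_large_lambda_null_model(self, toy_xy):
        X, y = toy_xy
        model = rp.fit_lasso_logistic(X, y, lambda_=10.0)
        assert np.all(model.coefficients == 0.0)
        prev = y.mean()
        assert model.intercept == pytest.approx(
            np.log(prev / (1 - prev)), abs=1e-9
        )

    def test_unpenalized_matches_brute_force(self, toy_xy):
        X, y = toy_xy
        Z = (X - X.mean(0)) / X.std(0)
        model = rp.fit_lasso_logistic(X, y, lambda_=0.0, tol=1e-10)
        oracle, _ = brute_force_fit(Z, y, 0.0)
        np.testing.assert_allclose(model.coefficients, oracle[1:], atol=1e-4)
        assert model.intercept == pytest.approx(oracle[0], abs=1e-4)

    def test_penalized_objective_near_oracle(self, toy_xy):
        X, y = toy_xy
        lam = 0.05
        Z = (X - X.mean(0)) / X.std(0)
        model = rp.fit_lasso_logistic(X, y, lambda_=lam, tol=1e-10)
        _, oracle_obj = brute_force_fit(Z, y, lam)
        mine = nll(
            np.r_[model.intercept, model.coefficients], Z, y
        ) + lam * np.abs(model.coefficients).sum()
        assert mine <= oracle_obj + 1e-6

    def test_sample_duplication_invariance(self, toy_xy):
        X, y = toy_xy
        lam = 0.02
        a = rp.fit_lasso_logistic(X, y, lam)
        b = rp.fit_lasso_logistic(
            np.vstack([X, X]), np.concatenate([y, y]), lam
        )
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=2e-5)

    def test_constant_design_unpenalized_rejected(self):
        X = np.ones((10, 3))
        y = np.array([0, 1] * 5)
        with pytest.raises(ConvergenceError):
            rp.fit_lasso_logistic(X, y, 0.0)

    def test_negative_lambda_rejected(self, toy_xy):
        X, y = toy_xy
        with pytest.raises(ValueError):
            rp.fit_lasso_logistic(X, y, -0.1)

    def test_regularization_path_monotone_sparsity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 30))
        w = np.zeros(30)
        w[:5] = 1.0
        y = (rng.random(120) < 1 / (1 + np.exp(-X @ w))).astype(int)
        nnz = [
            rp.fit_lasso_logistic(X, y, lam).n_nonzero
            for lam in (0.001, 0.003, 0.01, 0.03, 0.1, 0.3)
        ]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_labels_as_strings(self, toy_xy):
        X, y = toy_xy
        names = np.where(y == 1, "Treg", "Tconv")
        a = rp.fit_lasso_logistic(X, y, 0.01)
        b = rp.fit_lasso_logistic(X, names, 0.01)
        np.testing.assert_allclose(a.coefficients, b.coefficients)


class TestPredictProba:
    def _null_model(self, p=4, intercept=0.0):
        return FittedModel(
            intercept=intercept,
            coefficients=np.zeros(p),
            lambda_=1.0,
            center=np.zeros(p),
            scale=np.ones(p),
        )

    def test_zero_model_gives_half(self):
        m = self._null_model()
        probs = rp.predict_proba(m, np.random.default_rng(0).normal(size=(5, 4)))
        np.testing.assert_allclose(probs, 0.5)

    def test_log_three_gives_three_quarters(self):
        m = self._null_model(intercept=np.log(3.0))
        probs = rp.predict_proba(m, np.zeros((1, 4)))
        assert probs[0] == pytest.approx(0.75)

    def test_monotone_in_positive_channel(self):
        m = self._null_model()
        m.coefficients[2] = 1.0
        lo = rp.predict_proba(m, np.array([[0, 0, 0.5, 0]]))
        hi = rp.predict_proba(m, np.array([[0, 0, 1.5, 0]]))
        assert hi[0] > lo[0]

    def test_axis_mismatch_rejected(self):
        m = self._null_model(p=4)
        with pytest.raises(ValueError, match="channels"):
            rp.predict_proba(m, np.zeros((2, 5)))


def brute_force_auc(scores, y):
    """Pairwise concordance with ties counted one half (integer arithmetic)."""
    s = np.asarray(scores)
    y = np.asarray(y)
    pos = s[y == 1]
    neg = s[y == 0]
    num2 = 0  # twice the concordant count
    for p in pos:
        for n in neg:
            if p > n:
                num2 += 2
            elif p == n:
                num2 += 1
    return num2 / (2.0 * pos.size * neg.size)


class TestRocAuc:
    def test_perfect_separation(self):
        out = rp.roc_and_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert out["auc"] == 1.0

    def test_all_tied_scores(self):
        out = rp.roc_and_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert out["auc"] == 0.5

    def test_hand_example(self):
        out = rp.roc_and_auc(
            [0.9, 0.8, 0.3], ["Treg", "Tconv", "Treg"]
        )
        assert out["auc"] == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            rp.roc_and_auc([0.1, 0.9], [1, 1])

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 60))
            scores = rng.integers(0, 8, size=n) / 7.0  # forces ties
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            out = rp.roc_and_auc(scores, y)
            assert out["auc"] == brute_force_auc(scores, y)

    @given(
        st.lists(
            st.tuples(st.integers(0, 10), st.integers(0, 1)),
            min_size=4, max_size=60,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_roc_curve_invariants(self, pairs):
        scores = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([p[1] for p in pairs])
        if y.sum() in (0, y.size):
            return
        out = rp.roc_and_auc(scores, y)
        fpr, tpr = np.array(out["fpr"]), np.array(out["tpr"])
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0)
        assert np.all(np.diff(tpr) >= 0)
        assert out["auc"] == brute_force_auc(scores, y)


class TestConfusion:
    def test_perfect(self):
        out = rp.confusion_at_threshold([0.9, 0.1], ["Treg", "Tconv"], 0.5)
        assert out["accuracy"] == 1.0
        assert out["tp"] == 1 and out["tn"] == 1

    def test_all_predicted_treg_on_balanced(self):
        out = rp.confusion_at_threshold(
            [0.9, 0.8, 0.9, 0.8], [1, 0, 1, 0], 0.5
        )
        assert out["accuracy"] == 0.5

    def test_tie_goes_to_treg(self):
        out = rp.confusion_at_threshold([0.5], ["Tconv"], 0.5)
        assert out["fp"] == 1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        scores = rng.random(60)
        y = rng.integers(0, 2, size=60)
        lo = rp.confusion_at_threshold(scores, y, 0.5)
        hi = rp.confusion_at_threshold(scores, y, 0.9)
        sens = lambda c: c["tp"] / max(c["tp"] + c["fn"], 1)
        spec = lambda c: c["tn"] / max(c["tn"] + c["fp"], 1)
        assert sens(hi) <= sens(lo)
        assert spec(hi) >= spec(lo)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rp.confusion_at_threshold([], [], 0.5)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            rp.confusion_at_threshold([0.5], [1], 1.5)


class TestSelectLambda:
    def _data(self, seed=0, informative=True):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(80, 8))
        if informative:
            logits = 1.5 * X[:, 0] - 1.0 * X[:, 1]
            y = (rng.random(80) < 1 / (1 + np.exp(-logits))).astype(int)
        else:
            y = rng.integers(0, 2, size=80)
        if y.sum() < 4 or y.sum() > 76:
            y[:4] = [0, 1, 0, 1]
        return X, y

    def test_single_value_grid(self):
        X, y = self._data()
        assert select_lambda_cv(X, y, lambda_grid=[0.02], seed=1) == 0.02

    def test_deterministic(self):
        X, y = self._data()
        a = select_lambda_cv(X, y, seed=5)
        b = select_lambda_cv(X, y, seed=5)
        assert a == b

    def test_negative_grid_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError):
            select_lambda_cv(X, y, lambda_grid=[-0.1, 0.1])

    def test_empty_grid_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError):
            select_lambda_cv(X, y, lambda_grid=[])

    def test_pure_noise_prefers_sparse_regime(self):
        # Noise labels: the 1-SE rule should usually land the selection in
        # the all-zero-coefficient regime.  Simulation of this exact setup
        # measures ~70-80% (the plain argmax rule manages only ~40%); the
        # frozen bound leaves a 2-seed margin below the measured rate.
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            X, y = self._data(seed=seed, informative=False)
            lam = select_lambda_cv(
                X, y, folds=5, lambda_grid=(0.01, 0.05, 0.2, 1.0), seed=seed
            )
            model = rp.fit_lasso_logistic(X, y, lam)
            hits += model.n_nonzero == 0
        assert hits >= 12


class TestAnnotateBands:
    def _model_with_peak(self, axis, center, value):
        coefs = np.zeros(axis.size)
        coefs[np.argmin(np.abs(axis - center))] = value
        return FittedModel(
            intercept=0.0, coefficients=coefs, lambda_=0.01,
            center=np.zeros(axis.size), scale=np.ones(axis.size), axis=axis,
        )

    def _table(self):
        return BandAssignmentTable(
            pd.DataFrame(
                {
                    "center_cm1": [1603.0],
                    "tol_cm1": [5.0],
                    "assignment": ["phenyl ring"],
                    "sign": ["positive"],
                }
            )
        )

    def test_planted_coefficient_matched(self):
        axis = rp.make_axis(1500, 1700, 201)
        m = self._model_with_peak(axis, 1602.0, 0.8)
        out = rp.annotate_bands(m, self._table())
        band = out["bands"][0]
        assert band["matched"] and band["sign_agrees"]
        assert band["channel_cm1"] == pytest.approx(1602.0)

    def test_out_of_window_peak_unmatched(self):
        axis = rp.make_axis(1500, 2100, 301)
        m = self._model_with_peak(axis, 2000.0, 0.8)
        out = rp.annotate_bands(m, self._table())
        assert not out["bands"][0]["matched"]

    def test_all_zero_model(self):
        axis = rp.make_axis(1500, 1700, 201)
        m = self._model_with_peak(axis, 1602.0, 0.0)
        out = rp.annotate_bands(m, self._table())
        assert out["n_nonzero"] == 0
        assert not out["bands"][0]["matched"]

    def test_wrong_sign_flagged(self):
        axis = rp.make_axis(1500, 1700, 201)
        m = self._model_with_peak(axis, 1602.0, -0.8)
        out = rp.annotate_bands(m, self._table())
        band = out["bands"][0]
        assert band["matched"] and not band["sign_agrees"]


def test_model_json_round_trip(toy_xy, tmp_path):
    import json

    X, y = toy_xy
    axis = np.array([1000.0, 1010.0])
    m = rp.fit_lasso_logistic(X, y, 0.01, axis=axis, seed=3)
    d = m.to_dict()
    path = tmp_path / "model.json"
    path.write_text(json.dumps(d))
    back = FittedModel.from_dict(json.loads(path.read_text()))
    np.testing.assert_allclose(back.coefficients, m.coefficients)
    np.testing.assert_allclose(back.center, m.center)
    assert back.intercept == m.intercept


def test_evaluate_confusion_sums_to_n():
    rng = np.random.default_rng(4)
    scores = rng.random(40)
    y = rng.integers(0, 2, size=40)
    y[:2] = [0, 1]
    out = evaluate(scores, y)
    assert out["tp"] + out["tn"] + out["fp"] + out["fn"] == 40


def test_encode_labels_rejects_unknown():
    with pytest.raises(ValueError):
        encode_labels(["Treg", "CD8"])
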