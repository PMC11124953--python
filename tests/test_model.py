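import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gaitspeed.model import (
    SpeedModel,
    bic_score,
    fit_speed_model,
    forward_stepwise,
    predict,
    znorm_apply,
    znorm_fit,
)


def _frame(X, y, prefix="f"):
    df = pd.DataFrame(X, columns=[f"{prefix}{i:03d}" for i in range(X.shape[1])])
    df["y"] = y
    return df


# ---------------------------------------------------------------------------
# z-normalization
# ---------------------------------------------------------------------------

def test_znorm_population_denominator():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    stats = znorm_fit(df)
    z = znorm_apply(stats, df)
    np.testing.assert_allclose(z["a"], [-1.2247448, 0.0, 1.2247448], atol=1e-6)


def test_znorm_idempotent_on_standardized_column():
    rng = np.random.default_rng(0)
    x = rng.normal(size=500)
    x = (x - x.mean()) / x.std()
    df = pd.DataFrame({"a": x})
    z = znorm_apply(znorm_fit(df), df)
    np.testing.assert_allclose(z["a"], x, atol=1e-12)


def test_znorm_train_only_and_test_at_mean_maps_to_zero():
    train = pd.DataFrame({"a": [0.0, 2.0, 4.0]})
    stats = znorm_fit(train)
    test = pd.DataFrame({"a": [2.0]})
    assert znorm_apply(stats, test)["a"].iloc[0] == 0.0
    cols = znorm_apply(stats, train)
    assert abs(cols["a"].mean()) < 1e-10
    assert abs(cols["a"].std(ddof=0) - 1.0) < 1e-10


def test_znorm_drops_zero_variance_columns():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    stats = znorm_fit(df)
    assert stats.kept == ["a"] and stats.dropped == ["b"]


# ---------------------------------------------------------------------------
# BIC
# ---------------------------------------------------------------------------

def test_bic_formula_arithmetic():
    rss, n, k = 10.0, 100, 3
    assert bic_score(rss, n, k) == pytest.approx(n * math.log(rss / n) + k * math.log(n))


def test_bic_penalty_and_fit_terms():
    base = bic_score(10.0, 100, 3)
    assert bic_score(10.0, 100, 6) == pytest.approx(base + 3 * math.log(100))
    assert bic_score(5.0, 100, 3) == pytest.approx(base - 100 * math.log(2))


def test_bic_perfect_fit_sentinel():
    with pytest.warns(UserWarning):
        assert bic_score(0.0, 100, 3) == -np.inf
    with pytest.raises(ValueError):
        bic_score(1.0, 3, 3)


# ---------------------------------------------------------------------------
# forward stepwise selection
# ---------------------------------------------------------------------------

def test_stepwise_finds_planted_feature_first():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(500, 50))
    y = 3.0 * X[:, 7] + rng.normal(scale=0.5, size=500)
    model = forward_stepwise(_frame(X, y), [f"f{i:03d}" for i in range(50)])
    assert model.features[0] == "f007"


def test_stepwise_exhausts_small_pool():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(200, 4))
    y = X @ [1.0, -0.5, 0.3, 0.2] + rng.normal(scale=0.1, size=200)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = forward_stepwise(_frame(X, y), [f"f{i:03d}" for i in range(4)])
    assert len(model.features) == 4


def test_stepwise_reaches_cap_even_when_bic_worsens():
    """Selection never stops below the 10-term cap on a pure-noise pool."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(600, 30))
    y = rng.normal(size=600)  # no real signal: BIC worsens after step 1
    model = forward_stepwise(_frame(X, y), [f"f{i:03d}" for i in range(30)])
    assert len(model.features) == 10


def test_stepwise_first_pick_matches_exhaustive_search():
    """First selected feature equals the BIC-best single feature by brute
    force over every candidate, across 100 random problems."""
    rng = np.random.default_rng(42)
    for trial in range(100):
        n = int(rng.integers(40, 120))
        p = int(rng.integers(2, 9))
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p) * (rng.random(p) < 0.5)
        y = X @ beta + rng.normal(scale=1.0, size=n)
        names = [f"f{i:03d}" for i in range(p)]
        df = _frame(X, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = forward_stepwise(df, names, max_terms=2)
        best_name, best_bic = None, np.inf
        for name in names:
            fit = sm.OLS(y, sm.add_constant(df[[name]])).fit()
            bic = n * math.log(fit.ssr / n) + 2 * math.log(n)
            if bic < best_bic:
                best_name, best_bic = name, bic
        assert model.features[0] == best_name


def test_stepwise_skips_collinear_duplicate():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(300, 3))
    df = _frame(X, X[:, 0] * 2 + rng.normal(scale=0.1, size=300))
    df["f003"] = df["f000"]  # exact duplicate of the best feature
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = forward_stepwise(df, [f"f{i:03d}" for i in range(4)], max_terms=4)
    assert "f000" in model.features
    assert len(model.features) == 3  # duplicate skipped as singular


def test_stepwise_parameter_recovery_high_snr():
    """Planted 10-of-100 linear model, n=5000: recovery of the support and
    accurate coefficients."""
    rng = np.random.default_rng(7)
    n, p = 5000, 100
    X = rng.normal(size=(n, p))
    true_idx = rng.choice(p, size=10, replace=False)
    beta = np.zeros(p)
    beta[true_idx] = rng.uniform(0.5, 1.5, size=10) * rng.choice([-1, 1], size=10)
    y = X @ beta + rng.normal(scale=0.3, size=n)
    names = [f"f{i:03d}" for i in range(p)]
    model = forward_stepwise(_frame(X, y), names)
    recovered = {int(f[1:]) for f in model.features}
    assert len(recovered & set(true_idx)) >= 8
    fitted = np.zeros(p)
    for f, b in zip(model.features, model.coefs):
        fitted[int(f[1:])] = b
    rmse_coef = math.sqrt(np.mean((fitted[true_idx] - beta[true_idx]) ** 2))
    assert rmse_coef < 0.05


def test_no_leakage_from_test_targets():
    """Permuting held-out targets never changes the fitted model."""
    rng = np.random.default_rng(8)
    X = rng.normal(size=(400, 20))
    y = X[:, 3] + rng.normal(scale=0.3, size=400)
    df = _frame(X, y)
    df["subject_id"] = np.repeat(["A", "B", "C", "D"], 100)
    names = [f"f{i:03d}" for i in range(20)]
    train = df[df["subject_id"] != "D"]
    stats1, m1 = fit_speed_model(train, names)
    test = df[df["subject_id"] == "D"].copy()
    test["y"] = rng.permutation(test["y"].to_numpy())
    stats2, m2 = fit_speed_model(train, names)
    assert m1.features == m2.features
    np.testing.assert_array_equal(m1.coefs, m2.coefs)
    # predictions on the permuted-target table are unchanged too
    np.testing.assert_array_equal(predict(m1, stats1, test),
                                  predict(m2, stats2, test))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_predict_at_training_mean_returns_intercept():
    rng = np.random.default_rng(9)
    X = rng.normal(loc=5.0, scale=2.0, size=(300, 6))
    y = 1.0 + X[:, 0] * 0.4 + rng.normal(scale=0.2, size=300)
    df = _frame(X, y)
    names = [f"f{i:03d}" for i in range(6)]
    stats, model = fit_speed_model(df, names, max_terms=3)
    at_mean = pd.DataFrame([stats.means[model.features]], columns=model.features)
    assert predict(model, stats, at_mean)[0] == pytest.approx(model.intercept)


def test_predict_linear_arithmetic():
    stats = znorm_fit(pd.DataFrame({"a": [0.0, 1.0, 2.0]}))
    model = SpeedModel(
        combination="custom", features=["a"], intercept=1.0,
        coefs=np.array([0.5]), se=np.array([0.0]), tstats=np.array([0.0]),
        pvalues=np.array([0.0]), intercept_se=0.0, n_train=3)
    # a-value two population SDs above the mean -> z-score 2 -> 1 + 0.5*2
    sd = float(stats.stds["a"])
    table = pd.DataFrame({"a": [1.0 + 2 * sd]})
    assert predict(model, stats, table)[0] == pytest.approx(2.0)


def test_predict_missing_feature_is_fatal():
    stats = znorm_fit(pd.DataFrame({"a": [0.0, 1.0, 2.0]}))
    model = SpeedModel(
        combination="custom", features=["zzz"], intercept=0.0,
        coefs=np.array([1.0]), se=np.array([0.0]), tstats=np.array([0.0]),
        pvalues=np.array([0.0]), intercept_se=0.0, n_train=3)
    with pytest.raises(KeyError, match="zzz"):
        predict(model, stats, pd.DataFrame({"a": [1.0]}))


def test_in_sample_r2_matches_independent_refit():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(400, 8))
    y = X[:, 1] - 0.7 * X[:, 5] + rng.normal(scale=0.3, size=400)
    df = _frame(X, y)
    stats, model = fit_speed_model(df, [f"f{i:03d}" for i in range(8)], max_terms=2)
    yhat = predict(model, stats, df)
    r2 = np.corrcoef(y, yhat)[0, 1] ** 2
    oracle = sm.OLS(y, sm.add_constant(df[model.features])).fit().rsquared
    assert r2 == pytest.approx(oracle, abs=1e-10)
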