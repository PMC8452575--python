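import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ichradiomics.elasticnet import (
    ElasticNetModel,
    ModelError,
    cv_grid_search,
    fit_elastic_net,
    lambda_max,
    predict_probability,
    variable_importance,
)


def make_xy(n=200, p=8, k=3, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:k] = np.resize([1.5, -1.0, 0.8], k)
    eta = x @ beta
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    X = pd.DataFrame(x, columns=[f"f{j}" for j in range(p)])
    return X, y


def test_lasso_null_model_at_lambda_max():
    X, y = make_xy()
    xs = (X.to_numpy() - X.to_numpy().mean(0)) / X.to_numpy().std(0)
    lmax = lambda_max(xs, y, 1.0)
    model = fit_elastic_net(X, y, alpha=1.0, lam=lmax * 1.0001)
    assert np.all(model.coef == 0.0)
    prev = y.mean()
    assert model.intercept == pytest.approx(np.log(prev / (1 - prev)), abs=1e-6)


def test_unpenalised_limit_matches_mle():
    X, y = make_xy(n=300, p=4, k=2, seed=1)
    model = fit_elastic_net(X, y, alpha=0.5, lam=1e-8, tol=1e-10)
    xs = (X.to_numpy() - X.to_numpy().mean(0)) / X.to_numpy().std(0)

    def nll(w):
        eta = w[0] + xs @ w[1:]
        return np.sum(np.logaddexp(0, eta)) - y @ eta

    w0 = np.zeros(5)
    res = optimize.minimize(nll, w0, method="BFGS", options={"gtol": 1e-10})
    assert model.intercept == pytest.approx(res.x[0], abs=1e-3)
    assert np.allclose(model.coef, res.x[1:], atol=1e-3)


def test_ridge_keeps_all_coefficients_nonzero():
    X, y = make_xy(n=300, p=6, k=2, seed=2)
    model = fit_elastic_net(X, y, alpha=0.0, lam=0.05)
    assert np.all(model.coef != 0.0)


def test_lasso_produces_exact_zeros():
    X, y = make_xy(n=300, p=10, k=2, seed=3)
    model = fit_elastic_net(X, y, alpha=1.0, lam=0.1)
    assert np.sum(model.coef == 0.0) > 0


def test_fit_deterministic():
    X, y = make_xy(seed=4)
    m1 = fit_elastic_net(X, y, alpha=0.5, lam=0.02)
    m2 = fit_elastic_net(X, y, alpha=0.5, lam=0.02)
    assert np.array_equal(m1.coef, m2.coef)
    assert m1.intercept == m2.intercept


def test_active_set_monotone_with_lambda():
    X, y = make_xy(n=400, p=20, k=5, seed=5)
    xs = (X.to_numpy() - X.to_numpy().mean(0)) / X.to_numpy().std(0)
    lmax = lambda_max(xs, y, 1.0)
    lams = np.geomspace(lmax, lmax * 1e-3, 20)
    sizes = [np.sum(fit_elastic_net(X, y, 1.0, l).coef != 0.0) for l in lams]
    # broadly non-decreasing as the penalty relaxes
    assert sizes[0] <= 1
    assert sizes[-1] >= 5
    assert all(b >= a - 1 for a, b in zip(sizes, sizes[1:]))


def test_matches_sklearn_saga():
    sklearn_linear = pytest.importorskip("sklearn.linear_model")
    X, y = make_xy(n=500, p=8, k=3, seed=6)
    xs = (X.to_numpy() - X.to_numpy().mean(0)) / X.to_numpy().std(0)
    Xs = pd.DataFrame(xs, columns=X.columns)
    alpha, lam = 0.5, 0.05
    model = fit_elastic_net(Xs, y, alpha=alpha, lam=lam, tol=1e-10, standardise=False)
    clf = sklearn_linear.LogisticRegression(
        penalty="elasticnet", solver="saga", l1_ratio=alpha,
        C=1.0 / (len(y) * lam), max_iter=200000, tol=1e-12,
    ).fit(xs, y)
    assert np.allclose(model.coef, clf.coef_.ravel(), atol=2e-4)
    assert model.intercept == pytest.approx(clf.intercept_[0], abs=2e-4)


def test_model_json_roundtrip(tmp_path):
    X, y = make_xy(seed=7)
    model = fit_elastic_net(X, y, alpha=0.5, lam=0.02)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = ElasticNetModel.from_json(path)
    assert np.array_equal(back.coef, model.coef)
    assert np.allclose(predict_probability(back, X), predict_probability(model, X))


def test_predict_probability_null_model():
    X, y = make_xy(seed=8)
    xs = (X.to_numpy() - X.to_numpy().mean(0)) / X.to_numpy().std(0)
    lmax = lambda_max(xs, y, 1.0)
    model = fit_elastic_net(X, y, alpha=1.0, lam=lmax * 2)
    probs = predict_probability(model, X)
    assert np.allclose(probs, y.mean(), atol=1e-6)


def test_predict_probability_logit_identity():
    X, y = make_xy(seed=9)
    model = fit_elastic_net(X, y, alpha=0.2, lam=0.01)
    eta = model.linear_predictor(X)
    p = predict_probability(model, X)
    assert np.allclose(np.log(p / (1 - p)), eta, atol=1e-12)


def test_predict_missing_columns():
    X, y = make_xy(seed=10)
    model = fit_elastic_net(X, y, alpha=0.5, lam=0.02)
    with pytest.raises(ModelError, match="missing feature"):
        predict_probability(model, X.drop(columns=["f0"]))


def test_importance_known_coefficients():
    coefs = np.array(
        [-0.28305, 0.10061, -0.09417, 0.06405, -0.02980, 0.02967, 0.01588]
    )
    names = [f"v{i}" for i in range(7)]
    imp = variable_importance(coefs, names)
    assert imp.iloc[0] == pytest.approx(45.9, abs=0.05)
    assert imp.index[0] == "v0"
    assert imp["v1"] == pytest.approx(16.3, abs=0.05)
    assert imp["v2"] == pytest.approx(15.3, abs=0.05)
    assert imp.sum() == pytest.approx(100.0, abs=0.05)
    assert list(imp) == sorted(imp, reverse=True)


def test_importance_single_nonzero():
    imp = variable_importance(np.array([0.0, 2.5, 0.0]), ["a", "b", "c"])
    assert imp["b"] == pytest.approx(100.0)


def test_importance_all_zero_errors():
    with pytest.raises(ModelError):
        variable_importance(np.zeros(3), ["a", "b", "c"])


def test_cv_grid_search_signal_and_determinism():
    X, y = make_xy(n=250, p=10, k=3, seed=11)
    g1 = cv_grid_search(X, y, alphas=[0.0, 0.5, 1.0], k=5, seed=0,
                        n_lambda=20, lambda_min_ratio=1e-3)
    g2 = cv_grid_search(X, y, alphas=[0.0, 0.5, 1.0], k=5, seed=0,
                        n_lambda=20, lambda_min_ratio=1e-3)
    assert g1.cv_auc > 0.7
    assert g1.alpha == g2.alpha and g1.lam == g2.lam
    assert np.array_equal(g1.model.coef, g2.model.coef)
    assert set(g1.per_alpha.columns) >= {"alpha", "best_lambda", "cv_auc"}


def test_cv_grid_search_null_data_honest():
    rng = np.random.default_rng(13)
    X = pd.DataFrame(rng.standard_normal((300, 20)),
                     columns=[f"f{j}" for j in range(20)])
    y = rng.integers(0, 2, 300)
    g = cv_grid_search(X, y, alphas=[0.5, 1.0], k=5, seed=0,
                       n_lambda=20, lambda_min_ratio=1e-3)
    assert abs(g.cv_auc - 0.5) < 0.08
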