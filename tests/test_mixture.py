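import math

import numpy as np
import pandas as pd
import pytest

from hexcomb.mixture import (
    FitConfig, compare_models, design_matrix, em_intercept_mixture,
    fit_mixture, fit_single_binomial, information_criteria, mixture_mean,
    mixture_pmf, neg_loglik,
)


def _frame(y, **cols):
    return pd.DataFrame({"arrivals": y, **cols})


def test_pmf_normalises_and_is_nonnegative():
    rng = np.random.default_rng(0)
    ys = np.arange(9)
    for _ in range(200):
        a, p1, p2 = rng.uniform(0, 1, size=3)
        pmf = mixture_pmf(ys, a, p1, p2)
        assert np.all(pmf >= 0)
        assert np.sum(pmf) == pytest.approx(1.0, abs=1e-12)


def test_pmf_rejects_bad_parameters():
    with pytest.raises(ValueError):
        mixture_pmf(0, 1.2, 0.1, 0.8)
    with pytest.raises(ValueError):
        mixture_pmf(0, 0.5, -0.1, 0.8)


def test_mixture_mean_formula():
    assert mixture_mean(0.5, 0.0, 1.0) == pytest.approx(4.0)
    assert mixture_mean(1.0, 0.25, 0.9) == pytest.approx(2.0)


def test_neg_loglik_matches_arbitrary_precision_oracle():
    import mpmath
    mpmath.mp.dps = 60
    rng = np.random.default_rng(1)
    for _ in range(20):
        y = rng.integers(0, 9, size=5)
        X = np.column_stack([np.ones(5), rng.normal(size=5)])
        beta = rng.normal(size=2)
        p1, p2 = np.sort(rng.uniform(0.01, 0.99, size=2))
        got = neg_loglik(beta, p1, p2, y, X)
        total = mpmath.mpf(0)
        for yi, xi in zip(y, X):
            eta = mpmath.mpf(xi[0]) * beta[0] + mpmath.mpf(xi[1]) * beta[1]
            a = 1 / (1 + mpmath.e ** (-eta))
            b1 = mpmath.binomial(8, int(yi)) * mpmath.mpf(p1) ** int(yi) \
                * (1 - mpmath.mpf(p1)) ** (8 - int(yi))
            b2 = mpmath.binomial(8, int(yi)) * mpmath.mpf(p2) ** int(yi) \
                * (1 - mpmath.mpf(p2)) ** (8 - int(yi))
            total += mpmath.log(a * b1 + (1 - a) * b2)
        assert abs(got - float(-total)) <= 1e-10


def test_two_components_never_worse_than_one():
    rng = np.random.default_rng(2)
    for _ in range(20):
        y = rng.integers(0, 9, size=30)
        _, l0 = fit_single_binomial(y)
        em = em_intercept_mixture(y[None, :])
        assert em["loglik"][0] >= l0 - 1e-9


def test_em_label_convention_and_fit_agreement():
    rng = np.random.default_rng(3)
    y = np.concatenate([rng.binomial(8, 0.05, 20), rng.binomial(8, 0.8, 20)])
    em = em_intercept_mixture(y[None, :])
    assert em["pi1"][0] <= em["pi2"][0]
    fit = fit_mixture(_frame(y), covariates=(), config=FitConfig(seed=0))
    assert fit.pi1 <= fit.pi2
    assert fit.loglik == pytest.approx(float(em["loglik"][0]), abs=1e-6)


def test_intercept_only_fit_reproduces_sample_mean():
    # MLE property of the saturated-in-mean mixture: implied mean == y-bar
    rng = np.random.default_rng(4)
    y = np.concatenate([rng.binomial(8, 0.1, 15), rng.binomial(8, 0.7, 25)])
    fit = fit_mixture(_frame(y), covariates=(), config=FitConfig(seed=0))
    assert fit.implied_mean() == pytest.approx(y.mean(), abs=1e-6)


def test_fit_is_seed_deterministic(small_features):
    a = fit_mixture(small_features, ("local",), FitConfig(seed=5))
    b = fit_mixture(small_features, ("local",), FitConfig(seed=5))
    assert a.loglik == b.loglik
    assert np.array_equal(a.beta, b.beta)
    assert (a.pi1, a.pi2) == (b.pi1, b.pi2)


def test_positive_coefficient_means_fewer_arrivals():
    # groups flagged x=1 fail far more often -> fitted beta_x must be positive
    rng = np.random.default_rng(6)
    x = np.repeat([0, 1], 30)
    y = np.where(x == 1, rng.binomial(8, 0.05, 60), rng.binomial(8, 0.8, 60))
    fit = fit_mixture(_frame(y, x=x), ("x",), FitConfig(seed=0))
    assert fit.beta[fit.beta_names.index("x")] > 0


def test_design_matrix_interaction():
    df = _frame([1, 2, 3], first=[1, 0, 1], local=[1, 1, 0])
    X, names = design_matrix(df, ("first", "local", "first_x_local"))
    assert names == ["intercept", "first", "local", "first_x_local"]
    assert np.array_equal(X[:, 3], [1, 0, 0])


def test_information_criteria_formulas():
    aic, bic = information_criteria(10.0, 3, 40)
    assert aic == pytest.approx(26.0)
    assert bic == pytest.approx(20.0 + 3 * math.log(40))


def test_fit_input_validation():
    with pytest.raises(ValueError, match="at least 3"):
        fit_mixture(_frame([1, 2]), ())
    with pytest.raises(ValueError, match="0..8"):
        fit_mixture(_frame([1, 2, 9]), ())


def test_compare_models_requires_same_outcome(small_features):
    f1 = fit_mixture(small_features, (), FitConfig(seed=0))
    other = small_features.copy()
    other["arrivals"] = (other["arrivals"] + 1).clip(0, 8)
    f2 = fit_mixture(other, (), FitConfig(seed=0))
    with pytest.raises(ValueError, match="hash"):
        compare_models([f1, f2])


def test_compare_models_ranking(small_features):
    f_empty = fit_mixture(small_features, (), FitConfig(seed=0))
    f_local = fit_mixture(small_features, ("local",), FitConfig(seed=0))
    table = compare_models([f_empty, f_local])
    assert list(table["AIC"]) == sorted(table["AIC"])
    assert set(table["model"]) == {"empty", "local"}


def test_capped_coefficients_are_flagged():
    # perfectly separated covariate drives its coefficient to the cap
    y = np.array([0] * 10 + [7] * 10)
    x = np.array([1] * 10 + [0] * 10)
    fit = fit_mixture(_frame(y, x=x), ("x",), FitConfig(seed=0, beta_cap=8.0))
    assert fit.capped[fit.beta_names.index("x")]
    assert not fit.z_reliable
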