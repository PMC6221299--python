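"""Conditional logistic likelihood, Newton fit, sandwich, QIC, VIF.

Brute-force loop oracles re-derive the likelihood, gradient, and cluster
sandwich on small instances; a dense grid search checks the Newton
optimum; simulations check parameter recovery and interval coverage.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cranesel.clogit import (
    ClogitData,
    conditional_loglik,
    fit_clogit,
    qic,
    robust_variance,
    stratum_scores,
    vif_screen,
)
from cranesel.exceptions import ConfigurationError, SeparationError
from cranesel.simulate import simulate_choice_strata


def _random_instance(rng, n_strata=6, size=5, p=2, n_clusters=3):
    rows = n_strata * size
    X = rng.normal(size=(rows, p))
    stratum = np.repeat(np.arange(n_strata), size)
    used = np.zeros(rows, int)
    used[::size] = 1
    clusters = np.repeat(rng.integers(0, n_clusters, n_strata), size)
    return ClogitData.from_arrays(X, used, stratum, clusters)


# ---------------------------------------------------------------- oracles


def loglik_oracle(beta, data):
    """Direct softmax enumeration, one stratum at a time."""
    ll = 0.0
    for s in range(data.n_strata):
        rows = range(data.starts[s], data.starts[s + 1])
        etas = [float(data.X[i] @ beta) for i in rows]
        ll += etas[0] - np.log(sum(np.exp(e) for e in etas))
    return ll


def grad_oracle(beta, data, eps=1e-6):
    p = len(beta)
    g = np.zeros(p)
    for k in range(p):
        e = np.zeros(p)
        e[k] = eps
        g[k] = (loglik_oracle(beta + e, data) - loglik_oracle(beta - e, data)) / (
            2 * eps
        )
    return g


def sandwich_oracle(beta, data, naive_cov):
    """Explicit two-loop cluster sandwich with the g/(g-1) factor."""
    U = stratum_scores(beta, data)
    clusters = np.unique(data.cluster_of_stratum)
    g = len(clusters)
    B = np.zeros((U.shape[1], U.shape[1]))
    for c in clusters:
        Uc = U[data.cluster_of_stratum == c].sum(axis=0)
        B += np.outer(Uc, Uc)
    return naive_cov @ B @ naive_cov * g / (g - 1)


# ------------------------------------------------------------------ tests


def test_loglik_uniform_probabilities():
    """One stratum with 50 availables at beta = 0 gives -log 51."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(51, 3))
    data = ClogitData.from_arrays(
        X, np.r_[1, np.zeros(50, int)], np.zeros(51, int), np.zeros(51, int)
    )
    assert conditional_loglik(np.zeros(3), data) == pytest.approx(-np.log(51))


def test_loglik_location_invariance(rng):
    """Adding a constant to every covariate of one stratum leaves the
    conditional likelihood unchanged."""
    data = _random_instance(rng)
    beta = rng.normal(size=2)
    base = conditional_loglik(beta, data)
    X2 = data.X.copy()
    X2[data.starts[1] : data.starts[2]] += 3.7
    shifted = ClogitData(
        X2, data.starts, data.used_rows, data.cluster_of_stratum, data.names
    )
    assert conditional_loglik(beta, shifted) == pytest.approx(base, abs=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_loglik_and_gradient_match_oracle(seed):
    """Vectorized likelihood equals enumeration to 1e-10 on strata of
    size <= 6; gradient matches central differences."""
    rng = np.random.default_rng(seed)
    data = _random_instance(rng, n_strata=4, size=int(rng.integers(2, 7)))
    beta = rng.normal(scale=0.8, size=2)
    ll, grad = conditional_loglik(beta, data, gradient=True)
    assert ll == pytest.approx(loglik_oracle(beta, data), abs=1e-10)
    assert np.allclose(grad, grad_oracle(beta, data), atol=1e-5)


def test_hessian_matches_finite_difference(rng):
    data = _random_instance(rng)
    beta = rng.normal(size=2)
    _, _, H = conditional_loglik(beta, data, gradient=True, hessian=True)
    eps = 1e-5
    for k in range(2):
        e = np.zeros(2)
        e[k] = eps
        _, gp = conditional_loglik(beta + e, data, gradient=True)
        _, gm = conditional_loglik(beta - e, data, gradient=True)
        assert np.allclose(H[:, k], (gp - gm) / (2 * eps), atol=1e-5)


def test_fit_matches_grid_search():
    """On a tiny instance the Newton optimum equals a dense grid search of
    the likelihood over a bounded box to 1e-3."""
    data = _random_instance(np.random.default_rng(8), n_strata=8, size=4, p=2)
    fit = fit_clogit(data)
    grid = np.linspace(-3, 3, 241)
    best, best_ll = None, -np.inf
    for b1 in grid:
        for b2 in grid:
            ll = conditional_loglik(np.array([b1, b2]), data)
            if ll > best_ll:
                best, best_ll = (b1, b2), ll
    assert abs(fit.beta[0] - best[0]) < 1.5e-2 + 1e-3
    assert abs(fit.beta[1] - best[1]) < 1.5e-2 + 1e-3
    # and the score vanishes at the optimum
    _, grad = conditional_loglik(fit.beta, data, gradient=True)
    assert np.max(np.abs(grad)) < 1e-8


def test_score_zero_at_optimum_large(rng):
    ss = simulate_choice_strata(
        np.array([0.5, -0.3]), n_clusters=5, strata_per_cluster=40, rng=rng
    )
    data = ClogitData.from_strata(ss, standardize=False)
    fit = fit_clogit(data)
    _, grad = conditional_loglik(fit.beta, data, gradient=True)
    assert np.max(np.abs(grad)) < 1e-8
    assert fit.converged


def test_sandwich_matches_loop_oracle(rng):
    data = _random_instance(rng, n_strata=8, size=5, p=3, n_clusters=3)
    fit = fit_clogit(data)
    V = robust_variance(fit, data)
    V_oracle = sandwich_oracle(fit.beta, data, fit.naive_cov)
    assert np.allclose(V, V_oracle, atol=1e-12)
    # symmetric positive semi-definite
    assert np.allclose(V, V.T)
    assert np.all(np.linalg.eigvalsh(V) > -1e-12)


def test_duplicating_clusters_leaves_beta_unchanged(rng):
    data = _random_instance(rng, n_strata=6, size=4, p=2, n_clusters=2)
    fit = fit_clogit(data)
    X2 = np.vstack([data.X, data.X])
    used = np.zeros(len(X2), int)
    sizes = np.diff(data.starts)
    stratum = np.concatenate(
        [np.repeat(np.arange(data.n_strata), sizes),
         np.repeat(np.arange(data.n_strata) + data.n_strata, sizes)]
    )
    used[np.concatenate([data.used_rows, data.used_rows + len(data.X)])] = 1
    clusters = np.concatenate(
        [np.repeat(data.cluster_of_stratum, sizes),
         np.repeat(data.cluster_of_stratum + 10, sizes)]
    )
    data2 = ClogitData.from_arrays(X2, used, stratum, clusters)
    fit2 = fit_clogit(data2)
    assert np.allclose(fit2.beta, fit.beta, atol=1e-7)


def test_constant_within_stratum_covariate_rejected(rng):
    rows = 12
    X = np.column_stack([rng.normal(size=rows), np.repeat([1.0, 2.0, 3.0], 4)])
    stratum = np.repeat(np.arange(3), 4)
    used = np.zeros(rows, int)
    used[::4] = 1
    data = ClogitData.from_arrays(X, used, stratum, np.zeros(rows, int))
    with pytest.raises(ConfigurationError, match="constant within every stratum"):
        fit_clogit(data)


def test_separation_raises_named_error():
    """A covariate that perfectly separates used from available rows sends
    its coefficient to infinity; the fit must name it."""
    rng = np.random.default_rng(3)
    n_strata, size = 20, 5
    rows = n_strata * size
    sep = np.zeros(rows)
    sep[::size] = 1.0  # equals is_used: perfect separation
    X = np.column_stack([sep, rng.normal(size=rows)])
    used = np.zeros(rows, int)
    used[::size] = 1
    data = ClogitData.from_arrays(
        X, used, np.repeat(np.arange(n_strata), size), np.zeros(rows, int),
        names=["sep", "noise"],
    )
    with pytest.raises(SeparationError) as err:
        fit_clogit(data, max_iter=200)
    assert err.value.covariate == "sep"


def test_parameter_recovery_small():
    """Estimates land within 2 robust SE of the truth in most replicates
    (small-scale recovery; the full-scale check lives in acceptance)."""
    beta = np.array([0.6, -0.4, 0.2])
    hits = np.zeros(3)
    reps = 30
    for r in range(reps):
        ss = simulate_choice_strata(
            beta, n_clusters=10, strata_per_cluster=30, n_available=20,
            rng=1000 + r,
        )
        data = ClogitData.from_strata(ss, standardize=False)
        fit = fit_clogit(data)
        robust_variance(fit, data)
        hits += np.abs(fit.beta - beta) <= 2 * fit.robust_se
    assert np.all(hits / reps >= 0.8)


def test_qic_reduces_to_aic_like_limit(rng):
    """With the robust covariance replaced by the naive one the penalty is
    exactly 2p."""
    data = _random_instance(rng, n_strata=10, size=5, p=3)
    fit = fit_clogit(data)
    fit.robust_cov = fit.naive_cov.copy()
    assert qic(fit) == pytest.approx(-2 * fit.loglik + 2 * 3, rel=1e-12)


def test_qic_requires_converged_fit_and_robust_cov(rng):
    data = _random_instance(rng)
    fit = fit_clogit(data)
    with pytest.raises(ConfigurationError):
        qic(fit)  # no robust covariance yet


def test_vif_orthogonal_columns_are_one():
    rng = np.random.default_rng(4)
    n = 4000
    X = rng.normal(size=(n, 3))
    kept, table = vif_screen(X, ["a", "b", "c"])
    assert np.allclose(table["vif"], 1.0, atol=0.05)
    assert kept == ["a", "b", "c"]


def test_vif_correlated_pair_excluded():
    """Correlation 0.9 gives VIF ~ 1/(1-0.81) ~ 5.26, over the threshold."""
    rng = np.random.default_rng(5)
    n = 200_000
    x = rng.normal(size=n)
    y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
    kept, table = vif_screen(np.column_stack([x, y]), ["x", "y"], threshold=5.0)
    assert table.loc["x", "vif"] == pytest.approx(1 / (1 - 0.81), rel=0.05)
    assert table["excluded"].all()
    assert kept == []


def test_vif_duplicated_covariate_is_infinite():
    rng = np.random.default_rng(6)
    x = rng.normal(size=500)
    kept, table = vif_screen(np.column_stack([x, x]), ["x", "x_copy"])
    assert np.isinf(table["vif"]).all()
    assert kept == []


def test_vif_needs_two_covariates():
    with pytest.raises(ConfigurationError):
        vif_screen(np.ones((10, 1)), ["a"])
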