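"""Matched-set conditional logistic regression with cluster-robust inference.

The conditional likelihood of a 1:M matched stratum is the softmax of the
used row's linear predictor over the stratum:

    l(beta) = sum_s [ x_used,s' beta - log sum_{j in s} exp(x_j' beta) ]

Estimation proceeds under the independence working model (strata treated
as independent) by Newton-Raphson with step-halving; inference is
corrected for within-individual dependence with the cluster sandwich
A^{-1} B A^{-1}, where A is the observed information and B sums the outer
products of per-cluster score totals, with a g/(g-1) small-sample factor
for g clusters. Model comparison uses the Quasi-likelihood under
Independence Criterion, QIC = -2 l(beta_hat) + 2 trace(A V_robust).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .design import StrataSet
from .exceptions import ConfigurationError, SeparationError, StratumError

_SEPARATION_BOUND = 30.0


@dataclass
class ClogitData:
    """Row-grouped design data for the conditional likelihood.

    Rows are ordered so each stratum is contiguous with its used row first.
    """

    X: np.ndarray               # (n, p)
    starts: np.ndarray          # (n_strata + 1,) row offsets of strata
    used_rows: np.ndarray       # (n_strata,) row index of each used row
    cluster_of_stratum: np.ndarray  # (n_strata,) integer cluster codes
    names: list
    standardization: dict = field(default_factory=dict)

    @property
    def n_strata(self) -> int:
        return len(self.used_rows)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.cluster_of_stratum))

    @classmethod
    def from_arrays(cls, X, is_used, stratum_ids, cluster_ids, names=None,
                    standardization=None):
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ConfigurationError("non-finite covariates in design matrix")
        is_used = np.asarray(is_used).astype(int)
        stratum_ids = np.asarray(stratum_ids)
        order = np.lexsort((1 - is_used, pd.factorize(stratum_ids)[0]))
        X = X[order]
        is_used = is_used[order]
        stratum_ids = stratum_ids[order]
        cluster_ids = np.asarray(cluster_ids)[order]

        codes, _ = pd.factorize(stratum_ids)
        change = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate([[0], change, [len(codes)]])
        used_rows = starts[:-1]
        if not np.all(is_used[used_rows] == 1):
            raise StratumError("some stratum lacks a used row")
        sizes = np.diff(starts)
        used_per = np.add.reduceat(is_used, starts[:-1])
        if np.any(used_per != 1):
            raise StratumError("each stratum must contain exactly one used row")
        if np.any(sizes < 2):
            raise StratumError("strata must contain at least one available row")
        clus = pd.factorize(cluster_ids)[0]
        cluster_of_stratum = clus[used_rows]
        # a stratum must not span clusters
        if np.any(np.add.reduceat(clus, starts[:-1]) != cluster_of_stratum * sizes):
            raise StratumError("stratum rows span multiple clusters")
        names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
        return cls(X, starts, used_rows, cluster_of_stratum, names,
                   standardization or {})

    @classmethod
    def from_strata(cls, strata: StrataSet, terms=None, standardize: bool = True,
                    constants: dict | None = None):
        """Build fitting data from a StrataSet and a term list.

        ``terms`` defaults to all covariates as main effects.
        """
        if terms is None:
            terms = list(strata.categorical) + list(strata.continuous)
        X, names, consts = strata.design_matrix(
            terms, standardize=standardize, constants=constants
        )
        return cls.from_arrays(
            X,
            strata.df["is_used"].to_numpy(),
            strata.df["stratum_id"].to_numpy(),
            strata.df["cluster_id"].to_numpy(),
            names=names,
            standardization=consts,
        )

    def drop_columns(self, names) -> "ClogitData":
        """A new ClogitData without the named covariate columns."""
        names = set(names)
        keep = [i for i, n in enumerate(self.names) if n not in names]
        if len(keep) == len(self.names):
            return self
        return ClogitData(
            X=self.X[:, keep],
            starts=self.starts,
            used_rows=self.used_rows,
            cluster_of_stratum=self.cluster_of_stratum,
            names=[self.names[i] for i in keep],
            standardization=self.standardization,
        )

    def subset(self, stratum_idx) -> "ClogitData":
        """A new ClogitData restricted to the given stratum indices."""
        stratum_idx = np.asarray(stratum_idx)
        rows = np.concatenate(
            [np.arange(self.starts[i], self.starts[i + 1]) for i in stratum_idx]
        )
        sizes = self.starts[stratum_idx + 1] - self.starts[stratum_idx]
        starts = np.concatenate([[0], np.cumsum(sizes)])
        return ClogitData(
            X=self.X[rows],
            starts=starts,
            used_rows=starts[:-1],
            cluster_of_stratum=self.cluster_of_stratum[stratum_idx],
            names=self.names,
            standardization=self.standardization,
        )


def _eta_stats(beta, data: ClogitData):
    """Linear predictors, per-stratum log-sum-exp, and softmax weights."""
    eta = data.X @ beta
    starts = data.starts[:-1]
    m = np.maximum.reduceat(eta, starts)
    sizes = np.diff(data.starts)
    ex = np.exp(eta - np.repeat(m, sizes))
    denom = np.add.reduceat(ex, starts)
    lse = m + np.log(denom)
    p = ex / np.repeat(denom, sizes)
    return eta, lse, p


def conditional_loglik(beta, data: ClogitData, gradient: bool = False,
                       hessian: bool = False):
    """Conditional log-likelihood, optionally with gradient and Hessian.

    Within each stratum the selection probabilities are the softmax of the
    linear predictors, so they sum to one; the gradient and Hessian take
    the standard multinomial forms.
    """
    beta = np.asarray(beta, dtype=float)
    eta, lse, p = _eta_stats(beta, data)
    ll = float(np.sum(eta[data.used_rows]) - np.sum(lse))
    if not gradient and not hessian:
        return ll
    starts = data.starts[:-1]
    sizes = np.diff(data.starts)
    WX = data.X * p[:, None]
    xbar = np.add.reduceat(WX, starts, axis=0)           # (n_strata, p)
    out = [ll]
    if gradient:
        grad = data.X[data.used_rows].sum(axis=0) - xbar.sum(axis=0)
        out.append(grad)
    if hessian:
        H = -(data.X.T @ WX - xbar.T @ xbar)
        out.append(H)
    return tuple(out)


def stratum_scores(beta, data: ClogitData) -> np.ndarray:
    """Per-stratum score contributions U_s = x_used - E_beta[x]."""
    _, _, p = _eta_stats(np.asarray(beta, float), data)
    starts = data.starts[:-1]
    xbar = np.add.reduceat(data.X * p[:, None], starts, axis=0)
    return data.X[data.used_rows] - xbar


@dataclass
class FitResult:
    """Fitted conditional-logistic model with naive and robust covariance."""

    beta: np.ndarray
    names: list
    naive_cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_strata: int
    n_clusters: int
    robust_cov: np.ndarray | None = None
    qic: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.naive_cov))

    @property
    def robust_se(self) -> np.ndarray:
        if self.robust_cov is None:
            raise ValueError("robust covariance has not been computed")
        return np.sqrt(np.diag(self.robust_cov))

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def summary(self) -> pd.DataFrame:
        from scipy.stats import norm

        se = self.robust_se if self.robust_cov is not None else self.se
        z = self.beta / se
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            },
            index=self.names,
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(zip(self.names, map(float, self.beta))),
            "robust_se": (
                dict(zip(self.names, map(float, self.robust_se)))
                if self.robust_cov is not None
                else None
            ),
            "loglik": self.loglik,
            "qic": self.qic,
            "converged": self.converged,
            "n_strata": self.n_strata,
            "n_clusters": self.n_clusters,
            "metadata": self.metadata,
        }


def _check_identifiable(data: ClogitData):
    """Reject covariates that are constant within every stratum: the
    conditional likelihood cannot identify them."""
    starts = data.starts[:-1]
    for k, name in enumerate(data.names):
        col = data.X[:, k]
        mx = np.maximum.reduceat(col, starts)
        mn = np.minimum.reduceat(col, starts)
        if np.all(mx - mn < 1e-12):
            raise ConfigurationError(
                f"covariate {name!r} is constant within every stratum and "
                "cannot be identified by the conditional likelihood"
            )


def _check_separation(data: ClogitData):
    """Detect monotone likelihood along a covariate axis.

    If the used row attains the within-stratum maximum of covariate k in
    every stratum (strictly somewhere), the likelihood increases without
    bound as beta_k grows; symmetrically for minima. This is the exact
    single-axis separation condition and covers the common applied case
    of a one-hot level that is never (or always) the used row.
    """
    starts = data.starts[:-1]
    for k, name in enumerate(data.names):
        col = data.X[:, k]
        mx = np.maximum.reduceat(col, starts)
        mn = np.minimum.reduceat(col, starts)
        u = col[data.used_rows]
        if np.all(u >= mx - 1e-12) and np.any(u > mn + 1e-12):
            raise SeparationError(name)
        if np.all(u <= mn + 1e-12) and np.any(u < mx - 1e-12):
            raise SeparationError(name)


def fit_clogit(
    data: ClogitData,
    init=None,
    tol: float = 1e-8,
    max_iter: int = 50,
    max_halvings: int = 10,
) -> FitResult:
    """Newton-Raphson fit of the conditional logistic model.

    Converged when the max absolute score falls below ``tol``. Divergence
    of a coefficient beyond a fixed bound raises SeparationError naming
    the covariate; hitting ``max_iter`` returns a flagged result.
    """
    p = data.X.shape[1]
    _check_identifiable(data)
    _check_separation(data)
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    ll, grad, H = conditional_loglik(beta, data, gradient=True, hessian=True)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            it -= 1
            break
        try:
            delta = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(-H, grad, rcond=None)[0]
        step = 1.0
        for _ in range(max_halvings + 1):
            cand = beta + step * delta
            ll_new = conditional_loglik(cand, data)
            if ll_new > ll - 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            worst = data.names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(worst)
        ll, grad, H = conditional_loglik(beta, data, gradient=True, hessian=True)
    else:
        it = max_iter
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True
    if not converged:
        warnings.warn("Newton-Raphson did not converge", RuntimeWarning)
    naive_cov = np.linalg.inv(-H)
    return FitResult(
        beta=beta,
        names=list(data.names),
        naive_cov=naive_cov,
        loglik=ll,
        converged=converged,
        n_iter=it,
        n_strata=data.n_strata,
        n_clusters=data.n_clusters,
        metadata={"tol": tol, "qic_variant": "independence quasi-likelihood (Pan 2001)"},
    )


def robust_variance(
    fit: FitResult, data: ClogitData, small_sample_correction: bool = True
) -> np.ndarray:
    """Cluster sandwich covariance A^{-1} B A^{-1} at the fitted beta.

    A is the observed information; B sums outer products of per-cluster
    score totals. With g clusters, the g/(g-1) factor is applied unless
    disabled. Stores the result on ``fit`` and returns it.
    """
    g = data.n_clusters
    if g < 2:
        raise ConfigurationError("cluster sandwich undefined for fewer than 2 clusters")
    U = stratum_scores(fit.beta, data)
    p = U.shape[1]
    clus = data.cluster_of_stratum
    Uc = np.zeros((clus.max() + 1, p))
    np.add.at(Uc, clus, U)
    B = Uc.T @ Uc
    A_inv = fit.naive_cov
    V = A_inv @ B @ A_inv
    if small_sample_correction:
        V = V * (g / (g - 1))
    V = (V + V.T) / 2.0
    fit.robust_cov = V
    fit.metadata["sandwich_correction"] = (
        f"g/(g-1), g={g}" if small_sample_correction else "none"
    )
    return V


def qic(fit: FitResult) -> float:
    """Quasi-likelihood under Independence Criterion for a converged fit.

    QIC = -2 l(beta_hat) + 2 trace(A V_robust) with A the naive
    information; when V_robust equals the naive covariance the penalty
    reduces to 2p, the AIC-like limit.
    """
    if not fit.converged:
        raise ConfigurationError("QIC requires a converged fit")
    if fit.robust_cov is None:
        raise ConfigurationError("QIC requires the robust covariance")
    try:
        A_times_V = np.linalg.solve(fit.naive_cov, fit.robust_cov)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("naive information is singular") from exc
    value = float(-2.0 * fit.loglik + 2.0 * np.trace(A_times_V))
    fit.qic = value
    return value


def vif_screen(X, names, threshold: float = 5.0):
    """Variance inflation factors with exclusion at the threshold.

    VIF_k = 1/(1 - R^2_k) from regressing column k on the remaining
    columns (with intercept). Exactly collinear columns report inf.

    Returns
    -------
    kept : list of str
    table : DataFrame with columns vif, excluded
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ConfigurationError("VIF screening needs at least 2 covariates")
    Xc = np.column_stack([np.ones(len(X)), X])
    vifs = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in range(X.shape[1]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = variance_inflation_factor(Xc, k + 1)
            if not np.isfinite(v) or v < 0 or v > 1e12:
                v = np.inf
            vifs.append(float(v))
    table = pd.DataFrame({"vif": vifs}, index=list(names))
    table["excluded"] = table["vif"] >= threshold
    kept = [n for n, exc in zip(names, table["excluded"]) if not exc]
    return kept, table
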