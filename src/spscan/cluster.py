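"""Latent subgroup discovery: Gaussian mixtures with BIC model selection.

A bivariate sample that actually contains K latent subpopulations is
modeled as a K-component Gaussian mixture with unconstrained
full-covariance components. EM maximizes the likelihood for each K;
the Bayesian Information Criterion

    BIC(K) = -2 * loglik + n_params * ln(n),   n_params = 6K - 1 (bivariate)

is minimized over K = 1..k_max, so extra components are admitted only
when they improve the fit beyond their parameter cost. The same
machinery generalizes to d-dimensional feature matrices for clustering
on external covariates.

Implementation notes: EM is run from ``restarts`` k-means-seeded starts
and the best final log-likelihood wins; each M-step covariance receives a
ridge 1e-6 * (trace/d) * I against singular collapse; the per-iteration
log-likelihood trajectory is retained, and any decrease beyond 1e-8
aborts the fit (a correctness guard, since EM is monotone by
construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .errors import DataError, FitError, InsufficientDataError

__all__ = [
    "MixtureModel",
    "ClusterAssignment",
    "fit_gmm",
    "select_k",
    "assign",
    "cluster_features",
]

#: relative ridge added to each M-step covariance
_COV_REG = 1e-6
#: permitted downward log-likelihood jitter before EM is declared broken
_MONOTONE_TOL = 1e-8


@dataclass(frozen=True)
class MixtureModel:
    """Fitted K-component Gaussian mixture with full covariances.

    ``loglik_path`` holds the log-likelihood after every EM iteration of
    the winning start (length 1 for the closed-form K=1 fit).
    """

    K: int
    weights: np.ndarray
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)
    loglik: float
    bic: float
    n_params: int
    converged: bool
    seed: int
    n_iter: int
    loglik_path: np.ndarray = field(repr=False)
    shared_covariance: bool = False

    @property
    def d(self) -> int:
        return self.means.shape[1]


@dataclass(frozen=True)
class ClusterAssignment:
    """Hard labels and posterior responsibilities for one sample."""

    labels: np.ndarray
    responsibilities: np.ndarray  # (n, K)


def _n_params(K: int, d: int, shared_covariance: bool) -> int:
    cov_terms = d * (d + 1) // 2
    return (K - 1) + K * d + (1 if shared_covariance else K) * cov_terms


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of N(mean, cov) at each row of X, via Cholesky."""
    d = X.shape[1]
    chol = np.linalg.cholesky(cov)
    z = np.linalg.solve(chol, (X - mean).T)
    maha = np.sum(z * z, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    mx = a.max(axis=1)
    return mx + np.log(np.exp(a - mx[:, None]).sum(axis=1))


def _regularize(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    tr = np.trace(cov)
    ridge = _COV_REG * (tr / d) if tr > 0 else 1e-10
    return cov + max(ridge, 1e-10) * np.eye(d)


def _log_component_matrix(
    X: np.ndarray, weights: np.ndarray, means: np.ndarray, covs: np.ndarray
) -> np.ndarray:
    """(n, K) matrix of log(weight_k) + log N(x_i; mu_k, Sigma_k).

    All K components are handled in one stacked Cholesky solve — the EM
    inner loop lives here, so per-component Python overhead matters.
    """
    K, d, _ = covs.shape
    chols = np.linalg.cholesky(covs)  # (K, d, d), batched
    dev = (X[None, :, :] - means[:, None, :]).transpose(0, 2, 1)  # (K, d, n)
    z = np.linalg.solve(chols, dev)
    maha = np.einsum("kdn,kdn->kn", z, z)
    logdet = 2.0 * np.log(np.diagonal(chols, axis1=1, axis2=2)).sum(axis=1)
    out = (
        np.log(weights)[:, None]
        - 0.5 * (d * np.log(2.0 * np.pi) + logdet[:, None] + maha)
    )
    return out.T


def _m_step(
    X: np.ndarray, resp: np.ndarray, shared_covariance: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, d = X.shape
    K = resp.shape[1]
    nk = resp.sum(axis=0) + 1e-300
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    dev = X[None, :, :] - means[:, None, :]  # (K, n, d)
    covs = np.einsum("nk,knd,kne->kde", resp, dev, dev) / nk[:, None, None]
    if shared_covariance:
        pooled = np.tensordot(nk, covs, axes=1) / n
        covs = np.broadcast_to(pooled, (K, d, d)).copy()
    # ridge against singular collapse, scaled to each component's size
    tr = np.trace(covs, axis1=1, axis2=2)
    ridge = np.maximum(_COV_REG * tr / d, 1e-10)
    covs = covs + ridge[:, None, None] * np.eye(d)[None, :, :]
    return weights, means, covs


def _init_from_kmeans(X: np.ndarray, K: int, seed: int) -> np.ndarray:
    """One-hot responsibilities from a single k-means run."""
    km = KMeans(n_clusters=K, n_init=1, random_state=seed)
    labels = km.fit_predict(X)
    resp = np.zeros((X.shape[0], K))
    resp[np.arange(X.shape[0]), labels] = 1.0
    # an empty k-means cluster would zero out a component: soften
    if (resp.sum(axis=0) == 0).any():
        resp += 1e-3
        resp /= resp.sum(axis=1, keepdims=True)
    return resp


def _fit_k1(X: np.ndarray, seed: int, shared_covariance: bool) -> MixtureModel:
    """Closed-form single-component fit: ML mean and covariance."""
    n, d = X.shape
    mean = X.mean(axis=0)
    dev = X - mean
    cov = _regularize(dev.T @ dev / n)
    loglik = float(np.sum(_log_gauss(X, mean, cov)))
    p = _n_params(1, d, shared_covariance)
    return MixtureModel(
        K=1,
        weights=np.array([1.0]),
        means=mean[None, :],
        covariances=cov[None, :, :],
        loglik=loglik,
        bic=-2.0 * loglik + p * np.log(n),
        n_params=p,
        converged=True,
        seed=seed,
        n_iter=0,
        loglik_path=np.array([loglik]),
        shared_covariance=shared_covariance,
    )


def fit_gmm(
    points: np.ndarray,
    K: int,
    seed: int,
    restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    shared_covariance: bool = False,
) -> MixtureModel:
    """Fit a K-component full-covariance Gaussian mixture by EM.

    The best of ``restarts`` k-means-seeded starts (by final
    log-likelihood) is returned. Convergence is declared when the
    log-likelihood gain of an iteration drops below ``tol``.

    Raises
    ------
    InsufficientDataError
        If n < 5K, too few points to support K full-covariance components.
    FitError
        If the log-likelihood decreases beyond numerical jitter — EM is
        monotone, so a decrease means a broken update.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise DataError("points must be an (n, d) array")
    if not np.isfinite(X).all():
        raise DataError("non-finite input points")
    n, d = X.shape
    if K < 1:
        raise DataError("K must be >= 1")
    if n < 5 * K:
        raise InsufficientDataError(f"n={n} < 5K={5 * K}: too few points for K={K}")
    if K == 1:
        return _fit_k1(X, seed, shared_covariance)

    start_seeds = np.random.SeedSequence(seed).generate_state(restarts) % (2**31)
    best: MixtureModel | None = None
    for s in start_seeds:
        model = _em_single_start(
            X, K, int(s), tol, max_iter, shared_covariance, outer_seed=seed
        )
        if best is None or model.loglik > best.loglik:
            best = model
    assert best is not None
    return best


def _em_single_start(
    X: np.ndarray,
    K: int,
    start_seed: int,
    tol: float,
    max_iter: int,
    shared_covariance: bool,
    outer_seed: int,
) -> MixtureModel:
    n, d = X.shape
    resp = _init_from_kmeans(X, K, start_seed)
    weights, means, covs = _m_step(X, resp, shared_covariance)
    path: list[float] = []
    converged = False
    for it in range(max_iter):
        log_mat = _log_component_matrix(X, weights, means, covs)
        log_norm = _logsumexp_rows(log_mat)
        loglik = float(log_norm.sum())
        if path:
            gain = loglik - path[-1]
            if gain < -_MONOTONE_TOL:
                raise FitError(
                    f"EM log-likelihood decreased by {-gain:.3e} at iteration {it}"
                )
            path.append(loglik)
            if gain < tol:
                converged = True
                break
        else:
            path.append(loglik)
        resp = np.exp(log_mat - log_norm[:, None])
        weights, means, covs = _m_step(X, resp, shared_covariance)
    p = _n_params(K, d, shared_covariance)
    loglik = path[-1]
    return MixtureModel(
        K=K,
        weights=weights,
        means=means,
        covariances=covs,
        loglik=loglik,
        bic=-2.0 * loglik + p * np.log(n),
        n_params=p,
        converged=converged,
        seed=outer_seed,
        n_iter=len(path),
        loglik_path=np.asarray(path),
        shared_covariance=shared_covariance,
    )


def select_k(
    points: np.ndarray,
    k_max: int = 5,
    seed: int = 0,
    restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    shared_covariance: bool = False,
) -> MixtureModel:
    """Fit K = 1..k_max and return the fit with minimal BIC.

    Ties (within strict comparison) resolve toward smaller K because
    candidates are visited in increasing order. K values that are
    infeasible for the sample size are skipped; if every K fails, the
    per-K failures are reported together.
    """
    if k_max < 1:
        raise DataError("k_max must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(k_max) % (2**31)
    best: MixtureModel | None = None
    failures: list[str] = []
    for K in range(1, k_max + 1):
        try:
            model = fit_gmm(
                points,
                K,
                int(child_seeds[K - 1]),
                restarts=restarts,
                tol=tol,
                max_iter=max_iter,
                shared_covariance=shared_covariance,
            )
        except (InsufficientDataError, FitError) as exc:
            failures.append(f"K={K}: {exc}")
            continue
        if best is None or model.bic < best.bic:
            best = model
    if best is None:
        raise FitError("all mixture fits failed: " + "; ".join(failures))
    return best


def assign(model: MixtureModel, points: np.ndarray) -> ClusterAssignment:
    """Posterior responsibilities and maximum-posterior hard labels.

    Ties go to the lowest component index (argmax convention).
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.d:
        raise DataError(f"points must be (n, {model.d})")
    if not np.isfinite(X).all():
        raise DataError("non-finite input points")
    log_mat = _log_component_matrix(X, model.weights, model.means, model.covariances)
    resp = np.exp(log_mat - logsumexp(log_mat, axis=1)[:, None])
    return ClusterAssignment(labels=np.argmax(resp, axis=1), responsibilities=resp)


def cluster_features(
    features: np.ndarray,
    k_max: int = 5,
    seed: int = 0,
    restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ClusterAssignment:
    """Cluster observations on an external d-dimensional covariate block.

    Same mixture machinery as the bivariate case, generalized to d
    dimensions; the returned labels serve downstream as a manifest
    grouping of the (x, y) sample.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    model = select_k(
        X, k_max=k_max, seed=seed, restarts=restarts, tol=tol, max_iter=max_iter
    )
    return assign(model, X)
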