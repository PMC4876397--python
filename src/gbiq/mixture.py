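"""Model-based clustering of grid records.

Gaussian finite mixtures fitted by EM, with the number of components chosen
by BIC — the classification engine applied to grid medians (and to the
(median, IQR) pairs inside the nucleus filter). The EM loop, the covariance
families and the BIC bookkeeping are implemented here rather than delegated,
so that every quantity entering model selection (log-likelihood trace, free
parameter counts, the full BIC scan) is inspectable.

Conventions
-----------
* BIC = -2*loglik + p*ln(n) and is **minimized** (some mixture packages
  maximize the negated version; the sign convention here is the textbook one).
* Four covariance families, from simplest to richest:
  ``spherical-equal`` (one shared isotropic variance), ``spherical-varying``
  (isotropic per component), ``diagonal-varying``, ``full-varying``.
* Features are used on the raw intensity scale by default — grid medians are
  already commensurable within an image set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans, kmeans_plusplus

__all__ = [
    "COVARIANCE_FAMILIES",
    "FitError",
    "GaussianMixtureEM",
    "GaussianMixtureBIC",
    "Assignment",
    "fit_gmm",
    "select_model_bic",
    "assign",
    "suggest_k_kmeans",
    "designate_classes",
]

COVARIANCE_FAMILIES = (
    "spherical-equal",
    "spherical-varying",
    "diagonal-varying",
    "full-varying",
)

_LOG_2PI = np.log(2.0 * np.pi)


class FitError(RuntimeError):
    """EM could not produce a usable mixture fit."""


def _check_data(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"expected an n x d table, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")
    return X


def _n_cov_params(family: str, k: int, d: int) -> int:
    if family == "spherical-equal":
        return 1
    if family == "spherical-varying":
        return k
    if family == "diagonal-varying":
        return k * d
    if family == "full-varying":
        return k * d * (d + 1) // 2
    raise ValueError(f"unknown covariance family {family!r}")


def _log_gauss(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Log density of each point under each component, shape (n, k).

    ``covs`` is always stored as (k, d, d) full matrices; families only
    constrain what the M-step puts there. Batched over components.
    """
    d = X.shape[1]
    try:
        chol = np.linalg.cholesky(covs)                      # (k, d, d)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - regularized
        raise FitError("component covariance not positive-definite") from exc
    diff = X[None, :, :] - means[:, None, :]                 # (k, n, d)
    sol = np.linalg.solve(chol, diff.transpose(0, 2, 1))     # (k, d, n)
    maha = np.einsum("kdn,kdn->kn", sol, sol)
    logdet = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
    return (-0.5 * (d * _LOG_2PI + logdet[:, None] + maha)).T


class GaussianMixtureEM(BaseEstimator):
    """EM-fitted Gaussian mixture with a fixed component count.

    Parameters
    ----------
    n_components : int
        Number of mixture components (k).
    covariance_family : str
        One of :data:`COVARIANCE_FAMILIES`.
    n_init : int, default 10
        Independent k-means++-seeded restarts; the restart with the highest
        converged log-likelihood wins.
    tol : float, default 1e-8
        Relative log-likelihood change declaring convergence.
    max_iter : int, default 500
    reg_factor : float, default 1e-6
        Diagonal regularization: ``reg_factor * mean(feature variances)`` is
        added to every covariance diagonal, keeping fits positive-definite.
    random_state : int or None
        Seed; identical seeds give bit-identical fits.

    Attributes
    ----------
    weights_, means_, covariances_ : mixture parameters (covariances as
        (k, d, d) matrices regardless of family).
    loglik_ : float — converged log-likelihood of the best restart.
    loglik_trace_ : per-iteration log-likelihood of the best restart
        (non-decreasing, up to 1e-9 relative numerical slack).
    bic_ : float — -2*loglik + p*ln(n), minimized.
    n_parameters_ : free-parameter count entering the BIC.
    """

    def __init__(
        self,
        n_components: int = 1,
        covariance_family: str = "full-varying",
        n_init: int = 10,
        tol: float = 1e-8,
        max_iter: int = 500,
        reg_factor: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.covariance_family = covariance_family
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.reg_factor = reg_factor
        self.random_state = random_state

    # -- EM internals -----------------------------------------------------

    def _m_step(self, X: np.ndarray, resp: np.ndarray, reg: float):
        n, d = X.shape
        nk = resp.sum(axis=0) + 10.0 * np.finfo(np.float64).tiny
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        k = self.n_components
        fam = self.covariance_family
        diff = X[None, :, :] - means[:, None, :]              # (k, n, d)
        if fam == "full-varying":
            covs = np.einsum("nk,knd,kne->kde", resp, diff, diff)
            covs /= nk[:, None, None]
            covs += reg * np.eye(d)[None, :, :]
        else:
            # per-component, per-feature weighted variances
            var = np.einsum("nk,knd->kd", resp, diff * diff) / nk[:, None]
            covs = np.empty((k, d, d))
            if fam == "diagonal-varying":
                diag = var + reg
            elif fam == "spherical-varying":
                diag = np.repeat(var.mean(axis=1, keepdims=True) + reg, d, axis=1)
            elif fam == "spherical-equal":
                pooled = float((nk @ var.mean(axis=1)) / nk.sum()) + reg
                diag = np.full((k, d), pooled)
            else:
                raise ValueError(f"unknown covariance family {fam!r}")
            for j in range(k):
                covs[j] = np.diag(diag[j])
        return weights, means, covs

    def _init_params(self, X: np.ndarray, centers: np.ndarray, reg: float):
        n = X.shape[0]
        # hard assignment to seed centers -> initial responsibilities
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        resp = np.zeros((n, self.n_components))
        resp[np.arange(n), d2.argmin(axis=1)] = 1.0
        return self._m_step(X, resp, reg)

    def _em_iterations(self, X, params, reg: float, max_iter: int):
        """Run EM from ``params``; stop on relative tolerance or max_iter."""
        weights, means, covs = params
        trace = []
        prev = -np.inf
        loglik = -np.inf
        for _ in range(max_iter):
            log_comp = _log_gauss(X, means, covs) + np.log(weights)[None, :]
            log_norm = logsumexp(log_comp, axis=1)
            loglik = float(log_norm.sum())
            trace.append(loglik)
            if np.isfinite(prev) and abs(loglik - prev) <= self.tol * abs(prev):
                break
            prev = loglik
            resp = np.exp(log_comp - log_norm[:, None])
            weights, means, covs = self._m_step(X, resp, reg)
        return loglik, trace, (weights, means, covs)

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y=None, feature_names: list[str] | None = None):
        X = _check_data(X)
        n, d = X.shape
        k = self.n_components
        if self.covariance_family not in COVARIANCE_FAMILIES:
            raise ValueError(
                f"covariance_family must be one of {COVARIANCE_FAMILIES}, "
                f"got {self.covariance_family!r}"
            )
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if n <= k * d:
            raise ValueError(f"need n > k*d observations (n={n}, k={k}, d={d})")
        feat_var = X.var(axis=0)
        if np.all(feat_var == 0.0):
            raise FitError("degenerate data: all observations are identical")
        reg = self.reg_factor * float(feat_var.mean())

        rng = np.random.RandomState(self.random_state)
        if k == 1:
            params = self._init_params(X, X.mean(axis=0, keepdims=True), reg)
            loglik, trace, params = self._em_iterations(X, params, reg, self.max_iter)
        else:
            # triage the restarts with a short burn-in, then run only the
            # best seed to full convergence
            burn_in = min(30, self.max_iter)
            best = None
            for _ in range(self.n_init):
                centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=rng)
                params = self._init_params(X, centers, reg)
                cand = self._em_iterations(X, params, reg, burn_in)
                if best is None or cand[0] > best[0]:
                    best = cand
            loglik, trace, params = best
            if self.max_iter > burn_in:
                loglik, tail, params = self._em_iterations(
                    X, params, reg, self.max_iter - burn_in
                )
                trace = trace + tail
        weights, means, covs = params

        self.weights_ = weights
        self.means_ = means
        self.covariances_ = covs
        self.loglik_ = loglik
        self.loglik_trace_ = np.asarray(trace)
        self.n_features_in_ = d
        self.n_obs_ = n
        self.feature_names_ = list(feature_names) if feature_names else None
        self.n_parameters_ = (
            (k - 1) + k * d + _n_cov_params(self.covariance_family, k, d)
        )
        self.bic_ = -2.0 * loglik + self.n_parameters_ * np.log(n)
        return self

    def score_samples(self, X) -> np.ndarray:
        X = _check_data(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"model fitted on {self.n_features_in_} features, got {X.shape[1]}"
            )
        log_comp = _log_gauss(X, self.means_, self.covariances_)
        return logsumexp(log_comp + np.log(self.weights_)[None, :], axis=1)

    def predict_proba(self, X) -> np.ndarray:
        X = _check_data(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"model fitted on {self.n_features_in_} features, got {X.shape[1]}"
            )
        log_comp = _log_gauss(X, self.means_, self.covariances_)
        log_comp = log_comp + np.log(self.weights_)[None, :]
        return np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        # argmax takes the lowest index on exact posterior ties
        return self.predict_proba(X).argmax(axis=1)


class GaussianMixtureBIC(BaseEstimator):
    """Mixture with component count and covariance family chosen by BIC.

    Fits every ``(k, family)`` pair over ``k_range`` x ``families`` and keeps
    the minimum-BIC model; exact BIC ties resolve toward smaller ``k``, then
    the simpler family. The full scan is kept in ``scan_`` for inspection.
    """

    def __init__(
        self,
        k_range: tuple[int, int] = (1, 9),
        families: tuple[str, ...] = COVARIANCE_FAMILIES,
        n_init: int = 10,
        tol: float = 1e-8,
        max_iter: int = 500,
        random_state: int | None = None,
    ):
        self.k_range = k_range
        self.families = families
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None, feature_names: list[str] | None = None):
        X = _check_data(X)
        lo, hi = self.k_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid k_range {self.k_range}")
        rows, errors = [], []
        best: GaussianMixtureEM | None = None
        rng = np.random.RandomState(self.random_state)
        for k in range(lo, hi + 1):
            for fam in self.families:
                seed = int(rng.randint(0, 2**31 - 1))
                try:
                    m = GaussianMixtureEM(
                        n_components=k, covariance_family=fam,
                        n_init=self.n_init, tol=self.tol,
                        max_iter=self.max_iter, random_state=seed,
                    ).fit(X, feature_names=feature_names)
                except (FitError, ValueError) as exc:
                    errors.append(f"k={k} {fam}: {exc}")
                    continue
                rows.append(
                    {"k": k, "family": fam, "loglik": m.loglik_,
                     "n_parameters": m.n_parameters_, "bic": m.bic_}
                )
                if best is None or m.bic_ < best.bic_:  # strict: first wins ties
                    best = m
        if best is None:
            raise FitError("all mixture fits failed: " + "; ".join(errors))
        self.scan_ = pd.DataFrame(rows)
        self.best_model_ = best
        self.k_ = best.n_components
        self.covariance_family_ = best.covariance_family
        self.weights_ = best.weights_
        self.means_ = best.means_
        self.covariances_ = best.covariances_
        self.loglik_ = best.loglik_
        self.bic_ = best.bic_
        self.n_features_in_ = best.n_features_in_
        self.feature_names_ = best.feature_names_
        return self

    def predict(self, X):
        return self.best_model_.predict(X)

    def predict_proba(self, X):
        return self.best_model_.predict_proba(X)

    def score_samples(self, X):
        return self.best_model_.score_samples(X)


@dataclass(frozen=True)
class Assignment:
    """Hard labels plus posterior membership probabilities per record."""

    labels: np.ndarray
    responsibilities: np.ndarray


def fit_gmm(data, k: int, family: str = "full-varying",
            seed: int | None = None) -> GaussianMixtureEM:
    """Fit a k-component Gaussian mixture by EM (best of 10 restarts)."""
    return GaussianMixtureEM(
        n_components=k, covariance_family=family, random_state=seed
    ).fit(data)


def select_model_bic(data, k_range: tuple[int, int] = (1, 9),
                     families: tuple[str, ...] = COVARIANCE_FAMILIES,
                     seed: int | None = None) -> GaussianMixtureBIC:
    """Fit all (k, family) candidates and keep the minimum-BIC mixture."""
    return GaussianMixtureBIC(
        k_range=k_range, families=families, random_state=seed
    ).fit(data)


def assign(model, data) -> Assignment:
    """Posterior responsibilities and maximum-posterior hard labels."""
    resp = model.predict_proba(data)
    return Assignment(labels=resp.argmax(axis=1), responsibilities=resp)


def suggest_k_kmeans(data, k_max: int = 9, seed: int | None = None,
                     threshold: float = 0.85) -> int:
    """Suggest a cluster count from k-means distortions via the f(K) criterion.

    Runs k-means for K = 1..k_max and evaluates the distortion-ratio weight
    function f(K) = S_K / (a_K * S_{K-1}) with the published recursive weight
    schedule a_2 = 1 - 3/(4d), a_K = a_{K-1} + (1 - a_{K-1})/6. Returns the K
    minimizing f(K) among candidates with f(K) < ``threshold``; if no f(K)
    dips below the threshold the data carry no cluster structure and 1 is
    returned.
    """
    X = _check_data(data)
    n, d = X.shape
    if n <= k_max:
        raise ValueError(f"need more observations ({n}) than k_max ({k_max})")
    distortion = np.empty(k_max + 1)
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        distortion[k] = km.inertia_
    f = np.ones(k_max + 1)
    alpha = np.empty(k_max + 1)
    for k in range(2, k_max + 1):
        alpha[k] = (1.0 - 3.0 / (4.0 * d)) if k == 2 else (
            alpha[k - 1] + (1.0 - alpha[k - 1]) / 6.0
        )
        if distortion[k - 1] > 0:
            f[k] = distortion[k] / (alpha[k] * distortion[k - 1])
    candidates = [k for k in range(1, k_max + 1) if f[k] < threshold]
    if not candidates:
        return 1
    return int(min(candidates, key=lambda k: f[k]))


def designate_classes(model, assignment: Assignment,
                      counterstain: str, reporter: str) -> dict[int, str]:
    """Advisory biological labels for mixture components.

    Heuristic on the cluster mean profiles of the channel-median features:
    the lowest-counterstain cluster is "void" (cell-free), the highest-
    reporter cluster among the rest is "reporter(+)", the remaining cluster
    with the highest counterstain (nuclei without reporter signal) is
    "reporter(-)", and anything left is "other" (cytoplasm, feeder cells).
    Purely cosmetic: numeric labels stay authoritative and are never altered.
    """
    names = model.feature_names_
    if names is None:
        raise ValueError("model was fitted without feature names")

    def col(channel: str) -> int:
        target = f"{channel}_median"
        for i, nm in enumerate(names):
            if nm == target or nm == channel:
                return i
        raise KeyError(f"no feature for channel {channel!r} in {names}")

    cs, rep = col(counterstain), col(reporter)
    means = model.means_
    k = means.shape[0]
    labels = {j: "other" for j in range(k)}
    remaining = list(range(k))
    if k >= 2:
        void = min(remaining, key=lambda j: means[j, cs])
        labels[void] = "void"
        remaining.remove(void)
    pos = max(remaining, key=lambda j: means[j, rep])
    labels[pos] = "reporter(+)"
    remaining.remove(pos)
    if remaining:
        neg = max(remaining, key=lambda j: means[j, cs])
        labels[neg] = "reporter(-)"
    return labels
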