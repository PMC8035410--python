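"""Finite mixtures of restricted multivariate skew-t distributions.

Each component models Y = mu + delta*|W| + V where, given a Gamma(nu/2, nu/2)
mixing weight tau, W ~ N(0, 1/tau) and V ~ N(0, Sigma/tau).  The marginal
density is

    f(y) = 2 t_d(y; mu, Omega, nu) T_{nu+d}(A sqrt((nu+d)/(nu+Delta)))

with Omega = Sigma + delta delta', Delta the Mahalanobis distance under
Omega, q = delta' Omega^{-1} (y-mu), s^2 = 1 - delta' Omega^{-1} delta and
A = q/s.  Fitting is by ECME: the E-step uses the closed-form conditional
moments of (tau, tau*|W|, tau*W^2); the CM-steps update weights, locations,
skew vectors and scale matrices in closed form, and each component's
degrees of freedom by bounded maximization of the actual observed
log-likelihood (which keeps the likelihood monotone).  Component count is
chosen by BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import gammaln
from scipy.stats import t as t_dist
from sklearn.cluster import KMeans

NU_BOUNDS = (2.5, 200.0)


class MixtureError(RuntimeError):
    pass


class ZeroVarianceError(ValueError):
    pass


@dataclass
class Standardizer:
    """Column-wise zero-mean / unit-SD scaling with an exact inverse."""

    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    columns: list[str] | None = None

    def fit(self, X: np.ndarray, columns: list[str] | None = None) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to standardize")
        self.mean = X.mean(axis=0)
        self.sd = X.std(axis=0, ddof=1)
        self.columns = columns
        zero = np.flatnonzero(self.sd == 0)
        if zero.size:
            names = ([self.columns[k] for k in zero] if self.columns
                     else list(zero))
            raise ZeroVarianceError(f"zero-variance column(s): {names}")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sd + self.mean


def standardize(X: np.ndarray, columns: list[str] | None = None
                ) -> tuple[np.ndarray, Standardizer]:
    sc = Standardizer().fit(X, columns)
    return sc.transform(X), sc


@dataclass
class SkewTComponent:
    weight: float
    mu: np.ndarray
    Sigma: np.ndarray
    delta: np.ndarray
    nu: float


@dataclass
class MixtureFit:
    components: list[SkewTComponent]
    responsibilities: np.ndarray
    log_likelihood: float
    bic: float
    labels: np.ndarray
    converged: bool
    n_iter: int
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def G(self) -> int:
        return len(self.components)


def n_free_parameters(G: int, d: int) -> int:
    """(G-1) weights + per component (mu, delta, Sigma, nu)."""
    return (G - 1) + G * (2 * d + d * (d + 1) // 2 + 1)


def bic_score(log_likelihood: float, n_params: int, n: int) -> float:
    return -2.0 * log_likelihood + n_params * np.log(n)


# ---------------------------------------------------------------------------
# Component density and conditional moments
# ---------------------------------------------------------------------------


def _component_geometry(X: np.ndarray, mu: np.ndarray, Sigma: np.ndarray,
                        delta: np.ndarray):
    """Delta (Mahalanobis under Omega), q, s, logdet(Omega) for all rows."""
    Omega = Sigma + np.outer(delta, delta)
    try:
        L = linalg.cholesky(Omega, lower=True)
    except linalg.LinAlgError as exc:
        raise MixtureError("singular scale matrix") from exc
    diff = X - mu
    z = linalg.solve_triangular(L, diff.T, lower=True)
    Delta = np.sum(z * z, axis=0)
    v = linalg.cho_solve((L, True), delta)
    q = diff @ v
    s2 = 1.0 - delta @ v
    s2 = max(s2, 1e-12)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return Delta, q, np.sqrt(s2), logdet


def skewt_logpdf(X: np.ndarray, mu: np.ndarray, Sigma: np.ndarray,
                 delta: np.ndarray, nu: float) -> np.ndarray:
    """Log density of the restricted multivariate skew-t at each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[1]
    Delta, q, s, logdet = _component_geometry(X, mu, Sigma, delta)
    A = q / s
    M = A * np.sqrt((nu + d) / (nu + Delta))
    log_t = (gammaln((nu + d) / 2) - gammaln(nu / 2)
             - 0.5 * d * np.log(nu * np.pi) - 0.5 * logdet
             - 0.5 * (nu + d) * np.log1p(Delta / nu))
    cdf = t_dist.cdf(M, df=nu + d)
    return np.log(2.0) + log_t + np.log(np.maximum(cdf, 1e-300))


def _conditional_moments(X: np.ndarray, mu: np.ndarray, Sigma: np.ndarray,
                         delta: np.ndarray, nu: float):
    """E[tau | y], E[tau*u | y], E[tau*u^2 | y] for the latent (tau, u=|W|).

    Uses the closed forms in terms of scalar t cdfs; `xi` below is
    E[sqrt(tau) phi(A sqrt(tau)) / Phi(A sqrt(tau)) | y] obtained by direct
    integration over the Gamma mixing density.
    """
    X = np.atleast_2d(X)
    d = X.shape[1]
    Delta, q, s, logdet = _component_geometry(X, mu, Sigma, delta)
    A = q / s
    M = A * np.sqrt((nu + d) / (nu + Delta))
    M2 = A * np.sqrt((nu + d + 2) / (nu + Delta))
    T1 = np.maximum(t_dist.cdf(M, df=nu + d), 1e-300)
    T2 = np.maximum(t_dist.cdf(M2, df=nu + d + 2), 1e-300)
    e_tau = (nu + d) / (nu + Delta) * T2 / T1

    half = (nu + d + 1) / 2.0
    log_numer = (np.log(2.0) - 0.5 * (d + 1) * np.log(2 * np.pi) - 0.5 * logdet
                 + 0.5 * nu * np.log(nu / 2.0) + gammaln(half) - gammaln(nu / 2)
                 + half * np.log(2.0) - half * np.log(nu + Delta + A * A))
    log_t = (gammaln((nu + d) / 2) - gammaln(nu / 2)
             - 0.5 * d * np.log(nu * np.pi) - 0.5 * logdet
             - 0.5 * (nu + d) * np.log1p(Delta / nu))
    log_f = np.log(2.0) + log_t + np.log(T1)
    xi = np.exp(log_numer - log_f)

    e_tau_u = q * e_tau + s * xi
    e_tau_u2 = q * e_tau_u + s * s
    return e_tau, e_tau_u, e_tau_u2


def sample_skewt(n: int, mu, Sigma, delta, nu: float,
                 rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Draw n variates from one restricted skew-t component."""
    rng = np.random.default_rng(rng)
    mu = np.asarray(mu, float)
    Sigma = np.atleast_2d(np.asarray(Sigma, float))
    delta = np.asarray(delta, float)
    d = mu.size
    tau = rng.gamma(nu / 2.0, 2.0 / nu, size=n)
    u = np.abs(rng.standard_normal(n)) / np.sqrt(tau)
    L = linalg.cholesky(Sigma, lower=True)
    eps = (L @ rng.standard_normal((d, n))).T / np.sqrt(tau)[:, None]
    return mu + u[:, None] * delta + eps


def sample_skewt_mixture(n: int, components: list[SkewTComponent],
                         rng: np.random.Generator | int | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(rng)
    weights = np.array([c.weight for c in components])
    labels = rng.choice(len(components), size=n, p=weights / weights.sum())
    X = np.empty((n, components[0].mu.size))
    for g, comp in enumerate(components):
        idx = np.flatnonzero(labels == g)
        if idx.size:
            X[idx] = sample_skewt(idx.size, comp.mu, comp.Sigma, comp.delta,
                                  comp.nu, rng)
    return X, labels


# ---------------------------------------------------------------------------
# ECME fitting
# ---------------------------------------------------------------------------


def _log_density_matrix(X, comps):
    return np.column_stack([skewt_logpdf(X, c.mu, c.Sigma, c.delta, c.nu)
                            for c in comps])


def _total_loglik(X, comps):
    logd = _log_density_matrix(X, comps)
    logw = np.log([c.weight for c in comps])
    m = logd + logw
    mmax = m.max(axis=1, keepdims=True)
    return float(np.sum(mmax.ravel() + np.log(np.sum(np.exp(m - mmax), axis=1))))


def _ridge(Sigma: np.ndarray, rel: float = 1e-6) -> np.ndarray:
    d = Sigma.shape[0]
    return Sigma + rel * max(np.trace(Sigma) / d, 1e-12) * np.eye(d)


def _init_components(X: np.ndarray, G: int, seed: int | None,
                     init_nu: float) -> list[SkewTComponent]:
    n, d = X.shape
    if G == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=G, n_init=1, random_state=seed).fit(X)
        labels = km.labels_
    comps = []
    for g in range(G):
        idx = np.flatnonzero(labels == g)
        if idx.size < d + 2:
            idx = np.arange(n)
        mu = X[idx].mean(axis=0)
        Sigma = _ridge(np.atleast_2d(np.cov(X[idx].T)), rel=1e-3)
        comps.append(SkewTComponent(weight=max(idx.size, 1) / n, mu=mu,
                                    Sigma=Sigma, delta=np.zeros(d), nu=init_nu))
    total = sum(c.weight for c in comps)
    for c in comps:
        c.weight /= total
    return comps


def fit_skewt_mixture(X: np.ndarray, G: int,
                      seed: int | None = None, max_iter: int = 500,
                      tol: float = 1e-6, n_init: int = 5,
                      fix_skew: bool = False, fix_nu: float | None = None,
                      nu_update_every: int = 3) -> MixtureFit:
    """Fit a G-component restricted skew-t mixture by ECME.

    ``n_init`` k-means-seeded starts are run and the best log-likelihood
    kept.  ``fix_skew`` pins all skew vectors at zero and ``fix_nu`` pins
    the degrees of freedom (together they give a t / near-Gaussian mixture).
    The log-likelihood is checked to be non-decreasing at every iteration.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if G < 1:
        raise ValueError("G must be >= 1")
    if n <= G * (d + 1):
        raise MixtureError(f"too few rows ({n}) for G={G} components in {d}-D")
    rng = np.random.default_rng(seed)
    best: MixtureFit | None = None
    for start in range(n_init):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            fit = _fit_once(X, G, sub_seed, max_iter, tol, fix_skew, fix_nu,
                            nu_update_every)
        except MixtureError:
            continue
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    if best is None:
        raise MixtureError(f"all {n_init} starts failed for G={G}")
    return best


def _fit_once(X, G, seed, max_iter, tol, fix_skew, fix_nu, nu_update_every):
    n, d = X.shape
    init_nu = fix_nu if fix_nu is not None else 40.0
    comps = _init_components(X, G, seed, init_nu)
    prev_ll = -np.inf
    ll_path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logd = _log_density_matrix(X, comps)
        logw = np.log([c.weight for c in comps])
        m = logd + logw
        mmax = m.max(axis=1, keepdims=True)
        lse = mmax.ravel() + np.log(np.sum(np.exp(m - mmax), axis=1))
        ll = float(np.sum(lse))
        z = np.exp(m - lse[:, None])
        if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
            raise MixtureError(
                f"log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}")
        ll_path.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * max(1.0, abs(prev_ll)):
            converged = True
            break
        prev_ll = ll

        for g, comp in enumerate(comps):
            zg = z[:, g]
            sz = zg.sum()
            if sz < d + 1:
                raise MixtureError(f"component {g} collapsed (effective n={sz:.2f})")
            e1, e2, e3 = _conditional_moments(X, comp.mu, comp.Sigma,
                                              comp.delta, comp.nu)
            a11 = zg @ e1
            a12 = zg @ e2
            a22 = zg @ e3
            b1 = (zg * e1) @ X
            b2 = (zg * e2) @ X
            if fix_skew:
                mu = b1 / a11
                delta = np.zeros(d)
            else:
                det = a11 * a22 - a12 * a12
                if abs(det) < 1e-12 * max(a11 * a22, 1.0):
                    mu = b1 / a11
                    delta = comp.delta
                else:
                    mu = (a22 * b1 - a12 * b2) / det
                    delta = (a11 * b2 - a12 * b1) / det
            diff = X - mu
            S = (diff * (zg * e1)[:, None]).T @ diff
            cross = (zg * e2) @ diff
            S -= np.outer(cross, delta) + np.outer(delta, cross)
            S += a22 * np.outer(delta, delta)
            Sigma = S / sz
            try:
                linalg.cholesky(Sigma, lower=True)
            except linalg.LinAlgError:
                warnings.warn("regularizing singular scale matrix", stacklevel=2)
                Sigma = _ridge(Sigma, rel=1e-4)
            comp.weight = sz / n
            comp.mu = mu
            comp.delta = delta
            comp.Sigma = Sigma

        if fix_nu is None and it % nu_update_every == 0:
            # profile the observed likelihood over each nu_g; only component
            # g's density column changes, so the others are cached
            logd_cache = _log_density_matrix(X, comps)
            logw_cache = np.log([c.weight for c in comps])

            def total_ll(col_g, g):
                m2 = logd_cache + logw_cache
                m2[:, g] = col_g + logw_cache[g]
                m2max = m2.max(axis=1, keepdims=True)
                return float(np.sum(
                    m2max.ravel() + np.log(np.sum(np.exp(m2 - m2max), axis=1))))

            for g, comp in enumerate(comps):
                current = total_ll(logd_cache[:, g], g)

                def neg_ll(nu_val, comp=comp, g=g):
                    col = skewt_logpdf(X, comp.mu, comp.Sigma, comp.delta,
                                       nu_val)
                    return -total_ll(col, g)

                res = optimize.minimize_scalar(neg_ll, bounds=NU_BOUNDS,
                                               method="bounded",
                                               options={"xatol": 0.2})
                if res.success and -res.fun > current:
                    comp.nu = float(res.x)
                    logd_cache[:, g] = skewt_logpdf(X, comp.mu, comp.Sigma,
                                                    comp.delta, comp.nu)
    logd = _log_density_matrix(X, comps)
    logw = np.log([c.weight for c in comps])
    m = logd + logw
    mmax = m.max(axis=1, keepdims=True)
    lse = mmax.ravel() + np.log(np.sum(np.exp(m - mmax), axis=1))
    ll = float(np.sum(lse))
    z = np.exp(m - lse[:, None])
    p = n_free_parameters(G, d)
    return MixtureFit(components=comps, responsibilities=z,
                      log_likelihood=ll, bic=bic_score(ll, p, n),
                      labels=np.argmax(z, axis=1), converged=converged,
                      n_iter=it, loglik_path=np.asarray(ll_path))


def select_components(X: np.ndarray, G_range=range(1, 13),
                      seed: int | None = None, n_init: int = 5,
                      max_iter: int = 500, tol: float = 1e-6,
                      **fit_kwargs) -> tuple[MixtureFit, pd.DataFrame]:
    """Fit each G in ``G_range`` and return the BIC-minimizing fit + BIC table."""
    G_range = list(G_range)
    if not G_range:
        raise ValueError("G_range is empty")
    rng = np.random.default_rng(seed)
    rows = []
    best = None
    for G in G_range:
        try:
            fit = fit_skewt_mixture(X, G, seed=int(rng.integers(0, 2**31 - 1)),
                                    max_iter=max_iter, tol=tol, n_init=n_init,
                                    **fit_kwargs)
        except MixtureError as exc:
            rows.append({"G": G, "log_likelihood": np.nan, "bic": np.nan,
                         "converged": False, "error": str(exc)})
            continue
        rows.append({"G": G, "log_likelihood": fit.log_likelihood,
                     "bic": fit.bic, "converged": fit.converged, "error": ""})
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise MixtureError("all component counts failed to fit")
    return best, pd.DataFrame(rows)


def cluster_condition_summary(labels: np.ndarray, conditions: np.ndarray,
                              table: pd.DataFrame | None = None,
                              report_columns: list[str] | None = None
                              ) -> pd.DataFrame:
    """Per-cluster event counts/proportions by condition plus feature medians.

    ``table`` may carry extra per-event columns (e.g. amplitude) to report
    per cluster; amplitude is re-attached here for reporting only and is
    never part of the fitted feature space.
    """
    labels = np.asarray(labels)
    conditions = np.asarray(conditions)
    if labels.shape != conditions.shape:
        raise ValueError("labels and conditions must align")
    conds = sorted(pd.unique(conditions).tolist())
    rows = []
    for g in sorted(np.unique(labels)):
        in_g = labels == g
        row = {"cluster": int(g), "n_events": int(in_g.sum())}
        for cond in conds:
            n_c = int(np.sum(in_g & (conditions == cond)))
            row[f"n_{cond}"] = n_c
            row[f"prop_{cond}"] = n_c / max(in_g.sum(), 1)
        if table is not None and report_columns:
            for col in report_columns:
                row[f"median_{col}"] = float(np.nanmedian(
                    table.loc[in_g, col])) if in_g.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
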