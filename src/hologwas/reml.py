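"""Restricted maximum likelihood (REML) variance-component estimation.

The model is the standard multi-kernel linear mixed model

    y = X b + sum_k u_k + e,   u_k ~ N(0, sigma2_k K_k),   e ~ N(0, sigma2_e I)

with relationship kernels K_k (a GRM, per-segment MRMs, or any mix).  With a
single genomic kernel the genetic ratio sigma2_g / sigma2_p is the SNP
heritability h2; with a GRM plus four gut-segment MRMs the per-kernel ratios
are the "omics explainability" of the trait by host genetics and each
segment's microbiota.

Fitting uses average-information (AI) REML with an expectation-maximization
fallback and step-halving on non-improving steps, so the restricted
log-likelihood is non-decreasing across accepted iterations.  Single-kernel
models dispatch to an exact spectral path (one eigendecomposition of K, then
a 1-D profile-likelihood search over the variance ratio) which evaluates the
same restricted likelihood; both paths use

    lR = -1/2 [ (n-p) log 2pi + log|V| + log|X' V^-1 X| + y' P y ].

Components are floored at 1e-6 * var(y) when an update goes negative, and the
convergence criterion is an absolute change in lR below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import AbundanceTable, KernelMatrix

__all__ = [
    "VarianceComponentModel",
    "VarianceComponentResults",
    "HeritabilityResult",
    "reml_fit",
    "lrt_component",
    "screen_heritable_taxa",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HeritabilityResult:
    """A feature's variance-ratio estimate with its significance screen."""

    feature: str
    segment: str | None
    h2: float
    se: float
    lrt: float | None = None
    p: float | None = None
    heritable: bool | None = None


class VarianceComponentModel:
    """Multi-kernel variance-component mixed model.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Trait vector (FCR, or a taxon's CLR abundance).
    kernels : sequence of KernelMatrix or ndarray
        Random-effect relationship kernels; the residual identity kernel is
        implicit.  May be empty (residual-only model).
    exog : array-like, shape (n, p), optional
        Fixed-effect design matrix.  Defaults to an intercept.  An intercept
        column is NOT added automatically when ``exog`` is given.
    names : sequence of str, optional
        Component labels; defaults to kernel kinds/segments plus "residual".
    """

    def __init__(self, endog, kernels, exog=None, names=None) -> None:
        y = np.asarray(endog, dtype=float).ravel()
        n = y.size
        if exog is None:
            X = np.ones((n, 1))
        else:
            X = np.atleast_2d(np.asarray(exog, dtype=float))
            if X.shape[0] != n:
                raise ValueError("exog rows must match endog length")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        if n <= X.shape[1] + 1:
            raise ValueError("need n > rank(covariates) + 1 observations")
        mats = []
        auto_names = []
        for k in kernels:
            if isinstance(k, KernelMatrix):
                if k.n != n:
                    raise ValueError("kernel dimension does not match endog")
                k.validate_psd()
                mats.append(k.values)
                auto_names.append(k.segment if k.segment else
                                  ("genetic" if k.kind == "GRM" else "microbial"))
            else:
                km = np.asarray(k, dtype=float)
                if km.shape != (n, n):
                    raise ValueError("kernel dimension does not match endog")
                mats.append(km)
                auto_names.append(f"K{len(mats)}")
        if names is None:
            names = auto_names
        if len(names) != len(mats):
            raise ValueError("one name per kernel expected")
        self.endog = y
        self.exog = X
        self.kernels = mats
        self.names = list(names) + ["residual"]
        self.nobs = n

    # ------------------------------------------------------------------ likelihood

    def loglike_restricted(self, variances) -> float:
        """Restricted log-likelihood at the given component vector
        (kernel variances followed by the residual variance)."""
        ll, _, _, _ = self._ll_parts(np.asarray(variances, dtype=float))
        return ll

    def _ll_parts(self, theta):
        n, p = self.nobs, self.exog.shape[1]
        V = theta[-1] * np.eye(n)
        for t, K in zip(theta[:-1], self.kernels):
            V += t * K
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return -np.inf, None, None, None
        logdet_v = 2.0 * np.log(np.diag(L)).sum()
        Vinv = np.linalg.inv(V)
        X = self.exog
        VinvX = Vinv @ X
        XtVinvX = X.T @ VinvX
        sign, logdet_x = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            return -np.inf, None, None, None
        P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
        Py = P @ self.endog
        yPy = float(self.endog @ Py)
        ll = -0.5 * ((n - p) * _LOG2PI + logdet_v + logdet_x + yPy)
        return ll, P, Py, V

    # ------------------------------------------------------------------ fitting

    def fit(
        self,
        method: str = "auto",
        max_iter: int = 200,
        tol: float = 1e-8,
        start=None,
    ) -> "VarianceComponentResults":
        """Estimate the variance components by REML.

        ``method`` is ``"ai"`` (average-information with EM fallback),
        ``"spectral"`` (exact 1-D profile search; single-kernel models only)
        or ``"auto"`` (spectral when exactly one kernel, else AI).
        """
        if method == "auto":
            method = "spectral" if len(self.kernels) == 1 else "ai"
        if not self.kernels:
            return self._fit_null()
        if method == "spectral":
            if len(self.kernels) != 1:
                raise ValueError("spectral path requires exactly one kernel")
            return self._fit_spectral(tol=tol)
        if method != "ai":
            raise ValueError(f"unknown method {method!r}")
        return self._fit_ai(max_iter=max_iter, tol=tol, start=start)

    def _fit_null(self) -> "VarianceComponentResults":
        """Residual-only model; closed-form REML."""
        y, X = self.endog, self.exog
        n, p = self.nobs, X.shape[1]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        s2 = rss / (n - p)
        _, logdet_xx = np.linalg.slogdet(X.T @ X)
        ll = -0.5 * ((n - p) * (_LOG2PI + 1.0 + np.log(s2)) + logdet_xx)
        theta = np.array([s2])
        cov = np.array([[2.0 * s2**2 / (n - p)]])
        return VarianceComponentResults(self, theta, cov, ll, True, 0, [ll])

    def _fit_spectral(self, tol: float = 1e-8) -> "VarianceComponentResults":
        K = self.kernels[0]
        d, U = np.linalg.eigh(K)
        d = np.clip(d, 0.0, None)
        yt = U.T @ self.endog
        Xt = U.T @ self.exog
        lam, ll, n_eval = _profile_reml_1d(yt, Xt, d, tol=tol)
        s2e = _profiled_residual_variance(yt, Xt, d, lam)
        theta = np.array([lam * s2e, s2e])
        floor = 1e-6 * float(np.var(self.endog))
        theta = np.maximum(theta, floor)
        _, P, Py, _ = self._ll_parts(theta)
        cov = _ai_covariance(self.kernels, P, Py)
        return VarianceComponentResults(self, theta, cov, ll, True, n_eval, [ll])

    def _fit_ai(self, max_iter: int, tol: float, start=None) -> "VarianceComponentResults":
        y = self.endog
        n = self.nobs
        n_comp = len(self.kernels) + 1
        vary = float(np.var(y))
        floor = 1e-6 * vary
        theta = (np.full(n_comp, vary / n_comp) if start is None
                 else np.maximum(np.asarray(start, dtype=float), floor))
        ll, P, Py, _ = self._ll_parts(theta)
        history = [ll]
        pinned = np.zeros(n_comp, dtype=bool)  # components held at the floor
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            u = [K @ Py for K in self.kernels] + [Py]
            traces = [np.sum(P * K) for K in self.kernels] + [np.trace(P)]
            score = np.array([-0.5 * (tr - float(ui @ Py))
                              for ui, tr in zip(u, traces)])
            # release a pinned component when the likelihood pushes it up
            pinned &= ~(score > 0)
            active = ~pinned

            Ustack = np.column_stack(u)
            ai = 0.5 * (Ustack.T @ (P @ Ustack))
            ai = 0.5 * (ai + ai.T)

            accepted = False
            na = int(active.sum())
            if na:
                aa = ai[np.ix_(active, active)] + 1e-12 * np.eye(na)
                try:
                    delta = np.linalg.solve(aa, score[active])
                except np.linalg.LinAlgError:
                    delta = None
                if delta is not None:
                    for frac in (1.0, 0.5, 0.25, 0.1, 0.01):
                        cand = theta.copy()
                        cand[active] = theta[active] + frac * delta
                        hit = cand < floor
                        cand[hit] = floor
                        cll, cP, cPy, _ = self._ll_parts(cand)
                        if cll >= ll - 1e-12:
                            pinned |= hit
                            theta, P, Py, ll_new = cand, cP, cPy, cll
                            accepted = True
                            break
            if not accepted:
                # EM fallback: guaranteed-ascent direction
                em = theta + theta**2 * np.array(
                    [float(ui @ Py) - tr for ui, tr in zip(u, traces)]) / n
                cand = np.maximum(em, floor)
                cand[pinned] = floor
                cll, cP, cPy, _ = self._ll_parts(cand)
                if cll >= ll:
                    theta, P, Py, ll_new = cand, cP, cPy, cll
                    accepted = True
            if not accepted:
                converged = True  # no ascent direction left
                break
            history.append(ll_new)
            if (ll_new - ll) < tol and it > 1:
                ll = ll_new
                converged = True
                break
            ll = ll_new
        cov = _ai_covariance(self.kernels, P, Py)
        return VarianceComponentResults(self, theta, cov, ll, converged, it, history)


def _profiled_residual_variance(yt, Xt, d, lam) -> float:
    n, p = yt.size, Xt.shape[1]
    w = 1.0 / (lam * d + 1.0)
    XtW = Xt * w[:, None]
    G = Xt.T @ XtW
    b = XtW.T @ yt
    r = float(yt @ (w * yt) - b @ np.linalg.solve(G, b))
    return r / (n - p)


def _profile_loglik_1d(lam, yt, Xt, d) -> float:
    n, p = yt.size, Xt.shape[1]
    w = 1.0 / (lam * d + 1.0)
    XtW = Xt * w[:, None]
    G = Xt.T @ XtW
    sign, logdet_g = np.linalg.slogdet(G)
    if sign <= 0:
        return -np.inf
    b = XtW.T @ yt
    r = float(yt @ (w * yt) - b @ np.linalg.solve(G, b))
    s2 = r / (n - p)
    return -0.5 * ((n - p) * (_LOG2PI + 1.0 + np.log(s2))
                   - np.log(w).sum() + logdet_g)


def _profile_reml_1d(yt, Xt, d, tol: float = 1e-8):
    """Maximize the profiled restricted likelihood over the variance ratio
    lambda = sigma2_k / sigma2_e on a log grid plus local refinement."""
    grid = np.concatenate(([0.0], np.logspace(-4, 3, 40)))
    vals = np.array([_profile_loglik_1d(g, yt, Xt, d) for g in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi <= lo:
        hi = lo + 1.0
    res = optimize.minimize_scalar(
        lambda lam: -_profile_loglik_1d(lam, yt, Xt, d),
        bounds=(lo, hi), method="bounded",
        options={"xatol": max(1e-10, tol)},
    )
    best_lam, best_ll = float(res.x), float(-res.fun)
    if vals[0] >= best_ll:  # boundary optimum at lambda = 0
        best_lam, best_ll = 0.0, float(vals[0])
    return best_lam, best_ll, int(res.nfev) + len(grid)


def _ai_covariance(kernels, P, Py) -> np.ndarray:
    """Approximate covariance of the variance components: inverse AI matrix."""
    u = [K @ Py for K in kernels] + [Py]
    Ustack = np.column_stack(u)
    ai = 0.5 * (Ustack.T @ (P @ Ustack))
    ai = 0.5 * (ai + ai.T)
    try:
        return np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(ai)


class VarianceComponentResults:
    """Fitted variance components, their uncertainty and derived ratios."""

    def __init__(self, model, theta, cov_params, llf, converged, n_iter, history) -> None:
        self.model = model
        self.params = pd.Series(np.asarray(theta, dtype=float), index=model.names)
        self.cov_params = pd.DataFrame(cov_params, index=model.names, columns=model.names)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.history = list(history)

    @property
    def sigma2_p(self) -> float:
        """Phenotypic variance: the sum of all fitted components."""
        return float(self.params.sum())

    @property
    def ratios(self) -> pd.Series:
        """Per-component fraction of phenotypic variance (sums to 1)."""
        return self.params / self.sigma2_p

    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.clip(np.diag(self.cov_params.to_numpy()), 0, None)),
                         index=self.params.index)

    def heritability(self, component: str = "genetic") -> HeritabilityResult:
        """Variance ratio sigma2_c / sigma2_p with a delta-method SE."""
        if component not in self.params.index:
            raise ValueError(f"component {component!r} not in model")
        s = self.sigma2_p
        if s <= 0:
            raise ValueError("phenotypic variance is zero")
        h = float(self.params[component] / s)
        grad = (pd.Series(0.0, index=self.params.index)
                .add(pd.Series({component: 1.0}), fill_value=0.0) - h) / s
        var = float(grad @ self.cov_params.to_numpy() @ grad)
        return HeritabilityResult(feature=component, segment=None, h2=h,
                                  se=float(np.sqrt(max(var, 0.0))))

    def summary(self) -> str:
        lines = [
            "Variance-component REML results",
            "=" * 46,
            f"{'n obs':<22}{self.model.nobs}",
            f"{'fixed-effect rank':<22}{self.model.exog.shape[1]}",
            f"{'restricted loglik':<22}{self.llf:.6f}",
            f"{'converged':<22}{self.converged} ({self.n_iter} iterations)",
            "-" * 46,
            f"{'component':<14}{'sigma2':>10}{'ratio':>10}{'se':>10}",
        ]
        se = self.bse()
        for name in self.params.index:
            lines.append(
                f"{name:<14}{self.params[name]:>10.4f}{self.ratios[name]:>10.4f}{se[name]:>10.4f}"
            )
        lines.append("-" * 46)
        lines.append(f"{'sigma2_p':<14}{self.sigma2_p:>10.4f}")
        return "\n".join(lines)


def reml_fit(y, kernels, covariates=None, names=None, **fit_kw) -> VarianceComponentResults:
    """Convenience wrapper: build a :class:`VarianceComponentModel` and fit it."""
    return VarianceComponentModel(y, kernels, exog=covariates, names=names).fit(**fit_kw)


def lrt_component(
    full: VarianceComponentResults,
    reduced: VarianceComponentResults,
    boundary_mixture: bool = True,
) -> tuple[float, float]:
    """Likelihood-ratio test for one variance component on the boundary.

    LRT = 2 (ll_full - ll_reduced), clipped at zero.  The default null
    distribution is the 50:50 mixture of a point mass at zero and chi2(1)
    appropriate for a single variance testing sigma2 = 0 on the parameter
    boundary, giving p = 0.5 P(chi2_1 >= LRT); set ``boundary_mixture=False``
    for the plain chi2(1) reference.
    """
    if full.model.nobs != reduced.model.nobs or not np.allclose(
        full.model.endog, reduced.model.endog
    ):
        raise ValueError("full and reduced models must share the same data")
    if len(reduced.model.kernels) != len(full.model.kernels) - 1:
        raise ValueError("reduced model must omit exactly one variance component")
    lrt = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = stats.chi2.sf(lrt, 1)
    if boundary_mixture:
        p = 0.5 * p
    return float(lrt), float(p)


def screen_heritable_taxa(
    tables,
    grm: KernelMatrix,
    covariates=None,
    h2_threshold: float = 0.2,
    alpha: float = 0.05,
    boundary_mixture: bool = True,
) -> pd.DataFrame:
    """Single-kernel heritability screen of every taxon in every segment.

    Each taxon's (CLR-transformed) abundance is fitted with the genomic kernel
    and tested against the no-genetics model by LRT; a taxon is flagged
    heritable when h2 > ``h2_threshold`` AND p < ``alpha`` jointly.  One
    eigendecomposition of the GRM is shared across all taxa.  Fit failures
    surface as flagged rows (NaN estimates), never as dropped taxa.

    Returns a DataFrame with columns
    feature, segment, sigma2_g, sigma2_e, h2, se, lrt, p, heritable.
    """
    if isinstance(tables, AbundanceTable):
        tables = [tables]
    n = grm.n
    if covariates is None:
        X = np.ones((n, 1))
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != n:
            raise ValueError("covariates must match the GRM dimension")
    d, U = np.linalg.eigh(grm.values)
    d = np.clip(d, 0.0, None)
    Xt = U.T @ X
    p_rank = X.shape[1]
    _, logdet_xx = np.linalg.slogdet(X.T @ X)

    rows = []
    for t in tables:
        if t.samples != grm.samples:
            raise ValueError(f"sample order mismatch between GRM and {t.segment} table")
        for taxon in t.taxa:
            y = t.data[taxon].to_numpy(dtype=float)
            try:
                yt = U.T @ y
                lam, ll1, _ = _profile_reml_1d(yt, Xt, d)
                s2e = _profiled_residual_variance(yt, Xt, d, lam)
                s2g = lam * s2e
                h2 = s2g / (s2g + s2e)
                # reduced (no-genetics) closed form
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss = float(np.sum((y - X @ beta) ** 2))
                s20 = rss / (n - p_rank)
                ll0 = -0.5 * ((n - p_rank) * (_LOG2PI + 1.0 + np.log(s20)) + logdet_xx)
                lrt = max(0.0, 2.0 * (ll1 - ll0))
                p = stats.chi2.sf(lrt, 1)
                if boundary_mixture:
                    p = 0.5 * p
                # delta-method SE through the AI matrix, in rotated coordinates
                w = 1.0 / (lam * d + 1.0)
                WX = w[:, None] * Xt
                Pr = (np.diag(w) - WX @ np.linalg.solve(Xt.T @ WX, WX.T)) / s2e
                Py = Pr @ yt
                u1, u2 = d * Py, Py
                ai = 0.5 * np.array([
                    [u1 @ Pr @ u1, u1 @ Pr @ u2],
                    [u2 @ Pr @ u1, u2 @ Pr @ u2],
                ])
                try:
                    cov = np.linalg.inv(ai)
                except np.linalg.LinAlgError:
                    cov = np.linalg.pinv(ai)
                sp = s2g + s2e
                grad = np.array([(1.0 - h2) / sp, -h2 / sp])
                se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
                rows.append((taxon, t.segment, s2g, s2e, h2, se, lrt, p,
                             bool(h2 > h2_threshold and p < alpha)))
            except Exception:  # noqa: BLE001 - surfaced as a flagged row
                rows.append((taxon, t.segment, np.nan, np.nan, np.nan, np.nan,
                             np.nan, np.nan, False))
    return pd.DataFrame(
        rows,
        columns=["feature", "segment", "sigma2_g", "sigma2_e", "h2", "se",
                 "lrt", "p", "heritable"],
    )
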