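"""Average-information REML for variance-component models.

Model: y = X b + sum_j g_j + e with cov(g_j) = sigma2_j A_j and
cov(e) = sigma2_e I, so V = sum_j sigma2_j A_j + sigma2_e I.  The restricted
log-likelihood (constant terms dropped) is

    logL_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

Optimisation is AI-REML: components start at sigma2_p/(m+1), one EM warm-up
step, then Newton steps on the average-information matrix with step-halving
whenever logL decreases, and an active-set treatment of components pinned at
the variance floor (1e-6 * sigma2_p, GCTA's convention).  Single-GRM models
take a spectral shortcut: with A = Q diag(lam) Q', rotating y and X by Q'
makes V diagonal and every iteration O(n p^2).  Both routes maximise the same
objective and agree to numerical precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.stats import chi2

__all__ = [
    "VarianceComponentFit",
    "reml_loglik",
    "null_reml_loglik",
    "reml_fit",
    "reml_lrt",
    "fit_to_hsq",
]

_FLOOR_FRAC = 1e-6


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    pass


@dataclass
class VarianceComponentFit:
    """Result of a (possibly multi-GRM) REML fit.

    ``sigma2`` holds the genetic component variances followed by the residual
    variance; ``h2_observed`` is each genetic component's share of the total
    phenotypic variance on the observed scale.
    """

    sigma2: np.ndarray
    se_sigma2: np.ndarray
    h2_observed: np.ndarray
    se_h2_observed: np.ndarray
    h2_total: float
    se_h2_total: float
    loglik: float
    n_iter: int
    converged: bool
    boundary_flags: np.ndarray
    n: int
    names: list[str] = field(default_factory=list)
    ai_inv: np.ndarray | None = None

    @property
    def vp(self) -> float:
        return float(self.sigma2.sum())


# ---------------------------------------------------------------------------
# pure-definition likelihood (oracle surface)

def reml_loglik(sigma2, grms, y, X) -> float:
    """Restricted log-likelihood at the given component values.

    Direct evaluation from the definition (explicit inverse / determinant);
    intended as a slow, transparent reference for the iterative fitter.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n = y.size
    sigma2 = np.asarray(sigma2, dtype=float)
    V = sigma2[-1] * np.eye(n)
    for s, grm in zip(sigma2[:-1], grms):
        A = grm.A if hasattr(grm, "A") else np.asarray(grm)
        V = V + s * A
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        raise NotPositiveDefiniteError(
            f"V is not positive definite at sigma2={sigma2.tolist()}"
        )
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    signX, logdetX = np.linalg.slogdet(XtViX)
    if signX <= 0:
        raise NotPositiveDefiniteError("X'V^-1X is singular; X must be full rank")
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return float(-0.5 * (logdetV + logdetX + y @ P @ y))


def null_reml_loglik(y, X) -> tuple[float, float]:
    """Closed-form REML of the no-genetic-component model; returns (logL, sigma2_e)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = rss / (n - p)
    _, logdetXtX = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * ((n - p) * np.log(s2) + logdetXtX + (n - p))
    return float(ll), float(s2)


# ---------------------------------------------------------------------------
# backends

class _DenseBackend:
    """V represented as a sum of dense symmetric kernels (last = identity)."""

    def __init__(self, Bs, y, X):
        self.Bs = Bs
        self.y = y
        self.X = X
        self.n = y.size

    def _common(self, theta):
        V = np.zeros((self.n, self.n))
        for t, B in zip(theta, self.Bs):
            V += t * B
        try:
            c, low = sla.cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise NotPositiveDefiniteError(str(exc)) from exc
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        return (c, low), logdetV

    def loglik(self, theta):
        (c, low), logdetV = self._common(theta)
        ViX = sla.cho_solve((c, low), self.X, check_finite=False)
        Viy = sla.cho_solve((c, low), self.y, check_finite=False)
        XtViX = self.X.T @ ViX
        signX, logdetX = np.linalg.slogdet(XtViX)
        if signX <= 0:
            raise NotPositiveDefiniteError("X'V^-1X singular")
        C = np.linalg.inv(XtViX)
        Py = Viy - ViX @ (C @ (ViX.T @ self.y))
        return float(-0.5 * (logdetV + logdetX + self.y @ Py))

    def derivs(self, theta):
        (c, low), logdetV = self._common(theta)
        Vi = sla.cho_solve((c, low), np.eye(self.n), check_finite=False)
        W = Vi @ self.X
        XtViX = self.X.T @ W
        signX, logdetX = np.linalg.slogdet(XtViX)
        if signX <= 0:
            raise NotPositiveDefiniteError("X'V^-1X singular")
        C = np.linalg.inv(XtViX)
        WC = W @ C
        Py = Vi @ self.y - WC @ (W.T @ self.y)
        ll = float(-0.5 * (logdetV + logdetX + self.y @ Py))

        m = len(theta)
        us = []
        trPB = np.empty(m)
        for k, B in enumerate(self.Bs):
            trPB[k] = np.sum(Vi * B) - np.sum(WC * (B @ W))
            us.append(B @ Py)
        yPBPy = np.array([Py @ u for u in us])
        score = -0.5 * (trPB - yPBPy)
        Pu = [Vi @ u - WC @ (W.T @ u) for u in us]
        AI = 0.5 * np.array([[us[k] @ Pu[l] for l in range(m)] for k in range(m)])
        AI = 0.5 * (AI + AI.T)
        return ll, score, AI, yPBPy, trPB


class _SpectralBackend:
    """Single GRM + residual: V diagonal after rotation by the GRM eigenbasis."""

    def __init__(self, lam, ytil, Xtil):
        self.bs = [lam, np.ones_like(lam)]
        self.y = ytil
        self.X = Xtil
        self.n = ytil.size

    def _common(self, theta):
        d = theta[0] * self.bs[0] + theta[1]
        if np.any(d <= 0):
            raise NotPositiveDefiniteError("V has non-positive eigenvalues")
        W = self.X / d[:, None]
        XtViX = self.X.T @ W
        signX, logdetX = np.linalg.slogdet(XtViX)
        if signX <= 0:
            raise NotPositiveDefiniteError("X'V^-1X singular")
        C = np.linalg.inv(XtViX)
        WC = W @ C
        Py = self.y / d - WC @ (W.T @ self.y)
        ll = float(-0.5 * (np.sum(np.log(d)) + logdetX + self.y @ Py))
        return d, W, C, WC, Py, ll

    def loglik(self, theta):
        return self._common(theta)[-1]

    def derivs(self, theta):
        d, W, C, WC, Py, ll = self._common(theta)
        m = 2
        us = [b * Py for b in self.bs]
        trPB = np.array(
            [np.sum(b / d) - np.sum(WC * (b[:, None] * W)) for b in self.bs]
        )
        yPBPy = np.array([Py @ u for u in us])
        score = -0.5 * (trPB - yPBPy)
        Pu = [u / d - WC @ (W.T @ u) for u in us]
        AI = 0.5 * np.array([[us[k] @ Pu[l] for l in range(m)] for k in range(m)])
        AI = 0.5 * (AI + AI.T)
        return ll, score, AI, yPBPy, trPB


# ---------------------------------------------------------------------------
# optimiser

def optimize_ai_reml(
    backend,
    theta0,
    floors,
    max_iter: int = 100,
    tol_ll: float = 1e-6,
    tol_par: float = 1e-8,
    em_first: bool = True,
):
    """Maximise the restricted likelihood; returns (theta, ll, ai, n_iter, converged).

    ``floors`` gives each parameter's lower bound (NaN = unbounded, used for
    covariance parameters).  Convergence requires both |delta logL| < tol_ll
    and max relative parameter change < tol_par.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    floors = np.asarray(floors, dtype=float)
    scale = max(abs(theta).max(), 1e-30)

    ll, score, AI, yPBPy, trPB = backend.derivs(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if em_first and it == 1:
            delta = np.where(
                np.isfinite(floors), theta**2 * 2.0 * score / backend.n, 0.0
            )
        else:
            at_floor = np.isfinite(floors) & (theta <= floors * (1 + 1e-12))
            frozen = at_floor & (score < 0)
            free = ~frozen
            delta = np.zeros_like(theta)
            if free.any():
                sub = AI[np.ix_(free, free)]
                try:
                    delta[free] = np.linalg.solve(sub, score[free])
                except np.linalg.LinAlgError:
                    delta[free] = np.linalg.lstsq(sub, score[free], rcond=None)[0]

        accepted = False
        step = 1.0
        for _ in range(30):
            cand = theta + step * delta
            cand = np.where(np.isfinite(floors), np.maximum(cand, floors), cand)
            try:
                ll_new = backend.loglik(cand)
            except NotPositiveDefiniteError:
                step *= 0.5
                continue
            if ll_new >= ll - 1e-9 or step < 1e-8:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break

        dpar = np.max(np.abs(cand - theta) / np.maximum(np.abs(cand), 1e-10 * scale))
        dll = ll_new - ll
        theta = cand
        ll, score, AI, yPBPy, trPB = backend.derivs(theta)
        if abs(dll) < tol_ll and dpar < tol_par and it > 1:
            converged = True
            break

    return theta, ll, AI, it, converged


# ---------------------------------------------------------------------------
# public fitting API

def _delta_h2(theta, cov):
    """Variance-share point estimates and delta-method SEs."""
    tot = theta.sum()
    m = theta.size - 1
    h2 = theta[:m] / tot
    se = np.empty(m)
    for j in range(m):
        grad = -theta[j] / tot**2 * np.ones_like(theta)
        grad[j] += 1.0 / tot
        se[j] = np.sqrt(max(grad @ cov @ grad, 0.0))
    gtot = theta[:m].sum()
    grad = -gtot / tot**2 * np.ones_like(theta)
    grad[:m] += 1.0 / tot
    se_tot = np.sqrt(max(grad @ cov @ grad, 0.0))
    return h2, se, float(gtot / tot), float(se_tot)


def reml_fit(
    grms,
    y,
    X=None,
    max_iter: int = 100,
    tol_ll: float = 1e-6,
    tol_par: float = 1e-8,
    floor_frac: float = _FLOOR_FRAC,
) -> VarianceComponentFit:
    """Fit sigma2 for one or more GRMs plus a residual by AI-REML.

    ``grms`` is a sequence of :class:`~greml.grm.GRM` (or bare symmetric
    arrays); ``y`` and the rows of ``X`` must be aligned with the GRM ids.
    With a single GRM the spectral shortcut is used automatically.
    """
    grms = list(grms)
    if len(grms) == 0:
        raise ValueError("need at least one GRM")
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    ids = None
    for g in grms:
        A = g.A if hasattr(g, "A") else np.asarray(g)
        if A.shape != (n, n):
            raise ValueError("GRM size does not match phenotype length")
        if hasattr(g, "ids"):
            if ids is not None and g.ids != ids:
                raise ValueError("GRMs have mismatched sample ids")
            ids = g.ids

    if np.ptp(y) == 0:
        raise ValueError("phenotype has zero variance")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    vp = float(np.var(y - X @ beta, ddof=X.shape[1]))
    m = len(grms)
    theta0 = np.full(m + 1, vp / (m + 1))
    floors = np.full(m + 1, floor_frac * vp)

    if m == 1:
        g = grms[0]
        if hasattr(g, "eigh"):
            lam, Q = g.eigh()
        else:
            lam, Q = np.linalg.eigh(np.asarray(g))
        backend = _SpectralBackend(lam, Q.T @ y, Q.T @ X)
    else:
        Bs = [g.A if hasattr(g, "A") else np.asarray(g) for g in grms]
        Bs.append(np.eye(n))
        backend = _DenseBackend(Bs, y, X)

    theta, ll, AI, n_iter, converged = optimize_ai_reml(
        backend, theta0, floors, max_iter=max_iter, tol_ll=tol_ll, tol_par=tol_par
    )
    if not converged:
        warnings.warn(f"AI-REML did not fully converge after {n_iter} iterations")

    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(AI)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    h2, se_h2, h2_tot, se_tot = _delta_h2(theta, cov)
    names = [f"V(G{j + 1})" for j in range(m)] + ["V(e)"]
    if m == 1:
        names[0] = "V(G)"
    return VarianceComponentFit(
        sigma2=theta,
        se_sigma2=se,
        h2_observed=h2,
        se_h2_observed=se_h2,
        h2_total=h2_tot,
        se_h2_total=se_tot,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        boundary_flags=theta <= floors * (1 + 1e-9),
        n=n,
        names=names,
        ai_inv=cov,
    )


def reml_lrt(loglik_full: float, loglik_reduced: float, df: int = 1,
             boundary: bool = True) -> tuple[float, float]:
    """Likelihood-ratio test of nested REML fits.

    With ``boundary=True`` the null distribution is the 50:50 mixture of a
    point mass at zero and chi-square(df) appropriate when the tested variance
    component lies on the boundary of its parameter space.
    """
    if df < 1:
        raise ValueError("models are not nested (df < 1)")
    stat = max(0.0, 2.0 * (loglik_full - loglik_reduced))
    if boundary:
        p = 0.5 * float(chi2.sf(stat, df))
    else:
        p = float(chi2.sf(stat, df))
    return stat, p


def fit_to_hsq(fit: VarianceComponentFit, lrt: tuple[float, float] | None = None):
    """Render a fit as a GCTA-.hsq-style table (Source / Variance / SE rows)."""
    import pandas as pd

    rows = []
    for name, v, s in zip(fit.names, fit.sigma2, fit.se_sigma2):
        rows.append((name, v, s))
    rows.append(("Vp", fit.vp, np.nan))
    for j, name in enumerate(fit.names[:-1]):
        rows.append((f"{name}/Vp", fit.h2_observed[j], fit.se_h2_observed[j]))
    if len(fit.names) > 2:
        rows.append(("Sum of V(G)/Vp", fit.h2_total, fit.se_h2_total))
    rows.append(("logL", fit.loglik, np.nan))
    if lrt is not None:
        rows.append(("LRT", lrt[0], np.nan))
        rows.append(("Pval", lrt[1], np.nan))
    rows.append(("n", fit.n, np.nan))
    return pd.DataFrame(rows, columns=["Source", "Variance", "SE"])
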