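"""REML variance-component estimation for the expression mixed model.

The model is

    y = Xb + u + e,   u ~ N(0, A * sigma_o^2),   e ~ N(0, I * sigma_e^2)

with A the expression relationship matrix (ORM).  The quantity of interest
is rho^2 = sigma_o^2 / (sigma_o^2 + sigma_e^2), the proportion of
phenotypic variance attributable to genome-wide expression.

``fit_reml`` works in the eigenbasis of A: after rotating y and X by A's
eigenvectors the covariance is diagonal, sigma_o^2 * lambda_k + sigma_e^2,
so each restricted-likelihood evaluation is O(n).  The residual variance
and fixed effects are profiled out analytically and the single remaining
ratio gamma = sigma_o^2/sigma_e^2 is optimized by a coarse log-grid sweep
followed by bounded Brent refinement — a safeguarded 1-D search that
cannot diverge the way multi-parameter Newton steps can.  Standard errors
come from the inverse expected (Fisher) information of
(sigma_o^2, sigma_e^2) at the optimum, which for this model equals the
average-information matrix; the SE of rho^2 follows by the delta method:

    se(rho^2)^2 = g' Cov(sigma_o^2, sigma_e^2) g,
    g = (sigma_e^2, -sigma_o^2) / (sigma_o^2 + sigma_e^2)^2.

Boundary solutions (sigma_o^2 = 0) are legitimate converged fits and are
flagged rather than raised.  "Not converged" is a first-class output
state: the information matrix failing to be positive definite, or A
carrying no relationship signal at all (A proportional to I, where only
the sum of the two components is identifiable), yields
``converged=False`` with a diagnostic instead of an arbitrary split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .relationship import RelationshipMatrix

__all__ = [
    "CovariateDesign",
    "VarianceComponents",
    "design_from_phenotypes",
    "fit_reml",
    "fit_reml_multi",
    "restricted_loglik",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class CovariateDesign:
    """Full-column-rank fixed-effect design: intercept + factor dummies."""

    X: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if n <= p:
            raise ValueError("need more individuals than fixed-effect columns")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("design matrix is rank deficient: " + ", ".join(self.labels))

    @property
    def p(self) -> int:
        return self.X.shape[1]


def design_from_phenotypes(table: pd.DataFrame) -> CovariateDesign:
    """Intercept + sex dummy + season dummies from a phenotype table.

    Sex is a two-level factor and birth season up to three levels; with an
    explicit intercept the design uses one dummy fewer than levels per
    factor (reference coding).
    """
    cols = [np.ones(len(table))]
    labels = ["intercept"]
    for factor in ("sex", "season"):
        levels = sorted(pd.unique(table[factor].astype(str)))
        for lev in levels[1:]:
            cols.append((table[factor].astype(str) == lev).to_numpy(float))
            labels.append(f"{factor}={lev}")
    return CovariateDesign(X=np.column_stack(cols), labels=labels)


@dataclass
class VarianceComponents:
    sigma_o2: float
    sigma_e2: float
    rho2: float
    se_sigma_o2: float
    se_sigma_e2: float
    se_rho2: float
    loglik_restricted: float
    n_iter: int
    converged: bool
    boundary: bool = False
    message: str = ""

    def as_row(self) -> dict:
        """Report row mirroring a variance-components table; non-converged
        fits print as missing."""
        if not self.converged:
            return {
                "sigma_o2": np.nan, "se_sigma_o2": np.nan,
                "sigma_e2": np.nan, "se_sigma_e2": np.nan,
                "rho2": np.nan, "se_rho2": np.nan,
                "converged": False,
            }
        return {
            "sigma_o2": self.sigma_o2, "se_sigma_o2": self.se_sigma_o2,
            "sigma_e2": self.sigma_e2, "se_sigma_e2": self.se_sigma_e2,
            "rho2": self.rho2, "se_rho2": self.se_rho2,
            "converged": True,
        }


def restricted_loglik(
    y: np.ndarray, X: np.ndarray, A: np.ndarray, sigma_o2: float, sigma_e2: float
) -> float:
    """Dense restricted log-likelihood of y ~ N(Xb, sigma_o2*A + sigma_e2*I).

    Used for cross-checking the eigen-rotated profile path; O(n^3).
    """
    n, p = X.shape
    V = sigma_o2 * A + sigma_e2 * np.eye(n)
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign_x, logdet_x = np.linalg.slogdet(XtViX)
    if sign_x <= 0:
        return -np.inf
    b = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ b
    quad = float(r @ Vi @ r)
    return -0.5 * (logdet_v + logdet_x + quad + (n - p) * _LOG2PI)


def _profile_negloglik(gamma, lam, y_rot, X_rot, n, p):
    """-2x the profiled restricted log-likelihood at ratio gamma (without
    additive constants); also returns the profiled sigma_e^2."""
    d = gamma * lam + 1.0
    w = 1.0 / d
    Xw = X_rot * w[:, None]
    XtDX = X_rot.T @ Xw
    try:
        c = np.linalg.cholesky(XtDX)
    except np.linalg.LinAlgError:
        return np.inf, np.nan
    logdet_x = 2.0 * np.sum(np.log(np.diag(c)))
    Xty = Xw.T @ y_rot
    b = np.linalg.solve(XtDX, Xty)
    quad = float(y_rot @ (w * y_rot)) - float(Xty @ b)
    if quad <= 0:
        return np.inf, np.nan
    sigma_e2 = quad / (n - p)
    neg2ll = (n - p) * np.log(sigma_e2) + np.sum(np.log(d)) + logdet_x
    return neg2ll, sigma_e2


def _fisher_information(lam, X_rot, sigma_o2, sigma_e2):
    """Expected information of (sigma_o2, sigma_e2) on the eigenbasis.

    With V = diag(v), v_k = sigma_o2*lam_k + sigma_e2, and
    P = V^-1 - B B' where B = V^-1 X (X'V^-1X)^-1/2, each element
    I_rs = 0.5 tr(P A_r P A_s) reduces to O(n p^2) sums because A_1 = diag(lam)
    and A_2 = I are diagonal.
    """
    v = sigma_o2 * lam + sigma_e2
    Xw = X_rot / v[:, None]
    XtViX = X_rot.T @ Xw
    c = np.linalg.cholesky(XtViX)
    # B = V^-1 X L^-T with L lower Cholesky of X'V^-1X, so BB' = V^-1X (X'V^-1X)^-1 X'V^-1
    B = np.linalg.solve(c, Xw.T).T
    h = np.sum(B * B, axis=1)  # diag of BB'
    diags = (lam, np.ones_like(lam))
    info = np.empty((2, 2))
    for r in range(2):
        for s in range(r, 2):
            ar, asd = diags[r], diags[s]
            t1 = np.sum(ar * asd / v**2)
            t2 = np.sum(ar * asd / v * h)
            Mr = B.T @ (ar[:, None] * B)
            Ms = B.T @ (asd[:, None] * B)
            t3 = np.sum(Mr * Ms.T)
            info[r, s] = info[s, r] = 0.5 * (t1 - 2.0 * t2 + t3)
    return info


def fit_reml(
    y: np.ndarray,
    X: CovariateDesign,
    A: RelationshipMatrix,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> VarianceComponents:
    """REML fit of (sigma_o^2, sigma_e^2) for y ~ N(Xb, sigma_o2 A + sigma_e2 I)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if A.n != n or X.X.shape[0] != n:
        raise ValueError("y, X and A must refer to the same individuals in order")
    lam, U = A.eig()
    p = X.p

    # A proportional to I: only sigma_o2 + sigma_e2 is identifiable.
    if np.ptp(lam) < 1e-10 * max(1.0, lam.max()):
        return VarianceComponents(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            loglik_restricted=np.nan, n_iter=0, converged=False,
            message="relationship matrix proportional to identity: variance "
                    "components unidentifiable (only their sum is)",
        )

    y_rot = U.T @ y
    X_rot = U.T @ X.X

    def objective(log10_gamma: float) -> float:
        return _profile_negloglik(10.0 ** log10_gamma, lam, y_rot, X_rot, n, p)[0]

    # Coarse sweep over the ratio on a log grid (plus the gamma=0 boundary),
    # then bounded Brent around the best grid point.
    grid = np.linspace(-8.0, 8.0, 33)
    vals = np.array([objective(t) for t in grid])
    n_eval = len(grid)
    best = int(np.argmin(vals))
    f0, _ = _profile_negloglik(0.0, lam, y_rot, X_rot, n, p)
    if f0 <= vals[best]:
        gamma_hat, fmin, n_iter = 0.0, f0, n_eval
    else:
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        res = minimize_scalar(
            objective, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10, "maxiter": max_iter},
        )
        n_iter = n_eval + int(res.nfev)
        gamma_hat, fmin = 10.0 ** float(res.x), float(res.fun)
        if f0 < fmin:  # boundary still wins
            gamma_hat, fmin = 0.0, f0
    neg2ll, sigma_e2 = _profile_negloglik(gamma_hat, lam, y_rot, X_rot, n, p)
    sigma_o2 = gamma_hat * sigma_e2
    boundary = gamma_hat == 0.0
    loglik = -0.5 * (neg2ll + (n - p) + (n - p) * _LOG2PI)

    # SEs from inverse Fisher information; delta method for rho^2.
    try:
        info = _fisher_information(lam, X_rot, sigma_o2, sigma_e2)
        cov = np.linalg.inv(info)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError("information matrix not positive definite")
    except np.linalg.LinAlgError:
        return VarianceComponents(
            sigma_o2, sigma_e2, sigma_o2 / (sigma_o2 + sigma_e2),
            np.nan, np.nan, np.nan, loglik, n_iter, converged=False,
            boundary=boundary,
            message="information matrix not positive definite at the optimum",
        )
    se_o = float(np.sqrt(cov[0, 0]))
    se_e = float(np.sqrt(cov[1, 1]))
    tot = sigma_o2 + sigma_e2
    g = np.array([sigma_e2, -sigma_o2]) / tot**2
    se_rho2 = float(np.sqrt(g @ cov @ g))
    rho2 = min(max(sigma_o2 / tot, 0.0), 1.0)
    return VarianceComponents(
        sigma_o2=sigma_o2, sigma_e2=sigma_e2, rho2=rho2,
        se_sigma_o2=se_o, se_sigma_e2=se_e, se_rho2=se_rho2,
        loglik_restricted=loglik, n_iter=n_iter, converged=True,
        boundary=boundary,
        message="boundary solution (sigma_o2 = 0)" if boundary else "",
    )


def fit_reml_multi(
    y: np.ndarray,
    X: CovariateDesign,
    As: list[np.ndarray],
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, bool, int]:
    """Average-information REML with several relationship components.

    Fits y ~ N(Xb, sum_c theta_c A_c + theta_e I) and returns
    ``(theta, converged, n_iter)`` with theta ordered as the components of
    ``As`` followed by the residual.  AI updates with step halving and an
    EM fallback keep the components non-negative; used by the MOMENT scan
    when features are stratified into more than one random-effect bin.
    Dense O(n^3) per iteration — intended for the moderate n of a single
    study, not biobank scale.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    K = len(As)
    mats = [np.asarray(a, dtype=float) for a in As] + [np.eye(n)]
    vy = float(np.var(y, ddof=1))
    theta = np.full(K + 1, vy / (K + 1))
    floor = vy * 1e-8
    Xm = X.X

    def restricted_loglik_dense(yv, Xd, V):
        sign, logdet_v = np.linalg.slogdet(V)
        if sign <= 0:
            return -np.inf
        Vi = np.linalg.inv(V)
        XtViX = Xd.T @ Vi @ Xd
        sign_x, logdet_x = np.linalg.slogdet(XtViX)
        if sign_x <= 0:
            return -np.inf
        b = np.linalg.solve(XtViX, Xd.T @ Vi @ yv)
        r = yv - Xd @ b
        return -0.5 * (logdet_v + logdet_x + float(r @ Vi @ r))

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = sum(t * M for t, M in zip(theta, mats))
        Vi = np.linalg.inv(V)
        XtViX = Xm.T @ Vi @ Xm
        P = Vi - Vi @ Xm @ np.linalg.solve(XtViX, Xm.T @ Vi)
        Py = P @ y
        score = np.empty(K + 1)
        ai = np.empty((K + 1, K + 1))
        PMy = [M @ Py for M in mats]
        for r in range(K + 1):
            score[r] = -0.5 * (np.sum(P * mats[r]) - float(Py @ PMy[r]))
            for s in range(r, K + 1):
                ai[r, s] = ai[s, r] = 0.5 * float(PMy[r] @ P @ PMy[s])
        try:
            delta = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            delta = score / max(np.abs(score).max(), 1.0) * vy * 0.1
        # step-halve until the restricted likelihood does not decrease
        step = 1.0
        ll_new = -np.inf
        for _ in range(20):
            cand = np.maximum(theta + step * delta, floor)
            ll_new = restricted_loglik_dense(y, Xm, sum(t * M for t, M in zip(cand, mats)))
            if np.isfinite(ll_new) and ll_new >= ll_old - 1e-10:
                break
            step *= 0.5
        theta = np.maximum(theta + step * delta, floor)
        if abs(ll_new - ll_old) < tol and it > 1:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    theta = np.where(theta <= floor * 1.01, 0.0, theta)
    return theta, converged, it
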