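"""Dense REML estimation for the trial's mixed models.

Every model in the statistical layer is of the form

    y = X beta + Z u + e,    u ~ N(0, sigma2_u I),
    e ~ N(0, diag(sigma2_e[stratum_i]))

i.e. one optional random intercept term (genotype-by-replicate "slide"
effects, or genotype effects for heritability) plus residual variances that
may differ between strata (the two nitrogen levels).  With at most a few
hundred observations per trait the covariance matrix is built densely and
the restricted likelihood is maximised over log-variances with its analytic
gradient; non-negativity is automatic on the log scale and variances that
converge to the lower bound are reported as exact zeros.

Special cases with closed forms (single stratum, no random term) bypass the
optimiser so that ordinary-ANOVA equivalences hold to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .errors import ConvergenceError, SingularFitError

#: Relative size (vs var(y)) below which a converged variance is reported as 0.
ZERO_CLAMP_REL = 1e-7


@dataclass
class REMLResult:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_u: Optional[float]  # None if the model has no random term
    sigma2_e: Dict[str, float]  # residual variance per stratum
    loglik: float  # restricted log-likelihood (up to constant)
    converged: bool
    n_iter: int
    blup_u: Optional[np.ndarray] = None
    fitted: Optional[np.ndarray] = None
    n_obs: int = 0
    rank_x: int = 0


def _neg2reml_and_grad(theta, y, X, Z, stratum_masks):
    """-2 * restricted log-likelihood and gradient wrt log-variances.

    theta = [log sigma2_u]? + [log sigma2_e per stratum].
    """
    n, p = X.shape
    has_u = Z is not None
    k = len(stratum_masks)
    sig = np.exp(theta)
    if has_u:
        s_u, s_e = sig[0], sig[1:]
    else:
        s_u, s_e = None, sig

    d = np.zeros(n)
    for m, s in zip(stratum_masks, s_e):
        d[m] = s
    V = np.diag(d)
    if has_u:
        V += s_u * (Z @ Z.T)

    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        # V numerically singular at an extreme trial point: reject the step
        return 1e30, np.zeros_like(theta)
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = cho_solve((c, low), np.eye(n))
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    try:
        cx = np.linalg.cholesky(XtVinvX)
    except np.linalg.LinAlgError:
        return 1e30, np.zeros_like(theta)
    logdetXVX = 2.0 * np.sum(np.log(np.diag(cx)))
    XtVinvy = VinvX.T @ y
    beta = cho_solve((cx, True), XtVinvy)
    resid = y - X @ beta
    Py = Vinv @ resid
    yPy = float(resid @ Py)

    neg2 = logdetV + logdetXVX + yPy

    # P = Vinv - VinvX (XtVinvX)^-1 VinvX'
    W = cho_solve((cx, True), VinvX.T)  # (p, n)
    P = Vinv - VinvX @ W

    grad = np.zeros_like(theta)
    idx = 0
    if has_u:
        PZ = P @ Z
        tr = float(np.sum(PZ * Z))
        quad = float(np.sum((Z.T @ Py) ** 2))
        grad[0] = s_u * (tr - quad)
        idx = 1
    diagP = np.diag(P)
    for j, m in enumerate(stratum_masks):
        tr = float(diagP[m].sum())
        quad = float(np.sum(Py[m] ** 2))
        grad[idx + j] = s_e[j] * (tr - quad)
    return neg2, grad


def _newton_polish(theta, lb, ub, y, X, Zm, stratum_masks, max_iter=30):
    """Refine an approximate optimum to tight KKT conditions.

    Coordinates resting on the lower bound with an outward-pointing
    gradient are treated as boundary solutions (variance -> 0); the free
    coordinates are driven to a small gradient by damped Newton steps with
    a finite-difference Hessian of the analytic gradient.  Returns the
    polished parameters and a convergence flag.
    """
    theta = np.array(theta, dtype=float)
    gtol = 1e-9
    for _ in range(max_iter):
        f, g = _neg2reml_and_grad(theta, y, X, Zm, stratum_masks)
        at_lb = theta <= lb + 1e-8
        free = ~(at_lb & (g > 0))
        if not free.any() or np.max(np.abs(g[free])) < gtol:
            return theta, True
        # finite-difference Hessian on the free block
        idx = np.flatnonzero(free)
        h = 1e-5
        H = np.zeros((idx.size, idx.size))
        for a, i in enumerate(idx):
            tp = theta.copy(); tp[i] += h
            tm = theta.copy(); tm[i] -= h
            _, gp = _neg2reml_and_grad(tp, y, X, Zm, stratum_masks)
            _, gm = _neg2reml_and_grad(tm, y, X, Zm, stratum_masks)
            H[a] = (gp[idx] - gm[idx]) / (2 * h)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(idx.size), g[idx])
        except np.linalg.LinAlgError:
            step = g[idx]
        # damped line search on the Newton direction
        scale = 1.0
        for _ in range(25):
            trial = theta.copy()
            trial[idx] = np.clip(theta[idx] - scale * step, lb, ub)
            f_new, _ = _neg2reml_and_grad(trial, y, X, Zm, stratum_masks)
            if f_new <= f + 1e-12:
                break
            scale /= 2.0
        else:
            # no descent possible: accept if the gradient is merely loose
            return theta, bool(np.max(np.abs(g[free])) < 1e-4)
        if np.allclose(trial, theta):
            return theta, True
        theta = trial
    f, g = _neg2reml_and_grad(theta, y, X, Zm, stratum_masks)
    at_lb = theta <= lb + 1e-8
    free = ~(at_lb & (g > 0))
    return theta, bool(not free.any() or np.max(np.abs(g[free])) < 1e-4)


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    Z: Optional[np.ndarray] = None,
    strata: Optional[Sequence] = None,
    max_iter: int = 500,
) -> REMLResult:
    """REML fit of the one-random-term, stratified-residual model.

    Parameters
    ----------
    y, X
        Response and full-column-rank fixed-effect design.
    Z
        Random-effect indicator matrix (n x q) or None.
    strata
        Length-n labels assigning each observation to a residual stratum;
        None means a single homogeneous residual variance.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise SingularFitError("no residual degrees of freedom")
    if np.linalg.matrix_rank(X) < p:
        raise SingularFitError("fixed-effect design is rank deficient")

    if strata is None:
        labels = ["all"]
        stratum_masks = [np.ones(n, dtype=bool)]
    else:
        strata = np.asarray(strata)
        labels = sorted(map(str, np.unique(strata)))
        stratum_masks = [np.asarray(strata).astype(str) == lab for lab in labels]

    var_y = float(np.var(y)) or 1.0

    # closed form: single stratum, no random term -> OLS/REML identity
    if Z is None and len(labels) == 1:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        s2 = float(resid @ resid) / (n - p)
        XtX_inv = np.linalg.inv(X.T @ X)
        if s2 <= 0:
            s2_rep = 0.0
            cov = XtX_inv * 0.0
        else:
            s2_rep = s2
            cov = XtX_inv * s2
        ll = -0.5 * ((n - p) * np.log(max(s2, 1e-300)) + n * np.log(1.0)
                     + np.linalg.slogdet(X.T @ X)[1] + (n - p))
        return REMLResult(
            beta=coef, cov_beta=cov, sigma2_u=None,
            sigma2_e={labels[0]: s2_rep}, loglik=float(ll),
            converged=True, n_iter=0, fitted=X @ coef, n_obs=n, rank_x=p,
        )

    Zm = None if Z is None else np.asarray(Z, dtype=float)
    k = len(labels)
    n_par = (1 if Zm is not None else 0) + k
    x0 = np.log(np.full(n_par, max(var_y, 1e-12)))
    if Zm is not None:
        x0[0] = np.log(max(var_y / 2, 1e-12))
    lb = np.log(var_y * 1e-10)
    ub = np.log(var_y * 1e8)

    res = optimize.minimize(
        _neg2reml_and_grad,
        x0,
        args=(y, X, Zm, stratum_masks),
        jac=True,
        method="L-BFGS-B",
        bounds=[(lb, ub)] * n_par,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    theta, converged = _newton_polish(
        res.x, lb, ub, y, X, Zm, stratum_masks
    )
    if not converged:
        raise ConvergenceError(
            f"REML did not converge (optimizer message: {res.message})"
        )

    sig = np.exp(theta)
    if Zm is not None:
        s_u, s_e = float(sig[0]), sig[1:]
    else:
        s_u, s_e = None, sig

    # final GLS pass at the converged components
    d = np.zeros(n)
    for m, s in zip(stratum_masks, s_e):
        d[m] = s
    V = np.diag(d)
    if Zm is not None:
        V += s_u * (Zm @ Zm.T)
    c, low = cho_factor(V, lower=True)
    Vinv = cho_solve((c, low), np.eye(n))
    XtVinvX = X.T @ Vinv @ X
    cov_beta = np.linalg.inv(XtVinvX)
    beta = cov_beta @ (X.T @ Vinv @ y)
    resid = y - X @ beta
    blup = None
    if Zm is not None:
        blup = s_u * (Zm.T @ (Vinv @ resid))

    clamp = var_y * ZERO_CLAMP_REL
    sigma2_e = {lab: (0.0 if s < clamp else float(s)) for lab, s in zip(labels, s_e)}
    sigma2_u = None if s_u is None else (0.0 if s_u < clamp else float(s_u))

    return REMLResult(
        beta=beta,
        cov_beta=cov_beta,
        sigma2_u=sigma2_u,
        sigma2_e=sigma2_e,
        loglik=-0.5 * float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        blup_u=blup,
        fitted=X @ beta,
        n_obs=n,
        rank_x=p,
    )


def wald_f(result: REMLResult, idx: Sequence[int]) -> tuple[float, int]:
    """Wald F statistic for the joint nullity of coefficients *idx*.

    Returns ``(F, numerator_df)``; the denominator df is model-dependent
    (containment) and supplied by the caller.
    """
    idx = list(idx)
    b = result.beta[idx]
    C = result.cov_beta[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(C, b)) / len(idx)
    return stat, len(idx)
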