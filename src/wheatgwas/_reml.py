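"""EM-REML for Gaussian mixed models with independent random factors.

Model: y = X b + sum_k Z_k u_k + e, with u_k ~ N(0, sigma2_k I) and
e ~ N(0, sigma2_e I).  Estimation is expectation-maximization on the
restricted likelihood through Henderson's mixed-model equations; the EM
property guarantees a non-decreasing REML log-likelihood, which is recorded
per iteration.

This is deliberately a dense, dependency-light implementation: the models in
this package have at most a few hundred random-effect levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = ["RemlResult", "em_reml"]


@dataclass
class RemlResult:
    sigma2: dict[str, float]          # per random factor
    sigma2_residual: float
    beta: np.ndarray                  # fixed effects (full-rank design)
    blups: dict[str, np.ndarray]      # per factor, aligned with its levels
    loglik: float                     # final REML log-likelihood (up to a constant)
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    gradient_norm: float = float("nan")  # final relative loglik change


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Keep a maximal independent column subset of X (pivoted QR)."""
    if X.shape[1] == 0:
        return X
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    keep = sorted(piv[: int((diag > tol).sum())])
    return X[:, keep]


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    Z: dict[str, np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 500,
    start: dict[str, float] | None = None,
) -> RemlResult:
    """Fit the mixed model by EM-REML.

    Parameters
    ----------
    y : response vector, length n.
    X : fixed-effect design (an intercept column must be included by the
        caller); collinear columns are dropped internally.
    Z : mapping factor name -> (n, q_k) incidence matrix.
    tol : convergence threshold on the relative REML log-likelihood change.
    max_iter : iteration cap; non-convergence is reported, not raised.
    start : optional starting variances per factor (and "residual").
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    X = _drop_collinear(np.asarray(X, dtype=float))
    p = X.shape[1]
    if p >= n:
        raise ValueError(f"fixed-effect design leaves no residual dof (p={p}, n={n})")
    names = list(Z)
    Zmats = [np.asarray(Z[k], dtype=float) for k in names]
    q = [m.shape[1] for m in Zmats]
    Zall = np.hstack(Zmats) if Zmats else np.empty((n, 0))
    qtot = Zall.shape[1]
    vy = float(np.var(y)) if np.var(y) > 0 else 1.0
    floor = 1e-8 * vy

    # sufficient statistics
    XtX = X.T @ X
    XtZ = X.T @ Zall
    ZtZ = Zall.T @ Zall
    Xty = X.T @ y
    Zty = Zall.T @ y
    yty = float(y @ y)

    k = len(names)
    if start is None:
        s2 = {nm: vy / (k + 1) for nm in names}
        s2e = vy / (k + 1)
    else:
        s2 = {nm: max(float(start.get(nm, vy / (k + 1))), floor) for nm in names}
        s2e = max(float(start.get("residual", vy / (k + 1))), floor)

    # slices of the u-block per factor
    sl, off = {}, 0
    for nm, qk in zip(names, q):
        sl[nm] = slice(off, off + qk)
        off += qk

    def _loglik(s2, s2e, beta, u) -> float:
        # REML ll (up to constant) via |V| = |R||G||G^-1 + Z'R^-1 Z| and
        # X'V^-1X from the Woodbury identity.
        ginv_diag = np.concatenate(
            [np.full(q[i], 1.0 / s2[names[i]]) for i in range(k)]
        ) if k else np.empty(0)
        W = ZtZ / s2e + np.diag(ginv_diag)
        cw, low = linalg.cho_factor(W, lower=True)
        logdet_W = 2.0 * np.sum(np.log(np.diag(cw)))
        logdet_V = n * np.log(s2e) + sum(
            q[i] * np.log(s2[names[i]]) for i in range(k)
        ) + logdet_W
        WiZtX = linalg.cho_solve((cw, low), XtZ.T / s2e)
        XtViX = (XtX - XtZ @ WiZtX) / s2e
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        resid = yty - beta @ Xty - u @ Zty  # y'(y - Xb - Zu)
        yPy = resid / s2e
        return -0.5 * (logdet_V + logdet_XtViX + yPy)

    trace: list[float] = []
    beta = np.zeros(p)
    u = np.zeros(qtot)
    converged = False
    rel = float("nan")
    it = 0
    for it in range(1, max_iter + 1):
        ginv_diag = np.concatenate(
            [np.full(q[i], s2e / s2[names[i]]) for i in range(k)]
        ) if k else np.empty(0)
        # Henderson MME: [[X'X, X'Z],[Z'X, Z'Z + s2e*G^-1]] [b;u] = [X'y;Z'y]
        M = np.block([[XtX, XtZ], [XtZ.T, ZtZ + np.diag(ginv_diag)]])
        rhs = np.concatenate([Xty, Zty])
        C = linalg.inv(M, check_finite=False)
        sol = C @ rhs
        beta, u = sol[:p], sol[p:]

        trace.append(_loglik(s2, s2e, beta, u))
        if len(trace) > 1:
            denom = abs(trace[-2]) + 1e-12
            rel = (trace[-1] - trace[-2]) / denom
            if abs(rel) < tol:
                converged = True

        # EM updates
        Cuu = C[p:, p:]
        resid = yty - beta @ Xty - u @ Zty
        s2e_new = max(resid / (n - p), floor)
        for i, nm in enumerate(names):
            s = sl[nm]
            tr_C = np.trace(Cuu[s, s])
            s2[nm] = max((u[s] @ u[s] + s2e * tr_C) / q[i], floor)
        s2e = s2e_new
        if converged:
            break

    blups = {nm: u[sl[nm]] for nm in names}
    sigma2 = {nm: (0.0 if s2[nm] <= 2 * floor else float(s2[nm])) for nm in names}
    return RemlResult(
        sigma2=sigma2,
        sigma2_residual=float(s2e),
        beta=beta,
        blups=blups,
        loglik=trace[-1] if trace else float("nan"),
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
        gradient_norm=abs(rel),
    )
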