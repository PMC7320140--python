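"""Numba kernels for the elastic-net coordinate descent and its LOSO evaluation.

All kernels operate on standardized design matrices (columns centered, unit
population scale) and mean-centered responses. The objective being minimized is

    (1/2N) * sum_i (y_i - x_i' beta)^2 + lam * sum_j [ (1-alpha)/2 beta_j^2 + alpha |beta_j| ]

The intercept is handled outside the kernels (it is the response mean in the
centered parameterization and is never penalized).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def enet_cd(X, y, lam, alpha, beta, tol, max_iter):
    """Cyclic coordinate descent with an active-set strategy.

    Updates ``beta`` in place. Returns ``(n_sweeps, converged)`` where a sweep
    is one pass over either the full coordinate set or the current active set.
    Each coordinate update is the exact single-coordinate minimizer
    (soft-thresholding of the partial residual correlation, shrunk by the
    ridge part of the penalty).
    """
    n, p = X.shape
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)

    colsq = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        colsq[j] = s / n

    # residual for current beta
    r = y.copy()
    for j in range(p):
        bj = beta[j]
        if bj != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * bj

    active = np.empty(p, dtype=np.int64)
    n_sweeps = 0
    converged = False
    full_pass = True
    while n_sweeps < max_iter:
        n_sweeps += 1
        max_delta = 0.0
        if full_pass:
            n_active = 0
            for j in range(p):
                if colsq[j] == 0.0:
                    beta[j] = 0.0
                    continue
                bj = beta[j]
                rho = 0.0
                for i in range(n):
                    rho += X[i, j] * r[i]
                rho = rho / n + colsq[j] * bj
                if rho > l1:
                    bnew = (rho - l1) / (colsq[j] + l2)
                elif rho < -l1:
                    bnew = (rho + l1) / (colsq[j] + l2)
                else:
                    bnew = 0.0
                d = bnew - bj
                if d != 0.0:
                    for i in range(n):
                        r[i] -= X[i, j] * d
                    beta[j] = bnew
                    ad = abs(d)
                    if ad > max_delta:
                        max_delta = ad
                if beta[j] != 0.0:
                    active[n_active] = j
                    n_active += 1
            if max_delta < tol:
                converged = True
                break
            full_pass = False
        else:
            for k in range(n_active):
                j = active[k]
                bj = beta[j]
                rho = 0.0
                for i in range(n):
                    rho += X[i, j] * r[i]
                rho = rho / n + colsq[j] * bj
                if rho > l1:
                    bnew = (rho - l1) / (colsq[j] + l2)
                elif rho < -l1:
                    bnew = (rho + l1) / (colsq[j] + l2)
                else:
                    bnew = 0.0
                d = bnew - bj
                if d != 0.0:
                    for i in range(n):
                        r[i] -= X[i, j] * d
                    beta[j] = bnew
                    ad = abs(d)
                    if ad > max_delta:
                        max_delta = ad
            if max_delta < tol:
                # active set stable: confirm with a full KKT pass
                full_pass = True
    return n_sweeps, converged


@njit(cache=True)
def enet_path(X, y, lambdas_desc, alpha, tol, max_iter):
    """Warm-started path over a descending lambda sequence.

    Returns ``(betas, n_sweeps, converged)`` with one row of ``betas`` per
    lambda, in the order given (largest first).
    """
    n, p = X.shape
    nl = lambdas_desc.shape[0]
    betas = np.zeros((nl, p))
    sweeps = np.zeros(nl, dtype=np.int64)
    conv = np.zeros(nl, dtype=np.bool_)
    beta = np.zeros(p)
    for k in range(nl):
        ns, ok = enet_cd(X, y, lambdas_desc[k], alpha, beta, tol, max_iter)
        sweeps[k] = ns
        conv[k] = ok
        for j in range(p):
            betas[k, j] = beta[j]
    return betas, sweeps, conv


@njit(cache=True)
def loso_path_predictions(X, y, lambdas_desc, alpha, tol, max_iter):
    """Leave-one-subject-out held-out predictions along the lambda path.

    For each held-out row i the remaining rows are standardized (population
    convention), the response is centered, a warm-started path is fit, and the
    held-out row is predicted at every lambda. Also returns the intercept-only
    prediction per fold (the training-fold response mean).

    Returns ``(preds, preds0, all_conv)`` with ``preds`` of shape (N, L).
    """
    n, p = X.shape
    nl = lambdas_desc.shape[0]
    preds = np.empty((n, nl))
    preds0 = np.empty(n)
    all_conv = True
    Xt = np.empty((n - 1, p))
    yt = np.empty(n - 1)
    mu = np.empty(p)
    sd = np.empty(p)
    xi = np.empty(p)
    for i in range(n):
        k = 0
        for r in range(n):
            if r == i:
                continue
            for j in range(p):
                Xt[k, j] = X[r, j]
            yt[k] = y[r]
            k += 1
        m = n - 1
        ybar = 0.0
        for r in range(m):
            ybar += yt[r]
        ybar /= m
        for j in range(p):
            s = 0.0
            for r in range(m):
                s += Xt[r, j]
            mu[j] = s / m
        for j in range(p):
            s = 0.0
            for r in range(m):
                d = Xt[r, j] - mu[j]
                s += d * d
            v = np.sqrt(s / m)
            sd[j] = v if v > 0.0 else 1.0
        for j in range(p):
            for r in range(m):
                Xt[r, j] = (Xt[r, j] - mu[j]) / sd[j]
        yc = np.empty(m)
        for r in range(m):
            yc[r] = yt[r] - ybar
        betas, _, conv = enet_path(Xt, yc, lambdas_desc, alpha, tol, max_iter)
        for l in range(nl):
            if not conv[l]:
                all_conv = False
        for j in range(p):
            xi[j] = (X[i, j] - mu[j]) / sd[j]
        for l in range(nl):
            acc = ybar
            for j in range(p):
                acc += xi[j] * betas[l, j]
            preds[i, l] = acc
        preds0[i] = ybar
    return preds, preds0, all_conv
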