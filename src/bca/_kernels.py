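"""Numba-compiled inner loops.

Two hot paths live here: the single-site Metropolis-Hastings sweep for
Ising sampling, and a coordinate-descent solver for the L1-penalized
logistic regression path used by the regression baseline.  Everything
else in the package is vectorized numpy and does not need compilation.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def mh_sample_ising(W, r, beta, n_samples, burn_in_sweeps, thin_sweeps, seed):
    """Metropolis-Hastings sampling of an Ising model with fields.

    One sweep proposes M single-site flips (site chosen uniformly at
    random each proposal).  A flip of site i changes the energy by
    ``dU = -(r_i + sum_j W_ij x_j) * (x_i' - x_i)`` and is accepted with
    probability ``min(1, exp(-beta * dU))``.  After ``burn_in_sweeps``
    sweeps, one configuration is recorded every ``thin_sweeps`` sweeps.
    """
    np.random.seed(seed)
    M = r.shape[0]
    x = (np.random.rand(M) < 0.5).astype(np.float64)
    out = np.empty((n_samples, M), dtype=np.float64)
    total_sweeps = burn_in_sweeps + n_samples * thin_sweeps
    kept = 0
    for sweep in range(total_sweeps):
        for _ in range(M):
            i = np.random.randint(0, M)
            local = r[i]
            for j in range(M):
                local += W[i, j] * x[j]
            delta_x = 1.0 - 2.0 * x[i]
            dU = -local * delta_x
            if dU <= 0.0 or np.random.rand() < np.exp(-beta * dU):
                x[i] += delta_x
        if sweep >= burn_in_sweeps and (sweep - burn_in_sweeps + 1) % thin_sweeps == 0:
            if kept < n_samples:
                out[kept] = x
                kept += 1
    return out


@njit(cache=True)
def _cd_sweep(X, w, rr, beta, pf, lam, b0_box, n, p, active, full):
    """One coordinate-descent sweep on the weighted quadratic surrogate.

    Updates ``beta``, ``rr`` and the boxed intercept in place.  With
    ``full`` false only currently-active coordinates are visited.
    Returns the largest standardized-scale coefficient change.
    """
    max_delta = 0.0
    num = 0.0
    den = 0.0
    for i in range(n):
        num += w[i] * rr[i]
        den += w[i]
    d0 = num / den
    if d0 != 0.0:
        b0_box[0] += d0
        for i in range(n):
            rr[i] -= d0
        if np.abs(d0) > max_delta:
            max_delta = np.abs(d0)
    for j in range(p):
        if not full and active[j] == 0:
            continue
        num = 0.0
        den = 0.0
        for i in range(n):
            xij = X[i, j]
            if xij != 0.0:
                num += w[i] * xij * (rr[i] + xij * beta[j])
                den += w[i] * xij * xij
        if den <= 0.0:
            continue
        num /= n
        den /= n
        lam_j = lam * pf[j]
        if num > lam_j:
            new = (num - lam_j) / den
        elif num < -lam_j:
            new = (num + lam_j) / den
        else:
            new = 0.0
        d = new - beta[j]
        if d != 0.0:
            beta[j] = new
            for i in range(n):
                if X[i, j] != 0.0:
                    rr[i] -= d * X[i, j]
            scaled = np.abs(d) * pf[j]
            if scaled > max_delta:
                max_delta = scaled
        active[j] = 1 if beta[j] != 0.0 else 0
    return max_delta


@njit(cache=True)
def logistic_lasso_path(X, y, lambdas, pf, tol, max_inner):
    """L1-penalized logistic regression along a descending lambda grid.

    IRLS with inner coordinate descent on the weighted quadratic
    approximation (glmnet-style), warm-started across the grid.
    Feature j is penalized by ``lambda * pf[j]``: passing the column
    standard deviations as ``pf`` reproduces the standardized lasso
    (centering is absorbed by the unpenalized intercept) while keeping
    a sparse 0/1 design fast.  Returns ``(coefs, intercepts, logliks)``
    with ``coefs`` of shape ``(n_lambdas, p)`` and the log-likelihood
    of each fitted model.
    """
    n, p = X.shape
    n_lam = lambdas.shape[0]
    coefs = np.zeros((n_lam, p))
    intercepts = np.zeros(n_lam)
    logliks = np.zeros(n_lam)

    beta = np.zeros(p)
    ybar = y.mean()
    if 0.0 < ybar < 1.0:
        b0 = np.log(ybar / (1.0 - ybar))
    else:
        b0 = 0.0
    # null log-likelihood, for early path termination at saturation
    if 0.0 < ybar < 1.0:
        ll_null = n * (ybar * np.log(ybar) + (1.0 - ybar) * np.log(1.0 - ybar))
    else:
        ll_null = 0.0
    eta = np.full(n, b0)
    w = np.empty(n)
    rr = np.empty(n)   # working residual of the quadratic approximation
    rr0 = np.empty(n)
    b0_box = np.empty(1)
    b0_box[0] = b0

    active = np.zeros(p, dtype=np.uint8)
    for li in range(n_lam):
        lam = lambdas[li]
        prev_ll = -np.inf
        for _outer in range(50):
            # quadratic approximation at the current eta; the same pass
            # accumulates the current log-likelihood for convergence
            ll_cur = 0.0
            for i in range(n):
                pr = 1.0 / (1.0 + np.exp(-eta[i]))
                wi = pr * (1.0 - pr)
                if wi < 1e-5:
                    wi = 1e-5
                w[i] = wi
                rr[i] = (y[i] - pr) / wi
                rr0[i] = rr[i]
                e = eta[i]
                if e > 30.0:
                    lse = e
                elif e < -30.0:
                    lse = 0.0
                else:
                    lse = np.log(1.0 + np.exp(e))
                ll_cur += y[i] * e - lse
            if _outer > 0 and np.abs(ll_cur - prev_ll) < 1e-7 * (1.0 + np.abs(ll_cur)):
                break
            prev_ll = ll_cur
            # inner CD on the penalized weighted least squares: alternate
            # one full sweep (KKT check over all coordinates) with sweeps
            # over the active set only
            for _cycle in range(max_inner):
                full_delta = _cd_sweep(X, w, rr, beta, pf, lam, b0_box,
                                       n, p, active, True)
                b0 = b0_box[0]
                if full_delta < tol:
                    break
                for _inner in range(max_inner):
                    act_delta = _cd_sweep(X, w, rr, beta, pf, lam, b0_box,
                                          n, p, active, False)
                    b0 = b0_box[0]
                    if act_delta < tol:
                        break
            # move eta to the new linear predictor: eta += (rr0 - rr)
            eta_change = 0.0
            for i in range(n):
                de = rr0[i] - rr[i]
                eta[i] += de
                if np.abs(de) > eta_change:
                    eta_change = np.abs(de)
            if eta_change < 1e-5:
                break
        coefs[li] = beta
        intercepts[li] = b0
        ll = 0.0
        for i in range(n):
            # numerically safe log(1 + exp(eta))
            e = eta[i]
            if e > 30.0:
                lse = e
            elif e < -30.0:
                lse = 0.0
            else:
                lse = np.log(1.0 + np.exp(e))
            ll += y[i] * e - lse
        logliks[li] = ll
        # stop the path once the fit is essentially saturated (glmnet rule);
        # later, denser fits cannot win a complexity-penalized selection
        if ll >= 0.001 * ll_null:
            for rest in range(li + 1, n_lam):
                logliks[rest] = np.nan
            break
    return coefs, intercepts, logliks
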