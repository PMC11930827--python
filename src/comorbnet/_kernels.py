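"""Numerical kernels: systematic-scan Gibbs sampling of a binary Markov random
field, and an l1-penalized logistic regression path solver (IRLS outer loop
with coordinate descent on the local quadratic model, warm-started across the
penalty path, glmnet-style).  Kept separate so the hot loops stay plain numpy
code that numba can compile.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_chain(w, b, n_samples, burn_in, thinning, seed):
    """Single-chain systematic-scan Gibbs sampler for a pairwise binary MRF.

    The joint is P(x) ∝ exp(Σ_{i<j} w_ij x_i x_j + Σ_i b_i x_i); each site is
    resampled in fixed node order from the conditional
    P(x_i = 1 | x_-i) = sigmoid(b_i + Σ_j w_ij x_j).  After ``burn_in`` full
    sweeps, one row is recorded every ``thinning`` sweeps.
    """
    p = w.shape[0]
    np.random.seed(seed)
    x = np.empty(p, dtype=np.int8)
    for i in range(p):
        x[i] = 1 if np.random.random() < 0.5 else 0
    out = np.empty((n_samples, p), dtype=np.int8)
    kept = 0
    sweep = 0
    while kept < n_samples:
        for i in range(p):
            eta = b[i]
            for j in range(p):
                eta += w[i, j] * x[j]
            prob = 1.0 / (1.0 + np.exp(-eta))
            x[i] = 1 if np.random.random() < prob else 0
        sweep += 1
        if sweep > burn_in and (sweep - burn_in) % thinning == 0:
            out[kept] = x
            kept += 1
    return out


@njit(cache=True, inline="always")
def _nll(eta, y, n):
    """Mean negative log-likelihood at linear predictor eta (stable)."""
    s = 0.0
    for r in range(n):
        e = eta[r]
        if e > 0.0:
            s += e + np.log1p(np.exp(-e)) - y[r] * e
        else:
            s += np.log1p(np.exp(e)) - y[r] * e
    return s / n


@njit(cache=True)
def logistic_lasso_path(Z, y, lambdas, pen, max_outer=25, max_inner=400,
                        tol=1e-9, devmax=0.999, outer_budget=500):
    """Warm-started l1 logistic path solver.

    Z : (n, q) float64 design, no intercept column; y : (n,) in {0, 1};
    lambdas : decreasing penalties on the mean log-likelihood scale;
    pen : (q,) per-slope penalty multipliers (intercept unpenalized).

    Per lambda value: iterate (a) a quadratic (IRLS) expansion at the current
    estimate with curvature weights pv(1-pv) floored at 1e-6, (b) coordinate
    descent on the expansion over the active set (non-zero slopes plus KKT
    violators), (c) a step-halving safeguard on the penalized objective.
    Two glmnet-style guards bound worst-case work on ill-conditioned
    (near-separable) columns: once the fraction of null deviance explained
    exceeds ``devmax`` the remaining penalties are carried forward unchanged,
    and once ``outer_budget`` IRLS expansions have been spent over the whole
    path each remaining penalty gets a single warm-started expansion.

    Returns (coefs[L, q], intercepts[L], loglik[L]) with loglik the total
    unpenalized log-likelihood at the returned solution.
    """
    n, q = Z.shape
    L = lambdas.shape[0]
    ZT = np.ascontiguousarray(Z.T)

    ybar = 0.0
    for r in range(n):
        ybar += y[r]
    ybar /= n
    b0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(q)
    eta = np.full(n, b0)

    coefs = np.zeros((L, q))
    intercepts = np.empty(L)
    loglik = np.empty(L)

    pv = np.empty(n)
    wv = np.empty(n)
    null_dev = 2.0 * _nll(eta, y, n) * n    # saturated ll is 0 for binary y
    frozen = False
    outer_spent = 0
    for li in range(L):
        if frozen:
            coefs[li] = beta
            intercepts[li] = b0
            loglik[li] = loglik[li - 1]
            continue
        lam = lambdas[li]
        obj = _nll(eta, y, n)
        for j in range(q):
            obj += lam * pen[j] * abs(beta[j])
        iters = max_outer if outer_spent < outer_budget else 1
        for _ in range(iters):
            outer_spent += 1
            for r in range(n):
                pv[r] = 1.0 / (1.0 + np.exp(-eta[r]))
                wr = pv[r] * (1.0 - pv[r])
                wv[r] = wr if wr > 1e-6 else 1e-6
            g = np.dot(ZT, pv - y) / n
            g0 = 0.0
            h00 = 0.0
            for r in range(n):
                g0 += pv[r] - y[r]
                h00 += wv[r]
            g0 /= n
            h00 /= n

            # active set: current support plus KKT violators
            act = np.empty(q, dtype=np.int64)
            n_act = 0
            for j in range(q):
                if beta[j] != 0.0 or abs(g[j]) > lam * pen[j] + 1e-12:
                    act[n_act] = j
                    n_act += 1
            if n_act == 0:
                d0 = -g0 / h00
                if abs(d0) < tol:
                    break
                b0 += d0
                for r in range(n):
                    eta[r] += d0
                obj = _nll(eta, y, n)
                continue
            A = act[:n_act]

            # quadratic model on (intercept, active slopes); Gram via BLAS
            ZA = np.empty((n, n_act))
            ZAw = np.empty((n, n_act))
            for a in range(n_act):
                j = A[a]
                for r in range(n):
                    zrj = Z[r, j]
                    ZA[r, a] = zrj
                    ZAw[r, a] = zrj * wv[r]
            m = n_act + 1
            H = np.empty((m, m))
            grad = np.empty(m)
            grad[0] = g0
            H[0, 0] = h00
            colsum = np.dot(np.ascontiguousarray(ZAw.T), np.ones(n)) / n
            for a in range(n_act):
                H[0, a + 1] = colsum[a]
                H[a + 1, 0] = colsum[a]
                grad[a + 1] = g[A[a]]
            Hs = np.dot(np.ascontiguousarray(ZAw.T), ZA) / n
            for a in range(n_act):
                for c in range(n_act):
                    H[a + 1, c + 1] = 0.5 * (Hs[a, c] + Hs[c, a])

            # CD on the quadratic model; v = proposed (b0, beta_A)
            v = np.empty(m)
            v[0] = b0
            for a in range(n_act):
                v[a + 1] = beta[A[a]]
            v0 = v.copy()
            hd = np.zeros(m)            # H @ (v - v0), kept incrementally
            for _ in range(max_inner):
                maxd = 0.0
                for c in range(m):
                    hc = H[c, c]
                    if hc < 1e-12:
                        hc = 1e-12
                    # model derivative in coordinate c, self-term removed
                    t = grad[c] + hd[c] - hc * (v[c] - v0[c])
                    u = hc * v0[c] - t
                    if c == 0:
                        newv = u / hc
                    else:
                        thr = lam * pen[A[c - 1]]
                        if u > thr:
                            newv = (u - thr) / hc
                        elif u < -thr:
                            newv = (u + thr) / hc
                        else:
                            newv = 0.0
                    d = newv - v[c]
                    if d != 0.0:
                        v[c] = newv
                        for cc in range(m):
                            hd[cc] += H[cc, c] * d
                        if abs(d) > maxd:
                            maxd = abs(d)
                if maxd < 0.1 * tol:
                    break

            base_change = 0.0
            for c in range(m):
                if abs(v[c] - v0[c]) > base_change:
                    base_change = abs(v[c] - v0[c])
            if base_change < tol:
                break

            # step-halving safeguard on the true penalized objective
            step = 1.0
            accepted = False
            new_eta = np.empty(n)
            for _ in range(25):
                nb0 = v0[0] + step * (v[0] - v0[0])
                for r in range(n):
                    new_eta[r] = eta[r] + nb0 - b0
                for a in range(n_act):
                    j = A[a]
                    nbj = v0[a + 1] + step * (v[a + 1] - v0[a + 1])
                    d = nbj - beta[j]
                    if d != 0.0:
                        for r in range(n):
                            new_eta[r] += d * Z[r, j]
                # inactive slopes are all zero: penalty runs over A only
                pobj = _nll(new_eta, y, n)
                for a in range(n_act):
                    j = A[a]
                    nbj = v0[a + 1] + step * (v[a + 1] - v0[a + 1])
                    pobj += lam * pen[j] * abs(nbj)
                if pobj <= obj + 1e-14:
                    b0 = v0[0] + step * (v[0] - v0[0])
                    for a in range(n_act):
                        j = A[a]
                        beta[j] = v0[a + 1] + step * (v[a + 1] - v0[a + 1])
                    for r in range(n):
                        eta[r] = new_eta[r]
                    obj = pobj
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            if base_change * step < tol:
                break
        coefs[li] = beta
        intercepts[li] = b0
        loglik[li] = -_nll(eta, y, n) * n
        if null_dev > 0.0 and 1.0 - (-2.0 * loglik[li]) / null_dev > devmax:
            frozen = True
    return coefs, intercepts, loglik
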