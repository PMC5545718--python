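"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately written with a different algorithm than the
package path it checks: explicit loops, direct likelihood formulas through
``slogdet``/``inv``, and log-gamma enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def naive_grm(dosages: np.ndarray) -> np.ndarray:
    """Explicit double-loop standardized relationship matrix."""
    n, m = dosages.shape
    p = np.array([np.nanmean(dosages[:, j]) / 2 for j in range(m)])
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            tot, cnt = 0.0, 0
            for j in range(m):
                xa, xb = dosages[a, j], dosages[b, j]
                if np.isnan(xa) or np.isnan(xb):
                    continue
                denom = 2 * p[j] * (1 - p[j])
                tot += (xa - 2 * p[j]) * (xb - 2 * p[j]) / denom
                cnt += 1
            out[a, b] = out[b, a] = tot / cnt
    return out


def hwe_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by direct log-gamma enumeration of all tables."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)

    def logprob(h):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (
            gammaln(n + 1)
            - gammaln(hom_r + 1)
            - gammaln(h + 1)
            - gammaln(hom_c + 1)
            + h * np.log(2.0)
            + gammaln(n_A + 1)
            + gammaln(n_a + 1)
            - gammaln(2 * n + 1)
        )

    hs = np.arange(rare % 2, rare + 1, 2)
    lp = np.array([logprob(int(h)) for h in hs])
    pr = np.exp(lp - lp.max())
    pr /= pr.sum()
    p_obs = pr[list(hs).index(n_Aa)]
    return float(min(pr[pr <= p_obs * (1 + 1e-12)].sum(), 1.0))


def reml_loglik_direct(A: np.ndarray, y: np.ndarray, sg2: float, se2: float) -> float:
    """Definitional restricted log-likelihood via slogdet/inv (intercept only)."""
    n = len(y)
    V = sg2 * A + se2 * np.eye(n)
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    X = np.ones((n, 1))
    B = X.T @ Vi @ X
    beta = np.linalg.solve(B, X.T @ Vi @ y)
    r = y - X @ beta
    return float(-0.5 * (logdetV + np.linalg.slogdet(B)[1] + r @ Vi @ r))


def univariate_grid_argmax(A, y, coarse_step=0.02, fine_step=1e-3, upper=None):
    """Two-stage grid search of the univariate restricted likelihood.

    The coarse grid covers (about 0, upper]^2 at ``coarse_step``; the fine
    grid refines a band of +-1.5 coarse steps around the coarse argmax at
    ``fine_step`` resolution, so the returned argmax is accurate to the fine
    resolution. Near-zero grid points are included for boundary optima.
    """
    if upper is None:
        upper = 3.0 * float(np.var(y, ddof=1))
    grid = np.r_[1e-8, np.arange(coarse_step, upper, coarse_step)]
    best, best_ll = None, -np.inf
    for sg in grid:
        for se in grid:
            ll = reml_loglik_direct(A, y, sg, se)
            if ll > best_ll:
                best, best_ll = (sg, se), ll
    c = best
    fg = np.r_[1e-8, np.arange(max(c[0] - 1.5 * coarse_step, fine_step), c[0] + 1.5 * coarse_step, fine_step)]
    fe = np.r_[1e-8, np.arange(max(c[1] - 1.5 * coarse_step, fine_step), c[1] + 1.5 * coarse_step, fine_step)]
    best, best_ll = None, -np.inf
    for sg in fg:
        for se in fe:
            ll = reml_loglik_direct(A, y, sg, se)
            if ll > best_ll:
                best, best_ll = (sg, se), ll
    return best, best_ll


def bivariate_loglik_direct(A11, A22, A12, y1, y2, g1, g12, g2, e1, e2) -> float:
    """Definitional stacked-model restricted log-likelihood."""
    n1, n2 = len(y1), len(y2)
    n = n1 + n2
    V = np.zeros((n, n))
    V[:n1, :n1] = g1 * A11 + e1 * np.eye(n1)
    V[n1:, n1:] = g2 * A22 + e2 * np.eye(n2)
    V[:n1, n1:] = g12 * A12
    V[n1:, :n1] = g12 * A12.T
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    X = np.zeros((n, 2))
    X[:n1, 0] = 1
    X[n1:, 1] = 1
    y = np.concatenate([y1, y2])
    B = X.T @ Vi @ X
    beta = np.linalg.solve(B, X.T @ Vi @ y)
    r = y - X @ beta
    return float(-0.5 * (logdetV + np.linalg.slogdet(B)[1] + r @ Vi @ r))


def bivariate_grid_argmax(A11, A22, A12, y1, y2, grid_step=5e-3, half_width=0.025, n_starts=4, seed=0):
    """3-parameter grid over the genetic (co)variances, residuals profiled.

    Stage 1 locates the restricted-likelihood optimum with multi-start
    Nelder-Mead over all five parameters of the definitional likelihood
    (variances on log scale, the covariance through a bounded tanh map so
    ``|g12| <= sqrt(g1 g2)`` always holds). Stage 2 lays a 3-parameter grid
    of resolution ``grid_step`` over ``+-half_width`` around that optimum,
    maximising the two residual variances numerically at each grid point.
    Returns ((g1, g12, g2), loglik) of the grid argmax.
    """
    from scipy.optimize import minimize

    v1 = float(np.var(y1, ddof=1))
    v2 = float(np.var(y2, ddof=1))
    rng = np.random.default_rng(seed)

    def unpack(t):
        g1, g2, e1, e2 = np.exp(t[:4])
        g12 = np.tanh(t[4]) * np.sqrt(g1 * g2)
        return g1, g12, g2, e1, e2

    def neg(t):
        g1, g12, g2, e1, e2 = unpack(t)
        return -bivariate_loglik_direct(A11, A22, A12, y1, y2, g1, g12, g2, e1, e2)

    best_t, best_val = None, np.inf
    for s in range(n_starts):
        t0 = np.array(
            [
                np.log(v1 * rng.uniform(0.2, 0.8)),
                np.log(v2 * rng.uniform(0.2, 0.8)),
                np.log(v1 * rng.uniform(0.2, 0.8)),
                np.log(v2 * rng.uniform(0.2, 0.8)),
                rng.uniform(-0.5, 1.5),
            ]
        )
        res = minimize(neg, t0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
        if res.fun < best_val:
            best_t, best_val = res.x, res.fun
    c1, c12, c2, ce1, ce2 = unpack(best_t)

    def profiled(g1, g12, g2, start):
        if g1 <= 0 or g2 <= 0 or abs(g12) > np.sqrt(g1 * g2):
            return -np.inf, start

        def neg_e(lr):
            e1, e2 = np.exp(lr)
            return -bivariate_loglik_direct(A11, A22, A12, y1, y2, g1, g12, g2, e1, e2)

        res = minimize(neg_e, np.log(start), method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 120})
        return -res.fun, np.exp(res.x)

    axis = np.arange(-half_width, half_width + grid_step / 2, grid_step)
    center = (c1, c12, c2)
    warm = (ce1, ce2)
    best, best_ll = None, -np.inf
    for _ in range(6):  # re-center while the argmax sits on the box edge
        best, best_ll = None, -np.inf
        at_edge = False
        for d1 in axis:
            for d2 in axis:
                for d12 in axis:
                    g1, g2, g12 = center[0] + d1, center[2] + d2, center[1] + d12
                    ll, warm = profiled(g1, g12, g2, warm)
                    if ll > best_ll:
                        best, best_ll = (g1, g12, g2), ll
                        at_edge = max(abs(d1), abs(d2), abs(d12)) >= half_width - grid_step / 2
        if not at_edge:
            break
        center = (best[0], best[1], best[2])
    return best, best_ll
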