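"""Variance-component estimation by restricted maximum likelihood (REML).

Univariate model: ``y = Xb + g + e`` with ``V = sg2*A + se2*I`` for a
genetic relationship matrix ``A``. The univariate fit rotates into the
eigenbasis of ``A`` (V becomes diagonal), making each iteration O(n p^2).

Bivariate model: two traits measured on *disjoint* individual sets, stacked
with ``V = [[sg1^2 A11 + se1^2 I, sg12 A12], [sg21 A21, sg2^2 A22 + se2^2 I]]``
and residual covariance fixed at zero (no shared individuals). The genetic
correlation is ``rg = sg12 / sqrt(sg1^2 sg2^2)``.

Both fits take one EM step then average-information (AI) updates with
step-halving, constrain variances non-negative by projection and
``|rg| <= 1`` by bounding the covariance, and report sampling covariances
from the inverse AI matrix at the optimum.
"""

from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .types import (
    GRM,
    BivariateComponents,
    GeneticCorrelationEstimate,
    HeritabilityEstimate,
    VarianceComponents,
)

__all__ = [
    "fit_greml_univariate",
    "fit_greml_bivariate",
    "liability_transform",
    "estimate_liability_h2",
    "compare_h2",
]

_FLOOR_FRAC = 1e-8  # variance floor as a fraction of phenotypic variance
_MAX_HALVINGS = 30


def _as_matrix(grm: Union[GRM, np.ndarray]) -> np.ndarray:
    return grm.values if isinstance(grm, GRM) else np.asarray(grm, dtype=float)


def _active_set_newton(theta, grad, AI, floors) -> np.ndarray:
    """AI-Newton step restricted to parameters not pinned at their floor.

    A parameter sitting at its floor with a gradient pushing it further
    down is held fixed; solving for the remaining parameters alone keeps
    the step well-conditioned at boundary optima.
    """
    floors = np.broadcast_to(np.asarray(floors, dtype=float), theta.shape)
    pinned = (theta <= floors * (1 + 1e-6) + 1e-300) & (grad < 0)
    delta = np.zeros_like(theta)
    free = np.flatnonzero(~pinned)
    if len(free) == 0:
        return delta
    sub = AI[np.ix_(free, free)]
    try:
        delta[free] = np.linalg.solve(sub, grad[free])
    except np.linalg.LinAlgError:
        delta[free] = np.linalg.pinv(sub) @ grad[free]
    return delta


def _design(n: int, covariates: Optional[np.ndarray]) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([X, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular covariate design")
    return X


def fit_greml_univariate(
    grm: Union[GRM, np.ndarray],
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    constrain: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
    eig: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> VarianceComponents:
    """AI-REML fit of ``(sg2, se2)`` for one phenotype.

    ``phenotype`` must be aligned with the GRM rows (case-control studies
    pass the 0/1 status vector directly; the observed-scale estimate is
    transformed afterwards with :func:`liability_transform`). ``eig`` may
    carry a precomputed ``numpy.linalg.eigh`` decomposition of the GRM to
    amortise it across repeated fits on the same relationship matrix.
    """
    A = _as_matrix(grm)
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if A.shape != (n, n):
        raise ValueError("GRM and phenotype are not aligned")
    X = _design(n, covariates)

    d, U = np.linalg.eigh(A) if eig is None else eig
    yt = U.T @ y
    Xt = U.T @ X

    vp = float(np.var(y, ddof=1))
    floor = _FLOOR_FRAC * vp if constrain else -np.inf
    theta = np.array([vp / 2.0, vp / 2.0])

    def quantities(th):
        sg2, se2 = th
        v = sg2 * d + se2
        if np.any(v <= 0):
            return None
        vinv = 1.0 / v
        XtV = Xt * vinv[:, None]
        B = Xt.T @ XtV
        try:
            cB = linalg.cho_factor(B)
        except linalg.LinAlgError:
            return None
        beta = linalg.cho_solve(cB, XtV.T @ yt)
        Py = vinv * (yt - Xt @ beta)
        yPy = float(yt @ Py)
        _, logdetB = np.linalg.slogdet(B)
        ll = -0.5 * (np.sum(np.log(v)) + logdetB + yPy)

        def trP(w):  # tr(P diag(w))
            t1 = float(np.sum(w * vinv))
            T = Xt.T @ (Xt * (w * vinv**2)[:, None])
            return t1 - float(np.trace(linalg.cho_solve(cB, T)))

        trPA, trPI = trP(d), trP(np.ones(n))
        yPAPy = float(np.sum(d * Py**2))
        yPIPy = float(np.sum(Py**2))
        grad = -0.5 * np.array([trPA - yPAPy, trPI - yPIPy])

        def Pw(w):
            return vinv * w - XtV @ linalg.cho_solve(cB, XtV.T @ w)

        W = np.column_stack([d * Py, Py])
        PW = np.column_stack([Pw(W[:, 0]), Pw(W[:, 1])])
        AI = 0.5 * (W.T @ PW)
        return ll, grad, AI, (yPAPy, yPIPy, trPA, trPI)

    q = quantities(theta)
    if q is None:
        raise ValueError("invalid starting point for REML")
    ll = q[0]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, grad, AI, (yPAPy, yPIPy, trPA, trPI) = q
        if it == 1:  # one EM step for stability
            delta = np.array(
                [
                    theta[0] ** 2 * (yPAPy - trPA) / n,
                    theta[1] ** 2 * (yPIPy - trPI) / n,
                ]
            )
        else:
            delta = _active_set_newton(theta, grad, AI, floor)
        step = 1.0
        for _ in range(_MAX_HALVINGS):
            prop = np.maximum(theta + step * delta, floor)
            qp = quantities(prop)
            if qp is not None and qp[0] >= ll - 1e-10:
                break
            step /= 2.0
        else:
            # AI direction cannot improve: fall back to a guaranteed-ascent EM step
            em = np.array(
                [
                    theta[0] ** 2 * (yPAPy - trPA) / n,
                    theta[1] ** 2 * (yPIPy - trPI) / n,
                ]
            )
            prop = np.maximum(theta + em, floor)
            qp = quantities(prop)
            if qp is None or qp[0] <= ll + tol:
                converged = True  # numerical optimum (possibly on the boundary)
                break
        theta, q = prop, qp
        if abs(qp[0] - ll) < tol:
            ll = qp[0]
            converged = True
            break
        ll = qp[0]
    AI = q[2]
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(AI)
    return VarianceComponents(
        sigma_g2=float(theta[0]),
        sigma_e2=float(theta[1]),
        sampling_covariance=cov,
        log_likelihood=float(ll),
        n_iterations=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# bivariate fit on disjoint individual sets

def fit_greml_bivariate(
    grm: GRM,
    pheno_1: pd.Series,
    pheno_2: pd.Series,
    constrain: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
    polish_max_n: int = 500,
) -> Tuple[BivariateComponents, GeneticCorrelationEstimate]:
    """Bivariate AI-REML genetic correlation between two disjoint cohorts.

    ``pheno_1`` and ``pheno_2`` are pandas Series indexed by sample id; the
    two index sets must not overlap and must all be present in the GRM.

    Projected AI updates can stall on the constraint boundary (a variance
    at its floor or ``|rg| = 1``) for small, noisy problems; when the
    stacked size is at most ``polish_max_n`` the fit is therefore refined
    with a derivative-free simplex pass on a bounded reparametrisation of
    the restricted likelihood and the better optimum is kept.
    """
    ids1, ids2 = list(pheno_1.index), list(pheno_2.index)
    if set(ids1) & set(ids2):
        raise ValueError("traits share individuals; residual covariance is not identifiable")
    n1, n2 = len(ids1), len(ids2)
    n = n1 + n2
    Afull = grm.submatrix(ids1 + ids2)
    A11, A22 = Afull[:n1, :n1], Afull[n1:, n1:]
    A12 = Afull[:n1, n1:]
    y = np.concatenate([pheno_1.to_numpy(dtype=float), pheno_2.to_numpy(dtype=float)])
    X = np.zeros((n, 2))
    X[:n1, 0] = 1.0
    X[n1:, 1] = 1.0

    vp1 = float(np.var(y[:n1], ddof=1))
    vp2 = float(np.var(y[n1:], ddof=1))
    floors = np.array([_FLOOR_FRAC * vp1, np.nan, _FLOOR_FRAC * vp2, _FLOOR_FRAC * vp1, _FLOOR_FRAC * vp2])
    # theta order: (g1, g12, g2, e1, e2)
    theta = np.array([vp1 / 2, 0.5 * np.sqrt(vp1 * vp2) / 2, vp2 / 2, vp1 / 2, vp2 / 2])

    def project(th):
        th = th.copy()
        if constrain:
            for k in (0, 2, 3, 4):
                th[k] = max(th[k], floors[k])
            cmax = np.sqrt(th[0] * th[2])
            th[1] = np.clip(th[1], -cmax, cmax)
        return th

    def build_V(th):
        g1, g12, g2, e1, e2 = th
        V = np.empty((n, n))
        V[:n1, :n1] = g1 * A11
        V[n1:, n1:] = g2 * A22
        V[:n1, n1:] = g12 * A12
        V[n1:, :n1] = V[:n1, n1:].T
        V[np.arange(n1), np.arange(n1)] += e1
        V[np.arange(n1, n), np.arange(n1, n)] += e2
        return V

    def quantities(th):
        V = build_V(th)
        try:
            cV = linalg.cho_factor(V, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cV[0]))))
        Vinv = linalg.cho_solve(cV, np.eye(n), check_finite=False)
        VinvX = Vinv @ X
        B = X.T @ VinvX
        try:
            Binv = np.linalg.inv(B)
        except np.linalg.LinAlgError:
            return None
        P = Vinv - VinvX @ Binv @ VinvX.T
        Py = P @ y
        yPy = float(y @ Py)
        _, logdetB = np.linalg.slogdet(B)
        ll = -0.5 * (logdetV + logdetB + yPy)

        Py1, Py2 = Py[:n1], Py[n1:]
        trs = np.array(
            [
                float(np.sum(P[:n1, :n1] * A11)),
                2.0 * float(np.sum(P[:n1, n1:] * A12)),
                float(np.sum(P[n1:, n1:] * A22)),
                float(np.trace(P[:n1, :n1])),
                float(np.trace(P[n1:, n1:])),
            ]
        )
        W = np.zeros((n, 5))
        W[:n1, 0] = A11 @ Py1
        W[:n1, 1] = A12 @ Py2
        W[n1:, 1] = A12.T @ Py1
        W[n1:, 2] = A22 @ Py2
        W[:n1, 3] = Py1
        W[n1:, 4] = Py2
        yPVPy = W.T @ Py
        grad = -0.5 * (trs - yPVPy)
        AI = 0.5 * (W.T @ (P @ W))
        return ll, grad, AI, (yPVPy, trs)

    theta = project(theta)
    q = quantities(theta)
    if q is None:
        raise ValueError("invalid starting point for bivariate REML")
    ll = q[0]
    converged = False
    it = 0
    ns = np.array([n1, n, n2, n1, n2], dtype=float)  # EM denominators per component
    for it in range(1, max_iter + 1):
        _, grad, AI, (yPVPy, trs) = q
        if it == 1:
            delta = theta**2 * (yPVPy - trs) / ns
            delta[1] = 0.0  # covariance left to AI updates
        else:
            # g12 has no floor (nan): never treated as pinned
            delta = _active_set_newton(theta, grad, AI, floors)
        step = 1.0
        for _ in range(_MAX_HALVINGS):
            prop = project(theta + step * delta)
            qp = quantities(prop)
            if qp is not None and qp[0] >= ll - 1e-10:
                break
            step /= 2.0
        else:
            # AI direction cannot improve: try an EM step on the variances
            em = theta**2 * (yPVPy - trs) / ns
            em[1] = 0.0
            prop = project(theta + em)
            qp = quantities(prop)
            if qp is None or qp[0] <= ll + tol:
                converged = True  # numerical optimum (possibly on the boundary)
                break
        theta, q = prop, qp
        if abs(qp[0] - ll) < tol:
            ll = qp[0]
            converged = True
            break
        ll = qp[0]

    if n <= polish_max_n:
        theta, q, refined = _polish_bivariate(theta, quantities, build_V, X, y, n)
        if refined:
            converged = True
            ll = q[0]

    AI = q[2]
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(AI)
    g1, g12, g2, e1, e2 = theta
    comps = BivariateComponents(
        sigma_g2_1=float(g1),
        sigma_g2_2=float(g2),
        sigma_g12=float(g12),
        sigma_e2_1=float(e1),
        sigma_e2_2=float(e2),
        sampling_covariance=cov,
        log_likelihood=float(ll),
        n_iterations=it,
        converged=converged,
    )
    denom = np.sqrt(g1 * g2)
    rg = float(g12 / denom) if denom > 0 else float("nan")
    if constrain:
        rg = float(np.clip(rg, -1.0, 1.0))
    # delta method on (g1, g12, g2)
    if denom > 0 and np.isfinite(rg):
        grad_rg = np.array([-rg / (2 * g1), 1.0 / denom, -rg / (2 * g2)])
        sub = cov[np.ix_([0, 1, 2], [0, 1, 2])]
        se_rg = float(np.sqrt(max(grad_rg @ sub @ grad_rg, 0.0)))
    else:
        se_rg = float("nan")
    return comps, GeneticCorrelationEstimate(rg=rg, se_rg=se_rg)


def _polish_bivariate(theta, quantities, build_V, X, y, n):
    """Simplex refinement of the bivariate optimum on a bounded parametrisation.

    Variances are optimised on the log scale, the genetic covariance through
    ``g12 = tanh(t) * sqrt(g1 g2)`` so the |rg|<=1 constraint is built in.
    Returns (theta, quantities(theta), improved_flag); only a strictly
    better restricted likelihood replaces the AI solution.
    """
    from scipy.optimize import minimize

    lo = 1e-10 * float(np.var(y, ddof=1))

    def loglik_only(th):
        V = build_V(th)
        try:
            cV = linalg.cho_factor(V, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cV[0]))))
        VinvX = linalg.cho_solve(cV, X, check_finite=False)
        Vinvy = linalg.cho_solve(cV, y, check_finite=False)
        B = X.T @ VinvX
        try:
            beta = np.linalg.solve(B, X.T @ Vinvy)
        except np.linalg.LinAlgError:
            return -np.inf
        yPy = float(y @ Vinvy - (X.T @ Vinvy) @ beta)
        _, logdetB = np.linalg.slogdet(B)
        return -0.5 * (logdetV + logdetB + yPy)

    def to_t(th):
        g1, e1, e2 = max(th[0], lo), max(th[3], lo), max(th[4], lo)
        g2 = max(th[2], lo)
        r = np.clip(th[1] / np.sqrt(g1 * g2), -1 + 1e-9, 1 - 1e-9)
        return np.array([np.log(g1), np.log(g2), np.log(e1), np.log(e2), np.arctanh(r)])

    def from_t(t):
        g1, g2, e1, e2 = np.exp(np.clip(t[:4], -40, 40))
        g12 = np.tanh(t[4]) * np.sqrt(g1 * g2)
        return np.array([g1, g12, g2, e1, e2])

    def neg(t):
        return -loglik_only(from_t(t))

    res = minimize(
        neg, to_t(theta), method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 3000, "maxfev": 3000},
    )
    cand = from_t(res.x)
    q_old = quantities(theta)
    q_new = quantities(cand)
    if q_new is not None and (q_old is None or q_new[0] > q_old[0] + 1e-9):
        return cand, q_new, True
    return theta, q_old, False


# ---------------------------------------------------------------------------
# scale transformation and comparisons

def liability_transform(
    h2_observed: float,
    se_observed: float,
    prevalence_K: float,
    case_proportion_P: float,
) -> HeritabilityEstimate:
    """Observed-scale to liability-scale h2 for ascertained case-control data.

    ``h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) z^2)`` where ``z`` is the
    standard-normal density at the liability threshold ``Phi^{-1}(1-K)``;
    the SE scales by the same factor. The transform is linear in
    ``h2_obs`` and does not depend on sample size.
    """
    K, P = prevalence_K, case_proportion_P
    if not (0 < K < 1 and 0 < P < 1):
        raise ValueError("K and P must be in (0, 1)")
    thr = stats.norm.isf(K)
    z = float(stats.norm.pdf(thr))
    factor = (K * (1 - K)) ** 2 / (P * (1 - P) * z**2)
    return HeritabilityEstimate(
        h2_observed=float(h2_observed),
        se_observed=float(se_observed),
        h2_liability=float(h2_observed * factor),
        se_liability=float(se_observed * factor),
        prevalence_K=K,
        case_proportion_P=P,
        z_density=z,
    )


def estimate_liability_h2(
    grm: Union[GRM, np.ndarray],
    phenotype: np.ndarray,
    prevalence: float,
    covariates: Optional[np.ndarray] = None,
) -> Tuple[VarianceComponents, HeritabilityEstimate]:
    """Convenience: observed-scale GREML on 0/1 status plus liability transform."""
    y = np.asarray(phenotype, dtype=float)
    fit = fit_greml_univariate(grm, y, covariates=covariates)
    P = float(np.mean(y))
    est = liability_transform(fit.h2_observed, fit.se_h2_observed, prevalence, P)
    return fit, est


def compare_h2(est_1, est_2, scale: str = "liability") -> Tuple[float, float]:
    """Two-sided z-test for a difference between two independent h2 estimates.

    ``z = (h2_1 - h2_2) / sqrt(se_1^2 + se_2^2)``. Accepts
    :class:`HeritabilityEstimate` objects (compared on the requested scale)
    or plain ``(h2, se)`` pairs.
    """
    def unpack(e):
        if isinstance(e, HeritabilityEstimate):
            if scale == "liability":
                return e.h2_liability, e.se_liability
            return e.h2_observed, e.se_observed
        h2, se = e
        return float(h2), float(se)

    h1, s1 = unpack(est_1)
    h2, s2 = unpack(est_2)
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard errors must be positive")
    zstat = (h1 - h2) / np.sqrt(s1**2 + s2**2)
    p = 2.0 * float(stats.norm.sf(abs(zstat)))
    return float(zstat), min(p, 1.0)
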