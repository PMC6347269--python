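"""Null frailty model: covariates plus a log-normal polygenic frailty.

The hazard for offspring ``ij`` is ``h0(t) exp(X_ij alpha + Q_ij)`` with the
log-frailties ``Q`` jointly normal, ``Q ~ N(0, sigma2 * A)``, where ``A`` is
the block-diagonal relationship matrix (2x kinship: unit diagonal, 0.5
between full sibs).  With ``A`` on the relationship scale, ``sigma2`` is the
per-subject polygenic variance of the log hazard.

Estimation is the penalized-partial-likelihood realization standard for
Gaussian frailties: an inner Newton maximizes the Breslow partial
log-likelihood penalized by ``Q' A^-1 Q / (2 sigma2)`` jointly in
``(alpha, Q)``, and an outer 1-D search maximizes the Laplace-approximate
marginal likelihood over ``sigma2`` (coarse log grid, then bounded
refinement).  ``sigma2 = 0`` (plain Cox, ``Q = 0``) is an admissible
boundary solution; with one offspring per family and no covariates the
model degenerates to ``theta = 1`` exactly.

The baseline hazard cancels from the partial likelihood and is never
estimated.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .family_data import CohortDataset, Pedigree
from .riskset import SurvivalContext

logger = logging.getLogger(__name__)


@dataclass
class KinshipStructure:
    """Block-diagonal relationship matrix A = 2*Phi over offspring."""

    offspring_ids: list[str]
    blocks: list[tuple[str, np.ndarray, np.ndarray]]  # (family_id, row idx, block)

    def dense(self) -> np.ndarray:
        n = len(self.offspring_ids)
        a = np.zeros((n, n))
        for _, idx, blk in self.blocks:
            a[np.ix_(idx, idx)] = blk
        return a

    def dense_inverse(self) -> np.ndarray:
        n = len(self.offspring_ids)
        a = np.zeros((n, n))
        for _, idx, blk in self.blocks:
            a[np.ix_(idx, idx)] = np.linalg.inv(blk)
        return a

    def logdet(self) -> float:
        return float(sum(np.linalg.slogdet(blk)[1] for _, idx, blk in self.blocks))


def build_kinship(ped: Pedigree) -> KinshipStructure:
    """Relationship blocks for nuclear families: a sibship of size s gets a
    s x s block with 1 on the diagonal and 0.5 off (full sibs)."""
    off_ids = ped.offspring_ids
    row_of = {s: i for i, s in enumerate(off_ids)}
    blocks = []
    for fid in ped.family_ids:
        idx = np.array([row_of[r.individual_id] for r in ped.offspring(fid)])
        s = len(idx)
        blk = np.full((s, s), 0.5)
        np.fill_diagonal(blk, 1.0)
        blocks.append((fid, idx, blk))
    return KinshipStructure(offspring_ids=list(off_ids), blocks=blocks)


@dataclass
class FitOptions:
    sigma2: str = "estimate"  # "estimate" or "fixed"
    sigma2_value: float = 0.0  # used when sigma2 == "fixed"
    max_outer: int = 50
    max_inner: int = 100
    tol: float = 1e-6
    sigma2_grid: tuple[float, float, int] = (1e-3, 4.0, 16)


@dataclass
class NullFrailtyFit:
    alpha_hat: np.ndarray
    Q_hat: np.ndarray
    sigma2_hat: float
    eta: np.ndarray
    theta: np.ndarray
    converged: bool
    n_iter_inner: int
    n_iter_outer: int
    loglik_trace: list = field(default_factory=list)
    partial_loglik: float = np.nan
    warnings: list = field(default_factory=list)


def _cox_fit(
    y: np.ndarray, d: np.ndarray, x: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, bool, int]:
    """Unpenalized Cox partial-likelihood fit (alpha only, Q = 0)."""
    n, p = x.shape
    alpha = np.zeros(p)
    if p == 0:
        ctx = SurvivalContext(y, d, np.ones(n))
        return alpha, ctx.partial_loglik(np.zeros(n)), True, 0
    ll_old = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        eta = x @ alpha
        ctx = SurvivalContext(y, d, np.exp(eta))
        ll = ctx.partial_loglik(eta)
        grad = x.T @ ctx.score_eta()
        hess = ctx.information_proj(x)
        step = np.linalg.solve(hess + 1e-12 * np.eye(p), grad)
        t = 1.0
        while t > 1e-8:
            cand = alpha + t * step
            eta_c = x @ cand
            ll_c = SurvivalContext(y, d, np.exp(eta_c)).partial_loglik(eta_c)
            if ll_c >= ll - 1e-12:
                break
            t /= 2.0
        alpha = alpha + t * step
        if np.max(np.abs(grad)) < tol * max(1.0, n) and abs(ll - ll_old) < tol * (
            1 + abs(ll)
        ):
            converged = True
            break
        ll_old = ll
    eta = x @ alpha
    ll = SurvivalContext(y, d, np.exp(eta)).partial_loglik(eta)
    return alpha, ll, converged, it


def _penalized_newton(
    y: np.ndarray,
    d: np.ndarray,
    x: np.ndarray,
    a_inv: np.ndarray,
    sigma2: float,
    start: Optional[tuple[np.ndarray, np.ndarray]],
    tol: float,
    max_iter: int,
) -> dict:
    """Inner Newton on (alpha, Q) at fixed sigma2 > 0."""
    n, p = x.shape
    alpha = np.zeros(p) if start is None else start[0].copy()
    q = np.zeros(n) if start is None else start[1].copy()
    pinv = a_inv / sigma2

    def pen_ll(alpha, q):
        eta = x @ alpha + q
        ctx = SurvivalContext(y, d, np.exp(eta))
        return ctx.partial_loglik(eta) - 0.5 * q @ pinv @ q, ctx, eta

    ll, ctx, eta = pen_ll(alpha, q)
    converged = False
    for it in range(1, max_iter + 1):
        g_eta = ctx.score_eta()
        grad = np.concatenate([x.T @ g_eta, g_eta - pinv @ q])
        if np.max(np.abs(grad)) < tol * max(1.0, n):
            converged = True
            break
        h = ctx.information_dense()
        m = np.empty((p + n, p + n))
        hx = h @ x
        m[:p, :p] = x.T @ hx
        m[:p, p:] = hx.T
        m[p:, :p] = hx
        m[p:, p:] = h + pinv
        m[np.arange(p + n), np.arange(p + n)] += 1e-10
        step = np.linalg.solve(m, grad)
        t = 1.0
        while t > 1e-10:
            ll_c, ctx_c, eta_c = pen_ll(alpha + t * step[:p], q + t * step[p:])
            if ll_c >= ll - 1e-10:
                break
            t /= 2.0
        alpha = alpha + t * step[:p]
        q = q + t * step[p:]
        ll, ctx, eta = ll_c, ctx_c, eta_c
    h = ctx.information_dense()
    return {
        "alpha": alpha,
        "Q": q,
        "eta": eta,
        "pen_loglik": ll,
        "partial_loglik": ctx.partial_loglik(eta),
        "H": h,
        "converged": converged,
        "n_iter": it,
    }


def _laplace_marginal(res: dict, a_inv: np.ndarray, a_logdet: float, sigma2: float) -> float:
    """Laplace-approximate marginal log-likelihood at the inner optimum."""
    n = len(res["Q"])
    k = res["H"] + a_inv / sigma2
    sign, logdet_k = np.linalg.slogdet(k)
    if sign <= 0:  # pragma: no cover - should not occur at an optimum
        return -np.inf
    return res["pen_loglik"] - 0.5 * (n * np.log(sigma2) + a_logdet) - 0.5 * logdet_k


def fit_null_frailty(
    cohort: CohortDataset,
    kinship: KinshipStructure,
    options: Optional[FitOptions] = None,
) -> NullFrailtyFit:
    """Fit the null model (no variant effects) on the offspring.

    Returns risk scores ``theta = exp(X alpha_hat + Q_hat)`` for the score
    tests.  With no covariates and ``sigma2`` fixed at 0 the fit is exact and
    immediate (``theta = 1``).
    """
    opts = options or FitOptions()
    pheno = cohort.phenotypes
    if pheno is None:
        raise ValueError("cohort has no phenotypes")
    if list(pheno.subject_ids) != list(kinship.offspring_ids):
        raise ValueError("kinship and phenotype subject order differ")
    y, d, x = pheno.time, pheno.event, pheno.covariates
    n, p = x.shape
    if d.sum() == 0:
        raise ValueError("no events in cohort")
    if p > 0 and np.linalg.matrix_rank(x) < p:
        raise ValueError("covariate matrix is rank deficient")
    warns: list[str] = []
    trace: list[tuple[float, float]] = []

    sibship_sizes = [len(idx) for _, idx, _ in kinship.blocks]
    if max(sibship_sizes) == 1 and opts.sigma2 == "estimate":
        warns.append(
            "one offspring per family: the polygenic variance is weakly "
            "identified; sigma2_hat = 0 is a common and admissible outcome"
        )
        logger.warning(warns[-1])

    def cox_result(sigma2=0.0):
        alpha, ll, conv, it = _cox_fit(y, d, x, opts.tol, opts.max_inner)
        eta = x @ alpha
        return NullFrailtyFit(
            alpha_hat=alpha,
            Q_hat=np.zeros(n),
            sigma2_hat=sigma2,
            eta=eta,
            theta=np.exp(eta),
            converged=conv,
            n_iter_inner=it,
            n_iter_outer=0,
            loglik_trace=[(0.0, ll)],
            partial_loglik=ll,
            warnings=warns,
        )

    if opts.sigma2 == "fixed" and opts.sigma2_value == 0.0:
        return cox_result()

    a_inv = kinship.dense_inverse()
    a_logdet = kinship.logdet()

    if opts.sigma2 == "fixed":
        res = _penalized_newton(
            y, d, x, a_inv, opts.sigma2_value, None, opts.tol, opts.max_inner
        )
        return NullFrailtyFit(
            alpha_hat=res["alpha"],
            Q_hat=res["Q"],
            sigma2_hat=opts.sigma2_value,
            eta=res["eta"],
            theta=np.exp(res["eta"]),
            converged=res["converged"],
            n_iter_inner=res["n_iter"],
            n_iter_outer=0,
            loglik_trace=[(opts.sigma2_value, res["pen_loglik"])],
            partial_loglik=res["partial_loglik"],
            warnings=warns,
        )

    # outer profile over sigma2: coarse log grid, then bounded refinement
    cache: dict[float, dict] = {}
    start: Optional[tuple[np.ndarray, np.ndarray]] = None
    n_eval = 0

    def profile(s2: float) -> float:
        nonlocal start, n_eval
        s2 = float(s2)
        if s2 in cache:
            return cache[s2]["lm"]
        res = _penalized_newton(y, d, x, a_inv, s2, start, opts.tol, opts.max_inner)
        start = (res["alpha"], res["Q"])
        res["lm"] = _laplace_marginal(res, a_inv, a_logdet, s2)
        cache[s2] = res
        trace.append((s2, res["lm"]))
        n_eval += 1
        return res["lm"]

    lo, hi, ngrid = opts.sigma2_grid
    grid = np.geomspace(lo, hi, int(ngrid))
    # sigma2 -> 0 limit of the Laplace marginal is the plain Cox log-likelihood
    cox0 = cox_result()
    lm0 = cox0.partial_loglik
    lms = [profile(s2) for s2 in grid]
    best = int(np.argmax(lms))
    if lms[best] <= lm0:
        cox0.warnings.append("sigma2 profile maximized at the boundary sigma2 = 0")
        logger.info(cox0.warnings[-1])
        cox0.loglik_trace = trace
        cox0.n_iter_outer = n_eval
        return cox0
    left = grid[max(best - 1, 0)]
    right = grid[min(best + 1, len(grid) - 1)]
    if best == 0:
        left = lo / 10.0
    if best == len(grid) - 1:
        right = hi * 4.0
    r = minimize_scalar(
        lambda t: -profile(np.exp(t)),
        bounds=(np.log(left), np.log(right)),
        method="bounded",
        options={"xatol": opts.tol, "maxiter": opts.max_outer},
    )
    s2_hat = float(np.exp(r.x))
    res = cache.get(s2_hat)
    if res is None:
        profile(s2_hat)
        res = cache[s2_hat]
    return NullFrailtyFit(
        alpha_hat=res["alpha"],
        Q_hat=res["Q"],
        sigma2_hat=s2_hat,
        eta=res["eta"],
        theta=np.exp(res["eta"]),
        converged=res["converged"] and r.success,
        n_iter_inner=res["n_iter"],
        n_iter_outer=n_eval,
        loglik_trace=trace,
        partial_loglik=res["partial_loglik"],
        warnings=warns,
    )


def trivial_null_fit(n_offspring: int) -> NullFrailtyFit:
    """Degenerate null fit (no covariates, sigma2 = 0): theta = 1 for all."""
    z = np.zeros(n_offspring)
    return NullFrailtyFit(
        alpha_hat=np.empty(0),
        Q_hat=z,
        sigma2_hat=0.0,
        eta=z,
        theta=np.ones(n_offspring),
        converged=True,
        n_iter_inner=0,
        n_iter_outer=0,
    )
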