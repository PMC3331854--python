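"""Maximization of the (penalized) half-sib REML likelihood.

Parameters are the elements of the canonical decomposition: the q canonical
eigenvalues lambda_i, restrained to [0.0001, 0.9999], and the q^2 free
elements t_ij of the transformation T.  The eigenvalue bounds are enforced
through a smooth logistic map from the real line onto the interval, so the
search itself is unconstrained and the estimated sigma_G is positive
semi-definite and sigma_E positive definite by construction.

A quasi-Newton ascent (L-BFGS with finite-difference gradients on the
analytic objective) locates the maximum, followed by a bounded
derivative-free compass search that confirms convergence; solutions along a
grid of tuning factors are warm-started from the previous grid point, with
the baseline quantities the penalties need frozen from the psi = 0 fit
before any penalized fit runs.

For unpenalized fits the optimizer is started at the closed-form solution
of the balanced one-way MANOVA: the generalized eigenvalues of M_B with
respect to M_W, truncated where the eigenvalue bounds bind.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.special import expit, logit

from .core import CanonicalForm, CovariancePair, canonical_decompose, compose_matrices
from .exceptions import ConfigurationError, DegenerateTraitError, InvalidInputError
from .likelihood import HalfSibStats, loglik_mats
from .penalties import PenaltySpec

__all__ = ["LAMBDA_MIN", "LAMBDA_MAX", "FitResult", "FitPath", "fit", "fit_path", "anova_start"]

#: bounds on estimated canonical eigenvalues
LAMBDA_MIN = 1e-4
LAMBDA_MAX = 0.9999

_U_BOUND = 25.0  # |u| cap for the logistic parameterisation
_U_START_BOUND = 8.0  # |u| cap for warm-start points (keeps gradients alive)
_BIG = 1e12


def _lam_from_u(u: np.ndarray) -> np.ndarray:
    return LAMBDA_MIN + (LAMBDA_MAX - LAMBDA_MIN) * expit(u)


def _u_from_lam(lam: np.ndarray, bound: float = _U_BOUND) -> np.ndarray:
    """Map eigenvalues to start values of the unconstrained parameter u.

    For penalized fits, starts are clipped to |u| <= 8 rather than the
    search bound: the logistic map's gradient vanishes at extreme u, so a
    warm start taken exactly at a pinned bound would freeze that
    eigenvalue even when the penalty wants to pull it into the interior.
    Unpenalized fits start at the exact bound (the constrained optimum
    pins there), which converges in a handful of iterations.
    """
    frac = (np.asarray(lam, dtype=float) - LAMBDA_MIN) / (LAMBDA_MAX - LAMBDA_MIN)
    frac = np.clip(frac, 1e-10, 1.0 - 1e-10)
    return np.clip(logit(frac), -bound, bound)


@dataclass(frozen=True)
class FitResult:
    """A single (penalized) REML solution."""

    pair: CovariancePair
    form: CanonicalForm
    logL: float
    logLP: float
    psi: float
    converged: bool
    iterations: int


@dataclass
class FitPath:
    """Solutions along an ascending grid of tuning factors.

    ``fits[0]`` is the unpenalized (psi = 0) fit; ``penalty`` carries the
    baseline quantities frozen from it.
    """

    psi_grid: np.ndarray
    fits: List[FitResult]
    penalty: Optional[PenaltySpec] = None

    @property
    def baseline(self) -> FitResult:
        return self.fits[0]

    def loglik_curve(self) -> np.ndarray:
        """Unpenalized log-likelihood of each solution on the training data."""
        return np.array([f.logL for f in self.fits])


def _pd_inverse_logdet(S: np.ndarray):
    """(S^-1, log|S|) via LAPACK Cholesky; None when S is not PD."""
    c, info = scipy.linalg.lapack.dpotrf(S, lower=1)
    if info != 0:
        return None
    linv, info = scipy.linalg.lapack.dtrtri(c, lower=1)
    if info != 0:
        return None
    return linv.T @ linv, 2.0 * float(np.sum(np.log(np.diag(c))))


def _objective_factory(stats: HalfSibStats, penalty: Optional[PenaltySpec], psi):
    """Build negobj(params) -> (value, gradient) for the penalized deviance.

    Both strata factor as T D T' with diagonal D (D_W = I - Lambda/4,
    D_B = I + (n-1) Lambda / 4), so the likelihood gradient with respect to
    (lambda, T) is available in closed form:

        dlogL/dT      = 2 (G_B T D_B + G_W T D_W)
        dlogL/dlam_i  = (n-1)/4 t_i' G_B t_i - 1/4 t_i' G_W t_i

    with G_X = -w_X/2 (Sigma_X^-1 - Sigma_X^-1 M_X Sigma_X^-1).  Penalty
    gradients come from :meth:`PenaltySpec.scaled_gradient` and are chained
    through sigma_G = T Lambda T', sigma_E = T (I - Lambda) T'.
    """
    q = stats.q
    s, n = stats.s, stats.n
    w_B, w_W = s - 1.0, s * (n - 1.0)
    c_B, c_W = (n - 1.0) / 4.0, -0.25
    M_B, M_W = stats.M_B, stats.M_W
    span = LAMBDA_MAX - LAMBDA_MIN
    scaled = penalty is not None and np.max(np.atleast_1d(psi)) > 0.0
    nparam = q + q * q
    bad = (_BIG, np.zeros(nparam))

    def negobj(params: np.ndarray, need_grad: bool = True):
        sig = expit(params[:q])
        lam = LAMBDA_MIN + span * sig
        T = params[q:].reshape(q, q)
        D_W = 1.0 - 0.25 * lam
        D_B = 1.0 + c_B * lam
        TD_W = T * D_W
        TD_B = T * D_B
        Sigma_W = TD_W @ T.T
        Sigma_B = TD_B @ T.T
        inv_B = _pd_inverse_logdet(Sigma_B)
        if inv_B is None:
            return bad
        inv_W = _pd_inverse_logdet(Sigma_W)
        if inv_W is None:
            return bad
        SinvB, ld_B = inv_B
        SinvW, ld_W = inv_W
        tr_B = float(np.sum(SinvB * M_B))
        tr_W = float(np.sum(SinvW * M_W))
        f = 0.5 * (w_B * (ld_B + tr_B) + w_W * (ld_W + tr_W))  # -logL
        if not need_grad:
            if scaled:
                need_mats = penalty.kind not in (
                    "P_lambda", "P_lambda_log", "P_lambda_log2",
                    "P_beta_fixed", "P_beta_mom", "P_beta_order")
                pair = (_RawPair((T * lam) @ T.T, (T * (1.0 - lam)) @ T.T)
                        if need_mats else None)
                try:
                    pen = penalty.scaled_value(pair=pair, lambdas=lam, psi=psi)
                except (ArithmeticError, DegenerateTraitError):
                    return bad
                if not np.isfinite(pen):
                    return bad
                f += 0.5 * pen
            return f, None
        G_B = -0.5 * w_B * (SinvB - SinvB @ M_B @ SinvB)
        G_W = -0.5 * w_W * (SinvW - SinvW @ M_W @ SinvW)
        grad_T = -2.0 * (G_B @ TD_B + G_W @ TD_W)          # d(-logL)/dT
        grad_lam = -(c_B * np.einsum("ij,ij->j", T, G_B @ T)
                     + c_W * np.einsum("ij,ij->j", T, G_W @ T))
        if scaled:
            need_mats = penalty.kind not in (
                "P_lambda", "P_lambda_log", "P_lambda_log2",
                "P_beta_fixed", "P_beta_mom", "P_beta_order")
            sigma_G = (T * lam) @ T.T if need_mats else None
            sigma_E = (T * (1.0 - lam)) @ T.T if need_mats else None
            pair = _RawPair(sigma_G, sigma_E) if need_mats else None
            try:
                pen = penalty.scaled_value(pair=pair, lambdas=lam, psi=psi)
                g_lam_p, G_Gp, G_Ep = penalty.scaled_gradient(
                    lam, sigma_G, sigma_E, psi)
            except (ArithmeticError, DegenerateTraitError):
                return bad
            if not np.isfinite(pen):
                return bad
            f += 0.5 * pen
            if g_lam_p is not None:
                grad_lam = grad_lam + 0.5 * g_lam_p
            if G_Gp is not None:
                grad_T = grad_T + (G_Gp @ (T * lam))
                grad_lam = grad_lam + 0.5 * np.einsum("ij,ij->j", T, G_Gp @ T)
            if G_Ep is not None:
                grad_T = grad_T + (G_Ep @ (T * (1.0 - lam)))
                grad_lam = grad_lam - 0.5 * np.einsum("ij,ij->j", T, G_Ep @ T)
        grad_u = grad_lam * span * sig * (1.0 - sig)
        return f, np.concatenate([grad_u, grad_T.reshape(-1)])

    return negobj


class _RawPair:
    """Duck-typed covariance pair without validation, for hot loops."""

    __slots__ = ("sigma_G", "sigma_E")

    def __init__(self, sigma_G, sigma_E):
        self.sigma_G = sigma_G
        self.sigma_E = sigma_E

    @property
    def sigma_P(self):
        return self.sigma_G + self.sigma_E

    @property
    def q(self):
        return self.sigma_G.shape[0]


def anova_start(stats: HalfSibStats) -> CanonicalForm:
    """Closed-form balanced one-way MANOVA estimate, projected into bounds.

    Simultaneously diagonalizes (M_B, M_W); where the generalized
    eigenvalue d_i implies a canonical eigenvalue inside the bounds the
    unconstrained solution (Sigma_B = M_B, Sigma_W = M_W component-wise) is
    kept, otherwise d_i is pinned at the bound and the stratum variance
    pooled with likelihood weights.
    """
    s, n = stats.s, stats.n
    if s * (n - 1) < stats.q:
        raise InvalidInputError("M_W rank-deficient: need s(n-1) >= q")
    try:
        d, V = scipy.linalg.eigh(stats.M_B, stats.M_W)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as err:
        raise InvalidInputError(f"M_W not positive definite: {err}") from err
    # d_i relates to the canonical eigenvalue via lam = 4(d-1)/(n + d - 1)
    d_lo = 1.0 + LAMBDA_MIN * n / (4.0 - LAMBDA_MIN)
    d_hi = 1.0 + LAMBDA_MAX * n / (4.0 - LAMBDA_MAX)
    w_b, w_w = s - 1.0, s * (n - 1.0)
    sb = np.empty_like(d)
    sw = np.empty_like(d)
    for i, di in enumerate(d):
        if d_lo <= di <= d_hi:
            sb[i], sw[i] = di, 1.0
        else:
            rho = d_lo if di < d_lo else d_hi
            sw[i] = (w_b * di / rho + w_w) / (w_b + w_w)
            sb[i] = rho * sw[i]
    Tm = np.linalg.inv(V).T  # M_W = Tm Tm'
    Sigma_B = (Tm * sb) @ Tm.T
    Sigma_W = (Tm * sw) @ Tm.T
    sigma_G = 4.0 / n * (Sigma_B - Sigma_W)
    sigma_E = Sigma_W - 0.75 * sigma_G
    lam, U = scipy.linalg.eigh(sigma_G, sigma_G + sigma_E)
    lam = np.clip(lam[::-1], LAMBDA_MIN, LAMBDA_MAX)
    T = np.linalg.inv(U[:, ::-1]).T
    return CanonicalForm(lambdas=lam, T=T)


def _compass_polish(negobj, params, fval, *, max_evals=500, step0=1e-4, shrink=0.01,
                    min_step=5e-7):
    """Simple derivative-free search confirming no further improvement.

    Probes +/- step along every coordinate, accepting improvements, and
    shrinks the step when a sweep yields none.
    """
    x, f = params, fval
    step = step0
    evals = 0
    while step >= min_step and evals < max_evals:
        improved = False
        for i in range(x.size):
            for sgn in (1.0, -1.0):
                if evals >= max_evals:
                    break
                xt = x.copy()
                xt[i] += sgn * step
                ft = negobj(xt)
                evals += 1
                if ft < f - 1e-12:
                    x, f = xt, ft
                    improved = True
                    break
        if not improved:
            step *= shrink
    return x, f, evals


def fit(stats: HalfSibStats, penalty: Optional[PenaltySpec] = None, psi=0.0,
        start: Optional[CanonicalForm] = None, *, max_iter: int = 200,
        polish_evals: int = 500, gtol: float = 1e-5) -> FitResult:
    """Maximize the (penalized) REML log-likelihood for a single psi.

    Parameters
    ----------
    stats
        Sufficient statistics of the data.
    penalty, psi
        Penalty specification (with baseline set, if it needs one) and
        tuning factor; ``psi = 0`` or ``penalty=None`` gives standard REML.
    start
        Warm start; defaults to the closed-form MANOVA solution.
    """
    scaledpen = penalty is not None and np.max(np.atleast_1d(psi)) > 0.0
    if scaledpen and penalty.needs_baseline and penalty.baseline is None:
        raise ConfigurationError(
            f"penalty {penalty.kind} needs baseline quantities; run the "
            "unpenalized fit first (see fit_path)"
        )
    q = stats.q
    if start is None:
        start = anova_start(stats)
    lam0 = np.clip(start.lambdas, LAMBDA_MIN, LAMBDA_MAX)
    start_bound = _U_START_BOUND if scaledpen else _U_BOUND
    params0 = np.concatenate([_u_from_lam(lam0, start_bound), start.T.reshape(-1)])
    negobj = _objective_factory(stats, penalty, psi)
    f0 = negobj(params0)[0]
    if f0 >= _BIG:
        raise InvalidInputError("infeasible starting point for fit()")
    fun_only = lambda p: negobj(p, need_grad=False)[0]  # noqa: E731
    bounds = [(-_U_BOUND, _U_BOUND)] * q + [(None, None)] * (q * q)
    res = scipy.optimize.minimize(
        negobj, params0, method="L-BFGS-B", jac=True, bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": gtol, "maxcor": 20},
    )
    x, f = (res.x, res.fun) if res.fun <= f0 else (params0, f0)
    x, f, _ = _compass_polish(fun_only, x, f, max_evals=polish_evals)
    lam = _lam_from_u(x[:q])
    T = x[q:].reshape(q, q)
    sigma_G, sigma_E = compose_matrices(lam, T)
    pair = CovariancePair(sigma_G=sigma_G, sigma_E=sigma_E)
    form = canonical_decompose(pair)
    logL = float(loglik_mats(sigma_G, sigma_E, stats))
    psi_scalar = float(np.max(np.atleast_1d(psi)))
    return FitResult(
        pair=pair,
        form=form,
        logL=logL,
        logLP=float(-f),
        psi=psi_scalar,
        converged=bool(res.success or f < res.fun),
        iterations=int(res.nit),
    )


def fit_path(stats: HalfSibStats, penalty: Optional[PenaltySpec],
             psi_grid: Sequence[float], **fit_kwargs) -> FitPath:
    """Sequential warm-started fits along an ascending psi grid.

    The grid must start at 0; the unpenalized fit supplies both the warm
    start for the first penalized fit and the frozen baseline quantities
    (extreme eigenvalues, sigma_P^0, R_P^0, moment beta shapes).
    """
    grid = np.asarray(psi_grid, dtype=float)
    if grid.size == 0 or grid[0] != 0.0:
        raise ConfigurationError("psi grid must start at 0")
    if np.any(np.diff(grid) <= 0.0):
        raise ConfigurationError("psi grid must be strictly increasing")
    base_fit = fit(stats, None, 0.0, **fit_kwargs)
    frozen = None
    if penalty is not None:
        frozen = penalty.with_baseline(base_fit.pair) if penalty.needs_baseline else penalty
    fits = [base_fit]
    current = base_fit.form
    for psi in grid[1:]:
        if penalty is None:
            fits.append(base_fit)
            continue
        result = fit(stats, frozen, float(psi), start=current, **fit_kwargs)
        fits.append(result)
        current = result.form
    return FitPath(psi_grid=grid, fits=fits, penalty=frozen)
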