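"""Penalty functions for penalized REML estimation.

Two families of penalties are provided, all designed so that a tuning
factor psi > 0 shrinks the estimate toward the penalty's minimizer:

* **Canonical-eigenvalue penalties** act on the eigenvalues lambda_i of
  sigma_P^-1 sigma_G: the variance among eigenvalues (``P_lambda``, the
  likelihood analogue of 'bending'), the variance on the log scale
  (``P_lambda_log``; ``P_lambda_log2`` adds the log(1 - lambda) part), and
  negative log beta-density kernels (``P_beta_fixed`` with fixed shapes,
  ``P_beta_mom`` with method-of-moments shapes, ``P_beta_order`` treating
  the eigenvalues as order statistics of a uniform sample).

* **Matrix-divergence penalties** derive from an inverse-Wishart prior with
  the unpenalized phenotypic matrix as scale: ``P_Sigma`` shrinks sigma_G
  toward sigma_P^0 (``P_Sigma2`` also shrinks sigma_E), and ``P_rho`` /
  ``P_rho2`` do the same on the correlation scale, shrinking R_G (and R_E)
  toward R_P^0.  Each part has the form C log|S| + tr(S^-1 Omega) with
  C = (psi + q + 1)/psi; with C ~ 1 it is the Kullback-Leibler divergence
  from the target.

Several penalties need quantities *frozen from the unpenalized fit* (the
extreme eigenvalues used to rescale, sigma_P^0, R_P^0, the moment-estimated
beta shapes).  These live in an immutable :class:`PenaltyBaseline` attached
to the :class:`PenaltySpec` once the psi = 0 fit is available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import scipy.linalg

from .core import CovariancePair, canonical_decompose, correlation_from_covariance
from .exceptions import BoundaryError, ConfigurationError

__all__ = [
    "PENALTY_KINDS",
    "PenaltyBaseline",
    "PenaltySpec",
    "p_lambda",
    "p_lambda_log",
    "p_lambda_log2",
    "p_beta_fixed",
    "estimate_beta_shapes",
    "p_beta_mom",
    "p_beta_order",
    "p_sigma",
    "p_sigma2",
    "p_rho",
    "p_rho2",
]

EIGENVALUE_KINDS = (
    "P_lambda",
    "P_lambda_log",
    "P_lambda_log2",
    "P_beta_fixed",
    "P_beta_mom",
    "P_beta_order",
)
MATRIX_KINDS = ("P_Sigma", "P_Sigma2", "P_rho", "P_rho2")
PENALTY_KINDS = EIGENVALUE_KINDS + MATRIX_KINDS

#: kinds that need baseline quantities from the unpenalized fit
BASELINE_KINDS = frozenset(
    {"P_beta_fixed", "P_beta_mom", "P_beta_order", "P_Sigma", "P_Sigma2", "P_rho", "P_rho2"}
)
#: two-part penalties that support separate genetic/residual tuning factors
TWO_PART_KINDS = frozenset({"P_lambda_log2", "P_Sigma2", "P_rho2"})

_RESCALE_EPS = 1e-6


@dataclass(frozen=True)
class PenaltyBaseline:
    """Quantities frozen from the unpenalized (psi = 0) fit."""

    lambdas0: np.ndarray
    sigma_P0: np.ndarray
    R_P0: np.ndarray
    alpha_mom: Optional[float] = None
    beta_mom: Optional[float] = None

    @property
    def lambda_1(self) -> float:
        """Largest unpenalized canonical eigenvalue."""
        return float(np.max(self.lambdas0))

    @property
    def lambda_q(self) -> float:
        """Smallest unpenalized canonical eigenvalue."""
        return float(np.min(self.lambdas0))


@dataclass(frozen=True)
class PenaltySpec:
    """Identity and hyperparameters of a penalty.

    Parameters
    ----------
    kind
        One of :data:`PENALTY_KINDS`.
    alpha, beta
        Beta shape parameters for ``P_beta_fixed`` (default 2, 2).
    z
        Modifier constant for ``P_beta_mom`` / ``P_beta_order`` (default 1).
    c_approx_one
        Evaluate the inverse-Wishart weight C as 1 instead of
        (psi + q + 1)/psi, giving the pure KL-divergence form.
    separate_tuning
        Allow a (psi_G, psi_E) pair for the two-part penalties.
    """

    kind: str
    alpha: float = 2.0
    beta: float = 2.0
    z: float = 1.0
    c_approx_one: bool = False
    separate_tuning: bool = False
    baseline: Optional[PenaltyBaseline] = None

    def __post_init__(self):
        if self.kind not in PENALTY_KINDS:
            raise ConfigurationError(f"unknown penalty kind {self.kind!r}")
        if self.alpha <= 0.0 or self.beta <= 0.0:
            raise ConfigurationError("beta shape parameters must be positive")
        if self.z < 0.0:
            raise ConfigurationError("z must be non-negative")
        if self.separate_tuning and self.kind not in TWO_PART_KINDS:
            raise ConfigurationError(
                f"separate tuning factors only apply to {sorted(TWO_PART_KINDS)}"
            )

    # ------------------------------------------------------------------
    @property
    def needs_baseline(self) -> bool:
        return self.kind in BASELINE_KINDS

    def with_baseline(self, pair0: CovariancePair) -> "PenaltySpec":
        """Freeze baseline quantities from the unpenalized estimate."""
        form0 = canonical_decompose(pair0)
        sigma_P0 = pair0.sigma_P
        base = PenaltyBaseline(
            lambdas0=form0.lambdas.copy(),
            sigma_P0=sigma_P0.copy(),
            R_P0=correlation_from_covariance(sigma_P0),
        )
        if self.kind == "P_beta_mom":
            a, b = estimate_beta_shapes(form0.lambdas)
            base = replace(base, alpha_mom=a, beta_mom=b)
        return replace(self, baseline=base)

    def _require_baseline(self) -> PenaltyBaseline:
        if self.baseline is None:
            raise ConfigurationError(
                f"penalty {self.kind} requires baseline quantities from the "
                "unpenalized fit; call with_baseline() first"
            )
        return self.baseline

    # ------------------------------------------------------------------
    def value(self, pair: Optional[CovariancePair] = None,
              lambdas: Optional[np.ndarray] = None, psi: float = 1.0) -> float:
        """Evaluate P(theta).

        Eigenvalue penalties use ``lambdas`` (computed from ``pair`` if
        absent); matrix penalties use ``pair``.  ``psi`` only enters the
        matrix penalties through the weight C.
        """
        if self.kind in EIGENVALUE_KINDS:
            if lambdas is None:
                if pair is None:
                    raise ConfigurationError("need lambdas or a covariance pair")
                lambdas = canonical_decompose(pair).lambdas
            return self._eigen_value(np.asarray(lambdas, dtype=float))
        if pair is None:
            raise ConfigurationError("matrix penalties need a covariance pair")
        return self._matrix_value(pair.sigma_G, pair.sigma_E, psi)

    def scaled_value(self, pair: Optional[CovariancePair] = None,
                     lambdas: Optional[np.ndarray] = None, psi=1.0) -> float:
        """Evaluate psi * P(theta), well defined for every psi >= 0.

        For the inverse-Wishart penalties the product psi * C equals
        psi + q + 1 analytically, so the scaled penalty is continuous down
        to psi = 0 (psi = 0 itself bypasses penalization in the objective).
        ``psi`` may be a (psi_G, psi_E) pair for two-part penalties with
        ``separate_tuning``.
        """
        psi_G, psi_E = self._split_psi(psi)
        if self.kind in EIGENVALUE_KINDS:
            if lambdas is None:
                if pair is None:
                    raise ConfigurationError("need lambdas or a covariance pair")
                lambdas = canonical_decompose(pair).lambdas
            lambdas = np.asarray(lambdas, dtype=float)
            if self.kind == "P_lambda_log2" and psi_G != psi_E:
                return (psi_G * p_lambda_log(lambdas)
                        + psi_E * p_lambda_log(1.0 - lambdas))
            return psi_G * self._eigen_value(lambdas)
        if pair is None:
            raise ConfigurationError("matrix penalties need a covariance pair")
        return self._matrix_scaled(pair.sigma_G, pair.sigma_E, psi_G, psi_E)

    def _split_psi(self, psi):
        arr = np.atleast_1d(np.asarray(psi, dtype=float))
        if arr.size == 1:
            return float(arr[0]), float(arr[0])
        if arr.size == 2:
            if not self.separate_tuning:
                raise ConfigurationError(
                    "a (psi_G, psi_E) pair requires separate_tuning=True"
                )
            return float(arr[0]), float(arr[1])
        raise ConfigurationError("psi must be a scalar or a (psi_G, psi_E) pair")

    # ------------------------------------------------------------------
    def _eigen_value(self, lam: np.ndarray) -> float:
        if self.kind == "P_lambda":
            return p_lambda(lam)
        if self.kind == "P_lambda_log":
            return p_lambda_log(lam)
        if self.kind == "P_lambda_log2":
            return p_lambda_log2(lam)
        if self.kind == "P_beta_fixed":
            return p_beta_fixed(lam, self)
        if self.kind == "P_beta_mom":
            return p_beta_mom(lam, self)
        return p_beta_order(lam, self)

    def _matrix_value(self, sigma_G, sigma_E, psi) -> float:
        psi_G, psi_E = self._split_psi(psi)
        q = sigma_G.shape[0]
        parts = self._matrix_parts(sigma_G, sigma_E)
        total = 0.0
        for (logdet, trace), p in zip(parts, (psi_G, psi_E)):
            total += _iw_weight(p, q, self.c_approx_one) * logdet + trace
        return total

    def _matrix_scaled(self, sigma_G, sigma_E, psi_G, psi_E) -> float:
        q = sigma_G.shape[0]
        parts = self._matrix_parts(sigma_G, sigma_E)
        total = 0.0
        for (logdet, trace), p in zip(parts, (psi_G, psi_E)):
            if self.c_approx_one:
                total += p * (logdet + trace)
            else:
                # psi * C = psi + q + 1 exactly
                total += (p + q + 1) * logdet + p * trace
        return total

    # ------------------------------------------------------------------
    def scaled_gradient(self, lambdas: np.ndarray, sigma_G: np.ndarray,
                        sigma_E: np.ndarray, psi):
        """Gradient of psi * P(theta).

        Returns ``(d_lambda, d_sigma_G, d_sigma_E)``: eigenvalue penalties
        populate the first slot, matrix penalties the matrix slots (None
        where a slot does not apply).  Matches :meth:`scaled_value`
        including the clamping of rescaled eigenvalues, whose clamped
        components get zero gradient.
        """
        psi_G, psi_E = self._split_psi(psi)
        lam = np.asarray(lambdas, dtype=float)
        q = lam.size
        if self.kind in EIGENVALUE_KINDS:
            return self._eigen_scaled_grad(lam, psi_G, psi_E), None, None
        c1_G = psi_G if self.c_approx_one else psi_G + q + 1
        c1_E = psi_E if self.c_approx_one else psi_E + q + 1
        base = self._require_baseline()
        if self.kind in ("P_Sigma", "P_Sigma2"):
            G_G = _iw_grad(sigma_G, base.sigma_P0, c1_G, psi_G)
            G_E = (_iw_grad(sigma_E, base.sigma_P0, c1_E, psi_E)
                   if self.kind == "P_Sigma2" else None)
            return None, G_G, G_E
        G_G = _iw_corr_grad(sigma_G, base.R_P0, c1_G, psi_G)
        G_E = (_iw_corr_grad(sigma_E, base.R_P0, c1_E, psi_E)
               if self.kind == "P_rho2" else None)
        return None, G_G, G_E

    def _eigen_scaled_grad(self, lam, psi_G, psi_E):
        if self.kind == "P_lambda":
            return psi_G * 2.0 * (lam - lam.mean())
        if self.kind == "P_lambda_log":
            logs = np.log(lam)
            return psi_G * 2.0 * (logs - logs.mean()) / lam
        if self.kind == "P_lambda_log2":
            logs = np.log(lam)
            logs1 = np.log1p(-lam)
            return (psi_G * 2.0 * (logs - logs.mean()) / lam
                    - psi_E * 2.0 * (logs1 - logs1.mean()) / (1.0 - lam))
        if self.kind == "P_beta_mom":
            base = self._require_baseline()
            a = base.alpha_mom + self.z - 1.0
            b = base.beta_mom + self.z - 1.0
            return -psi_G * (a / lam - b / (1.0 - lam))
        base = self._require_baseline()
        lo, hi = base.lambda_q, base.lambda_1
        rng = hi - lo
        star_raw = (lam - lo) / rng
        clamped = (star_raw <= _RESCALE_EPS) | (star_raw >= 1.0 - _RESCALE_EPS)
        star = np.clip(star_raw, _RESCALE_EPS, 1.0 - _RESCALE_EPS)
        if self.kind == "P_beta_fixed":
            # exponents (alpha - 1, beta - 1) on every component
            am1 = np.full(lam.size, self.alpha - 1.0)
            bm1 = np.full(lam.size, self.beta - 1.0)
        else:  # P_beta_order: exponents (z + i - 1, z + q - i) by ascending rank i
            order = np.argsort(star, kind="stable")
            rank = np.empty(lam.size, dtype=float)
            rank[order] = np.arange(lam.size)  # 0-based rank = i - 1
            am1 = self.z + rank
            bm1 = self.z + lam.size - 1.0 - rank
        grad = -psi_G * (am1 / star - bm1 / (1.0 - star)) / rng
        grad[clamped] = 0.0
        return grad

    def _matrix_parts(self, sigma_G, sigma_E):
        """[(logdet, trace)] for the one or two inverse-Wishart parts."""
        base = self._require_baseline()
        if self.kind in ("P_Sigma", "P_Sigma2"):
            target = base.sigma_P0
            mats = [sigma_G] if self.kind == "P_Sigma" else [sigma_G, sigma_E]
        else:
            target = base.R_P0
            mats = [correlation_from_covariance(sigma_G)]
            if self.kind == "P_rho2":
                mats.append(correlation_from_covariance(sigma_E))
        return [_logdet_trace_inv(m, target) for m in mats]


def _iw_weight(psi: float, q: int, c_approx_one: bool) -> float:
    if c_approx_one:
        return 1.0
    if psi <= 0.0:
        raise ConfigurationError("C = (psi + q + 1)/psi is undefined at psi = 0")
    return (psi + q + 1) / psi


def _pd_inverse(S: np.ndarray) -> np.ndarray:
    c, info = scipy.linalg.lapack.dpotrf(S, lower=1)
    if info != 0:
        raise BoundaryError("matrix penalty gradient at a non-PD matrix")
    linv, info = scipy.linalg.lapack.dtrtri(c, lower=1)
    if info != 0:
        raise BoundaryError("matrix penalty gradient at a singular matrix")
    return linv.T @ linv


def _iw_grad(S: np.ndarray, target: np.ndarray, c_logdet: float,
             c_trace: float) -> np.ndarray:
    """d/dS of c_logdet * log|S| + c_trace * tr(S^-1 target)."""
    Sinv = _pd_inverse(S)
    return c_logdet * Sinv - c_trace * (Sinv @ target @ Sinv)


def _iw_corr_grad(S: np.ndarray, target: np.ndarray, c_logdet: float,
                  c_trace: float) -> np.ndarray:
    """Same as :func:`_iw_grad` but for the penalty on the correlation
    matrix R = D^-1/2 S D^-1/2 of S, chained back to S.

    With K = dP/dR, the chain rule gives
    dP/dS = D^-1/2 K D^-1/2 - diag(diag(K R) / diag(S)).
    """
    d = np.diag(S)
    if np.any(d <= 0.0):
        raise BoundaryError("non-positive variance while forming correlations")
    inv_sd = 1.0 / np.sqrt(d)
    R = S * np.outer(inv_sd, inv_sd)
    np.fill_diagonal(R, 1.0)
    K = _iw_grad(R, target, c_logdet, c_trace)
    G = K * np.outer(inv_sd, inv_sd)
    G = G - np.diag(np.diag(K @ R) / d)
    return 0.5 * (G + G.T)


def _logdet_trace_inv(S: np.ndarray, target: np.ndarray):
    """(log|S|, tr(S^-1 target)); BoundaryError if S is not PD."""
    c, info = scipy.linalg.lapack.dpotrf(S, lower=1)
    if info != 0:
        raise BoundaryError("matrix penalty evaluated at a non-PD matrix")
    linv, info = scipy.linalg.lapack.dtrtri(c, lower=1)
    if info != 0:
        raise BoundaryError("matrix penalty evaluated at a singular matrix")
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    Sinv = linv.T @ linv
    trace = float(np.sum(Sinv * target))
    return logdet, trace


# ----------------------------------------------------------------------
# eigenvalue penalties


def p_lambda(lambdas: np.ndarray) -> float:
    """Variance-style penalty sum_i (lambda_i - mean)^2 ('bending')."""
    lam = np.asarray(lambdas, dtype=float)
    return float(np.sum((lam - lam.mean()) ** 2))


def _check_open_unit(lam: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0) or np.any(lam >= 1.0):
        raise BoundaryError("log-scale penalties need eigenvalues strictly inside (0, 1)")
    return lam


def p_lambda_log(lambdas: np.ndarray) -> float:
    """Variance of log(lambda_i) around its mean."""
    lam = _check_open_unit(lambdas)
    logs = np.log(lam)
    return float(np.sum((logs - logs.mean()) ** 2))


def p_lambda_log2(lambdas: np.ndarray) -> float:
    """Variance of log(lambda_i) plus variance of log(1 - lambda_i)."""
    lam = _check_open_unit(lambdas)
    return p_lambda_log(lam) + p_lambda_log(1.0 - lam)


def rescale_to_baseline_range(lambdas: np.ndarray, baseline: PenaltyBaseline) -> np.ndarray:
    """lambda* = (lambda - lambda_q^0) / (lambda_1^0 - lambda_q^0), clamped.

    During optimization an eigenvalue may leave the unpenalized range, which
    the range estimate only covers approximately; values are clamped to
    [eps, 1 - eps] (eps = 1e-6) so the log kernels stay finite.
    """
    lo, hi = baseline.lambda_q, baseline.lambda_1
    if hi - lo <= 1e-10:
        raise ConfigurationError(
            "degenerate baseline eigenvalue range; rescaled beta penalties "
            "are not applicable"
        )
    star = (np.asarray(lambdas, dtype=float) - lo) / (hi - lo)
    return np.clip(star, _RESCALE_EPS, 1.0 - _RESCALE_EPS)


def p_beta_fixed(lambdas: np.ndarray, spec: PenaltySpec) -> float:
    """Negative log beta kernel on range-rescaled eigenvalues (fixed shapes)."""
    base = spec._require_baseline()
    star = rescale_to_baseline_range(lambdas, base)
    a, b = spec.alpha, spec.beta
    return float(-np.sum((a - 1.0) * np.log(star) + (b - 1.0) * np.log1p(-star)))


def estimate_beta_shapes(lambdas0: np.ndarray) -> tuple[float, float]:
    """Method-of-moments beta shapes from unpenalized eigenvalues.

    ``v = q * mean(1 - mean) / sum((lambda_i - mean)^2) - 1``, then
    ``alpha = mean * v`` and ``beta = (1 - mean) * v``.
    """
    lam = np.asarray(lambdas0, dtype=float)
    if lam.size < 2:
        raise ConfigurationError("need at least two eigenvalues")
    mean = float(lam.mean())
    if not 0.0 < mean < 1.0:
        raise ConfigurationError("mean eigenvalue must lie in (0, 1)")
    spread = float(np.sum((lam - mean) ** 2))
    if spread <= 1e-10:
        raise ConfigurationError(
            "zero spread among eigenvalues; moment estimators are undefined"
        )
    v = lam.size * mean * (1.0 - mean) / spread - 1.0
    if v <= 0.0:
        raise ConfigurationError(
            "eigenvalue spread exceeds that of any beta distribution"
        )
    return mean * v, (1.0 - mean) * v


def p_beta_mom(lambdas: np.ndarray, spec: PenaltySpec) -> float:
    """Negative log beta kernel with moment shapes, acting on lambda directly.

    Exponents are (alpha + z - 1) and (beta + z - 1); the constant z >= 0
    guarantees a uni-modal kernel even when the moment estimates fall below
    one.
    """
    base = spec._require_baseline()
    if base.alpha_mom is None:
        raise ConfigurationError("baseline lacks moment-estimated beta shapes")
    lam = _check_open_unit(lambdas)
    a = base.alpha_mom + spec.z - 1.0
    b = base.beta_mom + spec.z - 1.0
    return float(-np.sum(a * np.log(lam) + b * np.log1p(-lam)))


def p_beta_order(lambdas: np.ndarray, spec: PenaltySpec) -> float:
    """Order-statistic beta kernels on range-rescaled eigenvalues.

    The i-th smallest rescaled eigenvalue receives shape parameters
    (z + i - 1, z + q - i) in the negative-log kernel, the marginal
    distribution of uniform order statistics when z = 0.
    """
    base = spec._require_baseline()
    star = np.sort(rescale_to_baseline_range(lambdas, base))  # ascending
    q = star.size
    i = np.arange(1, q + 1, dtype=float)
    a = spec.z + i - 1.0
    b = spec.z + q - i
    return float(-np.sum(a * np.log(star) + b * np.log1p(-star)))


# ----------------------------------------------------------------------
# matrix-divergence penalties (functional forms; dispatch via PenaltySpec)


def p_sigma(pair: CovariancePair, spec: PenaltySpec, psi: float) -> float:
    """C log|sigma_G| + tr(sigma_G^-1 sigma_P^0), C = (psi + q + 1)/psi."""
    return replace(spec, kind="P_Sigma", separate_tuning=False).value(pair=pair, psi=psi)


def p_sigma2(pair: CovariancePair, spec: PenaltySpec, psi) -> float:
    """Two-part inverse-Wishart penalty on sigma_G and sigma_E."""
    return replace(spec, kind="P_Sigma2").value(pair=pair, psi=psi)


def p_rho(pair: CovariancePair, spec: PenaltySpec, psi: float) -> float:
    """C log|R_G| + tr(R_G^-1 R_P^0): shrink genetic toward phenotypic correlations."""
    return replace(spec, kind="P_rho", separate_tuning=False).value(pair=pair, psi=psi)


def p_rho2(pair: CovariancePair, spec: PenaltySpec, psi) -> float:
    """Two-part correlation-divergence penalty on R_G and R_E."""
    return replace(spec, kind="P_rho2").value(pair=pair, psi=psi)
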