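"""REML log-likelihood for balanced paternal half-sib designs.

For ``s`` unrelated sires with ``n`` progeny each, the data are summarized
without loss by the between- and within-sire mean-square/cross-product
matrices M_B and M_W of a one-way MANOVA.  With sire variance sigma_G / 4,
the two strata have expectations

    Sigma_W = sigma_E + (3/4) sigma_G        (within sires)
    Sigma_B = Sigma_W + (n/4) sigma_G        (between sires)

and the REML log-likelihood, apart from a constant, is

    logL = -1/2 [ (s-1) (log|Sigma_B| + tr(Sigma_B^-1 M_B))
                + s(n-1) (log|Sigma_W| + tr(Sigma_W^-1 M_W)) ].

Penalized estimation maximizes logL_P = logL - (psi/2) P(theta) for a
penalty P and tuning factor psi >= 0; psi = 0 recovers standard REML.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .core import CovariancePair
from .exceptions import BoundaryError, InvalidInputError

__all__ = [
    "HalfSibStats",
    "stats_from_families",
    "reml_loglik",
    "penalized_loglik",
    "record_loglik_oracle",
]


@dataclass(frozen=True)
class HalfSibStats:
    """Sufficient statistics of a balanced half-sib dataset.

    Parameters
    ----------
    s, n
        Number of sires and progeny per sire (s >= 2, n >= 2).
    M_B, M_W
        Between- and within-sire mean-square/cross-product matrices with
        s - 1 and s(n - 1) degrees of freedom respectively.
    family_means, family_sscp
        Optional per-family summaries (s x q means, s x q x q within-family
        SSCP matrices) retained so that cross-validation can re-pool
        arbitrary subsets of complete sire families.
    """

    s: int
    n: int
    M_B: np.ndarray
    M_W: np.ndarray
    family_means: Optional[np.ndarray] = None
    family_sscp: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.s < 2 or self.n < 2:
            raise InvalidInputError(f"need s >= 2 and n >= 2, got s={self.s}, n={self.n}")
        M_B = np.atleast_2d(np.asarray(self.M_B, dtype=float))
        M_W = np.atleast_2d(np.asarray(self.M_W, dtype=float))
        for name, m in (("M_B", M_B), ("M_W", M_W)):
            if m.shape[0] != m.shape[1] or not np.all(np.isfinite(m)):
                raise InvalidInputError(f"{name} must be a finite square matrix")
            if not np.allclose(m, m.T, rtol=1e-8, atol=1e-10):
                raise InvalidInputError(f"{name} must be symmetric")
        if M_B.shape != M_W.shape:
            raise InvalidInputError("M_B and M_W must have equal shape")
        object.__setattr__(self, "M_B", 0.5 * (M_B + M_B.T))
        object.__setattr__(self, "M_W", 0.5 * (M_W + M_W.T))
        if self.family_means is not None:
            fm = np.asarray(self.family_means, dtype=float)
            fs = np.asarray(self.family_sscp, dtype=float)
            if fm.shape != (self.s, self.q) or fs.shape != (self.s, self.q, self.q):
                raise InvalidInputError("family summaries have inconsistent shapes")
            object.__setattr__(self, "family_means", fm)
            object.__setattr__(self, "family_sscp", fs)

    @property
    def q(self) -> int:
        return self.M_B.shape[0]

    @property
    def has_families(self) -> bool:
        return self.family_means is not None

    def subset(self, idx: Sequence[int]) -> "HalfSibStats":
        """Re-pool a subset of complete families into new statistics."""
        if not self.has_families:
            raise InvalidInputError("no per-family summaries available")
        idx = np.asarray(idx, dtype=int)
        return stats_from_families(self.family_means[idx], self.family_sscp[idx], self.n)


def stats_from_families(means: np.ndarray, sscp: np.ndarray, n: int) -> HalfSibStats:
    """Pool per-family means and within-family SSCP matrices.

    ``M_W`` is the pooled within SSCP divided by s(n-1); ``M_B`` is
    n * sum_i (ybar_i - ybar)(ybar_i - ybar)' / (s-1).
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    sscp = np.asarray(sscp, dtype=float)
    s = means.shape[0]
    if s < 2:
        raise InvalidInputError("need at least two families")
    centred = means - means.mean(axis=0)
    M_B = n * (centred.T @ centred) / (s - 1)
    M_W = sscp.sum(axis=0) / (s * (n - 1))
    return HalfSibStats(
        s=s, n=n, M_B=M_B, M_W=M_W, family_means=means, family_sscp=sscp
    )


def strata_covariances(sigma_G: np.ndarray, sigma_E: np.ndarray, n: int):
    """(Sigma_W, Sigma_B) implied by a parameter pair for family size n."""
    Sigma_W = sigma_E + 0.75 * sigma_G
    Sigma_B = Sigma_W + 0.25 * n * sigma_G
    return Sigma_W, Sigma_B


def _logdet_and_trace(Sigma: np.ndarray, M: np.ndarray):
    """(log|Sigma|, tr(Sigma^-1 M)) via Cholesky; None if Sigma not PD.

    Uses raw LAPACK (dpotrf/dtrtri) to keep overhead low in the
    optimizer's hot loop.
    """
    c, info = scipy.linalg.lapack.dpotrf(Sigma, lower=1)
    if info != 0:
        return None
    linv, info = scipy.linalg.lapack.dtrtri(c, lower=1)
    if info != 0:
        return None
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    Sinv = linv.T @ linv
    trace = float(np.sum(Sinv * M))
    return logdet, trace


def loglik_mats(sigma_G: np.ndarray, sigma_E: np.ndarray, stats: HalfSibStats):
    """Raw-array likelihood; returns -inf when Sigma_W or Sigma_B is not PD.

    Fast path shared by :func:`reml_loglik` and the optimizer.
    """
    Sigma_W, Sigma_B = strata_covariances(sigma_G, sigma_E, stats.n)
    b = _logdet_and_trace(Sigma_B, stats.M_B)
    if b is None:
        return -np.inf
    w = _logdet_and_trace(Sigma_W, stats.M_W)
    if w is None:
        return -np.inf
    s, n = stats.s, stats.n
    return -0.5 * ((s - 1) * (b[0] + b[1]) + s * (n - 1) * (w[0] + w[1]))


def reml_loglik(pair: CovariancePair, stats: HalfSibStats) -> float:
    """Balanced half-sib REML log-likelihood (up to an additive constant).

    Raises
    ------
    BoundaryError
        If Sigma_W or Sigma_B is not positive definite at ``pair``.
    """
    value = loglik_mats(pair.sigma_G, pair.sigma_E, stats)
    if not np.isfinite(value):
        raise BoundaryError("Sigma_W or Sigma_B not positive definite")
    return float(value)


def penalized_loglik(pair: CovariancePair, stats: HalfSibStats, psi, penalty) -> float:
    """Penalized objective logL_P = logL - (psi/2) P(theta).

    ``psi = 0`` (or ``penalty is None``) bypasses the penalty entirely and
    returns the unpenalized likelihood.  ``psi`` may be a scalar or, for the
    two-part penalties with separate tuning, a (psi_G, psi_E) pair.
    """
    base = reml_loglik(pair, stats)
    if penalty is None or _psi_is_zero(psi):
        return base
    scaled = penalty.scaled_value(pair=pair, psi=psi)
    return base - 0.5 * scaled


def _psi_is_zero(psi) -> bool:
    return float(np.max(np.atleast_1d(np.asarray(psi, dtype=float)))) == 0.0


def record_loglik_oracle(records, pair: CovariancePair) -> float:
    """Direct multivariate-normal REML likelihood of a tiny balanced dataset.

    Builds the full (s n q) covariance matrix of the stacked records with a
    per-trait overall mean as the only fixed effect and evaluates
    -1/2 [log|V| + log|X'V^-1 X| + r'V^-1 r].  Differs from
    :func:`reml_loglik` on the matching sufficient statistics by a constant
    that does not depend on (sigma_G, sigma_E).  Intended for validation on
    tiny problems only (s * n * q up to a few hundred).
    """
    y = np.asarray(records, dtype=float)
    if y.ndim != 3:
        raise InvalidInputError("records must have shape (s, n, q): balanced design")
    s, n, q = y.shape
    if s * n * q > 2000:
        raise InvalidInputError("record-level oracle is restricted to tiny datasets")
    Sigma_W, _ = strata_covariances(pair.sigma_G, pair.sigma_E, n)
    # per-sire covariance block: J_n x sigma_G/4 + I_n x Sigma_W
    block = np.kron(np.ones((n, n)), pair.sigma_G / 4.0) + np.kron(np.eye(n), Sigma_W)
    V = np.kron(np.eye(s), block)
    X = np.tile(np.eye(q), (s * n, 1))
    yvec = y.reshape(s * n * q)
    c, low = scipy.linalg.cho_factor(V, lower=True)
    Vinv_X = scipy.linalg.cho_solve((c, low), X)
    XtVinvX = X.T @ Vinv_X
    beta = np.linalg.solve(XtVinvX, Vinv_X.T @ yvec)
    resid = yvec - X @ beta
    quad = float(resid @ scipy.linalg.cho_solve((c, low), resid))
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    logdet_X = float(np.linalg.slogdet(XtVinvX)[1])
    return -0.5 * (logdet_V + logdet_X + quad)
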