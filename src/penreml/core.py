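"""Covariance pairs and the canonical decomposition.

The parameter state of a multivariate quantitative-genetic analysis is the
pair of genetic and residual covariance matrices (sigma_G, sigma_E) among q
traits, with phenotypic covariance sigma_P = sigma_G + sigma_E.  The
canonical decomposition simultaneously diagonalizes the pair,

    sigma_G = T diag(lambda) T'      sigma_E = T diag(1 - lambda) T',

where the canonical eigenvalues lambda_i are the eigenvalues of
sigma_P^{-1} sigma_G and T T' = sigma_P.  For a single trait the canonical
eigenvalue is the heritability; for valid models all lambda_i lie in [0, 1].
This parameterisation underpins both the eigenvalue-shrinkage penalties and
the bounded-eigenvalue REML optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .exceptions import DegenerateTraitError, DomainError, InvalidInputError

__all__ = [
    "CovariancePair",
    "CanonicalForm",
    "CorrelationSet",
    "canonical_decompose",
    "canonical_compose",
    "to_correlations",
    "heritabilities",
    "correlation_from_covariance",
]

#: relative tolerance for positive semi-definiteness checks: the smallest
#: eigenvalue may be as low as -PSD_RTOL times the largest one.
PSD_RTOL = 1e-8

#: absolute tolerance for canonical eigenvalues straying outside [0, 1]
EIG_TOL = 1e-8


def _as_symmetric(mat, name: str) -> np.ndarray:
    arr = np.asarray(mat, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1, 1)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise InvalidInputError(f"{name} must be a square matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite entries")
    if not np.allclose(arr, arr.T, rtol=1e-8, atol=1e-10):
        raise InvalidInputError(f"{name} is not symmetric")
    return 0.5 * (arr + arr.T)


def _check_psd(mat: np.ndarray, name: str, *, strict: bool) -> None:
    eig = np.linalg.eigvalsh(mat)
    scale = max(eig[-1], 0.0)
    tol = PSD_RTOL * max(scale, 1.0)
    if strict:
        # positive definite beyond round-off noise
        if eig[0] <= tol:
            raise InvalidInputError(
                f"{name} must be positive definite (min eigenvalue {eig[0]:.3e})"
            )
    elif eig[0] < -tol:
        raise InvalidInputError(
            f"{name} must be positive semi-definite (min eigenvalue {eig[0]:.3e})"
        )


@dataclass(frozen=True)
class CovariancePair:
    """Genetic and residual covariance matrices for ``q`` traits.

    Parameters
    ----------
    sigma_G
        Symmetric q x q additive-genetic covariance matrix (trait units^2);
        must be positive semi-definite.
    sigma_E
        Symmetric q x q residual covariance matrix; must be positive
        definite.
    """

    sigma_G: np.ndarray
    sigma_E: np.ndarray

    def __post_init__(self):
        g = _as_symmetric(self.sigma_G, "sigma_G")
        e = _as_symmetric(self.sigma_E, "sigma_E")
        if g.shape != e.shape:
            raise InvalidInputError("sigma_G and sigma_E must have the same shape")
        # sigma_E may sit on the boundary (all canonical eigenvalues = 1),
        # but the phenotypic matrix must be strictly positive definite.
        _check_psd(g, "sigma_G", strict=False)
        _check_psd(e, "sigma_E", strict=False)
        _check_psd(g + e, "sigma_P", strict=True)
        object.__setattr__(self, "sigma_G", g)
        object.__setattr__(self, "sigma_E", e)

    @property
    def q(self) -> int:
        return self.sigma_G.shape[0]

    @property
    def sigma_P(self) -> np.ndarray:
        """Phenotypic covariance matrix sigma_G + sigma_E."""
        return self.sigma_G + self.sigma_E


@dataclass(frozen=True)
class CanonicalForm:
    """Canonical eigenvalues (descending) and transformation matrix T."""

    lambdas: np.ndarray
    T: np.ndarray

    def __post_init__(self):
        lam = np.atleast_1d(np.asarray(self.lambdas, dtype=float))
        T = np.atleast_2d(np.asarray(self.T, dtype=float))
        if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(T))):
            raise InvalidInputError("canonical form contains non-finite entries")
        if T.shape != (lam.size, lam.size):
            raise InvalidInputError("T must be q x q with q = len(lambdas)")
        object.__setattr__(self, "lambdas", lam)
        object.__setattr__(self, "T", T)

    @property
    def q(self) -> int:
        return self.lambdas.size


@dataclass(frozen=True)
class CorrelationSet:
    """Genetic, residual and phenotypic correlation matrices."""

    R_G: np.ndarray
    R_E: np.ndarray
    R_P: np.ndarray


def canonical_decompose(pair: CovariancePair) -> CanonicalForm:
    """Decompose (sigma_G, sigma_E) into canonical eigenvalues and T.

    Solves the symmetric generalized eigenproblem ``sigma_G v = lambda
    sigma_P v`` (numerically via :func:`scipy.linalg.eigh`), which is the
    stable equivalent of diagonalizing the nonsymmetric sigma_P^{-1} sigma_G.
    Eigenvalues are returned in descending order; column signs of T are fixed
    by making the largest-magnitude element of each column positive so that
    the decomposition is deterministic.

    Raises
    ------
    InvalidInputError
        If sigma_P is numerically singular.
    DomainError
        If any canonical eigenvalue lies outside [0, 1] by more than a small
        numerical tolerance (sigma_G is then not a valid genetic fraction of
        sigma_P); values inside the tolerance are clipped.
    """
    sigma_P = pair.sigma_P
    try:
        lam, V = scipy.linalg.eigh(pair.sigma_G, sigma_P)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as err:
        raise InvalidInputError(f"sigma_P is singular: {err}") from err
    # eigh returns ascending eigenvalues with V' sigma_P V = I; flip to
    # descending and take T = inv(V)' so that T T' = sigma_P.
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    V = V[:, order]
    if np.any(lam < -EIG_TOL) or np.any(lam > 1.0 + EIG_TOL):
        raise DomainError(
            "canonical eigenvalues outside [0, 1]: "
            f"range [{lam.min():.6g}, {lam.max():.6g}]"
        )
    lam = np.clip(lam, 0.0, 1.0)
    T = np.linalg.inv(V).T
    # deterministic sign convention per column
    idx = np.argmax(np.abs(T), axis=0)
    signs = np.sign(T[idx, np.arange(T.shape[1])])
    signs[signs == 0] = 1.0
    T = T * signs
    return CanonicalForm(lambdas=lam, T=T)


def canonical_compose(form: CanonicalForm) -> CovariancePair:
    """Rebuild (sigma_G, sigma_E) from canonical eigenvalues and T.

    ``sigma_G = T diag(lambda) T'`` and ``sigma_E = T diag(1 - lambda) T'``.
    """
    lam = form.lambdas
    if np.any(lam < -EIG_TOL) or np.any(lam > 1.0 + EIG_TOL):
        raise DomainError("lambdas must lie in [0, 1]")
    lam = np.clip(lam, 0.0, 1.0)
    T = form.T
    sigma_G = (T * lam) @ T.T
    sigma_E = (T * (1.0 - lam)) @ T.T
    sigma_G = 0.5 * (sigma_G + sigma_G.T)
    sigma_E = 0.5 * (sigma_E + sigma_E.T)
    return CovariancePair(sigma_G=sigma_G, sigma_E=sigma_E)


def compose_matrices(lambdas: np.ndarray, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw (sigma_G, sigma_E) arrays from eigenvalues and T, no validation.

    Fast path used inside optimization loops where the inputs are feasible
    by construction.
    """
    sigma_G = (T * lambdas) @ T.T
    sigma_E = (T * (1.0 - lambdas)) @ T.T
    return 0.5 * (sigma_G + sigma_G.T), 0.5 * (sigma_E + sigma_E.T)


def correlation_from_covariance(mat: np.ndarray) -> np.ndarray:
    """Correlation matrix R[i,j] = M[i,j] / sqrt(M[i,i] M[j,j])."""
    mat = np.asarray(mat, dtype=float)
    d = np.diag(mat)
    if np.any(d <= 0.0):
        raise DegenerateTraitError(
            "zero or negative variance on the diagonal; correlations undefined"
        )
    inv_sd = 1.0 / np.sqrt(d)
    R = mat * np.outer(inv_sd, inv_sd)
    np.fill_diagonal(R, 1.0)
    return R


def to_correlations(pair: CovariancePair) -> CorrelationSet:
    """Genetic, residual and phenotypic correlation matrices of a pair."""
    return CorrelationSet(
        R_G=correlation_from_covariance(pair.sigma_G),
        R_E=correlation_from_covariance(pair.sigma_E),
        R_P=correlation_from_covariance(pair.sigma_P),
    )


def heritabilities(pair: CovariancePair) -> np.ndarray:
    """Per-trait heritabilities h2_i = sigma_G[i,i] / sigma_P[i,i]."""
    var_P = np.diag(pair.sigma_P)
    if np.any(var_P <= 0.0):
        raise DegenerateTraitError("non-positive phenotypic variance")
    return np.diag(pair.sigma_G) / var_P
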