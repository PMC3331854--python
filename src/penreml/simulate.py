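"""Simulation of balanced paternal half-sib data.

Families are multivariate normal: the i-th sire contributes an effect
g_i ~ N(0, sigma_G / 4), progeny deviate with within-family covariance
Sigma_W = sigma_E + (3/4) sigma_G, so family means have covariance
Sigma_B / n and the pooled within-family SSCP is Wishart(Sigma_W, s(n-1)).

Two generators are provided.  The default, family-level generator draws
each family's mean and within-family SSCP directly (normal + Bartlett
Wishart), which is exact in distribution, fast, and keeps the per-family
summaries cross-validation needs.  The record-level generator draws every
progeny record; it is used to validate the fast generator and the
likelihood, and whenever raw records are wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .exceptions import InvalidInputError
from .likelihood import HalfSibStats, stats_from_families, strata_covariances
from .scenarios import PopulationScenario

__all__ = [
    "SimConfig",
    "simulate_dataset",
    "simulate_records",
    "records_to_stats",
    "validation_stats",
]


@dataclass(frozen=True)
class SimConfig:
    """Size and seeding of a simulated half-sib study."""

    s: int
    n: int = 10
    replicates: int = 1
    seed: Optional[int] = None

    def __post_init__(self):
        if self.s < 2 or self.n < 2:
            raise InvalidInputError(
                f"need s >= 2 sires and n >= 2 progeny, got s={self.s}, n={self.n}"
            )
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")


def _rng(config: SimConfig, rng: Union[np.random.Generator, int, None]):
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is not None:
        return np.random.default_rng(rng)
    return np.random.default_rng(config.seed)


def _wishart_bartlett(rng: np.random.Generator, chol: np.ndarray, df: int,
                      size: int) -> np.ndarray:
    """``size`` draws from Wishart(chol chol', df), shape (size, q, q).

    Uses the Bartlett decomposition for df >= q and a sum of df outer
    products of normal vectors otherwise (integer df).
    """
    q = chol.shape[0]
    if df >= q:
        A = np.zeros((size, q, q))
        rows, cols = np.tril_indices(q, k=-1)
        if rows.size:
            A[:, rows, cols] = rng.standard_normal((size, rows.size))
        diag_df = df - np.arange(q)
        A[:, np.arange(q), np.arange(q)] = np.sqrt(
            rng.chisquare(diag_df, size=(size, q))
        )
        L = chol @ A
        return L @ L.transpose(0, 2, 1)
    X = rng.standard_normal((size, df, q)) @ chol.T
    return X.transpose(0, 2, 1) @ X


def simulate_dataset(scenario: PopulationScenario, config: SimConfig,
                     rng: Union[np.random.Generator, int, None] = None) -> HalfSibStats:
    """Draw one balanced half-sib dataset as sufficient statistics.

    Family means and within-family SSCP matrices are sampled exactly from
    their joint distribution under the scenario truth; per-family summaries
    are retained so folds of complete families can be re-pooled.
    """
    gen = _rng(config, rng)
    s, n = config.s, config.n
    truth = scenario.truth
    Sigma_W, Sigma_B = strata_covariances(truth.sigma_G, truth.sigma_E, n)
    chol_mean = np.linalg.cholesky(Sigma_B / n)
    means = gen.standard_normal((s, truth.q)) @ chol_mean.T
    chol_W = np.linalg.cholesky(Sigma_W)
    sscp = _wishart_bartlett(gen, chol_W, n - 1, s)
    return stats_from_families(means, sscp, n)


def simulate_records(scenario: PopulationScenario, config: SimConfig,
                     rng: Union[np.random.Generator, int, None] = None) -> np.ndarray:
    """Draw raw progeny records, shape (s, n, q), mean zero."""
    gen = _rng(config, rng)
    s, n = config.s, config.n
    truth = scenario.truth
    q = truth.q
    Sigma_W, _ = strata_covariances(truth.sigma_G, truth.sigma_E, n)
    chol_G4 = np.linalg.cholesky(truth.sigma_G / 4.0 + 1e-14 * np.eye(q))
    chol_W = np.linalg.cholesky(Sigma_W)
    sire = gen.standard_normal((s, q)) @ chol_G4.T
    within = gen.standard_normal((s, n, q)) @ chol_W.T
    return sire[:, None, :] + within


def records_to_stats(records: np.ndarray, *, check_balance: bool = True) -> HalfSibStats:
    """One-way MANOVA sufficient statistics from an (s, n, q) record array."""
    y = np.asarray(records, dtype=float)
    if y.ndim != 3:
        raise InvalidInputError("records must have shape (s, n, q)")
    s, n, _ = y.shape
    means = y.mean(axis=1)
    centred = y - means[:, None, :]
    sscp = np.einsum("snq,snr->sqr", centred, centred)
    return stats_from_families(means, sscp, n)


def validation_stats(scenario: PopulationScenario, config: SimConfig) -> HalfSibStats:
    """Noiseless validation statistics M_B = Sigma_B, M_W = Sigma_W.

    Equivalent to averaging infinitely many additional samples; used by the
    V-infinity tuning strategy.  Deterministic: no randomness enters.
    """
    truth = scenario.truth
    Sigma_W, Sigma_B = strata_covariances(truth.sigma_G, truth.sigma_E, config.n)
    return HalfSibStats(s=config.s, n=config.n, M_B=Sigma_B, M_W=Sigma_W)
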