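"""Selection of the tuning factor psi.

Four strategies are provided, each picking a value from the psi grid:

* ``V-infinity``: maximize the unpenalized likelihood of each path estimate
  on noiseless validation statistics built from the population parameters
  (M_B = Sigma_B, M_W = Sigma_W) — the oracle available in simulations.
* ``V1``: the same with a single independently sampled validation dataset.
* ``CV(K)``: K-fold cross-validation, folds formed by sequentially
  assigning complete sire families; the across-fold mean of the held-out
  unpenalized likelihood is maximized.  Penalty baselines are re-derived
  inside each training fold so no information leaks from the held-out data.
* ``L-limit``: the largest psi whose unpenalized-likelihood drop from the
  psi = 0 maximum stays within delta; delta = 1.92 (half the 5% chi-square
  critical value with one degree of freedom) keeps the change statistically
  non-significant — the pragmatic "mild penalty" choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimator import FitPath, fit_path
from .exceptions import ConfigurationError
from .likelihood import HalfSibStats, reml_loglik
from .penalties import PenaltySpec

__all__ = [
    "build_psi_grid",
    "thin_grid",
    "TuningChoice",
    "choose_validation",
    "choose_cv",
    "choose_likelihood_limit",
    "cv_folds",
]

#: default likelihood-drop limit: half the 5% chi-square(1) critical value
LIKELIHOOD_DROP_LIMIT = 1.92

_GRID_SEGMENTS = (
    (0.0, 2.0, 0.1),
    (2.2, 5.0, 0.2),
    (5.5, 10.0, 0.5),
    (11.0, 100.0, 1.0),
    (102.0, 250.0, 2.0),
    (255.0, 500.0, 5.0),
    (510.0, 1000.0, 10.0),
)


def build_psi_grid() -> np.ndarray:
    """The standard 311-value tuning-factor grid.

    Segments: 0-2 by 0.1, 2.2-5 by 0.2, 5.5-10 by 0.5, 11-100 by 1,
    102-250 by 2, 255-500 by 5 and 510-1000 by 10.
    """
    values = []
    for lo, hi, step in _GRID_SEGMENTS:
        count = int(round((hi - lo) / step)) + 1
        values.extend(round(lo + k * step, 10) for k in range(count))
    grid = np.asarray(values, dtype=float)
    assert grid.size == 311 and np.all(np.diff(grid) > 0)
    return grid


def thin_grid(grid: np.ndarray, every: int) -> np.ndarray:
    """Coarsen a psi grid for scaled-down experiments.

    Keeps every ``every``-th value *within each constant-step segment* of
    the grid (plus the final point), so the dense low-psi region — where
    selection concentrates for spread-eigenvalue scenarios — retains
    proportionate resolution.
    """
    grid = np.asarray(grid, dtype=float)
    if every <= 1:
        return grid.copy()
    steps = np.round(np.diff(grid), 10)
    breaks = np.flatnonzero(np.diff(steps) != 0.0) + 1
    keep: list[float] = []
    start = 0
    for stop in list(breaks + 1) + [grid.size]:
        keep.extend(grid[start:stop:every])
        start = stop
    if keep[-1] != grid[-1]:
        keep.append(grid[-1])
    return np.unique(np.asarray(keep))


@dataclass(frozen=True)
class TuningChoice:
    """Chosen tuning factor plus the selection-criterion curve."""

    strategy: str
    psi_chosen: float
    index: int
    criterion_curve: np.ndarray


def choose_validation(path: FitPath, val_stats: HalfSibStats,
                      strategy: str = "Vinf") -> TuningChoice:
    """Pick psi maximizing the unpenalized likelihood on validation data.

    ``val_stats`` is either the noiseless population construction
    (V-infinity) or one extra simulated dataset (V1).
    """
    if not path.fits:
        raise ConfigurationError("empty fit path")
    curve = np.array([reml_loglik(f.pair, val_stats) for f in path.fits])
    idx = int(np.argmax(curve))
    return TuningChoice(strategy=strategy, psi_chosen=float(path.psi_grid[idx]),
                        index=idx, criterion_curve=curve)


def cv_folds(s: int, K: int) -> list[np.ndarray]:
    """Fold membership by sequential assignment: family i -> fold i mod K."""
    if K < 2:
        raise ConfigurationError("cross-validation needs K >= 2")
    if s < 2 * K:
        raise ConfigurationError(f"need at least 2 families per fold: s={s}, K={K}")
    idx = np.arange(s)
    return [idx[idx % K == k] for k in range(K)]


def choose_cv(family_data: HalfSibStats, K: int, penalty: PenaltySpec,
              psi_grid, **fit_kwargs) -> TuningChoice:
    """K-fold cross-validation over complete sire families.

    For each fold, a full psi path is fitted on the complementary families
    (with penalty baselines re-derived from that training fold) and the
    unpenalized likelihood of every path estimate is evaluated on the
    held-out fold's own statistics; psi maximizing the across-fold mean is
    chosen.
    """
    if not family_data.has_families:
        raise ConfigurationError("cross-validation needs per-family summaries")
    folds = cv_folds(family_data.s, K)
    grid = np.asarray(psi_grid, dtype=float)
    all_idx = np.arange(family_data.s)
    curves = []
    for fold in folds:
        train = family_data.subset(np.setdiff1d(all_idx, fold))
        val = family_data.subset(fold)
        path = fit_path(train, penalty, grid, **fit_kwargs)
        curves.append([reml_loglik(f.pair, val) for f in path.fits])
    mean_curve = np.mean(np.asarray(curves), axis=0)
    idx = int(np.argmax(mean_curve))
    return TuningChoice(strategy=f"CV{K}", psi_chosen=float(grid[idx]),
                        index=idx, criterion_curve=mean_curve)


def choose_likelihood_limit(path: FitPath,
                            delta: float = LIKELIHOOD_DROP_LIMIT) -> TuningChoice:
    """Largest grid psi whose unpenalized-likelihood drop stays within delta.

    The rule is literal: the largest satisfying psi is taken even when the
    drop curve is non-monotone and smaller grid values violate the bound.
    psi = 0 always satisfies it.
    """
    if not path.fits:
        raise ConfigurationError("empty fit path")
    logL0 = path.baseline.logL
    drops = np.abs(np.array([f.logL for f in path.fits]) - logL0)
    ok = np.flatnonzero(drops <= delta)
    idx = int(ok[-1])
    return TuningChoice(strategy=f"L(delta={delta:g})",
                        psi_chosen=float(path.psi_grid[idx]),
                        index=idx, criterion_curve=drops)
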