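"""Losses, PRIAL, bias summaries and the replicate-level experiment runner.

The quality of an estimate is measured against the population truth by the
entropy and quadratic losses

    L1(S, Shat) = tr(S^-1 Shat) - log|S^-1 Shat| - q
    L2(S, Shat) = tr(S^-1 Shat - I)^2

and the effect of penalization by the percentage reduction in average loss,

    PRIAL = 100 [ Lbar1(S, Shat^0) - Lbar1(S, Shat^psi) ] / Lbar1(S, Shat^0),

with losses averaged over replicates before the ratio is formed.  Bias
summaries report, per parameter, the deviation of the replicate mean from
the truth (absolute and in percent) and the mean absolute deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import scipy.linalg

from .core import correlation_from_covariance, heritabilities
from .estimator import fit, fit_path
from .exceptions import ConfigurationError, InvalidInputError
from .likelihood import HalfSibStats
from .penalties import PenaltySpec
from .scenarios import PopulationScenario
from .simulate import SimConfig, simulate_dataset, validation_stats
from .tuning import (LIKELIHOOD_DROP_LIMIT, choose_cv, choose_likelihood_limit,
                     choose_validation)

__all__ = [
    "entropy_loss",
    "quadratic_loss",
    "prial",
    "BiasStats",
    "bias_stats",
    "Strategy",
    "ExperimentSummary",
    "run_experiment",
    "bootstrap_se",
]


def entropy_loss(truth: np.ndarray, estimate: np.ndarray) -> float:
    """L1(Sigma, Sigma_hat) = tr(Sigma^-1 Sigma_hat) - log|Sigma^-1 Sigma_hat| - q."""
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    q = truth.shape[0]
    try:
        c, low = scipy.linalg.cho_factor(truth, lower=True)
    except (scipy.linalg.LinAlgError, ValueError) as err:
        raise InvalidInputError(f"truth matrix must be positive definite: {err}") from err
    A = scipy.linalg.cho_solve((c, low), estimate)
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        raise InvalidInputError("estimate must be positive definite")
    return float(np.trace(A) - logdet - q)


def quadratic_loss(truth: np.ndarray, estimate: np.ndarray) -> float:
    """L2(Sigma, Sigma_hat) = tr(Sigma^-1 Sigma_hat - I)^2."""
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    c, low = scipy.linalg.cho_factor(truth, lower=True)
    A = scipy.linalg.cho_solve((c, low), estimate) - np.eye(truth.shape[0])
    return float(np.trace(A @ A))


def prial(avg_loss_unpenalized: float, avg_loss_penalized: float) -> float:
    """Percentage reduction in average loss due to penalization."""
    if avg_loss_unpenalized <= 0.0:
        raise InvalidInputError("PRIAL undefined for zero unpenalized loss")
    return 100.0 * (avg_loss_unpenalized - avg_loss_penalized) / avg_loss_unpenalized


@dataclass(frozen=True)
class BiasStats:
    """Bias of replicate-mean estimates relative to the truth."""

    truth: np.ndarray
    mean_estimates: np.ndarray
    #: |mean estimate - truth| per parameter
    absolute: np.ndarray
    #: 100 (mean estimate - truth) / truth; NaN where truth = 0
    relative: np.ndarray
    #: mean over replicates of |estimate - truth| per parameter
    mean_abs_dev: np.ndarray
    #: Monte-Carlo standard error of the replicate mean, per parameter
    se_mean: np.ndarray


def bias_stats(truth_params: np.ndarray, estimates: np.ndarray) -> BiasStats:
    """Bias summaries from a replicates x parameters matrix of estimates."""
    truth = np.atleast_1d(np.asarray(truth_params, dtype=float))
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    if est.shape[1] != truth.size:
        raise InvalidInputError("estimates must be (replicates, parameters)")
    mean = est.mean(axis=0)
    dev = mean - truth
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(truth != 0.0, 100.0 * dev / truth, np.nan)
    nrep = est.shape[0]
    se = est.std(axis=0, ddof=1) / np.sqrt(nrep) if nrep > 1 else np.full_like(mean, np.nan)
    return BiasStats(
        truth=truth,
        mean_estimates=mean,
        absolute=np.abs(dev),
        relative=rel,
        mean_abs_dev=np.abs(est - truth).mean(axis=0),
        se_mean=se,
    )


def bootstrap_se(samples: np.ndarray, stat_fn, n_boot: int = 500,
                 seed: int = 0) -> float:
    """Bootstrap standard error of a statistic of replicate rows."""
    rng = np.random.default_rng(seed)
    samples = np.asarray(samples)
    nrep = samples.shape[0]
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, nrep, nrep)
        stats[b] = stat_fn(samples[idx])
    return float(stats.std(ddof=1))


# ----------------------------------------------------------------------


@dataclass(frozen=True)
class Strategy:
    """Tuning-factor selection strategy.

    ``kind`` is one of "Vinf", "V1", "CV" (with ``K`` folds) or "Llimit"
    (with likelihood-drop limit ``delta``).
    """

    kind: str
    K: int = 3
    delta: float = LIKELIHOOD_DROP_LIMIT

    def __post_init__(self):
        if self.kind not in ("Vinf", "V1", "CV", "Llimit"):
            raise ConfigurationError(f"unknown strategy {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "CV":
            return f"CV{self.K}"
        if self.kind == "Llimit":
            return f"L(delta={self.delta:g})"
        return self.kind


@dataclass
class ExperimentSummary:
    """Aggregated results of a scenario x penalty x strategy experiment."""

    scenario: str
    s: int
    n: int
    replicates: int
    penalty: Optional[str]
    strategy: Optional[str]
    #: PRIAL per component (None when no penalty was applied)
    prial: Dict[str, Optional[float]]
    prial_se: Dict[str, Optional[float]]
    mean_loss_unpenalized: Dict[str, float]
    mean_loss_penalized: Dict[str, Optional[float]]
    increased_loss_fraction: Dict[str, Optional[float]]
    psi_chosen: np.ndarray
    n_nonconverged: int
    bias_lambda: BiasStats
    bias_h2: BiasStats
    bias_rg: BiasStats
    rg_pairs: List[tuple]
    #: mean over trait pairs of |replicate-mean deviation| of genetic correlations
    rg_mean_abs_bias: float
    rg_mean_abs_bias_se: float
    details: dict = field(default_factory=dict, repr=False)


def _upper_pairs(q: int) -> List[tuple]:
    return [(i + 1, j + 1) for i in range(q) for j in range(i + 1, q)]


def _collect_params(pair) -> tuple:
    h2 = heritabilities(pair)
    R_G = correlation_from_covariance(pair.sigma_G)
    iu = np.triu_indices(R_G.shape[0], k=1)
    return h2, R_G[iu]


def run_experiment(scenario: PopulationScenario, config: SimConfig,
                   penalty: Optional[PenaltySpec] = None,
                   strategy: Optional[Strategy] = None,
                   psi_grid: Optional[np.ndarray] = None,
                   *, include_rg_loss: bool = False,
                   **fit_kwargs) -> ExperimentSummary:
    """Simulate, fit and summarize one experimental cell.

    Per replicate: simulate a dataset, obtain the unpenalized fit, and —
    when a penalty and strategy are given — trace the psi path, select the
    tuning factor, and score losses of the selected estimate against the
    truth.  Replicates use independent seed substreams spawned from
    ``config.seed``, so results do not depend on execution order.
    """
    if penalty is not None:
        if strategy is None:
            raise ConfigurationError("a penalty requires a selection strategy")
        if psi_grid is None:
            raise ConfigurationError("a penalty requires a psi grid")
        psi_grid = np.asarray(psi_grid, dtype=float)
    truth = scenario.truth
    comps = ["G", "E", "P"] + (["R_G"] if include_rg_loss else [])
    truth_mats = {
        "G": truth.sigma_G, "E": truth.sigma_E, "P": truth.sigma_P,
        "R_G": correlation_from_covariance(truth.sigma_G),
    }
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.replicates)
    val_inf = validation_stats(scenario, config) if (
        strategy is not None and strategy.kind == "Vinf") else None

    loss0 = {c: [] for c in comps}
    loss1 = {c: [] for c in comps}
    lam_est, h2_est, rg_est = [], [], []
    psi_sel = []
    nonconv = 0
    iu_truth = np.triu_indices(truth.q, k=1)
    rg_truth = truth_mats["R_G"][iu_truth]

    for child in child_seeds:
        rng = np.random.default_rng(child)
        data = simulate_dataset(scenario, config, rng=rng)
        if penalty is None:
            base = fit(data, None, 0.0, **fit_kwargs)
            chosen = base
            nonconv += 0 if base.converged else 1
        else:
            path = fit_path(data, penalty, psi_grid, **fit_kwargs)
            nonconv += sum(0 if f.converged else 1 for f in path.fits)
            if strategy.kind == "Vinf":
                choice = choose_validation(path, val_inf, "Vinf")
            elif strategy.kind == "V1":
                extra = simulate_dataset(scenario, config, rng=rng)
                choice = choose_validation(path, extra, "V1")
            elif strategy.kind == "CV":
                choice = choose_cv(data, strategy.K, penalty, psi_grid, **fit_kwargs)
            else:
                choice = choose_likelihood_limit(path, strategy.delta)
            base = path.baseline
            chosen = path.fits[choice.index]
            psi_sel.append(choice.psi_chosen)
        est_mats0 = {
            "G": base.pair.sigma_G, "E": base.pair.sigma_E, "P": base.pair.sigma_P,
        }
        est_mats1 = {
            "G": chosen.pair.sigma_G, "E": chosen.pair.sigma_E,
            "P": chosen.pair.sigma_P,
        }
        if include_rg_loss:
            est_mats0["R_G"] = correlation_from_covariance(base.pair.sigma_G)
            est_mats1["R_G"] = correlation_from_covariance(chosen.pair.sigma_G)
        for c in comps:
            loss0[c].append(entropy_loss(truth_mats[c], est_mats0[c]))
            loss1[c].append(entropy_loss(truth_mats[c], est_mats1[c]))
        lam_est.append(chosen.form.lambdas)
        h2, rg = _collect_params(chosen.pair)
        h2_est.append(h2)
        rg_est.append(rg)

    loss0 = {c: np.asarray(v) for c, v in loss0.items()}
    loss1 = {c: np.asarray(v) for c, v in loss1.items()}
    penalized = penalty is not None
    prial_val, prial_se_val, frac_up, mean1 = {}, {}, {}, {}
    for c in comps:
        if penalized:
            prial_val[c] = prial(loss0[c].mean(), loss1[c].mean())
            pair_losses = np.column_stack([loss0[c], loss1[c]])
            prial_se_val[c] = bootstrap_se(
                pair_losses, lambda m: prial(m[:, 0].mean(), m[:, 1].mean()))
            frac_up[c] = float(np.mean(loss1[c] > loss0[c]))
            mean1[c] = float(loss1[c].mean())
        else:
            prial_val[c] = prial_se_val[c] = frac_up[c] = mean1[c] = None

    lam_est = np.asarray(lam_est)
    truth_lam = scenario.canonical_eigenvalues()
    rg_est = np.asarray(rg_est)
    rg_bias = bias_stats(rg_truth, rg_est)
    dev = rg_est - rg_truth

    def _mab(d):
        return float(np.abs(d.mean(axis=0)).mean())

    return ExperimentSummary(
        scenario=scenario.name,
        s=config.s,
        n=config.n,
        replicates=config.replicates,
        penalty=penalty.kind if penalized else None,
        strategy=strategy.label if strategy is not None else None,
        prial=prial_val,
        prial_se=prial_se_val,
        mean_loss_unpenalized={c: float(loss0[c].mean()) for c in comps},
        mean_loss_penalized=mean1,
        increased_loss_fraction=frac_up,
        psi_chosen=np.asarray(psi_sel),
        n_nonconverged=nonconv,
        bias_lambda=bias_stats(truth_lam, lam_est),
        bias_h2=bias_stats(scenario.h2, np.asarray(h2_est)),
        bias_rg=rg_bias,
        rg_pairs=_upper_pairs(truth.q),
        rg_mean_abs_bias=_mab(dev),
        rg_mean_abs_bias_se=bootstrap_se(dev, _mab),
        details={
            "loss_unpenalized": loss0,
            "loss_penalized": loss1 if penalized else None,
            "rg_estimates": rg_est,
            "lambda_estimates": lam_est,
        },
    )
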