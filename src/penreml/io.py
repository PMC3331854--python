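"""Readers and writers: phenotype records, sufficient statistics, scenarios,
and experiment summaries.

Phenotype records are delimited text with a header row — a sire identifier
column followed by one column per trait, one row per progeny.  The design
must be balanced (equal progeny per sire) and complete (no missing values).
Sufficient statistics and scenario definitions travel as YAML; experiment
summaries are written as CSV (one row per component) plus a JSON detail
file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .evaluation import ExperimentSummary
from .exceptions import InvalidInputError
from .likelihood import HalfSibStats, stats_from_families
from .scenarios import PopulationScenario, build_scenario

__all__ = [
    "read_records",
    "write_records",
    "read_stats",
    "write_stats",
    "read_scenario",
    "write_scenario",
    "summary_to_frame",
    "write_summary",
]

PathLike = Union[str, Path]


def read_records(path: PathLike) -> HalfSibStats:
    """Read balanced half-sib phenotype records and pool them into statistics.

    Computes M_B and M_W exactly as the between/within mean squares of a
    one-way MANOVA and keeps the per-family summaries.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise InvalidInputError("records need a sire column plus at least one trait")
    if df.isna().any().any():
        raise InvalidInputError("missing values are not supported")
    sire_col = df.columns[0]
    traits = df.columns[1:]
    values = df[traits].to_numpy(dtype=float)
    counts = df[sire_col].value_counts()
    if counts.nunique() != 1:
        offenders = counts[counts != counts.iloc[0]].index.tolist()
        raise InvalidInputError(
            f"unbalanced design: sires {offenders} have different progeny counts"
        )
    n = int(counts.iloc[0])
    if len(counts) < 2:
        raise InvalidInputError("need at least two sires")
    if n < 2:
        raise InvalidInputError("need at least two progeny per sire")
    # group in order of first appearance
    order = df[sire_col].drop_duplicates().tolist()
    means, sscps = [], []
    grouped = df.groupby(sire_col, sort=False)
    for sire in order:
        block = grouped.get_group(sire)[traits].to_numpy(dtype=float)
        mu = block.mean(axis=0)
        centred = block - mu
        means.append(mu)
        sscps.append(centred.T @ centred)
    return stats_from_families(np.asarray(means), np.asarray(sscps), n)


def write_records(path: PathLike, records: np.ndarray,
                  trait_names=None, float_format: str = "%.17g") -> None:
    """Write an (s, n, q) record array as delimited text (CSV)."""
    y = np.asarray(records, dtype=float)
    s, n, q = y.shape
    names = trait_names or [f"trait_{k + 1}" for k in range(q)]
    sire = np.repeat(np.arange(1, s + 1), n)
    df = pd.DataFrame(y.reshape(s * n, q), columns=names)
    df.insert(0, "sire", sire)
    df.to_csv(path, index=False, float_format=float_format)


def write_stats(path: PathLike, stats: HalfSibStats) -> None:
    """Serialize sufficient statistics (without family detail) as YAML."""
    payload = {
        "s": int(stats.s),
        "n": int(stats.n),
        "M_B": stats.M_B.tolist(),
        "M_W": stats.M_W.tolist(),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_stats(path: PathLike) -> HalfSibStats:
    payload = yaml.safe_load(Path(path).read_text())
    return HalfSibStats(
        s=int(payload["s"]), n=int(payload["n"]),
        M_B=np.asarray(payload["M_B"], dtype=float),
        M_W=np.asarray(payload["M_W"], dtype=float),
    )


def write_scenario(path: PathLike, scenario: PopulationScenario) -> None:
    """Serialize a population scenario as YAML.

    Correlations are written explicitly so the file is self-contained; the
    Roman-numeral id and the reconstruction flag are kept as metadata.
    """
    payload = {
        "name": scenario.name,
        "q": int(scenario.q),
        "h2": scenario.h2.tolist(),
        "corr": (
            {"scenario": scenario.corr_scenario}
            if scenario.corr_scenario is not None
            else {"R_G": scenario.R_G.tolist(), "R_E": scenario.R_E.tolist()}
        ),
        "phen_var": scenario.phen_var.tolist(),
        "reconstructed_h2": bool(scenario.reconstructed),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_scenario(path: PathLike) -> PopulationScenario:
    payload = yaml.safe_load(Path(path).read_text())
    corr = payload["corr"]
    if "scenario" in corr:
        corr_spec = corr["scenario"]
    else:
        corr_spec = (np.asarray(corr["R_G"], dtype=float),
                     np.asarray(corr["R_E"], dtype=float))
    return build_scenario(
        payload["name"], np.asarray(payload["h2"], dtype=float), corr_spec,
        phen_var=np.asarray(payload["phen_var"], dtype=float),
        reconstructed=bool(payload.get("reconstructed_h2", False)),
    )


def summary_to_frame(summary: ExperimentSummary) -> pd.DataFrame:
    """One row per covariance component with PRIAL and loss columns."""
    rows = []
    for comp, value in summary.prial.items():
        rows.append({
            "scenario": summary.scenario,
            "s": summary.s,
            "n": summary.n,
            "replicates": summary.replicates,
            "penalty": summary.penalty or "none",
            "strategy": summary.strategy or "none",
            "component": comp,
            "prial_pct": value,
            "prial_se_pct": summary.prial_se[comp],
            "mean_entropy_loss_unpenalized": summary.mean_loss_unpenalized[comp],
            "mean_entropy_loss_penalized": summary.mean_loss_penalized[comp],
            "fraction_increased_loss": summary.increased_loss_fraction[comp],
        })
    return pd.DataFrame(rows)


def write_summary(path_csv: PathLike, summary: ExperimentSummary,
                  path_json: PathLike = None) -> None:
    """Write the CSV summary (4 decimals) and optional JSON detail file."""
    frame = summary_to_frame(summary)
    frame.to_csv(path_csv, index=False, float_format="%.4f")
    if path_json is not None:
        detail = {
            "scenario": summary.scenario,
            "s": summary.s,
            "n": summary.n,
            "replicates": summary.replicates,
            "penalty": summary.penalty,
            "strategy": summary.strategy,
            "prial": summary.prial,
            "psi_chosen": summary.psi_chosen.tolist(),
            "n_nonconverged": summary.n_nonconverged,
            "rg_mean_abs_bias": summary.rg_mean_abs_bias,
            "rg_mean_abs_bias_se": summary.rg_mean_abs_bias_se,
            "rg_pairs": [list(p) for p in summary.rg_pairs],
            "rg_mean_deviation": (summary.bias_rg.mean_estimates
                                  - summary.bias_rg.truth).tolist(),
            "loss_unpenalized": {k: v.tolist() for k, v in
                                 summary.details["loss_unpenalized"].items()},
        }
        if summary.details.get("loss_penalized") is not None:
            detail["loss_penalized"] = {
                k: v.tolist() for k, v in summary.details["loss_penalized"].items()
            }
        Path(path_json).write_text(json.dumps(detail, indent=1))
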