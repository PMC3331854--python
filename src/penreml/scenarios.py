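"""Population-parameter scenarios for the simulation study.

A scenario combines a heritability set, a correlation scenario (Roman
numerals I-VII) and a phenotypic-variance pattern into true (sigma_G,
sigma_E) matrices via sigma_X = D_X R_X D_X, with D_X the diagonal matrix
of component standard deviations.

The catalogue holds 90 scenarios: 12 heritability sets (A-L) crossed with
correlation scenarios I-V for q = 5 traits, and 10 sets (M-V) crossed with
I, VI and VII for q = 9.  Heritability means are 0.4 (A-G, M-Q), 0.3 (H)
or 0.2 (I-L, S-V), declining with trait number; sets A, I, M and R have
equal values, sets E, H and O span an interval of 0.80, and sets G, H, L,
U and V are markedly uneven.  Only the equal-value sets and set T are fully
pinned down by those constraints; the remaining sets are documented
reconstructions satisfying them (see ``RECONSTRUCTED_SETS``) and are
flagged as non-canonical in scenario files this module writes.

Correlation formulas use 1-based trait indices i < j, with a leading minus
bound to the base of a power, e.g. ``(-0.8)**|i-j| + 0.02 i``; the
alternative reading ``-(0.8**|i-j|)`` is available through
``convention="minus_outside"`` for sensitivity checks (it does not yield a
positive-definite matrix for every scenario).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .core import CovariancePair, canonical_decompose
from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "PopulationScenario",
    "correlation_matrix",
    "phenotypic_variances",
    "build_scenario",
    "catalogue",
    "HERITABILITY_SETS_Q5",
    "HERITABILITY_SETS_Q9",
    "RECONSTRUCTED_SETS",
]

# ----------------------------------------------------------------------
# heritability sets

#: q = 5 sets, means 0.4 (A-G), 0.3 (H), 0.2 (I-L)
HERITABILITY_SETS_Q5: Dict[str, Tuple[float, ...]] = {
    "A": (0.40, 0.40, 0.40, 0.40, 0.40),
    "B": (0.50, 0.45, 0.40, 0.35, 0.30),
    "C": (0.60, 0.50, 0.40, 0.30, 0.20),
    "D": (0.70, 0.55, 0.40, 0.25, 0.10),
    "E": (0.85, 0.57, 0.35, 0.18, 0.05),
    "F": (0.65, 0.55, 0.45, 0.25, 0.10),
    "G": (0.90, 0.60, 0.30, 0.15, 0.05),
    "H": (0.85, 0.35, 0.15, 0.10, 0.05),
    "I": (0.20, 0.20, 0.20, 0.20, 0.20),
    "J": (0.30, 0.25, 0.20, 0.15, 0.10),
    "K": (0.35, 0.28, 0.20, 0.12, 0.05),
    "L": (0.55, 0.25, 0.10, 0.06, 0.04),
}

#: q = 9 sets, means 0.4 (M-Q), 0.3 (R, equal values), 0.2 (S-V); T as printed
HERITABILITY_SETS_Q9: Dict[str, Tuple[float, ...]] = {
    "M": (0.40,) * 9,
    "N": (0.60, 0.55, 0.50, 0.45, 0.40, 0.35, 0.30, 0.25, 0.20),
    "O": (0.85, 0.72, 0.60, 0.48, 0.38, 0.26, 0.15, 0.11, 0.05),
    "P": (0.70, 0.60, 0.50, 0.45, 0.40, 0.35, 0.30, 0.20, 0.10),
    "Q": (0.55, 0.50, 0.48, 0.44, 0.40, 0.36, 0.32, 0.30, 0.25),
    "R": (0.30,) * 9,
    "S": (0.30, 0.275, 0.25, 0.225, 0.20, 0.175, 0.15, 0.125, 0.10),
    "T": (0.50, 0.50, 0.20, 0.15, 0.15, 0.10, 0.10, 0.05, 0.05),
    "U": (0.65, 0.45, 0.25, 0.15, 0.10, 0.08, 0.05, 0.04, 0.03),
    "V": (0.80, 0.40, 0.20, 0.10, 0.08, 0.06, 0.06, 0.05, 0.05),
}

#: sets whose individual values are reconstructions (constraints satisfied,
#: exact values not canonical); A, I, M, R and T are fully determined.
RECONSTRUCTED_SETS = frozenset(
    {"B", "C", "D", "E", "F", "G", "H", "J", "K", "L",
     "N", "O", "P", "Q", "R", "S", "U", "V"}
)

_Q5_CORR = ("I", "II", "III", "IV", "V")
_Q9_CORR = ("I", "VI", "VII")


# ----------------------------------------------------------------------
# correlation scenarios


def _corr_entry(scenario_id: str, side: str, i: int, j: int,
                convention: str) -> float:
    """Off-diagonal correlation for 1-based trait indices i < j."""
    def pw(base: float, k: int) -> float:
        if convention == "minus_outside" and base < 0:
            return -((-base) ** k)
        return base ** k

    k = abs(i - j)
    if scenario_id == "I":
        return 0.0
    if scenario_id == "II":
        return 0.8 if side == "genetic" else 0.0
    if scenario_id == "III":
        return pw(0.6, k) if side == "genetic" else pw(-0.4, k) + 0.5
    if scenario_id == "IV":
        return pw(-0.8, k) + 0.02 * i if side == "genetic" else pw(-0.4, k) + 0.5
    if scenario_id == "V":
        if side == "genetic":
            return (-1.0) ** i * 0.05 * j + 0.5
        return (-1.0) ** j * 0.1 * i + 0.2
    if scenario_id == "VI":
        if side == "genetic":
            return pw(0.7, k)
        return (-1.0) ** j * 0.05 * i + 0.2
    if scenario_id == "VII":
        return pw(-0.8, k) + 0.02 * i if side == "genetic" else pw(-0.2, k) + 0.5
    raise ConfigurationError(f"unknown correlation scenario {scenario_id!r}")


def correlation_matrix(scenario_id: str, q: int, side: str,
                       convention: str = "minus_to_base") -> np.ndarray:
    """Population correlation matrix for a scenario.

    Parameters
    ----------
    scenario_id
        Roman numeral "I" .. "VII".  Scenarios II-V are defined for q = 5,
        VI-VII for q = 9; I is generic.
    side
        "genetic" or "residual".
    convention
        "minus_to_base" (default) binds a leading minus to the base of a
        power; "minus_outside" applies it to the whole power.
    """
    if side not in ("genetic", "residual"):
        raise ConfigurationError("side must be 'genetic' or 'residual'")
    if scenario_id != "I":
        if scenario_id in ("II", "III", "IV", "V") and q != 5:
            raise ConfigurationError(f"scenario {scenario_id} is defined for q = 5")
        if scenario_id in ("VI", "VII") and q != 9:
            raise ConfigurationError(f"scenario {scenario_id} is defined for q = 9")
    R = np.eye(q)
    for i in range(1, q + 1):
        for j in range(i + 1, q + 1):
            r = _corr_entry(scenario_id, side, i, j, convention)
            R[i - 1, j - 1] = R[j - 1, i - 1] = r
    eig_min = np.linalg.eigvalsh(R).min()
    if eig_min <= 0.0:
        raise ConfigurationError(
            f"correlation scenario {scenario_id} ({side}, q={q}, {convention}) "
            f"is not positive definite (min eigenvalue {eig_min:.4g})"
        )
    return R


def phenotypic_variances(scenario_id: str, q: int) -> np.ndarray:
    """Phenotypic variance pattern tied to a correlation scenario.

    Unit variances for I; 1.5^(i-1) for II; (3, 2, 1, 2, 3) for III-V;
    (2, 1, 3, 2, 1, 2, 3, 1, 2) for VI and VII.
    """
    if scenario_id == "I":
        return np.ones(q)
    if scenario_id == "II":
        return 1.5 ** np.arange(q)
    if scenario_id in ("III", "IV", "V"):
        return np.array([3.0, 2.0, 1.0, 2.0, 3.0])
    if scenario_id in ("VI", "VII"):
        return np.array([2.0, 1.0, 3.0, 2.0, 1.0, 2.0, 3.0, 1.0, 2.0])
    raise ConfigurationError(f"unknown correlation scenario {scenario_id!r}")


# ----------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationScenario:
    """A named population truth.

    Attributes
    ----------
    name
        Label such as "T-VI".
    h2
        Per-trait heritabilities.
    corr_scenario
        Roman-numeral id, or None when explicit matrices were supplied.
    R_G, R_E
        Genetic and residual correlation matrices.
    phen_var
        Phenotypic variances sigma_i^2.
    truth
        Derived CovariancePair with sigma_G[i,i] = h2_i sigma_i^2 and
        sigma_E[i,i] = (1 - h2_i) sigma_i^2.
    reconstructed
        True when the heritability set is a documented reconstruction
        rather than a fully printed one.
    """

    name: str
    h2: np.ndarray
    R_G: np.ndarray
    R_E: np.ndarray
    phen_var: np.ndarray
    truth: CovariancePair
    corr_scenario: Optional[str] = None
    reconstructed: bool = False

    @property
    def q(self) -> int:
        return self.h2.size

    def canonical_eigenvalues(self) -> np.ndarray:
        return canonical_decompose(self.truth).lambdas


def build_scenario(name: str, h2, corr_scenario: Union[str, Tuple[np.ndarray, np.ndarray]],
                   phen_var=None, *, convention: str = "minus_to_base",
                   reconstructed: bool = False) -> PopulationScenario:
    """Assemble a PopulationScenario from heritabilities, correlations and variances.

    ``corr_scenario`` is either a Roman-numeral id or an explicit
    ``(R_G, R_E)`` tuple.  When a numeral is given and ``phen_var`` is None
    the scenario's variance pattern is used.
    """
    h2 = np.asarray(h2, dtype=float)
    q = h2.size
    if np.any(h2 <= 0.0) or np.any(h2 >= 1.0):
        raise InvalidInputError("heritabilities must lie strictly in (0, 1)")
    if isinstance(corr_scenario, str):
        R_G = correlation_matrix(corr_scenario, q, "genetic", convention)
        R_E = correlation_matrix(corr_scenario, q, "residual", convention)
        corr_id: Optional[str] = corr_scenario
        if phen_var is None:
            phen_var = phenotypic_variances(corr_scenario, q)
    else:
        R_G, R_E = (np.asarray(m, dtype=float) for m in corr_scenario)
        corr_id = None
        if phen_var is None:
            phen_var = np.ones(q)
    phen_var = np.asarray(phen_var, dtype=float)
    if phen_var.size != q or np.any(phen_var <= 0.0):
        raise InvalidInputError("phenotypic variances must be positive, length q")
    sd_G = np.sqrt(h2 * phen_var)
    sd_E = np.sqrt((1.0 - h2) * phen_var)
    sigma_G = R_G * np.outer(sd_G, sd_G)
    sigma_E = R_E * np.outer(sd_E, sd_E)
    try:
        truth = CovariancePair(sigma_G=sigma_G, sigma_E=sigma_E)
    except InvalidInputError as err:
        raise ConfigurationError(f"scenario {name!r} truth is invalid: {err}") from err
    return PopulationScenario(
        name=name, h2=h2, R_G=R_G, R_E=R_E, phen_var=phen_var, truth=truth,
        corr_scenario=corr_id, reconstructed=reconstructed,
    )


def catalogue(convention: str = "minus_to_base") -> List[PopulationScenario]:
    """All 90 catalogued scenarios: 60 for q = 5 and 30 for q = 9."""
    out: List[PopulationScenario] = []
    for set_name, h2 in HERITABILITY_SETS_Q5.items():
        for corr in _Q5_CORR:
            out.append(build_scenario(
                f"{set_name}-{corr}", h2, corr, convention=convention,
                reconstructed=set_name in RECONSTRUCTED_SETS,
            ))
    for set_name, h2 in HERITABILITY_SETS_Q9.items():
        for corr in _Q9_CORR:
            out.append(build_scenario(
                f"{set_name}-{corr}", h2, corr, convention=convention,
                reconstructed=set_name in RECONSTRUCTED_SETS,
            ))
    return out


def get_scenario(name: str, convention: str = "minus_to_base") -> PopulationScenario:
    """Look up a catalogue scenario such as "T-VI" by name."""
    set_name, _, corr = name.partition("-")
    sets = HERITABILITY_SETS_Q5 if set_name in HERITABILITY_SETS_Q5 else HERITABILITY_SETS_Q9
    if set_name not in sets or not corr:
        raise ConfigurationError(f"unknown scenario name {name!r}")
    return build_scenario(
        name, sets[set_name], corr, convention=convention,
        reconstructed=set_name in RECONSTRUCTED_SETS,
    )
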