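"""Growth, maturation, weight, and natural mortality over annual steps.

Lengths follow individual von Bertalanffy trajectories applied as annual
increments, with a density-dependent multiplier that suppresses somatic
growth as population biomass approaches carrying capacity. Maturation is
length-triggered at a fixed fraction of the individual's own asymptotic
length and is irreversible. Natural mortality is an annual Bernoulli
survival with instantaneous rates: juveniles younger than three are exempt
(their mortality is folded into the egg-to-recruit bottleneck), immature
fish experience M = 0.15 yr⁻¹, and mature fish pay an additional 0.1 yr⁻¹
reproductive cost. No individual lives past 25 years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Individual",
    "MortalityParams",
    "MATURATION_FRACTION",
    "WEIGHT_COEF",
    "WEIGHT_EXP",
    "weight_from_length",
    "grow",
    "maturation_threshold",
    "is_newly_mature",
    "natural_survival_prob",
]

#: Length at maturation as a fraction of the individual's asymptotic length.
MATURATION_FRACTION = 0.66

#: Length (cm) → weight (kg) allometry W = 3.52e-6 · L^3.19.
WEIGHT_COEF = 3.52e-6
WEIGHT_EXP = 3.19


@dataclass
class Individual:
    """One fish, as a scalar record.

    The simulation engine stores the population as flat arrays for speed;
    this record type is the per-fish view used by the scalar operations and
    their contracts. ``mature`` is monotone (never unset) and ``length``
    can never exceed ``linf``.
    """

    id: int
    birth_year: int
    age: int
    genotype: "object"
    linf: float
    k: float
    length: float = 0.0
    mature: bool = False
    lifetime_recruits: int = 0
    alive: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.age <= 25:
            raise ValueError("age must lie in [0, 25] while alive")
        if self.length < 0 or self.length > self.linf + 1e-9:
            raise ValueError("length must lie in [0, linf]")


@dataclass(frozen=True)
class MortalityParams:
    """Instantaneous natural-mortality rates (yr⁻¹) and age limits."""

    m_immature: float = 0.15
    reproductive_cost: float = 0.1
    juvenile_age_cutoff: int = 3
    max_age: int = 25

    def __post_init__(self) -> None:
        if self.m_immature < 0 or self.reproductive_cost < 0:
            raise ValueError("mortality rates must be non-negative")


def weight_from_length(length: "float | np.ndarray") -> "float | np.ndarray":
    """Somatic weight (kg) from length (cm) by the cod length–weight power law."""
    length = np.asarray(length, dtype=float)
    if np.any(length < 0):
        raise ValueError("length must be non-negative")
    w = WEIGHT_COEF * length**WEIGHT_EXP
    return float(w) if w.ndim == 0 else w


def grow(
    length: "float | np.ndarray",
    linf: "float | np.ndarray",
    k: "float | np.ndarray",
    density_ratio: float = 0.0,
    theta: float = 1.0,
) -> "float | np.ndarray":
    """One annual von Bertalanffy increment with density-dependent suppression.

    ``length' = length + (linf − length)·(1 − e^(−k))·max(0, 1 − theta·density_ratio)``

    where ``density_ratio`` is the population biomass over carrying capacity.
    The result never exceeds ``linf`` and never shrinks.
    """
    if density_ratio < 0:
        raise ValueError("density_ratio must be non-negative")
    length = np.asarray(length, dtype=float)
    linf = np.asarray(linf, dtype=float)
    suppression = max(0.0, 1.0 - theta * density_ratio)
    new = length + (linf - length) * (1.0 - np.exp(-np.asarray(k, dtype=float))) * suppression
    new = np.minimum(new, linf)
    return float(new) if new.ndim == 0 else new


def maturation_threshold(linf: "float | np.ndarray") -> "float | np.ndarray":
    """Length (cm) at which a fish with the given L∞ matures."""
    t = MATURATION_FRACTION * np.asarray(linf, dtype=float)
    return float(t) if t.ndim == 0 else t


def is_newly_mature(
    length: "float | np.ndarray",
    linf: "float | np.ndarray",
    already_mature: "bool | np.ndarray",
) -> "bool | np.ndarray":
    """Maturity flag after this year's growth; boundary inclusive, irreversible."""
    now = np.asarray(length, dtype=float) >= maturation_threshold(linf)
    out = np.logical_or(now, already_mature)
    return bool(out) if out.ndim == 0 else out


def natural_survival_prob(
    age: "int | np.ndarray",
    mature: "bool | np.ndarray",
    p: MortalityParams = MortalityParams(),
) -> "float | np.ndarray":
    """Annual natural-survival probability by age class and maturity.

    Ages below the juvenile cutoff survive with probability one (the
    egg-to-recruit survival already covers those years); immature fish
    survive with ``e^(−M)``; mature fish with ``e^(−(M + cost))``. The
    hard cap at ``max_age`` is applied separately at the ageing step.
    """
    age = np.asarray(age)
    mature = np.asarray(mature, dtype=bool)
    s_imm = np.exp(-p.m_immature)
    s_mat = np.exp(-(p.m_immature + p.reproductive_cost))
    prob = np.where(age < p.juvenile_age_cutoff, 1.0, np.where(mature, s_mat, s_imm))
    return float(prob) if prob.ndim == 0 else prob
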