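"""Size-selective harvest with a minimum-size limit and a biomass moratorium.

Trawl selectivity is logistic in length (half-retention at 50 cm). A fish
is catchable only if strictly longer than the 45 cm minimum-size threshold;
its annual capture probability is the product of the instantaneous fishing
mortality F and the selectivity. Fishing stops for good — a moratorium —
once population biomass falls to 15% of its value at the onset of fishing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .life_history import weight_from_length

__all__ = [
    "FishingParams",
    "selectivity",
    "capture_prob",
    "harvest",
    "fishing_should_stop",
]


@dataclass(frozen=True)
class FishingParams:
    """Harvest parameters: F (yr⁻¹), gear selectivity, and the stop rule."""

    F: float = 0.1
    min_size_cm: float = 45.0
    sel_intercept: float = -12.5
    sel_slope: float = 0.25
    stop_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if not 0.0 < self.stop_fraction < 1.0:
            raise ValueError("stop_fraction must lie in (0, 1)")


def selectivity(
    length: "float | np.ndarray", p: FishingParams = FishingParams()
) -> "float | np.ndarray":
    """Logistic trawl selectivity, strictly increasing in length."""
    length = np.asarray(length, dtype=float)
    if np.any(length < 0):
        raise ValueError("length must be non-negative")
    x = p.sel_intercept + p.sel_slope * length
    s = 1.0 / (1.0 + np.exp(-x))
    return float(s) if s.ndim == 0 else s


def capture_prob(
    length: "float | np.ndarray", p: FishingParams
) -> "float | np.ndarray":
    """Annual probability of capture: F·selectivity above the size limit.

    The 45 cm threshold is exclusive — only fish *longer* than the minimum
    size are catchable — so the probability is zero at or below it and is
    always bounded by F.
    """
    length = np.asarray(length, dtype=float)
    prob = np.where(length > p.min_size_cm, p.F * selectivity(length, p), 0.0)
    return float(prob) if prob.ndim == 0 else prob


def harvest(
    lengths: np.ndarray, p: FishingParams, rng: np.random.Generator
) -> tuple[np.ndarray, int, float]:
    """One fishing season over the population's length vector.

    Each fish is captured in an independent Bernoulli trial at its capture
    probability. Returns ``(captured_mask, catch_count, catch_biomass_kg)``;
    catch biomass is the summed weight of the removed fish.
    """
    lengths = np.asarray(lengths, dtype=float)
    prob = capture_prob(lengths, p)
    captured = rng.random(lengths.shape) < prob
    catch_biomass = float(np.sum(weight_from_length(lengths[captured]))) if captured.any() else 0.0
    return captured, int(captured.sum()), catch_biomass


def fishing_should_stop(
    current_biomass: float, biomass_at_onset: float, p: FishingParams
) -> bool:
    """Moratorium trigger: biomass at or below ``stop_fraction`` of onset biomass.

    The caller latches the result — once fishing stops it never resumes
    within a run.
    """
    if biomass_at_onset <= 0:
        raise ValueError("biomass_at_onset must be positive")
    return current_biomass <= p.stop_fraction * biomass_at_onset
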