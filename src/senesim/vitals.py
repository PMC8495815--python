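"""Per-individual annual vital rates.

Growth follows each fish's own von Bertalanffy curve, slowed by the
population-level density factor (a fish receives only a fraction of a year of
"growth time" when biomass is near carrying capacity).  Maturation is a size
threshold (67% of the individual's L∞) gated at age 2.  Egg production is a
linear function of fresh weight, multiplied by the age-specific fecundity
factor (reproductive senescence) and the density factor.  Natural mortality
is an instantaneous annual rate from an age schedule (constant, or increasing
with age for actuarial senescence) plus a one-off survival cost in the year
of maturation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .empirics import (
    FecundityFactors,
    FecundityModel,
    LengthWeightFit,
    LinfKRegression,
    fecundity,
    predict_weight_g,
)

__all__ = [
    "Individual",
    "MortalitySchedule",
    "LifeHistoryConfig",
    "VitalsError",
    "constant_mortality",
    "senescent_mortality",
    "draw_k",
    "grow",
    "maturation_check",
    "eggs_produced",
    "natural_mortality_rate",
    "survives_natural",
    "MAX_AGE",
]

MAX_AGE = 7  # hard lifespan cap (years), local lifespan estimate

#: Increase in instantaneous natural mortality applied once, in the year an
#: individual matures.  Stand-in estimated as the age-2 -> age-3 increment of
#: the senescent schedule (0.258 - 0.200).
DEFAULT_MATURATION_COST = 0.058


class VitalsError(ValueError):
    pass


@dataclass
class Individual:
    """Simulation agent; the engine stores these fields as parallel arrays."""

    id: int
    female: bool
    age: int
    length: float  # cm
    l_inf: float  # cm
    k: float  # per year
    genotype: np.ndarray | None = None
    mature: bool = False
    age_at_maturation: int | None = None
    alive: bool = True


@dataclass(frozen=True)
class MortalitySchedule:
    """Instantaneous natural mortality by age class (ages 2..6+).

    ``mode`` is "constant" (no actuarial senescence) or "senescent"
    (rates non-decreasing with age).  Age 7 uses the 6+ rate; death at the
    end of age 7 is forced by the lifespan cap regardless.
    """

    mode: str
    m_by_age: dict[int, float]
    maturation_cost: float = DEFAULT_MATURATION_COST

    def __post_init__(self):
        if self.mode not in ("constant", "senescent"):
            raise VitalsError(f"unknown mortality mode {self.mode!r}")
        if sorted(self.m_by_age) != [2, 3, 4, 5, 6]:
            raise VitalsError("mortality schedule must cover ages 2..6+")
        rates = [self.m_by_age[a] for a in range(2, 7)]
        if any(r < 0 for r in rates) or self.maturation_cost < 0:
            raise VitalsError("mortality rates must be non-negative")
        if self.mode == "senescent" and any(b < a for a, b in zip(rates, rates[1:])):
            raise VitalsError("senescent mortality must be non-decreasing in age")

    def rate_array(self) -> np.ndarray:
        """Rates indexed by age 0..MAX_AGE (0 below age 2; age 7 = 6+ rate)."""
        out = np.zeros(MAX_AGE + 1)
        for a in range(2, MAX_AGE + 1):
            out[a] = self.m_by_age[min(a, 6)]
        return out


def constant_mortality(m: float = 0.257, maturation_cost: float = DEFAULT_MATURATION_COST):
    """Age-independent adult natural mortality (no actuarial senescence)."""
    return MortalitySchedule("constant", {a: m for a in range(2, 7)}, maturation_cost)


def senescent_mortality(
    rates: tuple[float, ...] = (0.2, 0.258, 0.314, 0.372, 0.428),
    maturation_cost: float = DEFAULT_MATURATION_COST,
):
    """Natural mortality increasing with age (actuarial senescence)."""
    return MortalitySchedule(
        "senescent", dict(zip(range(2, 7), rates)), maturation_cost
    )


@dataclass
class LifeHistoryConfig:
    """Bundle of the life-history constants and fitted empirical relations."""

    fecundity_model: FecundityModel = field(
        default_factory=lambda: FecundityModel(intercept=39.06, slope=118.47)
    )
    length_weight: LengthWeightFit = field(
        default_factory=lambda: LengthWeightFit(a=7e-6, b=2.943)
    )
    fecundity_factors: FecundityFactors = field(
        default_factory=lambda: FecundityFactors({1: 0.0, **{a: 1.0 for a in range(2, 8)}})
    )
    k_regression: LinfKRegression = field(
        default_factory=lambda: LinfKRegression(intercept=1.27, slope=-0.13, resid_sd=0.30)
    )
    maturation_fraction: float = 0.67
    min_maturation_age: int = 2
    max_age: int = MAX_AGE
    egg_to_age2_survival: float = 0.002

    def __post_init__(self):
        if not 0 < self.maturation_fraction < 1:
            raise VitalsError("maturation_fraction must lie in (0, 1)")
        if not 0 <= self.egg_to_age2_survival <= 1:
            raise VitalsError("egg_to_age2_survival must be a probability")


def draw_k(l_inf, reg: LinfKRegression, rng: np.random.Generator):
    """Draw the growth coefficient k (per year) for a fish of given L∞ (cm).

    ln k = intercept + slope * L∞ + N(0, resid_sd); drawn once at birth.
    """
    l_inf = np.asarray(l_inf, dtype=float)
    if np.any(l_inf <= 0):
        raise VitalsError("l_inf must be positive")
    ln_k = reg.predict_ln_k(l_inf)
    if reg.resid_sd > 0:
        ln_k = ln_k + rng.normal(0.0, reg.resid_sd, size=l_inf.shape)
    return np.exp(ln_k)


def grow(length, l_inf, k, growth_time):
    """Advance length along the vB curve by ``growth_time`` of a year.

    length' = L∞ - (L∞ - length) e^{-k * growth_time}; monotone, never
    exceeding L∞.  Accepts scalars or arrays.
    """
    gt = np.asarray(growth_time, dtype=float)
    if np.any(gt < 0) or np.any(gt > 1):
        raise VitalsError("growth_time must lie in [0, 1]")
    return l_inf - (l_inf - np.asarray(length, dtype=float)) * np.exp(-np.asarray(k) * gt)


def maturation_check(ind: Individual, cfg: LifeHistoryConfig) -> bool:
    """Mature the individual if it newly qualifies; return True if it did.

    Maturation requires age >= min_maturation_age (second autumn) and length
    >= maturation_fraction * L∞.
    """
    if not ind.alive:
        raise VitalsError("maturation_check on a dead individual")
    if ind.mature:
        return False
    if ind.age >= cfg.min_maturation_age and ind.length >= cfg.maturation_fraction * ind.l_inf:
        ind.mature = True
        ind.age_at_maturation = ind.age
        return True
    return False


def eggs_produced(
    female: Individual,
    factors: FecundityFactors,
    lw: LengthWeightFit,
    fec: FecundityModel,
    density_factor: float,
) -> float:
    """Expected egg count of one mature female this year.

    eggs = (fecundity at current weight) * age factor * density factor; the
    weight comes from the length-weight fit (length cm -> mm).
    """
    if not (female.alive and female.mature and female.female):
        raise VitalsError("eggs_produced requires a live, mature female")
    if not 0 <= density_factor <= 1:
        raise VitalsError("density_factor must lie in [0, 1]")
    w = predict_weight_g(10.0 * female.length, lw)
    return float(fecundity(w, fec)) * factors.factor(female.age) * density_factor


def natural_mortality_rate(
    age: int, sched: MortalitySchedule, newly_mature: bool = False
) -> float:
    """Instantaneous natural mortality of an adult this year.

    Ages 2..7 only (juvenile survival is folded into the single egg-to-age-2
    probability); age 7 uses the 6+ rate.  The maturation cost is added only
    in the year the individual matures.
    """
    if not 2 <= age <= MAX_AGE:
        raise VitalsError(f"natural mortality is defined for ages 2..{MAX_AGE}, got {age}")
    rate = sched.m_by_age[min(age, 6)]
    if newly_mature:
        rate += sched.maturation_cost
    return rate


def survives_natural(rate: float, rng: np.random.Generator) -> bool:
    """Bernoulli survival with probability exp(-rate)."""
    if rate < 0:
        raise VitalsError("mortality rate must be non-negative")
    return bool(rng.random() < np.exp(-rate))
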