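"""Empirical parameterization of vendace life history.

This module turns field samples (scale-annulus growth trajectories,
length-weight pairs, and a gonadosomatic-index table) into the constants the
simulator needs:

* back-calculated lengths-at-age from scale radii (Monastyrsky relation),
* per-fish von Bertalanffy (vB) growth fits,
* the ln(k)-on-L∞ regression that couples growth rate to asymptotic length,
* the allometric length-weight power law,
* the fecundity-weight linear model, and
* age-specific fecundity multipliers derived from GSI ratios
  (reproductive senescence).

Units are explicit throughout: scale radii are in arbitrary but consistent
units, field lengths in mm, simulator lengths in cm, weights in g.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "EmpiricsError",
    "VBFitError",
    "VBParams",
    "LinfKRegression",
    "LengthWeightFit",
    "FecundityModel",
    "FecundityFactors",
    "EmpiricalParameters",
    "back_calculate",
    "vb_length",
    "fit_vb",
    "fit_k_on_linf",
    "fit_length_weight",
    "predict_weight_g",
    "fecundity",
    "gsi_to_factors",
    "recover_k_regression",
]

# Allometric exponent of the Monastyrsky scale-to-body back-calculation,
# pooled estimate across Finnish vendace stocks.
MONASTYRSKY_B = 0.641

# Printed fecundity multipliers for the extrapolated ages (no stated
# extrapolation scheme reproduces them, so they are carried as constants).
EXTRAPOLATED_FACTORS = {5: 0.612, 6: 0.498}


class EmpiricsError(ValueError):
    """Invalid input to a parameterization routine."""


class VBFitError(EmpiricsError):
    """A von Bertalanffy fit failed; carries the offending fish id."""

    def __init__(self, message: str, fish_id=None):
        super().__init__(message)
        self.fish_id = fish_id


@dataclass(frozen=True)
class VBParams:
    """von Bertalanffy growth parameters for one individual.

    ``l_inf`` (asymptotic length) and ``l0`` (length at age 0) share a length
    unit; ``k`` is per year.
    """

    l_inf: float
    k: float
    l0: float = 0.0

    def __post_init__(self):
        if not (self.l_inf > 0 and self.k > 0):
            raise EmpiricsError(f"l_inf and k must be positive, got {self}")
        if not self.l0 < self.l_inf:
            raise EmpiricsError(f"l0 must be below l_inf, got {self}")


@dataclass(frozen=True)
class LinfKRegression:
    """OLS fit of ln(k) on L∞ (cm): ln k = intercept + slope*L∞ + N(0, resid_sd)."""

    intercept: float
    slope: float
    resid_sd: float

    def __post_init__(self):
        if self.resid_sd < 0:
            raise EmpiricsError("resid_sd must be non-negative")

    def predict_ln_k(self, l_inf_cm):
        return self.intercept + self.slope * np.asarray(l_inf_cm, dtype=float)


@dataclass(frozen=True)
class LengthWeightFit:
    """Allometric length-weight relation W = a * L^b with L in mm, W in g."""

    a: float
    b: float

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise EmpiricsError("length-weight parameters must be positive")


@dataclass(frozen=True)
class FecundityModel:
    """Linear egg count model: eggs = intercept + slope * weight_g."""

    intercept: float
    slope: float

    def __post_init__(self):
        if not self.slope > 0:
            raise EmpiricsError("fecundity slope must be positive")


@dataclass(frozen=True)
class FecundityFactors:
    """Age-specific multipliers on the fecundity model.

    Age 1 is pre-reproductive (factor 0). In the senescent mode the factors
    are GSI ratios to age 1 and decline with age; in the non-senescent mode
    every reproductive age has factor 1.
    """

    factor_by_age: Mapping[int, float]

    def __post_init__(self):
        f = dict(self.factor_by_age)
        if f.get(1, 0.0) != 0.0:
            raise EmpiricsError("age-1 fecundity factor must be 0 (pre-reproductive)")
        if any(v < 0 or v > 1 for v in f.values()):
            raise EmpiricsError("fecundity factors must lie in [0, 1]")
        object.__setattr__(self, "factor_by_age", f)

    def factor(self, age: int) -> float:
        ages = self.factor_by_age
        return ages[min(age, max(ages))]

    def as_array(self, max_age: int) -> np.ndarray:
        """Factors indexed by age 0..max_age (ages 0 and 1 are 0)."""
        out = np.zeros(max_age + 1)
        for a in range(1, max_age + 1):
            out[a] = self.factor(a)
        return out


# ---------------------------------------------------------------------------
# Back-calculation
# ---------------------------------------------------------------------------

def back_calculate(
    catch_length: float,
    scale_radius: float,
    annulus_radii: Sequence[float],
    b_exp: float = MONASTYRSKY_B,
) -> np.ndarray:
    """Back-calculate lengths at ages 1..n from scale annuli.

    Monastyrsky relation: ``L_t = L * (S_t / S) ** b`` where ``L`` is the
    length at catch, ``S`` the whole-scale radius and ``S_t`` the radius to
    annulus ``t``.  Returns lengths in the unit of ``catch_length``.
    """
    radii = np.asarray(annulus_radii, dtype=float)
    if b_exp <= 0:
        raise EmpiricsError("Monastyrsky exponent must be positive")
    if catch_length <= 0 or scale_radius <= 0:
        raise EmpiricsError("catch length and scale radius must be positive")
    if radii.size == 0:
        raise EmpiricsError("at least one annulus radius is required")
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise EmpiricsError("annulus radii must be positive and strictly increasing")
    if np.any(radii >= scale_radius):
        raise EmpiricsError("annulus radii must lie inside the scale radius")
    return catch_length * (radii / scale_radius) ** b_exp


# ---------------------------------------------------------------------------
# von Bertalanffy fitting
# ---------------------------------------------------------------------------

def vb_length(t, l_inf, k, l0=0.0):
    """Evaluate the vB curve L_t = L∞ - (L∞ - L0) e^{-kt}."""
    t = np.asarray(t, dtype=float)
    return l_inf - (l_inf - l0) * np.exp(-k * t)


def _profile_rss(k: float, ages: np.ndarray, lengths: np.ndarray, l0, w):
    """For fixed k the vB model is linear in the remaining parameters.

    With free L0 it is linear in (L∞, c) where c = L∞ - L0; with L0 fixed it
    is linear in c alone.  Returns (weighted rss, l_inf, c) from the
    conditional (weighted) linear least-squares fit.
    """
    e = np.exp(-k * ages)
    sw = np.sqrt(w)
    if l0 is None:
        X = sw[:, None] * np.column_stack([np.ones_like(ages), -e])
        beta, *_ = np.linalg.lstsq(X, sw * lengths, rcond=None)
        resid = sw * lengths - X @ beta
        return float(resid @ resid), float(beta[0]), float(beta[1])
    x = 1.0 - e
    y = lengths - l0
    c = float((w * x) @ y / ((w * x) @ x))
    resid = sw * (y - c * x)
    return float(resid @ resid), l0 + c, c


def fit_vb(
    ages: Sequence[float],
    lengths: Sequence[float],
    fish_id=None,
    l0: float | None = None,
    weights=None,
    k_bounds: tuple[float, float] = (0.02, 3.0),
    n_grid: int = 40,
) -> VBParams:
    """Nonlinear least-squares fit of the vB growth curve.

    The only nonlinear parameter is ``k``; the fit profiles it out with a
    conditional linear solve, scans a log-spaced ``k`` grid and polishes the
    best bracket with bounded scalar minimization (objective tolerance 1e-10).

    ``l0`` fixes the length at age 0 (the simulator's convention is L0 = 0);
    ``l0=None`` fits it freely, which needs at least 4 points -- a free
    3-parameter fit to a 3-point trajectory would simply interpolate the
    measurement noise and return an arbitrarily wild L∞.

    ``weights`` are relative inverse-variance weights, used when the points
    have unequal measurement error (e.g. a directly measured catch length is
    far more precise than scale-derived back-calculated lengths).
    """
    ages = np.asarray(ages, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    w = np.ones_like(ages) if weights is None else np.asarray(weights, dtype=float)
    min_pts = 3 if l0 is not None else 4
    if ages.shape != lengths.shape or ages.size < min_pts:
        raise VBFitError(
            f"need at least {min_pts} (age, length) points for this fit", fish_id
        )
    if np.any(lengths <= 0):
        raise VBFitError("lengths must be positive", fish_id)
    if w.shape != ages.shape or np.any(w <= 0):
        raise VBFitError("weights must be positive, one per point", fish_id)

    grid = np.geomspace(k_bounds[0], k_bounds[1], n_grid)
    rss = np.array([_profile_rss(k, ages, lengths, l0, w)[0] for k in grid])
    i = int(np.argmin(rss))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda k: _profile_rss(k, ages, lengths, l0, w)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    k_hat = float(res.x) if res.fun <= rss[i] else float(grid[i])
    _, l_inf, c = _profile_rss(k_hat, ages, lengths, l0, w)
    if not (l_inf > 0 and c > 0 and l_inf > np.max(lengths) * 0.999):
        raise VBFitError(
            f"vB fit degenerate (l_inf={l_inf:.3g}, c={c:.3g})", fish_id
        )
    # Guard against a profiled L∞ marginally below the largest observation.
    l_inf = max(l_inf, np.max(lengths) * (1 + 1e-12))
    return VBParams(l_inf=l_inf, k=k_hat, l0=l_inf - c)


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

def fit_k_on_linf(fits: Sequence[VBParams]) -> LinfKRegression:
    """OLS of ln(k) on L∞ (cm) across individual vB fits.

    The residual SD uses the unbiased n-2 denominator; it later serves as the
    within-genotype spread of ln(k) drawn at birth in the simulator.
    """
    if len(fits) < 3:
        raise EmpiricsError("need at least 3 vB fits for the ln(k)-L∞ regression")
    k = np.array([f.k for f in fits], dtype=float)
    x = np.array([f.l_inf for f in fits], dtype=float)
    if np.any(k <= 0):
        raise EmpiricsError("all k must be positive")
    y = np.log(k)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    resid_sd = math.sqrt(float(resid @ resid) / (len(fits) - 2))
    return LinfKRegression(intercept=float(intercept), slope=float(slope), resid_sd=resid_sd)


def fit_length_weight(pairs: Sequence[tuple[float, float]]) -> LengthWeightFit:
    """Fit W = a L^b by OLS on the log-log scale (L in mm, W in g)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise EmpiricsError("need at least 3 (length, weight) pairs")
    if np.any(arr <= 0):
        raise EmpiricsError("lengths and weights must be positive")
    b, ln_a = np.polyfit(np.log(arr[:, 0]), np.log(arr[:, 1]), 1)
    return LengthWeightFit(a=float(np.exp(ln_a)), b=float(b))


def predict_weight_g(length_mm, fit: LengthWeightFit):
    """Fresh weight (g) at length (mm) under the allometric fit."""
    return fit.a * np.asarray(length_mm, dtype=float) ** fit.b


def fecundity(weight_g, model: FecundityModel):
    """Egg count of a female of the given fresh weight (g)."""
    w = np.asarray(weight_g, dtype=float)
    if np.any(w < 0):
        raise EmpiricsError("weight must be non-negative")
    return model.intercept + model.slope * w


# ---------------------------------------------------------------------------
# GSI-derived fecundity factors
# ---------------------------------------------------------------------------

def gsi_to_factors(
    gsi_by_age: Mapping[int, float],
    max_age: int = 7,
    mode: str = "senescent",
    extrapolate: bool = False,
) -> FecundityFactors:
    """Convert median GSI by age into age-specific fecundity multipliers.

    Senescent mode: factor(age) = GSI(age) / GSI(1) for ages 2..4; ages beyond
    the observed data default to the carried constants (0.612 for age 5, 0.498
    for 6+).  With ``extrapolate=True`` the tail is instead predicted by a
    linear fit of GSI on age over ages 1..4 and expressed as a ratio to age 1
    (clipped to [0, 1]).  Non-senescent mode: 0 at age 1, 1 at all later ages.
    """
    if mode not in ("senescent", "non-senescent"):
        raise EmpiricsError(f"unknown mode {mode!r}")
    if mode == "non-senescent":
        return FecundityFactors({1: 0.0, **{a: 1.0 for a in range(2, max_age + 1)}})

    missing = [a for a in (1, 2, 3, 4) if a not in gsi_by_age]
    if missing:
        raise EmpiricsError(f"GSI table missing ages {missing}")
    if any(gsi_by_age[a] <= 0 for a in (1, 2, 3, 4)):
        raise EmpiricsError("GSI values must be positive")

    base = float(gsi_by_age[1])
    factors = {1: 0.0}
    for a in range(2, min(4, max_age) + 1):
        factors[a] = float(gsi_by_age[a]) / base
    if extrapolate:
        ages = np.array([1.0, 2.0, 3.0, 4.0])
        gsi = np.array([gsi_by_age[a] for a in (1, 2, 3, 4)], dtype=float)
        slope, intercept = np.polyfit(ages, gsi, 1)
        for a in range(5, max_age + 1):
            factors[a] = float(np.clip((intercept + slope * a) / base, 0.0, 1.0))
    else:
        for a in range(5, max_age + 1):
            factors[a] = EXTRAPOLATED_FACTORS[min(a, 6)]
    # Senescent factors must not increase with age.
    vals = [factors[a] for a in sorted(factors) if a >= 2]
    if any(b > a for a, b in zip(vals, vals[1:])):
        raise EmpiricsError("senescent fecundity factors must be non-increasing")
    return FecundityFactors(factors)


# ---------------------------------------------------------------------------
# Pipeline and parameter file
# ---------------------------------------------------------------------------

def recover_k_regression(
    samples,
    b_exp: float = MONASTYRSKY_B,
    catch_season_fraction: float = 1.0,
    catch_weight: float = 16.0,
) -> LinfKRegression:
    """Full parameterization pipeline on a set of field samples.

    For every sample: back-calculate mm lengths at ages 1..n from the scale
    radii, append the measured catch length as the observation at age
    ``n + catch_season_fraction`` (the fish is caught after the plus-growth
    season beyond its last annulus), fit the vB curve with L0 = 0 (the
    simulator's recruit convention), convert to cm, then regress ln(k) on L∞
    across fish.  Fish whose vB fit fails are dropped.

    ``catch_weight`` is the relative inverse-variance weight of the catch
    point: the catch length is a direct caliper measurement (mm precision)
    while back-calculated lengths carry scale-reading error a few mm wide, so
    the catch point is weighted as (length error / catch error)^2 -- 16 for
    the default 2 mm vs 0.5 mm.
    """
    fits = []
    for s in samples:
        lengths_mm = back_calculate(s.catch_length, s.scale_radius, s.annulus_radii, b_exp)
        ages = np.arange(1, lengths_mm.size + 1, dtype=float)
        ages = np.append(ages, s.age_at_catch + catch_season_fraction)
        lengths_cm = np.append(lengths_mm, s.catch_length) / 10.0
        w = np.append(np.ones(lengths_mm.size), catch_weight)
        try:
            fits.append(fit_vb(ages, lengths_cm, fish_id=s.fish_id, l0=0.0, weights=w))
        except VBFitError:
            continue
    return fit_k_on_linf(fits)


@dataclass
class EmpiricalParameters:
    """The simulator's life-history input produced by the parameterization stage."""

    k_regression: LinfKRegression
    length_weight: LengthWeightFit
    fecundity_model: FecundityModel
    factors_senescent: FecundityFactors
    factors_flat: FecundityFactors = field(
        default_factory=lambda: gsi_to_factors({}, mode="non-senescent")
    )

    def to_json(self, path) -> None:
        doc = {
            "k_regression": asdict(self.k_regression),
            "length_weight": asdict(self.length_weight),
            "fecundity_model": asdict(self.fecundity_model),
            "factors_senescent": {str(a): v for a, v in self.factors_senescent.factor_by_age.items()},
            "factors_flat": {str(a): v for a, v in self.factors_flat.factor_by_age.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "EmpiricalParameters":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            k_regression=LinfKRegression(**doc["k_regression"]),
            length_weight=LengthWeightFit(**doc["length_weight"]),
            fecundity_model=FecundityModel(**doc["fecundity_model"]),
            factors_senescent=FecundityFactors({int(a): v for a, v in doc["factors_senescent"].items()}),
            factors_flat=FecundityFactors({int(a): v for a, v in doc["factors_flat"].items()}),
        )
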