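"""Synthetic field samples with the statistical structure of the Lake
Puulavesi vendace collections.

No raw scale-reading data accompany the study system, so this module builds
internally consistent stand-ins: growth trajectories whose catch-length
summaries match the published sample (n = 93, ages 3/4/5/6 in counts
34/20/37/2, catch lengths ~146 +- 8.6 mm), a small length-weight sample, and
the median-GSI-by-age table.  Every sample is generated from an explicit
ground truth (the published ln(k)-L∞ regression and allometric constants), so
the parameterization stage in :mod:`senesim.empirics` can be tested as a
round trip.

Scale radii are synthesized by inverting the Monastyrsky back-calculation
with the same exponent used to read real scales; this is a self-consistent
stand-in, not a model of real scale growth.
"""
from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .empirics import MONASTYRSKY_B

__all__ = [
    "FieldSample",
    "GeneratorTruth",
    "NoiseConfig",
    "DEFAULT_N_BY_AGE",
    "generate_trajectories",
    "generate_weight_data",
    "generate_gsi_table",
    "trajectories_to_csv",
    "trajectories_from_csv",
    "weight_data_to_csv",
    "gsi_table_to_csv",
]

#: Published age composition of the growth-trajectory sample.
DEFAULT_N_BY_AGE = {3: 34, 4: 20, 5: 37, 6: 2}

#: Published median GSI (per mille) by age; the age-1 value printed as "25"
#: is read as 25,000 -- the printed fecundity factors (0.990, 0.927, 0.754)
#: are exactly the ratios to 25,000.
GSI_TABLE = {1: 25_000.0, 2: 24_747.0, 3: 23_184.0, 4: 18_841.0}


@dataclass(frozen=True)
class FieldSample:
    """One sampled fish: catch record plus per-annulus scale radii.

    ``annulus_radii`` has one entry per completed year (strictly increasing,
    all below ``scale_radius``).  ``median_gsi_by_age`` is population-level
    information and usually carried separately (None here).
    """

    fish_id: str
    age_at_catch: int
    catch_length: float  # mm
    scale_radius: float
    annulus_radii: tuple[float, ...]
    fresh_weight: float | None = None  # g
    median_gsi_by_age: Mapping[int, float] | None = None

    def __post_init__(self):
        radii = np.asarray(self.annulus_radii, dtype=float)
        if radii.size != self.age_at_catch:
            raise ValueError("one annulus radius per completed year is required")
        if np.any(np.diff(radii) <= 0) or np.any(radii >= self.scale_radius):
            raise ValueError("annulus radii must be strictly increasing and inside the scale")


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground truth behind the synthetic trajectories.

    ``linf_mean_cm``/``linf_sd_cm`` are calibration constants chosen so the
    catch-length summaries match the published sample; the ln(k) relation and
    Monastyrsky exponent are the published estimates.  ``catch_season_fraction``
    places the catch that fraction of a growth year beyond the last annulus
    (vendace are fished at the end of the open-water season, so nearly a full
    season of plus-growth separates the last annulus from the catch length).
    """

    linf_mean_cm: float = 16.0
    linf_sd_cm: float = 0.9
    k_intercept: float = 1.27
    k_slope: float = -0.13
    k_resid_sd: float = 0.30
    b_exp: float = MONASTYRSKY_B
    catch_season_fraction: float = 1.0
    lw_a: float = 7e-6
    lw_b: float = 2.943


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement noise.

    ``length_sd_mm`` perturbs the back-calculated lengths-at-age (scale
    reading under 20-40x magnification; a couple of mm is typical for small
    coregonids).  ``catch_sd_mm`` perturbs the catch length, a direct caliper
    measurement recorded at 1 mm precision, so its error is a fraction of a
    millimetre.  ``lw_rel_sd`` is the lognormal relative SD of weights about
    the allometric curve.
    """

    length_sd_mm: float = 2.0
    catch_sd_mm: float = 0.5
    lw_rel_sd: float = 0.10

    def __post_init__(self):
        if min(self.length_sd_mm, self.catch_sd_mm, self.lw_rel_sd) < 0:
            raise ValueError("noise SDs must be non-negative")

    def scaled(self, factor: float) -> "NoiseConfig":
        return NoiseConfig(self.length_sd_mm * factor, self.catch_sd_mm * factor,
                           self.lw_rel_sd)


def _vb_mm(linf_cm: float, k: float, t) -> np.ndarray:
    return 10.0 * linf_cm * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def generate_trajectories(
    n_by_age: Mapping[int, int] | None = None,
    truth: GeneratorTruth = GeneratorTruth(),
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    length_window: tuple[float, float] = (120.0, 170.0),
    max_attempts: int = 100,
) -> list[FieldSample]:
    """Generate scale-reading samples from the vB + ln(k)-L∞ ground truth.

    Per fish: draw L∞ ~ N(mean, sd); draw ln k from the published regression
    with its residual SD; evaluate the vB curve (L0 = 0) at integer ages for
    the true back-calculable lengths and at ``age + catch_season_fraction``
    for the catch length; add measurement noise; then invert Monastyrsky
    (scale radius fixed at 1) so the radii are exactly consistent with the
    noisy lengths.  Draws violating monotonicity or the catch-length window
    are redrawn (up to ``max_attempts``); the default window is the published
    range of the field sample (120-170 mm), so the generated catch lengths
    reproduce its mean and spread by construction.
    """
    if n_by_age is None:
        n_by_age = DEFAULT_N_BY_AGE
    if any(c < 0 for c in n_by_age.values()):
        raise ValueError("age-class counts must be non-negative")
    rng = np.random.default_rng(seed)
    samples: list[FieldSample] = []
    fish_no = 0
    for age in sorted(n_by_age):
        for _ in range(n_by_age[age]):
            fish_no += 1
            for attempt in range(max_attempts):
                linf = rng.normal(truth.linf_mean_cm, truth.linf_sd_cm)
                if linf <= 0:
                    continue
                ln_k = truth.k_intercept + truth.k_slope * linf + rng.normal(0.0, truth.k_resid_sd)
                k = float(np.exp(ln_k))
                ages = np.arange(1, age + 1, dtype=float)
                true_lengths = _vb_mm(linf, k, ages)
                true_catch = float(_vb_mm(linf, k, age + truth.catch_season_fraction))
                lengths = true_lengths + rng.normal(0.0, noise.length_sd_mm, size=age)
                catch = true_catch + rng.normal(0.0, noise.catch_sd_mm)
                ok = (
                    np.all(lengths > 0)
                    and np.all(np.diff(lengths) > 0)
                    and np.all(lengths < catch)
                    and length_window[0] <= catch <= length_window[1]
                )
                if not ok:
                    continue
                radii = (lengths / catch) ** (1.0 / truth.b_exp)
                samples.append(
                    FieldSample(
                        fish_id=f"F{fish_no:03d}",
                        age_at_catch=age,
                        catch_length=float(catch),
                        scale_radius=1.0,
                        annulus_radii=tuple(float(r) for r in radii),
                    )
                )
                break
            else:
                raise RuntimeError(
                    f"no admissible trajectory for age {age} after {max_attempts} attempts"
                )
    return samples


def generate_weight_data(
    n: int = 27,
    lw_truth: tuple[float, float] = (7e-6, 2.943),
    noise_sd: float = 0.10,
    seed: int = 0,
    length_range: tuple[float, float] = (120.0, 170.0),
    length_mean: float = 146.0,
    length_sd: float = 8.63,
) -> list[tuple[float, float]]:
    """(length mm, weight g) pairs: W = a L^b exp(N(0, noise_sd)).

    Lengths are normal draws matching the published sample moments, clipped
    to the published range.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    a, b = lw_truth
    rng = np.random.default_rng(seed)
    lengths = np.clip(rng.normal(length_mean, length_sd, size=n), *length_range)
    weights = a * lengths**b * np.exp(rng.normal(0.0, noise_sd, size=n))
    return [(float(l), float(w)) for l, w in zip(lengths, weights)]


def generate_gsi_table(age1_gsi: float | None = None) -> dict[int, float]:
    """The median-GSI-by-age table (ages 1..4).

    ``age1_gsi`` overrides the 25,000 reading of the age-1 entry.
    """
    table = dict(GSI_TABLE)
    if age1_gsi is not None:
        table[1] = float(age1_gsi)
    return table


# ---------------------------------------------------------------------------
# CSV interfaces (RFC-4180, header row, UTF-8)
# ---------------------------------------------------------------------------

def trajectories_to_csv(samples: Sequence[FieldSample], path_or_buf) -> None:
    """Long format: fish_id, age, annulus_radius, scale_radius, catch_length."""

    def _write(fh):
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["fish_id", "age", "annulus_radius", "scale_radius", "catch_length"])
        for s in samples:
            for age, r in enumerate(s.annulus_radii, start=1):
                w.writerow([s.fish_id, age, repr(r), repr(s.scale_radius), repr(s.catch_length)])

    if isinstance(path_or_buf, io.IOBase):
        _write(path_or_buf)
    else:
        with open(path_or_buf, "w", encoding="utf-8", newline="") as fh:
            _write(fh)


def trajectories_from_csv(path_or_buf) -> list[FieldSample]:
    import pandas as pd

    df = pd.read_csv(path_or_buf)
    samples = []
    for fish_id, grp in df.groupby("fish_id", sort=False):
        grp = grp.sort_values("age")
        samples.append(
            FieldSample(
                fish_id=str(fish_id),
                age_at_catch=int(grp["age"].max()),
                catch_length=float(grp["catch_length"].iloc[0]),
                scale_radius=float(grp["scale_radius"].iloc[0]),
                annulus_radii=tuple(float(r) for r in grp["annulus_radius"]),
            )
        )
    return samples


def weight_data_to_csv(pairs: Sequence[tuple[float, float]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["length_mm", "weight_g"])
        for l, wt in pairs:
            w.writerow([repr(l), repr(wt)])


def gsi_table_to_csv(table: Mapping[int, float], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["age", "median_gsi"])
        for age in sorted(table):
            w.writerow([age, repr(table[age])])
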