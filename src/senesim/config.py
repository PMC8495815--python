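"""Assembly of default configurations and YAML/JSON round-tripping.

The four study scenarios differ only in which senescence channels are
switched on (age-increasing natural mortality; GSI-derived declining
fecundity factors) and in the gear used during the fishing phase.
"""
from __future__ import annotations

from dataclasses import asdict, replace

import yaml

from .empirics import FecundityFactors, gsi_to_factors
from .engine import DensityConfig, ScenarioConfig, SimConfig
from .genetics import PhenotypeMap
from .synthdata import generate_gsi_table
from .vitals import LifeHistoryConfig, constant_mortality, senescent_mortality

__all__ = ["make_sim_config", "make_scenario", "dump_config", "load_config"]


def make_sim_config(
    reproductive_senescence: bool = False,
    actuarial_senescence: bool = False,
    dd_slope: float | None = None,
    env_sd: float | None = None,
) -> SimConfig:
    """Default simulation bundle for a given senescence mode."""
    factors = gsi_to_factors(
        generate_gsi_table(),
        mode="senescent" if reproductive_senescence else "non-senescent",
    )
    life = LifeHistoryConfig(fecundity_factors=factors)
    mortality = senescent_mortality() if actuarial_senescence else constant_mortality()
    sim = SimConfig(life=life, mortality=mortality)
    if dd_slope is not None:
        sim.density = replace(sim.density, dd_slope=dd_slope)
    if env_sd is not None:
        sim.pmap = replace(sim.pmap, env_sd=env_sd)
    return sim


def make_scenario(
    senescent: bool = False, gear: str = "none", seed: int = 0, n_replicates: int = 100
) -> tuple[SimConfig, ScenarioConfig]:
    """The standard paired design: both senescence channels on, or neither."""
    sim = make_sim_config(senescent, senescent)
    scen = ScenarioConfig(
        reproductive_senescence=senescent,
        actuarial_senescence=senescent,
        gear=gear,
        seed=seed,
        n_replicates=n_replicates,
    )
    return sim, scen


def dump_config(path, sim: SimConfig, scenario: ScenarioConfig) -> None:
    doc = {
        "scenario": asdict(scenario),
        "density": asdict(sim.density),
        "phenotype_map": asdict(sim.pmap),
        "mortality": asdict(sim.mortality),
        "life": {
            "fecundity_model": asdict(sim.life.fecundity_model),
            "length_weight": asdict(sim.life.length_weight),
            "fecundity_factors": {
                str(a): v for a, v in sim.life.fecundity_factors.factor_by_age.items()
            },
            "k_regression": asdict(sim.life.k_regression),
            "maturation_fraction": sim.life.maturation_fraction,
            "min_maturation_age": sim.life.min_maturation_age,
            "max_age": sim.life.max_age,
            "egg_to_age2_survival": sim.life.egg_to_age2_survival,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> tuple[SimConfig, ScenarioConfig]:
    from .empirics import FecundityModel, LengthWeightFit, LinfKRegression
    from .vitals import MortalitySchedule

    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    life_doc = doc["life"]
    life = LifeHistoryConfig(
        fecundity_model=FecundityModel(**life_doc["fecundity_model"]),
        length_weight=LengthWeightFit(**life_doc["length_weight"]),
        fecundity_factors=FecundityFactors(
            {int(a): v for a, v in life_doc["fecundity_factors"].items()}
        ),
        k_regression=LinfKRegression(**life_doc["k_regression"]),
        maturation_fraction=life_doc["maturation_fraction"],
        min_maturation_age=life_doc["min_maturation_age"],
        max_age=life_doc["max_age"],
        egg_to_age2_survival=life_doc["egg_to_age2_survival"],
    )
    mort_doc = dict(doc["mortality"])
    mort_doc["m_by_age"] = {int(a): v for a, v in mort_doc["m_by_age"].items()}
    sim = SimConfig(
        life=life,
        pmap=PhenotypeMap(**doc["phenotype_map"]),
        density=DensityConfig(**doc["density"]),
        mortality=MortalitySchedule(**mort_doc),
    )
    return sim, ScenarioConfig(**doc["scenario"])
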