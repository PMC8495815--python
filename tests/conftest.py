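import numpy as np
import pytest

from senesim import engine
from senesim.config import make_scenario, make_sim_config
from senesim.engine import ScenarioConfig


@pytest.fixture(scope="session")
def nonsen_equilibrium():
    """Full unfished burn-in of the default (no-senescence) configuration."""
    sim = make_sim_config(False, False)
    res = engine.burn_in(sim, ScenarioConfig(seed=11), years=1000)
    return sim, res


@pytest.fixture(scope="session")
def sen_equilibrium():
    """Full unfished burn-in with both senescence channels active."""
    sim = make_sim_config(True, True)
    res = engine.burn_in(sim, ScenarioConfig(seed=11), years=1000)
    return sim, res


@pytest.fixture(scope="session")
def scenario_runs(nonsen_equilibrium, sen_equilibrium):
    """Paired 500-year replicate runs for the gear x senescence design.

    20 replicates per combination; replicate i shares its RNG stream seed
    across all four combinations (paired-seed design), starting from the
    respective equilibrium snapshot.
    """
    n_reps = 20
    streams = np.random.SeedSequence(2024).spawn(n_reps)
    out = {}
    for sen, (sim, res) in ((False, nonsen_equilibrium), (True, sen_equilibrium)):
        for gear in ("trawl", "gillnet"):
            _, scen = make_scenario(senescent=sen, gear=gear, n_replicates=n_reps)
            runs = [
                engine.run_years(
                    res.population.copy(), sim, scen, np.random.default_rng(ss)
                )
                for ss in streams
            ]
            out[(sen, gear)] = runs
    return out
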