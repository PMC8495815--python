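import numpy as np
import pandas as pd
import pytest

from senesim import engine
from senesim.config import make_scenario, make_sim_config
from senesim.engine import (
    DensityConfig,
    Population,
    ScenarioConfig,
    density_factor,
)
from senesim.vitals import MortalitySchedule


def small_population(sim, n=400, seed=0, aged=True):
    rng = np.random.default_rng(seed)
    pop = engine.founder_population(n, sim.life, sim.pmap, rng, length_cm=6.0)
    if aged:
        pop.age = rng.integers(2, 6, n).astype(np.int16)
        pop.length = 0.7 * pop.l_inf
        pop.mature = pop.length >= 0.67 * pop.l_inf
        pop.age_mat = np.where(pop.mature, 2.0, np.nan)
        pop.len_mat = np.where(pop.mature, pop.length, np.nan)
    return pop


class TestDensityFactor:
    def test_half_growth_at_85pct_of_capacity(self):
        cfg = DensityConfig(carrying_capacity=75.0, dd_slope=-5.0)
        assert density_factor(0.85 * 75.0, cfg) == pytest.approx(0.5, abs=1e-15)

    def test_empty_water_gives_nearly_full_growth(self):
        cfg = DensityConfig(carrying_capacity=75.0, dd_slope=-15.0)
        assert density_factor(0.0, cfg) == pytest.approx(0.99999, abs=1e-5)

    def test_at_capacity_growth_is_strongly_reduced(self):
        cfg = DensityConfig(carrying_capacity=75.0, dd_slope=-15.0)
        assert density_factor(75.0, cfg) == pytest.approx(0.095, abs=0.001)

    def test_strictly_decreasing_and_bounded(self):
        cfg = DensityConfig()
        vals = [density_factor(b, cfg) for b in np.linspace(0, 150, 40)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert all(0 < v < 1 for v in vals)

    def test_positive_slope_rejected(self):
        with pytest.raises(engine.EngineError):
            DensityConfig(dd_slope=1.0)


class TestAnnualStep:
    def test_empty_population_yields_zero_record(self):
        sim = make_sim_config()
        pop, rec = engine.annual_step(Population.empty(), sim, 0, np.random.default_rng(0))
        assert pop.n == 0 and rec.n_fish == 0 and rec.biomass_units == 0.0

    def test_no_mature_males_means_no_recruits(self):
        sim = make_sim_config()
        pop = small_population(sim, n=200, seed=1)
        pop.female[:] = True
        pop, rec = engine.annual_step(pop, sim, 0, np.random.default_rng(0))
        assert rec.recruits == 0

    def test_conservation_without_mortality(self):
        """With natural mortality disabled and no fishing, individuals are
        conserved: n' = n + recruits (no fish is old enough to age out)."""
        sim = make_sim_config()
        pop = small_population(sim, n=500, seed=2)
        n0 = pop.n
        pop, rec = engine.annual_step(
            pop, sim, 0, np.random.default_rng(3), disable_natural_mortality=True
        )
        assert pop.n == n0 + rec.recruits
        assert rec.natural_deaths == 0

    def test_lifespan_cap_removes_age_seven(self):
        sim = make_sim_config()
        pop = small_population(sim, n=100, seed=4)
        pop.age[:] = 7
        pop, _ = engine.annual_step(pop, sim, 0, np.random.default_rng(0),
                                    disable_natural_mortality=True)
        assert pop.n == 0 or pop.age.max() <= 7
        assert np.all(pop.age <= 7)

    def test_length_never_exceeds_linf(self):
        sim = make_sim_config()
        pop = small_population(sim, n=300, seed=5)
        for year in range(10):
            pop, _ = engine.annual_step(pop, sim, year, np.random.default_rng(year))
            assert np.all(pop.length <= pop.l_inf + 1e-9)


class TestBurnIn:
    def test_zero_founders_raise_extinction(self):
        sim = make_sim_config()
        with pytest.raises(engine.ExtinctionError):
            engine.founder_population(0, sim.life, sim.pmap, np.random.default_rng(0))

    def test_carrying_capacity_scales_equilibrium_biomass(self):
        """Doubling the carrying capacity roughly doubles equilibrium biomass."""
        ratios = []
        for seed in range(3):
            tails = []
            for cc in (75.0, 150.0):
                sim = make_sim_config()
                sim.density = DensityConfig(carrying_capacity=cc, dd_slope=sim.density.dd_slope)
                res = engine.burn_in(sim, ScenarioConfig(seed=seed, initial_n=1000), years=350)
                tails.append(res.records["biomass_units"].tail(80).mean())
            ratios.append(tails[1] / tails[0])
        assert 1.6 <= np.mean(ratios) <= 2.4

    def test_equilibrium_biomass_in_published_band(self, nonsen_equilibrium):
        _, res = nonsen_equilibrium
        tail = res.records["biomass_units"].tail(100)
        assert 56.0 <= tail.mean() <= 61.0
        assert res.stable

    def test_biomass_never_exceeds_twice_capacity(self, nonsen_equilibrium):
        _, res = nonsen_equilibrium
        assert res.records["biomass_units"].max() <= 150.0

    def test_demographic_balance_at_equilibrium(self, nonsen_equilibrium):
        """Annual natural deaths balance recruits reaching age 2 (the
        recruits of two years earlier, since juveniles carry no mortality)."""
        _, res = nonsen_equilibrium
        r = res.records.tail(52)
        removals = (r["natural_deaths"] + r["aged_out"]).iloc[2:].to_numpy(float)
        arriving = r["recruits"].iloc[:-2].to_numpy(float)
        ratio = arriving.mean() / removals.mean()
        assert 0.8 <= ratio <= 1.25


class TestReproducibility:
    def test_identical_seed_gives_identical_series(self):
        sim, scen = make_scenario(senescent=False, gear="trawl", n_replicates=1)
        scen = ScenarioConfig(
            gear="trawl", pristine_years=15, fishing_years=5, recovery_years=5,
            n_replicates=1,
        )
        pop0 = small_population(sim, n=600, seed=6)
        frames = []
        for _ in range(2):
            rr = engine.run_years(pop0.copy(), sim, scen, np.random.default_rng(77))
            frames.append(rr.records)
        pd.testing.assert_frame_equal(frames[0], frames[1])
        other = engine.run_years(pop0.copy(), sim, scen, np.random.default_rng(78))
        assert not frames[0].equals(other.records)

    def test_gear_none_never_catches(self):
        sim, scen = make_scenario(senescent=False, gear="none")
        scen = ScenarioConfig(gear="none", pristine_years=5, fishing_years=5,
                              recovery_years=2, n_replicates=1)
        pop0 = small_population(sim, n=400, seed=7)
        rr = engine.run_years(pop0.copy(), sim, scen, np.random.default_rng(0))
        assert (rr.records["catch_biomass_units"] == 0).all()
        assert (rr.records["catch_n"] == 0).all()

    def test_run_scenario_replicates_are_deterministic(self):
        sim, _ = make_scenario()
        scen = ScenarioConfig(gear="trawl", pristine_years=8, fishing_years=4,
                              recovery_years=2, n_replicates=3, seed=5)
        pop0 = small_population(sim, n=400, seed=8)
        a = engine.run_scenario(sim, scen, [pop0])
        b = engine.run_scenario(sim, scen, [pop0])
        for ra, rb in zip(a, b):
            pd.testing.assert_frame_equal(ra.records, rb.records)


class TestSnapshotIO:
    def test_population_csv_round_trip(self, tmp_path):
        sim = make_sim_config()
        pop = small_population(sim, n=50, seed=9)
        path = tmp_path / "snap.csv"
        engine.population_to_csv(pop, path)
        back = engine.population_from_csv(path)
        assert back.n == pop.n
        assert np.array_equal(back.age, pop.age)
        assert np.array_equal(back.female, pop.female)
        assert np.allclose(back.length, pop.length)
        assert np.allclose(back.l_inf, pop.l_inf)
        assert np.array_equal(back.genotype, pop.genotype)

    def test_run_metadata_written(self, tmp_path):
        import json

        sim, scen = make_scenario()
        path = tmp_path / "meta.json"
        engine.write_run_metadata(path, sim, scen, extra={"note": 1})
        doc = json.loads(path.read_text())
        assert doc["density"]["dd_slope"] == sim.density.dd_slope
        assert doc["note"] == 1


class TestCalibration:
    def test_calibrate_dd_slope_returns_candidate_in_band(self):
        sim = make_sim_config()
        chosen, table = engine.calibrate_dd_slope(
            sim, candidates=(-5.0,), years=350, seed=0
        )
        assert chosen == -5.0
        assert len(table) == 1


class TestMortalityScheduleValidation:
    def test_incomplete_schedule_rejected(self):
        with pytest.raises(Exception):
            MortalitySchedule("constant", {2: 0.2, 3: 0.2})
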