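# senesim

An individual-based eco-evolutionary simulation of how **senescence** shapes
the dynamics of a vendace-like (*Coregonus albula*) fish population under
size-selective fishing. It is aimed at fisheries scientists and
life-history theorists who want to ask: all else equal, what do an
age-increasing natural mortality rate (actuarial senescence) and an
age-declining reproductive output (reproductive senescence) do to a
population's asymptotic length, biomass, and abundance across pristine,
intensively harvested, and recovery phases?

## The model

Each fish grows along its own von Bertalanffy curve

```
L_t = L∞ − (L∞ − L0) e^(−k t)
```

where the asymptotic length L∞ is an evolving quantitative trait: 10 diploid
loci with 0/1 alleles, Mendelian inheritance, an affine allele-sum → L∞ map
plus a normal environmental deviation calibrated so the midparent–offspring
heritability is h² ≈ 0.2–0.3. The growth coefficient is tied to L∞ through
the empirically fitted relation `ln k = 1.27 − 0.13·L∞` (residual SD 0.30),
so small-L∞ genotypes grow fast and mature early.

The annual cycle: density-dependent growth (a logistic function of biomass
relative to carrying capacity — at 85% of capacity, growth time is halved),
size-gated maturation (67% of L∞, never before the second autumn, with a
one-off survival cost), random mating with weight-based fecundity
(`eggs = 39.06 + 118.47·W`, W from `W = a·L^b`), an egg-to-age-2 survival of
p = 0.002, instantaneous natural mortality by age class, and optionally a
fishery: logistic (trawl/seine) or dome-shaped (gillnet) retention with
F = 0.7 for the fully selected length.

Senescence enters in two switchable channels, parameterized by age class:

| age class            | 2     | 3     | 4     | 5     | 6+    |
|----------------------|-------|-------|-------|-------|-------|
| M, no senescence     | 0.257 | 0.257 | 0.257 | 0.257 | 0.257 |
| M, senescent         | 0.200 | 0.258 | 0.314 | 0.372 | 0.428 |
| fecundity factor     | 0.990 | 0.927 | 0.754 | 0.612 | 0.498 |

The empirical layer is re-fittable: scale-annulus growth trajectories are
back-calculated with Monastyrsky's relation `L_t = L·(S_t/S)^0.641`, refit
per fish, and regressed to recover the ln(k)–L∞ coupling. Because the raw
Lake Puulavesi samples are not public, `senesim.synthdata` generates
statistically matched stand-ins (n = 93, ages 3/4/5/6 in counts 34/20/37/2,
catch lengths ~120–170 mm) from a declared ground truth, making the whole
parameterization stage testable as a round trip.

## Worked example

```python
import numpy as np
from senesim import empirics, engine, genetics, synthdata
from senesim.config import make_sim_config
from senesim.engine import ScenarioConfig

# 1. synthesize a field sample and refit the growth machinery
samples = synthdata.generate_trajectories(seed=1)
reg = empirics.recover_k_regression(samples)
print(f"ln(k) = {reg.intercept:.2f} {reg.slope:+.2f} * L_inf   (resid SD {reg.resid_sd:.2f})")

lw = empirics.fit_length_weight(synthdata.generate_weight_data(seed=1))
print(f"W = {lw.a:.2e} * L^{lw.b:.3f}  ->  {empirics.predict_weight_g(146, lw):.1f} g at 146 mm")

factors = empirics.gsi_to_factors(synthdata.generate_gsi_table())
print("fecundity factors:", {a: round(factors.factor(a), 3) for a in range(1, 8)})

# 2. burn a population in to ecological and evolutionary equilibrium (~20 s)
sim = make_sim_config(reproductive_senescence=False, actuarial_senescence=False)
res = engine.burn_in(sim, ScenarioConfig(seed=1), years=1000)
tail = res.records.tail(100)
print(f"equilibrium: biomass {tail.biomass_units.mean():.1f} units, "
      f"N {tail.n_fish.mean():.0f}, mean L_inf {tail.mean_l_inf.mean():.2f} cm, "
      f"stable={res.stable}")

# 3. heritability of L∞ on the equilibrium population
env = genetics.calibrate_env_sd(sim.pmap, res.population.genotype,
                                rng=np.random.default_rng(0))
pmap = genetics.PhenotypeMap(env_sd=env)
mid, off = genetics.simulate_midparent_offspring(
    res.population.genotype, pmap, np.random.default_rng(1), n_pairs=5000)
print(f"calibrated env SD {env:.2f} cm -> h2 = "
      f"{genetics.estimate_heritability(mid, off):.2f}")
```

prints (seed 1):

```
ln(k) = 1.01 -0.11 * L_inf   (resid SD 0.23)
W = 1.47e-05 * L^2.794  ->  16.4 g at 146 mm
fecundity factors: {1: 0.0, 2: 0.99, 3: 0.927, 4: 0.754, 5: 0.612, 6: 0.498, 7: 0.498}
equilibrium: biomass 58.6 units, N 23546, mean L_inf 10.56 cm, stable=True
calibrated env SD 2.12 cm -> h2 = 0.24
```

Reading the numbers: a single 93-fish synthetic sample recovers the
ln(k)–L∞ coupling with the right sign and magnitude (the generating slope is
−0.13; single-sample estimates scatter around it); the fitted length–weight
curve predicts 16.4 g at the mean catch length; the unfished population
levels off at ~59 biomass units against a carrying capacity of 75 (within
the expected 56–61 band) with a mean asymptotic length near 10.6 cm under
density-dependent stunting; and the calibrated environmental deviation puts
the heritability of L∞ at 0.24.

The full experiment — 500-year scenarios (200 pristine / 100 fishing / 200
recovery) replicated from saved burn-in snapshots — runs through the CLI:

```bash
senesim synth --seed 1 --out data/
senesim parameterize --data data/ --out params.json
senesim burn-in --out snapshots/ --snapshots 100
senesim simulate --snapshots snapshots/ --out results/ --replicates 100 --seed 1
senesim summarize --results results/ --baseline 0:100 --out summary/
```

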