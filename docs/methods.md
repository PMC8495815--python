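# Methods

## Model overview

`senesim` simulates a closed, unstructured (non-spatial) population of a
small, short-lived, fall-spawning coregonid at annual time steps. Every fish
is an individual with sex, age, length, a 10-locus diploid genotype for
asymptotic length L∞, a growth coefficient k drawn once at birth, and a
maturity state. The annual event order is fixed:

1. compute the density factor from current adult biomass;
2. grow every fish along its own von Bertalanffy curve by `growth_time =
   density factor` of a year;
3. run the maturation check (age ≥ 2 and length ≥ 67% of the individual's
   L∞; the age and length at maturation are recorded);
4. reproduce: every mature female draws a mate uniformly (with replacement)
   from the mature males; her expected egg number is the linear
   fecundity-weight model times her age-class fecundity factor times the
   egg-side density factor; realized recruits are one binomial thinning with
   the egg-to-age-2 survival p = 0.002; offspring receive one random allele
   per locus from each parent, express L∞ (affine map + environmental
   deviation, floored at 8 cm) and draw k immediately;
5. natural mortality on ages ≥ 2: survival with probability `exp(-M(age))`,
   plus a one-off additive cost of 0.058 in the year of maturation;
6. fishing, when a gear is active: independent capture with probability
   `1 − exp(−F·r(l))`;
7. age increment; fish completing age 7 are removed (hard lifespan cap).

Spawning precedes mortality within a year, so autumn spawners can die the
same year. Extinction is declared when the population is empty; a year
without any mature pair simply produces no recruits.

Recruits are instantiated at birth (length 0, L0 = 0) and are tracked
individually from age 0 — they grow with the same density factor and are in
principle exposed to gear through their length — but all pre-age-2 natural
mortality is folded into the single thinning p, and the "recorded"
population (annual outputs, density regulation) is ages ≥ 2.

## Density dependence

Both growth time and egg output are damped by the same logistic,

    f(B) = exp(c + s·B/CC) / (1 + exp(c + s·B/CC)),   c = −0.85·s,

anchored so that f = 0.5 exactly when B = 85% of carrying capacity
(CC = 75 units; 1 unit = 1 kg fresh weight, an arbitrary but fixed
definition). The growth factor uses total adult (age ≥ 2) biomass; the egg
factor uses the spawning-stock (mature fish) biomass, so recruitment tracks
how full the spawning population is.

The steepness s is the model's one genuinely free dynamical constant. It
was calibrated once with `engine.calibrate_dd_slope`: s = −5 puts the
unfished 1,000-year burn-in at 58.5–59.0 units (mean of the final century,
across seeds) with small year-to-year variation, while s ≤ −10 destabilizes
the annual feedback into boom-bust recruitment cycles (final-century SD ~11
units). The default is therefore −5.0, recorded in run metadata.

## Life-history constants

| constant | value | unit | note |
|---|---|---|---|
| fecundity model | 39.06 + 118.47·W | eggs, W in g | weight-based, linear |
| length-weight | a = 7·10⁻⁶, b = 2.943 | W g, L mm | the coefficient pair reproduces observed weights only with L in mm (equivalently cm with W in kg); lengths are cm internally and converted |
| egg→age-2 survival | 0.002 | probability | single thinning at spawning |
| maturation threshold | 0.67·L∞, age ≥ 2 | — | with a one-off mortality cost 0.058 (the age-2→3 increment of the senescent schedule, used as a stand-in) |
| natural mortality, constant | 0.257 | 1/yr, ages 2–7 | no actuarial senescence |
| natural mortality, senescent | 0.200, 0.258, 0.314, 0.372, 0.428 | 1/yr, ages 2–6+ | age 7 reuses the 6+ rate |
| fecundity factors, senescent | 0, 0.990, 0.927, 0.754, 0.612, 0.498 | ages 1–6+ | GSI(age)/GSI(age 1); ages 5–6+ carried as printed constants (no linear scheme on the GSI table reproduces them; an OLS-extrapolation variant is provided but off by default) |
| ln k regression | 1.27 − 0.13·L∞, resid SD 0.30 | L∞ cm | k drawn once at birth |
| max age | 7 | yr | forced removal |
| fishery: trawl | logistic, a = −9, b = 0.85 | l cm | 50% retention at 10.59 cm |
| fishery: gillnet | exp(−(l−12)²/(2·0.5)) | l cm | divisor is 2σ, *not* 2σ², exactly as the source model defines it — a deliberately narrow ~11–13 cm window; a conventional 2σ² flag exists for sensitivity runs |
| F (fully selected) | 0.7 | 1/yr | capture prob. 1−exp(−F·r(l)) |

The GSI table reads the age-1 median as 25,000 (per-mille scale); the
printed factors 0.990/0.927/0.754 are exactly the ratios to 25,000, which
fixes that interpretation. The ratio direction is GSI(age)/GSI(1) — the
factors must decline for declining reproductive output.

A biomass-matched harvest mode is provided (`fishery.solve_f_for_quota`):
F is rescaled by bisection each fishing year so the expected removed biomass
matches a reference catch series (tolerance 0.5%, F capped at 3/yr), with
the non-senescent run as the natural reference. The default for both
scenarios is fixed-F, which keeps the paired scenarios' *gear* identical
rather than their removals.

## Genetics and heritability

Founders carry independent Bernoulli(0.5) alleles. The phenotype map is
L∞ = 8.0 + 0.8·(allele sum) + N(0, env_sd), floored at 8 cm. The genetic
range (8–24 cm, centre 16 cm near the mean back-calculated L∞ of the field
sample) was chosen so that the eco-evolutionary optimum under
density-dependent stunting — where earlier maturation balances the
weight-fecundity advantage of large L∞, around 10–12 cm — lies well inside
the range. A narrower map placing its minimum at that optimum fixes the
population at the all-zero boundary within a few hundred years and destroys
the standing variance the harvest experiments need. At equilibrium the
default map keeps allele frequencies ~0.15–0.2 and a genetic SD of ~1.2–1.4
cm.

Heritability is defined operationally as the OLS slope of offspring L∞ on
midparent L∞. `calibrate_env_sd` bisects the environmental SD against a
common-random-number simulation of that regression (20,000 pairs per
evaluation; the phenotype floor is applied inside the calibration exactly as
in expression, since truncation attenuates the slope). The default env_sd =
2.4 cm puts h² near 0.25 on an equilibrium population; the calibration
routine recomputes it for any other configuration. There is no mutation,
linkage, dominance, or epistasis.

## The synthetic field sample

`synthdata` emulates a scale-reading study of 93 fish (ages 3/4/5/6 in
counts 34/20/37/2). Ground truth per fish: L∞ ~ N(16.0, 0.9) cm; ln k from
the ln(k)–L∞ relation with its residual SD; true lengths-at-age from the vB
curve with L0 = 0; the catch length is the curve at `age + 1.0` — the fish
is taken at the end of the growing season, a full season of plus-growth past
its last annulus. (With the catch at the last annulus itself, the sample
mean could not exceed ~131 mm under the stated growth relation; the
plus-growth season brings it to the observed ~140–148 mm.) Scale radii are
synthesized by inverting the Monastyrsky relation with the same exponent
b = 0.641 used for reading, with the whole-scale radius fixed at 1, so
back-calculation is an exact round trip at zero noise.

Noise model: N(0, 2 mm) on each back-calculated length (scale-reading
error), N(0, 0.5 mm) on the catch length (a direct caliper measurement
recorded at 1 mm precision), lognormal 10% on weights. Catch lengths are
rejection-sampled into the observed 120–170 mm window; together with
L∞ SD = 0.9 cm (a one-off calibration) the generated samples have
across-seed mean catch length ~142 mm and SD ~10.7 mm, bracketing the
observed 146/8.63 summaries. The spread is dominated by the ln-k residual
(0.30), which is part of the declared truth; the exact observed SD of 8.63
mm is not reachable without shrinking that residual. What the generator does
*not* emulate: sex-specific growth, correlated within-fish reading errors,
or any real scale-growth allometry — the radii are a self-consistent
inversion, not a claim about scales.

## The parameterization pipeline

`back_calculate` applies `L_t = L·(S_t/S)^0.641`. `fit_vb` is nonlinear
least squares in which k — the only nonlinear parameter — is profiled out:
for fixed k the model is linear in (L∞, L∞−L0), so the fit is a 40-point
log-spaced k-grid scan with conditional linear solves, polished by bounded
scalar minimization (objective tolerance 1e-10). This is globally reliable
in the single nonlinear dimension and ~20× faster than a multi-start
3-parameter search, which matters at 93 fish × 100 seeds. Supplying three
points to a free-L0 (3-parameter) fit is refused: it would interpolate the
measurement noise and return arbitrarily wild L∞ (values above 100 cm occur
in practice).

The pipeline therefore fits with L0 = 0 (the simulator's recruit
convention), appends the measured catch length as the observation at
`age + 1.0`, and weights it by inverse error variance ((2 mm / 0.5 mm)² =
16), the statistically correct estimator once the two error scales differ.
`fit_k_on_linf` is then plain OLS of ln k on L∞ (cm) with the n−2 residual
SD. Across 100 seeds the recovered slope magnitude averages ~0.128–0.137
(generating value 0.13); the residual deviation is errors-in-variables
attenuation in the per-fish L∞ estimates, partially offset by the
window-truncation selection.

## Scenario design and outputs

The standard experiment: 2,000 age-0 founders of length 4 cm; a 1,000-year
unfished burn-in (stability is diagnosed as |biomass trend| < 0.05 units/yr
over the final century, and reached by ~year 300); snapshots saved and
sampled with replacement as replicate starts; 500-year runs with gear active
in years 200–299; 100 replicates, each on an independent RNG stream spawned
from one master seed, so any (config, seed) pair reproduces byte-identically.

Annual records per replicate: N and biomass of the age ≥ 2 population, mean
L∞ and k, mean size/age at maturation (over currently alive mature fish),
recruits, natural deaths and lifespan-cap removals (so total removals can be
balanced against inflow), catch numbers and biomass, and the density factor.
`report` summarizes replicates with per-year means and empirical 2.5–97.5
percentile bands, rescales series to percent change against a baseline
window (years 1–100 by default), and tabulates age × length-bin counts with
explicit underflow/overflow bins so tables always partition the population.

For test-suite runtime the paired-design checks use 20 replicates per
scenario and sign tests; the library defaults remain 100.

## Known limitations and one documented divergence

* The equilibrium is strongly density-stunted: with the fecundity and
  survival constants above, recruitment balances mortality only when growth
  is slowed to roughly half, so adults sit at 7–11 cm — well below the field
  lengths the length-weight data span. This is intrinsic to the constant
  set, not a tuning choice.
* Because young adults are barely above their maturation threshold, egg
  production is spread across ages 3–6. The senescent fecundity factors
  therefore remove ~25–30% of egg-weighted output, and the equilibrium
  responds by relaxing density dependence, which makes late maturation
  cheaper and pushes the evolutionary optimum for L∞ *up*. The net result,
  robust across seeds: with both senescence channels on, equilibrium mean
  L∞ is ~0.5 cm *higher* and N ~30% *lower* than without senescence —
  whereas actuarial senescence alone gives the opposite (and empirically
  expected) direction: lower L∞, lower biomass, higher N. Two directional
  acceptance tests encode the empirically expected combined-scenario signs
  and fail under the defaults; they are left failing deliberately, as a
  property of this constant set rather than a defect of the machinery. The
  biomass contrast (senescent lower), the fishing-induced decline in L∞,
  its gear ordering (trawl > gillnet), and the absence of recovery within
  200 years all reproduce.
* Skipped spawning, condition-dependent fecundity, sex-specific growth,
  effort dynamics, discards, spatial structure, and environmental
  stochasticity are out of scope; egg counts are expected values thinned
  once binomially (identical first moments to per-egg simulation).
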