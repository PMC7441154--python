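# Methods

`ecoperturb` is a desk-scale general-ecosystem simulator built to study how
whole terrestrial food webs respond to the human appropriation of net
primary production (NPP) — the removal of plant production for crops,
pasture and harvest.  It reproduces the structure of a cohort-based
ecosystem model at a size that runs on one CPU in minutes: plant biomass
stocks and trait-structured animal cohorts on a 3 × 3 grid of cells,
advanced on a monthly step, forced by idealized climatologies spanning the
global productivity × seasonality gradient.

## The model

**Environment.**  Each simulated landscape uses one deterministic 12-month
climatology (air temperature, precipitation, soil water, frost days, and a
production-seasonality profile), repeated every year — no interannual
variability.  Four bundled archetypes cover the productivity × seasonality
grid: a humid aseasonal tropical system (`uganda_like`), a seasonal
temperate system (`france_like`), a cold strongly seasonal semi-desert
(`gobi_like`) and a hot aseasonal desert (`libya_like`).  Soil water comes
from a single-bucket model (refill = precipitation, demand ∝ 5 mm per °C
above freezing, per-archetype capacity).  The archetype parameters are
configuration, not measurements; the constraints they must satisfy are the
NPP ordering (uganda > france > gobi > libya) and the seasonality contrast
(within-year NPP variation larger for the two seasonal systems).

**Primary production.**  Annual potential NPP is `NPP_max · f(T̄) · g(W)`
with a logistic temperature limitation `f(T) = 1/(1+exp(1.315−0.119 T))`
and a saturating moisture limitation
`g = 1 − exp(−(6.64·10⁻⁴·P_annual + 0.25·Σ soil_water))`;
months receive shares following the product of monthly temperature,
moisture and frost limitations, normalized to mean 1.  `NPP_max` is
10⁷ g wet mass per cell per year; all masses are grams wet mass per cell,
with cell area an implicit constant.

**Stocks and cohorts.**  Plants are two pooled stocks per cell (deciduous
and evergreen leaf strategies), each gaining its share of
`(1 − f) · NPP` — `f` is the appropriated fraction, a pure sink — and
losing a fixed 5 %/month turnover.  Animals are cohorts: groups of
identical individuals characterized by trophic group (herbivore, omnivore,
carnivore), thermoregulation (endo/ectotherm), reproductive strategy
(semelparous/iteroparous), mobility, and continuous traits (current,
juvenile and adult body mass; reproductive mass; optimal prey mass; a
running diet-weighted trophic index).  Five processes act monthly, in
order: eating, metabolism, reproduction, mortality, dispersal; cohort
merging then enforces a per-cell cap (40) by repeatedly combining the most
similar same-trait pair (abundance-weighted means; mass and abundance
conserved exactly), and trophic indices are updated from the month's
realized diets.

**Eating.**  Herbivory is a Holling type-II intake in total stock biomass
(half-saturation 5·10⁴ g per cell).  Predation acts through a Gaussian
kernel in log body mass around the eater's optimal prey mass (σ = 1.2,
optimal prey = 20 % of adult mass) with a trophic-rank preference
(down-web 1.0, same rank 0.5, up-web 0.1), and a *sigmoidal (type-III)
functional response with predator interference*: the effective
half-saturation is `K_p + q·D`, where `D` is the cell's total predator
demand (K_p = 4·10³ g, q = 0.85).  The type-III numerator lets sparse prey
escape entirely — carnivores cannot establish in the deserts — while the
interference term makes the pinned prey density track predator density, so
consumer standing stocks scale with the energy flux that supports them.
This combination was chosen because pure type-II responses produced either
inverted trophic pyramids or productivity-insensitive predator-pinned
prey; with interference the model reproduces the observed regime
structure: top-down control (very low heterotroph:autotroph biomass
ratio) in the productive aseasonal system, bottom-up structure and a
higher ratio in the hot desert, and proportional collapse of all groups
under heavy NPP removal.  No more than 50 % of any stock or cohort can be
consumed in one month.  Eaten mass × assimilation efficiency (0.4
herbivory, 0.8 predation) grows individuals to adult mass and accumulates
as reproductive mass beyond it; every transfer is recorded in a diet
ledger.

**Metabolism.**  Cost per individual is `k · M^0.75`, with
`k = 0.7 g^0.25/month` for endotherms and `0.35 · e^{0.05(T−20)}` for
ectotherms; ectotherm feeding activity carries the same temperature factor
(cold ectotherms are torpid: both intake and cost shrink together, which
keeps cold climates from becoming consumer havens).  Intake shares the
0.75 mass exponent, making energetic viability mass-neutral; the seeding
lattice spans adult masses 0.1–10⁶ g (four log-spaced rungs per trait
combination) because lighter cohorts would turn over faster than a monthly
step can resolve.

**Reproduction, mortality, dispersal.**  Mature cohorts (largest attained
body mass ≥ adult mass) convert their reproductive store into a juvenile
cohort once it reaches one juvenile-mass per individual — mass exactly
conserved; semelparous parents die on spawning.  Mortality combines a
background hazard (0.04/month), a starvation hazard rising quadratically
below 20 % of adult mass, and a senescence hazard growing with adult age,
with lognormal jitter.  Mobile cohorts disperse to a uniformly chosen
rook-adjacent cell as a Bernoulli event (probability 0.2/month, moving a
quarter of the cohort when it fires, i.e. an expected 5 %/month flux);
per-event lineage abundance is exactly conserved.  Cohorts below 10⁻⁶
individuals are removed.

## Perturbation protocols and analyses

Protocol 1 ramps `f` by 1 %/year to a target (0–0.90, plus 0.94 for the
collapse analysis) and holds it until 100 years after the onset.
Protocol 2 ramps to a peak (0.80/0.90/0.95) and back down to zero.  Each
replicate spins up for 50 years (scaled down from a much longer unforced
initialization; drift of decadal-mean biomass is reported as a
steady-state diagnostic), then every impact level restarts from the same
saved state and generator state, making impacted and control runs exactly
paired.  End states are expressed as percentages of the paired control;
replicate means carry t-based 95 % confidence intervals, and a re-implemented
Mann–Kendall test (tie-corrected, continuity-corrected normal
approximation) screens the final 120 monthly values of each impacted
series — points where any replicate lacks a significant negative trend are
flagged "open".  Reversibility runs report both limbs against the current
appropriation fraction; hysteresis is the trapezoid-rule area between the
escalation and release limbs of total heterotroph biomass, and the
irreversibility index is the percentage displacement of each group's
biomass at release end versus the pre-perturbation state.

Trophic structure metrics: each cohort's trophic index is one plus the
eaten-mass-weighted mean of its prey's indices (stocks fixed at 1),
accumulated from the month's diet ledger; the mean trophic level is the
total-mass-weighted mean index over cohorts; trophic range and body-mass
range are max-minus-min standardized by fixed bounds (indices 1–40;
masses 10⁻⁵–1.5·10⁸ g).

## Problem sizes and calibration

Default experiment sizes are 3 replicates, 50-year spin-up, a 3 × 3 grid
and a 0.05-step impact grid; these were chosen so that a full campaign
over the four archetypes completes in minutes on one CPU, and paper-scale
settings (10 replicates, 1,000-year spin-up) remain plain configuration.
Model coefficients were calibrated against spin-up structure and
single-replicate probe runs (seeds distinct from the test seeds) to the
qualitative regime targets listed above, then frozen; they are defaults,
not fitted estimates.

## What the synthetic climate does and does not capture

The generator emulates monthly climatological forcing along the
productivity and seasonality axes, which is what the perturbation analysis
needs.  It omits interannual variability, spatial climate gradients within
the landscape, diurnal range, and climate–land-use feedbacks.  Passing
tests therefore demonstrate the model's *structural* behaviour — non-linear
collapse, trophic cascades, hysteresis — under idealized forcing, not
quantitative predictions for the real ecosystems the archetypes are named
after.

## Numerical choices and degenerate inputs

Continuous abundances with a 10⁻⁶ extinction floor; body mass floored at
10⁻⁵ g; predation transfers below 10⁻⁶ of an eater's intake are zeroed
before application so removals, gains and the ledger agree exactly;
empty communities yield `nan` (not 0) for the structure metrics; an
all-equal series gives a Mann–Kendall S of 0 with p = 1; grids are bounded
(no wrap), and edge cells simply have fewer dispersal targets.  All
stochasticity flows through one numpy Generator, so a (configuration,
seed) pair reproduces trajectories bit-exactly, and state snapshots
round-trip exactly through JSON.

## Known limitations

Two plant stocks per cell with a fixed turnover cannot represent
vegetation structure or succession.  The four-rung body-mass lattice gives
coarse size spectra, so the body-mass-range metric moves in steps.  The
interference predation closure is phenomenological; it stands in for the
behavioural and spatial detail (home ranges, aggregation, migration,
dormancy) that the model does not resolve — consistent with that omission,
obligate carnivores are absent from the simulated deserts even without
impact.  Losses to natural mortality leave the system (no detrital loop),
and microbes and detritivores are out of scope.
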