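# Methods

## Scope and design

`pesim` simulates the five-year effect of school physical-education (PE)
policy on youth overweight/obesity in a synthetic urban cohort, then the
lifetime clinical and economic consequences from age 18. It is built as a
library (with a thin CLI) in four layers — population, youth ABM +
metabolism, adult life-course, economics — each independently testable and
each configurable from a single `SimConfig` object that serialises to YAML.

Desk-scale runs default to 20,000 agents with results reported as
prevalences and per-100,000 rates, so they are directly comparable to the
full 218,163-agent population; full scale is a config change.

## Synthetic population

No census microdata or map data are used. Defaults:

- ages integer-uniform on 6–18, sex ratio 1:1, four rectangular districts
  with uniform home placement;
- schools (1,083 at full scale, scaled proportionally) split evenly
  primary/secondary per district; each agent attends the nearest school of
  its level (primary ≤ 11 y, secondary 12–18 y) in its district;
- activity locations (parks/gyms/school grounds) placed uniformly;
  proximity factor `exp(−d/1 km)` to the nearest location;
- SES (5 ordinal strata) and an activity-propensity score `Beta(2,2)` drawn
  independently (a correlation structure is a config hook, not a default).

**Anthropometry.** BMI-for-age z is drawn `Normal(mu0, sigma_z)` against a
packaged smooth synthetic LMS reference (`synthetic_bmi_lms.csv`; any table
with the same columns can be substituted). `mu0` is set so the configured
baseline combined prevalence (z > +1; default 29.0%) holds in expectation.
`sigma_z` defaults to 1.25: high-prevalence urban populations are
overdispersed relative to an international reference, and this value is the
package's design calibration of that stand-in default — together with the
intake calibration below it reproduces both the five-year no-PE prevalence
endpoint and the magnitude of the published PE effects. Height is the
reference median plus a Normal offset (SD 5.5 cm); the fat / fat-free split
uses a sex-specific body-fat-percent regression on BMI and age
(`bf% = 1.4 + 1.51·BMI − 0.70·age − 3.6·male`, clamped to 5–60%), an
explicit assumption with coefficients in config.

## Youth model

**Calendar.** 365-day years; 200 school days (40 weeks × 5 days,
configurable). PE sessions fall on the earliest weekdays, deterministically.

**Scenarios** (packaged): `no_pe`; `pe_observed` (primary 1×40 min/wk,
secondary 2×40, boys active 32% / girls 26% of class); `pe_guidelines`
(primary 3×40 = 120 min/wk, secondary 3×60 = 180 min/wk, 50% active);
`pe_guidelines_spillover` (guidelines + after-school uplift ×1.5 in weeks
with PE attendance). Program cost is a scenario field (5-year NPV).

**PE energy.** Active class time is at 6 METs; the remaining class time is
light activity at 2 METs (standing, instruction). A class with *zero*
active fraction is treated as fully sedentary, which makes the null policy
(PE offered, nobody active, no spillover) bit-identical to no PE — a tested
invariant. Expenditure uses the incremental convention
`(METs − 1) × kg × h` so resting energy is not double-counted against
maintenance; gross-MET accounting is available behind
`MetabolicConfig.use_gross_mets`.

**After-school activity.** Each day every agent draws participation with
`p = logistic(−3.45 + 1.2·propensity + 0.6·proximity + 0.3·ses)`,
a stand-in for an unavailable socio-cognitive model; the defaults give a
mean daily p ≈ 0.075, i.e. ≈40% of agents active at least once per week.
An event is 100 minutes at 6 METs. Under spillover scenarios the
probability is multiplied by the uplift (clamped to 1) in weeks the agent
attended PE. Paired scenario runs share one seeded random stream, so
after-school draws are common random numbers and scenario contrasts are
low-variance.

**Intake.** Daily intake = maintenance of the agent's *reference weight*
(its personal baseline z carried along the growth reference, interpolated
within the year) + growth-accretion energy + the agent's *expected*
after-school expenditure + `surplus × m_i`, with `m_i` lognormal (σ = 0.35,
mean 1) and a hard cap at 2,800 kcal/day. Intake never responds to the
activity actually realised (no compensatory eating) — in particular PE
expenditure is never compensated, which is what generates the policy
effect. The single global `surplus` is the calibrated parameter: a seeded
bisection (`calibrate_intake`) finds the value for which the simulated
five-year no-PE prevalence hits the configured target (default 30.65%,
tolerance 0.25 pp), representing a rising obesity trend from the 29%
baseline. The result is persisted in the config for reuse.

## Metabolism

Two-compartment energy balance: daily imbalance E partitions with the
Forbes-type fraction `p = C/(C + FM)`; `ΔFFM = p·E/ρ_lean`,
`ΔFM = (1−p)·E/ρ_fat`, defaults ρ_fat = 9,500, ρ_lean = 1,800 kcal/kg,
C = 10.4 kg — standard literature values, explicitly implementation
defaults. Maintenance is Schofield-band BMR × PAL (default 1.4; the PAL
excludes the explicitly modelled activity). Height follows the packaged
synthetic velocity table and is held beyond age 19. A fat-mass floor
(0.5 kg) guards pathological deficits, with a diagnostic count; the energy
ledger (`ρ_fat·ΔFM + ρ_lean·ΔFFM = ΣE`) closes to 1e-6 relative error and
is a tested invariant.

Students attend school through their 18th year; the BMI-z at the age-18
crossing is recorded as the hand-off to the adult model (younger agents
carry their end-of-horizon z to 18 along the reference, z-preserving).

## Adult life-course

Fifteen mutually exclusive states — BMI category {normal, overweight,
obese at 25/30 kg/m²} × condition axis {healthy, diabetes, post-CHD,
post-stroke, cancer-survivor} — plus absorbing death. This composition is
a structural assumption; the state map and every table are CSV data, so a
different enumeration is a data change. Annual cycle: (1) BMI-category
transition (age-band/sex row-stochastic tables), (2) independent Bernoulli
incidence per eligible condition (stroke, CHD, type-2 diabetes, nine
cancers with sex restrictions; by age band, sex and BMI category),
(3) death from background mortality + first-year case fatality + prevalent
excess, with the cause attributed proportionally to the hazard
contributions. The condition axis keeps the highest-priority condition
(CHD > stroke > cancer > diabetes, the cost ordering).

All tables ship as editable synthetic fixtures with plausible magnitudes
(validated for row-stochasticity, range, and coverage at load); no parity
with any specific published parameter set is claimed, so lifetime
averted-event *counts* are indicative only — the tested guarantees are
structural (matrix-power oracle on toy chains, absorbing death, paired
monotonicity in entry BMI).

**PSA.** Monte Carlo trials redraw triangular multipliers per parameter
group (incidence 0.8/1.0/1.2, mortality 0.85/1.0/1.15, cost 0.75/1.0/1.25,
disability 0.8/1.0/1.2); the distribution family per group is a config
key. The published design uses 1,000 trials; desk-scale examples and tests
use 20–200 to keep runtimes in seconds.

## Economics

Reference year for NPV is the simulation start; costs and DALYs discount
at 3%/yr, with adult years offset by each agent's time-to-18. Costs are US
proxies converted by the OECD comparative price-level ratio (default
0.45); for cancers/ESRD the Mexican subsequent-year cost is the Mexican
first-year cost divided by the US first:subsequent ratio. Per person-year
the dominance rule accrues only the costliest active condition (its cost
and disability weight); productivity loss = annual income (default
$9,000/yr, a proxy including benefits, accrued regardless of age or
employment) × accrued weight. YLD accrues as the discounted disability
weight per lived year; YLL as a discounted annuity over the remaining life
expectancy at death from the packaged synthetic life table (a WHO-style
extract can be supplied by path). The standalone closed forms
(`cases × dw × duration`; `deaths × e(age)`) are exposed as separate
operations. ICERs, dominance flags and budget thresholds
(cost-saving = gross savings; cost-effective = savings + WTP × ΔDALY) are
computed identically whether ledgers come from simulation or from a
published table ("printed-ledger mode").

Note: in the published scenario table this package mirrors, the ICER pair
$5,786/$5,058 reconciles arithmetically with the row labelled "meeting
guidelines" while the $31.5M/$39.7M savings and ΔDALY = 11,118.84
reconcile with the row labelled "not meeting guidelines"; the package
reports by whatever ledger it is fed and does not attempt to resolve the
labelling.

## What the synthetic generator does and does not show

The generator reproduces the *statistical* structure the analysis needs
(marginals, prevalence, proximity, school assignment) but not real
geography, census joint distributions, household structure, or the
original socio-cognitive behavioural model. Passing tests therefore
demonstrate that the modelling chain — calibration, energy balance, policy
dose-response, Markov accounting, CEA arithmetic — behaves correctly and
reproduces the published aggregate arithmetic and effect magnitudes under
these documented stand-ins; they do not validate the stand-in parameter
values against real Mexico City data.

## Numerical choices

- Seeding: `numpy` `SeedSequence`; master seed fans out to stage seeds via
  fixed tags; paired runs share streams. Everything is bit-reproducible.
- Bisection: bracket [−150, 250] kcal/day, ≤24 iterations, stops at the
  prevalence tolerance or a 0.5 kcal bracket; an out-of-bracket target
  raises with the achievable range; a zero-surplus fixed point returns
  immediately.
- Ties/degenerates: PE days on earliest weekdays; zero-active classes are
  sedentary; dominance ties break on disability weight; fat floor 0.5 kg;
  LMS inversion clamps its base at 1e-6; intake clipped to
  [600, 2800] kcal/day.
- Day counting: 365-day years (no leap days); ages advance by 1/365 per
  step.

## Known limitations

No weather/holiday structure beyond the school calendar; no intra-day
scheduling or transport; no adult behavioural modelling; ESRD appears only
through the cost-ratio rule, not as a tracked state; no compensatory
intake or adaptive thermogenesis; parity with the original study's child
metabolic model and appendix parameter tables is not claimed.
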