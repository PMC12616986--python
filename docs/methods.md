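# Methods

`lactsel` predicts selection response on dairy-cow lactation efficiency by
coupling two simulators: a reduced-form bioenergetic lifetime model of the
cow (the gene-to-phenotype map) and a stochastic genomic breeding scheme
(the selection machinery), joined by a three-step pipeline. This note
documents the model, its assumptions and parameters, the numerical
choices, and what the synthetic data do and do not show.

## The bioenergetic cow model

Each cow is driven by four genetically variable acquisition/allocation
(AA) input traits:

| trait | meaning | unit | mean |
|---|---|---|---|
| `bas_acq` | maximal intake of a non-lactating mature cow | kg DM/d | 7.00 |
| `lact_acq` | peak intake increment during lactation | kg DM/d | 10.25 |
| `f_prio_gs` | decay rate of the growth-allocation priority with age | 1/d | 0.0035 |
| `lact_all` | energy-allocation coefficient to lactation at calving | – | 0.56 |

All four have heritability 0.35 and phenotypic CV 0.10, are mutually
uncorrelated, and are sampled under the infinitesimal model in paternal
half-sib families (the reference design is 200 sires × 100 daughters).

**Daily step.** Expected intake is a maturity curve rising to `bas_acq`
plus, when lactating, a normalized lactation curve whose peak increment
equals `lact_acq` exactly. Achieved intake is the minimum of expected
intake and the daily feed offer. Metabolizable energy (intake × dietary
ME content) is partitioned maintenance-first (`0.30 MJ ME/kg^0.75/d`),
and the surplus is split by time-varying allocation coefficients:
lactation (`lact_all·exp(−0.0005·DIM)`; the persistency is fixed and
non-genetic), gestation (a fixed cubic ramp over the 282-d gestation, no
individual variability), growth (`0.85·exp(−f_prio_gs·age)`), with the
residual stored as labile body reserves. Storage tapers to zero between
body-reserve ratios 0.17 and 0.24 (unstored surplus dissipates as heat,
reported inside the maintenance allocation so that the five allocations
sum to intake energy *exactly* on every day).

**Milk drive and mobilization.** The lactation energy demand is computed
against the surplus the cow would have at peak intake, approached with an
8-day time constant — faster than intake itself rises — which opens the
classic early-lactation energy deficit. Deficits (from the drive or from
a binding feed offer) are covered by mobilizing labile mass, up to
12 MJ/d, at 0.60 MJ delivered per MJ stored (cycling energy through body
reserves is lossy). `alloc_reserves` reports the *net* daily flow into
the labile pool; storage and mobilization can co-occur at moderate
restriction (reserve turnover). Milk is `alloc_lactation / 5.06` kg
energy-corrected milk per MJ ME.

**Reproduction and culling.** The herd is a single seasonal cohort: day 1
of the calendar is the first day of the calving season, heifers reach the
first-mating age of 424 d exactly on the first day of a mating season
(10 weeks, 21-d oestrus cycles), and gestation lasts 282 d, so first
calvings land on the season start. The per-insemination conception
probability is a product of three components: decreasing in milk yield
(logistic, midpoint 27 kg, scale 4.5), increasing in the body-reserve
ratio (logistic, midpoint 0.16, scale 0.02), and decreasing in the energy
mobilized that day (exp(−0.05·MJ)). Pregnant cows dry off at
min(calving − 90 d, season start − 56 d). Cows open at the end of the
mating season are culled — heifers immediately, lactating cows at 280
days in milk (the culling decision does not erase milk already being
produced). Cows are also culled when reserves fall below 1% of body
weight, and after a maximum parity of 8.

**Calibration.** The free constants above were calibrated once, jointly,
so that the non-limiting (HS) baseline population approaches the
reference pre-selection summaries — about 5.9 completed lactations and
about 37.5% lifetime efficiency, with first-calving body weight ≈ 370 kg,
third-lactation peak milk ≈ 18 kg/d and 280-d milk ≈ 4,200 kg — and so
that the limiting (MS) environment falls below it on completed lactations
(≈ 5.0) and lifetime efficiency (≈ 35), as observed. They are exposed in
`HerdConfig` and are never changed by scale presets. Two structural
limits are worth knowing: with maintenance-first partitioning and
`lact_all = 0.56`, lifetime efficiency saturates near the high-30s; and
the environment contrast depends on feed restriction overlapping the
mating season (the seasonal phase of the offer is a free knob, default
peak at day 300, i.e. the trough sits mid mating season).

## Feed environments

The dietary ME content is shared by both environments (10.85–12.45 MJ/kg
DM, annual mean exactly 11.70). The HS offer is unconstrained; the MS
offer is a deterministic seasonal curve with range exactly [10, 16.8] kg
DM/d and annual mean exactly 12.2. Both curves are power-of-cosine
shapes: the exponent is solved so the discrete 365-day mean matches the
target mean to machine precision; a two-harmonic sum cannot produce the
required peak/trough asymmetry of the offer without leaving the target
range, and a single harmonic cannot give an ME mean of 11.70 between
extremes averaging 11.65.

## Derived traits

Body weight at first calving; and, in third lactation: 280-d cumulative
energy-corrected milk (lactations of 220–279 d are completed with a
least-squares cubic spline with 8 equispaced interior knots; lactations
under 220 d yield no phenotype), mean daily intake, lactation efficiency
(energy to milk / energy intake, %), and the interval from first
insemination to conception. Lifetime efficiency is the same ratio from
birth to culling. Third-lactation summaries are survivor-biased by
construction; population tables carry both survivor-only and all-cow
counts.

## Quantitative genetics

Variance components come from the paternal half-sib sire model by the
method of moments (exact ANOVA for the balanced design; the information
on genetic correlations sits in the ~200 sire effects, so a single design
draw carries a per-correlation sampling SE near 0.08 — recovery tests
therefore average over replicate populations). Correlation matrices are
bent to positive definiteness by iterated eigenvalue flooring with the
unit diagonal restored; bending is idempotent and leaves PD input
untouched. The total-merit-index correlations are
`cor(TMI, trait) = (Gw)_i / sqrt(w'Gw)` with weights on the genetic-SD
scale. Deterministic genomic accuracy offers two variants (a records/Me
ratio and the heavier-shrinkage form that integrates over segment
effects), combining bull daughter-group reliability
`n·h²/4 / (1+(n−1)·h²/4)` and cow own-performance reliability on the
effective-record scale, times the marker-captured share
`sqrt(M/(M+Me))`, with `Me = 2NeL/ln(4NeL)`. The Bulmer update is
`h²' = α/(α + (1−h²)/h²)`, residual variance unchanged.

## Breeding scheme

A closed nucleus (reference scale: 20,000 cows in 200 herds, 100 sires
per year, 4,000 genotyped calves per sex, 400 MOET heifers flushed twice
with 3 offspring per mating; 30-year horizon, 20-year burn-in) with all
traits expressed in genetic-SD units. Direct genomic values are
polygenic pseudo-traits of heritability 0.99 whose genetic correlation
with the underlying trait equals the GEBV accuracy (0.68 Milk and
BWcalv1, 0.60 DMI, 0.58 IFC, and 0.60 for lactation efficiency — the
feed-intake reference cows also carry efficiency phenotypes, and without
an efficiency DGV the index cannot move the allocation trait the
efficiency goal selects on). Cows record BWcalv1 at first calving and
Milk + IFC per lactation (residual correlation 0.11 within a lactation;
repeated lactations treated as independent given the breeding value — no
permanent-environment effect). Evaluation is multi-trait animal-model
BLUP via Henderson's mixed-model equations with the pedigree A-inverse
(inbreeding ignored in the Mendelian-sampling variance), assembled over a
sliding window of the last six birth cohorts plus their parents, and
solved by conjugate gradients with a per-animal block-Jacobi
preconditioner, warm starts, and a ranking-grade tolerance (2e-5; the
standalone `blup_evaluate` keeps 1e-8 and matches a dense GLS oracle).
Each year the best genotyped one-year-old males become sires for one
year, each herd keeps its best females aged 1–5, the best heifers are
flushed, and matings are random. Trends are regressions of cohort-mean
TBVs on birth year over the post-burn-in years; variance retention α is
the post-burn-in within-cohort TBV variance of the AA traits; inbreeding
rate comes from gene-dropping Monte Carlo (128 drops; cohort means have
negligible Monte-Carlo error); the generation interval is the mean
parental age at birth of offspring that themselves become parents.

## The linking pipeline

1. simulate the founder population in both environments and estimate the
   10-trait panel (AA traits × Milk/DMI/IFC per environment) with the
   half-sib estimator;
2. run the breeding scheme per goal — by default on the packaged
   reference panel (the packaged estimates for this system); the
   self-estimated panel can be used instead via configuration
   (`link.use_estimated_panel`), which is the fully self-consistent mode
   used by the feedback-off consistency check;
3. shift the AA means by (annual response × genetic SD × horizon), reduce
   h² by the Bulmer update with the scheme's α (residual variances and
   AA correlations unchanged), re-simulate 2,000 cows per environment,
   and report annualized phenotype changes standardized by the baseline
   genetic SD estimated in that environment (floored at h² = 0.01 of the
   phenotypic variance when the sire variance clamps to zero, as happens
   for the low-heritability fertility trait).

Before/after populations share their random numbers (the standardized
founder draws depend only on seed and family structure, and conception
draws are issued for every cow on every insemination day), so responses
are paired differences with most Monte-Carlo noise removed; an identity
update returns exactly zero response.

**Internal consistency.** With the conception feedback disabled and an
unconstrained offer, the mechanistic map is close to linear and the
mechanistic milk response reproduces the conventional correlated-response
prediction built on the same self-estimated parameters to within ~10%
(tested at 20%, which covers the residual estimation bias of the
half-sib step and mild curvature of the map). With feedbacks on, the
methods diverge exactly where the biology says they should: goals that
raise milk and mobilization depress conception, lengthening the interval
to conception (positive = unfavourable) while the conventional
prediction, anchored to baseline covariances, calls fertility improved.

## What the synthetic data show — and what they do not

The generator *is* the study design: deterministic seasonal feed curves
matching the stated means/ranges, uncorrelated AA traits at h² = 0.35
and CV 0.10, a seasonal single-cohort herd, and a nucleus selected on a
TMI. Passing tests demonstrate the method's internal behaviour (exact
index algebra, unbiased parameter recovery, selection response and its
feedback signatures, environment contrasts), not field accuracy: the
daily-step bioenergetic model is a reduced form — its absolute trait
scales (e.g. milk in kg, body weight) are calibrated, not fitted to farm
data; lactation persistency, health, calf rearing and within-day dynamics
are not modelled; weather is deterministic. Re-estimating the genetic
panel from the reduced-form model yields higher complex-trait
heritabilities (~0.5) than the reference panel (~0.33), a known property
of this map documented here so that users are not surprised when the
`estimate` step and the packaged panel disagree.

## Problem sizes used by the default test run

Herd fixtures use 200-cow cohorts; parameter-recovery tests use the full
200 × 100 founder design (averaged over 24 replicates); scheme tests use
a 600-cow nucleus over 16 years with 3 replicates (null tests, 200 cows);
re-simulations use 1,500–2,000 cows. The acceptance script uses one
365-day calendar year for the feed-offer target and a 1,000-cow nucleus
with 3 replicates for the generation-interval target. These sizes are the
package's desk-scale defaults; the `paper` preset restores the full study
design.
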