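# Methods

This note documents the models, parameter choices and numerical
conventions behind `mmsurv`: what the synthetic generator simulates, how
the analysis stages are defined, and which design decisions were genuinely
open.

## Time axis

Mother-machine recordings begin before the culture reaches steady state,
so analyses discard the first four hours and re-zero time ("retained
time"): drugs are present during retained hours 2–14 and the experiment
ends at hour 24.  The simulator therefore emits a 4-hour preamble ahead of
retained hour 0 (28 h of raw frames at 5-minute cadence for glu-aa/glu,
10-minute for gly), and the pipeline's first step performs the same
discard a segmentation export would need.

## Synthetic lineage generator

Each lineage is the mother cell of one dead-end microchannel.

**Growth and division.**  A lineage draws a constant elongation rate
μ ~ lognormal with configured median (1.13 / 0.54 / 0.28 h⁻¹ per medium)
and cell-to-cell CV 0.15.  Within a cycle, length grows exponentially;
division is a sizer: the cell splits when it reaches twice the target
birth length (2 μm) times lognormal threshold noise (CV 0.1), and the
mother keeps the proximal half.  A sizer is the simplest rule with stable
size homeostasis; nothing downstream depends on the homeostasis model.
Area is length × a fixed 1 μm width — a proxy adequate for
fluorescence-per-area ratios.

**Tetracycline.**  TET multiplies the rate by (1 − r), approached and
released with a 1 h first-order lag; r = 0.16 in glu-aa (published), and
0.14 under the combination.  The TET effect is growth-rate dependent and
strongest in fast media; for glu/gly no values are published and the
defaults r = 0.10/0.05 (combination 0.09/0.045) are package choices,
tagged as such and configurable.

**Ciprofloxacin fates.**  Under CIP (alone or combined) each lineage draws
a fate from (p_survive, p_die_low, p_die_high).  The default probabilities
encode the published survival fractions together with the published
high-SOS shares; e.g. glu-aa CIP = (0.36, 0.52, 0.12) and glu-aa CIP-TET
= (0.77, 0.15, 0.08).  The no-drug and TET conditions are death-free apart
from a 3% age-related hazard in the final four hours, reproducing the
small late-death population seen in long mother-machine runs.

**Death dynamics.**  Low-SOS deaths grow and divide normally until an
abrupt, permanent growth arrest at a death time drawn uniformly over
retained hours [3, 17] (deaths occur throughout exposure and for a few
hours after removal).  High-SOS deaths stop dividing at drug onset and
filament; their elongation rate decays with a time constant that scales
with the medium's doubling time (1.5/3/6 h for glu-aa/glu/gly, floored at
0.3× the cell's own rate) before arresting abruptly at a death time drawn
from [3, 6].  Two considerations fix these choices: filamentation at full
rate in glu-aa would exceed the 40 μm channel within ~2.5 h and censor the
very class being studied, and the pre-death rate must stay above the
classifier's detection floor in slow media so that "growth stop" is a
well-defined event.  Concentrating high-SOS deaths early in exposure is
consistent with the SOS spike accompanying growth arrest during treatment.

**Reporters.**  SOS expression (GFP per area) rests at the medium's
baseline (118/95/93 a.u.), rises first-order (τ = 2 h) toward the induced
level (227/473/462 a.u.) during CIP exposure, and relaxes back (τ = 1.2 h)
after removal — survivors return to baseline within ~5 h.  After any
death, production stops and both reporter concentrations bleach
exponentially at 0.5 h⁻¹ (qualitatively an exponential decrease; the rate
itself is a package default).  In high-SOS cells the frozen volume
concentrates continued SOS expression: after a 20-minute maturation lag
the concentration ramps over 1 h to 10× the induced level, then bleaches.
The 10× factor is the published scale of the high-SOS sub-population; the
ramp time and maturation lag are package defaults.

**Censoring.**  Lineages vanish by random washout (exponential,
0.005 h⁻¹) or by truncation at the 40 μm channel length (surviving cells
can transiently filament with probability 0.05 for 1–2.5 h).  Both paths
terminate the observation; ground truth records them as "lost".

**Replicates and randomness.**  Replicate-to-replicate variability adds
Gaussian noise (sd 0.02) to the survival probability, rescaling the two
death classes proportionally so their ratio — the composition of death
modes — is unchanged; jittering each class independently would distort the
small high-SOS probability disproportionately.  Measurement noise is
multiplicative lognormal (CV 0.03) on length, area and totals.  Random
streams are keyed by (seed, condition, replicate, lineage), so enlarging a
population never reshuffles existing lineages and identical (config, seed)
runs are byte-identical.

**What the generator does not emulate.**  No images or spatial geometry;
no daughter-cell tracking; no lineage-level correlation between growth
rate and fate (deaths are drawn independently of μ, whereas in reality
fast-growing low-SOS cells die preferentially); no drug-concentration
dose-response (fate probabilities are per-condition constants); division
timing is a pure sizer.  Passing tests therefore demonstrate that the
*analysis* recovers known ground truth under realistic noise, censoring
and class imbalance — not that the generator is a mechanistic model of
DNA-damage-induced death.

## Elongation-rate estimation

Per-generation rates are ordinary least squares on (time, ln length) —
μ is the slope, S₀ the fitted birth length — with fits of fewer than three
frames marked invalid.  Unweighted regression is used; partial generations
at observation edges are fitted if they satisfy the 3-frame rule.  Two
per-frame series are derived: the generation fit broadcast to its frames
(the per-cell-cycle view used for windowed distributions) and sliding
regression slopes of ln length that never cross a division (the
instantaneous view the classifier needs for filamenting cells).  For the
smoothed series the window is 1.5 h, shrinking to the whole generation
when a generation is shorter — the generation fit is then the best
available estimate.  Windowed population summaries pool per-frame values
into consecutive 2-h windows and report medians, the headline statistic
throughout.

## Fate classification

With mu_ref the population median drug-free rate (pre-drug window), a
lineage is **dead** at the earliest time t* ≥ drug onset where the forward
regression slope over the next 1 h falls below
max(0.05·mu_ref, 0.05 h⁻¹) and the smoothed rate never exceeds
max(0.2·mu_ref, 0.1 h⁻¹) afterwards; transient arrest followed by
sustained regrowth voids the call.  Death time is the start of the arrest,
biased by at most about one frame.  The absolute floors matter in slow
media: at 10-minute cadence the slope-noise floor (~0.03 h⁻¹) exceeds 5%
of μ = 0.28 h⁻¹, so a purely fractional threshold would be
noise-dominated.  Observations ending early (washout, channel-length
truncation) are right-censored at the last frame; death takes precedence
over later censoring.  QC removes lineages initially filamented (mean
early length > 2× twice the median birth length) or initially non-growing
(mean smoothed rate in the first 2 h below the arrest threshold — judged
only on frames inside the window, since a generation born before drug
onset can extend across the whole run in slow media).

**SOS sub-classification.**  The low/high threshold is 3× the survivors'
median SOS expression over the final 2 h of exposure (falling back to an
absolute threshold, with a warning, below 20 survivors).  A dead lineage
is high-SOS if its peak expression between drug onset and 3 h past its
death time reaches the threshold.  The two simulated classes sit an order
of magnitude apart, so any multiplier between ~2 and ~8 separates them;
3 sits safely inside the gap.  The constants reconstruct the published
phenomenology (abrupt arrest, no recovery, ~10× SOS gap) rather than copy
unpublished threshold tables, so agreement is validated against the
simulator's ground truth, not cell-for-cell against the original labels.

## Survival analysis

Event durations run from drug onset; lineages alive at the end are
censored there.  Curves use the product-limit estimator with Greenwood
variance and log(−log) 95% intervals (lifelines); ties follow the standard
deaths-before-censorings convention.  The replicate survival fraction Sf
is, by default, the Kaplan–Meier estimate at the end of the experiment.
With no censoring this equals survivors/(survivors+deaths) exactly; under
the ~10% independent washout of these experiments it remains unbiased,
whereas dropping censored lineages from the denominator under-counts
survivors (−1.8 pp at default settings) because survivors stay at risk of
washout for the full 24 h while dying lineages leave early.  The simpler
"exclude" and "censored-as-survivors" conventions are available.
SOS-stratified survival treats deaths of the other class as non-events, so
1 − Sf_low is the fraction of the population dying with low SOS.

## Interaction statistics

Bliss expectation and its reported SEM follow the published formulas
exactly: pairwise products over the Cartesian product of replicate pairs,
and SEM = sqrt(σ_CIP/√n_CIP + σ_TET/√n_TET) with σ the sd of the
single-drug replicate Sf values.  That formula sums standard errors, not
variances, under the root — dimensionally unusual, but kept as the default
for comparability; conventional log-scale propagation is available as
`sem_method="propagated"`.  The Bliss null is tested as a contrast
(mean ln Sf_CIP + mean ln Sf_TET − mean ln Sf_combo) in a one-way OLS
layout with pooled residual variance, one-sided against negative contrast
(combination survives more than independence predicts); this is the
minimal ANOVA model satisfying the stated hypothesis.  Pairwise t-tests
are pooled-variance by default (Welch optional).  No multiple-testing
correction is applied; per-medium tests are reported as such.

## Numerical conventions and edge cases

Windows are half-open [t0, t1); the final frame always falls in a
(possibly partial, flagged) window.  Generation boundaries in tables are
trusted; the 0.6-ratio length-drop detector is a fallback whose ratio must
leave headroom above 0.5·e^(μΔt) in fast media.  Degenerate inputs raise:
non-positive lengths/areas, zero survival fractions (log undefined),
empty replicates, all-singleton ANOVA arms.  Identical groups give
(statistic 0, p 1) for both the log-rank and t tests.  Censored-only
populations give S ≡ 1.

## Problem sizes

Validation uses 300–1500 lineages per condition and two to three
replicates of 500 for the headline recoveries — the replicate structure of
the study itself (420–1005 lineages per curve, 2–3 replicates).  At these
sizes the expected sampling noise is ~1–2 percentage points on
proportions, well inside the ±3–4 point acceptance bands; the Bliss test
in the slow medium is assessed with three replicates per arm because with
two (residual df = 3) its power at the study's effect size makes the
p < 0.005 outcome seed-dependent.
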