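# Methods

## Respirometry model and unit contract

The gas-exchange equations assume pull-mode, flow-through respirometry with
a water-vapor-scrubbed excurrent stream: only the incurrent flow FRᵢ enters
the calculation (an excurrent-flow column in input files is ignored with a
logged notice), and barometric/STP correction is taken as done upstream by
the instrument.  VO₂ and VCO₂ are mass-specific (mL kg⁻¹ h⁻¹, dividing by a
single per-trace body mass — the nearest weighing; animals weighed a few
times a week do not justify sub-day interpolation).  The CO₂ equation is
oriented so that net CO₂ production is positive (excurrent minus incurrent);
the mirrored term ordering sometimes printed for this equation yields
negative production and is deliberately not used.

Inside the oxycaloric formula EE = (3.815 + 1.232·RER)·VO₂·BM the unit
contract is VO₂ in L kg⁻¹ h⁻¹ and BM in kg; only those units give the
plausible ~1 kcal h⁻¹ magnitude for a 0.1 kg animal, and a sanity guard
warns when EE leaves (0.01, 100) kcal h⁻¹ for a 50–150 g body mass.  RER
values outside [0.7, 1.0] are flagged, never clipped: transient values above
1 occur with carbohydrate loading/lipogenesis and below 0.7 with measurement
error.  Timestamps may be irregular (multiplexed instruments skip samples);
day/night means are unweighted sample means, since time-weighting across
gaps is a modelling choice the data do not force.

A note on an algebraic property: VO₂ is exactly invariant to adding the same
constant to both CO₂ fractions (they enter the O₂ equation only as a
difference), whereas VCO₂ is not (Fₑ′CO₂ appears alone in its denominator
and cross term).  The tests pin this down.

## Changepoint extrema

The extrema of a daily metabolic profile are defined through mean-shift
segmentation rather than raw argmin/argmax, which at 10-min cadence are
dominated by single-sample noise.  The segmentation is PELT: the exact
penalized dynamic program over partitions with a Gaussian change-in-mean
(SSE) cost and a linear penalty, with candidate pruning that keeps every
candidate within one penalty of the running optimum — the conservative
bound that remains exact under a minimum segment length (a tighter prune
can discard the only admissible candidate of a near-future step).  The
test suite verifies equality with an independent exhaustive dynamic program
on random series.

Defaults: minimum segment length 3 samples; penalty 3·log(n) **scaled by a
robust noise-variance estimate** (median absolute successive difference,
Gaussian-consistent).  The scale factor matters: an unscaled 3·log(n) is
effectively infinite for RER (variance ~10⁻³) and effectively zero for VO₂
(variance ~10⁵).  Both knobs are configurable; an explicitly passed penalty
is used as-is on the raw SSE scale.

Max is searched only among segments overlapping the dark-phase window and
Min only in the light-phase window, matching the night-active biology of the
study species.  hMax/hMin is the clock time of the winning segment's first
sample inside the window ("time at which the change is achieved"); ties go
to the earliest segment.  Multi-day recordings are segmented once; extrema
are taken per 24 h cycle and then averaged — values arithmetically, times
circularly.  Recordings are assumed to start/end at window boundaries (the
generator starts at lights-on); partial edge windows of arbitrary recordings
would contribute plateau values and are a known limitation.

Circular statistics use the resultant vector; the mean is declared undefined
when the mean resultant length falls below 10⁻⁸ (e.g. three times 8 h
apart).  The circular mean agrees with the arithmetic mean to well under a
minute for clusters a few hours wide — the regime of extremum times — but
deviates at third-moment order for spreads approaching the half-circle; it
is not a drop-in replacement for the linear mean of wide distributions.
CTL→CR time shifts are signed shortest arcs in (−720, 720] minutes, negative
meaning the event moved earlier (an advance), so a trough advance under
restriction appears as a negative shift.

## Flux metrics

OxCR, MtRC and GlcP follow the kit conventions exactly, including the
asymmetry that stressed OCR is the **max** of the three post-FCCP cycles
while stressed ECAR is their **mean**.  All metrics are per-well percentages
of that well's own baseline (removing cell-seeding bias — the stated purpose
of the normalization), normalized first and averaged across wells after.
The metabolic potential is reported both as the 2-D displacement from the
basal (100, 100) phenotype and as its Euclidean norm; the scalarization of
a 2-D gap is a design choice, so the raw displacement is retained for
alternatives.  A rotenone/antimycin phase is accepted and ignored.  Wells
failing QC (missing phase, nonpositive baseline) are excluded with logged
reasons; a sample with zero valid wells is an explicit missing marker.

## Biomarkers

Urinary analytes are divided by creatinine (mg mL⁻¹).  The mtDNA/nuDNA
ratio uses the efficiency-power ΔCt model E^(mean Ct_nu − mean Ct_mt) with
E = 2.0 by default and configurable in (1, 2]; a standard-curve
quantification mode is out of scope.  Replicate means run over all available
Cts (up to two triplicate runs).  The glycaemia repeat rule takes the first
reading when it lies inside the configured normal range — default (50, 150)
mg dL⁻¹, an explicit placeholder for an unspecified instrument range — and
otherwise the mean of all repeats, flagged.  Thiols and GPx arrive already
protein-normalized.

## Cohort statistics

With six animals per sex, contrasts are exact nonparametric tests by full
enumeration: signed-rank over all 2ⁿ sign assignments of the observed
|difference| midranks (zeros dropped; all-zero samples degenerate with
p = 1), rank-sum over all C(n₁+n₂, n₁) midrank assignments, two-sided
p = min(1, 2·min(P(W≤w), P(W≥w))).  These replace mixed-model Wald tables
deliberately: at this n the exact permutation null needs no distributional
assumptions, and the enumeration is instantaneous.  No multiple-testing
correction is applied to the correlation network or the PCA dimension
description; the significance ladder for annotations is *** <0.001,
** <0.01, * <0.05, ° <0.1.

Percent change is per-individual, V = 100·(CR − CTL)/CTL; group summaries
report the mean ± SD of individual V values and, separately, the percent
change of group means — the two coincide only when all individuals share
the same baseline, and both are exported.

Dixon's Q uses the gap/range variant by sample size (r10 for n ≤ 7, r11 for
8–10, r22 for 11–13), testing both extremes and taking the larger ratio,
against embedded two-sided 5% critical values: the published table for r10
and simulation-calibrated values (2×10⁶ normal null samples, which
reproduce the published r10 row to <0.003) for the larger-n variants.

PCA mean-imputes missing cells (simple column means — an iterative-PCA
imputation would add machinery without changing the rank-1 structure these
cohort matrices carry), drops zero-variance columns with a notice, z-scores
with population SD, and decomposes by SVD, so retained scores·loadingsᵀ
reconstructs the standardized matrix exactly.  The dimension description
reports each variable's Pearson correlation (and two-sided p) with each
component and each category's v-statistic
v = (x̄_cat − x̄)/√(((N − n)/(N − 1))·σ²/n) on the component scores.

## Synthetic cohort generator

The generator emulates the study conditions: 6 females + 6 males, paired
CTL→CR, 4 recording days at 10-min sampling under 14 h light (dark
17:00–03:00), with every group-level mean and SD taken from the published
summary table of the source experiment (the `reference` module).  Animal-level
values are drawn from those group distributions — normal for most endpoints,
moment-matched log-normal for the right-skewed hormones (cortisol,
testosterone, estradiol; printed SDs like +667 ± 1024 % are impossible for
a positive-support normal) and for the copy-number ratio.  CTL and CR draws
are independent within a group because the source reports no pairing
correlation; per-individual percent-change SDs are therefore not calibrated,
only group means/SDs are.

Gas traces are built by **inverting the analysis equations** rather than
simulating chamber physics: the pipeline's contract is the equations, so a
target VO₂/RER daily profile is chosen per animal-condition, VCO₂ = RER·VO₂,
and the excurrent fractions are solved by a fixed-point iteration given
FᵢO₂ = 0.2095, FᵢCO₂ = 0.0004, 30 L h⁻¹ flow and the drawn body mass
(profiles whose fractions leave (0,1) are rejected at construction).  The
daily profile is a two-plateau square wave — night plateau with a 3 h
nocturnal peak, day plateau with a 4 h diurnal trough, plateau levels solved
so the window means equal the drawn targets, and excursion start times drawn
from the published hMax/hMin statistics (clamped into their windows with a
margin that leaves a detectable plateau at the edges).  A fixed-width
logistic smoothing ramp is available but defaults to zero width: the
unsmoothed square wave is the simplest shape whose ground-truth extrema are
unambiguous, and it keeps the changepoint recovery contract at ±1 sampling
interval (a ramp interacts with the first-sample time convention through
partially-ramped samples).  The manifest records ground truth from the
realized noiseless profile, so round trips are checked against what was
actually synthesized.

Measurement noise is multiplicative log-normal (unit mean) applied to
VO₂/VCO₂ before the inversion (2 % per sample), to flux cycles (2 %), to
assay values (5 %), plus 0.08-cycle Ct jitter and a 3 mg dL⁻¹ glucometer
SD; `noise_scale` multiplies all of these and zero makes every round trip
exact to machine precision.  Animal-level spread is biology, not noise, and
is never scaled.  Because the coupling and reserve metrics take the min/max
of three noisy cycles, their naive expectation is biased by the expected
extreme of the noise factors (≈1 ± 0.85σ); the generator divides the
programmed plateaus by that factor (Gauss–Hermite quadrature) so programmed
metrics are recovered without bias — exact at zero noise.  Optional
well dropout emulates culture-contamination attrition.  A single seed
determines everything; identical seeds give byte-identical CSVs.

## Validation and problem sizes

`crmetab.validation` re-derives every scalar endpoint from generated
fixtures and checks (a) noiseless round trips — phase means, flux metrics,
copy-number ratios at machine precision; extremum clock times within one
sampling interval — and (b) default-noise recovery, the fraction of
(variable × sex × condition) group means within 2 SEM (SD/√6) of their
programmed values across independently seeded cohorts, expected near the
nominal ~95 % and required to exceed 90 %.  The recovery suites use
100 seeded cohorts in the acceptance script (a few tens of seconds) and
smaller counts in interactive drivers; oracle-equivalence suites use 1000
random gas-trace inputs, 200 random series of length ≤ 40 against the
exhaustive changepoint program, and every n ≤ 8 for the exact tests.

## Known limitations

- No instrument drift, washout-lag (Z-transform) or chamber-volume
  modelling; no torpor-bout classifier or cosinor fitting.
- Extrema extraction assumes recordings aligned to window boundaries;
  partial edge windows contribute plateau values.
- The changepoint penalty of the original analyses is unreported, so
  numeric equality of hMax/hMin with any published per-animal value is not
  expected — direction and ordering properties are the validated surface.
- The synthetic cohort draws endpoints independently across variables and
  conditions: cross-variable correlation structure (and hence the exact
  variance shares of a PCA on real data) is not emulated, so passing tests
  demonstrate pipeline correctness, not biological covariance realism.
- Mixed-model (Wald χ²) tables are intentionally replaced by exact
  rank/permutation contrasts; ELISA curve fitting, Bradford normalization
  and qPCR standard curves are upstream of the package's inputs.
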