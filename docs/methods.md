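# Methods

This note documents the models and procedures the package implements, the
defaults it ships, what the synthetic generators do and do not emulate, and
the numerical and design choices made where the problem left them open.

## Chamber characterization

A reverberation chamber exposes samples to a statistically uniform,
isotropic field by mechanically stirring the cavity modes. When the chamber
is small relative to available field probes, uniformity is assessed through
the one-port reflection coefficient instead of Cartesian field samples: over
N stirrer positions the stirred component `S11_st,i = S11_i − ⟨S11⟩` should
behave like a circular complex Gaussian, so `|S11_st|` is Rayleigh.

Three per-frequency statistics are computed on `|S11_st|`:

- **Anderson–Darling against Rayleigh.** The Rayleigh scale is estimated by
  maximum likelihood, `σ̂ = sqrt(Σx²/2N)` — the estimator reproduces the
  estimated-parameter critical-value table whose 5% point is the 1.341
  threshold used for the modified statistic `A²ₘ = A²(1 + 0.6/N)`. Because
  `x ↦ x²` maps Rayleigh(σ) to Exponential(2σ²) monotonically and the ML
  estimators correspond, the statistic is identical to the
  exponential-with-estimated-mean AD test, which the suite uses as an
  independent oracle. CDF values are clamped to [1e−12, 1−1e−12] before
  logarithms. Decision direction is the standard one: compatibility with
  Rayleigh means `A²ₘ ≤ 1.341` (large values reject). Our own Monte Carlo
  puts the 95th percentile of A²ₘ at ≈ 1.32 for N = 64, consistent with the
  1.341 table value within the tolerance used everywhere here.
- **Lag-1 autocorrelation** of the position series with circular indexing
  (`x(N+1) ≡ x(1)`, matching a summation bound of k = N); a non-circular
  variant is available via `circular=False`. Thresholds t₂ are the tabulated
  0.707 / 0.246 / 0.123 for N = 8 / 64 / 256; for other N the 1.96/√N
  normal approximation is used (it reproduces 0.123 at N = 256). These are
  one-sided ~2.5% bounds: i.i.d. noise falls below threshold ~97.9% of the
  time at N = 256, which the suite freezes from its own Monte Carlo.
- **Coefficient of variation** sd/mean (sample sd, ddof = 1) of `|S11_st|`,
  ideally √(4/π − 1) ≈ 0.5227. A band summary interval mean(CV) ± 2·sd(CV)
  is computed over frequencies at or above a cutoff, default 3.6 GHz (the
  figure-caption convention; 2.74 GHz is a documented alternative).

`characterize()` smooths A²ₘ with an order-8 and r(1) with an order-6
least-squares polynomial (unweighted, on a centered/scaled frequency axis
for conditioning) and CV with a 100-point moving mean; the usable band is
the set of frequencies where both smoothed statistics clear their
thresholds, and the verdict is that condition at the target frequency.

The **lowest usable frequency** uses the smooth Weyl estimate of the
cumulative mode count, `N(f) = (8π/3)·abd·(f/c)³ − (a+b+d)(f/c) + ½`,
root-solved for N = 100 by bracketed bisection (tolerance < 1 MHz). For the
built 466 × 436 × 600 mm cavity this gives 1.411 GHz; brute-force TE/TM
eigenmode enumeration agrees within 5% at 3.6 GHz.

## Dosimetry

Field solving (FDTD) is out of scope; the package consumes voxel grids of
RMS internal field and conductivity and performs the bookkeeping:

- `P_abs = Σ σ|E|²·dV` over a material mask (uniform cubic voxels).
- Quadratic rescaling `P_abs(E_new) = P_abs(E_ref)·(E_new/E_ref)²`. The
  quadratic law is the physically correct one for a linear dielectric and is
  the only law consistent with the reference dose pairs the package ships
  (66.7 nW → 1.04 µW and 7.19 µW → 1.12×10⁻⁴ W for 46.2 → 182.6 V/m,
  a factor (182.6/46.2)² = 15.6).
- Whole-body SAR = P_abs/(ρV) with ρ = 1000 kg/m³ for water and larva alike;
  1 µW/mm³ corresponds to 1 W/kg.
- Plane-wave power density S = E²/377 Ω and its inverse.
- Exposure-averaging plane-wave sets: the canonical 12 (6 axis directions ×
  2 axis-aligned polarizations) and the extended 52 (26 directions:
  the axes plus 45°/135° zenith at every 45° azimuth and the diagonal 90°
  zenith azimuths; two deterministic orthonormal polarizations each). The
  symmetry reduction of 52 runs to 22 distinct simulations is carried as
  metadata only, since it depends on the sample's symmetry.
- Larva volumes: prolate spheroid `(π/6)·L·W²` with body length as polar
  axis and head width as equatorial diameter, or watertight STL meshes via
  signed-tetrahedron volume (trimesh). Instar spheroid dimensions ship as an
  editable placeholder CSV whose volumes match the published per-instar
  scale (≈0.063 mm³ for L1 to ≈4.47 mm³ for L4); users should replace them
  with measured dimensions.

Dose summaries label the condition by the loaded-chamber incident fields
(46.2 V/m → LE, 182.6 V/m → HE) because the shipped reference doses are
computed at those values.

## Development statistics

Event times are whole days (daily observation); ties are handled by the
standard corrections throughout.

- **Survival**: Kaplan–Meier with death as the event and adult emergence as
  right-censoring (lifelines). Without censoring the estimator equals the
  empirical survival function, which the suite checks exactly.
- **Development timing**: pairwise Mantel–Cox log-rank tests (df = 1) on
  pupation or emergence day, with deaths censored at death day — dead larvae
  cannot reach the development event, and censoring (rather than exclusion)
  uses their time at risk. Each comparison carries a Schoenfeld-residual
  proportional-hazards check from a two-group Cox fit; p < 0.001 flags the
  comparison unreliable.
- **Slope resampling**: development rate is 1/duration. For a condition pair
  (e.g. low/high temperature), B = 10,000 bootstrap slopes
  `(r₂ − r₁)/(T₂ − T₁)` are drawn with rate and temperature sampled
  independently and uniformly from each condition's measured values
  (temperatures are condition-level measurements, so no per-larva pairing
  exists); T₂ = T₁ draws are rejected and redrawn, with the redraw count
  reported. Control-pair and exposed-pair slope distributions are compared
  by Welch's unequal-variance t-test with Welch–Satterthwaite df.
  *Caveat (measured by this package's own calibration):* because the Welch
  test's resolution scales as 1/√B while the slope-distribution means carry
  finite-data variability of order 1/√n_data (here as few as 7 temperature
  measurements in one condition) plus a pair-specific Jensen bias from
  E[1/(T₂−T₁)], the comparison is strongly anticonservative at B ≫ n_data:
  with no exposure effect built in, it rejected at the 5% level in ~68% of
  seeded replicates at the study design. Results of this method should be
  read as descriptive of the two bootstrap distributions, not as a
  calibrated hypothesis test; its power against real slope differences is
  monotone and large, which the suite verifies.
- **Wing length**: Gaussian linear mixed model on individual wing
  measurements of one sex, fixed effects condition + diet + condition×diet
  against the LC/Tetramin baseline, random intercept per replicate run. The
  fit is the package's own closed-form profiled REML for the
  random-intercept model (the per-group inverse `(I + λJ)⁻¹` is analytic;
  the scalar variance ratio λ is optimized by bounded scalar minimization
  with the λ → 0 boundary checked). Satterthwaite degrees of freedom are
  computed by the delta method on (σ², τ²) with a finite-difference REML
  Hessian. The fit is cross-checked in the suite against statsmodels
  MixedLM, and reproduces lme4/lmerTest estimates, standard errors,
  variance components and dfs on the same data. The interaction block is
  tested by a likelihood-ratio test between ML fits (χ², df = 3, reported
  positive). Sexes are fitted separately rather than as a covariate.
  The diet effect size is reported as |diet coefficient|/intercept, rounded
  to a whole percent.
- **Asymmetry and mortality**: Kruskal–Wallis on |left − right| wing length
  and on per-run mortality rates (deaths/(deaths + emergences)) across the
  condition × diet groups (df = 7 for the full 4 × 2 design). The degenerate
  all-tied case is defined as H = 0, p = 1.

## Synthetic generators

`simulate_s11` draws `S11(pos, f) = μ(f) + s(f)·z` with z circular complex
Gaussian ("rayleigh" family), optionally plus a fixed per-position offset
("rician" family) that survives the mean subtraction and breaks the Rayleigh
behaviour. Sweeps are rescaled if needed to remain passive (|S11| ≤ 1).

`simulate_cohort` mirrors the study design: 4 conditions × 5 runs × 168
larvae (half per diet), per-condition water-temperature lists with the
study's means, spreads and counts (LC 28.23 ± 0.63 n = 84, LE 28.16 ± 0.19
n = 7, HC 30.33 ± 0.11 n = 96, HE 29.95 ± 0.70 n = 38). Development rate is
`a_diet + b_diet·T + ε` at the condition's mean temperature, with
b = 0.012 /day/°C and intercepts placing Tetramin pupation near 6 days and
milk near 7.5 days at 28 °C (typical rearing-temperature response for this
species), noise sd 0.015 /day, and a rate floor at 1/30 per day; pupation is
the rounded reciprocal and emergence follows after a fixed 2-day pupal lag.
Mortality is Bernoulli at 6% (the study's overall rate) with death day
uniform before pupation; sex is 1:1; wing lengths for up to 10 measured
larvae per sex per run and diet follow the random-intercept LMM with the
published coefficient set as generating defaults (intercept 2992.23 µm,
milk −386.16 µm, run sd 38.86, residual sd 101.22; both wings drawn
independently around the individual mean).

Not emulated: per-larva temperature histories (temperatures are
condition-level), batch infections (the discarded-run phenomenon),
generation structure beyond a label, non-proportional-hazard shapes of real
development curves, and any real S11 frequency response (μ and s are smooth
profiles). Passing tests therefore demonstrate correctness of the
computations and calibration of the tests under the assumed structure — not
that real chambers or cohorts satisfy that structure.

## Problem sizes and reproducibility

Monte-Carlo calibrations use 50,000 replicates for the AD critical value,
400 for log-rank calibration, 200 cohorts for LMM recovery, and 100 seeds
for the slope-resampling calibration — sizes at which the binomial noise is
well below the asserted tolerances. All stochastic operations take explicit
seeds (numpy `default_rng`); the pipeline stamps every report with the seed
and a configuration hash, and reruns are byte-identical.

## Known limitations

- The AD threshold 1.341 and t₂ table are treated as fixed constants; no
  interpolation across N beyond the 1.96/√N approximation.
- The LMM supports a single random intercept (run); crossed generation
  effects are not implemented.
- Touchstone support covers one-port v1 files (RI/MA/DB); no v2, no
  multi-port.
- The slope-resampling test's anticonservatism at B ≫ n_data is inherent to
  the method as specified (see above); the package reports it as specified
  rather than re-calibrating it.
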