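# Methods

## The estimation model

All length relations are power laws fitted on log10 scales by
standardized major axis (SMA, historically "reduced major axis")
regression: for predictor x (a centrum length, a regional mean CL, or a
series sum, mm) and response y (SVL, TL, or species maximum TL, mm),

    log10 y = elevation + slope · log10 x,
    slope = sign(r) · s_y / s_x,   elevation = ȳ − slope · x̄,

computed on the log-transformed sample.  SMA treats x and y
symmetrically and is preferred over OLS here because fossil predictions
routinely extrapolate beyond the extant size range.  The 95% CI of the
slope uses the F-statistic construction standard for SMA:
`B = F(0.95; 1, n−2)·(1−r²)/(n−2)`, CI `= slope·(√(B+1) ± √B)`; the
p-value is the Pearson correlation test on the log scale.  Original-
scale prediction is `10^elevation · x^slope`; inversion is exact
(`(y/10^elevation)^(1/slope)`), enabling the chained estimates below.

Prediction uncertainty, where raw training data are available, comes
from a percentile bootstrap: (x, y) pairs are resampled with
replacement, each resample refitted and evaluated at the target x, and
the 2.5th/97.5th percentiles reported.  Degenerate resamples (zero
variance on either axis) are redrawn with a cap of 10× the requested
replicates; the resampling unit is the individual pair, and whether
pairs are resampled before or after log transformation is immaterial.
BCa correction is deliberately not used — the plain percentile interval
is the simplest estimator consistent with resampling the dataset.
Published-coefficient models carry no raw data, so they yield point
estimates only.

## Anatomy and predictors

The measured column runs from the axis (C2 — the atlas has no separate
centrum body to measure; the axis CL includes the odontoid) to the 10th
caudal: 35 positions, of which C2..S2 (25) are precaudal.  The first
caudal is biconvex; by convention its CL excludes both condyles — a
measurement note only, the value is taken as given.  Units are mm
throughout (the CLI offers an m→mm convenience flag for length
records).

Predictors follow a 10-region / 4-series scheme chosen for positional
identifiability and CL homogeneity.  Region predictors are member
means; they tolerate missing members but are flagged `complete=False`
so callers can decide (the accept/reject policy for partial regions is
deliberately left to the caller).  Series predictors are member sums
and refuse incomplete series, since a partial sum is biased low —
impute first.  When a fragmentary specimen supports several predictors
the chooser prefers C2–D15 sum, then D1–15, then C2–9, then the region
with the most measured members (ties broken by the higher published TL
R²).

Within-region CL heterogeneity bounds the error of using a single
vertebra of uncertain position for its region mean; the
`region_deviation_stats` table (mean % deviation of the extreme member
from the region mean, per individual) quantifies it, and in both real
and default synthetic columns sits in the few-percent band (~2–6%).

## Imputation

A missing CL at position p is `CL_av(p) · ΣCL_ind / ΣCL_av`, where
CL_av is the per-position mean over conspecific individuals with
complete C2–Ca10 series (falling back to congeners; never across
genera), and the two sums run over the *intersection* of the
individual's available positions — so the rule is exactly scale
equivariant and recovers a deleted position perfectly when the
individual matches the reference shape.  The genus is parsed as the
first whitespace token of the species name unless a taxonomy map is
supplied.  Imputed values are flagged, carry unknown suture state, and
may feed predictors for the same individual, which are then flagged
incomplete downstream.

## Maturity and species-maximum bounds

Neurocentral sutures close caudal-to-cranial during growth, and
precaudal closure begins only after sexual maturity in extant
crocodylians; partial and full closure are equivalent everywhere
("closure has begun").  The classifier returns:

* **YES / upper bound** — any precaudal suture partially/fully closed.
  The specimen is at least as large as its species' smallest mature
  individual, whose CLs scale with the species maximum TL, so the
  species-maximum model evaluated at the specimen's predictor bounds
  the species maximum TL from above.
* **NO / lower bound** — all observed precaudals open *plus* positive
  evidence the closure front has not reached them: an open sacral, or
  an open caudal (which implies open sacrals under the sequence).
* **INDETERMINATE / no bound** — e.g. an isolated open dorsal: the
  front may sit anywhere behind it.  Requiring positive evidence for
  the lower bound is what separates this case from the open-sacral one.

Bound direction is a function of suture states only, never of size.
Columns violating the closure sequence (a closed position cranial to an
open one) are flagged with a warning but still classified by the
precaudal rule.  With multiple conspecific specimens the species
maximum TL interval is [max of lower bounds, min of upper bounds];
empty intervals are flagged as inconsistent.  If one specimen's
maximum-TL upper bound falls below another's absolute TL the two cannot
be conspecific (reported with a CI-overlap caveat when intervals are
available).

Species enter the species-maximum regression through their smallest
osteologically mature individual, and only when the TL gap to the
nearest-sized fully-open individual is under 30% — otherwise sparse
sampling could grossly overestimate the closure size.  The gap
denominator (the mature individual's TL) is a package choice; the
alternatives differ negligibly at the relevant magnitudes.  Mature-size
ratio summaries use literature male TLs only for the male mean (three
reference species have male TLs back-estimated from female ones via the
mean male/female ratio of the ten literature species) and all species
for the female mean.  Wild and captive individuals are pooled.

## Phylogenetic signal

Species-level regressions are justified as non-phylogenetic by Pagel's
λ: the Brownian covariance implied by an ultrametric tree (entries =
shared root-to-MRCA path lengths, Myr) has its off-diagonals scaled by
λ ∈ [0, 1], and λ is estimated by profile maximum likelihood of the GLS
regression of y on (1, x) with covariance σ²V(λ), σ² and coefficients
profiled analytically.  The search runs bounded scalar optimization on
five sub-intervals of [0, 1] (tolerance 1e-8) plus the exact endpoints,
because the likelihood can be flat at small n.  The λ=1 null is tested
by likelihood ratio against χ²(1); since the null sits on the boundary
of the domain the tail probability is halved (the ½χ²₀ + ½χ²₁ mixture
convention).  The regression inside the λ fit is OLS-form GLS, not SMA:
signal testing and allometric line fitting are separate concerns.
λ = 0 reduces to OLS on an ultrametric tree (verified to machine
precision); non-ultrametric trees are accepted with a warning.  The fit
refuses n < 3 (λ unidentifiable), and one fit is reported per predictor
when several are tested.

The packaged 13-tip test tree (root age 87.14 Myr) has four clades
splitting near the root with shallow within-clade divergences — the
shape that maximizes the contrast between Brownian covariance and
independence, giving the λ=1 test high power at n = 13.  On it,
independent species data drive the median λ̂ to 0 with the Brownian
null rejected in ≳99% of replicates, while Brownian data keep the
median λ̂ ≈ 1.  Note that the λ MLE is a boundary estimator: under
independence a minority of replicates still land at intermediate λ̂, so
distributional summaries (medians, rejection rates), not per-replicate
guarantees, are the meaningful recovery statements.

## Synthetic data generator

The generator emulates the structure of an extant comparative sample;
its defaults are the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| n_species / n_individuals | 18 / 95 | sample structure |
| max_tl_range_mm | 1900–6300 | species maximum TLs (log-uniform) |
| svl_law / tl_law | (1.329, 0.980) / (2.504, 0.983) | body length vs ΣCL (mm) |
| profile | packaged 35-vector | normalized CL shape (short axis, long mid-dorsals, tapering caudals) |
| closure_fraction_of_max | 0.95 → 0.40, linear | TL fraction at which each position closes; strictly decreasing craniocaudally so caudals close first |
| maturity_fraction | 0.45 | sexual maturity as a TL fraction; must precede the smallest precaudal closure fraction (≈0.56 at S2) |
| partial_band | 0.05 | PARTIAL within 5% below the closure size (exercises parsing; partial and closed merge anyway) |
| noise_cv | 0.03 | lognormal CL measurement noise (mean-corrected) |
| missingness_rate | 0.05 | per-position deletion probability |
| hatchling_fraction | 0.15 | lower end of the ontogenetic TL draw |

Individual TLs are log-uniform across ontogeny — simple and
juvenile-to-adult inclusive; survivorship-weighted distributions are out
of scope.  ΣCL follows from inverting the TL law, per-position CLs from
the profile times noise, suture states deterministically from TL
against the species' closure sizes (osteological maturity in the ground
truth begins at the PARTIAL onset, (1−band)×the smallest precaudal
closure size, since partial closure counts).  `fossilize` deletes
positions and strips length records; no further taphonomy is modeled.
The default CL profile is a qualitative shape constant, not a
figure-derived measurement; users may override it.

What the generator does *not* emulate: real museum samples concentrate
near adult sizes, whereas the log-uniform draw spreads thin across
ontogeny — so with ~5 individuals per species fewer synthetic species
pass the 30% smallest-mature gap cutoff than in a real collection; and
real measurement error is probably position- and size-dependent rather
than i.i.d. lognormal.  Passing tests therefore demonstrate correctness
of the estimators under the stated generative model, not robustness to
every property of real samples.

## Numerical choices and degenerate inputs

* n < 3 or zero log-scale variance refuse to fit; exact collinearity
  reports R² = 1 with a floor on the p-value.
* `slope = 0` models refuse inversion; prediction requires positive x.
* The sign of a bootstrap resample's slope follows the sign of its
  covariance (ties resolve positive); degenerate resamples are redrawn.
* Published coefficients are applied at printed 3-decimal precision;
  chained predictions can drift ≤0.5% relative to source values — the
  reproduction tolerances account for this.
* Reports print meters at 2 decimals (mm internally; `--mm` for raw);
  every output header records the seed and the model source, and
  PUBLISHED/FITTED coefficients are never silently mixed.

## Known limitations

SVL–TL conversion coefficients are taxon-specific and not packaged;
users must supply literature values.  The species-maximum relation is
calibrated on 13 extant species spanning 1.9–6.3 m, so bounds for taxa
far outside that range (giant or dwarf crocodyliforms) inherit
extrapolation risk on top of coefficient rounding.  Application beyond
crown Crocodylia assumes a shared precaudal vertebral formula, similar
body proportions, and similar suture-closure timing; tail-proportion
deviations (some notosuchians) bias TL more than SVL.  Histological
maturity indicators and internal ossification are out of scope.
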