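# Methods

This note documents the models, numerical choices and limitations behind
`qwa`, in the spirit of a package methods appendix.  Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Anatomical traits and ring partitioning

Cell-level traits follow the standard quantitative wood anatomy
definitions: the conduit diameter is the equivalent-circle diameter of
the lumen, d = 2√(A/π) (an ellipse-aware alternative is deliberately not
assumed — image-analysis exports differ, and the equivalent circle is the
common convention); mean hydraulic diameter is the power mean
DH = Σd⁵/Σd⁴, which weights each conduit by its contribution to
Hagen–Poiseuille conductance; CWT averages the radial and tangential
single-wall thicknesses; anatomical density AD = CWA/(CWA + A) is a
geometry-based proxy for wood density, bounded in [0, 1].

Rings are divided into 100 equal-width tangential sectors by
floor(rel_pos × 100) + 1.  Earlywood/latewood classification uses Mork's
index in the form m = 4 × (single radial wall) / (radial lumen diameter)
(equivalently 2 × double wall / lumen), latewood iff m ≥ 1 — the cited
index's usual formulation and boundary convention.  When the radial lumen
diameter is not exported, the equivalent-circle diameter stands in.
Classification is applied per sector by majority vote of its cells (ties
→ latewood, consistent with the ≥ boundary); per-cell classification is
available as an option.  Part widths split the measured ring width by the
fraction of classified sectors in each part, so EW + LW width equals ring
width exactly.

Outlier removal within each ring × part uses Tukey fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] with type-7 (linear-interpolation)
quartiles.  A `literal` mode implements the rule occasionally
printed in field protocols — remove x > 1.5·Q3 or x < 1.5·Q1 — which is
almost certainly a misstatement of Tukey fences: for right-skewed
positive data the literal lower bound can delete a quarter of the sample,
so the mode applies the literal fences only when 1.5·Q1 lies below the
median and otherwise falls back to Tukey fences with a warning.  Upstream
image-quality prefiltering ("cells misassigned between ring parts") is
not quantifiable from measurement exports and is out of scope; only the
quartile stage is implemented.

Annual aggregation uses medians (CWT, AD) per tree × year × part —
robust to the skewed within-ring distributions — and the DH power mean
over the part's cells.  Sector profiles store the per-sector medians of
d, CWT and AD; empty sectors stay missing.

## Drought index

PET is Thornthwaite's temperature-based method with mid-month day-length
correction (PET = 0 for months ≤ 0 °C), the usual default when only
monthly temperature is available; latitudes beyond the polar circle are
refused.  The k-month water balance Dₖ (rolling sum of P − PET) is
standardized per calendar month with a three-parameter log-logistic
distribution fitted by unbiased probability-weighted moments over the
calibration period (default: the full record, ≥ 30 years), then mapped
through the standard-normal quantile; the first k − 1 months are
undefined.  The log-logistic is always right-skewed (L-skewness 1/β), so
for a left-skewed monthly sample the PWM shape estimate is inadmissible;
in that case the mirrored sample is fitted and F_X(x) = 1 − F₋X(−x) used,
which preserves standardization and monotonicity.  Severe drought years
have 3-month SPEI < −1.5 in any month March–October.  With 62-year
records the per-month SPEI mean and sd are within a few thousandths of 0
and 1 (measured by the acceptance script).

Because SPEI is standardized against the record's own variability, a
~60-year record almost always contains natural months below −1.5: the
synthetic generator's planted droughts are always recovered, but the
flagged calendar legitimately contains additional natural drought years.

## Detrending, prewhitening, chronologies

The detrending curve solves (I + λ DᵀD) f = y with D the second
difference; the penalty eigenvalue at frequency f is 16·sin⁴(πf), so
λ = 1/(16·sin⁴(π/p)) gives exactly 50% amplitude response at wavelength
p (default 30 years) — the flexible-spline standard of dendrochronology.
Measured response: 0.50 at 30 years, >0.95 at 300, <0.1 at 5, monotone
in frequency.  Indices are raw/fit ratios; non-positive fitted values are
floored at 5% of the series' mean magnitude with a warning.  Gaps inside
a tree's span split the series into separately detrended segments.

Prewhitening fits AR(p), p ∈ 0..min(10, n/4), by AIC and returns
residuals re-centered to the input mean (so index units survive).  AIC
keeps a spurious lag with probability ≈ 0.16 per candidate, so order 0 is
only the modal choice on white noise — the behavior of the reference
dendro tooling, accepted here.  On AR(1) input (φ = 0.7, 100-year
series) residual |lag-1 autocorrelation| stays below 0.1 in ≈ 95% of
simulations; the residual-acf sd is ≈ √(φ²(1−φ²)/n) even for a perfect
fit, so much shorter series fail that bound for purely sampling reasons.

Trees are combined per year by the Tukey biweight robust location
(u = (x − t)/(9·MAD), weights (1 − u²)², iterated to 1e-8; zero MAD →
median), with sample depth tracked per year.

Climate–growth correlations are Pearson's r per variable × month over the
20-month window previous-March … current-October, with climate detrended
per calendar month by the same spline-ratio procedure (SPEI enters
already standardized, at the 6-month scale).  Significance uses a
year-resampling bootstrap percentile interval (default 1000 resamples,
α = 0.05, seeded).  Under independence the measured significance rate is
≈ 0.05–0.07 — the small anti-conservatism of percentile intervals for
correlations at n = 60 is expected and documented rather than corrected,
as it is the referenced tooling's behavior class.

## Intra-annual statistics

Ring profiles are min–max normalized, (x − min)/(max − min), removing
tree-level scale and ontogenetic level so only intra-ring shape remains;
constant rings are excluded (zero range).  Group profiles are sector-wise
means across rings, LOESS-smoothed (local linear, span 0.3 — narrow
enough to keep the earlywood→latewood transition, wide enough to remove
sector noise); the 95% band is mean ± 1.96·SE computed per sector before
smoothing and smoothed with the same operator, keeping band and mean
consistent.

The Gini coefficient uses the sorted-sample identity
G = Σ(2i − n − 1)x₍ᵢ₎/(n²x̄) (equal to the pairwise mean absolute
difference normalization; verified against the O(n²) oracle to 1e-10).
Bootstrap intervals — percentile and BCa from one shared resample array;
bias correction from the fraction of resamples below the point estimate,
acceleration from jackknife skewness with an O(n) leave-one-out update —
agree with scipy's BCa implementation.  Coverage against the analytic
lognormal Gini G = 2Φ(σ/√2) − 1 is ≈ 0.91 at σ = 0.5 (G ≈ 0.28, the
inequality regime of observed wood-trait profiles); under much stronger
skew (σ = 0.8) every bootstrap flavor — including scipy's — undercovers,
a documented property of bootstrap Gini inference, not an implementation
artifact.

Drought-phase analysis collects rings at d − 1, d, d + 1 around each
drought year d per group; a neighbor year that is itself a drought is
excluded from before/after (preventing contamination in consecutive
droughts), and phases without eligible rings are omitted with a
diagnostic.  Phase pairs are compared by the KS D statistic in two modes:

- **profile** (default): D between the two phase-mean 100-sector
  profiles, with a *year-label permutation* p-value (999 permutations).
  Rings of one year share a season and are strongly correlated, and so
  are the sectors of a mean profile; iid-based asymptotic KS p-values are
  therefore badly anti-conservative here.  Permuting whole years between
  the two phases is calibrated under year-level exchangeability by
  construction.
- **pooled**: classical asymptotic KS on the pooled normalized sector
  values of the two phases, kept because the pooling unit of the original
  protocol is ambiguous; its p-values should be read as descriptive.

Group contrasts (pure vs mixed within drought years) use the classical
two-sample KS (scipy, asymptotic).  The drought/non-drought Gini table
pools normalized sector values per site × forest type × phase stratum;
ring-width inequality (RWI rows) pools spline-detrended annual ring-width
indices instead, since ring width has no intra-annual profile.

## Synthetic data generator

The generator emulates the study design the pipeline targets: two forest
type groups (pure/mixed), 9 trees per group, 62 years from 1958, ~300
tracheids per ring, monthly climate with continental normals (mean annual
temperature ≈ 8.3 °C, annual precipitation 565 mm), interannual sd
1.5 °C / cv 0.35, and a 0.3 °C/decade warming trend.  All randomness
flows from one root seed through named substreams (climate, trees);
identical configurations are byte-identical.

Planted droughts subtract a stated number of precipitation standard
deviations (clipped at zero) and add a proportional warm anomaly in the
listed months; the default demo regime plants six spring/summer droughts
with month timing varying between events, as real droughts do.

Cells follow a logistic earlywood→latewood transition (center 0.65 of
ring width, matching the ~⅔ earlywood share of pine rings): expected
lumen diameter falls 26 → 12 µm and wall thickness rises 3.2 → 5.4 µm,
with lognormal cell noise (σ = 0.18 diameter, 0.10 wall), tree effects
(σ = 0.05) and a juvenile trend.  Wall area uses an annulus model
CWA = π(dt + t²).  Ring width follows a negative-exponential age trend
(2.8 → 1.2 mm, 25-year decay) times a climate factor.  Climate coupling
(ring width 0.25, earlywood lumen 0.05 per sd of an Apr–Aug moisture
proxy) gives chronologies a recoverable climate signal; both can be set
to 0 for a null generator.

Group-specific drought effects multiply the *expected earlywood
anatomical density* in drought years and/or the year after (wall
thickness is back-solved from the scaled wall area), so a 1.15 multiplier
is exactly a 15% AD elevation; multipliers are capped where AD would
exceed 0.95 and rejected when ≤ 0.

What the generator does not emulate: cambial phenology (cell counts per
ring are constant, not growth-dependent), oak neighbours (only the pine
response conditioned on group), spatial stand structure, measurement
artifacts of image segmentation, and missing rings.  Passing tests
therefore demonstrate that the statistical machinery recovers known
signals under realistic noise — not that real pine populations behave
like the generator.

## Problem sizes and determinism

The replicate experiments use the study-scale configuration (9 + 9 trees
× 62 years × 300 cells/ring ≈ 335 k cells per dataset): 50 effect and 50
null replicates for the legacy-recovery experiment, 200 simulations for
prewhitening and BCa coverage, 1000 replicates for the correlation
type-I rate, 1000/500 random vectors for the Gini and KS oracles.  Every
stochastic routine takes an explicit seed; `scripts/acceptance.py`
derives all of its seeds from the single `--seed` argument.

## Known limitations

- The SPEI PET method and calibration window of any given study are
  rarely reported; comparisons to published SPEI series are qualitative.
- Percentile bootstrap CIs (correlations) are mildly anti-conservative at
  n ≈ 60; BCa Gini intervals undercover under strong skew.
- The literal outlier rule is supplied for reproduction purposes only.
- The pooled KS mode ignores within-ring correlation; use profile mode
  for inference.
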