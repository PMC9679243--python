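# Methods

This note records the model, the defaults, and the judgment calls — what a
maintainer needs to know before trusting or changing a number.

## Life cycle and data correction

The modeled life cycle has three live states on top of a continuous size
variable (rosette diameter, mm):

* **NORMAL** — vegetative or axillary-flowering rosette with measurable
  diameter;
* **BOLTER** — terminal-bud reproduction; the rosette is absent, so the
  plant is alive with diameter 0 or missing (0 and missing are
  canonicalized to missing);
* **DORMANT** — alive belowground, invisible to the census.

Dormant plants are recorded dead, so dormancy is *inferred*: any interior
`0` flanked by live observations is corrected to `1`
(`correct_reincarnation`), and the flipped positions are the dormant years
(`score_dormancy`). Two consequences are inherent to this inference and are
not bugs:

1. **Right-censoring.** A dormancy episode is detected only if the plant is
   seen alive again before the final census. Fitted dormancy-entry rates
   therefore estimate *apparent* dormancy, a lower bound on the latent
   rate; the final intercensus interval can never contribute a detected
   entry into dormancy and is excluded from those fits.
2. **Conditioning on re-emergence.** Every detected dormant plant-year
   belongs to a plant that was later alive, so observed dormant survival is
   structurally ≈ 1. The kernel uses this apparent rate; it partially
   offsets the undercounted entry rate in the population-level projection.

Plants never observed alive are retained in the cohort summaries but carry
no transitions. A record scored dead with a positive diameter is rejected
as contradictory. Census years must be consecutive; gaps raise an error
rather than being imputed.

## Vital-rate regressions

Each rate is fitted per population as a GLM of size `z` (binomial-logit for
probabilities, Poisson-log for counts, truncated Gaussian for growth),
comparing four nested fixed-effect structures — intercept-only, `z`, `z²`,
`z + z²` — under an identical year structure and observation set. Model
choice is by small-sample AICc with a parsimony rule: the lowest-AICc model
wins unless competitors are within 2 units, in which case the candidate
with fewest effects is chosen (ties resolve by lower AICc, then canonical
name order, so the choice does not depend on input ordering).

**Year effects.** Year-to-year variation enters as sum-coded year
intercepts, so the model intercept is the average-year intercept and the
fitted dummies are per-year deviations. The between-year SD is recovered by
method of moments — the variance of the fitted deviations minus their mean
squared standard error, clipped at zero — and its estimation uncertainty is
propagated into bootstrap draws as a scaled chi-square with
`n_years − 1` degrees of freedom. With hundreds of observations per year
this is numerically indistinguishable from a random-intercept fit for the
fixed coefficients, keeps one code path for all three response families,
and yields an exact AICc. Quadrat-within-transect effects are not fitted:
kernels are population-level objects, and a quadrat intercept would enter
only to be integrated out again at its mode.

**Growth.** Next-year diameters cannot be ≤ 0, so growth is a
zero-left-truncated Gaussian regression fitted by maximum likelihood
(analytic gradient, observed information from differenced scores). This is
the same density the discretized growth kernel uses after eviction
renormalization; an untruncated least-squares fit is visibly biased at
small sizes. Growth pools all transitions that end NORMAL — re-emerging
bolters and dormants pass through the same growth map from their latent
size. The residual SD is constant (no size-dependent variance).

**Degenerate data.** A constant binary/count response falls back to an
intercept-only estimate with (k+½)/(n+1) shrinkage, flagged. Quasi-complete
separation (any coefficient or SE running to the boundary, including a year
dummy for a year with a constant response) fails that candidate; if all
candidates fail, the fit is retried without year effects and flagged
`year_effects_dropped`. Sparse sizeless-state rates (< 10 usable rows)
borrow the NORMAL intercept-only estimate or, for never-observed
transitions, a near-zero probability, always flagged.

**Reproduction and recruitment.** Reproduction is a hurdle: flowering
probability (binomial-logit) times fruit count given flowering, modeled as
1 + Poisson on the mean extra fruits — a reproducing plant carries at least
one fruit, which makes the hurdle exactly identifiable from fruit counts.
The recruitment rate is total new recruits in year t+1 over total fruits in
year t, pooled across intervals (the Poisson MLE; per-interval ratios are
unstable when a year's fruit total is near zero). Recruit sizes are a
zero-truncated Normal fitted by MLE to observed first-year sizes.

**Bootstrap draws.** β* ~ MVN(β̂, Σ̂_β) (covariance repaired by eigenvalue
clipping if needed), one fresh year deviation per intercensus interval from
N(0, σ*) with σ*² redrawn each replicate. Draw-level predictions are
guarded: Poisson linear predictors are clipped at ±30 and the expected
fruit count is capped at the population's largest observed count — a
predicted *mean* above every observation is pure extrapolation, and without
the cap a wild draw of a weakly identified quadratic occasionally produces
astronomically large recruitment. Recruitment rate and recruit-size
parameters are held at their point estimates across draws (a known
understatement of uncertainty; the regression coefficients dominate).

## Kernel assembly

One annual kernel is a 3×3 grid of n×n blocks on a shared midpoint-rule
mesh (default 150 points, 0 mm to 110% of the largest observed diameter).
Column `j` of each block distributes the fate of an individual at mesh size
`z_j`:

* survival `s_X(z)` per state, then transition among states conditional on
  survival; if a fitted transition pair sums above one at some size it is
  rescaled onto the simplex;
* everything ending NORMAL passes through the growth density
  `N(μ(z), σ²)·h`, column-renormalized so no mass is evicted at the mesh
  boundaries; everything ending BOLTER or DORMANT sits on the block
  diagonal (latent-size memory), so exits from those states can remain
  size-dependent;
* reproduction adds recruits to the NORMAL rows only (bolters reproduce;
  dormants cannot): expected fruits × recruits-per-fruit × the
  zero-truncated recruit-size density (normalized on the mesh).

Entries are validated non-negative and finite; assembly errors name the
offending block and column. The dominant eigenvalue of an assembled kernel
matches a long power iteration to < 1e-8 (tested).

**Comparing kernels.** `max_relative_error` evaluates relative entry error
above a floor of 1e-2 × the reference's largest entry. The floor is a
property of the metric, not a tolerance: on a Gaussian tail the relative
error from a mean shift Δμ is ≈ Δμ·d/σ² at distance d, which diverges as
entries shrink, so a fixed relative tolerance is only meaningful over
entries carrying non-negligible mass (the default floor keeps two orders of
magnitude of entries in scope). Consistency checks against the generating
kernel additionally restrict to source columns inside the observed size
range (0.5–99.5 percentiles): beyond the largest observed rosette the
regression is pure extrapolation.

## Stochastic projection

λ_S is estimated from one long sequence (default 50,000 steps) of annual
kernels drawn independently and uniformly with replacement (IID
environments, no autocorrelation): at each step the annual λ is the ratio
of vector totals and the vector is renormalized to sum one; λ_S is the
geometric mean. No burn-in is removed — at 50,000 steps the transient
contributes O(10⁻⁵) to the mean log growth (the identical-kernel test shows
agreement with the dense eigensolver to < 1e-4). The initial vector is
uniform over all mesh cells of all three live states; dormant plants are
alive, so all three segments count toward population size.

Transient projections scale that uniform vector to the final census size
and run a 22-year horizon, redrawing a kernel each year. After each step
the *total* is rounded to the nearest integer and the stage vector rescaled
to it (per-cell rounding across 450 cells would annihilate the vector);
extinction is total ≤ 0 — the species is a self-compatible hermaphrodite,
so a single plant can found a population and no quasi-extinction cushion is
applied (the threshold is configurable).

Each bootstrap replicate contributes one λ_S, one extinction proportion and
one mean final size across trajectories (trajectory medians are used for
the per-year trajectory summary because population size is strongly
right-skewed). Across replicates: λ_S is summarized by median and 2.5/97.5
percentiles; extinction probability and predicted size by means and
percentile intervals (numpy's linear-interpolation quantile). Bootstrap
means of predicted size can exceed their own 95% interval when a few
boom-sequence replicates dominate — a feature of heavy-tailed growth, which
is why medians are reported alongside.

## Synthetic censuses

The generator is an individual-based simulation of the census process:
tagged plants on 1 m² quadrats nested in 1–3 transects, five populations of
300–500 initial plants, eight annual censuses. It emits exactly what a
field crew would record — dormant years as survival-0 rows (so downstream
code must reconstruct reincarnations), bolter years as survival-1 rows with
missing diameter, dead tags revisited with survival-0 rows, new recruits
appearing as new ids with small diameters — plus a `TruthRecord` holding
the parameters, the realized year deviations and the true per-plant state
matrices for oracle comparisons.

**Default preset** (the study-shaped conditions): logit-quadratic survival
and flowering peaking at mid sizes, Gaussian growth with slight shrinkage
of large rosettes, ~10% annual dormancy entry with geometric duration
capped at 3 years, size-dependent bolting, shifted-Poisson fecundity,
recruitment at 0.2 recruits per fruit with ~4 mm recruits, and large
interannual SDs concentrated in survival (1.2 on the logit scale) and the
reproduction pathway (1.2 on logit/log scales). These values were set once
so that the implied dynamics match the qualitative regime of the source
system: censused populations that swing through years of rapid growth and
severe decline while producing median λ_S ≈ 0.45–0.6 (the interannual
variance, mostly via boom/bust recruitment, is what drags the stochastic
growth rate below the mean-environment eigenvalue of ≈ 0.85). They are
synthetic presets, not estimates of any real population's rates.

**Recovery preset** (`recovery_params`): a single population held
near-stationary (λ ≈ 1) so that a 5000-plant cohort remains at risk through
all seven transitions; used for parameter-recovery studies where the
default declining preset would run out of plants.

**Validation preset** (`validation_params`): recovery preset with dormancy
disabled (both entry routes), zero year SDs and sizes kept away from the
zero boundary. Estimator-consistency checks (fitted kernel vs the
closed-form `truth_kernel`) are run here because (i) the truth kernel is
defined only for a homogeneous environment, and (ii) reincarnation-based
inference targets apparent dormancy, so latent dormancy rates are not
identifiable from census records by construction — with dormancy on, the
comparison would measure that censoring, not implementation correctness. A
separate test proves the reconstruction recovers *exactly* the detectable
dormant years against the simulator's true state matrices.

What the generator does **not** emulate: quadrat/transect random effects
(hooks exist, default SD 0 — magnitudes for the real system are
unpublished), observation error in diameters, density dependence (absent
from the models by design), temporally autocorrelated environments, and a
seed bank (the species has none). Passing tests on synthetic data therefore
demonstrate correctness of the inference machinery under the stated model,
not robustness to these unmodeled features of real data.

## Genetics–demography link

Transforms: natural log for λ_S, predicted N and density (with +0.5
individuals only where a predicted size is exactly 0); logit for H_O, F_IS
and extinction probability (boundary values pulled inward by 0.001). Both
constants are configurable and reported. Pearson correlations with
two-sided p-values from the t distribution on n−2 df; every
predictor × outcome pair is evaluated for all populations and for the East
genetic group (n = 4) separately; subsets below n = 3 are flagged, and
zero-variance inputs raise instead of returning NaN. No multiple-testing
correction is applied — at n = 5 the power analysis already shows only
|r| > 0.94 is detectable at power 0.75 (bias-adjusted Fisher-z equation
`atanh(r) + r/(2(n−1)) = (z_{1−α/2} + z_power)/√(n−3)`, solved by Brent
bracketing to 1e-9).

Correlations computed from the packaged (printed, rounded) tables differ in
the second decimal from values computed on unrounded estimates; tests
allow ±0.02 for exactly this reason.

## Numerical choices, in one place

* Mesh: midpoint rule; entry = h × density; growth and recruit densities
  renormalized on the mesh (eviction correction).
* AICc: `−2ℓ + 2k + 2k(k+1)/(n−k−1)`, k counting all estimated parameters
  (year dummies; +1 for the Gaussian residual SD); ∞ when n ≤ k+1.
* Separation guards: |coefficient| > 15 or SE > 30 on a link scale fails a
  binomial/Poisson candidate.
* MVN draws: covariance symmetrized and eigenvalue-clipped at 0.
* Poisson predictions: linear predictor clipped at ±30; expected fruits
  capped at the population's observed maximum.
* λ_S: early-stops to 0 if the vector hits exactly zero mass.
* Percentiles: numpy default linear interpolation.
* Transition pairs exceeding probability 1 at some size: rescaled onto the
  simplex.

## Known limitations

* Dormancy quantities are apparent, not latent (see above); multi-year
  terminal dormancy at the end of the record is indistinguishable from
  death.
* Recruitment-rate and recruit-size uncertainty is not propagated through
  the bootstrap.
* The year-variance sampling distribution (scaled chi-square, df =
  n_years − 1) is an approximation to the REML uncertainty of a variance
  component; it is isolated in `draw_coefficients` as a swap-in point.
* Growth residual SD is size-independent; the mesh upper bound (110% of the
  observed maximum) makes predictions beyond observed sizes extrapolation,
  relevant mainly to bootstrap draws of quadratic terms.
* Fitting populations separately forgoes any pooling of information across
  populations; with very sparse populations the flagged fallbacks engage.
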