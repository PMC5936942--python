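# Methods

This note documents the statistical models, the synthetic data-generating
process, the numerical choices and the known limitations of `fjordbeta`.

## Diversity partitioning

Beta diversity is measured as the total variance of the (Hellinger-
transformed) time × species matrix Y: with column means ȳ_j and
s_ij = (y'_ij − ȳ_j)², SS_total = Σ_ij s_ij and BD_total = SS_total/(n−1).
Row shares LCBD_i = SS_i/SS_total quantify how unusual each sampling time's
composition is relative to the whole series; column shares SCBD_j do the
same per species. Both sum to one exactly, and SS_total equals (1/n) times
the sum of squared pairwise Euclidean distances between transformed rows —
the identity the test suite checks against a brute-force pairwise oracle.

LCBD significance uses a null that permutes abundances independently within
each species column: species abundance distributions are preserved while
joint temporal structure is destroyed. p = (1 + #{LCBD* ≥ LCBD})/(1 + n_perm).
No multiplicity correction is applied by default. All-zero community rows
(empty frames) are excluded with a warning rather than imputed, since the
Hellinger transform is undefined for them.

## Temporal eigenfunctions (dbMEM)

The temporal autocorrelation basis follows the truncated-distance
principal-coordinate construction: pairwise time distances (days) above a
truncation threshold t — by default the largest within-block spacing — are
replaced by 4t; −D²/2 is Gower-centred and eigendecomposed; eigenvectors
with |λ| > 1e-10·max|λ| are retained at unit norm. Moran's I for each
eigenfunction is computed against binary connectivity (pairs within t) and
compared with its expectation E(I) = −1/(n−1) to classify positive versus
negative temporal correlation. On a regular grid the eigenfunctions are
numerically indistinguishable from sinusoids, and the construction
reproduces the reference R implementation (vegan's `pcnm`) to 1e-8 on a
shared example, which one test verifies by calling `Rscript`.

Irregular sampling is handled in two ways. Small gaps are padded with the
minimal number of equally spaced *supplementary* points so no within-block
spacing exceeds 24 h; these points shape the basis but are removed before
any response modelling, at a small, reported cost in orthogonality (the
maximum off-diagonal Gram entry is logged and stored). The long
instrument-service gap is never padded: eigenfunctions are built per
deployment block and assembled block-diagonally ("staggered"), so cross-
block columns are exactly orthogonal and no eigenfunction spans unsampled
time. Positive-class eigenfunctions are banded into broad (172–53 d),
medium (26–11 d) and fine (7.5–2.7 d) time scales by the peak of a
Lomb–Scargle periodogram evaluated on the eigenfunction's own (possibly
irregular) grid; the pipeline builds the banded sub-models from the second
deployment block only, which has the fewer gaps, and does not subdivide the
negative class.

## Constrained ordination and variance partitioning

`RDA` regresses the centred response matrix on centred predictors by least
squares and takes an SVD of the fitted values; R² = SS(fitted)/SS(total),
adjusted by Ezekiel's formula 1 − (1 − R²)(n−1)/(n−m−1). Model significance
uses unrestricted row permutation of Y with R² as statistic (monotone in the
pseudo-F at fixed m). Two kinds of site scores are exposed: linear-
combination scores (from the fitted values) and weighted-averaging scores
(the observed compositions projected on the canonical axes). The turnover
ordination on (t, t²) uses the weighted-averaging scores for trajectories,
since only those can close the loop when the composition itself returns to
its starting state.

Predictor handling mirrors standard practice for ecological tables:
responses are first purged of significant (α = 0.05) linear time trends;
predictors are screened to VIF ≤ 10 by iteratively dropping the worst
column; forward selection minimizes the multivariate AIC surrogate
n·ln(RSS_total/n) + 2m with RSS summed over response columns and
deterministic column-order tie-breaking. The double-stopping rule (stop
once the full model's adjusted R² is exceeded) is available as an option
but off by default.

Three-set variance partitioning fits the seven component RDAs (each
predictor set alone, each pair, all three), converts each to adjusted R²,
and solves the linear inclusion–exclusion system exactly for the seven Venn
regions; the residual is 1 − adjR²(all three). Component models are
evaluated by projection with the rank (not the raw column count) in the
Ezekiel correction, so unions of overlapping or duplicated sets remain well
defined. Negative fractions are reported as-is and merely flagged "not
shown" in the display.

## Segmented regression

The rate model is the continuous piecewise-linear regression
y = b₀ + b₁x + Σ_h d_h (x − ψ_h)₊ + ε. Breakpoints are estimated by
iterative linearization: at working values ψ the design gains indicator
columns −1(x > ψ_h); the fitted indicator coefficient divided by the slope
change is the first-order update to ψ_h, iterated to a 1e-6 (relative)
fixed point with the best-RSS iterate kept, initialized from a 20-point
interior grid searched greedily one breakpoint at a time. Breakpoints are
constrained to keep at least three observations on each side and at least
three median sampling steps apart; if refinement collapses, the best grid
solution is returned flagged `converged=False`. Per-segment slopes are
cumulative sums of the difference coefficients; their covariance is taken
from the indicator-augmented design so first-order breakpoint uncertainty
propagates into the slope intervals — without this the 95% intervals
covered only ~85% in simulation, with it ~94%. Segments are classified
increase / decrease / no-change by whether the 95% CI excludes zero.

The breakpoint count is chosen by AIC after sequential forward addition.
Each breakpoint is charged 1 + 3 degrees of freedom — its slope-change
coefficient plus a ~3-df cost for the adaptively estimated knot, the
convention used for knots in adaptive regression splines — giving
AIC = n·ln(RSS/n) + 2(2 + 4k). With the naive 1-df knot charge the searched
breakpoint's non-regularity made AIC select spurious breaks in about a
third of null simulations; with the knot cost the true size is recovered in
≥90% of simulated linear and two-break series.

The hysteresis report compares, around a stated reoxygenation time, the
steepest significantly decreasing segment before it with the steepest
significantly increasing segment after it, and reports their ratio
(>1 means recovery is slower than decline). The "decline interval" used to
contrast guilds is the span of the *principal* decline — the decreasing
segment with the largest total change — which is robust to shallow,
long-merged segments that AIC sometimes produces at low signal-to-noise.

## Environmental metrics

pO₂ (kPa) = (C/C_sat(T,S)) · x_O₂ · (P_atm − p_H₂O(T,S)), with the
Garcia–Gordon (1992) ml l⁻¹ solubility fit and the Weiss–Price (1980)
seawater vapour pressure; x_O₂ = 0.20946, P_atm = 101.325 kPa. Hydrostatic
pressure is accepted in the signature but does not enter: partial pressure
at depth is set by gas content relative to surface equilibration. The
oxygen sensor offset (default 0.048 ml l⁻¹, the histogram minimum of the
raw record) is subtracted with clamping at zero, zero being interpreted as
anoxia.

Window summaries use half-open trailing windows (t − w, t], so a sample at
an imaging timestamp belongs to exactly one window; s.d. uses the n−1
denominator and is 0 for single-sample windows; a window with no
observations yields missing values, never zeros.

Decadal trends are OLS slopes on the linearly interpolated record after
truncating it at the first and last seasonal maximum, located on a 30-day
smoothed copy within 1.5 years of each end; truncation at matching seasonal
phase removes the phase bias a partial cycle otherwise adds (a noiseless
trend + sinusoid is recovered exactly). Annual threshold durations count
observed samples below threshold times the sampling interval, in years
starting on the 16 March anniversary; years with under 50% coverage are
reported missing, not zero, and the duration trend is an OLS slope on year
index.

## The synthetic scenario

The generator's defaults encode the study conditions the pipeline is meant
to recover, over a 442-day deployment (20 Feb 2012 – 6 May 2013) sampled
every minute (environment) and every 12 h (community):

- **Oxygen**: piecewise-linear seasonal template — 1.9 ml l⁻¹ plateau,
  120-day decline from 20 May, anoxic floor at 0, 60-day renewal — with the
  renewal onset placed so the template spends exactly 174 days below the
  0.5 ml l⁻¹ severe-hypoxia threshold. Short-term variability (per-minute
  AR(1) with 0.995 autocorrelation, plus diurnal and M2-tidal harmonics)
  scales with template²/baseline, so it shrinks with the mean and vanishes
  at the floor; the quadratic coupling keeps the daily-mean threshold
  crossings sharp enough that the realized severe-hypoxia duration stays
  within ±2 days of the programmed value. Temperature warms 8→9 °C in
  anti-phase; backscatter is logistic in oxygen (suppressed in severe
  hypoxia); a 0.048 ml l⁻¹ sensor offset is added for preprocessing to
  remove.
- **Community** (13 archetypes; expected densities are exposed as ground
  truth): mobile species track a logistic occupancy of oxygen at a
  rate-limited (symmetric) approach; thresholds 0.2–0.7 ml l⁻¹, with the
  flatfish analogue at its 0.36 ml l⁻¹ critical oxygen level and a ×(1 +
  0.4·cos) midnight-peaking diel factor; the squat-lobster analogue adds a
  Gaussian migration pulse (peak 123 ind m⁻², ~3 weeks, late May). Sessile
  species accumulate exposure-days below 0.5 ml l⁻¹ (saturating at lag+12
  days, decaying at 0.35 d/d once oxygen recovers) and, once exposure
  exceeds a 45-day lag, decline at fixed rates (guild total 0.62 ind m⁻²
  d⁻¹) that continue ~34 days past reoxygenation, then recover at 0.3× the
  death rate — a programmed hysteresis ratio of 10/3. Emergent infauna
  (four species, 120 ind m⁻² combined) are present only below ~0.1 ml l⁻¹.
  Counts in the 2.7 m² imaged area are negative-binomial (dispersion 20);
  the sessile guild uses the Poisson limit, since repeat images of the same
  attached individuals carry little extra-Poisson noise.
- **Drivers and gaps**: seven binary biological drivers with logistic
  on-rates in oxygen (mats and worm tubes at low O₂, zooplankton swarms at
  high) or season (phytoplankton); ordinal visibility ranks tied to
  backscatter. 28% of samples are masked missing in geometric-length runs,
  including one contiguous 15-day service gap from 16 August; masks never
  alter stored values.

Carrying densities, response rates, mortality lags and stress dynamics are
free parameters of the generator, chosen once so that the programmed season
exhibits the documented qualitative structure (a brief mobile crash versus
a protracted sessile mortality spanning reoxygenation; an anoxia-phase
assemblage dominated by emergent infauna that is the most compositionally
distinct of the series; an end state resembling the start). What the
end-to-end tests show is therefore that the estimators recover *programmed*
structure from realistically noisy, gappy data — not that real communities
behave this way. Known divergences from real data: no observation-level
visibility effects on counts, no species interactions, no spatial
heterogeneity, piecewise-linear (not smooth) seasonal forcing, and
stationary observation noise within guilds.

Two auxiliary constructions serve the long-term metrics: a multi-year
trend+sinusoid oxygen record with a programmed −0.067 ml l⁻¹ yr⁻¹ slope,
and a square-wave record whose annual below-threshold duration grows by
exactly 12.4 days yr⁻¹.

## Problem sizes and determinism

Default analyses run at the native scale of one deployment: ~636k
environmental samples, ~880 community samples (≈630 observed), ~320
analysis rows at 24-h resolution, 999 LCBD permutations. The Monte-Carlo
validation studies use n = 200 series with 500 replicates for breakpoint
recovery and 100 replicates for selection behaviour. Every stochastic step
takes an explicit seed; fixed seeds give bit-identical outputs, which the
pipeline's checksum manifest makes checkable.

## Limitations

- Sub-properties of the end-to-end season that depend on segmentation
  topology (the hysteresis ratio estimate, principal decline spans) carry
  ~10–20% sampling error at the default noise level; across random seeds
  roughly one run in ten misses one of them even though the estimators are
  unbiased.
- The supplementary-point rule uses equal spacing within each gap; other
  placements are possible and change the basis slightly.
- Permutation schemes (within-species for LCBD, unrestricted rows for RDA)
  ignore temporal autocorrelation under the null and are therefore
  anti-conservative for strongly autocorrelated residuals; the dbMEM
  covariates are the intended remedy within the models themselves.
- The segmented model enforces continuity; discontinuous regime shifts are
  out of scope.
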