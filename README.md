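# fjordbeta

Temporal beta-diversity analysis for benthic communities in seasonally
hypoxic basins.

Cabled seafloor observatories produce two data streams that rarely fit
standard community-ecology tooling: minute-resolution environmental records
(dissolved oxygen, temperature, salinity, pressure, acoustic backscatter)
and an irregular, gappy time × species abundance matrix from time-lapse
imagery. `fjordbeta` implements the full analysis chain used to ask how a
seafloor community declines under seasonal deoxygenation and recovers after
reoxygenation, and which processes — environmental forcing or temporal
autocorrelation — structure it at which time scales. It is aimed at benthic
ecologists and biological-oceanography groups working with observatory time
series.

## What it computes

**Environmental preprocessing** (`fjordbeta.envseries`) — constant
sensor-offset correction with clamping at anoxia; oxygen partial pressure
pO₂ = (C / C_sat(T,S)) · x_O₂ · (P_atm − p_H₂O), with Garcia–Gordon
solubility; trailing 12-h window summaries (mean, s.d., max, min) aligned to
imaging times; gap interpolation, centred running means; decadal trends with
phase-aligned truncation; annual cumulative days below hypoxia thresholds
(0.5 and 0.88 ml l⁻¹) and their linear trend.

**Diversity partitioning** (`fjordbeta.diversity`) — Shannon H′, Pielou J;
Hellinger transform; total beta diversity as the variance of the community
matrix, BD_total = SS_total/(n−1), partitioned exactly into per-time-point
local contributions (LCBD, with within-species permutation p-values) and
per-species contributions (SCBD).

**Temporal eigenfunctions** (`fjordbeta.dbmem`) — distance-based Moran's
eigenvector maps on irregular time grids: truncated distance matrix,
principal-coordinate decomposition, Moran's I classification into positive/
negative temporal correlation, supplementary-point padding of small gaps, a
block-diagonal "staggered" basis across a multi-day service gap, and
broad/medium/fine scale bands (172–53, 26–11, 7.5–2.7 days) by periodogram.

**Constrained ordination** (`fjordbeta.ordination`) — statsmodels-style
`RDA(endog, exog).fit()` returning an `RDAResults` with canonical axes,
adjusted R² (Ezekiel), and a row-permutation test; linear detrending; VIF
screening (≤ 10); greedy forward selection under a multivariate AIC;
three-set variance partitioning (environment / positive / negative temporal
correlation) by inclusion–exclusion on adjusted R²; and the (t, t²)
turnover ordination.

**Piecewise rates** (`fjordbeta.segmented`) — `SegmentedModel(x, y).fit(k)`:
continuous piecewise-linear regression via grid-initialized iterative
linearization, breakpoint count chosen by AIC under sequential forward
addition, per-segment slopes with 95% CIs classified as
increase/decrease/no-change, and a decline-vs-recovery (hysteresis) report.

**Synthetic scenario generator** (`fjordbeta.simulate`) — a fully programmed
seasonal hypoxia cycle (plateau–decline–anoxic floor–renewal; variability
shrinking with the mean; 174 days of severe hypoxia by default) plus a
13-species community with guild-specific dynamics: rapid mobile exclusion, a
mass-migration pulse peaking at 123 ind m⁻², lagged sessile mortality that
continues after reoxygenation with a 3.33× decline:recovery asymmetry,
infaunal emergence during anoxia, and a midnight-peaking diel signal in one
flatfish-like species. Because the ground truth is known, every estimator in
the chain can be validated end to end.

The `fjordbeta` command line (`simulate`, `preprocess`, `diversity`,
`dbmem`, `model`, `segments`, `trends`, `all`) runs the pipeline stagewise
and writes CSV/JSON intermediates plus a checksum manifest.

## Worked example

```python
import fjordbeta as fb

cfg = fb.PipelineConfig(scenario=fb.default_scenario(seed=0), seed=0)
r = fb.run_pipeline(cfg, through="segments")

print(r.segments["sessile"]["fit"].summary())
print(r.varpart.summary())
print("BD_total %.4f" % r.beta.bd_total, "| peak LCBD at", r.beta.lcbd.idxmax())
```

prints

```
Segmented regression: sessile
=============================
n = 333, breakpoints = 2, AIC = 1037.93, RSS = 7080, converged = True
breakpoints at x = 225.267 (se 1.801), 386.147 (se 1.949)
 segment       from         to      slope     95% lo     95% hi  class
       1      0.000    225.267    -0.0006    -0.0114     0.0101  no_change
       2    225.267    386.147    -0.6270    -0.6444    -0.6097  decrease
       3    386.147    441.000     0.1639     0.0763     0.2516  increase
Variance partition (adjusted R2 fractions)
==========================================
  [env     ] 0.0015
  [pos     ] 0.2349
  [neg     ] 0.0000
  [env_pos ] 0.7095
  [env_neg ] -0.0000  (not shown)
  [pos_neg ] -0.0000  (not shown)
  [all     ] 0.0000
  [residual] 0.0540
BD_total 0.2010 | peak LCBD at 2013-01-22 00:00:00
```

Reading this: sessile abundance was flat for ~225 days, declined at
0.63 ind m⁻² day⁻¹ for ~161 days (continuing well past reoxygenation), then
recovered at only 0.16 ind m⁻² day⁻¹ — a hysteresis ratio of 3.8 against a
programmed 3.33. Most community variance (71%) is explained jointly by the
environmental predictors and positive temporal correlation, and the most
compositionally unusual sampling time falls in the programmed anoxic period.

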