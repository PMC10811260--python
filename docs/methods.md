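# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of the package. It states
no empirical result that the test suite or `scripts/acceptance.py` do not
themselves compute.

## Trial design

Each field is an incomplete block design: `blocks × columns × rows` plots
(default 3 × 5 × 53 = 795), every accession replicated `reps` times
(default 2) and a control cultivar over-replicated (default 7×) so the grid
fills exactly; construction fails loudly on any capacity mismatch. The two
fields share the design rules but are randomized independently from named
child streams of one seed.

The source trial only states that the two replicates are "distributed over
three blocks". We place the two replicates of an accession in **distinct
blocks** whenever capacity allows (greedy on the blocks with most remaining
slots, randomized ties), because that maximizes spatial separation and is
standard incomplete-block practice; a flag disables the rule. Border plots
are representable (`is_border`) but excluded from every analysis.

Maturity is classified from first-year flowering codes (FLD; day of year,
non-flowering = 222): *early* iff any plot flowered (`FLD < 222`), *late*
iff all plots carry the code, *unknown* without data. A value above 222 is
an error — the code is the documented ceiling of the encoding. The evidence
count (number of plots seen) is reported alongside the label.

## Trait extraction

- **CC** is a pixel fraction of the plot polygon; the vegetation mask is an
  input (an excess-green helper exists for RGB rasters but is not part of
  the validated core).
- **CH** is the 0.90 quantile of heights over vegetation pixels, using
  linear interpolation between order statistics. Quantile conventions
  differ across tools, so the convention is fixed and tested against a
  sort-based oracle.
- **CWSI** uses the canonical empirical form `(Tc − Twet)/(Tdry − Twet)`.
  Wet/dry references are per-scene inputs; when no measured reference
  panels exist, the 1st/99th percentiles of the scene temperature
  distribution stand in. Values outside [0, 1] are clamped with a warning
  counter. Raster/scene I/O uses TIFF (`tifffile`) and plain GeoJSON
  polygons rasterized with `skimage.draw.polygon`; georeferencing and
  orthomosaic generation are out of scope.
- **CWD** accumulates `ET0 − effective precipitation − irrigation` daily,
  signed positive-when-dry (drought severity convention). Effective
  precipitation is zero inside a shelter window. The accumulation origin is
  configurable (default: the weather table's first day) because reporting
  conventions differ.

Drought duration is counted as `end DOY − start DOY` (nights spent under
the shelters): the two default timelines give 50 days (DOY 134–184) and 69
days (DOY 134–203).

## Quality control

Three exclusion classes mirror field practice: plot-level faults
(`not_established`, `damaged`) drop the plot for **all** variables;
cell-level flags drop only the flagged cell; and a statistical fence
excludes unflagged values outside median ± 3·IQR within each
variable × field × DOY. The 3·IQR multiplier is deliberately conservative
(≈ ±4 σ under normality) so genuine genetic tails survive. The fence is
re-applied until no further value falls outside it, which makes the filter
idempotent by construction rather than only in the typical case.

Ground-vs-UAV validation pairs each rising-plate-meter date with the
nearest UAV flight at most 7 days away (ties toward the earlier flight) and
reports the per-plot Pearson r per pair; pairs with fewer than three common
plots are reported as undefined rather than silently dropped.

## Variance-component models

Per dated variable and per field we fit
`Y = μ + Accession (+ Block) (+ Column) (+ Row) + ε` with all terms
independent Gaussian random effects. Because columns are nested in blocks,
the full model is overparameterized; exactly six reduced structures are
candidates (Accession alone, plus Block, Column, Row, Block+Row,
Column+Row). The Column factor is coded as the (block, column) pair (15
levels per field); Row is the row index shared across blocks (a positional
effect). Both codings are configurable.

Estimation is REML on the profiled scale: with
`V = σ²_R (I + Σ γ_k Z_k Z_kᵀ)` and `γ_k = σ²_k/σ²_R`, the residual
variance has a closed form at every γ, and the profiled −2·restricted
log-likelihood is minimized by L-BFGS-B with an analytic gradient under
`γ_k ≥ 0` bounds. Numerical choices:

- responses are rescaled to unit variance for optimizer conditioning (the
  reported likelihood is transformed back exactly);
- deterministic start at γ = 1 (an equal split of the total variance), with
  two fallback starts (0.1, 10) only if the default fails — fits are
  reproducible;
- convergence tolerance 1e-8 on the objective; boundary estimates are
  reported as exact zeros with a boundary flag;
- AIC = −2·logLik + 2k with k = intercept + all variance components
  including the residual; a boundary component still counts (the simplest
  consistent convention). Ties break toward fewer components. Comparing
  AIC across candidates under the *restricted* likelihood is valid here
  because every candidate shares the identical fixed part (intercept only).

BLUPs are `μ̂ + û_i` with `û = γ Zᵀ H⁻¹ (y − Xβ̂)` (the conditional means),
and `H² = V_G/(V_G + V_R)`, undefined when both variances vanish. Fits are
cross-checked in the test suite against three independent oracles: the
balanced one-way ANOVA identity, a dense grid search of the likelihood
surface, and statsmodels' MixedLM (components, intercept and restricted
log-likelihood).

Models are fitted separately within each field: the drought index compares
field-specific accession values, and pooling fields would conflate the
treatment with spatial structure. FLD can be fitted like a continuous trait
but carries a censoring code (222) used as numeric; it is excluded from the
default pipeline fits.

## Drought-response index

`Yr_i = (C_i − D_i)/C_i` on per-accession BLUPs (a raw-means mode exists
for diagnostics). The source analysis does not state whether accession
values were BLUPs or plot means; BLUP-based is the default here because the
index is explicitly built on the mixed-model pipeline. A denominator guard
(|C| below 1% of the median absolute control value) returns a missing index
instead of an explosive one; above the guard no clamping is applied — large
negative indices are legitimate. The Z-test uses the sample standard
deviation (`z = mean/(sd/√n)`, two-sided normal p), appropriate for panels
of hundreds of accessions; its type-I error at n = 395 is verified by
simulation.

## Multivariate analysis and ranking

PCA standardizes variables by default (they mix %, cm and unitless scales),
drops and counts incomplete rows, and errors on constant columns. All
components are retained so explained fractions sum to one. The top-quartile
ranking uses the interpolated 75th percentile and **includes** values tied
with the threshold, consistent with the tie-inclusive top-set rule
(every accession whose hit count reaches the target-size-th largest count
is selected, so ties enlarge the set). Missing cells neither score nor
penalize.

## The synthetic generator

The generator produces the statistical structure the analysis assumes plus
the features that make the analysis non-trivial:

- observation = inverse-link(link(μ_v(t)) + g_i + u_block + u_column +
  u_row + treatment) + noise, with per-variable variance components;
- the drought treatment is a **proportional** reduction δ(t) (linear ramp
  to `delta_max` over the shelter window, linear fade over the recovery
  phase) with per-accession sensitivity `s_i ~ N(0, gxe_sd²)`. For
  identity-link traits (CH) the factor `(1 − δ)^(1+s_i)` multiplies the
  systematic part, so the expected relative index is exactly δ(t) when
  G×E is off — this is what makes Yr recovery checkable against an
  analytic target. For CC the shift `log(1 − δ)·(1+s_i)` acts on a logit
  scale mapped to [0, 100] (odds multiplied by `(1 − δ)^(1+s)`), and noise
  is added on the link scale so bounds always hold; near saturation the
  CC index is therefore attenuated relative to δ, which mirrors how closed
  canopies compress cover differences;
- CWSI *increases* under drought (`base + gain·δ(t)·(1+s_i)`), emitted as
  thermal scenes (canopy temperatures between fixed wet/dry references) so
  the pipeline exercises the scene-to-CWSI extraction;
- early-maturity accessions get a canopy-height boost inside flowering
  windows, creating the bimodal CH distributions seen in diverse clover
  panels; CH_rpm measures the same canopy as CH (shared genetic and
  spatial effects) with its own instrument noise;
- faults hit observation rows at a configurable rate (50% value-displacing
  outliers, 50% plot-fault flags);
- weather is a seasonal sinusoid (ET0, temperature, radiation) with
  Bernoulli-exponential rain, calibrated to a temperate maritime site
  (~850 mm/yr, midsummer ET0 ≈ 3.5 mm/day).

All randomness flows through named substreams (layout, effects, noise,
faults, weather) of one seed, so components can be varied independently.
Every realized effect lands in a `TruthRecord` for recovery tests.

What the generator does **not** emulate: crop-growth mechanism (no soil
water or light interception), plant mortality, spatially autocorrelated
noise beyond the block/column/row terms, lodging, or flight-to-flight
sensor drift. Passing recovery tests therefore demonstrates that the
estimators are correct under the assumed model, not that the model captures
every feature of real trials.

## Validation studies and problem sizes

The recovery studies (`cloverpheno.studies`) use a 200-accession panel on a
3 × 5 × 27 grid (405 plots/field), 20 simulation seeds per condition, one
identity-link trait with the variances under study, and no maturity boost
or faults — those features are deliberate confounders exercised by their
own tests and would change the truth a recovery study is asked to recover.
Calibration studies use the reference panel size (n = 395) with 10,000
replicates. These sizes keep the full validation under a minute while
leaving Monte-Carlo error well inside the assertion bands.

## Known limitations

- No spatial correlation structures (AR1), fixed covariates, multi-trait
  models, or standard errors for H².
- Flight-level exclusions (unreliable UAV campaigns) are config-driven, not
  inferred from the data.
- The two production years are independent pipeline runs sharing a design;
  no pooled-year model is offered, since a perennial crop's second year is
  not a replicate of its first.
- Yr on a bounded trait (CC) is attenuated near saturation by design; CH is
  the cleaner readout of proportional growth reduction.
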