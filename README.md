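# cloverpheno

Analysis toolkit for drought-response phenotyping of red clover
(*Trifolium pratense*) in paired field trials: an irrigated **control field**
next to a **drought field** covered by mobile rain-out shelters during early
summer. It is written for forage breeders and quantitative geneticists who
evaluate large accession panels with UAV-derived traits and need to turn
plot-level observations into accession-level drought-response rankings.

Because raw data from such trials are rarely public, the package ships a
first-class synthetic trial generator with known ground truth, so every
stage of the analysis — from raster trait extraction to the final
top-set overlap — is testable end to end.

## What it computes

**Trial design.** Two identical incomplete block layouts (per field: 3
blocks × 5 columns × 53 rows = 795 single-row plots), every accession
replicated twice over the three blocks and an over-replicated control
cultivar filling the grid exactly. Accession maturity (early/late ≈
double-cut/single-cut) is classified from first-year flowering: *early* iff
the accession flowered in at least one plot.

**Plot traits.**

- canopy cover `CC = 100 · (#vegetation pixels)/(#pixels)` (%),
- canopy height `CH` = Q90 of per-pixel height above soil over vegetation
  pixels (cm),
- crop water stress index `CWSI = (Tc − Twet)/(Tdry − Twet)` from thermal
  scenes (0 = fully transpiring, 1 = non-transpiring),
- cumulative water deficit `CWD(t) = Σ (ET0 − P_eff − irrigation)` (mm,
  positive = drier; rain is excluded under the shelters).

**Variance components.** Per dated variable (e.g. `CC_178`) and per field,
the intercept-plus-random-effects model

    Y = μ + Accession + Block + Column + Row + ε

is too rich for the nested design, so six reduced structures (`A`, `A+B`,
`A+C`, `A+R`, `A+B+R`, `A+C+R`) are fitted by REML and the AIC-lowest one
kept. From the best fit: `BLUP_i = μ̂ + û_i`, and broad-sense heritability
`H² = V_G/(V_G + V_R)`.

**Drought response.** Per accession and variable,
`Yr = (Control − Drought)/Control` from the two fields' BLUPs (positive =
trait reduced by drought); two-sided Z-tests ask whether the panel-mean Yr
differs from zero at each date.

**Multivariate structure & ranking.** PCA of the (standardized) BLUP or Yr
matrices with maturity/origin/type overlays, and the breeder's ranking:
count the variables for which an accession reaches the top 25%, take the
best ~50 per field (ties included), and measure the overlap between the
control and drought selections.

## Worked example

The numbered scripts under `analysis/` run a complete season on a synthetic
trial (80 accessions, 3 × 5 × 11 plots per field, drought ramping to a 40%
growth reduction by shelter removal at DOY 184):

```bash
python analysis/01_simulate_trial.py
python analysis/02_quality_control.py
python analysis/03_fit_models.py
python analysis/04_drought_response.py
python analysis/05_multivariate_ranking.py
python analysis/06_validation_studies.py
```

Stage 4 prints the seasonal drought-response trajectory:

```
variable  doy   mean_yr stars  in_drought_window
      CC  149  0.086070   ***               True
      CH  165  0.250773   ***               True
      CH  178  0.356962   ***               True
      CH  205  0.252814   ***              False
      CH  256  0.001235                    False
    CWSI  206 -0.472452   ***              False

peak mean growth reduction during drought: 0.36 (CH)
```

Mean Yr for canopy height climbs to 0.36 at the last flight under the
shelters (the imposed effect at that date is δ(178) ≈ 0.35), stays elevated
through the recovery flights and fades to ~0 by DOY 256; CWSI shows the
opposite sign because drought *raises* canopy temperature. Stage 5 then
reports the selection overlap:

```
variable  n_control  n_drought  n_both  fraction_of_control
      CC         26         26      18             0.692308
      CH         41         26      23             0.560976
```

i.e. 56–69% of the accessions a breeder would pick in the control field are
also top performers under drought — the two fields' genetic signals are
shared, so selection under good conditions partially transfers. Stage 6
validates the machinery against the generator's truth (H² recovered within
±0.01 at 0.2/0.5/0.8; REML identical to the balanced-ANOVA closed form to
2 × 10⁻⁷).

The same stages are available as CLI verbs
(`cloverpheno simulate|qc|cwd|fit|yr|pca|rank|run`), each a thin wrapper
over the library.

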