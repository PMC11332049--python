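# phenoshift

Flowering phenology from opportunistic, presence-only plant observations.

Citizen-science apps and species-reporting platforms produce millions of
plant records per year. Each record is only "species X was seen here on this
date", with no phenological stage attached — yet for conspicuous species most
records cluster around peak flowering, so the *distribution of observation
dates* carries phenological signal. This package turns such records into
grid-cell phenometrics and bioclimatic gradient estimates, for ecologists who
want to monitor inter-annual phenological shifts without dedicated observer
networks.

## What it computes

**Median observation date (MOD).** Observations are projected onto an
equal-area grid (50 × 50 km cells, Lambert azimuthal equal-area over Europe
by default). For every species × year × cell with at least 25 records, the
MOD is the 50th percentile of a two-parameter Weibull distribution fitted by
maximum likelihood to the observation days-of-year. Because the plug-in MLE
quantile is biased in small samples, a parametric bootstrap (default 250
draws) estimates the mean bias of the estimator under the fitted
distribution and subtracts it; the same bootstrap yields a percentile
confidence interval re-centred on the corrected estimate.

**Spatial interpolation with an area of applicability (AOA).** Cells below
the 25-record threshold are filled by RBF support-vector regression on
standardized elevation, latitude and longitude — but only inside the AOA:
cells whose predictor-space dissimilarity index (minimum standardized
distance to the training cells, scaled by the mean pairwise training
distance) stays below the training cells' leave-one-out whisker threshold
(Q75 + 1.5·IQR).

**Thermal time.** Growing degree days accumulate as
GDD(d) = Σ max(0, (Tmin+Tmax)/2 − 5 °C) from January 1. Evaluating each
cell's cumulative GDD at its MOD links a phenological shift between years to
the shift in temperature accumulation.

**Bioclimatic gradients.** Per species and year, ordinary least squares on
cell-level MODs:

    MOD = m_elev · elev + m_lat · lat + m_lon · lon + n + ε

with Holm-adjusted coefficient p-values, the elevation coefficient also
reported per 1000 m. Inter-annual shifts are tested per species with a
paired two-sided Wilcoxon signed-rank test on cells estimated in both years;
species are classified spring-/summer-flowering by their reference-year
median MOD against DOY 172; and the seasonal course of each gradient
coefficient is summarised by a quadratic fit against species median MOD.

A first-class synthetic-data generator (`phenoshift.synthetic`) produces
observation sets and daily temperature fields with known ground truth —
linear median-DOY surfaces, clustered observation effort, seasonal climate
with lapse and latitude gradients, and GDD-coupled flowering — so every
stage is validated by parameter recovery.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (ground truth: 20 d per 1000 m, 4 d per °latitude, 0.5 d per
°longitude, a 7-day delay in the second year, first year 2 °C warmer):

```bash
python analysis/01_simulate.py --seed 1      # 48,092 observations, 400 cells
python analysis/02_estimate_mod.py --seed 1  # 597 cell MODs, mean |err| 1.49 d
python analysis/03_interpolate_aoa.py --seed 1
python analysis/04_gdd_coupling.py --seed 1
python analysis/05_gradients_shifts.py --seed 1
```

Step 05 prints the recovered gradients:

```
           species  year  m_elev_per_km  m_lat  m_lon  intercept     r2  n_cells
Synthetica exempli  2020         20.129  3.988  0.499     -52.03 0.9905      297
Synthetica exempli  2021         19.946  4.020  0.505     -46.77 0.9897      300

paired shift test: median shift 6.93 d, p = 5.20e-38
```

i.e. the elevational gradient is recovered to 0.13 d/km, the latitudinal
gradient to 0.01 d/°, and the 7-day inter-annual shift to 0.07 d. Step 04
shows the thermal-time side: a median MOD shift of +6.9 d (earlier flowering
in the warm year) is matched by a GDD-at-MOD shift of −75.6 °C·d — the
complementary-sign pattern expected when flowering only partially tracks
temperature accumulation.

The same pipeline runs from a single config on real inputs
(observation CSVs with `species, longitude, latitude, date` columns, an
elevation point table, E-OBS-style NetCDF temperatures):

```bash
phenoshift run --config config.yaml
```

or stage by stage via `phenoshift simulate | grid | estimate | interpolate |
gdd | analyze`.

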