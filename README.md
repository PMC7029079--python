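# plasticlim

Optimality analysis of transgenerational plasticity under autocorrelated
annual climate.

Given long-format monthly climate tables (site, year, month,
precipitation, daily-maximum temperature), the pipeline

1. aggregates precipitation over the hydrologic year (Oct–Sep, labelled
   by the ending year) and temperature over the early (Mar–May) and
   late (Jul–Sep) growing seasons;
2. summarizes each site's interannual structure: mean, interannual SD,
   linear trend, autocorrelations and partial autocorrelations at lags
   1–12, and seasonal cross-correlations;
3. grid-searches plasticity "genotypes" for the strategy maximizing
   geometric-mean fitness at each site, in raw and linearly detrended
   (residual) variants:
   - **precipitation model** — parental-effect slope `m ∈ [-1, 1]` and
     multigeneration persistence `g ∈ [0, 1]`, weighting the previous
     three years' deviations as `(1, g, g²)/(1+g+g²)`; full (m, g)
     fitness landscapes with local-maxima/bimodality detection;
   - **temperature model** — four transgenerational slopes
     (`m_ee, m_el, m_le, m_ll`: parent season → offspring season) plus a
     within-generation slope `w` (current early-season cue → late-season
     phenotype); 5⁵ = 3,125 genotypes on the default value set
     `{-0.2, 0, 0.1, 0.3, 0.5}`.

A seeded synthetic climate generator (stationary AR(p) parameterized by
partial autocorrelations; VAR(1) seasonal pairs with correlated
innovations; exact monthly disaggregation) replaces any external climate
download, so everything here runs offline.

## CLI

```bash
# synthetic monthly climate for 5 sites, AR(1) precipitation
plasticlim simulate --kind precip --sites 5 --n-years 120 --pacf 0.3 \
    --seed 1 --out clim.csv

# per-site descriptive statistics
plasticlim summarize --input clim.csv --out summary.csv

# per-site optima (raw and residual variants)
plasticlim optimize-precip --input clim.csv --variant both --out optima.csv
plasticlim optimize-temp   --input temps.csv --variant both --out optima_t.csv

# full batch report: results, optimum histograms, ACF regression (temp)
plasticlim report --input clim.csv --model precip --out-dir report/
```

Every subcommand accepts `--config cfg.yaml` whose keys override the
flags. Input CSV dialect: header
`site_id,lat,lon,year,month,ppt_mm,tmax_c`, "." decimal, empty cell =
missing. Years with any missing month in an aggregation window are
dropped, never imputed.

## Layout

- `src/plasticlim/climate_io.py` — CSV reading/validation, hydrologic and
  seasonal aggregation
- `src/plasticlim/synthetic.py` — seeded AR(p)/VAR(1) generators, monthly
  disaggregation
- `src/plasticlim/tstats.py` — detrending, ACF/PACF (Durbin–Levinson),
  cross-correlations, per-site summaries
- `src/plasticlim/precip.py` — precipitation optimality model and fitness
  landscapes
- `src/plasticlim/temp.py` — temperature optimality model
- `src/plasticlim/report.py` — batch pipeline, histograms, ACF
  regression, strategy classification
- `src/plasticlim/cli.py` — `plasticlim` console entry point
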