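# Methods

`geohealth` builds regional living-environment embeddings from multimodal
geospatial data and relates them to population health outcomes estimated
from medical claims. This note documents the models and procedures, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## Pipeline model

The pipeline treats a study area as a set of polygonal regions (two-tier
hierarchy, rook adjacency) and produces, per region and calendar year, a
feature vector with three named blocks:

* **DEnv** — dynamic environment. Each gridded environmental variable is
  reduced to a regional monthly series (mean over pixels whose centers fall
  in the polygon; missing pixels excluded), then to four meteorological
  season means — winter {Jan, Feb, Dec}, spring {Mar–May}, summer {Jun–Aug},
  fall {Sep–Nov} — concatenated across variables. Width = 4 × (number of
  dynamic variables).
* **LC** — land cover. Per-pixel cover fractions are zonally averaged and
  then averaged over all timestamps into one static fraction per land type
  per region. Fractions sum to 1 per pixel by construction and the zonal
  and temporal means preserve that sum exactly (linearity), which the test
  suite asserts to 1e-9.
* **Img** — visual features. RGB tiles on a 500 m point grid are expanded
  to 12 channels (R, G, B plus nine derived indices: ExG, ExR, ExGR, NGRDI,
  GLI, VARI, MGRVI, RGBVI, IKAW, all epsilon-guarded with eps = 1e-8), each
  channel summarized by mean, population sd, median, max, min and a 20-bin
  histogram over the channel's fixed range — 300 features per tile. A
  region's Img row is the elementwise mean over its grid points' vectors.

Fusion is column-wise concatenation of the requested blocks ("All" = DEnv +
LC + Img); any feature scaling is fit on a declared training index only.

Disease prevalence is estimated per (region, year, ICD-10 group) at three
hierarchy levels — chapter, block, 3-character category; claims codes are
truncated to their category (first three characters, uppercased) and rolled
up. Prevalence = distinct patients carrying the group / distinct patients
with ≥1 visit recorded in that region-year. The per-region-year denominator
was chosen over a national-per-year denominator (the natural alternative);
with it, prevalence(parent) ≥ prevalence(child) and ≤ Σ children hold
exactly per region-year, which the suite asserts.

### Analyses

* **Urban–rural disparity.** For an ICD group, a 2×2 table of distinct
  patients (case = carries the group in the pooled years; exposed = resides
  in a designated urban region). OR = (a·d)/(b·c) with the Woolf 95% CI
  `exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`; any zero cell triggers the
  Haldane–Anscombe 0.5 correction on all four cells and is flagged. Woolf +
  Haldane were chosen as the standard textbook pair; both are isolated
  behind `odds_ratio` so an exact method could be swapped in.
* **Feature–prevalence correlation.** Spearman rank correlation between
  every feature column and every prevalence target across region-years,
  Benjamini–Hochberg adjusted across all pairs (0.05 for "significant" in
  the heatmap rendering). p-values use the exact permutation distribution
  of the rank correlation for tie-free samples with n ≤ 8 and the
  t-approximation with n−2 df otherwise — the convention R's `cor.test`
  uses. The t-approximation alone misses the exact p by up to ~0.05 at
  n = 5, which would break the package's stated oracle guarantee.
* **Regression harness.** Random-forest regressors (default 500 trees,
  unlimited depth, seeded) predict z-scored targets (statistics fit on
  training rows only; metrics are therefore on the standardized scale, and
  R² = 1 − SS_res/SS_tot about the test-set mean). Generalization regimes:
  spatial interpolation (random whole-region holdout), spatial
  extrapolation (contiguous block beyond a centroid-x percentile cut) and
  temporal forecasting (train years < cutoff). "+S" appends the mean of
  rook-neighbor rows; "+T" appends the same region's prior-year row;
  appended columns are namespaced, first-year rows with no lag are dropped
  from training with a logged count. Enhancement-as-feature-augmentation is
  the simplest reading of boosting a model with neighborhood/history
  information; it is isolated behind `augment_spatiotemporal` so a stacked
  residual model could replace it.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, not
any real data source:

* **Environment**: value(pixel, t) = static spatial Gaussian random field
  (smoothed white noise, normalized to `field_sd`, correlation length in
  km) + an annual anomaly field (a fresh spatially correlated field per
  calendar year, sd `anomaly_sd`) + `A·sin(2π·month/12 + phase)` + white
  noise. The anomaly term gives the environment realistic interannual,
  regionally varying variability; without it every year's embedding would
  be identical up to noise and temporal forecasting would be degenerate.
* **Tiles**: latent smooth greenness field on the 500 m point grid; each
  tile is Gaussian texture around per-channel base levels, with the green
  base `0.25 + 0.5·sigmoid(w·g)` — strictly monotone in greenness for
  w > 0, independent at w = 0.
* **Claims**: patients have a fixed residence region, 1–5 visits per year
  (uniform), visit dates uniform within the year. Per leaf code c and year,
  P(carry) = logistic(α_c + β_cᵀ z(region, year)) with z the per-variable
  z-scored annual regional environment means; carried codes attach to one
  uniformly chosen visit of that patient-year. A toy 3-level hierarchy
  (2 chapters × 2 blocks × 2 categories, ICD-10-shaped) ships with the
  claims. The α, β are ground truth for calibration and recovery studies.

Default study conditions (`SimConfig`): a 4×4 lattice of 4 km regions
(pixel size 1 km, the coarsest allowed = 16 pixels/region), years
2016–2022, 20 000 patients, three dynamic variables (temperature, humidity,
NDVI; amplitudes 1.0/0.6/0.8, correlation length 10 km, field sd 1, anomaly
sd 0.5, noise sd 0.5), three land types, 64×64 tiles at 500 m spacing.
These sizes keep a full end-to-end replicate at a few seconds on one CPU so
the calibration studies can run 100 seeded replicates; they are scaled-down
but structurally faithful study conditions, chosen once.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: geodesic geometry and reprojection error (the
synthetic world is planar km; real adapters must supply an equal-area
projection), raster misalignment and missing swaths, image content beyond
first-order color statistics, patient mobility (residence is static),
code co-occurrence structure, visit-frequency heterogeneity, and
reporting/claims biases.

## Validation studies

`geohealth.studies` (driven by `scripts/acceptance.py` and the acceptance
test suite) recomputes:

* oracle equivalence: zonal means vs a brute-force point-in-polygon loop on
  50 random convex polygons; channel statistics vs per-channel numpy
  recomputation; Spearman p vs the exhaustive 120-permutation distribution
  at n = 5; Woolf OR/CI vs statsmodels' independent 2×2 implementation on
  1 000 random tables;
* conservation/monotonicity: histogram masses, land-cover sums, prevalence
  hierarchy dominance;
* CI calibration: with β = 0 links the urban–rural CI contains 1 at the
  nominal rate over 100 seeds (3 simulated years, 20 000 patients); with a
  planted β = 1 on an urban-elevated indicator the CI excludes 1;
* parameter recovery: with a strong single-variable link (β = 1.5,
  20 000 patients) the All-subset forest (200 trees in the repeated study)
  attains high spatial-interpolation R², summarized by the 100-seed median;
* history enhancement: on delayed-dominant lag targets
  y_t = 0.5·s_t + 1.0·s_{t−1} + ε (s = standardized DEnv row mean,
  ε ~ N(0, 0.2²); a distributed-lag exposure response), "+T" improves
  forecasting R² in the large majority of 100 seeded runs (6×6 lattice,
  last two years held out — a single held-out year of 16 regions makes the
  R² comparison mostly noise);
* determinism: two pipeline runs under one config produce byte-identical
  manifests.

## Numerical and design notes

* Pixel membership is by center containment, not area weighting — a
  documented dialect switch point; points on shared edges go to the
  lexicographically smaller region id.
* Calendar months in UTC; no partial-month proration. December belongs to
  its own calendar year's winter (no cross-year winter), keeping each annual
  embedding a function of exactly one year's data.
* Histogram bin edges are fixed per channel from analytic ranges (RGB
  [0,1]; most indices [−1,1]; ExG [−2,2]; ExR [−1,1.4]; ExGR [−3.4,3]).
  VARI's guarded ratio is analytically unbounded, so its histogram range is
  pinned to [−1,1] with overflow clipped into the edge bins; upper-edge
  values fall in the last bin. Per-image ranges would make features
  incomparable across tiles.
* Tile statistics use the population sd (pixels are the tile's full
  population). The batched float32 path agrees with the float64 single-tile
  path to ~1e-5; oracle tests run the float64 path.
* Missing data propagate (never silently zero): empty zonal regions, empty
  seasons and regions without grid points are NaN and logged; modeling
  drops incomplete rows with a logged count. No imputation by default.
* Manifests contain the config hash, seed, stage list and SHA-256 digests
  of every output — nothing wall-clock — so reruns are byte-identical.

## Limitations

Feature engineering only (no learned visual embeddings or fusion); no
geodesic support in the generator; no kriging or raster resampling beyond
ingest alignment; the odds-ratio analysis treats patients as independent
(no within-region clustering adjustment); the exact Spearman p is limited
to tie-free n ≤ 8.
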