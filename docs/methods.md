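# Methods

This note records the models, conventions and design choices behind
`standcompare`, in the order the pipeline runs.

## Plot geometry and census protocol

Three plot "dialects" are supported.

| dialect | tree stratum | sapling stratum | size measure |
|---|---|---|---|
| `ifri_standard` | 10 m circle (π·10² ≈ 314.16 m²), stems ≥ 10 cm DBH | 3 m circle (≈ 28.27 m²), saplings 2.5–10 cm + shrubs/lianas ≥ 2.5 cm | diameter |
| `india_5m` | 5 m circle (≈ 78.54 m²) | same 5 m circle | circumference |
| `gentry_reference` | single 0.1-ha layout: ten 100 m² transects, every stem ≥ 2.5 cm | (same) | diameter |

Stratum areas are always computed from the radii at full double precision;
rounded figures such as 314 or 28.3 m² are presentation values, not
protocol. Circumference records are converted on read (DBH = C/π).
Useful identities that follow: three standard tree plots cover
0.0942 ha, almost exactly one reference transect (0.1 ha); twelve 5-m plots
cover exactly the same tree-stratum area as three standard plots
(12·π·5² = 3·π·10²).

Stems recorded outside their lifeform's stratum (a "tree" of 6 cm, a
"sapling" of 14 cm) are field errors: they are flagged and excluded from
structure metrics rather than silently reassigned, because the recorded
lifeform and the plot radius it implies cannot both be trusted. A sanity
filter excludes stems above a configurable DBH ceiling (default 10 m — a
diameter that in practice means a circumference, height or unit error).
The filter's scope is configurable (`structure_only` vs `all`); the default
removes flagged stems from *all* metrics, which keeps one invariant set of
stems per visit and cannot materially change a species count.

Species labels are normalized mechanically only: trim, collapse internal
whitespace, casefold. No fuzzy matching, so distinct spellings remain
distinct species; datasets needing orthographic review must be cleaned
upstream.

## Basal area

Per stem, A = π·DBH²/4; per stratum, stem areas are summed and divided by
(number of plots × nominal stratum area); the per-hectare tree and sapling
components are added. Shrubs and lianas never enter BA (their measurement
is too inconsistent across field teams) but always enter biodiversity
pools. Partial or edge plots are not supported — the per-hectare scaling
assumes every plot was censused in full.

## Rarefied richness

Individual-based rarefaction with replacement: `n_draw` = 100 stems,
`reps` = 1000 repetitions, median reported. Choices worth noting:

* The median of an even number of repetitions is the mean of the two
  central order statistics, so half-integer values occur.
* Pools smaller than 100 stems remain computable (the draw is with
  replacement); such forests are genuinely species-poor and their SR is
  still meaningful.
* Randomness protocol: every estimate takes one root seed; repetition *r*
  draws from an independent child stream (`SeedSequence.spawn`), making
  results independent of iteration order and safe to parallelize.
* For S equally abundant species the expected unique count has the closed
  form S·(1 − (1 − 1/S)^n); the test suite and the acceptance script hold
  the sampler to it within Monte-Carlo error.

### Effort harmonization against reference transects

A typical focal forest samples ~1 ha of tree stratum; a reference transect
samples 0.1 ha, and it censuses *all* small stems while focal plots census
them only in the small inner circle. Two corrections make SR comparable:

* focal side — each repetition first draws 3 plots without replacement
  (≈ 0.094 ha) and rarefies within them; the 5-m dialect draws 12 plots for
  trees/palms (exactly the 3-plot tree area) and 1 independently chosen
  plot for the other lifeforms (≈ 78.5 vs ≈ 84.8 m²). Plot subsets are
  re-drawn independently every repetition.
* reference side — all stems ≥ 10 cm enter every repetition, but stems
  < 10 cm are taken from one uniformly chosen 100 m² subplot (the other
  nine subplots' small stems are ignored that repetition), matching the
  ≈ 85 m² of small-stem area in three focal plots.

## Annualized change

The relative-change-per-year convention ((v₂ − v₁)/v₁)/(y₂ − y₁) is the
default; a compound rate (v₂/v₁)^(1/(y₂−y₁)) − 1 is available via
configuration. Both are zero exactly when the metric is unchanged and carry
the sign of the change; over short revisit intervals they differ little.
Change is undefined when the baseline value is zero; such forests are
reported as missing.

## Regional intercomparison

For sites a, b: TD(a,b) = √(haversine_km(a,b)² + |Δelevation_m|²), with
Earth radius 6371 km. The mixed units are deliberate: 1 m of altitude is
treated as equivalent to 1 km of horizontal distance, reflecting the
roughly equal temperature changes of a 1 km climb and an ~800–1000 km
poleward journey at mid latitudes. Neighborhoods are all candidates with
0 < TD ≤ 1000 (inclusive cutoff). Weights are TD⁻², normalized to sum
to 1.

The weighted SD uses the normalized-weight population form
σ = √(Σ wᵢ(vᵢ − μ)²). This is the right convention for a descriptive
z-score (it is not an inferential standard error) and gives clean
equivariance: adding a constant to all values, or scaling all values by
k > 0, leaves z unchanged. Further conventions:

* The focal forest is never its own neighbor; a candidate at TD = 0
  (co-located) would have infinite weight and is excluded with a warning.
* `min_neighbors` = 2 (an SD needs at least two points); forests with
  smaller neighborhoods get a missing z with a reason, never a silent drop.
  Be aware that an SD from 2–3 neighbors is noisy; z-scores from minimal
  neighborhoods can be extreme and are best interpreted with the
  `n_neighbors` column in view.
* An SD at rounding-noise level (≤ 10⁻¹² relative) is treated as zero; the
  z is then 0 if the focal value equals the weighted mean and missing
  otherwise.
* When a forest has several visits, only the designated current visit
  (latest by default) enters the candidate pool, so a forest is not
  compared against itself across time.

Reference mode runs the identical code path with old-growth transect plots
as the candidate pool (and no self-exclusion, since focal and reference
ids never coincide).

## Evaluation statistics

**Major axis (model II) regression.** Both variables are measured with
error and neither is naturally the response, so the fitted line is the
major axis of the bivariate covariance ellipse: the direction of the
leading eigenvector of the 2×2 sample covariance matrix, through the
centroid. Closed form: slope = (s_yy − s_xx + √((s_yy − s_xx)² + 4s_xy²)) /
(2s_xy), carrying the sign of the covariance; when s_xy = 0 the axis is
coordinate-aligned (slope 0, or a vertical axis reported as +∞ with
undefined intercept). Swapping x and y inverts the slope and leaves the
fit unchanged. Significance is a two-tailed permutation test on the Pearson
correlation (999 shuffles of y by default, observed statistic counted in
the numerator), which is assumption-light and self-contained; r² is the
squared Pearson correlation.

**ANOVA / Tukey HSD.** Ordinal ratings versus continuous metrics use
one-way fixed-effects ANOVA (scipy) followed by Tukey's honestly
significant difference test (statsmodels; Tukey–Kramer for unbalanced
groups). Groups with fewer than two observations are excluded with a
warning. Pairwise outcomes are summarized as a compact letter display
(insert-and-absorb algorithm): groups sharing a letter are not
significantly different at α. For two ordinal variables the analysis is
run both ways (each variable once as the response).

**Rating codes.** User questions (change in density / in forested area)
code decrease/no change/increase as −1/0/1; forester questions (density /
species diversity relative to the region) code very low…very high as
−2…2.

## Synthetic data generator

The generator emulates the structure of multi-country community-forest
monitoring data so every stage can be tested and calibrated offline:

* **Landscape**: `n_clusters` widely separated regions (≥ ~4000 km apart,
  so cutoff-1000 neighborhoods never span clusters), with within-cluster
  scatter of ~50 km and ~120 m of elevation; a gentle regional field moves
  log stem-density and log species-pool size with latitude and elevation;
  each forest adds an independent latent deviation ("condition",
  SD 0.4 on the log scale) — the signal recovery tests re-identify.
  The condition acts on the species pool with a ×1.5 multiplier so
  rarefied richness spans a wide range across forests, as real
  multi-biome inventories do.
* **Communities**: log-series species abundances (shape 0.98, pool 60 at
  baseline), truncated-exponential DBH per stratum (scale 12 cm above the
  10 cm tree minimum; 2.5 cm scale inside the 2.5–10 cm band), ~35 stems
  per plot across a tree/palm/sapling/shrub/liana mix of
  0.50/0.05/0.30/0.08/0.07.
* **Reference transects**: ten 100 m² subplots; an old-growth "uplift"
  (default 0.5 on the log scale) raises density, tree fraction and tree
  size. Eight transects per cluster are generated: reference networks are
  dense in the regions they cover, and a reference neighborhood of only
  2–3 plots yields a degenerate weighted SD and meaningless z-scores.
* **Ratings**: each forest's rater forms latent appraisals
  condition + halo·g + noise·ε per variable, where g is a shared
  per-forest sentiment; thresholds at ±0.43 (and ±1.28 for the 5-level
  forester codes) discretize. `halo` controls how strongly ratings of
  unrelated attributes correlate.
* **Revisits**: a fraction of forests (default 0.25) get a baseline visit
  whose condition differs by a drift ~ N(0.15, 0.25), giving annualized
  change a known sign.

What the generator does **not** emulate: climate covariates, soils, spatial
autocorrelation of species composition, succession, observer error in
species identification. Passing tests therefore demonstrate the estimators'
internal correctness and their behaviour under known effect structure —
not calibration against any real inventory.

## Problem sizes and numerical choices

The simulation studies use 100-forest landscapes (the scale at which
inverse-square-weighted neighborhoods have ~20 usable neighbors per
forest), 1000 rarefaction repetitions per estimate, and 10⁵ repetitions
for the equal-abundance calibration. The 3- vs 4-plot robustness check
standardizes both richness variants against the same reference transects
and compares them after rescaling each to mean 0, SD 1; on synthetic
landscapes the major-axis fit of the rescaled values has slope 1,
intercept 0 and R² ≈ 0.96–0.98.

Known limitations: no partial-plot support; no taxonomic synonym
resolution; z-scores from minimal neighborhoods are noisy (see above);
permutation p-values have a resolution floor of 1/(permutations + 1).
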