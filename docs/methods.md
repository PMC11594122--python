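# Methods

This note records the scientific and numerical choices behind
`tractscape`: what the models assume, what the synthetic generator does
and does not emulate, and where the design was genuinely open.

## Pipeline model

The pipeline treats an area-level health outcome (a prevalence rate in
percent, e.g. share of adults with BMI ≥ 30) as a function of the
visual appearance of the area in medium-resolution (10 m) overhead
imagery. Its stages and their assumptions:

1. **Reconciliation.** Tract identifiers carry two trailing
   subdivision digits in both dialects (decimal names `XXXX.YY`,
   all-digit GEOIDs). Dissolving to the base id assumes subdivisions
   are spatially nested in their base tract and that a
   population-weighted mean is the right way to merge member rates —
   exact when the published rates are themselves population ratios.
   Merging errors out when some (but not all) members lack rates:
   silently dropping members would bias the weighted mean. A layer
   with no rates at all (a bare boundary file) dissolves with missing
   outcomes.
2. **Chipping.** Fixed-size square windows, 0-based half-open pixel
   coordinates, affine georeferencing per chip. Ragged edges are
   clamped (the last row/column window is shifted inward to end at the
   image edge) rather than zero-padded: every window is full-size, no
   artificial black borders enter the feature extractor, and a
   10,980-px tile yields exactly ⌈10980/224⌉² = 2500 windows. Clamped
   edge windows overlap their neighbors by the remainder (4 px on a
   10,980/224 grid); interior windows are disjoint.
3. **Normalization.** Raw integer reflectance is divided by a fixed
   divisor (default 10,000, the L2A surface-reflectance convention)
   and clipped to [0, 1]. A per-image min-max mode exists behind a
   flag but is not the default because it destroys cross-image
   comparability. ImageNet standardization
   (means 0.485/0.456/0.406, sds 0.229/0.224/0.225) is applied
   directly to the [0, 1] values; those constants were derived on
   display-range photographs, so reflectance imagery is merely mapped
   into a comparable numeric range, not into the network's native
   distribution.
4. **Pixel membership.** A pixel belongs to the tract that covers its
   center (the common rasterization convention). Centers on a shared
   boundary go to the lexicographically smallest tract id — a
   deterministic tie-break that also makes counts sum exactly to
   chip_size² when tracts partition the footprint. Tracts must already
   be in the raster's coordinate system; a mismatch raises.
5. **Usable chips.** A chip enters the analysis iff its footprint is
   geometrically covered by the state boundary and it intersects at
   least one tract.
6. **Aggregation.** Pixel-count-weighted means in both directions
   (tract features, chip outcomes). Both are convex combinations, so
   every aggregate lies within the componentwise range of its inputs —
   a property the tests exploit.
7. **Regression.** "GLM" means Gaussian-identity least squares. With
   D = 2048 features and n in the hundreds the problem is
   underdetermined; the default is the minimum-norm pseudoinverse
   solution, with ridge shrinkage available. The forest is a seeded
   bootstrap ensemble with `max_features="sqrt"`: with D ≫ n,
   full-scan splits dominate run time without improving accuracy
   (verified on fixed design matrices, where `sqrt`, 0.2 and 1.0 gave
   statistically indistinguishable out-of-fold R²).

## Synthetic generator

The generator produces data with the *structure* of a statewide
tract-level analysis and a *known* explainable variance share:

- **Region.** Voronoi cells of seeded uniform points, clipped to a
  rectangular extent: a guaranteed partition with widely varying cell
  areas (roughly 20-fold spread at n = 250), echoing the heavy spread
  of real tract areas. Identifiers follow the decimal name dialect;
  populations are uniform in a configurable range.
- **Latent fields.** K seeded white-noise rasters blurred with a
  Gaussian kernel (sigma = field_length_scale / pixel_size), then
  standardized to mean 0, variance 1. Blurred noise was chosen over an
  explicit covariance kernel because it is cheap at raster scale and
  gives direct smoothness control; it approximates a Gaussian random
  field with a squared-exponential-like kernel.
- **Raster.** Each of 3 bands is a fixed affine mixture of the K
  fields plus seeded pixel noise (default sd 0.1 in field units),
  min-max rescaled per band into [0, 10000] and quantized to unsigned
  16-bit. A 3-band sensor observes only 3 of the K latent
  combinations, so the default mixing puts the outcome-relevant
  combination (the β direction) in band 1 and two seeded orthogonal
  unit mixtures in the other bands. This is deliberate: the premise of
  the whole modelling exercise is that the imagery reflects the
  environmental characteristics that drive the outcome, and a random
  mixing would leave roughly half of a 6-dimensional β invisible to
  any extractor, making recovery impossible *by construction* rather
  than by statistical difficulty.
- **Outcomes.** outcome_t = base + Σ_k β_k · mean_k(t) + ε_t, with
  mean_k(t) the pixel-center mean of field k over tract t (the same
  membership rule the pipeline uses) and ε ~ N(0, noise_sd²), clipped
  to [0, 100]. When a target R² is configured instead of a noise sd,
  the noise sd is calibrated from the realized signal variance so that
  signal/(signal + noise_sd²) equals the target for every realization.
  The truth object records realized variances and the resulting R².

### Study conditions

The default configuration — the conditions under which the recovery
claims are made — is: 250 tracts over a 12.32 km square at 10 m
pixels, K = 6 latent fields with length scale 2000 m,
β = (3, −2, 1.5, −1, 1, 0.5) in percentage points per standardized
field unit, base rate 39.2%, noise calibrated to true R² = 0.6, chips
of 28 px (280 m) giving a 44×44 grid of 1936 chips (~8 chips per
tract). The chip size mirrors the tract-to-chip *ratio* of a statewide
analysis (median ~14 chips per tract) at a raster size that keeps a
ten-seed study in minutes on one CPU; the real-data default of 224 px
chips is unchanged in the chipping module.

### What the generator does not emulate

Real radiometry (cloud, atmosphere, sensor response), UTM zone
overlaps and reprojection, real tract shapes (urban slivers, water
boundaries), spatially structured noise in the outcome estimates
(small-area estimates have population-dependent uncertainty), and any
nonlinear imagery–outcome link. Passing the recovery tests therefore
shows the *pipeline arithmetic and plumbing* preserve an area-level
linear signal; it does not validate the scientific claim that visual
features predict real outcome rates.

## Evaluation choices

- **Pooled out-of-fold R².** Each sample has exactly one out-of-fold
  prediction; the pooled R² over those predictions is the package's
  headline recovery statistic. Per-fold R² values (and their mean) are
  reported too, but with n/k ≈ 25 test samples per fold they are
  noticeably noisier and downward-biased relative to the pooled value.
- **Adjusted R² and effective p.** The predictor count defaults to the
  rank of the training design matrix, capped so the adjustment
  denominator stays positive. With D ≫ n this rank is large relative
  to small test folds and per-fold adjusted R² becomes strongly
  negative — arithmetically correct and a faithful signal that the
  adjustment is near-degenerate there; callers with a substantive
  effective dimension can pass their own `p_eff`. When
  n ≤ p_eff + 1 the adjustment is undefined and reported as NaN with a
  log note, never silently clamped.
- **Signed error.** signed_error = actual − predicted, so positive
  means the model under-predicted the rate. Threshold subsets keep
  tracts with |signed_error| ≥ θ; for a single out-of-fold prediction
  per tract, the per-tract "RMSE" reduces to this absolute error.
- **Determinism.** Every stochastic component (point sampling, field
  noise, outcome noise, splits, forests, the surrogate's projection)
  is seeded through independent named streams derived from the config
  seed; identical configs give bit-identical outputs, which the tests
  assert.

## Numerical details

- Areas and pixel counts are exact in the planar CRS; there is no
  geodesy anywhere.
- Boundary simplification is Douglas–Peucker, tolerance-parameterized;
  a bisection helper finds the gentlest tolerance meeting a maximum
  vertex count (e.g. a 54-vertex query footprint), since the algorithm
  itself has no vertex-count knob.
- Skewness of a constant band is defined as 0 (guarding a 0/0); a
  feature constant up to roundoff gets Pearson correlation 0 with a
  log note.
- Single-sample CV folds (leave-one-out) have undefined per-fold R²;
  the fold records NaN while the pooled predictions remain valid.
- The surrogate extractor computes 23 base descriptors per band (7
  moments/extremes/gradient statistics + 16 block means on a 4×4
  grid) and lifts them to D dimensions with a seeded Gaussian
  projection scaled by 1/√69 — injective on the base space with
  probability 1, so distinct base descriptors stay distinct.

## Known limitations

- The surrogate descriptor is intentionally simple; it preserves
  smooth radiometric structure well but is blind to texture beyond
  first gradients, so it is a stand-in for — not an approximation of —
  deep-network activations.
- Chips overlapping multiple rasters are not deduplicated during
  aggregation; upstream product selection is responsible (documented
  contract).
- The population-weighted merge requires complete member rates; there
  is no imputation path.
- Recovery at true R² = 0.6 lands near 0.52–0.53 pooled out-of-fold
  R² for the forest at n = 250: the shortfall is estimation error of
  the regressor, not pipeline leakage, as the noiseless variant
  reaches ≥ 0.99 for both model families.
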