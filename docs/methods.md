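# Methods

## Scope and data model

The package analyses repeated, spatially explicit surveys of rectangular
forest plots: per tree a species code, x/y position (m, origin at the
lower-left corner), stem diameter at breast height d (cm) per survey, an
optional measured height (m), and a live/removed status.  Plots are
even-aged; ingrowth and mortality other than thinning are out of scope.
Tree lists travel as a strict TSV dialect (tab-separated, decimal
points, empty fields for missing numerics, `# key: value` header lines
carrying plot geometry and the simulation seed).

## Sample circles and edge correction

Around every tree a circle of radius `sr = 0.25 h` is constructed, h
being the measured height where available and otherwise the allometric
height prediction at the period-start age.  Circle membership is
evaluated under a periodic (toroidal) boundary via the minimum-image
convention, which is exact while `sr` is below half the shorter plot
side; the code rejects larger radii.  Membership is half-open
(distance < sr inside, = sr outside), making the decision deterministic.
All circle metrics are translation-invariant on the torus, and the
neighbor search is tested against a brute-force sweep over all nine
shifted plot copies.

Densities are computed on the *remaining stand*: diameters at the period
start, membership restricted to trees that survive to the period end.
Variants including removed trees are available behind a flag but are not
used in the default model tables.

## Local density, mixing and growth metrics

- `SDIci` / `SDIc`: Reineke stand density index on the circle without /
  with the centre tree, `SDI = N (dq/25)^(−α)` with `N = 10000/a · n`.
  α is stored as the (negative) self-thinning slope, so α = −1.605
  reproduces the classical `N (dq/25)^{1.605}` and SDI = N at
  dq = 25 cm.  In mixed circles the exponent is the basal-area-weighted
  mean of the species' α values — one defensible aggregate among
  several; the weighting is a package decision.
- Mixing proportions weight species-wise local SDI by density-
  equivalence factors before normalizing, giving area-true shares for
  species with different growing-space demands.  A circle is mixed
  (m = 1) when the admixture (1 − dominant share) reaches the threshold,
  default 10 % (the comparison carries a 1e-12 tolerance so the ≥
  boundary is stable under float rounding).
- `IMc` sums the allometric dry-mass increment of circle trees with
  d ≥ 7 cm at the period start, scaled to Mg ha⁻¹ yr⁻¹; the 7 cm
  merchantability limit is applied to diameter, one reading of a limit
  that could also be applied to mass.  `LAIc` uses all circle trees.
- `id = 10 (d_end − d_start)/period` in mm yr⁻¹.  Non-positive
  increments are retained in the feature table and dropped, with
  reported counts, when a model's log transform requires positivity.

## Allometry

Height follows `ln h = a₀ + a₁ ln d + a₂ ln age + a₃ ln d · ln age`
(OLS; single-age designs drop the age terms with a flagged downgrade).
Mass and leaf area are power laws `ln y = a₀ + a₁ ln d`.  Back-transforms
multiply by `CF = exp(s²/2)`, the standard lognormal retransformation
correction, with s² the log-scale residual variance; whether the original
analyses used this or a ratio-of-means correction is not documented, so
the choice is recorded here as the package's own.  Carbon is 0.5 × dry
mass.  Merchantable volume is `(π/4)(d/100)² h f` with a configurable
form factor and zero below 7 cm — deliberately simpler than the full
stem-form coefficient systems used in yield research.  Unknown species
fall back to generalized conifer/broadleaf parameter sets, never
silently to another concrete species.

The shipped default species parameters are **synthetic** placeholders
(plausible Central European magnitudes: heights ≈ 20 m at d = 20 cm,
≈ 300 kg dry mass at d = 25 cm, α = −1.664/−1.789, equivalence factor
1.9 for the broadleaf); real analyses must supply measured values.

## Mixed models

Each model regresses a log metric on log covariates plus the dummy m,
with a random intercept per tree (REML via statsmodels MixedLM) to
absorb the serial correlation of repeated observations of a tree; no
plot-level nesting is used.  p-values use the large-sample normal
approximation.  When no tree repeats, the fit falls back to OLS with a
flag.  A constant dummy raises a degenerate-design error.  The model-8
growth equation is implemented with main effects
(`ln id ~ ln d + ln SDIci + m`); an interaction-only density variant
(`8i`) exists because the published equation and its coefficient listing
disagree on this point.  Model 5 follows the displayed equation
(`ln id ~ ln dqc + m`) rather than the longer variable string of the
coefficient table.  Reduced model-6 rows (three coefficients) are read
with the dummy in the last slot.

Confidence bands are parametric bootstrap: resample tree effects and
residuals from the fitted τ² and σ², refit, predict on a grid, take
percentile intervals; deterministic given the seed, aborting if more
than 10 % of refits fail.

## Trade-off curve

Equalizing models 9 and 10 in `ln SDIc` gives
`IMc = K id^γ e^{δ m}` with `γ = b₁/a₁`, `K = exp(b₀ − b₁a₀/a₁)`,
`δ = b₂ − b₁a₂/a₁`.  The printed closed-form version of this equation in
the source material is typographically corrupted, so the package treats
the symbolic elimination above as normative and verifies it against a
numerical sweep of the common density over [100, 2000] trees ha⁻¹
(agreement to 1e-10 relative).  `e^δ` is the density-matched mixed/mono
productivity ratio.

## Stand summaries

Per survey: quadratic mean diameter over live trees, merchantable volume
(d ≥ 7 cm), LAI and carbon over all live trees, each per hectare.  The
periodic annual volume increment credits trees removed during a period
at the period end (`IV = (V_end + V_removed − V_start)/period`), so the
bookkeeping is invariant to when within the period the removal happened;
the crediting convention is a package decision.

## Synthetic stand generator

The generator emulates the study conditions the analysis assumes:

- **Geometry**: rectangular plots; the standard experiment uses
  160 × 160 m (2.56 ha) with 1600 trees (625 stems ha⁻¹), surveys at
  ages 50/55/60 — stem densities, diameters (lognormal, meanlog 3.0 ≈
  20 cm, sdlog 0.2) and 5-year re-survey intervals typical of long-term
  thinning-experiment series.
- **Pattern**: a square planting grid with uniform jitter of ±40 % of
  the spacing, or a Matérn-style parent–offspring cluster process; both
  wrap toroidally.
- **Mixing layout**: intimate (per-tree random assignment with species
  shares realized exactly by largest-remainder rounding, removing a
  nuisance variance from recovery tests) or patches (square cells
  allotted to species, mixing concentrated at patch boundaries).  The
  standard experiment uses 30 m patches, yielding ≈ 20 % mixed circles —
  enough contrast to identify the dummy.
- **Growth law**: `ln id = γ₀ + γ₁ ln d + γ₂ ln SDIci + β m + b + ε`
  with defaults γ₀ = 0.5, γ₁ = 0.8, γ₂ = −0.25 (≈ 3–5 mm yr⁻¹ at
  d = 20 cm and SDIci ≈ 500, size-dependent and density-suppressed), the
  tree effect b ~ N(0, τ²) drawn once per tree, ε i.i.d. per
  observation; τ = 0.2, σ = 0.1 by default.  Increments are generated in
  mm yr⁻¹ and converted once (`d += id·period/10`), floored at a small
  positive value so diameters never shrink.  Local SDIci and m are
  computed by the same neighborhood code the analysis uses, so the
  fitted model is exactly matched to the generative design.
- **Thinning**: optional removal from above (largest d first,
  `floor(n·fraction)` stems, ties by tree id).  Intensities are free
  parameters, as the source material does not state them.

What the generator does *not* emulate: measurement error on d, ingrowth,
natural mortality, height measurement subsets (heights are always
imputed), site gradients, or crown plasticity.  Passing recovery tests
therefore demonstrates the correctness and calibration of the estimation
chain under the assumed data-generating process, not robustness to
real-data pathologies.

## Parameter recovery and calibration

The standard validation fits the matched growth model (model 8) to the
simulated features.  The m-coefficient of the *density-only* model 9
would confound the dummy with the size differences mixing itself induces
after the first period, so the matched model is the right instrument for
checking unbiasedness; the model-9 route is still exercised end to end.
With β = 0.20 the replicate mean of the estimate falls within ±0.02 of
truth and every replicate within 3 standard errors; with β = 0 at least
90 % of replicates are within 2 standard errors of zero.  The test suite
runs 20 replicates of each condition; the acceptance script defaults to
8 to keep its runtime in minutes.

## Numerical choices

- REML convergence via L-BFGS with a derivative-free Powell retry at the
  τ² = 0 boundary, where the information matrix is singular.
- All randomness flows through `numpy.random.default_rng` seeded from
  the experiment seed; identical config + seed reproduces every output
  byte.
- Empty circles give SDIci = 0 (dropped by log-model filters); the
  generator floors SDIci at 1 inside its own log only, so such trees are
  excluded from fitting rather than biasing it.
- Bundled reference coefficients are guarded by a sha256 checksum test.

## Known limitations

- The simplified volume model and synthetic allometric defaults make the
  *absolute* stand summaries illustrative; relative comparisons
  (mixed vs mono) are the supported use.
- Only a tree-level random intercept is supported — no crossed or nested
  plot effects, no model selection.
- Crown fields are carried as pass-through only; no crown-based metrics.
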