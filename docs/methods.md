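# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limits of `lingrisk`.

## Risk components

**Range size** is the area (km²) of the union of a language's range
polygons after projection to a Behrmann equal-area cylindrical
projection on the authalic sphere (R = 6 371 007.181 m; the projection
is exactly equal-area, so per-cell comparisons are unit-consistent).
Overlapping polygons of one language are unioned before measuring, so
shared area is never double-counted; irreparable geometries exclude the
language with a per-language error record.

**Speaker growth rate.** For every language with at least three survey
records including one non-zero count, a two-parameter Poisson log-link
GLM, log E[Nₜ] = a + r·t, is fitted by Newton/Fisher scoring (relative
tolerance 1e-10, 100 iterations; years are centred internally, which
changes only the intercept). The year coefficient r is the growth rate,
kept on the log scale; exp(r) is the annual ratio comparable with the
1.016/yr global human figure. Series whose likelihood diverges (e.g. a
lone non-zero count at the end) are flagged non-convergent and excluded
downstream. Overdispersion is deliberately ignored: the estimand is the
trend, and the plain-Poisson score equations define it.

Because the *initial* population (the count at the oldest survey year)
is used as the predictor in the growth–population analysis, a
correlation between growth rate and oldest survey year would make that
analysis circular; `growth_rate_survey_bias` reports tie-corrected
Kendall τ-b with its two-sided p-value as the standard check.

**Transmission score** maps vulnerable → 1 … critically endangered → 4,
everything else → 0; a missing status excludes the language rather than
scoring 0.

## Breakpoint (segmented) regression

The segmented model y = b₀ + b₁x + b₂(x−ψ)₊ + ε is fitted by least
squares jointly over slopes and the break ψ. The estimator is iterative
linearisation (augment with the hinge and its indicator, update
ψ ← ψ + γ̂/b̂₂ until |Δψ| < 1e-6·range(x)), with three safeguards that
make it agree with an exhaustive profile search:

- a 100-point coarse profile scan locates candidate basins and supplies
  starts (the predictor median is always among them);
- the best few basins are polished by bounded scalar minimisation of the
  profile RSS;
- ties in RSS break to the smallest ψ.

Degeneracy (no interior break) is declared when the profile RSS is
monotone to the scan edge or the slope change is negligible against the
data scale; the caller then falls back to the linear family. The 95% CI
for ψ uses the delta method on the augmented design
(se(ψ) = se(γ̂)/|b̂₂|, the convention of the standard segmented-fitting
packages) with a case-resampling bootstrap (500 draws) as the
alternative, because the delta method is unreliable near degenerate
breaks.

Model families null/linear/quadratic/segmented are compared by AIC from
the Gaussian maximum likelihood with k = 2/3/4/5 parameters (the error
variance counts). Exact fits are snapped to RSS = 0 on a common scale so
the comparison reduces to parameter counts. Population and range enter
the pairwise analyses as log₁₀ (their printed confidence intervals are
multiplicatively symmetric); growth rate stays raw. Breakpoints on log₁₀
predictors are back-transformed (10^ψ) to speakers or km².

## Equal-area gridding

Cells are 192 972.5 m squares (≈2° at 30° N/S) anchored at the
lower-left of the projected extent (configurable; the anchor is not
identifiable from the method itself). A cell contains a language iff the
range polygon overlaps it with positive area — mere boundary touching
does not count. Per-cell summaries are medians (midpoint convention for
even counts) of log₁₀ range, log₁₀ population, growth rate and
transmission score over member languages, plus covariate means; cells
with < 50% land or no member carrying a given response drop out of that
response's regression table. Latitudinal bands are grid rows (equal true
area), labelled by central latitude, with band land area
Σ land_fraction × cell area.

## SAR error models and model averaging

The non-spatial OLS baseline leaves strong residual autocorrelation
(checked by Moran's I, I = (n/S0)·z′Wz / z′z, permutation p with 999
seeded draws), so inference uses the SAR error model

    y = Xβ + u,  u = λWu + ε,  ε ~ N(0, σ²I)

with W the row-standardised binary adjacency of cell centroids within a
distance band. β and σ² are concentrated out; the profile likelihood
logL(λ) = const + ln|I − λW| − (n/2)ln(RSS(λ)/n) is maximised by a
coarse grid plus bounded refinement to 1e-8, with λ̂ never allowed to do
worse than λ = 0. The log-determinant uses the real spectrum of W
(W = D⁻¹A is similar to a symmetric matrix), cached per weights object
so the all-subsets sweep pays the eigendecomposition once; a sparse-LU
route is provided for problems too large to decompose densely and agrees
with the eigenvalue route to 1e-8. Isolated cells keep zero-weight rows
rather than being dropped, so n is constant across candidate distances
and their AICs are comparable. AIC counts k = p + 2 (β, λ, σ²); the OLS
AIC counts p + 1 on the same convention. Candidate neighbourhood
distances default to 250–500 km in 50-km steps plus 1000/2000 km (range,
population) or 1000/1500 km (growth, transmission); the minimum-AIC
distance is adopted.

Candidate covariates first pass a collinearity screen: pairs with
|Pearson r| > 0.8 drop the lower-priority member, and tolerances
(1 − R² of each survivor on the rest) are reported. All 2^p subsets
(p ≤ 20 guard) are fitted with λ re-estimated per model; Akaike weights
wᵢ = exp(−Δᵢ/2)/Σ, the 95% confidence set is the smallest weight-ranked
prefix reaching 0.95, and averaging is conditional ("natural"): each
variable averages over the confidence-set models containing it with
weights renormalised within that subset, with the Burnham–Anderson
unconditional SE √(seᵢ² + (bᵢ − b̄)²) averaged the same way, z = |b̄|/se,
and Σwᵢ (over the 95% set, renormalised) as the importance measure.
Zero-substitution averaging is available by configuration. Language
richness is excluded as a covariate for the range-size and
population-size responses (richness can be a consequence of small
ranges, confounding the causal reading) and included for growth and
transmission.

**Nagelkerke pseudo-R²** is Cox–Snell 1 − exp(−(2/n)(logL − logL₀))
divided by its maximum 1 − exp((2/n)·logL₀). For continuous responses
the null log-likelihood can be positive when the response variance is
tiny, which breaks the normalisation; both likelihoods are therefore
evaluated on the unit-variance response (a pure shift of both logLs that
leaves the likelihood ratio untouched).

## IUCN-style categorisation

Criteria and default thresholds (all configurable):

| criterion | VU | EN | CR | extra condition |
|---|---|---|---|---|
| A3 decline over 3 generations | > 30% | > 50% | > 80% | — |
| B1 range km² | < 20 000 | < 5 000 | < 100 | continuing decline (r < 0) |
| C1 population | < 10 000 | < 2 500 | < 250 | decline ≥ 10%/3G, 20%/2G, 25%/1G |
| D1 population | < 1 000 | < 250 | < 50 | — |
| D2 range km² | < 20 | — | — | — |

Generation length G defaults to 25 years; the three-generation decline
is 1 − exp(3G·r) for r < 0. Size thresholds are strict ("smaller than"),
the A3 decline is strict ("exceeded"), and the C1 decline requirement is
inclusive ("at least", the v3.1 wording); a 1e-12 tie tolerance keeps
rates constructed to sit exactly on a boundary from drifting across it
by floating-point error. A language's category is the most severe level
any criterion triggers; criteria involving decline are evaluated only
when a growth estimate exists, and a language with neither area nor
population is data-deficient. B1 uses total polygon area as the
extent-of-occurrence surrogate and reduces the sub-conditions to
"continuing decline", which is all speaker data can support.

Threat maps count a threatened language in every cell its range
overlaps; extinct richness counts curated extinct-language points per
cell; the extinction-filter classification cuts the
threatened/extant and extinct/extant proportions at 0.25/0.25
(configurable) into low-both / high-threat-low-extinction /
low-threat-high-extinction / high-both.

## The synthetic world

The generator emulates the *structure* of a global language-range +
speaker-survey dataset at desk scale. Defaults (the study conditions for
all tests): a 40 × 20 grid of 192.9725-km cells, 600 languages, log₁₀
range sizes ~ N(3.3, 1.2²) km², log₁₀ populations ~ N(3.4, 1.3²)
speakers, baseline growth ln(1.016) with s.d. 0.01, decline threshold
334 speakers, full decline rate −0.03/yr, GDP coupling −0.005 per s.d.
of the (standardised) cell GDP field, survey series of 3–8 records in
1949–2005 with Poisson counts, 12% of declining languages flagged
extinct, 10% ocean cells, and nine covariate fields with
autocorrelation range 5 cells. With ~25% of languages below the
threshold, these sizes make the threshold recoverable while keeping a
full end-to-end run near ten seconds.

Design choices worth knowing:

- **Ranges** are contiguous blobs grown on an 8×-subdivided grid with
  the last subcell trimmed to a partial rectangle, so polygon areas
  equal the lognormal draw exactly while the gridding stage still
  exercises genuine polygon–cell intersection. Polygons are stored in
  geographic coordinates; axis-aligned edges survive the cylindrical
  round-trip exactly.
- **The decline regime is itself segmented**: above the threshold,
  r = baseline + GDP effect + noise; below it r falls linearly in
  log₁₀N₀, continuous at the threshold, reaching the full decline rate
  at a reference population (default 100 speakers) and steeper below.
  The growth–population relationship is therefore a genuine one-kink
  function whose break the segmented estimator can recover without
  bias. (A hard step regime — every small language at the full decline
  rate — is available as `decline_mode="step"`, but a one-kink fit of a
  step places the break systematically above the true threshold.)
- **Extinction is absorbing**: once a Poisson draw hits zero the series
  stays at zero. A configured fraction of declining languages is
  additionally flagged for the curated extinct-point layer (mirroring a
  GIS feature class that is separate from survey series) and forced to a
  terminal zero; the ledger distinguishes series that ended at zero
  (`extinct`) from the curated layer (`extinct_point`).
- **Covariate fields** are SAR draws (I − ρW)⁻¹ε on the rook grid with
  ρ = 1 − 1/range, standardised and scaled by √sill — the same spatial
  mechanism the inference assumes, testable from both sides. An optional
  response mode generates y = Xβ + (I − λW)⁻¹ε with configured λ and β
  for parameter-recovery studies.
- **Population–range coupling** (off by default, used in the
  reproduction script) replaces the independent lognormal range draw by
  a two-segment function of log₁₀ population, making the
  range–population breakpoint recoverable.

What the generator does **not** emulate: real geography (continents,
coastlines, countries), survey-effort heterogeneity, reporting error in
speaker counts beyond Poisson noise, language splits/merges, or the
population-size distribution of the real databases (the synthetic world
is skewed toward smaller communities, so its threatened proportion under
the IUCN rules is higher than an analysis of the real data would give).
Passing tests demonstrate that the estimators recover known generating
parameters under these conditions — not that any particular empirical
value holds for the world's languages.

## Numerical conventions and edge cases

- Seeds: every generator draws from named substreams of the configured
  seed; identical (config, seed) reproduce byte-identical artifacts.
- λ search interval: (1/ω_min + 1e-6, 1/ω_max − 1e-6) from the extreme
  eigenvalues of W (upper bound 1 under row-standardisation); boundary
  solutions are flagged.
- Permutation tests: 999 draws by default, seeded, two-sided against
  the expectation −1/(n−1).
- Even-count medians: midpoint convention.
- Degenerate inputs: constant responses make Moran's I and the
  collinearity screen error out explicitly; empty joins and missing
  upstream artifacts fail with named messages rather than silently.

## Limitations

Single breakpoint only (no multi-break search, no Davies test); SAR
error form only (no lag/Durbin models, no GWR); dateline-crossing
polygons are not handled beyond naive splitting; ellipsoidal areas are
approximated by the authalic sphere; the B2/C2/D-location/E criteria are
out of scope. The pipeline's per-criterion counts tally languages by
their worst category; alternative tallies require the per-criterion
columns in the assessment output.
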