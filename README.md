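# lingrisk

Spatial macroecology of language extinction risk.

Most of the world's ~7000 languages are spoken in small areas by small
speaker communities, and many are losing speakers fast. `lingrisk`
implements, as a tested and reusable pipeline, the quantitative machinery
for analysing this problem the way conservation biogeography analyses
species extinction risk:

- **Risk components per language** — range size (total polygon area, km²,
  on an equal-area projection), speaker population size, and the speaker
  growth rate *r*: the year coefficient of a Poisson log-link GLM,
  log E[Nₜ] = a + r·t, fitted to irregular survey counts. *r* < 0 means
  decline; exp(*r*) is comparable with the global human growth ratio
  (1.016/yr). Intergenerational transmission is scored 0 (safe) to 4
  (critically endangered).
- **Threshold (breakpoint) relationships** — the pairwise relationships
  among the three components are compared across null, linear, quadratic
  and segmented regression families by AIC. The segmented model
  y = b₀ + b₁x + b₂(x−ψ)₊ estimates a threshold ψ jointly with the
  slopes (iterative linearisation cross-checked against an exhaustive
  profile-RSS search). The headline quantity is a minimum-viable-population
  threshold in the growth ~ log₁₀(initial population) relationship: below
  a few hundred speakers, languages decline sharply.
- **Spatially explicit driver inference** — language maps are gridded on a
  Behrmann equal-area cylindrical projection (192.9725 km cells, ≈2° at
  30° N/S), per-cell medians of the risk components are regressed on nine
  environmental/socioeconomic covariates with **SAR error models**
  y = Xβ + u, u = λWu + ε, fitted by maximum likelihood with
  row-standardised distance-band weights W (the neighbourhood distance is
  itself selected by AIC). All-subsets **multimodel inference** produces
  Akaike weights wᵢ, a 95% confidence set, model-averaged coefficients and
  SEs (Burnham–Anderson), and per-variable Σwᵢ importances. Moran's I
  diagnostics verify the spatial filtering; Nagelkerke pseudo-R² summarises
  fit.
- **Threat categorisation** — every language is assessed against IUCN-style
  criteria A3 (decline > 30/50/80% over three generations,
  1 − exp(3G·r)), B1 (small range + decline), C1 (small population +
  decline), D1 (very small population) and D2 (very small range), and
  mapped into threatened-richness, extinct-richness and extinction-filter
  classes per grid cell.
- **Synthetic world generator** — a first-class module that generates
  range polygons, speaker time series, spatially autocorrelated covariate
  fields and extinct-point layers with a complete ground-truth ledger, so
  every stage above is testable end-to-end without proprietary data.

The package is aimed at macroecologists and quantitative linguists who
want the full pipeline, and at spatial statisticians who want the
individual estimators (`SegmentedRegression`, `SarErrorRegression` follow
the scikit-learn fit/predict convention).

## Worked example

Recover the minimum-viable-population threshold from a synthetic world:

```python
from lingrisk import SyntheticConfig, fit_growth_rate
from lingrisk.synthetic import generate_world
from lingrisk.components import component_table, eligible_series
from lingrisk.segmented import pairwise_threshold_analyses

world = generate_world(SyntheticConfig(seed=42))
estimates = [fit_growth_rate(s) for s in world.series if eligible_series(s)]
table = component_table(world.records, growth_estimates=estimates)

result = pairwise_threshold_analyses(table)["growth_vs_initial_population"]
bp = result["breakpoint"]
print(f"best family : {result['best_family']}")
print(f"threshold   : {result['psi_natural']:.0f} speakers "
      f"(95% CI {result['psi_ci_natural'][0]:.0f}-{result['psi_ci_natural'][1]:.0f})")
print(f"slopes      : {bp.slope_left:+.4f} / {bp.slope_right:+.4f} per decade")
print(f"declining   : {(table['rate'] < 0).mean():.1%} of languages with a growth rate")
```

prints

```
best family : segmented
threshold   : 369 speakers (95% CI 314-435)
slopes      : +0.0893 / +0.0009 per decade
declining   : 21.5% of languages with a growth rate
```

i.e. the four-family AIC comparison picks the segmented model, growth
rates rise steeply with population below ~370 speakers (the generating
threshold is 334) and are flat above it, and about a fifth of languages
are in decline.

The same analysis runs from the shell, stage by stage or end to end:

```bash
lingrisk run --out out/ --seed 42            # simulate ... report
lingrisk breakpoints --out out/              # rerun one stage
```

Each run writes CSV/GeoJSON artifacts plus `manifest.json` with row
counts, exclusion tallies and content hashes (identical config + seed
reproduce identical hashes).

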