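# Methods

## Scope and design

The package reimplements a global marine-food-footprint analysis chain as a
library: trophic footprint mapping, seafood sourcing distances, a supply
ceiling model and demand projection. The original analyses ran on mapped
global catches (30-arc-minute cells), satellite primary-production fields,
trade records and UN population scenarios; none of these ship here.
Instead, a first-class synthetic-world generator produces all inputs with
retained ground truth, which turns every analysis into a testable
round-trip: the generator knows the answer, the analysis must recover it.

## Grid and geometry

Regular lat/lon grids with exact spherical-band cell areas
`A = R²·Δλ·(sin φ₂ − sin φ₁)` and mean Earth radius `R = 6371 km`
throughout (areas and great-circle distances). The full grid sums to
`4πR²` to machine precision, which the tests assert against the analytic
sphere. Land cells are placed uniformly at random (the generator does not
attempt coastline realism); coastal cells are sea cells rook-adjacent to
land, falling back to all sea cells on land-free grids so ports and
mariculture origins always exist. Resolution is a parameter: 30-min cells
(360×720) at full scale, tiny grids in tests and examples.

## Synthetic world

* **Primary production.** Per-cell annual PP = lognormal areal density
  (mean 140 t C km⁻² yr⁻¹, the observed global-ocean mean scale; spatial
  CV default 0.5) × cell area, with an independent lognormal interannual
  factor (CV default 0.05, matching the few-percent year-to-year
  variability of satellite PP totals). Both CVs at zero give exactly
  `mean_pp × area`, which anchors the degeneracy tests.
* **Countries and EEZs.** Sea cells ordered west→east are split into
  contiguous stripes, one per country, covering `eez_fraction` (default
  0.7) of the sea; the rest is high seas. Ports sit on coastal cell
  centres, at least one per country.
* **Catches.** In each EEZ cell the first-year tonnage inverts the
  footprint formula: `C_i = share_i · f · PP_mean · CR · TE^(TL_i−1)` with
  calibration constants CR = 9, TE = 0.1, so the implied PPR/PP ratio
  equals the target fraction `f` exactly (the round-trip test requires
  1e-9). Later years scale by `(1 + effort_trend)^(y−y₀)`. Pipeline
  defaults `f = 0.08`, trend 3%/yr over 1950–2011 reproduce the
  qualitative growth from a sub-band footprint to ≳30% exploitation.
* **Trade.** Each catch record exports a fixed fraction (default 0.35) to
  a population-weighted importer, so conservation (traded ≤ caught) holds
  at every aggregation level by construction; exact provenance is retained
  as ground truth for the matcher tests. Mariculture production (constant
  per country) trades the same way.
* **Population/consumption.** Constant-rate growth; all scenarios share
  the median path through the historical window and diverge after it.
  Historical consumption is `a + b·pop + N(0, σ)`; the default slope
  0.02 t person⁻¹ yr⁻¹ (~20 kg per capita) matches observed per-capita
  seafood consumption scale, and default growth rates (0.6/1.1/1.6% after
  2011) bracket plausible demographic futures so that the median scenario
  crosses all three supply ceilings before 2100.

What the generator does **not** emulate: real coastline or EEZ geometry,
taxon-specific catch composition drawn from real landings, processing and
re-export chains, price effects, or climate-driven PP trends. Passing
tests therefore demonstrate correctness of the estimators under known
ground truth, not agreement with the historical data series.

## Footprint analysis

`PPR = Σ (C_i/CR)(1/TE)^(TL_i−1)` per record, aggregated per cell, EEZ or
globally. Exploitation bands are half-open — [0.10, 0.20), [0.20, 0.30),
[0.30, ∞) — a normalisation chosen so the bands are disjoint and
exhaustive above 10%; areas are reported in km² × 10⁶ against the
multi-year mean PP. The accessible-ocean percentage restricts both
numerator (annual-mean PPR) and denominator (mean PP) to sea cells
strictly shallower than 1,000 m.

The Monte Carlo layer draws, per trial, TE from a truncated normal (mean
10%, sd 3.03 percentage points ≈ the 90% band over 5–15%; truncation
bounds default to (0.05, 0.15) and are configurable) and a global PP level
from a normal over the annual accessible totals, applied as a single
multiplicative factor — global data constrain the level, not the per-cell
pattern. A single-year PP pool gives sd 0 and is flagged
(`degenerate_pp_pool`) rather than rejected. With both variances zero
every trial equals the deterministic value (asserted at 1e-12). The CI is
the 2.5/97.5 percentile of trials; it is strongly right-skewed whenever
high-TL catch is present, because `(1/TE)^(TL−1)` explodes as TE
approaches its lower bound — a real feature of the model, not an artefact.

## Sourcing distance

Distances are haversine great circles. The export matcher is a
deterministic three-tier hierarchy per (year, exporter): exact
(year, exporter, taxon) matches allocated pro-rata across that taxon's
cells by tonnage; residues pooled across all taxa pro-rata; anything left
flagged unmatched and logged, never dropped. The matcher is deliberately
simple and pluggable — the original "fuzzy-fit" procedure is not specified
anywhere in enough detail to clone.

The bootstrap draws a category (probability ∝ category tonnage), then a
record within it. With tonnage-weighted within-category sampling (the
default) the inclusion probability of a record is already proportional to
its tonnage, so the trial statistic is the **unweighted** median of the
sample; weighting again would converge to the tonnage²-weighted median.
Under the alternative uniform within-category sampling the trial statistic
is the tonnage-weighted median. Both converge to the catch-weighted median
of the record population; the coverage experiment verifies ≥93% CI
coverage over 200 replicate record sets (400 records, 400 trials × 1,000
samples each — sizes chosen to keep the full-suite experiment in tens of
seconds while leaving bootstrap noise well below the CI width). The
weighted median uses the lower-value tie rule for determinism. Records are
canonically sorted and zero-tonnage rows dropped before sampling, making
estimates invariant to input permutation and zero-weight padding.
"5% confidence limits by ranking" is read as the two-sided 95% interval
(2.5/97.5 percentiles); Shapiro–Wilk at α = 0.05 flags non-normal trial
distributions (constant trials are reported as not-rejected without
testing).

## Supply ceilings

`F = W·fr`, `M = F·fm·rfm/ffm`, `S = W(1−fr) + M`, feed-to-product
conversion fixed at 1.0. Parameter table (min, mean, max): W (94.5, 105,
126) Mt; fr (0.25, 0.36, 0.45); fm (0.7, 0.9, 1.0); rfm (0.21, 0.22,
0.24). **rfm defaults to the range midpoint 0.225**, not the tabulated
mean: only the midpoint reproduces the headline 144/177/220 Mt ceilings
after rounding (the mean gives 142/174/215); the tabulated mean remains
available as `RFM_PUBLISHED_MEAN`. Sensitivity sampling defaults to
independent uniforms over each range; a truncated-normal family (mean at
the tabulated mean, 95% mass inside the range) is available. Uniform
sampling over the full ranges yields a 95% CI width near 40% of the mean —
the much tighter "<2% of the mean" figure sometimes quoted for this model
is not reproducible under any sampling family over the full ranges, so the
package reports the spread rather than asserting it.

## Demand projection

"GLM" is realized as Gaussian-identity OLS (statsmodels): with no stated
family or link, ordinary least squares on totals is the parsimonious
reading; per-capita fitting is a caller-side transform. Projection applies
the fitted line to scenario population paths directly (no autoregressive
structure). Crossing years use strict exceedance on annual points with no
sub-year interpolation, which makes the crossing year monotone
non-decreasing in the limit (tested).

## Pipeline and determinism

Each stage derives its RNG substream as
`SeedSequence([master_seed, sha256(master_seed:stage_name)])`, so stages
are individually rerunnable and independent of each other's draw counts.
All tables are computed in memory and written only after every stage
succeeds; the manifest (config hash, seed, per-file SHA-256) is written
last. CSV is the primary interface; gridded fields can be exported through
xarray's NetCDF3 backend if xarray is installed (optional extra).

## Numerical choices and limitations

* Float comparisons in calibration round-trips are asserted at 1e-9
  relative; exact-claim degeneracies (zero-variance Monte Carlo) at 1e-12.
* Per-cell standard deviations over identical years are forced to exact 0
  to honour the "no interannual noise ⇒ sd 0" contract despite float
  rounding.
* Monte Carlo PP draws are clipped away from zero to avoid sign flips in
  the denominator at extreme draws.
* Problem sizes in tests and the acceptance script (grids up to 50×100,
  10⁵-trial Monte Carlo reruns, 200-replicate coverage experiments) were
  chosen so the whole suite runs in well under a minute of CPU apart from
  the coverage experiment; they are desk-scale stand-ins, not the full
  360×720 × 62-year problem, which the same code handles by configuration.
* The distance estimate is a strict minimum (nearest ports, direct great
  circles, no processing chains); the supply model ignores fish-oil
  co-products beyond what `rfm` folds in, and the 200 Mt
  climate-plus-discards composite scenario is documented but not computed,
  as its combination rule is not recoverable.
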