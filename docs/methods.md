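# Methods

This note records the models behind `lcckit`, the conventions chosen
where the standard formulations leave room, and what the synthetic
test bed does and does not demonstrate.

## Footprint accounts

The ecological footprint side follows the classic component method.
Per-capita consumption of each item is `C_i = (P_i + I_i − E_i) / p`;
the area demanded is `aa_i = C_i / W_i` with `W_i` the world-average
yield (kg/ha for biotic items; for energy items, an energy-equivalent
absorption coefficient in GJ/ha). Demand is aggregated per land
category and weighted by equivalence factors; supply is per-capita
area times yield and equivalence factors with a 12% biodiversity
set-aside:

```
PEF = Σ_j e_j Σ_{i∈j} aa_i
PBC = (1 − s) Σ_j a_j y_j e_j ,   s = 0.12 by default
```

All results are reported in ha·ca⁻¹ after equivalence weighting.
Conventions adopted:

* **Per-capita areas.** Supply areas enter the account as
  `a_j = total_area / population` of the same year; a single
  population series per year serves both the consumption and the area
  side (year-end vs mid-year population is not distinguished).
* **Two footprint lines.** Fossil-energy land has zero yield factor in
  the default table, so it supplies no biocapacity; totals are
  reported as PEF I (excluding it) and PEF II (including it), with
  balances I and II defined as PBC minus each line.
* **Negative net consumption.** If a region exports more of an item
  than it produces plus imports, `C_i < 0`. The elementary operation
  returns the negative value with a `DataQualityWarning` so the datum
  stays visible, but the pipeline floors the item's area contribution
  at zero when aggregating: a region cannot exert negative demand on a
  land category.
* **Energy coefficients.** Land-equivalent coefficients for energy
  items are not universal constants; they are required configuration
  (per-item `W_i` in the item registry) with no hidden defaults. The
  synthetic default scenario supplies the conventional
  global-average values (coal-type 55, oil-type 71, natural gas 93,
  electricity 1000, heat 1163 GJ/ha).
* **Annual intensity.** Rates of change of a yearly series are
  reported as the compound annual growth rate
  `(v_end / v_start)^(1/(years)) − 1`. Published intensity figures for
  this kind of analysis often cannot be reproduced from endpoint
  values alone because the underlying yearly series are unpublished
  and the averaging convention is rarely stated; the CAGR convention
  here is explicit and is the one all tests use.
* **Precision.** Ledgers are stored at full floating precision;
  rendered reports round to two decimals.

## Index-system scoring

The composite index works on a year × indicator judgement matrix.
Each column is min–max normalized with polarity — positive indicators
as `(x − min)/(max − min)`, negative as `(max − x)/(max − min)` — so 1
is always the best observed condition. Indicator weights are
proportional to the dispersion of the normalized column, the idea
being that an indicator that separates years strongly should influence
the ranking more:

```
W_j = σ(Y_j) / Σ_k σ(Y_k),   F_i = Σ_j Y_ij W_j
```

Conventions adopted:

* **Dispersion measure.** `σ` is the population standard deviation
  (root mean squared deviation, ddof = 0). The root-free alternative
  (mean squared deviation) yields genuinely different weights — the
  normalization in the ratio does not cancel the root — so the choice
  is exposed as `dispersion={"rmsd","msd"}` with `rmsd` the default.
* **Degenerate columns.** A constant column carries no ranking
  information; it is normalized to 0.5 everywhere (with a warning) and
  receives weight 0 through `σ = 0`, so the 0.5 never influences a
  score. A matrix in which *every* column is constant cannot be
  weighted and raises an error.
* **One weight vector.** Weights are computed once from the full
  normalized matrix (history plus projections), not per year, so
  scores are comparable across years.
* **Normalization window.** When projecting, min/max are taken over
  the union of historical and projected years. This is what allows a
  projected year to pin the 0 or 1 end of a column — monotone
  indicators then reach exactly 1 (or 0) in the last projected year.
* **Projection.** Each indicator is extrapolated by an ordinary
  least-squares straight line in calendar year. OLS is exactly the
  generating model of the synthetic panels, making projections
  unbiased there; real indicators are under no obligation to be
  linear, and long-horizon extrapolations should be read as scenario
  arithmetic, not forecasts.
* **Layer scores.** Layer scores are weight-inclusive partial sums
  over the layer's indicators, so B1 + B2 + B3 = F exactly; a layer's
  maximum attainable score is its weight sum.
* **Grade boundaries.** The five bins are closed below and open above
  with the top bin closed (`[0.8, 1]`); a score exactly on a boundary
  takes the higher class. The scale is configurable via YAML.

The bundled reference table of published weights and normalized values
reconstructs the published year-2000 layer scores for the ecological
(B2 = 0.10) and economic (B3 = 0.07) layers at two decimals. The
published social-layer value (B1 = 0.11) does not reconstruct from the
rounded table (the weighted sum of the printed values gives 0.10), so
it is documented here rather than asserted anywhere; the unrounded
inputs behind the published aggregate are not available.

## Synthetic city generator

The generator produces panels with known ground truth so that both
pipelines are testable offline:

* Flows, population and areas follow geometric trends
  `v_t = v_0 (1+g)^t`; flow noise is multiplicative lognormal with
  unit mean and configurable coefficient of variation (preserving
  non-negativity). Because trends are geometric, a configured demand
  growth rate reappears exactly as the footprint CAGR when noise is
  zero — a closed-form check the tests exploit.
* Indicators follow straight lines `x_t = x_0 + b t` with additive
  Gaussian noise of sd `cv · |x_0|`, matching the OLS projection
  model.
* All randomness comes from `numpy.random.default_rng` (PCG64) seeded
  from the scenario seed; identical configuration and seed give
  identical panels across runs and platforms.

The default scenario is a 13-year panel for a rapidly urbanizing
coastal city of about two million inhabitants growing at 5%/yr, with
21 consumption items (12 biotic, 9 energy) and the 20-indicator
framework: arable/forest/pasture/fishery areas shrink while built-up
area grows, energy demand outpaces population, and most indicators
improve. Magnitudes are order-of-magnitude plausible for such a city,
no more; the generated panels are not a statistical emulation of any
real yearbook series. Consequently, passing tests demonstrate the
correctness and internal consistency of the accounting and scoring
machinery and the recoverability of known ground truth — they do not
validate the realism of any particular city's data, and real panels
bring problems (structural breaks, definition changes, missing years)
the generator deliberately omits.

## Problem sizes and numerics

The test suite and the reproduction script run at desk scale: 13-year
panels, 20 indicators, 100-seed recovery batches, and 100 random 5×20
matrices for the brute-force scoring oracle. Identities (balance =
PBC − PEF, F = B1 + B2 + B3, ΣW = 1) are asserted at 1e−12–1e−9;
stochastic recovery uses a 2-standard-error band on the standardized
projection bias. Degenerate inputs (empty consumption, constant
columns, single-year panels) are exercised explicitly: empty
consumption means zero demand, constant columns are inert, and
trend classification requires at least two years.

## Known limitations

* The footprint account is a static aggregate: it treats any
  consumption as drawing down biocapacity and ignores CO₂ absorption
  by non-fossil land categories (each category has a single exclusive
  function).
* Index scores are relative to the observed (plus projected) window;
  adding a year can change every normalized value and weight, so
  scores from different windows are not directly comparable.
* The dispersion-weighting scheme is the only one implemented;
  entropy or expert-judgement weights are out of scope.
* Linear projection of indicators ignores saturation and policy
  shifts; projected grades far from the data window inherit all of
  that fragility.
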