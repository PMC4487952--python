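"""Seeded synthetic city-panel generator.

Produces multi-year input panels with known ground truth so that both
assessment pipelines can be exercised and checked offline: a
consumption/area panel set for the footprint accounts and a
20-indicator panel for the index system.

Generating model
----------------
* Flows (production, imports, exports), population and land areas
  follow geometric trends: ``v_t = v_0 * (1 + g)^t`` with per-item /
  per-category growth rates ``g`` (fraction per year).  A configured
  demand growth therefore appears verbatim as the compound annual
  growth rate of the resulting footprint series when noise is off.
* Flow noise is multiplicative lognormal with unit mean (sigma chosen
  from the coefficient of variation), which keeps flows non-negative.
* Indicators follow straight lines ``x_t = x_0 + b * t`` with additive
  Gaussian noise of standard deviation ``cv * |x_0|`` — exactly the
  model the OLS projection step assumes, so projections are unbiased
  by construction.

Randomness comes from ``numpy.random.default_rng`` (the PCG64 bit
generator), seeded from the scenario seed, so identical configurations
reproduce identical panels across runs and platforms.

The default scenario sketches a rapidly urbanizing coastal city of
about two million people: arable and forest areas shrink, built-up
area and fossil-energy demand grow fast, and most social/environmental
/economic indicators improve — so the footprint ledger shows a widening
ecological deficit while the composite index score rises.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .efa import AreaPanel, ConsumptionPanel, ItemRegistry
from .errors import ValidationError
from .ism import validate_meta

__all__ = [
    "ItemSpec",
    "AreaSpec",
    "IndicatorSpec",
    "ScenarioConfig",
    "default_scenario",
    "gen_efa_panels",
    "gen_ism_panel",
    "write_inputs",
]


@dataclass(frozen=True)
class ItemSpec:
    """One consumption item: baseline year-0 flows and their trend.

    Flows are kg/yr for biotic items and GJ/yr for energy items;
    ``world_yield`` is kg/ha or GJ/ha accordingly.  ``growth`` is the
    geometric trend (fraction/yr) applied to all three flows;
    ``noise_cv`` the coefficient of variation of the lognormal noise.
    """

    item_id: str
    land_category: str
    world_yield: float
    production: float
    imports: float
    exports: float
    growth: float = 0.0
    noise_cv: float = 0.0


@dataclass(frozen=True)
class AreaSpec:
    """One land category's baseline total area (ha) and geometric trend."""

    land_category: str
    area: float
    growth: float = 0.0


@dataclass(frozen=True)
class IndicatorSpec:
    """One indicator: linear trend ``baseline + slope * t`` plus
    Gaussian noise with sd ``noise_cv * |baseline|``."""

    indicator_id: str
    layer: str
    polarity: str
    baseline: float
    slope: float
    noise_cv: float = 0.0
    description: str = ""


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete recipe for one synthetic city.

    Identical configuration (including ``seed``) always yields
    identical panels.
    """

    start_year: int = 2000
    n_years: int = 13
    population: float = 2_050_000.0
    population_growth: float = 0.05
    items: tuple[ItemSpec, ...] = ()
    areas: tuple[AreaSpec, ...] = ()
    indicators: tuple[IndicatorSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValidationError("n_years must be >= 1")
        if self.population <= 0:
            raise ValidationError("population must be > 0")
        if self.population_growth <= -1:
            raise ValidationError("population_growth must be > -1")
        for it in self.items:
            if it.noise_cv < 0:
                raise ValidationError(f"negative noise_cv for {it.item_id}")
            if it.growth <= -1:
                raise ValidationError(f"growth <= -1 for {it.item_id}")
            if it.world_yield <= 0:
                raise ValidationError(f"world_yield <= 0 for {it.item_id}")
            if min(it.production, it.imports, it.exports) < 0:
                raise ValidationError(f"negative baseline flow for {it.item_id}")
        for ar in self.areas:
            if ar.area < 0:
                raise ValidationError(f"negative area for {ar.land_category}")
            if ar.growth <= -1:
                raise ValidationError(f"growth <= -1 for {ar.land_category}")
        for ind in self.indicators:
            if ind.noise_cv < 0:
                raise ValidationError(
                    f"negative noise_cv for {ind.indicator_id}"
                )

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start_year, self.start_year + self.n_years))

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        """Build a config from a (YAML-friendly) dict; unspecified
        sections fall back to the default scenario."""
        base = default_scenario()
        kwargs = {
            key: data.get(key, getattr(base, key))
            for key in (
                "start_year",
                "n_years",
                "population",
                "population_growth",
                "seed",
            )
        }
        kwargs["items"] = (
            tuple(ItemSpec(**d) for d in data["items"])
            if "items" in data
            else base.items
        )
        kwargs["areas"] = (
            tuple(AreaSpec(**d) for d in data["areas"])
            if "areas" in data
            else base.areas
        )
        kwargs["indicators"] = (
            tuple(IndicatorSpec(**d) for d in data["indicators"])
            if "indicators" in data
            else base.indicators
        )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# Default scenario
# ---------------------------------------------------------------------------

# 12 biotic items (kg, kg/ha) and 9 energy items (GJ, GJ/ha).  World
# yields for biotic items are the classic component-method averages;
# energy "yields" are global-average CO2-absorption land coefficients
# (coal-type 55, oil-type 71, gas 93 GJ/ha; electricity and heat use
# the conventional final-energy coefficients).
_DEFAULT_ITEMS: tuple[ItemSpec, ...] = (
    ItemSpec("crops", "arable", 2744, 2.0e8, 2.0e8, 0.5e8, 0.055, 0.03),
    ItemSpec("oil_plants", "arable", 1856, 0.20e8, 0.30e8, 0.05e8, 0.050, 0.03),
    ItemSpec("vegetables", "arable", 18000, 8.0e8, 1.0e8, 0.5e8, 0.055, 0.03),
    ItemSpec("poultry", "arable", 457, 0.15e8, 0.05e8, 0.01e8, 0.060, 0.03),
    ItemSpec("pork", "arable", 500, 0.60e8, 0.10e8, 0.02e8, 0.055, 0.03),
    ItemSpec("eggs", "arable", 400, 0.15e8, 0.02e8, 0.005e8, 0.055, 0.03),
    ItemSpec("fruits", "forest", 3500, 1.5e8, 0.8e8, 0.3e8, 0.045, 0.03),
    ItemSpec("tea", "forest", 566, 0.06e8, 0.02e8, 0.03e8, 0.040, 0.03),
    ItemSpec("beef", "pasture", 33, 0.04e8, 0.06e8, 0.005e8, 0.070, 0.03),
    ItemSpec("mutton", "pasture", 33, 0.02e8, 0.03e8, 0.002e8, 0.070, 0.03),
    ItemSpec("milk_dairy", "pasture", 502, 0.40e8, 0.30e8, 0.02e8, 0.070, 0.03),
    ItemSpec("aquatic_products", "fishery", 29, 1.2e8, 0.3e8, 0.7e8, 0.060, 0.03),
    ItemSpec("heating_power", "built_up", 1163, 2.0e6, 0.0, 0.0, 0.040, 0.03),
    ItemSpec("electricity", "built_up", 1000, 8.0e6, 4.0e6, 0.0, 0.050, 0.03),
    ItemSpec("raw_coal", "fossil_energy", 55, 5.0e6, 35.0e6, 0.0, 0.080, 0.03),
    ItemSpec("coal_products", "fossil_energy", 55, 0.0, 8.0e6, 0.0, 0.060, 0.03),
    ItemSpec("natural_gas", "fossil_energy", 93, 0.0, 5.0e6, 0.0, 0.120, 0.03),
    ItemSpec("petroleum", "fossil_energy", 71, 0.0, 45.0e6, 5.0e6, 0.090, 0.03),
    ItemSpec("diesel_oil", "fossil_energy", 71, 0.0, 15.0e6, 0.0, 0.080, 0.03),
    ItemSpec("lpg", "fossil_energy", 71, 0.0, 8.0e6, 0.0, 0.080, 0.03),
    ItemSpec("fuel_oil", "fossil_energy", 71, 0.0, 10.0e6, 1.0e6, 0.060, 0.03),
)

_DEFAULT_AREAS: tuple[AreaSpec, ...] = (
    AreaSpec("arable", 40_000.0, -0.020),
    AreaSpec("forest", 90_000.0, -0.005),
    AreaSpec("pasture", 3_000.0, -0.010),
    AreaSpec("fishery", 20_000.0, -0.010),
    AreaSpec("built_up", 31_000.0, 0.065),
    AreaSpec("fossil_energy", 0.0, 0.0),
)

_DEFAULT_INDICATORS: tuple[IndicatorSpec, ...] = (
    IndicatorSpec("C1", "B1", "negative", 1200.0, 65.0, 0.02, "Population density (ca/km2)"),
    IndicatorSpec("C2", "B1", "positive", 95.0, 0.2, 0.02, "Employment rate (%)"),
    IndicatorSpec("C3", "B1", "negative", 42.0, -0.8, 0.02, "Engel coefficient (%)"),
    IndicatorSpec("C4", "B1", "positive", 12.0, 0.5, 0.02, "Residential land use rate (%)"),
    IndicatorSpec("C5", "B1", "positive", 800.0, 60.0, 0.02, "Year-end road area (1e4 m2)"),
    IndicatorSpec("C6", "B1", "positive", 0.020, -0.0006, 0.02, "Per capita arable land (ha)"),
    IndicatorSpec("C7", "B1", "positive", 55.0, 1.5, 0.02, "Urbanization rate (%)"),
    IndicatorSpec("C8", "B2", "positive", 35.0, 0.6, 0.02, "Green coverage (%)"),
    IndicatorSpec("C9", "B2", "positive", 60.0, 2.5, 0.02, "Industrial solid waste utilization (%)"),
    IndicatorSpec("C10", "B2", "positive", 85.0, 1.0, 0.02, "Wastewater discharge compliance (%)"),
    IndicatorSpec("C11", "B2", "negative", 3.5, -0.05, 0.02, "Environmental investment index (%)"),
    IndicatorSpec("C12", "B2", "positive", 40.0, 4.0, 0.02, "Centralized sewage treatment rate (%)"),
    IndicatorSpec("C13", "B2", "positive", 50.0, 3.5, 0.02, "Hazard-free garbage treatment rate (%)"),
    IndicatorSpec("C14", "B3", "positive", 500.0, 180.0, 0.02, "GDP (1e8 yuan)"),
    IndicatorSpec("C15", "B3", "positive", 800.0, 250.0, 0.02, "Industrial output (1e8 yuan)"),
    IndicatorSpec("C16", "B3", "positive", 45.0, 0.6, 0.02, "Tertiary industry share (%)"),
    IndicatorSpec("C17", "B3", "positive", 180.0, 60.0, 0.02, "Retail sales (1e8 yuan)"),
    IndicatorSpec("C18", "B3", "negative", 20.0, -0.3, 0.02, "Primary-industry intermediate consumption (1e8 yuan)"),
    IndicatorSpec("C19", "B3", "negative", 1.2, -0.05, 0.02, "Energy per unit industrial added value (tce/1e4 yuan)"),
    IndicatorSpec("C20", "B3", "positive", 55.0, 0.8, 0.02, "Effective irrigation ratio (%)"),
)


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The packaged urbanizing-coastal-city scenario (13 years)."""
    return ScenarioConfig(
        items=_DEFAULT_ITEMS,
        areas=_DEFAULT_AREAS,
        indicators=_DEFAULT_INDICATORS,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    # separate, reproducible streams for the two panel families
    return np.random.default_rng([stream, config.seed & 0x7FFFFFFF])


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative noise with coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _population_series(config: ScenarioConfig) -> pd.Series:
    values = [
        config.population * (1.0 + config.population_growth) ** t
        for t in range(config.n_years)
    ]
    return pd.Series(values, index=pd.Index(config.years, name="year"))


def gen_efa_panels(
    config: ScenarioConfig,
) -> tuple[ConsumptionPanel, AreaPanel, ItemRegistry]:
    """Generate the consumption panel, area panel and item registry."""
    if not config.items or not config.areas:
        raise ValidationError("scenario has no items or no areas")
    rng = _rng(config, stream=1)
    population = _population_series(config)

    flow_rows = []
    for item in config.items:
        for t, year in enumerate(config.years):
            trend = (1.0 + item.growth) ** t
            flow_rows.append(
                {
                    "year": year,
                    "item_id": item.item_id,
                    "production": item.production
                    * trend
                    * _lognormal_factor(rng, item.noise_cv),
                    "imports": item.imports
                    * trend
                    * _lognormal_factor(rng, item.noise_cv),
                    "exports": item.exports
                    * trend
                    * _lognormal_factor(rng, item.noise_cv),
                }
            )
    consumption = ConsumptionPanel(pd.DataFrame(flow_rows), population)

    area_rows = [
        {
            "year": year,
            "land_category": spec.land_category,
            "total_area_ha": spec.area * (1.0 + spec.growth) ** t,
        }
        for spec in config.areas
        for t, year in enumerate(config.years)
    ]
    areas = AreaPanel(pd.DataFrame(area_rows), population)

    registry = ItemRegistry(
        pd.DataFrame(
            {
                "land_category": [it.land_category for it in config.items],
                "world_yield": [it.world_yield for it in config.items],
            },
            index=pd.Index([it.item_id for it in config.items], name="item_id"),
        )
    )
    return consumption, areas, registry


def gen_ism_panel(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the year x indicator judgement matrix and its metadata."""
    if not config.indicators:
        raise ValidationError("scenario has no indicators")
    rng = _rng(config, stream=2)
    data = {}
    for ind in config.indicators:
        sd = ind.noise_cv * abs(ind.baseline)
        noise = rng.normal(0.0, sd, size=config.n_years) if sd > 0 else 0.0
        data[ind.indicator_id] = (
            ind.baseline
            + ind.slope * np.arange(config.n_years, dtype=float)
            + noise
        )
    matrix = pd.DataFrame(data, index=pd.Index(config.years, name="year"))
    meta = validate_meta(
        pd.DataFrame(
            {
                "indicator_id": [i.indicator_id for i in config.indicators],
                "layer": [i.layer for i in config.indicators],
                "polarity": [i.polarity for i in config.indicators],
                "description": [i.description for i in config.indicators],
            }
        )
    )
    return matrix, meta


def write_inputs(config: ScenarioConfig, outdir: str | Path) -> None:
    """Write one scenario's panels in the CSV schemas the pipelines read:
    consumption.csv, items.csv, population.csv, areas.csv,
    indicators.csv and indicator_meta.csv."""
    from .ism import write_indicators_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    consumption, areas, registry = gen_efa_panels(config)
    consumption.to_csv(outdir / "consumption.csv", outdir / "population.csv")
    areas.to_csv(outdir / "areas.csv")
    registry.to_csv(outdir / "items.csv")
    matrix, meta = gen_ism_panel(config)
    write_indicators_csv(matrix, outdir / "indicators.csv")
    meta.reset_index().to_csv(outdir / "indicator_meta.csv", index=False)


def with_seed(config: ScenarioConfig, seed: int) -> ScenarioConfig:
    """Copy of ``config`` with a different random seed."""
    return dataclasses.replace(config, seed=seed)
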