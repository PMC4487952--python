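"""Ecological footprint accounts.

Converts multi-year consumption and land-area panels for a region into
per-capita ecological footprint (PEF) and per-capita biocapacity (PBC)
ledgers, and from those the ecological surplus/deficit balance.

The accounting follows the standard component method.  Each consumption
item (grain, pork, raw coal, ...) is converted to per-capita annual
consumption

    C_i = (P_i + I_i - E_i) / p

(production plus imports minus exports over population), then to the
biologically productive area needed to supply it,

    aa_i = C_i / W_i

where ``W_i`` is the world-average yield of the item (kg/ha, or an
energy-equivalent per hectare for energy items).  Areas are aggregated
by land category and weighted by equivalence factors ``e_j`` so that
categories of different productivity become comparable:

    PEF = sum_j e_j * sum_{i in j} aa_i        [ha per capita]

Supply is the region's actual area per capita in each category, scaled
by its yield factor ``y_j`` (regional vs reference productivity) and
equivalence factor, with a fraction set aside for biodiversity:

    PBC = (1 - set_aside) * sum_j a_j * y_j * e_j

The balance PBC - PEF is an ecological surplus when positive and a
deficit when negative.  Fossil-energy land is a hypothetical category
that absorbs CO2 from fuel combustion: it appears on the demand side
only (its default yield factor is 0), which motivates reporting two
footprint lines — PEF I excludes it, PEF II includes it.
"""
from __future__ import annotations

import json
import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .errors import (
    ConfigurationError,
    DataQualityWarning,
    ValidationError,
)

#: The six biologically productive land categories.
LAND_CATEGORIES = (
    "arable",
    "forest",
    "pasture",
    "fishery",
    "built_up",
    "fossil_energy",
)

FOSSIL = "fossil_energy"

#: Fraction of biocapacity set aside for biodiversity protection.
DEFAULT_SET_ASIDE = 0.12


def _check_category(name: str) -> str:
    if name not in LAND_CATEGORIES:
        raise ConfigurationError(
            f"unknown land category {name!r}; expected one of {LAND_CATEGORIES}"
        )
    return name


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FactorTable:
    """Yield and equivalence factors per land category.

    ``yield_factors`` (y_j, dimensionless) compare the region's
    productivity in a category with the reference average;
    ``equivalence_factors`` (e_j, dimensionless, > 0) compare a
    category's average productivity with the all-land average.
    """

    yield_factors: Mapping[str, float]
    equivalence_factors: Mapping[str, float]

    def __post_init__(self) -> None:
        for cat in self.yield_factors:
            _check_category(cat)
        for cat, e in self.equivalence_factors.items():
            _check_category(cat)
            if not e > 0:
                raise ValidationError(
                    f"equivalence factor for {cat!r} must be > 0, got {e}"
                )
        for cat, y in self.yield_factors.items():
            if y < 0:
                raise ValidationError(
                    f"yield factor for {cat!r} must be >= 0, got {y}"
                )

    def y(self, category: str) -> float:
        try:
            return float(self.yield_factors[category])
        except KeyError:
            raise ConfigurationError(
                f"no yield factor for land category {category!r}"
            ) from None

    def e(self, category: str) -> float:
        try:
            return float(self.equivalence_factors[category])
        except KeyError:
            raise ConfigurationError(
                f"no equivalence factor for land category {category!r}"
            ) from None

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(c for c in LAND_CATEGORIES if c in self.equivalence_factors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "land_category": list(self.categories),
                "yield_factor": [self.y(c) for c in self.categories],
                "equivalence_factor": [self.e(c) for c in self.categories],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FactorTable":
        required = {"land_category", "yield_factor", "equivalence_factor"}
        if not required.issubset(frame.columns):
            raise ValidationError(
                f"factor table needs columns {sorted(required)}"
            )
        return cls(
            yield_factors=dict(
                zip(frame["land_category"], frame["yield_factor"].astype(float))
            ),
            equivalence_factors=dict(
                zip(
                    frame["land_category"],
                    frame["equivalence_factor"].astype(float),
                )
            ),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FactorTable":
        return cls.from_frame(pd.read_csv(path))


def _read_population(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path)
    if not {"year", "population"}.issubset(frame.columns):
        raise ValidationError("population table needs columns year,population")
    pop = frame.set_index("year")["population"].astype(float).sort_index()
    return pop


def _validate_population(population: pd.Series) -> pd.Series:
    population = population.astype(float).sort_index()
    if (population <= 0).any():
        raise ValidationError("population must be strictly positive every year")
    return population


@dataclass(frozen=True)
class ItemRegistry:
    """Maps each consumption item to its land category and world yield."""

    table: pd.DataFrame  # index item_id; columns land_category, world_yield

    def __post_init__(self) -> None:
        for cat in self.table["land_category"]:
            _check_category(cat)
        if (self.table["world_yield"] <= 0).any():
            raise ValidationError("world yields must be strictly positive")

    def category(self, item_id: str) -> str:
        try:
            return str(self.table.loc[item_id, "land_category"])
        except KeyError:
            raise ConfigurationError(f"item {item_id!r} not in registry") from None

    def world_yield(self, item_id: str) -> float:
        try:
            return float(self.table.loc[item_id, "world_yield"])
        except KeyError:
            raise ConfigurationError(f"item {item_id!r} not in registry") from None

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ItemRegistry":
        frame = pd.read_csv(path)
        required = {"item_id", "land_category", "world_yield_kg_per_ha"}
        if not required.issubset(frame.columns):
            raise ValidationError(f"item table needs columns {sorted(required)}")
        table = frame.rename(
            columns={"world_yield_kg_per_ha": "world_yield"}
        ).set_index("item_id")[["land_category", "world_yield"]]
        return cls(table)

    def to_csv(self, path: str | Path) -> None:
        out = self.table.rename(
            columns={"world_yield": "world_yield_kg_per_ha"}
        ).reset_index()
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class ConsumptionPanel:
    """Year x item flows (production, imports, exports) plus population."""

    flows: pd.DataFrame  # columns year,item_id,production,imports,exports
    population: pd.Series  # index year

    def __post_init__(self) -> None:
        required = {"year", "item_id", "production", "imports", "exports"}
        if not required.issubset(self.flows.columns):
            raise ValidationError(
                f"consumption panel needs columns {sorted(required)}"
            )
        for col in ("production", "imports", "exports"):
            if (self.flows[col] < 0).any():
                raise ValidationError(f"negative {col} in consumption panel")
        object.__setattr__(
            self, "population", _validate_population(self.population)
        )
        missing = set(self.flows["year"]) - set(self.population.index)
        if missing:
            raise ValidationError(
                f"no population for years {sorted(missing)}"
            )

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(set(int(y) for y in self.flows["year"])))

    @classmethod
    def from_csv(
        cls, flows_path: str | Path, population_path: str | Path
    ) -> "ConsumptionPanel":
        frame = pd.read_csv(flows_path)
        frame = frame.rename(
            columns={
                "production_kg": "production",
                "imports_kg": "imports",
                "exports_kg": "exports",
            }
        )
        return cls(frame, _read_population(population_path))

    def to_csv(self, flows_path: str | Path, population_path: str | Path) -> None:
        out = self.flows.rename(
            columns={
                "production": "production_kg",
                "imports": "imports_kg",
                "exports": "exports_kg",
            }
        )
        out.to_csv(flows_path, index=False)
        self.population.rename("population").reset_index().to_csv(
            population_path, index=False
        )


@dataclass(frozen=True)
class AreaPanel:
    """Year x land-category total areas (ha) plus population.

    Biocapacity is per capita, so total areas are divided by the same
    year's population before entering the supply formula.
    """

    areas: pd.DataFrame  # columns year,land_category,total_area_ha
    population: pd.Series  # index year

    def __post_init__(self) -> None:
        required = {"year", "land_category", "total_area_ha"}
        if not required.issubset(self.areas.columns):
            raise ValidationError(f"area panel needs columns {sorted(required)}")
        for cat in self.areas["land_category"]:
            _check_category(cat)
        if (self.areas["total_area_ha"] < 0).any():
            raise ValidationError("negative area in area panel")
        object.__setattr__(
            self, "population", _validate_population(self.population)
        )
        missing = set(self.areas["year"]) - set(self.population.index)
        if missing:
            raise ValidationError(f"no population for years {sorted(missing)}")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(set(int(y) for y in self.areas["year"])))

    def per_capita(self) -> pd.DataFrame:
        """Per-capita area a_j (ha/ca) as a year x category grid."""
        grid = self.areas.pivot_table(
            index="year", columns="land_category", values="total_area_ha",
            aggfunc="sum", fill_value=0.0,
        )
        return grid.div(self.population.loc[grid.index], axis=0)

    @classmethod
    def from_csv(
        cls, areas_path: str | Path, population_path: str | Path
    ) -> "AreaPanel":
        return cls(pd.read_csv(areas_path), _read_population(population_path))

    def to_csv(self, areas_path: str | Path) -> None:
        self.areas.to_csv(areas_path, index=False)


@dataclass(frozen=True)
class FootprintLedger:
    """Per-(year, category) footprint/biocapacity grid with yearly totals.

    ``cells`` holds one row per (year, land_category) with columns
    ``pef``, ``pbc`` and ``balance`` (= pbc - pef), all in ha/ca.
    ``totals`` is indexed by year with columns ``pef_I`` (excluding
    fossil-energy land), ``pef_II`` (including it), ``pbc``,
    ``balance_I`` and ``balance_II``.
    """

    cells: pd.DataFrame
    totals: pd.DataFrame

    @classmethod
    def from_cells(cls, cells: pd.DataFrame) -> "FootprintLedger":
        required = {"year", "land_category", "pef", "pbc", "balance"}
        if not required.issubset(cells.columns):
            raise ValidationError(f"ledger needs columns {sorted(required)}")
        cells = cells.sort_values(["year", "land_category"]).reset_index(drop=True)
        by_year = cells.groupby("year")
        pef_ii = by_year["pef"].sum()
        fossil = (
            cells[cells["land_category"] == FOSSIL]
            .set_index("year")["pef"]
            .reindex(pef_ii.index, fill_value=0.0)
        )
        totals = pd.DataFrame(
            {
                "pef_I": pef_ii - fossil,
                "pef_II": pef_ii,
                "pbc": by_year["pbc"].sum(),
            }
        )
        totals["balance_I"] = totals["pbc"] - totals["pef_I"]
        totals["balance_II"] = totals["pbc"] - totals["pef_II"]
        return cls(cells, totals)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(int(y) for y in self.totals.index)

    def series(self, category: str, field: str = "balance") -> pd.Series:
        """One category's yearly pef/pbc/balance as a year-indexed series."""
        _check_category(category)
        sub = self.cells[self.cells["land_category"] == category]
        return sub.set_index("year")[field].sort_index()

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "ledger.csv", index=False)
        self.totals.reset_index().rename(columns={"index": "year"}).to_csv(
            outdir / "totals.csv", index=False
        )
        payload = {
            "cells": self.cells.to_dict(orient="records"),
            "totals": {
                str(year): {k: float(v) for k, v in row.items()}
                for year, row in self.totals.iterrows()
            },
        }
        (outdir / "ledger.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def read(cls, ledger_csv: str | Path) -> "FootprintLedger":
        return cls.from_cells(pd.read_csv(ledger_csv))


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def per_capita_consumption(
    production: float, imports: float, exports: float, population: float
) -> float:
    """Annual per-capita consumption C = (P + I - E) / p.

    A negative result (the region exports more of the item than it
    produces and imports) is returned as-is with a
    :class:`DataQualityWarning`; aggregation floors it at zero.
    """
    if population <= 0:
        raise ValidationError(f"population must be > 0, got {population}")
    c = (production + imports - exports) / population
    if c < 0:
        warnings.warn(
            f"net consumption is negative ({c:.6g} per capita): "
            "the region is a net exporter of this item",
            DataQualityWarning,
            stacklevel=2,
        )
    return c


def component_footprint(consumption: float, world_yield: float) -> float:
    """Biologically productive area per capita aa = C / W (ha/ca)."""
    if world_yield <= 0:
        raise ValidationError(f"world yield must be > 0, got {world_yield}")
    return consumption / world_yield


class EFResult(NamedTuple):
    total: float
    by_category: dict[str, float]


def per_capita_ef(
    components: Mapping[str, Iterable[float]],
    factors: FactorTable,
    include_fossil: bool = True,
) -> EFResult:
    """Equivalence-weighted footprint PEF = sum_j e_j * sum_i aa_i.

    ``components`` maps each land category to the item areas aa_i
    belonging to it.  With ``include_fossil=False`` the fossil-energy
    category is left out of both the total and the breakdown (the
    "PEF I" line); with ``True`` it is included ("PEF II").
    """
    by_category: dict[str, float] = {}
    for category, areas in components.items():
        _check_category(category)
        if category == FOSSIL and not include_fossil:
            continue
        by_category[category] = factors.e(category) * float(sum(areas))
    return EFResult(sum(by_category.values()), by_category)


class BCResult(NamedTuple):
    total: float
    by_category: dict[str, float]


def per_capita_bc(
    areas: Mapping[str, float],
    factors: FactorTable,
    set_aside: float = DEFAULT_SET_ASIDE,
) -> BCResult:
    """Biocapacity PBC = (1 - set_aside) * sum_j a_j * y_j * e_j.

    ``areas`` maps land categories to per-capita areas a_j (ha/ca).
    The set-aside fraction (default 12%) is withheld for biodiversity
    protection; the per-category breakdown carries the same factor so
    it sums to the total.
    """
    if not 0 <= set_aside < 1:
        raise ValidationError(f"set_aside must be in [0, 1), got {set_aside}")
    by_category: dict[str, float] = {}
    for category, a in areas.items():
        _check_category(category)
        if a < 0:
            raise ValidationError(f"negative area for {category!r}: {a}")
        by_category[category] = (
            (1.0 - set_aside) * a * factors.y(category) * factors.e(category)
        )
    return BCResult(sum(by_category.values()), by_category)


class Balance(NamedTuple):
    value: float
    label: str  # "surplus" | "deficit" | "balanced"


def ecological_balance(pbc: float, pef: float) -> Balance:
    """Signed balance PBC - PEF: surplus if positive, deficit if negative."""
    value = pbc - pef
    if value > 0:
        label = "surplus"
    elif value < 0:
        label = "deficit"
    else:
        label = "balanced"
    return Balance(value, label)


def change_in_area(
    series: pd.Series, start_year: int, end_year: int
) -> float:
    """Absolute change value(end) - value(start) of a yearly series."""
    for year in (start_year, end_year):
        if year not in series.index:
            raise ValidationError(f"year {year} missing from series")
    return float(series.loc[end_year] - series.loc[start_year])


def annual_intensity(
    series: pd.Series, start_year: int, end_year: int
) -> float:
    """Compound annual growth rate of a yearly series between two years.

    Returns (v_end / v_start)^(1/(end-start)) - 1.  This is one of
    several possible "annual change in intensity" conventions; it is
    the one this package commits to and documents.
    """
    if end_year <= start_year:
        raise ValidationError("end_year must be after start_year")
    for year in (start_year, end_year):
        if year not in series.index:
            raise ValidationError(f"year {year} missing from series")
    v0 = float(series.loc[start_year])
    if v0 <= 0:
        raise ValidationError(f"start value must be > 0, got {v0}")
    v1 = float(series.loc[end_year])
    return (v1 / v0) ** (1.0 / (end_year - start_year)) - 1.0


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_efa(
    consumption: ConsumptionPanel,
    areas: AreaPanel,
    items: ItemRegistry,
    factors: FactorTable,
    set_aside: float = DEFAULT_SET_ASIDE,
) -> FootprintLedger:
    """Full footprint account: panels in, year x category ledger out.

    Both panels must cover the same years and every item in the
    consumption panel must be mapped in the registry.  Negative net
    consumption contributes zero demand (the warning from
    :func:`per_capita_consumption` still fires).
    """
    if not 0 <= set_aside < 1:
        raise ValidationError(f"set_aside must be in [0, 1), got {set_aside}")
    # an empty flow table means zero demand in every area-panel year
    years = consumption.years or areas.years
    if set(years) != set(areas.years):
        raise ConfigurationError(
            "consumption and area panels cover different years: "
            f"{consumption.years} vs {areas.years}"
        )
    unmapped = set(consumption.flows["item_id"]) - set(items.item_ids)
    if unmapped:
        raise ConfigurationError(f"unmapped items: {sorted(unmapped)}")

    percap_area = areas.per_capita()
    rows = []
    for year in years:
        pop = float(consumption.population.loc[year])
        demand: dict[str, float] = defaultdict(float)
        year_flows = consumption.flows[consumption.flows["year"] == year]
        for flow in year_flows.itertuples(index=False):
            c = per_capita_consumption(
                float(flow.production),
                float(flow.imports),
                float(flow.exports),
                pop,
            )
            aa = component_footprint(c, items.world_yield(flow.item_id))
            # a region cannot exert negative demand on a land category
            demand[items.category(flow.item_id)] += max(aa, 0.0)
        for category in LAND_CATEGORIES:
            pef_cat = factors.e(category) * demand.get(category, 0.0)
            a_j = (
                float(percap_area.loc[year, category])
                if category in percap_area.columns
                else 0.0
            )
            pbc_cat = (
                (1.0 - set_aside) * a_j * factors.y(category) * factors.e(category)
            )
            rows.append(
                {
                    "year": year,
                    "land_category": category,
                    "pef": pef_cat,
                    "pbc": pbc_cat,
                    "balance": pbc_cat - pef_cat,
                }
            )
    return FootprintLedger.from_cells(pd.DataFrame(rows))
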