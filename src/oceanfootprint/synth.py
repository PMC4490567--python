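"""Synthetic world generation.

The analyses in this package were designed for global mapped-catch, trade,
primary-production and population data sets. None of those can ship with the
code, so this module builds self-consistent synthetic stand-ins with retained
ground truth:

* annual primary-production (PP) fields on a :class:`~oceanfootprint.grid.GridDefinition`,
* countries with contiguous EEZ blocks, coastal cells and ports,
* per-cell catch records with taxon trophic levels, calibrated so that the
  implied primary production required (PPR) is a known fraction of PP,
* export/import flows with exact provenance back to catch cells,
* population trajectories linearly linked to seafood consumption.

Every generator is a pure function of its arguments including ``seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import GridDefinition, coastal_sea_cells

logger = logging.getLogger(__name__)

# The canonical trophic back-calculation constants used for calibration:
# 9 t wet weight per t carbon, 10% transfer efficiency per trophic step.
CALIBRATION_CR = 9.0
CALIBRATION_TE = 0.1

HIGH_SEAS = -1


@dataclass
class PPFieldSet:
    """Annual primary production per grid cell, tonnes C per cell per year."""

    values: np.ndarray  # (n_years, n_cells); zero on land
    years: np.ndarray

    @property
    def mean_per_cell(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def sd_per_cell(self) -> np.ndarray:
        sd = self.values.std(axis=0, ddof=0)
        sd[np.ptp(self.values, axis=0) == 0] = 0.0  # exact when years identical
        return sd

    def annual_totals(self, cell_mask: np.ndarray | None = None) -> np.ndarray:
        """Total PP per year, optionally restricted to a boolean cell mask."""
        v = self.values if cell_mask is None else self.values[:, cell_mask]
        return v.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long format (year, cell_id, pp) for CSV export."""
        n_years, n_cells = self.values.shape
        return pd.DataFrame(
            {
                "year": np.repeat(self.years, n_cells),
                "cell_id": np.tile(np.arange(n_cells), n_years),
                "pp": self.values.reshape(-1),
            }
        )


@dataclass
class WorldState:
    """Countries, EEZ assignment, ports, taxa and population."""

    countries: list[str]
    eez: np.ndarray  # cell_id -> country index, HIGH_SEAS for none
    ports: pd.DataFrame  # columns: country, lat, lon
    coastal: dict[str, np.ndarray]  # country -> coastal cell_ids
    taxa: dict[str, float]  # taxon -> trophic level
    population: pd.DataFrame  # columns: country, year, persons

    def eez_cells(self, country: str) -> np.ndarray:
        idx = self.countries.index(country)
        return np.flatnonzero(self.eez == idx)

    def country_of_cell(self, cell_id: int) -> str | None:
        idx = self.eez[cell_id]
        return None if idx == HIGH_SEAS else self.countries[idx]

    def ports_of(self, country: str) -> pd.DataFrame:
        return self.ports[self.ports["country"] == country]


@dataclass
class CatchTable:
    """Wild-capture landings: (year, cell_id, taxon, country, tonnage)."""

    records: pd.DataFrame

    @property
    def n_taxa(self) -> int:
        return int(self.records["taxon"].nunique())

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.records["year"].unique())

    def total_tonnage(self) -> float:
        return float(self.records["tonnage"].sum())


@dataclass
class TradeTable:
    """Export flows plus ground-truth provenance.

    ``trades`` has one row per (year, exporter, importer, source_kind, taxon)
    flow; ``provenance`` links each wild record_id to originating cells (and
    each mariculture record to its origin country) with tonnage split.
    """

    trades: pd.DataFrame  # record_id, year, exporter, importer, source_kind, taxon, tonnage
    provenance: pd.DataFrame  # record_id, cell_id, origin_country, tonnage

    def wild(self) -> pd.DataFrame:
        return self.trades[self.trades["source_kind"] == "wild"]

    def mariculture(self) -> pd.DataFrame:
        return self.trades[self.trades["source_kind"] == "mariculture"]


@dataclass
class PopulationScenarios:
    """Global population scenarios and historical consumption.

    ``history`` carries the fitting window (year, population, consumption in
    tonnes/yr); ``scenarios`` the low/median/high projected populations.
    """

    history: pd.DataFrame
    scenarios: pd.DataFrame  # scenario, year, population
    history_end: int

    def scenario(self, label: str) -> pd.DataFrame:
        return self.scenarios[self.scenarios["scenario"] == label]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_pp_fields(
    grid: GridDefinition,
    years: int | Sequence[int],
    mean_pp: float = 140.0,
    spatial_cv: float = 0.5,
    interannual_cv: float = 0.05,
    seed: int = 0,
) -> PPFieldSet:
    """Generate annual PP fields with lognormal spatial pattern.

    ``mean_pp`` is an areal productivity in tonnes C km^-2 yr^-1 (the global
    ocean mean is ~140); per-cell annual PP is ``density * area`` where the
    densities are lognormal with mean ``mean_pp`` and coefficient of
    variation ``spatial_cv``, and each year multiplies the cell base by an
    independent lognormal factor with mean 1 and cv ``interannual_cv``.
    Both cvs at zero give exactly ``mean_pp * area`` everywhere at sea.
    """
    if spatial_cv < 0 or interannual_cv < 0:
        raise ValueError("coefficients of variation must be >= 0")
    if mean_pp <= 0:
        raise ValueError("mean_pp must be positive")
    sea = grid.table["sea_mask"].to_numpy()
    if not sea.any():
        raise ValueError("grid has no sea cells")

    if isinstance(years, (int, np.integer)):
        year_labels = np.arange(int(years))
    else:
        year_labels = np.asarray(list(years), dtype=int)
    if year_labels.size < 1:
        raise ValueError("need at least one year")

    rng = np.random.default_rng(seed)
    n_cells = len(grid.table)
    area = grid.table["area_km2"].to_numpy()

    density = np.full(n_cells, mean_pp)
    if spatial_cv > 0:
        sigma2 = np.log1p(spatial_cv**2)
        mu = np.log(mean_pp) - sigma2 / 2.0
        density = rng.lognormal(mu, np.sqrt(sigma2), size=n_cells)
    base = density * area
    base[~sea] = 0.0

    values = np.tile(base, (year_labels.size, 1))
    if interannual_cv > 0:
        sigma2 = np.log1p(interannual_cv**2)
        eps = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=values.shape)
        values = values * eps
    return PPFieldSet(values=values, years=year_labels)


def generate_world(
    grid: GridDefinition,
    n_countries: int,
    taxa_spec: Sequence[tuple[str, float]],
    seed: int = 0,
    eez_fraction: float = 0.7,
    ports_per_country: int = 2,
    years: Sequence[int] | None = None,
    base_pop_range: tuple[float, float] = (1e6, 1e8),
    pop_growth: float = 0.01,
) -> WorldState:
    """Partition sea cells into contiguous country EEZ blocks and place ports.

    Sea cells are ordered column-major (west to east) and the first
    ``eez_fraction`` of them are split into ``n_countries`` contiguous
    stripes; the remainder is high seas. Ports sit on coastal cell centres
    (every country keeps at least one). Per-country populations follow
    smooth exponential growth from a log-uniform base.
    """
    if n_countries < 1:
        raise ValueError("n_countries must be >= 1")
    taxa = {}
    for name, tl in taxa_spec:
        tl = float(tl)
        if not 1.0 <= tl <= 5.0:
            raise ValueError(f"trophic level of {name!r} out of [1, 5]: {tl}")
        taxa[str(name)] = tl
    if not taxa:
        raise ValueError("taxa_spec must list at least one taxon")
    if not 0.0 < eez_fraction <= 1.0:
        raise ValueError("eez_fraction must be in (0, 1]")

    rng = np.random.default_rng(seed)
    sea_ids = grid.sea_cells
    if sea_ids.size == 0:
        raise ValueError("grid has no sea cells")

    # column-major order -> longitudinally contiguous stripes per country
    rows, cols = grid.rowcol(sea_ids)
    order = np.lexsort((rows, cols))
    ordered = sea_ids[order]
    n_eez = max(n_countries, int(np.ceil(eez_fraction * ordered.size)))
    n_eez = min(n_eez, ordered.size)
    if n_countries > n_eez:
        raise ValueError(
            f"cannot assign {n_countries} countries to {n_eez} EEZ-eligible cells"
        )
    eez_ids = ordered[:n_eez]

    countries = [f"C{i:02d}" for i in range(n_countries)]
    eez = np.full(len(grid.table), HIGH_SEAS, dtype=int)
    for idx, block in enumerate(np.array_split(eez_ids, n_countries)):
        eez[block] = idx

    coastal_all = set(coastal_sea_cells(grid).tolist())
    coastal: dict[str, np.ndarray] = {}
    port_rows = []
    for idx, country in enumerate(countries):
        cells = np.flatnonzero(eez == idx)
        cst = np.array(sorted(set(cells.tolist()) & coastal_all), dtype=int)
        if cst.size == 0:
            cst = cells  # land-free stripe: treat the whole EEZ as coastal
        coastal[country] = cst
        n_ports = min(max(1, ports_per_country), cst.size)
        port_cells = rng.choice(cst, size=n_ports, replace=False)
        plat, plon = grid.cell_latlon(port_cells)
        for la, lo in zip(plat, plon):
            port_rows.append((country, float(la), float(lo)))
    ports = pd.DataFrame(port_rows, columns=["country", "lat", "lon"])

    if years is None:
        years = [0]
    years = np.asarray(list(years), dtype=int)
    lo, hi = base_pop_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_countries))
    growth = (1.0 + pop_growth) ** (years - years.min())
    population = pd.DataFrame(
        {
            "country": np.repeat(countries, years.size),
            "year": np.tile(years, n_countries),
            "persons": np.repeat(base, years.size) * np.tile(growth, n_countries),
        }
    )
    return WorldState(
        countries=countries,
        eez=eez,
        ports=ports,
        coastal=coastal,
        taxa=taxa,
        population=population,
    )


def generate_catches(
    world: WorldState,
    grid: GridDefinition,
    pp: PPFieldSet,
    years: Sequence[int],
    effort_trend: float = 0.0,
    target_ppr_fraction: float = 0.1,
    seed: int = 0,
    coverage: float = 1.0,
    max_taxa_per_cell: int = 3,
) -> CatchTable:
    """Place catches in EEZ cells calibrated to a known PPR/PP ratio.

    In each seeded cell the first-year tonnage is chosen so that the implied
    PPR (at the calibration constants CR=9, TE=0.1) equals
    ``target_ppr_fraction`` times the cell's multi-year mean PP:

        C_i = share_i * target * PP_mean * CR * TE^(TL_i - 1)

    Later years multiply every tonnage by ``(1 + effort_trend)^(y - y0)``,
    so the footprint grows (or shrinks) geometrically while the spatial
    pattern stays fixed — the knob behind rising exploitation trends.
    """
    if not 0.0 < target_ppr_fraction < 1.0:
        raise ValueError("target_ppr_fraction must be in (0, 1)")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    years = np.asarray(list(years), dtype=int)
    if years.size == 0:
        raise ValueError("years must be non-empty")
    eligible = np.flatnonzero(world.eez != HIGH_SEAS)
    if eligible.size == 0 or not world.taxa:
        raise ValueError("world has no EEZ cells or no taxa")

    rng = np.random.default_rng(seed)
    if coverage < 1.0:
        n_keep = max(1, int(round(coverage * eligible.size)))
        eligible = np.sort(rng.choice(eligible, size=n_keep, replace=False))

    pp_mean = pp.mean_per_cell
    taxa_names = list(world.taxa)
    tls = np.array([world.taxa[t] for t in taxa_names])

    cell_col, taxon_col, base_col = [], [], []
    for cell in eligible:
        k = int(rng.integers(1, min(max_taxa_per_cell, len(taxa_names)) + 1))
        chosen = rng.choice(len(taxa_names), size=k, replace=False)
        shares = rng.dirichlet(np.ones(k))
        budget = target_ppr_fraction * pp_mean[cell]
        tonnage = (
            shares * budget * CALIBRATION_CR * CALIBRATION_TE ** (tls[chosen] - 1.0)
        )
        cell_col.extend([cell] * k)
        taxon_col.extend([taxa_names[j] for j in chosen])
        base_col.extend(tonnage.tolist())

    cell_arr = np.array(cell_col, dtype=int)
    base_arr = np.array(base_col)
    country_idx = world.eez[cell_arr]
    country_arr = np.array(world.countries, dtype=object)[country_idx]

    mult = (1.0 + effort_trend) ** (years - years.min())
    n_base = cell_arr.size
    records = pd.DataFrame(
        {
            "year": np.repeat(years, n_base),
            "cell_id": np.tile(cell_arr, years.size),
            "taxon": np.tile(np.array(taxon_col, dtype=object), years.size),
            "country": np.tile(country_arr, years.size),
            "tonnage": np.tile(base_arr, years.size) * np.repeat(mult, n_base),
        }
    )
    return CatchTable(records=records)


def generate_trade(
    world: WorldState,
    catches: CatchTable,
    mariculture_by_country: Mapping[str, float] | None = None,
    export_fraction: float = 0.3,
    seed: int = 0,
) -> TradeTable:
    """Export a fixed fraction of each country's production with provenance.

    Each catch record exports ``export_fraction`` of its tonnage to one
    importer drawn (population-weighted) among the other countries, so the
    per-(year, exporter, taxon) conservation bound holds record by record.
    Mariculture production exports the same fraction; its provenance is the
    origin country. The untraded remainder is domestic consumption.
    """
    if not 0.0 <= export_fraction <= 1.0:
        raise ValueError("export_fraction must be in [0, 1]")
    mariculture_by_country = dict(mariculture_by_country or {})
    for c, v in mariculture_by_country.items():
        if v < 0:
            raise ValueError(f"negative mariculture production for {c}")

    cols = ["record_id", "year", "exporter", "importer", "source_kind", "taxon", "tonnage"]
    pcols = ["record_id", "cell_id", "origin_country", "tonnage"]
    if export_fraction == 0.0 or len(world.countries) < 2:
        if export_fraction > 0 and len(world.countries) < 2:
            logger.warning("single-country world: no trade partners, empty trade table")
        return TradeTable(
            trades=pd.DataFrame(columns=cols), provenance=pd.DataFrame(columns=pcols)
        )

    rng = np.random.default_rng(seed)
    pop_mean = world.population.groupby("country")["persons"].mean()
    countries = np.array(world.countries, dtype=object)

    def draw_importers(exporters: np.ndarray) -> np.ndarray:
        """One importer per row, population-weighted, never the exporter."""
        out = np.empty(exporters.size, dtype=object)
        for exp in np.unique(exporters):
            others = countries[countries != exp]
            w = pop_mean.reindex(others).to_numpy()
            w = w / w.sum()
            mask = exporters == exp
            out[mask] = rng.choice(others, size=int(mask.sum()), p=w)
        return out

    rec = catches.records
    wild = rec.assign(
        importer=draw_importers(rec["country"].to_numpy()),
        traded=rec["tonnage"].to_numpy() * export_fraction,
    )
    wild = wild[wild["traded"] > 0]

    grouped = (
        wild.groupby(["year", "country", "importer", "taxon"], sort=True)["traded"]
        .sum()
        .reset_index()
        .rename(columns={"country": "exporter", "traded": "tonnage"})
    )
    grouped.insert(0, "record_id", np.arange(len(grouped)))
    grouped["source_kind"] = "wild"

    key = ["year", "country", "importer", "taxon"]
    prov = (
        wild.merge(
            grouped.rename(columns={"exporter": "country", "tonnage": "rec_total"}),
            on=key,
        )
        .groupby(["record_id", "cell_id"], sort=True)["traded"]
        .sum()
        .reset_index()
        .rename(columns={"traded": "tonnage"})
    )
    prov["origin_country"] = ""

    mrows, mprov = [], []
    rid = len(grouped)
    years = catches.years
    for country in sorted(mariculture_by_country):
        prod = mariculture_by_country[country]
        exported = prod * export_fraction
        if exported <= 0:
            continue
        importers = draw_importers(np.array([country] * years.size, dtype=object))
        for y, imp in zip(years, importers):
            mrows.append((rid, int(y), country, imp, "mariculture", "mariculture", exported))
            mprov.append((rid, -1, country, exported))
            rid += 1

    trade_parts = [df for df in (
        grouped[cols] if len(grouped) else None,
        pd.DataFrame(mrows, columns=cols) if mrows else None,
    ) if df is not None]
    prov_parts = [df for df in (
        prov[pcols] if len(prov) else None,
        pd.DataFrame(mprov, columns=pcols) if mprov else None,
    ) if df is not None]
    trades = (pd.concat(trade_parts, ignore_index=True)
              if trade_parts else pd.DataFrame(columns=cols))
    provenance = (pd.concat(prov_parts, ignore_index=True)
                  if prov_parts else pd.DataFrame(columns=pcols))
    return TradeTable(trades=trades, provenance=provenance)


def generate_population(
    base_pop: float,
    growth_rates: Mapping[str, float],
    consumption_intercept: float,
    consumption_slope: float,
    noise_sd: float,
    years: Sequence[int],
    seed: int = 0,
    history_end: int | None = None,
) -> PopulationScenarios:
    """Population scenarios with linearly linked historical consumption.

    All three scenarios share the median growth path through the historical
    window (ending at ``history_end``, default three-quarters through the
    span) and diverge only afterwards. Historical consumption is
    ``intercept + slope * population + N(0, noise_sd)``.
    """
    if base_pop <= 0:
        raise ValueError("base population must be positive")
    for k in ("low", "median", "high"):
        if k not in growth_rates:
            raise ValueError(f"growth_rates must define {k!r}")
    g = {k: float(v) for k, v in growth_rates.items()}
    if not g["high"] >= g["median"] >= g["low"]:
        raise ValueError("growth rates must satisfy high >= median >= low")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    years = np.asarray(list(years), dtype=int)
    y0 = int(years.min())
    if history_end is None:
        history_end = int(years[int(0.75 * (years.size - 1))])
    if history_end < y0:
        raise ValueError("history_end before first year")

    rng = np.random.default_rng(seed)
    hist_years = years[years <= history_end]
    if hist_years.size < 3:
        raise ValueError("historical window must span at least 3 years")

    pop_hist = base_pop * (1.0 + g["median"]) ** (hist_years - y0)
    consumption = (
        consumption_intercept
        + consumption_slope * pop_hist
        + (rng.normal(0.0, noise_sd, size=hist_years.size) if noise_sd > 0 else 0.0)
    )
    history = pd.DataFrame(
        {"year": hist_years, "population": pop_hist, "consumption": consumption}
    )

    frames = []
    pop_end = pop_hist[-1]
    for label in ("low", "median", "high"):
        pop = np.where(
            years <= history_end,
            base_pop * (1.0 + g["median"]) ** (years - y0),
            pop_end * (1.0 + g[label]) ** np.maximum(years - history_end, 0),
        )
        frames.append(pd.DataFrame({"scenario": label, "year": years, "population": pop}))
    scenarios = pd.concat(frames, ignore_index=True)
    return PopulationScenarios(
        history=history, scenarios=scenarios, history_end=int(history_end)
    )
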