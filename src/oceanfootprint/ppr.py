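"""Primary production required (PPR) footprint analysis.

The footprint of a catch is the photosynthetic carbon needed to grow it,
back-calculated through the food web:

    PPR = sum_i (C_i / CR) * (1 / TE)^(TL_i - 1)

with C_i the wet-weight catch of taxon i, CR the wet-weight-to-carbon
conversion ratio (9:1), TE the trophic transfer efficiency (10%) and TL_i
the taxon's trophic level (primary producers at 1). Dividing by the local
primary production PP gives an exploitation intensity; classifying cells
into ratio bands and summing their areas tracks how much ocean is fished at
10–20%, 20–30% and >=30% of its productivity, while restricting both sums to
accessible water (< 1000 m deep) gives the share of usable ocean production
diverted to seafood. A Monte Carlo layer propagates uncertainty in TE and in
the global PP level into that percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridDefinition
from .synth import CatchTable, PPFieldSet, WorldState, HIGH_SEAS

DEFAULT_DEPTH_LIMIT_M = 1000.0
BAND_THRESHOLDS = (0.10, 0.20, 0.30)
BAND_LABELS = ("area_10_20", "area_20_30", "area_ge30")


@dataclass(frozen=True)
class PPRParams:
    """Trophic back-calculation constants.

    cr: wet weight to carbon conversion ratio (9:1).
    te: transfer efficiency between trophic levels (canonical 10%).
    """

    cr: float = 9.0
    te: float = 0.10

    def __post_init__(self) -> None:
        if self.cr <= 0:
            raise ValueError("CR must be positive")
        if not 0.0 < self.te < 1.0:
            raise ValueError("TE must be in (0, 1)")


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings for the accessible-percentage uncertainty.

    TE is drawn from a truncated normal (mean 10%, s.d. 3.03 percentage
    points — the approximate 90% band from 5 to 15%); the global PP level
    from a normal with the mean and s.d. of the annual accessible-ocean PP
    totals.
    """

    n_trials: int = 1000
    te_mean: float = 0.10
    te_sd: float = 0.0303
    te_bounds: tuple[float, float] = (0.05, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        lo, hi = self.te_bounds
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("te_bounds must keep TE inside (0, 1)")


@dataclass
class MCResult:
    median: float
    ci_low: float
    ci_high: float
    trials: np.ndarray
    degenerate_pp_pool: bool = False


def _record_ppr(
    catches: pd.DataFrame, taxa: dict[str, float], params: PPRParams
) -> np.ndarray:
    """Per-record PPR in tonnes C; vectorised over the catch table."""
    taxa_ser = pd.Series(taxa, dtype=float)
    unknown = set(catches["taxon"]) - set(taxa_ser.index)
    if unknown:
        raise KeyError(f"taxa without trophic level: {sorted(unknown)}")
    if (taxa_ser < 1.0).any():
        bad = taxa_ser[taxa_ser < 1.0].index.tolist()
        raise ValueError(f"trophic level < 1 for {bad}")
    if (catches["tonnage"] < 0).any():
        raise ValueError("negative tonnage in catch table")
    tl = taxa_ser.reindex(catches["taxon"]).to_numpy()
    return (catches["tonnage"].to_numpy() / params.cr) * (1.0 / params.te) ** (tl - 1.0)


def compute_ppr(
    catches: CatchTable,
    taxa: dict[str, float],
    params: PPRParams = PPRParams(),
    group_by: str = "global",
    world: WorldState | None = None,
) -> float | pd.Series:
    """Aggregate PPR (tonnes C / yr) globally, per cell or per EEZ.

    ``group_by='cell'`` returns a Series indexed by cell_id, ``'eez'`` a
    Series indexed by country (high-seas catches under the fishing country's
    label is handled upstream: grouping here uses the cell's EEZ owner and
    drops high-seas cells), ``'global'`` a float. Sums are additive over
    disjoint groups by construction.
    """
    rec = catches.records
    ppr = _record_ppr(rec, taxa, params)
    if group_by == "global":
        return float(ppr.sum())
    if group_by == "cell":
        return pd.Series(ppr).groupby(rec["cell_id"].to_numpy()).sum().rename("ppr")
    if group_by == "eez":
        if world is None:
            raise ValueError("group_by='eez' requires a WorldState")
        owner = world.eez[rec["cell_id"].to_numpy()]
        keep = owner != HIGH_SEAS
        labels = np.array(world.countries, dtype=object)[owner[keep]]
        return pd.Series(ppr[keep]).groupby(labels).sum().rename("ppr")
    raise ValueError(f"unknown group_by: {group_by!r}")


def ratio_and_bands(
    catches: CatchTable,
    taxa: dict[str, float],
    pp: PPFieldSet,
    grid: GridDefinition,
    params: PPRParams = PPRParams(),
    thresholds: tuple[float, float, float] = BAND_THRESHOLDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(year, cell) PPR/PP ratios and exploitation-band areas per year.

    The denominator is the multi-year mean PP per cell. Band intervals are
    half-open — [0.10, 0.20), [0.20, 0.30), [0.30, inf) — so they are
    disjoint and exhaustive above the lowest threshold. Areas are reported
    in km^2 x 10^6. Cells without catch appear with ratio exactly 0.
    """
    t1, t2, t3 = thresholds
    sea = grid.table["sea_mask"].to_numpy()
    area = grid.table["area_km2"].to_numpy()
    pp_mean = pp.mean_per_cell

    rec = catches.records
    cell_ids = rec["cell_id"].to_numpy()
    if not sea[cell_ids].all():
        raise ValueError("catch recorded on a land cell")
    if (pp_mean[cell_ids] <= 0).any():
        raise ValueError("catch recorded on a zero-PP cell")

    # ratio table over the full (year x sea cell) lattice
    years = catches.years
    sea_ids = np.flatnonzero(sea)

    ppr_by = (
        rec.assign(ppr=_record_ppr(rec, taxa, params))
        .groupby(["year", "cell_id"])["ppr"]
        .sum()
    )
    full_index = pd.MultiIndex.from_product([years, sea_ids], names=["year", "cell_id"])
    ppr_full = ppr_by.reindex(full_index, fill_value=0.0)

    ratio_df = ppr_full.reset_index().rename(columns={"ppr": "ppr"})
    ratio_df["pp"] = pp_mean[ratio_df["cell_id"].to_numpy()]
    ratio_df["ratio"] = np.where(
        ratio_df["pp"] > 0, ratio_df["ppr"] / ratio_df["pp"], 0.0
    )

    cell_area = area[ratio_df["cell_id"].to_numpy()]
    r = ratio_df["ratio"].to_numpy()
    bands = pd.DataFrame(
        {
            "year": ratio_df["year"],
            BAND_LABELS[0]: np.where((r >= t1) & (r < t2), cell_area, 0.0),
            BAND_LABELS[1]: np.where((r >= t2) & (r < t3), cell_area, 0.0),
            BAND_LABELS[2]: np.where(r >= t3, cell_area, 0.0),
        }
    )
    band_areas = bands.groupby("year", as_index=False).sum()
    for col in BAND_LABELS:
        band_areas[col] = band_areas[col] / 1e6
    return ratio_df, band_areas


def _accessible_mask(grid: GridDefinition, depth_limit_m: float) -> np.ndarray:
    t = grid.table
    return (t["sea_mask"] & (t["depth_m"] < depth_limit_m)).to_numpy()


def _annual_mean_ppr_per_cell(
    catches: CatchTable, taxa: dict[str, float], params: PPRParams, n_cells: int
) -> np.ndarray:
    """Mean annual PPR per cell (tonnes C / yr) over the years present."""
    rec = catches.records
    out = np.zeros(n_cells)
    if rec.empty:
        return out
    ppr = _record_ppr(rec, taxa, params)
    sums = pd.Series(ppr).groupby(rec["cell_id"].to_numpy()).sum()
    out[sums.index.to_numpy()] = sums.to_numpy() / catches.years.size
    return out


def accessible_percentage(
    catches: CatchTable,
    taxa: dict[str, float],
    pp: PPFieldSet,
    grid: GridDefinition,
    params: PPRParams = PPRParams(),
    depth_limit_m: float = DEFAULT_DEPTH_LIMIT_M,
) -> float:
    """Share (%) of accessible-ocean PP required by the recorded catches.

    Accessible means strictly shallower than ``depth_limit_m`` (1000 m by
    default). Both numerator (annual-mean PPR) and denominator (mean PP) are
    restricted to accessible cells; deeper catches do not count and neither
    does deep-ocean productivity.
    """
    mask = _accessible_mask(grid, depth_limit_m)
    if not mask.any():
        raise ValueError("no accessible cells shallower than the depth limit")
    ppr = _annual_mean_ppr_per_cell(catches, taxa, params, len(grid.table))
    denom = float(pp.mean_per_cell[mask].sum())
    if denom <= 0:
        raise ValueError("accessible ocean has zero PP")
    return 100.0 * float(ppr[mask].sum()) / denom


def accessible_percentage_series(
    catches: CatchTable,
    taxa: dict[str, float],
    pp: PPFieldSet,
    grid: GridDefinition,
    params: PPRParams = PPRParams(),
    depth_limit_m: float = DEFAULT_DEPTH_LIMIT_M,
) -> pd.Series:
    """Accessible-ocean percentage per catch year (index: year)."""
    mask = _accessible_mask(grid, depth_limit_m)
    if not mask.any():
        raise ValueError("no accessible cells shallower than the depth limit")
    denom = float(pp.mean_per_cell[mask].sum())
    rec = catches.records
    ppr = _record_ppr(rec, taxa, params)
    in_mask = mask[rec["cell_id"].to_numpy()]
    num = (
        pd.Series(ppr[in_mask]).groupby(rec.loc[in_mask, "year"].to_numpy()).sum()
    )
    num = num.reindex(catches.years, fill_value=0.0)
    return (100.0 * num / denom).rename("accessible_percent")


def mc_accessible_percentage(
    catches: CatchTable,
    taxa: dict[str, float],
    pp: PPFieldSet,
    grid: GridDefinition,
    mc: MCConfig = MCConfig(),
    params: PPRParams = PPRParams(),
    depth_limit_m: float = DEFAULT_DEPTH_LIMIT_M,
) -> MCResult:
    """Monte Carlo uncertainty on the accessible-ocean percentage.

    Each trial draws one TE from a truncated normal and one global PP level
    from a normal over the annual accessible totals (applied as a single
    multiplicative factor — the paper-scale data only constrain the global
    level). The point estimate is the trial median; the CI the 2.5th/97.5th
    percentiles. Zero variances collapse every trial onto the deterministic
    value.
    """
    mask = _accessible_mask(grid, depth_limit_m)
    if not mask.any():
        raise ValueError("no accessible cells shallower than the depth limit")
    rng = np.random.default_rng(mc.seed)

    # catch summarised by trophic level inside the accessible mask
    rec = catches.records
    in_mask = mask[rec["cell_id"].to_numpy()]
    sub = rec[in_mask]
    taxa_ser = pd.Series(taxa, dtype=float)
    unknown = set(sub["taxon"]) - set(taxa_ser.index)
    if unknown:
        raise KeyError(f"taxa without trophic level: {sorted(unknown)}")
    tl = taxa_ser.reindex(sub["taxon"]).to_numpy()
    by_tl = (
        pd.Series(sub["tonnage"].to_numpy()).groupby(tl).sum()
        if len(sub)
        else pd.Series(dtype=float)
    )
    tl_levels = by_tl.index.to_numpy()
    carbon = by_tl.to_numpy() / params.cr  # catch carbon per TL group
    n_years = max(catches.years.size, 1)

    # TE draws
    if mc.te_sd > 0:
        lo, hi = mc.te_bounds
        a, b = (lo - mc.te_mean) / mc.te_sd, (hi - mc.te_mean) / mc.te_sd
        te = stats.truncnorm.rvs(a, b, loc=mc.te_mean, scale=mc.te_sd,
                                 size=mc.n_trials, random_state=rng)
    else:
        te = np.full(mc.n_trials, mc.te_mean)

    # global PP level draws from the annual accessible totals
    totals = pp.annual_totals(mask)
    pp_mu, pp_sd = float(totals.mean()), float(totals.std(ddof=0))
    degenerate = totals.size < 2 or pp_sd == 0.0
    if degenerate:
        pp_draw = np.full(mc.n_trials, pp_mu)
    else:
        pp_draw = rng.normal(pp_mu, pp_sd, size=mc.n_trials)
        pp_draw = np.clip(pp_draw, 1e-12 * pp_mu, None)
    denom_base = float(pp.mean_per_cell[mask].sum())
    denom = denom_base * (pp_draw / pp_mu)

    if tl_levels.size:
        # num(TE) = sum over TL groups of carbon * (1/TE)^(TL-1), per year
        powers = (1.0 / te)[:, None] ** (tl_levels[None, :] - 1.0)
        num = (powers * carbon[None, :]).sum(axis=1) / n_years
    else:
        num = np.zeros(mc.n_trials)
    trials = 100.0 * num / denom
    return MCResult(
        median=float(np.median(trials)),
        ci_low=float(np.percentile(trials, 2.5)),
        ci_high=float(np.percentile(trials, 97.5)),
        trials=trials,
        degenerate_pp_pool=degenerate,
    )


def eez_summary(
    catches: CatchTable,
    taxa: dict[str, float],
    pp: PPFieldSet,
    world: WorldState,
    grid: GridDefinition,
    params: PPRParams = PPRParams(),
    consumption_by_country: dict[str, float] | None = None,
    population_by_country: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-country exploitation intensity and per-capita consumption.

    ``ppr_percent`` is 100 x (annual-mean PPR of catches inside the EEZ) /
    (mean PP of the EEZ); ``per_capita_kg`` is 1000 x consumption tonnes /
    population. Countries whose EEZ has zero PP raise (no meaningful
    denominator).
    """
    consumption_by_country = consumption_by_country or {}
    population_by_country = population_by_country or {}
    ppr_cell = _annual_mean_ppr_per_cell(catches, taxa, params, len(grid.table))
    pp_mean = pp.mean_per_cell

    rows = []
    for idx, country in enumerate(world.countries):
        cells = np.flatnonzero(world.eez == idx)
        pp_total = float(pp_mean[cells].sum())
        if cells.size and pp_total <= 0:
            raise ValueError(f"country {country} has an EEZ with zero PP")
        ppr_pct = 100.0 * float(ppr_cell[cells].sum()) / pp_total if cells.size else 0.0
        cons = consumption_by_country.get(country)
        popn = population_by_country.get(country)
        if cons is not None:
            if popn is None or popn <= 0:
                raise ValueError(f"country {country} has consumption but no population")
            per_capita = 1000.0 * cons / popn
        else:
            per_capita = np.nan
        rows.append((country, ppr_pct, per_capita))
    return pd.DataFrame(rows, columns=["country", "ppr_percent", "per_capita_kg"])
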