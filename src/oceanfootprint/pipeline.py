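"""End-to-end reproducible runs.

One config (YAML or dict) plus one master seed drives: world generation ->
catches/trade -> PPR footprint + sourcing distances -> supply limits ->
demand projection. Each stage derives its own random substream from the
master seed and its stage name, so any stage can be rerun in isolation and
two runs with the same config are byte-identical. All tables are computed
in memory first and written only when every stage has succeeded (a failed
run leaves no partial bundle), with a manifest of config hash and file
digests written last.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distance as dist_mod
from . import ppr as ppr_mod
from . import projection as proj_mod
from . import supply as supply_mod
from . import synth
from ._rng import stage_seed
from .grid import GridDefinition, generate_grid

logger = logging.getLogger(__name__)

TONNES_PER_MT = 1e6

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "grid": {"n_lat": 12, "n_lon": 24, "land_fraction": 0.15,
             "depth_min_m": 50.0, "depth_max_m": 5000.0},
    "years": {"start": 1950, "end": 2011},
    "pp": {"mean_pp": 140.0, "spatial_cv": 0.5, "interannual_cv": 0.05},
    "world": {"n_countries": 4, "eez_fraction": 0.7, "ports_per_country": 2,
              "taxa": [["benthopelagic_low", 2.5], ["small_pelagic", 3.0],
                       ["demersal", 3.5], ["large_pelagic", 4.2]]},
    "catches": {"effort_trend": 0.03, "target_ppr_fraction": 0.08,
                "coverage": 1.0},
    "trade": {"export_fraction": 0.35, "mariculture_per_country": 2e5},
    "ppr": {"cr": 9.0, "te": 0.10, "depth_limit_m": 1000.0,
            "thresholds": [0.10, 0.20, 0.30]},
    "mc": {"n_trials": 1000, "te_mean": 0.10, "te_sd": 0.0303,
           "te_lo": 0.05, "te_hi": 0.15},
    "bootstrap": {"n_trials": 200, "n_samples": 1000, "within": "tonnage"},
    "supply": {"ffm_scenarios": [0.10, 0.07, 0.05], "n_sims": 1000,
               "sampling": "uniform"},
    "projection": {"base_pop": 2.5e9, "growth_low": 0.006,
                   "growth_median": 0.011, "growth_high": 0.016,
                   "consumption_intercept_t": 0.0,
                   "consumption_slope_t_per_person": 0.02,
                   "noise_sd_t": 2e6, "horizon": 2100},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration; one seed governs the whole run."""

    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "RunConfig":
        cfg = cls(raw=_merge(DEFAULT_CONFIG, overrides or {}))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str):
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def validate(self) -> None:
        c = self.raw
        g = c["grid"]
        if g["n_lat"] < 1 or g["n_lon"] < 1:
            raise ValueError("grid dimensions must be >= 1")
        y = c["years"]
        if y["end"] < y["start"]:
            raise ValueError("years.end must be >= years.start")
        if not 0 < c["catches"]["target_ppr_fraction"] < 1:
            raise ValueError("target_ppr_fraction must be in (0, 1)")
        if not 0 <= c["trade"]["export_fraction"] <= 1:
            raise ValueError("export_fraction must be in [0, 1]")
        ppr_mod.PPRParams(cr=c["ppr"]["cr"], te=c["ppr"]["te"])
        ppr_mod.MCConfig(
            n_trials=c["mc"]["n_trials"], te_mean=c["mc"]["te_mean"],
            te_sd=c["mc"]["te_sd"], te_bounds=(c["mc"]["te_lo"], c["mc"]["te_hi"]),
        )
        p = c["projection"]
        if not p["growth_high"] >= p["growth_median"] >= p["growth_low"]:
            raise ValueError("growth rates must satisfy high >= median >= low")
        if p["horizon"] <= y["end"]:
            raise ValueError("projection horizon must lie beyond the catch years")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()


@dataclass
class ResultBundle:
    """All output tables of one run plus the manifest."""

    distance_series: pd.DataFrame
    band_areas: pd.DataFrame
    accessible_series: pd.DataFrame
    supply_limits: pd.DataFrame
    demand_projection: pd.DataFrame
    crossings: pd.DataFrame
    eez_summary: pd.DataFrame
    manifest: dict

    TABLES = (
        "distance_series", "band_areas", "accessible_series",
        "supply_limits", "demand_projection", "crossings", "eez_summary",
    )

    def write(self, out_dir) -> dict[str, str]:
        """Write every table as CSV plus manifest.json; returns file digests."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        digests = {}
        for name in self.TABLES:
            path = out / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        self.manifest["files"] = digests
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return digests


def _stage(name):
    """Re-raise stage errors with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self
        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False
    return _Ctx()


def run_pipeline(config: RunConfig, out_dir=None) -> ResultBundle:
    """Execute every stage in dependency order and assemble the bundle."""
    c = config.raw
    seed = config.seed
    years = list(range(c["years"]["start"], c["years"]["end"] + 1))

    with _stage("grid"):
        g = c["grid"]
        grid = generate_grid(
            g["n_lat"], g["n_lon"], g["land_fraction"],
            (g["depth_min_m"], g["depth_max_m"]), seed=stage_seed(seed, "grid"),
        )

    with _stage("pp"):
        pp = synth.generate_pp_fields(
            grid, years, mean_pp=c["pp"]["mean_pp"],
            spatial_cv=c["pp"]["spatial_cv"],
            interannual_cv=c["pp"]["interannual_cv"],
            seed=stage_seed(seed, "pp"),
        )

    with _stage("world"):
        w = c["world"]
        world = synth.generate_world(
            grid, w["n_countries"], [(t, tl) for t, tl in w["taxa"]],
            seed=stage_seed(seed, "world"), eez_fraction=w["eez_fraction"],
            ports_per_country=w["ports_per_country"], years=years,
        )

    with _stage("catches"):
        catches = synth.generate_catches(
            world, grid, pp, years,
            effort_trend=c["catches"]["effort_trend"],
            target_ppr_fraction=c["catches"]["target_ppr_fraction"],
            coverage=c["catches"]["coverage"],
            seed=stage_seed(seed, "catches"),
        )
        logger.info("catches: %d records, %.1f t total",
                    len(catches.records), catches.total_tonnage())

    with _stage("trade"):
        mariculture = {ctry: float(c["trade"]["mariculture_per_country"])
                       for ctry in world.countries}
        trade = synth.generate_trade(
            world, catches, mariculture,
            export_fraction=c["trade"]["export_fraction"],
            seed=stage_seed(seed, "trade"),
        )
        traded = float(trade.wild()["tonnage"].sum())
        if traded > catches.total_tonnage() + 1e-6:
            raise ValueError("conservation violated: traded wild > caught")
        logger.info("trade: %d flows, %.1f t wild traded", len(trade.trades), traded)

    params = ppr_mod.PPRParams(cr=c["ppr"]["cr"], te=c["ppr"]["te"])
    depth_limit = c["ppr"]["depth_limit_m"]

    with _stage("ppr"):
        _, band_areas = ppr_mod.ratio_and_bands(
            catches, world.taxa, pp, grid, params,
            thresholds=tuple(c["ppr"]["thresholds"]),
        )
        mc_rows = []
        for i, year in enumerate(years):
            sub = synth.CatchTable(
                records=catches.records[catches.records["year"] == year]
            )
            mc = ppr_mod.MCConfig(
                n_trials=c["mc"]["n_trials"], te_mean=c["mc"]["te_mean"],
                te_sd=c["mc"]["te_sd"],
                te_bounds=(c["mc"]["te_lo"], c["mc"]["te_hi"]),
                seed=stage_seed(seed, f"mc-{year}"),
            )
            res = ppr_mod.mc_accessible_percentage(
                sub, world.taxa, pp, grid, mc, params, depth_limit
            )
            point = ppr_mod.accessible_percentage(
                sub, world.taxa, pp, grid, params, depth_limit
            )
            mc_rows.append((year, point, res.median, res.ci_low, res.ci_high))
        accessible_series = pd.DataFrame(
            mc_rows, columns=["year", "percent", "mc_median", "ci_low", "ci_high"]
        )

    with _stage("distance"):
        matched, unmatched = dist_mod.match_exports_to_catches(catches, trade.wild())
        records = dist_mod.assemble_distance_records(
            world, grid, catches, trade, matched, mariculture
        )
        distance_series = dist_mod.yearly_distance_series(
            records, n_trials=c["bootstrap"]["n_trials"],
            n_samples=c["bootstrap"]["n_samples"],
            seed=stage_seed(seed, "bootstrap"),
            within_category_weighting=c["bootstrap"]["within"],
        )

    with _stage("supply"):
        rows = []
        for ffm in c["supply"]["ffm_scenarios"]:
            res = supply_mod.supply_limit(supply_mod.SupplyParams(ffm=ffm))
            sens = supply_mod.supply_sensitivity(
                ffm, n_sims=c["supply"]["n_sims"],
                sampling=c["supply"]["sampling"],
                seed=stage_seed(seed, f"supply-{ffm}"),
            )
            rows.append((res.scenario, ffm, res.F, res.M, res.S,
                         sens.mean_S, sens.ci_low, sens.ci_high,
                         sens.range_to_mean_pct))
        supply_limits = pd.DataFrame(rows, columns=[
            "scenario", "ffm", "F_mt", "M_mt", "S_mt",
            "sens_mean_mt", "sens_ci_low_mt", "sens_ci_high_mt",
            "sens_range_to_mean_pct",
        ])

    with _stage("projection"):
        p = c["projection"]
        horizon = int(p["horizon"])
        scen = synth.generate_population(
            base_pop=p["base_pop"],
            growth_rates={"low": p["growth_low"], "median": p["growth_median"],
                          "high": p["growth_high"]},
            consumption_intercept=p["consumption_intercept_t"],
            consumption_slope=p["consumption_slope_t_per_person"],
            noise_sd=p["noise_sd_t"],
            years=range(c["years"]["start"], horizon + 1),
            seed=stage_seed(seed, "population"),
            history_end=c["years"]["end"],
        )
        fit = proj_mod.fit_from_scenarios(scen)
        demand = proj_mod.project_consumption(fit, scen, horizon=horizon)
        limits = {
            f"ffm={row.ffm:g}": row.S_mt * TONNES_PER_MT
            for row in supply_limits.itertuples()
        }
        crossings = proj_mod.crossing_table(demand, limits)

    with _stage("eez_summary"):
        final_year = years[-1]
        pop_final = world.population[world.population["year"] == final_year]
        pop_by = dict(zip(pop_final["country"], pop_final["persons"]))
        # global per-capita rate applied to each synthetic country population
        hist_cons = float(scen.history["consumption"].iloc[-1])
        global_pop = float(scen.history["population"].iloc[-1])
        per_cap = hist_cons / global_pop
        cons_by = {k: per_cap * v for k, v in pop_by.items()}
        eez = ppr_mod.eez_summary(
            catches, world.taxa, pp, world, grid, params,
            consumption_by_country=cons_by, population_by_country=pop_by,
        )

    manifest = {
        "config": c,
        "config_sha256": config.config_hash(),
        "seed": seed,
        "stages": ["grid", "pp", "world", "catches", "trade", "ppr",
                   "distance", "supply", "projection", "eez_summary"],
        "n_catch_records": int(len(catches.records)),
        "n_trade_flows": int(len(trade.trades)),
        "unmatched_export_tonnes": float(unmatched["tonnage"].sum()) if len(unmatched) else 0.0,
    }
    bundle = ResultBundle(
        distance_series=distance_series,
        band_areas=band_areas,
        accessible_series=accessible_series,
        supply_limits=supply_limits,
        demand_projection=demand,
        crossings=crossings,
        eez_summary=eez,
        manifest=manifest,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
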