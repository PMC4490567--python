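"""Seafood demand: historical fit and projection to 2100.

Global seafood consumption has tracked global population closely; the model
here is the identity-link Gaussian regression

    consumption = a + b * population + eps

fitted on the historical window and pushed forward along low/median/high
population scenarios. Comparing the projected demand with the supply
ceilings locates the first year demand can no longer be met.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synth import PopulationScenarios


@dataclass(frozen=True)
class ConsumptionFit:
    """OLS fit of consumption (tonnes/yr) on population (persons)."""

    intercept: float
    slope: float
    residual_sd: float
    slope_se: float
    fit_years: tuple[int, int]

    def predict(self, population: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(population, dtype=float)


def fit_consumption_model(
    population, consumption, years: tuple[int, int] | None = None
) -> ConsumptionFit:
    """Fit the consumption-population line by ordinary least squares."""
    pop = np.asarray(population, dtype=float)
    cons = np.asarray(consumption, dtype=float)
    if pop.size != cons.size or pop.size < 3:
        raise ValueError("need >= 3 paired (population, consumption) years")
    if (pop <= 0).any():
        raise ValueError("population must be strictly positive")
    if np.ptp(pop) == 0:
        raise ValueError("constant population: slope is unidentifiable")
    res = sm.OLS(cons, sm.add_constant(pop)).fit()
    dof = max(pop.size - 2, 1)
    return ConsumptionFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        residual_sd=float(np.sqrt(res.ssr / dof)),
        slope_se=float(res.bse[1]),
        fit_years=years or (0, pop.size - 1),
    )


def fit_from_scenarios(scen: PopulationScenarios) -> ConsumptionFit:
    h = scen.history
    return fit_consumption_model(
        h["population"], h["consumption"],
        years=(int(h["year"].min()), int(h["year"].max())),
    )


def project_consumption(
    fit: ConsumptionFit, scenarios: PopulationScenarios, horizon: int = 2100
) -> pd.DataFrame:
    """Projected consumption per (scenario, year) up to the horizon.

    Returns columns (scenario, year, population, projected_tonnes). With a
    non-negative slope the high scenario dominates the median dominates the
    low, pointwise.
    """
    if horizon < scenarios.history_end:
        raise ValueError("horizon is before the end of the historical window")
    s = scenarios.scenarios
    if int(s["year"].max()) < horizon:
        raise ValueError("scenarios do not cover the horizon")
    s = s[s["year"] <= horizon].copy()
    s["projected_tonnes"] = fit.predict(s["population"].to_numpy())
    return s.reset_index(drop=True)


def limit_crossing_year(projection: pd.DataFrame, limit: float) -> int | None:
    """First year whose projected consumption strictly exceeds the limit.

    ``projection`` is a single scenario's (year, projected_tonnes) table;
    returns None when the limit is never exceeded.
    """
    if limit <= 0:
        raise ValueError("limit must be positive")
    if len(projection) == 0:
        raise ValueError("empty projection")
    over = projection[projection["projected_tonnes"] > limit]
    return int(over["year"].min()) if len(over) else None


def crossing_table(
    projection: pd.DataFrame, limits: dict[str, float]
) -> pd.DataFrame:
    """Crossing years for every (scenario, named limit) pair."""
    rows = []
    for scenario, grp in projection.groupby("scenario"):
        for name, limit in limits.items():
            rows.append((scenario, name, limit, limit_crossing_year(grp, limit)))
    return pd.DataFrame(rows, columns=["scenario", "limit_name", "limit_tonnes", "crossing_year"])
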