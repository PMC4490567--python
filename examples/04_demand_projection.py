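"""Seafood demand to 2100 versus the supply ceilings.

Fits consumption on population over a synthetic historical window, projects
along low/median/high population scenarios and finds the first year each
supply ceiling is exceeded.
"""

import oceanfootprint as of
from oceanfootprint.projection import fit_from_scenarios

scen = of.generate_population(
    base_pop=2.5e9,
    growth_rates={"low": 0.006, "median": 0.011, "high": 0.016},
    consumption_intercept=0.0, consumption_slope=0.02,  # ~20 kg per capita
    noise_sd=2e6, years=range(1950, 2101), seed=1, history_end=2011)

fit = fit_from_scenarios(scen)
print(f"fit: consumption = {fit.intercept:.3g} + {fit.slope:.4f} * population "
      f"(residual sd {fit.residual_sd:.3g} t)")

proj = of.project_consumption(fit, scen, horizon=2100)
limits = {r.scenario: r.S * 1e6 for r in of.scenario_table()}
crossings = of.crossing_table(proj, limits)
print("\nfirst year projected demand exceeds each ceiling:")
print(crossings.to_string(index=False))
print("\nA 'None'/NaN crossing year means demand stays under that ceiling")
print("through 2100 for that population scenario.")
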