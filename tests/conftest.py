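import numpy as np
import pandas as pd
import pytest

import oceanfootprint as of


@pytest.fixture(scope="session")
def tiny_grid():
    """4 x 8 all-sea grid with uniform 500 m depth."""
    return of.generate_grid(4, 8, land_fraction=0.0, depth_params=(500.0, 500.0), seed=1)


@pytest.fixture(scope="session")
def small_world(tiny_grid):
    """Deterministic 3-country world with 4 taxa and 3 years of PP."""
    years = [2000, 2001, 2002]
    pp = of.generate_pp_fields(tiny_grid, years, mean_pp=140.0,
                               spatial_cv=0.3, interannual_cv=0.0, seed=2)
    world = of.generate_world(
        tiny_grid, 3,
        [("algae", 1.0), ("anchovy", 2.8), ("cod", 3.8), ("tuna", 4.3)],
        seed=3, eez_fraction=1.0, ports_per_country=2, years=years,
    )
    return tiny_grid, pp, world, years


@pytest.fixture(scope="session")
def small_catches(small_world):
    grid, pp, world, years = small_world
    catches = of.generate_catches(world, grid, pp, years,
                                  effort_trend=0.0, target_ppr_fraction=0.1,
                                  seed=4)
    return catches


def make_records(rng, n=200, zero_fraction=0.25):
    """Synthetic one-year distance records across all four categories."""
    cats = rng.choice(
        ["domestic_wild", "imported_wild", "imported_mariculture"],
        size=n, p=[0.5, 0.3, 0.2],
    )
    dist = np.exp(rng.normal(7.0, 0.8, size=n))
    ton = np.exp(rng.normal(8.0, 1.0, size=n))
    n_zero = int(zero_fraction * n)
    if n_zero:
        cats = np.concatenate([cats, ["domestic_mariculture"] * n_zero])
        dist = np.concatenate([dist, np.zeros(n_zero)])
        ton = np.concatenate([ton, np.exp(rng.normal(8.0, 1.0, size=n_zero))])
    return pd.DataFrame({
        "year": 2000, "category": cats, "distance_km": dist, "tonnage": ton,
    })
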