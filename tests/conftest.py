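import numpy as np
import pandas as pd
import pytest

from crownforge.stem_map import COLUMNS, StemMap, assign_plots, growth_stage


def make_stand(
    x, y, dbh, *, species=None, th=None, hcb=None, cw=None,
    stand_width=120.0, stand_height=140.0, plot_size=20.0,
) -> StemMap:
    """Build a small validated stand from coordinate/dbh arrays."""
    n = len(x)
    dbh = np.asarray(dbh, dtype=float)
    th = np.asarray(th, dtype=float) if th is not None else 2.0 + 0.8 * dbh
    hcb = np.asarray(hcb, dtype=float) if hcb is not None else 0.4 * th
    cw = np.asarray(cw, dtype=float) if cw is not None else 0.9 * dbh**0.6
    species = list(species) if species is not None else ["Betula luminifera"] * n
    group = {"Betula luminifera": "BL", "Pinus massoniana": "PM",
             "Platycarya strobilacea": "PS", "Liquidambar formosana": "LF",
             "Populus davidiana": "PD"}
    df = pd.DataFrame(
        {
            "tree_id": [f"t{i:04d}" for i in range(n)],
            "plot_id": None,
            "species_name": species,
            "species_group": [group.get(s, "Others") for s in species],
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
            "dbh": dbh,
            "th": th,
            "hcb": hcb,
            "cw": cw,
            "growth_stage": [growth_stage(v) for v in dbh],
        }
    )[list(COLUMNS)]
    return assign_plots(
        StemMap(df, stand_width=stand_width, stand_height=stand_height, plot_size=plot_size)
    )


def random_stand(rng: np.random.Generator, n: int = 50, **kwargs) -> StemMap:
    w = kwargs.get("stand_width", 120.0)
    h = kwargs.get("stand_height", 140.0)
    return make_stand(
        rng.uniform(0, w, n), rng.uniform(0, h, n), rng.uniform(1.0, 40.0, n), **kwargs
    )


@pytest.fixture
def small_stand() -> StemMap:
    rng = np.random.default_rng(42)
    return random_stand(rng, n=60)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
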