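import numpy as np
import pandas as pd
import pytest

from riverpress.schema import VARIABLE_ORDER, schema_map
from riverpress.synthetic import CellConfig, GeneratorConfig, default_config


def make_raw_row(site_id="S1", ecoregion=4, eft_code=3, catchment=50.0, **pressures):
    """One raw input row with every pressure at 1 unless overridden."""
    row = {
        "site_id": site_id,
        "country": "AT",
        "ecoregion": ecoregion,
        "eft_code": eft_code,
        "catchment_km2": catchment,
        "pop_density": 40.0,
    }
    row.update({c: 1 for c in VARIABLE_ORDER})
    row.update(pressures)
    return row


def make_raw_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def schema():
    return schema_map()


@pytest.fixture(scope="session")
def small_default_config():
    return default_config(n_total=400, seed=7)


def degenerate_config(value_picker, n=60, rho=0.0) -> GeneratorConfig:
    """Config putting all probability mass on value_picker(spec) per variable."""
    base = default_config(n_total=10, seed=0)
    marginals = {
        code: {value_picker(spec): 1.0} for code, spec in schema_map().items()
    }
    return GeneratorConfig(
        cells=[CellConfig(ecoregion=4, river_type="A", n_sites=n),
               CellConfig(ecoregion=14, river_type="F", n_sites=n)],
        marginals=marginals,
        rho=rho,
        env_ranges=base.env_ranges,
        countries=base.countries,
        seed=0,
    )


@pytest.fixture()
def scores_fixture():
    """Hand-built per-site scores covering all combinations and classes."""
    rows = [
        # site, eco, rt, dens, HPI, MPI, WQPI, CPI, GPI, cls, comb
        ("a", 4, "A", 10.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0, "NoP"),
        ("b", 4, "A", 20.0, 1.0, 1.0, 4.0, 1.0, 4.0, 1, "W"),
        ("c", 4, "B", 30.0, 3.0, 1.0, 1.0, 1.0, 3.0, 1, "HMC"),
        ("d", 9, "F", 80.0, 3.5, 3.0, 3.5, np.nan, 10.0, 3, "W+HMC"),
        ("e", 9, "F", 90.0, 5.0, 4.0, 4.0, 3.0, 16.0, 4, "W+HMC"),
        ("f", 9, "F", 55.0, 1.0, 2.0, 3.0, 3.0, 6.0, 2, "W+HMC"),
    ]
    df = pd.DataFrame(rows, columns=[
        "site_id", "ecoregion", "river_type", "pop_density",
        "HPI", "MPI", "WQPI", "CPI", "GPI", "GPI_class", "combination",
    ])
    df["affected_groups"] = (df[["HPI", "MPI", "WQPI", "CPI"]] >= 3).sum(axis=1)
    df["n_groups_scored"] = df[["HPI", "MPI", "WQPI", "CPI"]].notna().sum(axis=1)
    df["complete"] = df["n_groups_scored"] == 4
    return df
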