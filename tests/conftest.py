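"""Shared fixtures: small hand-built studies and a generated synthetic one."""

import numpy as np
import pandas as pd
import pytest

from countylines.data_model import (
    CovariateTable,
    LineCounts,
    ODMatrix,
    Study,
    Territory,
)
from countylines.synthetic import SyntheticConfig, make_study


def square_od(ids, values, kind):
    return ODMatrix(ids=tuple(ids), values=np.asarray(values, dtype=float), kind=kind)


@pytest.fixture
def tiny_study():
    """Three destinations at hand-checkable distances from one origin."""
    ids = ["london", "a", "b", "c"]
    territories = [
        Territory("london", "London", 8.9e6, 0.0, 0.0, "origin"),
        Territory("a", "A", 1.0e6, 50.0, 0.0, "south"),
        Territory("b", "B", 2.0e6, 0.0, 120.0, "south"),
        Territory("c", "C", 5.0e5, 300.0, 0.0, "north"),
    ]
    coords = np.array([[0, 0], [50, 0], [0, 120], [300, 0]], dtype=float)
    dist = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    cov = CovariateTable(
        pd.DataFrame(
            {
                "misuse_admissions": [8000.0, 900.0, 1500.0, 600.0],
                "poisoning_admissions": [4000.0, 500.0, 700.0, 200.0],
                "police_officers": [30000.0, 2000.0, 4500.0, 1200.0],
                "gdhi": [2.5e11, 2.2e10, 4.1e10, 9.0e9],
                "knife_crimes": [14000.0, 400.0, 1100.0, 250.0],
                "hospital_beds": [20000.0, 2500.0, 5200.0, 1400.0],
            },
            index=ids,
        )
    )
    lines = {
        "2019": LineCounts("london", "2019", pd.Series({"a": 60.0, "b": 30.0, "c": 10.0})),
        "2020": LineCounts("london", "2020", pd.Series({"a": 55.0, "b": 28.0, "c": 7.0})),
    }
    return Study(
        territories=territories,
        covariates=cov,
        distances=square_od(ids, dist, "distance"),
        travel_times=square_od(ids, dist / 1.0, "travel_time"),
        lines=lines,
        origin="london",
    )


@pytest.fixture(scope="session")
def synthetic_study():
    """Default-condition synthetic study (37 destinations, retail truth)."""
    return make_study(SyntheticConfig(seed=12345))


@pytest.fixture(scope="session")
def small_synthetic_study():
    """A reduced synthetic study for fast fitting tests."""
    return make_study(SyntheticConfig(seed=7, n_destinations=10, n_south=4))
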