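import numpy as np
import pandas as pd
import pytest

from hospeff import (
    HospitalPanel,
    UrgencyCatalogue,
    generate_catalogue,
    generate_panel,
    urgency_measures,
)
from hospeff.data import DIAG_PREFIX


def make_catalogue(entries):
    """entries: list of (code, u, group, chapter, los)."""
    return UrgencyCatalogue(
        pd.DataFrame(entries, columns=["code", "u", "group", "chapter", "los"])
    )


def make_panel(records, catalogue, **overrides):
    """records: list of dicts with hospital, year, diag (code->count) and
    optional covariate overrides; everything else gets sane defaults."""
    rows = []
    for rec in records:
        row = {
            "hospital": rec["hospital"],
            "year": rec.get("year", 2016),
            "beds": rec.get("beds", 100.0),
            "fte_physicians": rec.get("fte_physicians", 30.0),
            "fte_rn": rec.get("fte_rn", 80.0),
            "fte_na": rec.get("fte_na", 5.0),
            "outpatient_cases": rec.get("outpatient_cases", 1000.0),
            "ownership": rec.get("ownership", "public"),
            "teaching": rec.get("teaching", 0),
            "location": rec.get("location", "urban"),
            "lat": rec.get("lat", 52.0),
            "lon": rec.get("lon", 13.0),
            "htype": rec.get("htype", "general"),
        }
        for code in catalogue.table["code"]:
            row[DIAG_PREFIX + code] = 0
        for code, cnt in rec["diag"].items():
            row[DIAG_PREFIX + code] = cnt
        rows.append(row)
    return HospitalPanel(pd.DataFrame(rows), catalogue)


@pytest.fixture(scope="session")
def tiny_catalogue():
    # two groups/chapters; group LOS {2, 6} -> weights {0.5, 1.5}
    return make_catalogue(
        [
            ("A", 0.2, 1, 1, 2.0),
            ("B", 0.8, 2, 1, 6.0),
            ("C", 0.37, 1, 2, 2.0),
        ]
    )


@pytest.fixture(scope="session")
def catalogue241():
    return generate_catalogue(241, 241, 22, seed=1)


@pytest.fixture(scope="session")
def panel201(catalogue241):
    """Standard synthetic study population: 67 hospitals x 3 years."""
    return generate_panel(catalogue241, 67, [2015, 2016, 2017], seed=42)


@pytest.fixture(scope="session")
def measures201(panel201):
    panel, _ = panel201
    return urgency_measures(panel)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
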