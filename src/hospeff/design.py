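"""Second-stage design matrix construction.

One place defines the covariate layout so the data generator, the
regression ladder, and the recovery tests agree on column names and
reference groups: public ownership, large-city location, and a configurable
reference year (default 2017).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

DEFAULT_REFERENCE_YEAR = 2017

FOCAL_COLUMNS = ("urs", "urs2", "urd")


def build_design(
    table: pd.DataFrame,
    include_urs2: bool = False,
    include_urd: bool = False,
    reference_year: int = DEFAULT_REFERENCE_YEAR,
    include_year_dummies: bool = True,
) -> pd.DataFrame:
    """Design matrix (with intercept) from a merged per-DMU table.

    Expects columns urs, urd, hhi, ownership, teaching, location, year.
    Raises on numerically collinear designs (condition number > 1e10).
    """
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(table)),
        "urs": table["urs"].to_numpy(float),
    }
    if include_urs2:
        cols["urs2"] = cols["urs"] ** 2
    if include_urd:
        cols["urd"] = table["urd"].to_numpy(float)
    own = table["ownership"].astype(str)
    cols["own_nonprofit"] = (own == "nonprofit").to_numpy(float)
    cols["own_forprofit"] = (own == "forprofit").to_numpy(float)
    cols["teaching"] = table["teaching"].to_numpy(float)
    cols["hhi"] = table["hhi"].to_numpy(float)
    loc = table["location"].astype(str)
    for level in ("urban", "rural", "remote"):
        cols[f"loc_{level}"] = (loc == level).to_numpy(float)
    if include_year_dummies:
        years = sorted(int(y) for y in table["year"].unique())
        for y in years:
            if y != reference_year:
                cols[f"year_{y}"] = (
                    table["year"].astype(int) == y
                ).to_numpy(float)
    Z = pd.DataFrame(cols, index=table.index)
    # drop constant dummy columns (level absent from this sample); constant
    # continuous regressors are left in place and caught as collinear below
    dummy_prefixes = ("own_", "loc_", "year_", "teaching")
    keep = [
        c
        for c in Z.columns
        if not c.startswith(dummy_prefixes) or Z[c].to_numpy().std() > 0
    ]
    Z = Z[keep]
    cond = np.linalg.cond(Z.to_numpy())
    if cond > 1e10:
        raise InvalidArgumentError(
            f"collinear design (condition number {cond:.3g}); "
            f"columns: {list(Z.columns)}"
        )
    return Z
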