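"""Hospital market concentration within fixed-radius catchment areas.

Competition is proxied by a Herfindahl-Hirschman index (HHI): within the
great-circle catchment of a focal hospital (default radius 32 km), a separate
HHI is computed for each chapter of the diagnosis classification from squared
shares of inpatient discharges, and the chapter HHIs are averaged with the
focal hospital's own patient shares per chapter as weights. The index lives
in (0, 1]: 1 means the focal hospital is a monopolist in every chapter it
serves, values near 0 mean atomistic competition.

The focal hospital's own discharges are included in the chapter shares, and
markets are constructed within each observation year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import haversine_distances

from .data import HospitalPanel, UrgencyCatalogue
from .errors import DataIntegrityError, InvalidArgumentError

EARTH_RADIUS_KM = 6371.0088
DEFAULT_RADIUS_KM = 32.0


def haversine_km(latlon_a: np.ndarray, latlon_b: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix in km between (lat, lon) degree arrays."""
    a = np.radians(np.atleast_2d(latlon_a))
    b = np.radians(np.atleast_2d(latlon_b))
    return haversine_distances(a, b) * EARTH_RADIUS_KM


@dataclass(frozen=True)
class HHIResult:
    hospital: object
    year: int
    hhi: float
    n_competitors: int
    chapter_hhi: pd.Series  # index: chapter id, only chapters the focal serves


def _year_frame(panel: HospitalPanel, year: int) -> pd.DataFrame:
    t = panel.table
    sub = t[t["year"] == year]
    if sub[["lat", "lon"]].isna().to_numpy().any():
        raise DataIntegrityError(f"missing coordinates in year {year}")
    return sub


def catchment(
    panel: HospitalPanel,
    focal,
    year: int,
    radius_km: float = DEFAULT_RADIUS_KM,
) -> list:
    """Hospitals (incl. focal) within ``radius_km`` of the focal, same year."""
    sub = _year_frame(panel, year)
    if focal not in set(sub["hospital"]):
        raise InvalidArgumentError(f"hospital {focal!r} not in year {year}")
    coords = sub[["lat", "lon"]].to_numpy(float)
    fc = sub.loc[sub["hospital"] == focal, ["lat", "lon"]].to_numpy(float)
    d = haversine_km(fc, coords)[0]
    return sub.loc[d <= radius_km, "hospital"].tolist()


def weighted_hhi(
    panel: HospitalPanel,
    catalogue: UrgencyCatalogue | None = None,
    focal=None,
    year: int | None = None,
    radius_km: float = DEFAULT_RADIUS_KM,
) -> HHIResult:
    """Patient-share-weighted average of chapter-specific HHIs for one focal."""
    catalogue = catalogue or panel.catalogue
    table = hhi_table(panel, catalogue, radius_km=radius_km)
    try:
        row = table.loc[(focal, year)]
    except KeyError:
        raise InvalidArgumentError(f"({focal!r}, {year}) not in panel") from None
    chap_cols = [c for c in table.columns if c.startswith("hhi_c")]
    chapters = pd.Series(
        {int(c[len("hhi_c"):]): row[c] for c in chap_cols}
    ).dropna()
    return HHIResult(
        hospital=focal,
        year=year,
        hhi=float(row["hhi"]),
        n_competitors=int(row["n_competitors"]),
        chapter_hhi=chapters,
    )


def hhi_table(
    panel: HospitalPanel,
    catalogue: UrgencyCatalogue | None = None,
    radius_km: float = DEFAULT_RADIUS_KM,
) -> pd.DataFrame:
    """Weighted HHI for every hospital-year.

    Columns: ``hhi``, ``n_competitors``, and one ``hhi_c<chapter>`` column per
    catalogue chapter (NaN where the focal treats no cases in that chapter,
    since such chapters carry zero weight).
    """
    catalogue = catalogue or panel.catalogue
    chap_counts = panel.chapter_counts()
    chapters = list(chap_counts.columns)
    rows = []
    index = []
    for year in sorted(panel.table["year"].unique()):
        sub = _year_frame(panel, year)
        ids = sub["hospital"].to_numpy()
        coords = sub[["lat", "lon"]].to_numpy(float)
        cc = chap_counts.loc[
            pd.MultiIndex.from_arrays([ids, np.full(len(ids), year)])
        ].to_numpy(float)
        totals = cc.sum(axis=1)
        if np.any(totals <= 0):
            raise InvalidArgumentError("hospital with zero inpatient cases")
        adj = haversine_km(coords, coords) <= radius_km
        for i, hid in enumerate(ids):
            members = adj[i]
            market = cc[members]  # catchment x chapter counts
            denom = market.sum(axis=0)  # total chapter volume in catchment
            with np.errstate(invalid="ignore", divide="ignore"):
                shares = np.where(denom > 0, market / denom, 0.0)
            hhi_c = (shares**2).sum(axis=0)
            # focal serves the chapter but catchment total is 0 cannot occur
            # (focal's own cases are part of the catchment total)
            w = cc[i] / totals[i]
            hhi = float(hhi_c @ w)
            chap_vals = np.where(cc[i] > 0, hhi_c, np.nan)
            rows.append(
                [hhi, int(members.sum()) - 1, *chap_vals.tolist()]
            )
            index.append((hid, year))
    out = pd.DataFrame(
        rows,
        columns=["hhi", "n_competitors"]
        + [f"hhi_c{int(c):02d}" for c in chapters],
        index=pd.MultiIndex.from_tuples(index, names=["hospital", "year"]),
    )
    out["n_competitors"] = out["n_competitors"].astype(int)
    return out.sort_index()


def write_hhi_csv(table: pd.DataFrame, path) -> None:
    table.reset_index().to_csv(path, index=False)
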