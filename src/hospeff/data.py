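"""Core data containers: the diagnosis urgency catalogue and the hospital panel.

The catalogue maps each 4-digit diagnosis code to an urgency value u in [0, 1]
(the estimated probability that a case with this primary diagnosis is an
emergency rather than an elective admission), a case-mix group, a chapter of
the diagnosis classification, and the group's mean length of stay in days.

The panel holds one row per hospital-year with staffing and bed inputs,
outpatient volume, a wide block of per-diagnosis inpatient counts
(``diag_<code>`` columns), structural covariates, and WGS84 coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, InvalidArgumentError

logger = logging.getLogger(__name__)

DIAG_PREFIX = "diag_"

CATALOGUE_COLUMNS = ["code", "u", "group", "chapter", "los"]

PANEL_FIXED_COLUMNS = [
    "hospital",
    "year",
    "beds",
    "fte_physicians",
    "fte_rn",
    "fte_na",
    "outpatient_cases",
    "ownership",
    "teaching",
    "location",
    "lat",
    "lon",
    "htype",
]

OWNERSHIP_LEVELS = ("public", "nonprofit", "forprofit")
LOCATION_LEVELS = ("large_city", "urban", "rural", "remote")


@dataclass(frozen=True)
class UrgencyCatalogue:
    """Diagnosis catalogue with columns ``code, u, group, chapter, los``.

    ``u`` may be NaN for codes without an urgency value; such codes are
    excluded from urgency-score denominators downstream (with a logged share)
    but still contribute to case-mix-adjusted volume.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in CATALOGUE_COLUMNS if c not in t.columns]
        if missing:
            raise DataIntegrityError(f"catalogue missing columns {missing}")
        if t["code"].duplicated().any():
            dupes = t.loc[t["code"].duplicated(), "code"].tolist()
            raise DataIntegrityError(f"duplicate catalogue codes: {dupes[:5]}")
        u = t["u"].to_numpy(float)
        finite = np.isfinite(u)
        if np.any((u[finite] < 0) | (u[finite] > 1)):
            raise DataIntegrityError("urgency values must lie in [0, 1]")
        if np.any(t["los"].to_numpy(float) <= 0):
            raise DataIntegrityError("all group lengths of stay must be > 0")
        if t["group"].isna().any() or t["chapter"].isna().any():
            raise DataIntegrityError("group and chapter ids must be non-null")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def codes(self) -> pd.Index:
        return pd.Index(self.table["code"])

    @property
    def groups(self) -> np.ndarray:
        return np.sort(self.table["group"].unique())

    @property
    def chapters(self) -> np.ndarray:
        return np.sort(self.table["chapter"].unique())

    def u_by_code(self) -> pd.Series:
        return self.table.set_index("code")["u"]

    def group_by_code(self) -> pd.Series:
        return self.table.set_index("code")["group"]

    def chapter_by_code(self) -> pd.Series:
        return self.table.set_index("code")["chapter"]

    def group_los(self) -> pd.Series:
        """One mean length of stay per group (group-level attribute)."""
        return self.table.groupby("group")["los"].mean()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "UrgencyCatalogue":
        t = pd.read_csv(path, dtype={"code": str}, float_precision="round_trip")
        t["group"] = t["group"].astype(int)
        t["chapter"] = t["chapter"].astype(int)
        return cls(t)


@dataclass
class HospitalPanel:
    """Hospital-year records with diagnosis-count columns and a catalogue.

    Invariants enforced at construction: beds >= 1, at least one inpatient
    case per row, every ``diag_`` code resolves in the attached catalogue,
    and non-negative counts/FTEs throughout.
    """

    table: pd.DataFrame
    catalogue: UrgencyCatalogue = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PANEL_FIXED_COLUMNS if c not in t.columns]
        if missing:
            raise DataIntegrityError(f"panel missing columns {missing}")
        diag_cols = [c for c in t.columns if c.startswith(DIAG_PREFIX)]
        if not diag_cols:
            raise DataIntegrityError("panel has no diag_<code> columns")
        unknown = set(c[len(DIAG_PREFIX):] for c in diag_cols) - set(
            self.catalogue.codes
        )
        if unknown:
            raise DataIntegrityError(
                f"diagnosis codes not in catalogue: {sorted(unknown)[:5]}"
            )
        counts = t[diag_cols].to_numpy(float)
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise DataIntegrityError("diagnosis counts must be finite and >= 0")
        if np.any(counts.sum(axis=1) < 1):
            raise DataIntegrityError("every hospital-year needs >= 1 inpatient case")
        if np.any(t["beds"].to_numpy(float) < 1):
            raise DataIntegrityError("beds must be >= 1")
        for c in ("fte_physicians", "fte_rn", "fte_na", "outpatient_cases"):
            if np.any(t[c].to_numpy(float) < 0):
                raise DataIntegrityError(f"{c} must be >= 0")
        bad_own = set(t["ownership"]) - set(OWNERSHIP_LEVELS)
        if bad_own:
            raise DataIntegrityError(f"unknown ownership levels: {bad_own}")
        bad_loc = set(t["location"]) - set(LOCATION_LEVELS)
        if bad_loc:
            raise DataIntegrityError(f"unknown location levels: {bad_loc}")
        t = t.sort_values(["hospital", "year"], kind="mergesort").reset_index(
            drop=True
        )
        t["teaching"] = t["teaching"].astype(int)
        self.table = t
        self._diag_cols = [c for c in t.columns if c.startswith(DIAG_PREFIX)]

    def __len__(self) -> int:
        return len(self.table)

    @property
    def diag_cols(self) -> list[str]:
        return list(self._diag_cols)

    @property
    def diag_codes(self) -> list[str]:
        return [c[len(DIAG_PREFIX):] for c in self._diag_cols]

    def dmu_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(
            self.table[["hospital", "year"]], names=["hospital", "year"]
        )

    def counts(self) -> pd.DataFrame:
        """Diagnosis-count matrix (rows aligned to the panel, columns = codes)."""
        m = self.table[self._diag_cols].copy()
        m.columns = self.diag_codes
        m.index = self.dmu_index()
        return m

    def chapter_counts(self) -> pd.DataFrame:
        """Inpatient counts aggregated to catalogue chapters per hospital-year."""
        chap = self.catalogue.chapter_by_code().reindex(self.diag_codes)
        return self.counts().T.groupby(chap.to_numpy()).sum().T

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, catalogue: UrgencyCatalogue) -> "HospitalPanel":
        t = pd.read_csv(
            path, dtype={"hospital": str}, float_precision="round_trip"
        )
        return cls(t, catalogue)


def validate_panel_roundtrip(panel: HospitalPanel, path) -> bool:
    """Serialize then reparse; True when the round trip is lossless."""
    panel.to_csv(path)
    back = HospitalPanel.from_csv(path, panel.catalogue)
    a, b = panel.table, back.table
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for c in a.columns:
        if a[c].dtype.kind in "fc" or b[c].dtype.kind in "fc":
            if not np.allclose(
                a[c].to_numpy(float), b[c].to_numpy(float), rtol=0, atol=0
            ):
                return False
        elif not (a[c].astype(str) == b[c].astype(str)).all():
            return False
    return True


def require(condition: bool, message: str) -> None:
    if not condition:
        raise InvalidArgumentError(message)
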