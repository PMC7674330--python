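"""Case-composition statistics at the hospital-year level.

Four quantities characterise what a hospital treats:

* case-mix weights ``pi_g = LOS_g / mean_g(LOS_g)`` — a diagnosis group's
  mean length of stay relative to the grand mean across all G groups, so the
  weights average to one;
* adjusted inpatient volume ``sum_g pi_g * inpatients_{g,j}`` — inpatient
  discharges re-weighted by group severity, the first DEA output;
* the urgency score ``UrS_j`` — the case-weighted mean of the diagnosis-level
  urgency values u of the cases hospital j treated (0 = purely elective case
  mix, 1 = purely emergency);
* the urgency dispersion ``UrD_j`` — the case-weighted sample standard
  deviation (denominator n - 1) of u within hospital j.

UrS below 0.5 marks an elective-dominated case composition; 0.5 and above an
emergency-dominated one (the boundary belongs to the emergency side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import HospitalPanel, UrgencyCatalogue
from .errors import DataIntegrityError, InvalidArgumentError

logger = logging.getLogger(__name__)

ELECTIVE_LABEL = "elective-dominated"
EMERGENCY_LABEL = "emergency-dominated"


@dataclass(frozen=True)
class CaseMixWeights:
    """Per-group weights pi_g with mean exactly 1 across the G groups."""

    weights: pd.Series  # index: group id
    G: int

    def __post_init__(self) -> None:
        if np.any(self.weights.to_numpy() <= 0):
            raise InvalidArgumentError("case-mix weights must be positive")


def casemix_weights(catalogue: UrgencyCatalogue) -> CaseMixWeights:
    """Length-of-stay relative weights, one per diagnosis group."""
    los = catalogue.group_los()
    if len(los) == 0:
        raise InvalidArgumentError("catalogue is empty")
    if np.any(los.to_numpy() <= 0):
        raise InvalidArgumentError("all group LOS values must be > 0")
    pi = los / los.mean()
    return CaseMixWeights(weights=pi, G=len(pi))


def adjusted_inpatients(
    panel: HospitalPanel, weights: CaseMixWeights
) -> pd.Series:
    """Severity-adjusted inpatient volume per hospital-year.

    Each diagnosis count is multiplied by its group's case-mix weight and
    summed; linear in the counts.
    """
    counts = panel.counts()
    groups = panel.catalogue.group_by_code().reindex(counts.columns)
    unmapped = groups.index[~groups.isin(weights.weights.index)]
    if len(unmapped) > 0:
        raise DataIntegrityError(
            f"codes with no case-mix weight: {list(unmapped[:5])}"
        )
    w = weights.weights.reindex(groups.to_numpy()).to_numpy()
    values = counts.to_numpy(float) @ w
    return pd.Series(values, index=counts.index, name="adjusted_inpatients")


def _weighted_urgency(counts: pd.DataFrame, u: pd.Series):
    """Shared core: per-row weighted mean/SD of u, NaN-u codes excluded."""
    uvals = u.reindex(counts.columns).to_numpy(float)
    valid = np.isfinite(uvals)
    c_all = counts.to_numpy(float)
    c = c_all[:, valid]
    uv = uvals[valid]
    n_total = c_all.sum(axis=1)
    n = c.sum(axis=1)
    excluded_share = 1.0 - n.sum() / n_total.sum()
    if excluded_share > 0:
        logger.warning(
            "%.2f%% of inpatient cases have no urgency value and are "
            "excluded from UrS/UrD denominators",
            100 * excluded_share,
        )
    return c, uv, n, n_total


def urgency_score(
    panel: HospitalPanel, catalogue: UrgencyCatalogue | None = None
) -> pd.DataFrame:
    """Per-hospital-year urgency score with dominance classification."""
    catalogue = catalogue or panel.catalogue
    counts = panel.counts()
    c, uv, n, _ = _weighted_urgency(counts, catalogue.u_by_code())
    if np.any(n < 1):
        bad = counts.index[n < 1].tolist()
        raise InvalidArgumentError(
            f"zero urgency-valued inpatient cases for {bad[:5]}"
        )
    urs = (c @ uv) / n
    out = pd.DataFrame(
        {"urs": urs, "n_cases": n.astype(int)}, index=counts.index
    )
    out["dominance"] = np.where(urs >= 0.5, EMERGENCY_LABEL, ELECTIVE_LABEL)
    return out


def classify_urgency(urs: float) -> str:
    """0.5 and above is emergency-dominated; the boundary is emergency."""
    return EMERGENCY_LABEL if urs >= 0.5 else ELECTIVE_LABEL


def urgency_dispersion(
    panel: HospitalPanel, catalogue: UrgencyCatalogue | None = None
) -> pd.DataFrame:
    """Case-weighted sample SD of urgency values around UrS (denominator n-1)."""
    catalogue = catalogue or panel.catalogue
    counts = panel.counts()
    c, uv, n, _ = _weighted_urgency(counts, catalogue.u_by_code())
    if np.any(n < 2):
        bad = counts.index[n < 2].tolist()
        raise InvalidArgumentError(
            f"UrD needs >= 2 urgency-valued cases; offending rows: {bad[:5]}"
        )
    urs = (c @ uv) / n
    sq = c @ (uv**2)
    ss = sq - n * urs**2
    urd = np.sqrt(np.maximum(ss, 0.0) / (n - 1))
    return pd.DataFrame(
        {"urd": urd, "n_cases": n.astype(int)}, index=counts.index
    )


def urgency_measures(panel: HospitalPanel) -> pd.DataFrame:
    """UrS, UrD, case count, and adjusted inpatient volume in one table.

    Row order is deterministic: hospital, then year.
    """
    w = casemix_weights(panel.catalogue)
    adj = adjusted_inpatients(panel, w)
    urs = urgency_score(panel)
    urd = urgency_dispersion(panel)
    out = pd.DataFrame(
        {
            "urs": urs["urs"],
            "urd": urd["urd"],
            "n_cases": urs["n_cases"],
            "adjusted_inpatients": adj,
            "dominance": urs["dominance"],
        }
    )
    return out.sort_index()


def write_measures_csv(measures: pd.DataFrame, path) -> None:
    measures.reset_index().to_csv(path, index=False)
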