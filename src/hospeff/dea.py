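"""Nonparametric frontier estimation.

Farrell input-oriented technical efficiency under variable returns to scale
(VRS): for each decision-making unit (DMU) o with inputs x_o and outputs y_o,

    theta_o = min theta  s.t.  X' lam <= theta x_o,  Y' lam >= y_o,
                               sum(lam) = 1,  lam >= 0,

solved as one linear program per DMU against a common (intertemporal)
reference set. theta in (0, 1]; the Shephard distance is delta = 1/theta.
Constant returns (drop the convexity constraint) and the free disposal hull
(dominance only, no convexification) are provided for diagnostics, along
with Andersen-Petersen super-efficiency (DMU removed from its own reference
set; may exceed 1 or be infeasible under VRS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .data import HospitalPanel
from .errors import DataIntegrityError, InvalidArgumentError, NumericalError

logger = logging.getLogger(__name__)

DEFAULT_EPSILON_FLOOR = 0.01
_TOL = 1e-9

INPUT_COLUMNS = ["beds", "fte_physicians", "fte_rn", "fte_na"]
OUTPUT_NAMES = ["adjusted_inpatients", "outpatient_cases"]


@dataclass
class ProductionSet:
    """DMU-by-input and DMU-by-output matrices with labels.

    All inputs strictly positive (radial input measures are undefined at
    zero); outputs non-negative with at least one positive output per DMU.
    """

    dmu: list
    X: np.ndarray
    Y: np.ndarray
    input_names: list[str] = field(default_factory=list)
    output_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise InvalidArgumentError("X and Y must be 2-D")
        n = len(self.dmu)
        if self.X.shape[0] != n or self.Y.shape[0] != n:
            raise InvalidArgumentError("dmu labels and matrices disagree")
        if self.X.shape[1] < 1 or self.Y.shape[1] < 1:
            raise InvalidArgumentError("need >= 1 input and >= 1 output")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.Y)):
            raise InvalidArgumentError("non-finite entries in X or Y")
        if np.any(self.X <= 0):
            raise InvalidArgumentError(
                "all inputs must be > 0 (apply an epsilon floor upstream)"
            )
        if np.any(self.Y < 0) or np.any(self.Y.max(axis=1) <= 0):
            raise InvalidArgumentError(
                "outputs must be >= 0 with one positive output per DMU"
            )
        if not self.input_names:
            self.input_names = [f"x{i}" for i in range(self.X.shape[1])]
        if not self.output_names:
            self.output_names = [f"y{j}" for j in range(self.Y.shape[1])]

    @property
    def n(self) -> int:
        return len(self.dmu)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    def subset(self, mask: np.ndarray) -> "ProductionSet":
        mask = np.asarray(mask)
        return ProductionSet(
            dmu=[d for d, m in zip(self.dmu, mask) if m],
            X=self.X[mask],
            Y=self.Y[mask],
            input_names=list(self.input_names),
            output_names=list(self.output_names),
        )

    @classmethod
    def from_panel(
        cls,
        panel: HospitalPanel,
        adjusted: pd.Series,
        epsilon_floor: float = DEFAULT_EPSILON_FLOOR,
    ) -> "ProductionSet":
        """Build the 4-input / 2-output set the production model uses.

        Inputs: beds and the three FTE groups. Zero FTE cells occur in small
        hospitals; a radial input measure needs strictly positive inputs, so
        scattered zeros are floored at ``epsilon_floor`` with a logged
        warning, and an input column that is zero for every DMU is dropped
        (flooring it to a constant would force theta = 1 for all DMUs).
        Outputs: case-mix-adjusted inpatient volume and outpatient cases.
        """
        t = panel.table
        X = t[INPUT_COLUMNS].to_numpy(float).copy()
        input_names = list(INPUT_COLUMNS)
        all_zero = np.all(X <= 0, axis=0)
        if np.any(all_zero):
            dropped = [n for n, z in zip(input_names, all_zero) if z]
            logger.warning("dropping all-zero input columns: %s", dropped)
            X = X[:, ~all_zero]
            input_names = [n for n, z in zip(input_names, all_zero) if not z]
        n_floored = int((X <= 0).sum())
        if n_floored:
            logger.warning(
                "floored %d non-positive input cells to %.3g",
                n_floored,
                epsilon_floor,
            )
            X[X <= 0] = epsilon_floor
        adj = adjusted.reindex(panel.dmu_index()).to_numpy(float)
        if np.any(~np.isfinite(adj)):
            raise DataIntegrityError("adjusted inpatients missing for some DMUs")
        Y = np.column_stack([adj, t["outpatient_cases"].to_numpy(float)])
        dmu = list(panel.dmu_index())
        return cls(
            dmu=dmu,
            X=X,
            Y=Y,
            input_names=input_names,
            output_names=list(OUTPUT_NAMES),
        )


def _solve_radial_lp(
    x0: np.ndarray,
    y0: np.ndarray,
    Xref: np.ndarray,
    Yref: np.ndarray,
    vrs: bool,
):
    """One envelopment LP; returns (theta, status). status 0 = optimal."""
    n, p = Xref.shape
    q = Yref.shape[1]
    # variables: theta, lambda_1..n
    c = np.zeros(n + 1)
    c[0] = 1.0
    A_ub = np.empty((p + q, n + 1))
    A_ub[:p, 0] = -x0
    A_ub[:p, 1:] = Xref.T
    A_ub[p:, 0] = 0.0
    A_ub[p:, 1:] = -Yref.T
    b_ub = np.concatenate([np.zeros(p), -y0])
    if vrs:
        A_eq = np.ones((1, n + 1))
        A_eq[0, 0] = 0.0
        b_eq = np.ones(1)
    else:
        A_eq = b_eq = None
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(None, None)] + [(0, None)] * n,
        method="highs",
    )
    if res.status != 0:
        return np.nan, res.status
    return float(res.fun), 0


def _nondominated_mask(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """DMUs not weakly dominated (another DMU with <= inputs, >= outputs).

    Under input-oriented VRS the optimal intensity vector only needs
    non-dominated reference points (any weight on a dominated point can be
    moved to its dominator without losing feasibility), so the reference
    set may be shrunk to this subset without changing any score.
    """
    n = X.shape[0]
    le_x = np.all(X[:, None, :] <= X[None, :, :] + _TOL, axis=2)
    ge_y = np.all(Y[:, None, :] >= Y[None, :, :] - _TOL, axis=2)
    strict = np.any(X[:, None, :] < X[None, :, :] - _TOL, axis=2) | np.any(
        Y[:, None, :] > Y[None, :, :] + _TOL, axis=2
    )
    dominates = le_x & ge_y & strict  # [j, o]: j dominates o
    np.fill_diagonal(dominates, False)
    return ~dominates.any(axis=0)


def _batch_radial_vrs(
    Xref: np.ndarray, Yref: np.ndarray, X_eval: np.ndarray, Y_eval: np.ndarray
):
    """All evaluation LPs stacked into one block-diagonal sparse program."""
    nr, p = Xref.shape
    q = Yref.shape[1]
    ne = X_eval.shape[0]
    blocks = []
    for i in range(ne):
        A = np.empty((p + q + 1, nr + 1))
        A[:p, 0] = -X_eval[i]
        A[:p, 1:] = Xref.T
        A[p:p + q, 0] = 0.0
        A[p:p + q, 1:] = -Yref.T
        A[p + q, 0] = 0.0
        A[p + q, 1:] = 1.0  # convexity row, handled as equality below
        blocks.append(sparse.csr_matrix(A))
    rows_ub = [np.arange(p + q) + i * (p + q + 1) for i in range(ne)]
    full = sparse.block_diag(blocks, format="csr")
    keep_ub = np.concatenate(rows_ub)
    keep_eq = np.arange(p + q, ne * (p + q + 1), p + q + 1)
    A_ub = full[keep_ub]
    A_eq = full[keep_eq]
    b_ub = np.concatenate(
        [np.concatenate([np.zeros(p), -Y_eval[i]]) for i in range(ne)]
    )
    c = np.tile(np.concatenate([[1.0], np.zeros(nr)]), ne)
    bounds = [
        (None, None) if j % (nr + 1) == 0 else (0, None)
        for j in range(ne * (nr + 1))
    ]
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=np.ones(ne),
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        return None
    return res.x.reshape(ne, nr + 1)[:, 0]


def radial_input_scores(
    Xref: np.ndarray,
    Yref: np.ndarray,
    X_eval: np.ndarray | None = None,
    Y_eval: np.ndarray | None = None,
    vrs: bool = True,
    clip_at_one: bool = False,
    labels=None,
) -> np.ndarray:
    """Farrell input scores of evaluation points against a reference set.

    With the evaluation set equal to the reference set (the usual case)
    scores lie in (0, 1]; against a foreign reference (bootstrap pseudo
    frontiers) they may exceed 1. ``clip_at_one`` snaps tiny numerical
    overshoots when self-evaluation guarantees theta <= 1.

    VRS programs are solved as one batched sparse LP over the
    dominance-reduced reference set; a per-DMU fallback pinpoints the
    offending unit if the batch fails.
    """
    Xref = np.asarray(Xref, float)
    Yref = np.asarray(Yref, float)
    X_eval = Xref if X_eval is None else np.asarray(X_eval, float)
    Y_eval = Yref if Y_eval is None else np.asarray(Y_eval, float)
    out = None
    if vrs:
        keep = _nondominated_mask(Xref, Yref)
        Xr, Yr = Xref[keep], Yref[keep]
        out = _batch_radial_vrs(Xr, Yr, X_eval, Y_eval)
    if out is None:  # CRS, or batch failure: per-DMU loop
        out = np.empty(X_eval.shape[0])
        for i in range(X_eval.shape[0]):
            theta, status = _solve_radial_lp(
                X_eval[i], Y_eval[i], Xref, Yref, vrs
            )
            if status != 0:
                name = labels[i] if labels is not None else i
                raise NumericalError(
                    f"DEA LP failed for DMU {name!r} (HiGHS status {status});"
                    " self-referencing VRS programs are always feasible, so "
                    "failure signals solver trouble"
                )
            out[i] = theta
    if clip_at_one:
        if np.any(out > 1 + 1e-6):
            raise NumericalError("self-evaluated theta exceeded 1 materially")
        out = np.minimum(out, 1.0)
    return np.maximum(out, _TOL)


def dea_input_vrs(ps: ProductionSet, eval_mask: np.ndarray | None = None) -> pd.Series:
    """Input-oriented VRS efficiency against the full (pooled) reference set."""
    if eval_mask is None:
        Xe, Ye, labels = ps.X, ps.Y, ps.dmu
    else:
        eval_mask = np.asarray(eval_mask)
        Xe, Ye = ps.X[eval_mask], ps.Y[eval_mask]
        labels = [d for d, m in zip(ps.dmu, eval_mask) if m]
    theta = radial_input_scores(
        ps.X, ps.Y, Xe, Ye, vrs=True, clip_at_one=True, labels=labels
    )
    return pd.Series(theta, index=pd.Index(labels), name="theta")


def dea_input_crs(ps: ProductionSet) -> pd.Series:
    """Constant-returns variant (convexity constraint dropped); diagnostics only."""
    theta = radial_input_scores(
        ps.X, ps.Y, vrs=False, clip_at_one=True, labels=ps.dmu
    )
    return pd.Series(theta, index=pd.Index(ps.dmu), name="theta_crs")


def fdh_input(ps: ProductionSet) -> pd.Series:
    """Free disposal hull input efficiency (dominance only).

    theta_o = min over DMUs j dominating o in outputs of max_i x_{j,i}/x_{o,i};
    always >= the VRS score.
    """
    X, Y = ps.X, ps.Y
    n = ps.n
    theta = np.empty(n)
    for o in range(n):
        dominating = np.all(Y >= Y[o] - _TOL, axis=1)
        ratios = np.max(X[dominating] / X[o], axis=1)
        theta[o] = ratios.min()
    return pd.Series(
        np.minimum(theta, 1.0), index=pd.Index(ps.dmu), name="theta_fdh"
    )


def super_efficiency(ps: ProductionSet) -> pd.DataFrame:
    """Andersen-Petersen scores: own DMU excluded from the reference set.

    Scores may exceed 1; VRS exclusion can make the LP infeasible, which is
    reported as NaN with status "infeasible" rather than raised.
    """
    if ps.n < 2:
        raise InvalidArgumentError("super-efficiency needs >= 2 DMUs")
    scores = np.empty(ps.n)
    status = []
    for o in range(ps.n):
        mask = np.ones(ps.n, dtype=bool)
        mask[o] = False
        theta, st = _solve_radial_lp(
            ps.X[o], ps.Y[o], ps.X[mask], ps.Y[mask], vrs=True
        )
        if st == 0:
            scores[o] = theta
            status.append("ok")
        else:
            scores[o] = np.nan
            status.append("infeasible")
    return pd.DataFrame(
        {"superefficiency": scores, "status": status}, index=pd.Index(ps.dmu)
    )


@dataclass(frozen=True)
class DimensionalityReport:
    n: int
    dims: int  # p + q
    effective_sample_size: float
    fdh_efficient_share: float
    flag: str  # "pass" | "warn"


def dimensionality_diagnostics(
    ps: ProductionSet, warn_share: float = 0.5
) -> DimensionalityReport:
    """Curse-of-dimensionality diagnostics.

    Reports the effective sample size n^(2/(p+q+1)) — the parametric-rate
    equivalent of the nonparametric convergence rate — and the share of
    DMUs that are FDH-efficient; a high share warns that the sample cannot
    discriminate in this many dimensions.
    """
    theta_fdh = fdh_input(ps).to_numpy()
    share = float(np.mean(theta_fdh >= 1 - _TOL))
    dims = ps.p + ps.q
    eff = float(ps.n ** (2.0 / (dims + 1)))
    return DimensionalityReport(
        n=ps.n,
        dims=dims,
        effective_sample_size=eff,
        fdh_efficient_share=share,
        flag="warn" if share > warn_share else "pass",
    )


SCORE_BINS = ["1.00", "0.80-0.99", "0.60-0.79", "0.40-0.59", "<0.40"]


def bin_scores(scores) -> pd.Series:
    """Frequency table of efficiency scores over the standard reporting bins.

    A score counts as 1.00 only at (numerical) equality with one; the
    remaining bins are [0.80, 1), [0.60, 0.80), [0.40, 0.60), [0, 0.40).
    Shares sum to 1.
    """
    s = np.asarray(scores, dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise InvalidArgumentError("scores must be finite and > 0")
    if np.any(s > 1 + _TOL):
        raise InvalidArgumentError("scores above 1: use the Farrell scale")
    ones = s >= 1 - _TOL
    shares = np.array(
        [
            np.mean(ones),
            np.mean(~ones & (s >= 0.80)),
            np.mean(~ones & (s >= 0.60) & (s < 0.80)),
            np.mean(~ones & (s >= 0.40) & (s < 0.60)),
            np.mean(~ones & (s < 0.40)),
        ]
    )
    return pd.Series(shares, index=SCORE_BINS, name="share")
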