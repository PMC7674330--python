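"""Simar-Wilson double-bootstrap inference for two-stage DEA (algorithm #2).

The procedure couples the first-stage frontier estimate with the
second-stage truncated regression so that both the finite-sample bias of
the DEA scores and the serial dependence they induce are accounted for:

1. estimate Farrell scores theta-hat by DEA; work on the Shephard scale
   delta-hat = 1/theta-hat;
2. fit the left-truncated normal regression of delta-hat on the contextual
   variables z using the interior (delta-hat > 1) observations -> beta-hat,
   sigma-hat;
3. inner loop (L1 times): draw delta*_i ~ N(z_i beta-hat, sigma-hat^2)
   truncated at 1, rescale each DMU's inputs onto the implied pseudo
   frontier (x*_i = x_i * delta*_i / delta-hat_i), and re-evaluate the
   original DMUs against the pseudo reference set -> delta-hat*_{i,b};
4. bias-correct: bias_i = mean_b delta-hat*_{i,b} - delta-hat_i and
   delta-tilde_i = delta-hat_i - bias_i (strictly > 1 in practice, so the
   bias-corrected Farrell score is strictly < 1);
5. refit the truncated regression on delta-tilde -> beta-tilde, sigma-tilde;
6. outer loop (L2 times): simulate delta** from the fitted truncated model
   and refit the MLE; percentile intervals and bootstrap SEs of the
   coefficients come from these draws.

Replication counts default to L1 = 100 and L2 = 2000. Coefficients are
reported on the efficiency (Farrell) scale by sign-flipping the
Shephard-scale fit, so that positive coefficients read "more efficient";
the Shephard scale is available via ``scale="shephard"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dea import ProductionSet, dea_input_vrs, radial_input_scores
from .design import build_design
from .errors import InsufficientDataError, InvalidArgumentError, NumericalError
from .truncreg import TruncRegFit, sample_truncated, truncreg_mle

logger = logging.getLogger(__name__)

DEFAULT_L1 = 100
DEFAULT_L2 = 2000
_INTERIOR_TOL = 1e-9


@dataclass
class DoubleBootstrapResult:
    """Bias-corrected scores plus coefficient inference from algorithm #2."""

    scores: pd.DataFrame  # theta, delta, theta_bc, delta_bc, bias, ci_low, ci_high
    coef: pd.DataFrame  # estimate, se, ci_low, ci_high, stars (reporting scale)
    draws: np.ndarray  # L2 x (k+1) Shephard-scale coefficient+sigma draws
    fit_initial: TruncRegFit
    fit_bias_corrected: TruncRegFit
    L1: int
    L2: int
    seed: int
    scale: str
    alpha: float
    n_failed_inner: int
    n_failed_outer: int
    z_means: pd.Series
    urs_range: tuple | None
    ci_covers_estimate: bool = field(default=True)

    @property
    def coef_names(self) -> list[str]:
        return list(self.coef.index)


def _stars_from_draws(draws: np.ndarray, estimate: float) -> str:
    """Percentile-CI inversion at the 1/5/10% levels."""
    for stars, level in (("***", 0.01), ("**", 0.05), ("*", 0.10)):
        lo, hi = np.percentile(draws, [100 * level / 2, 100 * (1 - level / 2)])
        if lo > 0 or hi < 0:
            return stars
    return ""


def algorithm2(
    ps: ProductionSet,
    Z: pd.DataFrame,
    L1: int = DEFAULT_L1,
    L2: int = DEFAULT_L2,
    seed: int = 0,
    scale: str = "farrell",
    alpha: float = 0.05,
    max_retries: int = 5,
) -> DoubleBootstrapResult:
    """Run the double bootstrap on a production set and covariate frame.

    ``Z`` must contain an ``intercept`` column and be row-aligned with
    ``ps.dmu``. The seed feeds one master stream from which every
    replication draws an independent substream, so runs are bit-reproducible.
    """
    if L1 < 1 or L2 < 1:
        raise InvalidArgumentError("L1 and L2 must be >= 1")
    if scale not in ("farrell", "shephard"):
        raise InvalidArgumentError("scale must be 'farrell' or 'shephard'")
    if len(Z) != ps.n:
        raise InvalidArgumentError("Z rows must align with ps.dmu")
    Zmat = Z.to_numpy(float)
    names = list(Z.columns)
    n, k = Zmat.shape

    streams = np.random.SeedSequence(seed).spawn(L1 + L2)

    # step 1: conventional scores
    theta = dea_input_vrs(ps).to_numpy()
    delta = 1.0 / theta

    # step 2: truncated MLE on interior observations
    fit1 = truncreg_mle(delta, Z)
    mu1 = Zmat @ fit1.beta

    # step 3: inner loop -> pseudo frontiers, re-evaluated distances
    delta_star = np.empty((L1, n))
    n_failed_inner = 0
    for b in range(L1):
        rng_b = np.random.default_rng(streams[b])
        got = False
        for _ in range(max_retries):
            dstar = sample_truncated(rng_b, mu1, fit1.sigma, lower=1.0)
            X_pseudo = ps.X * (dstar / delta)[:, None]
            try:
                theta_b = radial_input_scores(
                    X_pseudo, ps.Y, ps.X, ps.Y, vrs=True, labels=ps.dmu
                )
            except NumericalError:
                continue
            delta_star[b] = 1.0 / theta_b
            got = True
            break
        if not got:
            delta_star[b] = np.nan
            n_failed_inner += 1
    if n_failed_inner:
        logger.warning("%d inner replications failed", n_failed_inner)

    # step 4: bias correction
    bias = np.nanmean(delta_star, axis=0) - delta
    delta_bc = delta - bias
    theta_bc = 1.0 / delta_bc
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    d_lo = 2 * delta - np.nanpercentile(delta_star, hi_q, axis=0)
    d_hi = 2 * delta - np.nanpercentile(delta_star, lo_q, axis=0)

    # step 5: refit on bias-corrected distances
    fit2 = truncreg_mle(delta_bc, Z)
    if fit2.n_used < n:
        logger.warning(
            "%d bias-corrected distances were not interior", n - fit2.n_used
        )
    mu2 = Zmat @ fit2.beta

    # step 6: outer loop -> coefficient draws
    draws = np.full((L2, k + 1), np.nan)
    n_failed_outer = 0
    for b in range(L2):
        rng_b = np.random.default_rng(streams[L1 + b])
        got = False
        for _ in range(max_retries):
            dstar = sample_truncated(rng_b, mu2, fit2.sigma, lower=1.0)
            try:
                f = truncreg_mle(dstar, Zmat, names=names)
            except (InsufficientDataError, NumericalError):
                continue
            draws[b, :k] = f.beta
            draws[b, k] = f.sigma
            got = True
            break
        if not got:
            n_failed_outer += 1
    if n_failed_outer:
        logger.warning("%d outer replications failed", n_failed_outer)
    ok = ~np.isnan(draws[:, 0])
    coef_draws = draws[ok][:, :k]

    est_shep = fit2.beta
    se = np.std(coef_draws, axis=0, ddof=1)
    ci_lo = np.percentile(coef_draws, lo_q, axis=0)
    ci_hi = np.percentile(coef_draws, hi_q, axis=0)
    stars = [
        _stars_from_draws(coef_draws[:, j], est_shep[j]) for j in range(k)
    ]
    if scale == "farrell":
        est, lo, hi = -est_shep, -ci_hi, -ci_lo
    else:
        est, lo, hi = est_shep, ci_lo, ci_hi
    coef = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": lo,
            "ci_high": hi,
            "stars": stars,
        },
        index=pd.Index(names, name="variable"),
    )
    covers = np.mean((coef["ci_low"] <= coef["estimate"])
                     & (coef["estimate"] <= coef["ci_high"]))
    if covers < 0.9:
        logger.warning(
            "percentile CIs cover only %.0f%% of point estimates", 100 * covers
        )

    scores = pd.DataFrame(
        {
            "theta": theta,
            "delta": delta,
            "theta_bc": theta_bc,
            "delta_bc": delta_bc,
            "bias": bias,
            "ci_low": 1.0 / d_hi,
            "ci_high": 1.0 / d_lo,
        },
        index=pd.Index(ps.dmu),
    )
    urs_range = None
    if "urs" in Z.columns:
        urs_range = (float(Z["urs"].min()), float(Z["urs"].max()))
    return DoubleBootstrapResult(
        scores=scores,
        coef=coef,
        draws=draws,
        fit_initial=fit1,
        fit_bias_corrected=fit2,
        L1=L1,
        L2=L2,
        seed=seed,
        scale=scale,
        alpha=alpha,
        n_failed_inner=n_failed_inner,
        n_failed_outer=n_failed_outer,
        z_means=Z.mean(),
        urs_range=urs_range,
        ci_covers_estimate=bool(covers >= 0.9),
    )


def model_ladder(
    ps: ProductionSet,
    table: pd.DataFrame,
    L1: int = DEFAULT_L1,
    L2: int = DEFAULT_L2,
    seed: int = 0,
    scale: str = "farrell",
    alpha: float = 0.05,
    reference_year: int = 2017,
) -> dict[str, DoubleBootstrapResult]:
    """The three-model specification ladder.

    Model I: linear UrS plus controls; Model II adds UrS squared; Model III
    adds the urgency dispersion. Controls: ownership dummies (public
    reference), teaching status, market concentration, location dummies
    (large-city reference), and year dummies (reference year configurable).
    """
    specs = {
        "I": dict(include_urs2=False, include_urd=False),
        "II": dict(include_urs2=True, include_urd=False),
        "III": dict(include_urs2=True, include_urd=True),
    }
    seeds = np.random.SeedSequence(seed).spawn(len(specs))
    out = {}
    for (name, spec), ss in zip(specs.items(), seeds):
        Z = build_design(table, reference_year=reference_year, **spec)
        out[name] = algorithm2(
            ps,
            Z,
            L1=L1,
            L2=L2,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            scale=scale,
            alpha=alpha,
        )
    return out


def quadratic_vertex(b_lin: float, b_sq: float) -> float:
    """Turning point -b1/(2 b2) of a quadratic coefficient pair."""
    if b_sq == 0:
        raise InvalidArgumentError("no vertex: squared coefficient is zero")
    return -b_lin / (2.0 * b_sq)


@dataclass
class MarginsGrid:
    """Predictive margins of efficiency over a UrS grid with pointwise CIs."""

    table: pd.DataFrame  # urs, fit, lo, hi
    scale: str
    fix_rule: str


def predictive_margins(
    result: DoubleBootstrapResult,
    grid,
    fix_rule: str = "means",
    urs_col: str = "urs",
    urs2_col: str = "urs2",
) -> MarginsGrid:
    """Predicted efficiency across UrS, other covariates fixed at means.

    For each outer-bootstrap coefficient draw the Shephard-scale linear
    predictor is evaluated on the grid and mapped to the efficiency scale as
    its reciprocal; the point curve and pointwise CIs are the mean and the
    2.5/97.5 percentiles across draws. The grid must stay within the
    observed UrS range.
    """
    if fix_rule != "means":
        raise InvalidArgumentError("only fix_rule='means' is supported")
    grid = np.asarray(grid, float)
    names = result.coef_names
    if urs_col in names:
        if result.urs_range is None:
            raise InvalidArgumentError("fit has no UrS column")
        lo, hi = result.urs_range
        if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
            raise InvalidArgumentError(
                f"grid [{grid.min():.3f}, {grid.max():.3f}] outside observed "
                f"UrS range [{lo:.3f}, {hi:.3f}]"
            )
    draws = result.draws
    ok = ~np.isnan(draws[:, 0])
    B = draws[ok][:, : len(names)]  # Shephard scale
    zbar = result.z_means.reindex(names).to_numpy(float)
    base = np.tile(zbar, (len(grid), 1))
    for col, vals in ((urs_col, grid), (urs2_col, grid**2)):
        if col in names:
            base[:, names.index(col)] = vals
    eta = base @ B.T  # grid x draws, Shephard linear predictor
    pred = 1.0 / eta if result.scale == "farrell" else eta
    fit = pred.mean(axis=1)
    lo_b, hi_b = np.percentile(pred, [2.5, 97.5], axis=1)
    table = pd.DataFrame({"urs": grid, "fit": fit, "lo": lo_b, "hi": hi_b})
    return MarginsGrid(table=table, scale=result.scale, fix_rule=fix_rule)
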