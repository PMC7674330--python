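"""Synthetic hospital populations with a known two-stage ground truth.

The generator emulates the statistical structure of a national acute-care
hospital census: a diagnosis catalogue with urgency values and group lengths
of stay; hospital-year records with four inputs (beds and three FTE groups),
two outputs (severity-adjusted inpatient and outpatient volume), diagnosis
count vectors, structural covariates, and coordinates with both clustered
(urban agglomeration) and isolated hospitals so market concentration spans
near-0 to 1.

The known-truth data-generating process runs the second-stage model in
reverse. For each hospital-year:

1. diagnosis counts are drawn Dirichlet-multinomial around a per-hospital
   urgency target (the Dirichlet concentration and the urgency tilt
   bandwidth control the dispersion measure UrD);
2. the realized urgency score, dispersion, and market concentration enter a
   covariate vector z, and the true Shephard inefficiency is
   delta = z'beta + eps with eps ~ N(0, sigma^2) left-truncated so
   delta >= 1 (drawn by inverse CDF);
3. an efficient input bundle is placed exactly on a monotone convex
   input-requirement frontier (Cobb-Douglas in inputs, CES-type aggregate of
   the two outputs with decreasing returns to scale, randomized input mix
   along the isoquant), then all inputs are scaled by delta.

By construction the generated bundle's true input-oriented Shephard distance
to the frontier is exactly delta, giving recovery tests a sharp target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import DIAG_PREFIX, HospitalPanel, UrgencyCatalogue
from .design import build_design
from .errors import InvalidArgumentError
from .market import hhi_table
from .measures import casemix_weights, adjusted_inpatients, urgency_measures
from .truncreg import sample_truncated

# Shephard-scale coefficients: positive = more inefficient. The focal block
# encodes a u-shape of efficiency in UrS (vertex near 0.44) and an
# efficiency penalty for urgency dispersion; control effects are an order
# of magnitude smaller, as in observed hospital samples.
DEFAULT_BETA: dict[str, float] = {
    "intercept": 0.90,
    "urs": 2.40,
    "urs2": -2.70,
    "urd": 0.80,
    "own_nonprofit": 0.07,
    "own_forprofit": -0.03,
    "teaching": 0.04,
    "hhi": -0.40,
    "loc_urban": -0.06,
    "loc_rural": -0.025,
    "loc_remote": 0.015,
    "year_2015": 0.010,
    "year_2016": 0.005,
}


@dataclass(frozen=True)
class FrontierParams:
    """Monotone convex input-requirement frontier.

    Required input aggregate: prod_k x_k^alpha_k = c(y) with
    c(y) = c0 * (w1 (y1/Y1)^kappa + w2 (y2/Y2)^kappa)^(rho/kappa).
    kappa >= 1 and rho >= 1 keep c convex (VRS-compatible); rho > 1 gives
    decreasing returns to scale. ``input_scale`` sets the typical efficient
    bundle (beds, physician/RN/assistant FTEs) at the reference outputs;
    ``mix_sd`` randomizes the input mix along the isoquant.
    """

    input_exponents: tuple = (0.30, 0.20, 0.35, 0.15)
    input_scale: tuple = (175.0, 53.0, 131.0, 8.8)
    output_weights: tuple = (0.65, 0.35)
    output_reference: tuple = (6500.0, 18000.0)
    kappa: float = 1.3
    rho: float = 1.2
    mix_sd: float = 0.10

    def validate(self) -> None:
        if len(self.input_exponents) != len(self.input_scale):
            raise InvalidArgumentError("frontier input dimensions disagree")
        if min(self.input_exponents) <= 0 or min(self.input_scale) <= 0:
            raise InvalidArgumentError("frontier parameters must be positive")
        if self.kappa < 1 or self.rho < 1:
            raise InvalidArgumentError(
                "kappa and rho must be >= 1 for a convex input requirement"
            )
        if min(self.output_weights) <= 0 or min(self.output_reference) <= 0:
            raise InvalidArgumentError("output weights/reference must be > 0")

    def required_aggregate(self, y1, y2) -> np.ndarray:
        """c(y): required Cobb-Douglas input aggregate.

        Normalized so that at the reference outputs the efficient bundle is
        exactly ``input_scale``.
        """
        w1, w2 = self.output_weights
        y1r = np.asarray(y1, float) / self.output_reference[0]
        y2r = np.asarray(y2, float) / self.output_reference[1]
        alpha = np.asarray(self.input_exponents, float)
        c0 = float(np.prod(np.asarray(self.input_scale, float) ** alpha))
        wsum = w1 + w2
        return c0 * (
            (w1 * y1r**self.kappa + w2 * y2r**self.kappa) / wsum
        ) ** (self.rho / self.kappa)


@dataclass
class TruthConfig:
    """Ground-truth parameters of the two-stage generating process."""

    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma: float = 0.15
    frontier: FrontierParams = field(default_factory=FrontierParams)
    # case-composition process
    urgency_target_mean: float = 0.46
    urgency_target_sd: float = 0.18
    tilt_bandwidth: float = 0.30
    concentration: float = 30.0
    mean_cases: float = 5500.0
    cases_log_sd: float = 0.55
    mean_outpatients: float = 18000.0
    outpatients_log_sd: float = 0.60
    year_jitter_sd: float = 0.08
    # geography; n_clusters None -> one cluster per ~14 hospitals, so market
    # density (hence the HHI distribution) is stable across population sizes
    n_clusters: int | None = None
    isolated_share: float = 0.20
    cluster_jitter_deg: float = 0.05
    lat_range: tuple = (47.5, 54.5)
    lon_range: tuple = (6.5, 14.5)
    # covariate frequencies (public/nonprofit/forprofit; teaching;
    # large_city/urban/rural/remote)
    ownership_probs: tuple = (0.34, 0.44, 0.22)
    teaching_prob: float = 0.57
    location_probs: tuple = (0.28, 0.35, 0.18, 0.19)
    reference_year: int = 2017

    def validate(self) -> None:
        if self.sigma <= 0:
            raise InvalidArgumentError("truth sigma must be > 0")
        if self.concentration <= 0 or self.tilt_bandwidth <= 0:
            raise InvalidArgumentError(
                "concentration and tilt bandwidth must be > 0"
            )
        self.frontier.validate()


@dataclass
class SyntheticTruth:
    """Realized ground truth returned alongside a generated panel."""

    beta: pd.Series  # aligned to the realized design columns
    sigma: float
    delta: pd.Series  # true Shephard inefficiency per DMU (>= 1)
    frontier_params: FrontierParams
    seed: int
    z: pd.DataFrame  # realized design matrix (intercept first)


def generate_catalogue(
    n_codes: int,
    n_groups: int,
    n_chapters: int,
    seed: int,
    mixture_weights: tuple = (0.45, 0.30, 0.25),
    low_shape: tuple = (2.0, 8.0),
    high_shape: tuple = (8.0, 2.0),
    los_log_mean: float = np.log(6.0),
    los_log_sd: float = 0.45,
) -> UrgencyCatalogue:
    """Random diagnosis catalogue.

    Urgency values come from a three-component mixture (mass near 0, mass
    near 1, a uniform component) so both the elective- and the
    emergency-dominated regime are reachable; the mixture shape is a
    configurable stand-in for the unknown empirical distribution. Lengths of
    stay are log-normal per group, shared by all codes in a group. Codes are
    partitioned over groups, groups over chapters.
    """
    if n_codes < 1 or n_groups < 1 or n_chapters < 1:
        raise InvalidArgumentError("counts must be positive")
    if n_codes < n_groups:
        raise InvalidArgumentError("need n_codes >= n_groups")
    if n_groups < n_chapters:
        raise InvalidArgumentError("need n_groups >= n_chapters")
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n_codes, p=np.asarray(mixture_weights))
    u = np.where(
        comp == 0,
        rng.beta(*low_shape, size=n_codes),
        np.where(
            comp == 1,
            rng.beta(*high_shape, size=n_codes),
            rng.uniform(size=n_codes),
        ),
    )
    # spread codes over groups round-robin, groups over chapters round-robin
    group = 1 + (np.arange(n_codes) % n_groups)
    chapter_of_group = 1 + (np.arange(n_groups) % n_chapters)
    group_los = np.exp(rng.normal(los_log_mean, los_log_sd, size=n_groups))
    digits = max(4, len(str(n_codes)))
    table = pd.DataFrame(
        {
            "code": [f"D{i:0{digits}d}" for i in range(n_codes)],
            "u": u,
            "group": group,
            "chapter": chapter_of_group[group - 1],
            "los": group_los[group - 1],
        }
    )
    return UrgencyCatalogue(table)


def _draw_coordinates(rng, n, cfg: TruthConfig):
    lat0, lat1 = cfg.lat_range
    lon0, lon1 = cfg.lon_range
    n_clusters = cfg.n_clusters or max(2, int(np.ceil(n / 14)))
    centers = np.column_stack(
        [
            rng.uniform(lat0, lat1, size=n_clusters),
            rng.uniform(lon0, lon1, size=n_clusters),
        ]
    )
    isolated = rng.uniform(size=n) < cfg.isolated_share
    which = rng.integers(0, n_clusters, size=n)
    jitter = rng.normal(0.0, cfg.cluster_jitter_deg, size=(n, 2))
    clustered = centers[which] + jitter
    free = np.column_stack(
        [rng.uniform(lat0, lat1, size=n), rng.uniform(lon0, lon1, size=n)]
    )
    coords = np.where(isolated[:, None], free, clustered)
    return coords[:, 0], coords[:, 1]


def _draw_counts(rng, catalogue, targets, totals, cfg: TruthConfig):
    """Dirichlet-multinomial diagnosis counts tilted toward a target urgency."""
    u = catalogue.table["u"].to_numpy(float)
    u_fill = np.where(np.isfinite(u), u, 0.5)
    h2 = 2.0 * cfg.tilt_bandwidth**2
    counts = np.empty((len(targets), len(u)), dtype=np.int64)
    for i, (t, n_cases) in enumerate(zip(targets, totals)):
        w = np.exp(-((u_fill - t) ** 2) / h2)
        alpha = cfg.concentration * w / w.sum()
        p = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(int(n_cases), p)
    return counts


def generate_panel(
    catalogue: UrgencyCatalogue,
    n_hospitals: int,
    years: list[int],
    truth: TruthConfig | None = None,
    seed: int = 0,
) -> tuple[HospitalPanel, SyntheticTruth]:
    """Balanced hospital-by-year panel with known two-stage truth.

    Hospital-level covariates (ownership, teaching, location, coordinates,
    urgency target, size) are fixed across years; case counts and the
    inefficiency draw are year-specific. Returns the panel and the realized
    ground truth (aligned coefficient vector, sigma, per-DMU delta).
    """
    if n_hospitals < 2:
        raise InvalidArgumentError("need at least 2 hospitals")
    if not years:
        raise InvalidArgumentError("need at least one year")
    truth = truth or TruthConfig()
    truth.validate()
    rng = np.random.default_rng(seed)
    cfg = truth

    # hospital-level structure
    hid = [f"h{i:04d}" for i in range(n_hospitals)]
    ownership = rng.choice(
        ["public", "nonprofit", "forprofit"],
        size=n_hospitals,
        p=np.asarray(cfg.ownership_probs),
    )
    teaching = (rng.uniform(size=n_hospitals) < cfg.teaching_prob).astype(int)
    location = rng.choice(
        ["large_city", "urban", "rural", "remote"],
        size=n_hospitals,
        p=np.asarray(cfg.location_probs),
    )
    lat, lon = _draw_coordinates(rng, n_hospitals, cfg)
    if cfg.urgency_target_sd > 0:
        m, v = cfg.urgency_target_mean, cfg.urgency_target_sd**2
        nu = m * (1 - m) / v - 1
        targets = rng.beta(m * nu, (1 - m) * nu, size=n_hospitals)
    else:
        targets = np.full(n_hospitals, cfg.urgency_target_mean)
    base_cases = np.exp(
        rng.normal(np.log(cfg.mean_cases), cfg.cases_log_sd, size=n_hospitals)
    )
    base_outp = np.exp(
        rng.normal(
            np.log(cfg.mean_outpatients),
            cfg.outpatients_log_sd,
            size=n_hospitals,
        )
    )

    # hospital-year rows (sorted order: hospital, then year)
    years = sorted(int(y) for y in years)
    rows = []
    counts_rows = []
    for i in range(n_hospitals):
        for y in years:
            n_cases = max(
                50, int(base_cases[i] * np.exp(rng.normal(0, cfg.year_jitter_sd)))
            )
            outp = base_outp[i] * np.exp(rng.normal(0, cfg.year_jitter_sd))
            counts = _draw_counts(
                rng, catalogue, [targets[i]], [n_cases], cfg
            )[0]
            counts_rows.append(counts)
            rows.append(
                {
                    "hospital": hid[i],
                    "year": y,
                    "ownership": ownership[i],
                    "teaching": teaching[i],
                    "location": location[i],
                    "lat": lat[i],
                    "lon": lon[i],
                    "htype": "general",
                    "outpatient_cases": outp,
                }
            )
    table = pd.DataFrame(rows)
    counts_mat = np.vstack(counts_rows)
    codes = catalogue.table["code"].tolist()
    table = pd.concat(
        [
            table,
            pd.DataFrame(
                counts_mat,
                columns=[DIAG_PREFIX + c for c in codes],
                index=table.index,
            ),
        ],
        axis=1,
    )
    # placeholder inputs so the provisional panel validates; real inputs
    # depend on delta, which depends on the realized covariates below
    for c in ("beds", "fte_physicians", "fte_rn", "fte_na"):
        table[c] = 1.0
    provisional = HospitalPanel(table.copy(), catalogue)

    # realized second-stage covariates
    meas = urgency_measures(provisional)
    hhi = hhi_table(provisional, catalogue)
    merged = provisional.table[
        ["hospital", "year", "ownership", "teaching", "location"]
    ].copy()
    merged.index = provisional.dmu_index()
    merged["urs"] = meas["urs"]
    merged["urd"] = meas["urd"]
    merged["hhi"] = hhi["hhi"]
    Z = build_design(
        merged,
        include_urs2=True,
        include_urd=True,
        reference_year=cfg.reference_year,
    )
    beta = pd.Series(
        {c: float(cfg.beta.get(c, 0.0)) for c in Z.columns}, index=Z.columns
    )
    mu = Z.to_numpy() @ beta.to_numpy()
    delta = sample_truncated(rng, mu, cfg.sigma, lower=1.0)

    # efficient bundle on the frontier, then radially scaled by delta
    w = casemix_weights(catalogue)
    adj = adjusted_inpatients(provisional, w)
    ptable = provisional.table
    y1 = adj.to_numpy(float)
    y2 = ptable["outpatient_cases"].to_numpy(float)
    fp = cfg.frontier
    alpha = np.asarray(fp.input_exponents, float)
    scale = np.asarray(fp.input_scale, float)
    c_req = fp.required_aggregate(y1, y2)
    n_rows = len(ptable)
    mix = scale[None, :] * np.exp(
        rng.normal(0.0, fp.mix_sd, size=(n_rows, len(alpha)))
    )
    agg = np.prod(mix ** alpha[None, :], axis=1)
    s = (c_req / agg) ** (1.0 / alpha.sum())
    x_eff = mix * s[:, None]
    X = x_eff * delta[:, None]
    ptable["beds"] = np.maximum(np.round(X[:, 0]), 1.0)
    ptable["fte_physicians"] = X[:, 1]
    ptable["fte_rn"] = X[:, 2]
    ptable["fte_na"] = X[:, 3]

    panel = HospitalPanel(ptable, catalogue)
    idx = provisional.dmu_index()
    return panel, SyntheticTruth(
        beta=beta,
        sigma=cfg.sigma,
        delta=pd.Series(delta, index=idx, name="delta"),
        frontier_params=fp,
        seed=seed,
        z=Z,
    )


def truncated_mean(mu: np.ndarray, sigma: float, lower: float = 1.0):
    """Analytic mean of N(mu, sigma^2) left-truncated at ``lower``."""
    a = (lower - np.asarray(mu, float)) / sigma
    lam = np.exp(stats.norm.logpdf(a) - stats.norm.logsf(a))
    return mu + sigma * lam
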