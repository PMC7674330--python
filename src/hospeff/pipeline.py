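"""End-to-end study orchestration: data in, tables out.

Runs the whole analysis at desk scale — exclusions, case-composition
measures, market concentration, frontier estimation with diagnostics, the
double-bootstrap regression ladder, predictive margins — and writes
deterministic CSV artifacts plus a run manifest. A sensitivity suite
re-runs the pipeline under the five standard perturbations (outpatient
output dropped, nursing FTEs merged, PCA single-FTE aggregation,
super-efficiency trimming at 1.2, per-year estimation) and a robustness
verdict compares the focal coefficients across variants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from . import __version__
from .bootstrap import (
    DoubleBootstrapResult,
    model_ladder,
    predictive_margins,
)
from .data import HospitalPanel, UrgencyCatalogue
from .dea import (
    ProductionSet,
    bin_scores,
    dimensionality_diagnostics,
    super_efficiency,
)
from .errors import InvalidArgumentError
from .market import hhi_table, write_hhi_csv
from .measures import urgency_measures, write_measures_csv

logger = logging.getLogger(__name__)

EXCLUDED_TYPES_DEFAULT = (
    "university",
    "psychiatric",
    "pediatric",
    "geriatric",
    "rehabilitation",
    "day_night",
)

FOCAL_MODEL = {"urs": "II", "urs2": "II", "urd": "III"}


@dataclass
class AnalysisConfig:
    """Everything a study run needs; serialized into the run manifest."""

    panel_csv: str | None = None
    catalogue_csv: str | None = None
    output_dir: str = "results/run"
    min_beds: int = 50
    excluded_types: tuple = EXCLUDED_TYPES_DEFAULT
    radius_km: float = 32.0
    epsilon_floor: float = 0.01
    L1: int = 100
    L2: int = 2000
    seed: int = 1
    scale: str = "farrell"
    alpha: float = 0.05
    reference_year: int = 2017
    superefficiency_trim: float = 1.2
    margins_points: int = 25
    sensitivity_L2: int | None = None  # smaller outer loop for variants

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["excluded_types"] = list(d["excluded_types"])
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "excluded_types" in raw:
            raw["excluded_types"] = tuple(raw["excluded_types"])
        return cls(**raw)


@dataclass
class ResultsBundle:
    config: AnalysisConfig
    panel: HospitalPanel
    exclusion_log: dict
    measures: pd.DataFrame
    hhi: pd.DataFrame
    production_set: ProductionSet
    scores: pd.DataFrame
    bins: pd.DataFrame
    diagnostics: dict
    ladder: dict[str, DoubleBootstrapResult]
    margins: pd.DataFrame
    table: pd.DataFrame = field(repr=False, default=None)


def apply_exclusions(
    panel: HospitalPanel, config: AnalysisConfig
) -> tuple[HospitalPanel, dict]:
    """Drop small hospitals and flagged facility types; log counts per rule.

    The bed threshold is strict (< min_beds excluded, min_beds retained).
    """
    t = panel.table
    log: dict[str, int] = {}
    small = t["beds"] < config.min_beds
    log[f"beds<{config.min_beds}"] = int(small.sum())
    drop = small.copy()
    for ht in config.excluded_types:
        hit = (t["htype"] == ht) & ~drop
        log[f"type:{ht}"] = int(((t["htype"] == ht)).sum())
        drop |= t["htype"] == ht
    kept = t[~drop].reset_index(drop=True)
    if len(kept) == 0:
        raise InvalidArgumentError("no hospitals remain after exclusions")
    log["excluded_total"] = int(drop.sum())
    log["retained"] = int(len(kept))
    return HospitalPanel(kept, panel.catalogue), log


def _merged_table(panel: HospitalPanel, measures, hhi) -> pd.DataFrame:
    merged = panel.table[
        ["hospital", "year", "ownership", "teaching", "location"]
    ].copy()
    merged.index = panel.dmu_index()
    merged["urs"] = measures["urs"]
    merged["urd"] = measures["urd"]
    merged["hhi"] = hhi["hhi"]
    return merged


def _write_regression_csv(result: DoubleBootstrapResult, path) -> None:
    out = result.coef.reset_index()
    out["L1"] = result.L1
    out["L2"] = result.L2
    out["scale"] = result.scale
    out.to_csv(path, index=False)


def run_study(
    config: AnalysisConfig,
    panel: HospitalPanel | None = None,
    catalogue: UrgencyCatalogue | None = None,
) -> ResultsBundle:
    """Execute the full pipeline and write artifacts to ``output_dir``.

    Deterministic given the config (same config -> byte-identical CSVs).
    On a stage failure all partial outputs of this run are removed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    stage = "load"
    try:
        if panel is None:
            if config.catalogue_csv is None or config.panel_csv is None:
                raise InvalidArgumentError(
                    "provide panel/catalogue objects or CSV paths"
                )
            catalogue = UrgencyCatalogue.from_csv(config.catalogue_csv)
            panel = HospitalPanel.from_csv(config.panel_csv, catalogue)
        catalogue = catalogue or panel.catalogue

        stage = "exclusions"
        panel, exclusion_log = apply_exclusions(panel, config)
        _write(
            "exclusions.json",
            lambda p: p.write_text(json.dumps(exclusion_log, indent=2)),
        )

        stage = "measures"
        measures = urgency_measures(panel)
        _write("measures.csv", lambda p: write_measures_csv(measures, p))

        stage = "market"
        hhi = hhi_table(panel, catalogue, radius_km=config.radius_km)
        _write("hhi.csv", lambda p: write_hhi_csv(hhi, p))

        stage = "dea"
        ps = ProductionSet.from_panel(
            panel, measures["adjusted_inpatients"], config.epsilon_floor
        )
        diag = dimensionality_diagnostics(ps)
        supereff = super_efficiency(ps)

        stage = "inference"
        table = _merged_table(panel, measures, hhi)
        ladder = model_ladder(
            ps,
            table,
            L1=config.L1,
            L2=config.L2,
            seed=config.seed,
            scale=config.scale,
            alpha=config.alpha,
            reference_year=config.reference_year,
        )
        scores = ladder["II"].scores.copy()
        scores["superefficiency"] = supereff["superefficiency"].to_numpy()
        scores["flag"] = np.where(
            (supereff["status"] == "infeasible")
            | (supereff["superefficiency"] > config.superefficiency_trim),
            "super-efficient",
            "",
        )
        scores.index = panel.dmu_index()
        _write(
            "scores.csv",
            lambda p: scores.reset_index().to_csv(p, index=False),
        )
        bins = pd.DataFrame(
            {
                "conventional": bin_scores(scores["theta"]),
                "bias_corrected": bin_scores(scores["theta_bc"]),
            }
        )
        _write(
            "bins.csv",
            lambda p: bins.rename_axis("te_score").reset_index().to_csv(
                p, index=False
            ),
        )
        for name, res in ladder.items():
            _write(
                f"regression_model_{name}.csv",
                lambda p, r=res: _write_regression_csv(r, p),
            )

        stage = "margins"
        lo, hi = ladder["II"].urs_range
        grid = np.linspace(lo, hi, config.margins_points)
        margins = predictive_margins(ladder["II"], grid).table
        _write("margins.csv", lambda p: margins.to_csv(p, index=False))

        stage = "manifest"
        diagnostics = {
            "n_dmus": ps.n,
            "inputs_plus_outputs": diag.dims,
            "effective_sample_size": diag.effective_sample_size,
            "fdh_efficient_share": diag.fdh_efficient_share,
            "dimensionality_flag": diag.flag,
            "mean_theta": float(scores["theta"].mean()),
            "mean_theta_bc": float(scores["theta_bc"].mean()),
        }
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "seed": config.seed,
            "package_version": __version__,
            "diagnostics": diagnostics,
        }
        _write(
            "manifest.json",
            lambda p: p.write_text(json.dumps(manifest, indent=2, sort_keys=True)),
        )
        _write(
            "diagnostics.json",
            lambda p: p.write_text(json.dumps(diagnostics, indent=2)),
        )
    except Exception as err:
        for path in written:
            path.unlink(missing_ok=True)
        raise type(err)(f"stage '{stage}' failed: {err}") from err

    return ResultsBundle(
        config=config,
        panel=panel,
        exclusion_log=exclusion_log,
        measures=measures,
        hhi=hhi,
        production_set=ps,
        scores=scores,
        bins=bins,
        diagnostics=diagnostics,
        ladder=ladder,
        margins=margins,
        table=table,
    )


def _pca_fte_input(X_fte: np.ndarray, epsilon: float) -> np.ndarray:
    """First-principal-component aggregate of the standardized FTE block.

    The component is sign-fixed so it correlates positively with staffing
    levels, then shifted to be strictly positive (DEA needs positive
    inputs); radial DEA is units-invariant, so the affine shift's scale is
    immaterial.
    """
    sd = X_fte.std(axis=0)
    std = (X_fte - X_fte.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if np.linalg.matrix_rank(std) < std.shape[1]:
        raise InvalidArgumentError("FTE block is rank-deficient; PCA undefined")
    pca = PCA(n_components=1, svd_solver="full")
    pc = pca.fit_transform(std)[:, 0]
    if pca.components_[0].sum() < 0:
        pc = -pc
    return pc - pc.min() + epsilon


def _variant_ps(
    name: str, bundle: ResultsBundle, config: AnalysisConfig
) -> ProductionSet | None:
    base = bundle.production_set
    names = base.input_names
    fte_idx = [i for i, n in enumerate(names) if n.startswith("fte_")]
    other_idx = [i for i in range(len(names)) if i not in fte_idx]
    if name == "no_outpatient":
        return ProductionSet(
            dmu=base.dmu,
            X=base.X,
            Y=base.Y[:, :1],
            input_names=names,
            output_names=base.output_names[:1],
        )
    if name == "merged_nursing":
        nursing_idx = [
            i for i, n in enumerate(names) if n in ("fte_rn", "fte_na")
        ]
        keep_idx = [i for i in range(len(names)) if i not in nursing_idx]
        nursing = base.X[:, nursing_idx].sum(axis=1)
        X = np.column_stack([base.X[:, keep_idx], nursing])
        return ProductionSet(
            dmu=base.dmu,
            X=X,
            Y=base.Y,
            input_names=[names[i] for i in keep_idx] + ["fte_nursing"],
            output_names=base.output_names,
        )
    if name == "pca_fte":
        pc = _pca_fte_input(base.X[:, fte_idx], config.epsilon_floor)
        X = np.column_stack([base.X[:, other_idx], pc])
        return ProductionSet(
            dmu=base.dmu,
            X=X,
            Y=base.Y,
            input_names=[names[i] for i in other_idx] + ["fte_pc1"],
            output_names=base.output_names,
        )
    return None


def sensitivity_suite(
    config: AnalysisConfig, bundle: ResultsBundle
) -> dict[str, dict[str, DoubleBootstrapResult]]:
    """Re-run the frontier + inference under the five standard variants."""
    L2 = config.sensitivity_L2 or config.L2
    seeds = np.random.SeedSequence(config.seed + 1).spawn(8)
    seed_iter = iter(
        int(s.generate_state(1)[0] % (2**31)) for s in seeds
    )
    out: dict[str, dict[str, DoubleBootstrapResult]] = {}

    def _ladder(ps, table, seed):
        return model_ladder(
            ps,
            table,
            L1=config.L1,
            L2=L2,
            seed=seed,
            scale=config.scale,
            alpha=config.alpha,
            reference_year=config.reference_year,
        )

    for name in ("no_outpatient", "merged_nursing", "pca_fte"):
        ps = _variant_ps(name, bundle, config)
        out[name] = _ladder(ps, bundle.table, next(seed_iter))

    # super-efficiency trim: drop outliers above the cutoff (and reference-
    # infeasible DMUs, which sit even further outside the support), re-run
    se = bundle.scores
    keep = ~(
        (se["flag"] == "super-efficient").to_numpy()
    )
    n_excluded = int((~keep).sum())
    # reuse the base seed so a trim that excludes nothing reproduces the
    # base run exactly (when sensitivity_L2 is unset)
    trimmed = bundle.production_set.subset(keep)
    out["superefficiency_trim"] = {
        "n_excluded": n_excluded,
        **_ladder(trimmed, bundle.table[keep], config.seed),
    }

    # per-year frontiers and regressions
    years = sorted(bundle.table["year"].unique())
    per_year = {}
    for y in years:
        mask = (bundle.table["year"] == y).to_numpy()
        per_year[int(y)] = _ladder(
            bundle.production_set.subset(mask),
            bundle.table[mask],
            next(seed_iter),
        )
    out["per_year"] = per_year
    return out


def _focal_row(ladder: dict[str, DoubleBootstrapResult], coef: str):
    model = FOCAL_MODEL[coef]
    if model not in ladder:
        return None
    res = ladder[model]
    if coef not in res.coef.index:
        return None
    row = res.coef.loc[coef]
    return np.sign(row["estimate"]), row["stars"] != ""


def robustness_verdict(
    base: dict[str, DoubleBootstrapResult],
    variants: dict[str, dict],
) -> pd.DataFrame:
    """Same-sign-and-significance indicator per focal coefficient.

    Purely descriptive: a variant "agrees" when the focal coefficient keeps
    the base sign and significance status (at the 10% level).
    """
    records = []
    for coef in ("urs", "urs2", "urd"):
        base_row = _focal_row(base, coef)
        if base_row is None:
            continue
        disagreeing = []
        n_checked = 0
        for vname, ladder in variants.items():
            sub = (
                ladder.items()
                if vname == "per_year"
                else [(vname, ladder)]
            )
            for label, lad in sub:
                if not isinstance(lad, dict) or FOCAL_MODEL[coef] not in lad:
                    continue
                row = _focal_row(lad, coef)
                if row is None:
                    continue
                n_checked += 1
                if row != base_row:
                    disagreeing.append(str(label))
        records.append(
            {
                "coefficient": coef,
                "base_sign": int(base_row[0]),
                "base_significant": bool(base_row[1]),
                "n_variants": n_checked,
                "n_agreeing": n_checked - len(disagreeing),
                "disagreeing": ";".join(disagreeing),
                "verdict": "robust" if not disagreeing else "not robust",
            }
        )
    return pd.DataFrame(records)
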