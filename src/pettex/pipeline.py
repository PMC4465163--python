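"""End-to-end study orchestration.

Runs the full analysis on a cohort — synthetic or read from files:
segmentation at every configured SUV threshold, per-lesion feature
extraction, ROC analysis of each PET parameter against each endpoint
(including the local-recurrence analysis repeated inside the T2 subgroup),
cutoff-dichotomized Kaplan-Meier/log-rank comparisons, univariate and
restricted multivariate Cox models, and the stability (2.0 vs 2.5
isocontour) and size-dependency correlation tables.

Endpoints: LR (local recurrence), LN (nodal relapse), DM (distant
metastasis), DSS (disease-specific survival: death attributed to tumor),
OS (overall survival).  Lesions are subgrouped at a 30 mm diameter into
T1/T2.  Every run is a pure function of its configuration and master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import features as ft
from . import stats as st
from . import synthetic as syn
from .volume import read_volume

logger = logging.getLogger("pettex")

#: Texture / first-order heterogeneity parameters entered into survival
#: models as cutoff-dichotomized "high risk" indicators.
DICHOTOMIZED_PARAMS = ("entropy", "correlation", "contrast",
                       "busyness", "coarseness", "cov")
#: Parameters modeled continuously in Cox regression (MTV on log scale).
CONTINUOUS_PARAMS = ("suv_max", "suv_mean")

ENDPOINTS = ("LR", "LR_T2", "LN", "DM", "DSS", "OS")
SURVIVAL_ENDPOINTS = ("LR_T2", "OS", "DSS")


class PipelineError(RuntimeError):
    """Raised when a study stage cannot produce a valid result."""


@dataclass
class StudyConfig:
    """Complete, serializable description of one study run."""

    mode: str = "synthetic"                       # synthetic | files
    n_patients: int = 45
    thresholds: tuple[float, ...] = (2.0, 2.5)
    endpoints: tuple[str, ...] = ENDPOINTS
    subgroup_diameter_mm: float = 30.0
    entropy_base: float = 2.0
    glcm_aggregation: str = "merged"
    seed: int = 0
    cohort_params: syn.CohortParams = field(default_factory=syn.CohortParams)
    outcome_params: syn.OutcomeParams = field(default_factory=syn.OutcomeParams)
    #: multivariate Cox model sets per survival endpoint (<= 3 covariates each);
    #: 'dose_proxy' is an independent stand-in for cumulative radiation dose,
    #: which has no phantom analogue
    multivariate_sets: dict = field(default_factory=lambda: {
        "DSS": [["high_entropy", "log_mtv_ml", "dose_proxy"]],
        "OS": [["high_entropy", "log_mtv_ml", "dose_proxy"]],
    })
    dose_proxy_mean: float = 40.0   # Gy-like scale
    dose_proxy_sd: float = 8.0
    # files mode
    volume_paths: tuple[str, ...] = ()
    outcomes_csv: Optional[str] = None

    def validate(self) -> None:
        if not self.thresholds:
            raise PipelineError("at least one SUV threshold is required")
        if not self.endpoints:
            raise PipelineError("endpoint list must be non-empty")
        unknown = set(self.endpoints) - set(ENDPOINTS)
        if unknown:
            raise PipelineError(f"unknown endpoints {sorted(unknown)}")
        if self.mode not in ("synthetic", "files"):
            raise PipelineError(f"unknown mode {self.mode!r}")
        if self.mode == "files" and (not self.volume_paths or not self.outcomes_csv):
            raise PipelineError("files mode needs volume_paths and outcomes_csv")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=list)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """The five result tables plus provenance."""

    roc_table: pd.DataFrame
    survival_table: pd.DataFrame
    cox_table: pd.DataFrame
    stability_table: pd.DataFrame
    size_table: pd.DataFrame
    provenance: dict

    TABLE_NAMES = ("roc_table", "survival_table", "cox_table",
                   "stability_table", "size_table")


def _endpoint_data(outcomes: pd.DataFrame, endpoint: str
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(selection mask, binary label, <time for survival endpoints>)."""
    sel = np.ones(len(outcomes), dtype=bool)
    if endpoint == "LR":
        lab = outcomes["lr_event"].to_numpy()
        time = outcomes["time_to_lr_months"].to_numpy()
    elif endpoint == "LR_T2":
        sel = (outcomes["t_stage"] == "T2").to_numpy()
        lab = outcomes["lr_event"].to_numpy()
        time = outcomes["time_to_lr_months"].to_numpy()
    elif endpoint == "LN":
        lab = outcomes["ln_event"].to_numpy()
        time = outcomes["os_time_months"].to_numpy()
    elif endpoint == "DM":
        lab = outcomes["dm_event"].to_numpy()
        time = outcomes["os_time_months"].to_numpy()
    elif endpoint == "DSS":
        lab = (outcomes["death_cause"] == "disease").to_numpy().astype(int)
        time = outcomes["os_time_months"].to_numpy()
    elif endpoint == "OS":
        lab = outcomes["os_event"].to_numpy()
        time = outcomes["os_time_months"].to_numpy()
    else:
        raise PipelineError(f"unknown endpoint {endpoint!r}")
    return sel, lab, time


def _parameter_columns(features: pd.DataFrame) -> list[str]:
    cols = list(ft.PARAMETER_COLUMNS)
    if "diameter_mm" in features and features["diameter_mm"].notna().all():
        cols.append("diameter_mm")
    return cols


def build_roc_table(features: pd.DataFrame, outcomes: pd.DataFrame,
                    endpoints: Sequence[str]) -> pd.DataFrame:
    """AUC with 95% CI per PET parameter x endpoint (Table-2-style)."""
    rows = []
    for param in _parameter_columns(features):
        scores_all = features[param].to_numpy(dtype=np.float64)
        for ep in endpoints:
            sel, lab, _ = _endpoint_data(outcomes, ep)
            row = {"parameter": param, "endpoint": ep, "n": int(sel.sum())}
            try:
                roc = st.roc_analysis(scores_all[sel], lab[sel])
                row.update(auc=roc.auc, ci_low=roc.ci_low, ci_high=roc.ci_high,
                           p=roc.p_vs_chance, cutoff=roc.optimal_cutoff,
                           significant=roc.p_vs_chance < 0.05, note="")
            except st.StatsError as exc:
                row.update(auc=np.nan, ci_low=np.nan, ci_high=np.nan,
                           p=np.nan, cutoff=np.nan, significant=False,
                           note=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def build_survival_table(features: pd.DataFrame, outcomes: pd.DataFrame,
                         roc_table: pd.DataFrame,
                         endpoints: Sequence[str] = SURVIVAL_ENDPOINTS
                         ) -> pd.DataFrame:
    """Kaplan-Meier/log-rank per parameter, dichotomized at the ROC cutoff
    determined for the matching endpoint label (Table-3-style)."""
    rows = []
    for param in _parameter_columns(features):
        scores = features[param].to_numpy(dtype=np.float64)
        for ep in endpoints:
            sel, lab, time = _endpoint_data(outcomes, ep)
            cut_rows = roc_table[(roc_table.parameter == param)
                                 & (roc_table.endpoint == ep)]
            cutoff = float(cut_rows.cutoff.iloc[0]) if len(cut_rows) else np.nan
            row = {"parameter": param, "endpoint": ep, "cutoff": cutoff}
            if not np.isfinite(cutoff):
                row.update(_empty_survival_cells(), note="no cutoff (degenerate ROC)")
                rows.append(row)
                continue
            high = scores[sel] >= cutoff
            try:
                comp = st.km_logrank(time[sel], lab[sel], high.astype(int))
            except st.StatsError as exc:
                row.update(_empty_survival_cells(), note=str(exc))
                rows.append(row)
                continue
            lo, hi = comp.groups[0], comp.groups[1]
            row.update(n_low=lo.n, events_low=lo.n_events,
                       mean_low=lo.restricted_mean_months,
                       median_low=lo.median_months,
                       n_high=hi.n, events_high=hi.n_events,
                       mean_high=hi.restricted_mean_months,
                       median_high=hi.median_months,
                       logrank_p=comp.logrank_p,
                       significant=comp.logrank_p < 0.05, note="")
            rows.append(row)
    return pd.DataFrame(rows)


def _empty_survival_cells() -> dict:
    return dict(n_low=0, events_low=0, mean_low=np.nan, median_low=np.nan,
                n_high=0, events_high=0, mean_high=np.nan, median_high=np.nan,
                logrank_p=np.nan, significant=False)


def _cox_covariate_pool(features: pd.DataFrame, roc_table: pd.DataFrame,
                        endpoint: str, dose_proxy: np.ndarray) -> pd.DataFrame:
    """Assemble the covariate pool for one survival endpoint: dichotomized
    texture flags (at that endpoint's ROC cutoff), standardized continuous
    texture values, continuous SUV measures, log MTV, diameter, and the dose
    stand-in.

    The ``high_*`` indicators mirror clinical reporting; the ``z_*`` columns
    carry the full continuous signal and are the right choice when a model
    must be correctly specified against a continuous driver (a dichotomized
    surrogate leaks residual signal into correlated covariates such as MTV).
    """
    pool = pd.DataFrame(index=features.index)
    for param in DICHOTOMIZED_PARAMS:
        cut_rows = roc_table[(roc_table.parameter == param)
                             & (roc_table.endpoint == endpoint)]
        if len(cut_rows) and np.isfinite(cut_rows.cutoff.iloc[0]):
            pool[f"high_{param}"] = (
                features[param] >= float(cut_rows.cutoff.iloc[0])).astype(float)
        x = features[param].astype(float)
        if x.std(ddof=0) > 0:
            pool[f"z_{param}"] = (x - x.mean()) / x.std(ddof=0)
    for param in CONTINUOUS_PARAMS:
        pool[param] = features[param].astype(float)
    pool["log_mtv_ml"] = np.log(features["mtv_ml"].astype(float))
    if "diameter_mm" in features and features["diameter_mm"].notna().all():
        pool["diameter_mm"] = features["diameter_mm"].astype(float)
    pool["dose_proxy"] = dose_proxy
    return pool


def build_cox_table(features: pd.DataFrame, outcomes: pd.DataFrame,
                    roc_table: pd.DataFrame, multivariate_sets: dict,
                    dose_proxy: np.ndarray,
                    endpoints: Sequence[str] = ("OS", "DSS")) -> pd.DataFrame:
    """Univariate Cox per covariate and restricted (<= 3 covariate)
    multivariate models per endpoint (Table-4-style)."""
    rows = []
    for ep in endpoints:
        _, ev, time = _endpoint_data(outcomes, ep)
        pool = _cox_covariate_pool(features, roc_table, ep, dose_proxy)
        for col in pool.columns:
            rows.append(_cox_row(pool[[col]], time, ev, ep, "univariate", col))
        for m, cols in enumerate(multivariate_sets.get(ep, [])):
            cols = [c for c in cols if c in pool.columns]
            rows.extend(_cox_row(pool[cols], time, ev, ep,
                                 f"multivariate_{m}", None))
    return pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["endpoint", "model", "covariate", "hr", "ci_low", "ci_high",
                 "p", "significant", "note"])


def _cox_row(X: pd.DataFrame, time, ev, endpoint, model, single_name):
    try:
        res = st.cox_fit(X, time, ev)
    except st.StatsError as exc:
        base = {"endpoint": endpoint, "model": model,
                "covariate": single_name or "+".join(X.columns),
                "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "significant": False, "note": str(exc)}
        return base if single_name else [base]
    out = []
    for _, r in res.table.iterrows():
        out.append({"endpoint": endpoint, "model": model,
                    "covariate": r.covariate, "hr": r.hr,
                    "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
                    "significant": r.p < 0.05, "note": ""})
    return out[0] if single_name else out


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full study and return its report.

    Stages (each logged): cohort generation or ingestion; segmentation and
    feature extraction at every configured threshold; ROC per parameter and
    endpoint; cutoff-dichotomized survival comparisons; Cox models; VOI
    stability and size-dependency correlations.
    """
    config.validate()
    stage_log: list[str] = []

    def stage(msg: str) -> None:
        stage_log.append(msg)
        logger.info("%s", msg)

    rng = np.random.default_rng(config.seed)
    primary_thr = config.thresholds[0]
    if config.mode == "synthetic":
        stage(f"generate synthetic cohort (n={config.n_patients}, "
              f"seed={config.seed})")
        cohort = syn.generate_cohort(
            config.n_patients, config.cohort_params, config.outcome_params,
            seed=int(rng.integers(0, 2**31 - 1)), voi_threshold=primary_thr)
        volumes, outcomes = cohort.volumes, cohort.outcomes
        diameters = [p.tumor_diameter_mm for p in cohort.phantom_params]
    else:
        stage(f"read {len(config.volume_paths)} volumes + outcomes table")
        volumes = [read_volume(p, patient_id=f"P{i:03d}")
                   for i, p in enumerate(config.volume_paths)]
        outcomes = pd.read_csv(config.outcomes_csv)
        diameters = (outcomes["diameter_mm"].tolist()
                     if "diameter_mm" in outcomes else [None] * len(volumes))
        if len(outcomes) != len(volumes):
            raise PipelineError("outcome table and volume list disagree in length")

    feature_frames: dict[float, pd.DataFrame] = {}
    for thr in config.thresholds:
        stage(f"segment + extract features at SUV {thr:g} isocontour")
        vecs = [ft.extract_all_features(
                    vol, threshold_suv=thr,
                    aggregation=config.glcm_aggregation,
                    entropy_base=config.entropy_base, diameter_mm=d)
                for vol, d in zip(volumes, diameters)]
        feature_frames[thr] = ft.features_to_frame(vecs)
    features = feature_frames[primary_thr]

    stage("ROC analysis per parameter and endpoint")
    roc_table = build_roc_table(features, outcomes, config.endpoints)

    stage("Kaplan-Meier / log-rank at ROC cutoffs")
    surv_eps = [ep for ep in SURVIVAL_ENDPOINTS if ep in config.endpoints
                or ep == "LR_T2" and "LR" in config.endpoints]
    survival_table = build_survival_table(features, outcomes, roc_table,
                                          endpoints=surv_eps or list(SURVIVAL_ENDPOINTS))

    stage("Cox proportional-hazards models")
    dose_proxy = rng.normal(config.dose_proxy_mean, config.dose_proxy_sd,
                            size=len(features))
    cox_eps = [ep for ep in ("OS", "DSS") if ep in config.endpoints]
    cox_table = build_cox_table(features, outcomes, roc_table,
                                config.multivariate_sets, dose_proxy,
                                endpoints=cox_eps or ("OS", "DSS"))

    if len(config.thresholds) >= 2:
        stage(f"stability: features at SUV {config.thresholds[0]:g} vs "
              f"{config.thresholds[1]:g}")
        stability_table = st.pearson_table(
            feature_frames[config.thresholds[0]],
            feature_frames[config.thresholds[1]],
            columns=list(ft.PARAMETER_COLUMNS))
    else:
        stability_table = pd.DataFrame()

    stage("size dependency: parameters vs MTV")
    size_table = st.size_dependency(
        features, columns=[c for c in ft.PARAMETER_COLUMNS if c != "mtv_ml"])

    provenance = {
        "package": "pettex",
        "version": _pkg_version,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "n_patients": len(features),
        "thresholds": list(config.thresholds),
        "stages": stage_log,
    }
    return StudyReport(roc_table=roc_table, survival_table=survival_table,
                       cox_table=cox_table, stability_table=stability_table,
                       size_table=size_table, provenance=provenance)


# ---------------------------------------------------------------------------
# report I/O


def write_report(report: StudyReport, outdir: str | Path) -> list[Path]:
    """Write the five tables as CSV plus a single JSON bundle and a log.

    Fails before writing anything if the directory cannot be created.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise PipelineError(f"output directory {outdir} is not writable: {exc}")
    written = []
    bundle = {"provenance": report.provenance, "tables": {}}
    for name in StudyReport.TABLE_NAMES:
        table: pd.DataFrame = getattr(report, name)
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)
        bundle["tables"][name] = json.loads(
            table.to_json(orient="table", double_precision=15))
    jpath = outdir / "report.json"
    jpath.write_text(json.dumps(bundle, indent=1, sort_keys=True))
    written.append(jpath)
    lpath = outdir / "study.log"
    lpath.write_text("\n".join(report.provenance["stages"]) + "\n")
    written.append(lpath)
    return written


def load_report(path: str | Path) -> StudyReport:
    """Re-read a JSON report bundle written by :func:`write_report`."""
    bundle = json.loads(Path(path).read_text())
    tables = {}
    for name in StudyReport.TABLE_NAMES:
        tables[name] = pd.DataFrame(
            bundle["tables"][name]["data"]).drop(columns=["index"],
                                                 errors="ignore")
    return StudyReport(provenance=bundle["provenance"], **tables)
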