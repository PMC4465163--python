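"""Outcome statistics: ROC/AUC with optimal cutoffs, Kaplan-Meier with
log-rank comparison, Cox proportional-hazards regression, and Pearson
correlation tables for feature stability and size dependency.

All tests are two-sided at the 5% level.  AUC is the Mann-Whitney statistic
(ties counted 1/2); its default confidence interval is DeLong's
distribution-free estimator, with the Hanley-McNeil normal approximation
available as an option.  Survival machinery (product-limit curves, log-rank,
partial-likelihood Cox fits with Efron tie handling) is delegated to
``lifelines``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time


class StatsError(ValueError):
    """Raised on inputs for which a statistic is undefined."""


# ---------------------------------------------------------------------------
# ROC


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray          # 1 - specificity, increasing
    tpr: np.ndarray          # sensitivity
    thresholds: np.ndarray   # score >= threshold classifies positive
    optimal_cutoff: float
    optimal_sensitivity: float
    optimal_specificity: float
    n_pos: int
    n_neg: int
    auc_se: float = 0.0
    ci_method: str = "delong"

    @property
    def p_vs_chance(self) -> float:
        """Two-sided normal test of AUC = 0.5 on the estimated AUC variance."""
        if self.auc_se == 0:
            return 0.0 if self.auc != 0.5 else 1.0
        return float(2 * sps.norm.sf(abs(self.auc - 0.5) / self.auc_se))


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based), ties averaged."""
    return sps.rankdata(x, method="average")


def _delong_auc_var(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via the placement-value decomposition."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n           # placement values of positives
    v10 = 1.0 - (tz[m:] - ty) / m     # placement values of negatives
    var = (np.var(v01, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v10, ddof=1) / n if n > 1 else 0.0)
    return float(auc), float(var)


def _hanley_mcneil_var(auc: float, m: int, n: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    return (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)


def roc_analysis(scores: Sequence[float], labels: Sequence[int],
                 ci_method: Literal["delong", "hanley-mcneil"] = "delong",
                 alpha: float = 0.05) -> ROCResult:
    """ROC curve, Mann-Whitney AUC with 95% CI, and the optimal cutoff.

    The optimal decision threshold minimizes the Euclidean distance between
    the ROC curve and the upper-left corner (0, 1) of the plot, with ties
    broken toward higher specificity.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise StatsError("scores and labels must be equal-length 1-D sequences")
    if set(np.unique(labels)) - {0, 1}:
        raise StatsError("labels must be binary 0/1")
    for cls, name in ((1, "positive"), (0, "negative")):
        if not np.any(labels == cls):
            raise StatsError(f"ROC undefined: no {name} cases in labels")

    auc, var = _delong_auc_var(scores, labels)
    m, n = int((labels == 1).sum()), int((labels == 0).sum())
    if ci_method == "hanley-mcneil":
        var = _hanley_mcneil_var(auc, m, n)
    elif ci_method != "delong":
        raise ValueError(f"unknown ci_method {ci_method!r}")
    zcrit = sps.norm.ppf(1 - alpha / 2)
    half = zcrit * np.sqrt(max(var, 0.0))
    ci_low, ci_high = float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))

    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    cut, sens, spec = _optimal_corner_cutoff(fpr, tpr, thr)
    return ROCResult(auc=auc, ci_low=ci_low, ci_high=ci_high,
                     fpr=fpr, tpr=tpr, thresholds=thr,
                     optimal_cutoff=cut, optimal_sensitivity=sens,
                     optimal_specificity=spec, n_pos=m, n_neg=n,
                     auc_se=float(np.sqrt(max(var, 0.0))), ci_method=ci_method)


def _optimal_corner_cutoff(fpr, tpr, thr) -> tuple[float, float, float]:
    d2 = (1.0 - tpr) ** 2 + fpr ** 2
    best = np.flatnonzero(d2 == d2.min())
    k = best[np.argmin(fpr[best])]  # ties toward higher specificity
    cut = thr[k]
    if np.isinf(cut):  # the 'classify none positive' corner
        cut = thr[1] if len(thr) > 1 else float(cut)
    return float(cut), float(tpr[k]), float(1.0 - fpr[k])


def optimal_cutoff(roc: ROCResult) -> float:
    """The decision threshold closest to the (0, 1) corner of the ROC plot."""
    return _optimal_corner_cutoff(roc.fpr, roc.tpr, roc.thresholds)[0]


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


@dataclass
class GroupSurvival:
    n: int
    n_events: int
    median_months: float        # NaN when never reached
    restricted_mean_months: float
    curve: pd.DataFrame         # columns: time, survival


@dataclass
class SurvivalComparison:
    groups: dict
    logrank_statistic: float
    logrank_p: float


def km_curve(times: Sequence[float], events: Sequence[int],
             label: str = "KM") -> GroupSurvival:
    """Product-limit survival estimate for one group."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    if len(times) == 0:
        raise StatsError("empty group in survival analysis")
    if np.any(times <= 0):
        raise StatsError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label)
    med = float(kmf.median_survival_time_)
    if np.isinf(med):
        med = float("nan")  # median not reached
    rmst = float(restricted_mean_survival_time(kmf, t=float(times.max())))
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    return GroupSurvival(n=len(times), n_events=int(events.sum()),
                         median_months=med, restricted_mean_months=rmst,
                         curve=curve)


def km_logrank(times: Sequence[float], events: Sequence[int],
               group: Sequence[int]) -> SurvivalComparison:
    """Two-group Kaplan-Meier estimate with a log-rank comparison."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    group = np.asarray(group, dtype=np.int64)
    if not (len(times) == len(events) == len(group)):
        raise StatsError("times, events and group must have equal length")
    groups = {}
    for g in (0, 1):
        sel = group == g
        if not sel.any():
            raise StatsError(f"group {g} has zero subjects")
        groups[g] = km_curve(times[sel], events[sel], label=f"group {g}")
    res = logrank_test(times[group == 0], times[group == 1],
                       event_observed_A=events[group == 0],
                       event_observed_B=events[group == 1])
    return SurvivalComparison(groups=groups,
                              logrank_statistic=float(res.test_statistic),
                              logrank_p=float(res.p_value))


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxResult:
    table: pd.DataFrame      # covariate, hr, ci_low, ci_high, p
    model_type: str          # univariate | multivariate
    n: int
    n_events: int


def cox_fit(covariates: pd.DataFrame, times: Sequence[float],
            events: Sequence[int],
            log_transform: Sequence[str] = (),
            max_covariates: int = 3) -> CoxResult:
    """Cox proportional-hazards fit (Efron tie handling via lifelines).

    At most ``max_covariates`` covariates are allowed in a multivariate
    model — the restriction imposed when event counts are low, as in a
    45-patient cohort with ~12 disease deaths.  Columns named in
    ``log_transform`` are log-transformed before fitting (the convention for
    metabolic tumor volume).  Non-convergence and constant covariates raise
    explicit errors instead of returning silent estimates.
    """
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(covariates)
    k = covariates.shape[1]
    if k == 0:
        raise StatsError("no covariates supplied")
    if k > max_covariates:
        raise StatsError(
            f"{k} covariates exceed the multivariate limit of {max_covariates} "
            "imposed for low event numbers")
    X = covariates.astype(np.float64).copy()
    for col in log_transform:
        if np.any(X[col] <= 0):
            raise StatsError(f"cannot log-transform non-positive covariate {col!r}")
        X[col] = np.log(X[col])
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise StatsError(f"constant covariate {col!r}")
    df = X.copy()
    df["_time"] = np.asarray(times, dtype=np.float64)
    df["_event"] = np.asarray(events, dtype=np.int64)
    if np.any(df["_time"] <= 0):
        raise StatsError("survival times must be positive")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as exc:
        raise StatsError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary
    if not np.all(np.isfinite(summ["se(coef)"])):
        raise StatsError("Cox model degenerate: non-finite standard errors "
                         "(possible separation)")
    table = pd.DataFrame({
        "covariate": summ.index,
        "hr": np.exp(summ["coef"]).to_numpy(),
        "ci_low": np.exp(summ["coef lower 95%"]).to_numpy(),
        "ci_high": np.exp(summ["coef upper 95%"]).to_numpy(),
        "p": summ["p"].to_numpy(),
    }).reset_index(drop=True)
    return CoxResult(table=table,
                     model_type="univariate" if k == 1 else "multivariate",
                     n=len(df), n_events=int(df["_event"].sum()))


def adjust_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg false-discovery-rate adjustment.

    Off by default everywhere — the reporting convention here, like the
    clinical tables it mirrors, is unadjusted per-test p-values — but
    available for callers who want FDR control across a table.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = sps.false_discovery_control(p[ok], method="bh")
    return out


# ---------------------------------------------------------------------------
# Pearson correlation tables


def pearson_table(frame_a: pd.DataFrame, frame_b: pd.DataFrame,
                  columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-feature Pearson correlation between two paired feature tables.

    Used to quantify stability of each PET parameter across VOI definitions
    (SUV 2.0 vs 2.5 isocontours).  Also reports each feature's range and
    mean +/- SD under both definitions.  Features with zero variance on
    either side get r = NaN and are flagged.
    """
    if len(frame_a) != len(frame_b):
        raise StatsError("paired feature tables must have equal length")
    if len(frame_a) < 3:
        raise StatsError("need at least 3 paired lesions for correlation")
    if columns is None:
        columns = [c for c in frame_a.columns
                   if c in frame_b.columns
                   and pd.api.types.is_numeric_dtype(frame_a[c])]
    rows = []
    for col in columns:
        a = frame_a[col].to_numpy(dtype=np.float64)
        b = frame_b[col].to_numpy(dtype=np.float64)
        degenerate = a.std(ddof=0) == 0 or b.std(ddof=0) == 0
        if degenerate:
            r, p = float("nan"), float("nan")
        else:
            r, p = sps.pearsonr(a, b)
        rows.append({
            "feature": col, "r": float(r), "p": float(p),
            "range_a": f"{a.min():.4g}-{a.max():.4g}",
            "mean_a": a.mean(), "sd_a": a.std(ddof=1),
            "range_b": f"{b.min():.4g}-{b.max():.4g}",
            "mean_b": b.mean(), "sd_b": b.std(ddof=1),
            "degenerate": bool(degenerate),
        })
    return pd.DataFrame(rows)


def size_dependency(features: pd.DataFrame,
                    columns: Optional[Sequence[str]] = None,
                    mtv_column: str = "mtv_ml") -> pd.DataFrame:
    """Pearson correlation of each PET parameter with metabolic tumor volume."""
    if len(features) < 3:
        raise StatsError("need at least 3 lesions for correlation")
    if columns is None:
        columns = [c for c in features.columns
                   if c != mtv_column and pd.api.types.is_numeric_dtype(features[c])]
    mtv = features[mtv_column].to_numpy(dtype=np.float64)
    if mtv.std(ddof=0) == 0:
        raise StatsError("MTV has zero variance across lesions")
    rows = []
    for col in columns:
        x = features[col].to_numpy(dtype=np.float64)
        if x.std(ddof=0) == 0:
            rows.append({"feature": col, "r": float("nan"), "p": float("nan"),
                         "degenerate": True})
            continue
        r, p = sps.pearsonr(x, mtv)
        rows.append({"feature": col, "r": float(r), "p": float(p),
                     "degenerate": False})
    return pd.DataFrame(rows)
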