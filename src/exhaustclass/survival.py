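"""Survival association of the class labels: KM, log-rank, multivariate Cox.

Follow-up is truncated at a 60-month horizon before estimation, matching
the published analysis design. Cox regression uses the partial likelihood
with Efron tie handling (lifelines); stage enters as ordered-categorical
indicator columns, and rows with missing covariates are dropped with a
logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .io import ClinicalTable, ValidationError

logger = logging.getLogger("exhaustclass")

STAGE_ORDER = ["I", "II", "III", "IV"]


@dataclass
class KMCurve:
    timeline: np.ndarray
    survival: np.ndarray  # S(t) at each timeline point, non-increasing from 1
    at_risk: np.ndarray  # numbers at risk entering each timeline point
    censor_times: np.ndarray
    horizon_months: float


@dataclass
class CoxFit:
    summary: pd.DataFrame  # covariate -> beta, se, hr, p
    n_used: int
    n_dropped_missing: int


def truncate_followup(clinical: ClinicalTable, horizon_months: float = 60.0) -> ClinicalTable:
    """Administratively censor any follow-up beyond the horizon.

    Times > horizon become the horizon with event flag 0; a time exactly at
    the horizon keeps its event flag.
    """
    t = clinical.table.copy()
    for tcol, ecol in (("os_time_months", "os_event"), ("pfs_time_months", "pfs_event")):
        if tcol not in t.columns:
            continue
        over = t[tcol] > horizon_months
        t.loc[over, ecol] = 0
        t.loc[over, tcol] = horizon_months
        if over.any():
            logger.info("truncate_followup: censored %d %s values at %g months",
                        int(over.sum()), tcol, horizon_months)
    return ClinicalTable(t)


def km_estimate(times, events, horizon_months: float = 60.0) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
    censor_times = np.sort(times[events == 0])
    return KMCurve(timeline=timeline, survival=surv, at_risk=at_risk,
                   censor_times=censor_times, horizon_months=horizon_months)


def logrank_test(times, events, group) -> tuple:
    """Two-group log-rank test; returns (chi-square, p) on 1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValidationError(f"log-rank test needs exactly 2 groups, got {len(levels)}")
    m0, m1 = group == levels[0], group == levels[1]
    res = _ll_logrank(times[m0], times[m1], event_observed_A=events[m0],
                      event_observed_B=events[m1])
    return float(res.test_statistic), float(res.p_value)


def _design_matrix(table: pd.DataFrame, labels: pd.Series, covariates) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov == "class":
            cols["class_EIC"] = (labels.loc[table["sample_id"]].to_numpy() == "EIC").astype(float)
        elif cov == "gender":
            g = table["gender"].astype(str).str.lower()
            cols["gender_male"] = g.map({"male": 1.0, "female": 0.0}).to_numpy()
        elif cov == "stage":
            stage = table["stage"].astype(str)
            # ordered categorical -> indicator per level above the reference
            for lvl in STAGE_ORDER[1:]:
                if (stage == lvl).any():
                    cols[f"stage_{lvl}"] = (stage == lvl).astype(float).to_numpy()
        elif cov == "age":
            cols["age"] = pd.to_numeric(table["age"], errors="coerce").to_numpy(dtype=float)
        else:
            cols[cov] = pd.to_numeric(table[cov], errors="coerce").to_numpy(dtype=float)
    return pd.DataFrame(cols, index=table.index)


def cox_fit(
    clinical: ClinicalTable,
    labels,
    covariates=("class", "gender", "stage", "age"),
    endpoint: str = "os",
    max_iter: int = 100,
) -> CoxFit:
    """Multivariate Cox proportional hazards (Efron ties, Wald p per coefficient).

    ``labels`` is a ClassLabels or a sample->EIC/REST Series. Rows with a
    missing covariate are dropped and counted; exactly collinear columns
    are an error.
    """
    lab = labels.labels if hasattr(labels, "labels") else labels
    t = clinical.table
    tcol, ecol = f"{endpoint}_time_months", f"{endpoint}_event"
    if tcol not in t.columns:
        raise ValidationError(f"clinical table lacks {tcol}")
    X = _design_matrix(t, lab, covariates)
    df = X.copy()
    df["T"] = t[tcol].to_numpy(dtype=float)
    df["E"] = t[ecol].to_numpy(dtype=float)
    n0 = len(df)
    df = df.dropna()
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("cox_fit: dropped %d rows with missing covariates", n_dropped)
    if df["E"].sum() < 1:
        raise ValidationError("Cox fit needs at least one event")

    Xc = df.drop(columns=["T", "E"])
    Xv = Xc.to_numpy()
    centered = Xv - Xv.mean(axis=0)
    if np.linalg.matrix_rank(centered) < Xc.shape[1]:
        raise ValidationError("collinear covariates in Cox design matrix")

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="T", event_col="E",
                fit_options={"max_steps": max_iter})
    except ConvergenceError as err:
        raise ValidationError(f"Cox fit failed to converge: {err}") from err
    summ = cph.summary
    out = pd.DataFrame({
        "beta": summ["coef"],
        "se": summ["se(coef)"],
        "hr": summ["exp(coef)"],
        "p": summ["p"],
        "ci_lower": summ["coef lower 95%"],
        "ci_upper": summ["coef upper 95%"],
    })
    return CoxFit(summary=out, n_used=len(df), n_dropped_missing=n_dropped)
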