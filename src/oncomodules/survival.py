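"""Survival evaluation of patient groups.

Kaplan–Meier product-limit curves per group, the g-sample log-rank test,
Cox proportional-hazards fits (Efron tie handling) with per-covariate Wald
tests, and Harrell's concordance index.  Times are durations in days with
event = 1 for death and 0 for censoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex

logger = logging.getLogger(__name__)

SURVIVAL_COLUMNS = ["time", "event"]


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check times positive and events binary."""
    missing = [c for c in SURVIVAL_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"survival table missing columns: {missing}")
    if len(records) == 0:
        raise ValueError("need at least one survival record")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (alive/censored) or 1 (dead)")
    return records


def kaplan_meier(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival table: time, at_risk, deaths, censored, survival.

    One row per distinct observed time; S is non-increasing with S(0) = 1
    (implicit).  Censored subjects leave the risk set after their time.
    """
    records = validate_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"])
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index \
        else kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame({
        "time": table.index.to_numpy(dtype=float),
        "at_risk": table["at_risk"].to_numpy(dtype=int),
        "deaths": table["observed"].to_numpy(dtype=int),
        "censored": table["censored"].to_numpy(dtype=int),
        "survival": [float(surv.loc[t]) for t in table.index],
    })
    return out.reset_index(drop=True)


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(records: pd.DataFrame, groups: pd.Series | np.ndarray
                 ) -> LogrankResult:
    """g-sample log-rank test; df = g − 1, upper-tail chi-square p."""
    records = validate_records(records)
    groups = np.asarray(groups)
    if len(groups) != len(records):
        raise ValueError("groups must align with records")
    g = len(np.unique(groups))
    if g < 2:
        raise ValueError("need at least 2 groups")
    res = multivariate_logrank_test(
        records["time"].to_numpy(), groups, records["event"].to_numpy())
    return LogrankResult(statistic=float(res.test_statistic),
                         df=g - 1, p_value=float(res.p_value))


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary.

    ``summary`` rows are covariates with columns coef, se, z, p,
    significant (Wald p < 0.05).  ``c_index`` is Harrell's concordance of
    the fitted linear predictor on the training records.
    """

    summary: pd.DataFrame
    c_index: float
    log_likelihood: float
    converged: bool
    n: int
    n_events: int

    @property
    def coefficients(self) -> pd.Series:
        return self.summary["coef"]

    def significant_covariates(self) -> pd.DataFrame:
        return self.summary[self.summary["significant"]]


def _check_design(features: pd.DataFrame) -> None:
    sd = features.std(axis=0, ddof=0)
    constant = sd.index[sd <= 1e-12].tolist()
    if constant:
        raise ValueError(f"constant covariate column(s): {constant}")
    X = features.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < X.shape[1]:
        corr = features.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = corr.stack()
        worst = pairs.idxmax()
        raise ValueError(
            "collinear covariates (design matrix rank "
            f"{rank} < {X.shape[1]}); most correlated pair: {worst}")


def cox_fit(features: pd.DataFrame, records: pd.DataFrame,
            alpha: float = 0.05) -> CoxFit:
    """Cox partial-likelihood fit with Efron ties and Wald tests.

    ``features`` and ``records`` are aligned on index.  Constant or
    collinear covariate columns are rejected by name; ``significant`` flags
    Wald p < ``alpha``.
    """
    records = validate_records(records)
    common = features.index.intersection(records.index)
    if len(common) == 0:
        raise ValueError("no overlapping patients between features and records")
    features = features.loc[common]
    records = records.loc[common]
    if int(records["event"].sum()) < 1:
        raise ValueError("need at least one event to fit a Cox model")
    _check_design(features)
    df = features.copy()
    df["time"] = records["time"].to_numpy(dtype=float)
    df["event"] = records["event"].to_numpy(dtype=int)
    cph = CoxPHFitter()  # lifelines uses Efron's method for ties
    try:
        cph.fit(df, duration_col="time", event_col="event")
        converged = True
    except Exception as exc:  # pragma: no cover - surfaced to the caller
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    summ = cph.summary
    out = pd.DataFrame({
        "coef": summ["coef"],
        "se": summ["se(coef)"],
        "z": summ["z"],
        "p": summ["p"],
    })
    out["significant"] = out["p"] < alpha
    return CoxFit(summary=out,
                  c_index=float(cph.concordance_index_),
                  log_likelihood=float(cph.log_likelihood_),
                  converged=converged,
                  n=len(df),
                  n_events=int(df["event"].sum()))


def cox_reports(features: pd.DataFrame, records: pd.DataFrame,
                groups: pd.Series | None = None,
                min_events: int = 10) -> dict[str, CoxFit]:
    """Cox fits for all patients pooled and per patient group.

    Groups with fewer than ``min_events`` events are skipped with a
    warning.  Constant columns within a group are dropped before fitting.
    """
    reports: dict[str, CoxFit] = {"all": cox_fit(features, records)}
    if groups is None:
        return reports
    for g in sorted(pd.unique(groups)):
        idx = groups.index[groups == g]
        idx = idx.intersection(features.index).intersection(records.index)
        sub_feat = features.loc[idx]
        sub_rec = records.loc[idx]
        if int(sub_rec["event"].sum()) < min_events:
            logger.warning("group %s skipped: only %d events", g,
                           int(sub_rec["event"].sum()))
            continue
        sd = sub_feat.std(axis=0, ddof=0)
        usable = sd.index[sd > 1e-12]
        if len(usable) < len(sub_feat.columns):
            logger.warning("group %s: dropping constant covariate(s) %s", g,
                           sorted(set(sub_feat.columns) - set(usable)))
        try:
            reports[f"group_{g}"] = cox_fit(sub_feat[usable], sub_rec)
        except (ValueError, RuntimeError) as exc:
            logger.warning("group %s Cox fit skipped: %s", g, exc)
    return reports


def concordance_index(risk_scores: pd.Series | np.ndarray,
                      records: pd.DataFrame) -> float:
    """Harrell's C over comparable pairs; higher risk should die earlier.

    Tied risk scores credit 0.5.  Raises on degenerate input with zero
    comparable pairs.
    """
    records = validate_records(records)
    risk = np.asarray(risk_scores, dtype=float)
    if len(risk) != len(records):
        raise ValueError("risk scores must align with records")
    try:
        # lifelines scores concordance for *survival-time-like* predictions,
        # so negate risk (higher risk = shorter survival).
        return float(_lifelines_cindex(
            records["time"].to_numpy(), -risk, records["event"].to_numpy()))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs in survival records") from exc
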