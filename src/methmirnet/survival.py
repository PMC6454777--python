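"""Kaplan-Meier curves, log-rank tests, hazard ratios and candidate
classification.

Candidate tumor suppressors / oncogenes are defined by a joint rule: a
feature must be differentially expressed in the right direction (down for
TS, up for OG) AND its tumor-sample expression, median-split into low/high
patient groups, must separate overall survival (log-rank p < alpha) with
the matching hazard direction (high expression protective for TS, HR < 1;
deleterious for OG, HR > 1).

The hazard ratio is the exponentiated maximum-partial-likelihood estimate
for a single binary covariate with Breslow tie handling, with a Wald p-value
from the observed information. KM estimation and the log-rank test are
delegated to lifelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

from .containers import ClinicalTable, OmicsMatrix
from .errors import AnalysisError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """Product-limit estimate: survival values at the distinct event times."""

    event_times: np.ndarray  # ascending, events only
    survival: np.ndarray     # S(t) just after each event time
    at_risk: np.ndarray      # number at risk at each event time

    def at(self, t: float) -> float:
        """S(t) of the step function (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CandidateSet:
    """Features classified as tumor suppressors (TS) or oncogenes (OG).

    ``members`` has one row per feature with columns
    ``hazard_ratio, logrank_p, n`` (patients used for that feature).
    """

    role: str   # "TS" | "OG"
    layer: str  # "mRNA" | "miRNA"
    members: pd.DataFrame

    @property
    def feature_ids(self) -> list[str]:
        return list(self.members.index)

    def __len__(self) -> int:
        return len(self.members)


def _as_arrays(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.shape != event.shape:
        raise ParameterError("time and event must have equal length")
    if time.size == 0:
        raise ParameterError("empty survival input")
    if (time <= 0).any():
        raise ParameterError("all survival times must be > 0")
    if not np.isin(event, (0, 1)).all():
        raise ParameterError("event indicators must be 0 or 1")
    return time, event


def km_estimate(time, event) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Censored subjects sharing an event time are counted at risk for that
    time (standard convention: events precede censorings at ties).
    """
    time, event = _as_arrays(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    is_event = table["observed"] > 0
    ev_times = table.index.to_numpy(dtype=float)[is_event.to_numpy()]
    surv = kmf.survival_function_at_times(ev_times).to_numpy(dtype=float)
    at_risk = table.loc[is_event, "at_risk"].to_numpy(dtype=float)
    return SurvivalCurve(event_times=ev_times, survival=surv, at_risk=at_risk)


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank (Mantel-Cox) test: (chi-square, p)."""
    ta, ea = _as_arrays(time_a, event_a)
    tb, eb = _as_arrays(time_b, event_b)
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _breslow_terms(time, event, group):
    """Per-event-time risk-set summaries for the Breslow partial likelihood."""
    order = np.argsort(-time, kind="stable")  # descending time
    t_sorted = time[order]
    e_sorted = event[order]
    g_sorted = group[order]
    # cumulative risk-set counts walking down in time
    n1_cum = np.cumsum(g_sorted)
    n0_cum = np.cumsum(1 - g_sorted)
    terms = []  # (d_total, d_group1, n0_at_risk, n1_at_risk)
    ev_times = np.unique(time[event == 1])
    for t in ev_times:
        at_risk = t_sorted >= t
        idx = at_risk.sum() - 1  # last index still at risk (descending order)
        n1 = n1_cum[idx]
        n0 = n0_cum[idx]
        here = (t_sorted == t) & (e_sorted == 1)
        d = int(here.sum())
        d1 = int(g_sorted[here].sum())
        terms.append((d, d1, float(n0), float(n1)))
    return terms


def cox_hr(time, event, group) -> tuple[float, float]:
    """Univariate Cox hazard ratio for a binary covariate, Breslow ties.

    Returns (hr, wald_p) with hr = exp(beta_hat) for group 1 vs group 0.
    Monotone likelihood (all events in one group) is flagged with a warning
    and reported as a boundary hr (0 or inf) with p = nan.
    """
    time, event = _as_arrays(time, event)
    group = np.asarray(group, dtype=float)
    if group.shape != time.shape:
        raise ParameterError("group must align with time/event")
    if not np.isin(group, (0, 1)).all():
        raise ParameterError("group labels must be 0 or 1")
    ev1 = event[group == 1].sum()
    ev0 = event[group == 0].sum()
    if ev1 + ev0 == 0:
        raise ParameterError("no events in either group")
    if ev1 == 0 or ev0 == 0:
        hr = 0.0 if ev1 == 0 else np.inf
        warnings.warn(
            "monotone partial likelihood (all events in one group); "
            f"hazard ratio at boundary ({hr})",
            stacklevel=2,
        )
        return hr, float("nan")

    terms = _breslow_terms(time, event, group)

    def score_info(beta: float) -> tuple[float, float]:
        eb = np.exp(beta)
        u = 0.0
        info = 0.0
        for d, d1, n0, n1 in terms:
            denom = n0 + n1 * eb
            pi = n1 * eb / denom
            u += d1 - d * pi
            info += d * pi * (1 - pi)
        return u, info

    beta = 0.0
    for _ in range(60):
        u, info = score_info(beta)
        if info <= 0:
            break
        step = u / info
        step = float(np.clip(step, -2.0, 2.0))
        beta += step
        if abs(step) < 1e-10:
            break
        if abs(beta) > 25:  # effectively monotone
            warnings.warn("partial-likelihood estimate diverging; hazard ratio at boundary",
                          stacklevel=2)
            return (np.inf if beta > 0 else 0.0), float("nan")
    _, info = score_info(beta)
    se = 1.0 / np.sqrt(info)
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return float(np.exp(beta)), float(p)


def median_split(values) -> np.ndarray:
    """Label patients 'high' iff value > median; ties go to 'low'."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ParameterError("median_split needs >= 2 patients")
    med = np.median(values)
    return np.where(values > med, "high", "low")


def classify_candidates(
    diff: pd.DataFrame,
    expr: OmicsMatrix,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    features: list[str] | None = None,
    endpoint: str = "os",
) -> tuple[CandidateSet, CandidateSet]:
    """Joint differential-expression + survival screen.

    ``diff`` is the differential_test output for ``expr``'s layer;
    ``features`` optionally restricts the screen (e.g. to top-k lists).
    Patients lacking the endpoint's time or event are excluded per feature.
    Returns (ts_candidates, og_candidates).
    """
    if not (0 < alpha <= 1):
        raise ParameterError(f"alpha {alpha} outside (0, 1]")
    tumor = expr.subset_samples(expr.tumor_samples())
    pid = tumor.patient_id
    if pid.isna().all():
        raise AnalysisError("tumor samples carry no patient ids; cannot join clinical data")
    surv = clinical.endpoint(endpoint)
    usable = pid[pid.isin(surv.index)]
    if usable.empty:
        raise AnalysisError("no overlap between tumor patients and clinical survival data")

    sig = diff[diff["significant"]]
    if features is not None:
        sig = sig.loc[sig.index.intersection(features)]

    sample_ids = usable.index
    time = surv.loc[usable.to_numpy(), "time"].to_numpy(dtype=float)
    event = surv.loc[usable.to_numpy(), "event"].to_numpy(dtype=float)

    rows_ts, rows_og = [], []
    for feat in sig.index:
        x = tumor.values.loc[feat, sample_ids].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() < 2:
            continue
        xv, tv, ev = x[ok], time[ok], event[ok]
        labels = median_split(xv)
        hi = labels == "high"
        if hi.all() or (~hi).all():
            continue
        chi, p_lr = logrank_test(tv[hi], ev[hi], tv[~hi], ev[~hi])
        if p_lr >= alpha:
            continue
        if ev[hi].sum() == 0 or ev[~hi].sum() == 0:
            continue  # monotone likelihood: hazard direction untestable
        hr, _ = cox_hr(tv, ev, hi.astype(float))
        direction = sig.loc[feat, "direction"]
        row = {"feature_id": feat, "hazard_ratio": hr, "logrank_p": p_lr, "n": int(ok.sum())}
        if direction == "down" and hr < 1:
            rows_ts.append(row)
        elif direction == "up" and hr > 1:
            rows_og.append(row)

    def _make(rows, role):
        df = pd.DataFrame(rows, columns=["feature_id", "hazard_ratio", "logrank_p", "n"])
        df = df.set_index("feature_id")
        return CandidateSet(role=role, layer=expr.layer, members=df)

    ts, og = _make(rows_ts, "TS"), _make(rows_og, "OG")
    logger.info(
        "classify_candidates(%s): %d TS, %d OG of %d significant features",
        expr.layer, len(ts), len(og), len(sig),
    )
    return ts, og
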