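"""Two-year recurrence analysis stratified by PRS group.

Cases are followed from anticoagulant discontinuation; recurrence within
the 24-month window is the event, administrative censoring applies at the
cap.  Within each clinical stratum (provoked / unprovoked) the high- vs
low-PRS contrast is summarized by Kaplan-Meier curves with Greenwood CIs,
the two-group log-rank test, and a univariable Cox proportional-hazards
hazard ratio with Efron tie handling (month-granular times tie heavily,
where Efron's approximation is the less biased choice).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import RECURRENCE_CAP_MONTHS, Cohort, RecurrenceRecord
from .errors import ValidationError
from .prs import PRSResult


@dataclass
class SurvivalFit:
    """Two-group recurrence comparison within one stratum."""

    stratum: str
    km_tables: dict[str, pd.DataFrame]  # group -> time/at_risk/events/survival/CI
    logrank_stat: float
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]
    hr_p: float
    n_per_group: dict[str, int]
    flag: str = ""  # "monotone_likelihood" etc.


def truncate_records(
    records: Sequence[RecurrenceRecord], cap: float = RECURRENCE_CAP_MONTHS
) -> list[RecurrenceRecord]:
    """Apply administrative censoring at the observation cap."""
    out = []
    for r in records:
        if r.time > cap:
            out.append(RecurrenceRecord(time=cap, event=False))
        else:
            out.append(r)
    return out


def _arrays(records: Sequence[RecurrenceRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=bool)
    if (t < 0).any():
        raise ValidationError("negative follow-up time")
    return t, e


def km_estimate(records: Sequence[RecurrenceRecord]) -> pd.DataFrame:
    """Product-limit survival estimate with Greenwood 95% CIs.

    Returns one row per distinct event time: time, at_risk, events,
    survival, ci_low, ci_high.
    """
    from lifelines import KaplanMeierFitter

    if not records:
        raise ValidationError("no records")
    t, e = _arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e, label="S")
    event_times = np.unique(t[e])
    table = kmf.event_table
    ci = kmf.confidence_interval_survival_function_
    rows = []
    for et in event_times:
        rows.append(
            {
                "time": et,
                "at_risk": int(table.loc[et, "at_risk"]),
                "events": int(table.loc[et, "observed"]),
                "survival": float(kmf.survival_function_.loc[et, "S"]),
                "ci_low": float(ci.loc[et].iloc[0]),
                "ci_high": float(ci.loc[et].iloc[1]),
            }
        )
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival",
                                       "ci_low", "ci_high"])


def logrank_test(
    group_a: Sequence[RecurrenceRecord], group_b: Sequence[RecurrenceRecord]
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value)."""
    from lifelines.statistics import logrank_test as _lr

    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    ta, ea = _arrays(group_a)
    tb, eb = _arrays(group_b)
    if not ea.any() and not eb.any():
        raise ValidationError("no events in either group; log-rank undefined")
    res = _lr(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    records: Sequence[RecurrenceRecord], group_indicator: Sequence[int]
) -> tuple[float, tuple[float, float], float, str]:
    """Univariable Cox PH fit of a binary group indicator (Efron ties).

    Returns (HR, (ci_low, ci_high), p, flag); a monotone partial likelihood
    (e.g. all events in one group) is flagged with NaN estimates rather
    than raised.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    t, e = _arrays(records)
    g = np.asarray(group_indicator, dtype=float)
    if len(g) != len(t):
        raise ValidationError("group indicator length mismatch")
    if not e.any():
        raise ValidationError("no events; Cox model undefined")
    if np.unique(g).size < 2:
        raise ValidationError("group indicator does not vary")
    df = pd.DataFrame({"time": t, "event": e.astype(int), "group": g})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # lifelines' partial likelihood uses Efron tie handling
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError):
        return math.nan, (math.nan, math.nan), math.nan, "monotone_likelihood"
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    if not np.isfinite(se) or abs(beta) > 15:
        return math.nan, (math.nan, math.nan), math.nan, "monotone_likelihood"
    from scipy import stats as _st

    z = _st.norm.ppf(0.975)
    return (
        math.exp(beta),
        (math.exp(beta - z * se), math.exp(beta + z * se)),
        float(cph.summary.loc["group", "p"]),
        "",
    )


def recurrence_analysis(
    cohort: Cohort,
    prs: PRSResult,
    cap: float = RECURRENCE_CAP_MONTHS,
) -> dict[str, SurvivalFit]:
    """High- vs low-PRS recurrence comparison per provoked/unprovoked stratum.

    Requires cases with follow-up, risk class, and a ``group`` column in the
    PRS result (run :func:`vtepanel.prs.median_split` first).  Strata with
    fewer than two subjects in either PRS group are skipped with a warning.
    """
    if "group" not in prs.scores.columns:
        raise ValidationError("PRS result carries no group labels; run median_split")
    fits: dict[str, SurvivalFit] = {}
    for stratum in ("provoked", "unprovoked"):
        members = [
            s
            for s in cohort.subjects
            if s.is_case and s.risk_class == stratum and s.followup is not None
        ]
        by_group: dict[str, list[RecurrenceRecord]] = {"low": [], "high": []}
        for s in members:
            label = prs.scores.loc[s.subject_id, "group"]
            by_group[label].append(s.followup)
        if min(len(by_group["low"]), len(by_group["high"])) < 2:
            warnings.warn(f"{stratum}: fewer than 2 subjects per PRS group; skipped")
            continue
        low = truncate_records(by_group["low"], cap)
        high = truncate_records(by_group["high"], cap)
        flag = ""
        try:
            stat, p = logrank_test(low, high)
        except ValidationError as exc:
            warnings.warn(f"{stratum}: log-rank undefined ({exc})")
            stat, p, flag = math.nan, math.nan, "no_events"
        if flag:
            hr, ci, hr_p = math.nan, (math.nan, math.nan), math.nan
        else:
            hr, ci, hr_p, flag = cox_fit(
                low + high, [0] * len(low) + [1] * len(high)
            )
        fits[stratum] = SurvivalFit(
            stratum=stratum,
            km_tables={"low": km_estimate(low), "high": km_estimate(high)},
            logrank_stat=stat,
            logrank_p=p,
            hr=hr,
            hr_ci=ci,
            hr_p=hr_p,
            n_per_group={"low": len(low), "high": len(high)},
            flag=flag,
        )
    return fits


def fits_to_frame(fits: Mapping[str, SurvivalFit]) -> pd.DataFrame:
    rows = []
    for name, fit in fits.items():
        rows.append(
            {
                "stratum": name,
                "n_low": fit.n_per_group["low"],
                "n_high": fit.n_per_group["high"],
                "logrank_chi2": fit.logrank_stat,
                "logrank_p": fit.logrank_p,
                "hr_high_vs_low": fit.hr,
                "hr_ci_low": fit.hr_ci[0],
                "hr_ci_high": fit.hr_ci[1],
                "hr_p": fit.hr_p,
                "flag": fit.flag,
            }
        )
    return pd.DataFrame(rows)
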