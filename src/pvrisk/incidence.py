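"""Period construction, propensity matching and annualized TE incidence.

The comparison of interest is between patients who stayed on hydroxyurea
(HU-alone) and patients who later switched to ruxolitinib. Each patient's
record is cut into aligned periods: a fixed 365-day pre-index period, a
post-index period (until the switch for switchers, or the switcher-cohort
median HU time for non-switchers), and a switch/no-switch period (the
ruxolitinib course, or its median length appended after the post-index period
for non-switchers). Incidence is annualized per 100 patient-years of period
person-time, counting all events in the period.

All intervals are half-open ``[start, end)`` in day offsets and truncated at
``record_end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord

logger = logging.getLogger(__name__)

PRE_INDEX_DAYS = 365
PERIOD_LABELS = ("pre_index", "post_index", "switch_or_noswitch")


@dataclass
class PeriodSet:
    """Per-patient labelled half-open intervals; absent periods omitted."""

    periods: dict = field(default_factory=dict)  # label -> (start, end)
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.periods.values())
        for (a, b) in ivs:
            if not b > a:
                raise ValueError("periods must have positive length")
        for (a, b), (c, d) in zip(ivs, ivs[1:]):
            if c < b:
                raise ValueError("periods must not overlap")


@dataclass
class IncidenceResult:
    cohort_label: str
    period_label: str
    n_patients: int
    events: int
    person_years: float
    ir_per_100: float | None


@dataclass
class MatchResult:
    pairs: list            # (treated_id, control_id)
    coefficients: dict     # propensity model coefficients by covariate column
    smd_pre: dict          # absolute standardized mean difference, pre-match
    smd_post: dict


def build_periods(
    patient: PatientRecord,
    median_hu_time: float,
    median_rux_time: float,
    switcher: bool,
) -> PeriodSet:
    """Aligned periods for one patient.

    Switchers use their own ruxolitinib course dates; non-switchers use the
    switcher-cohort median HU / ruxolitinib treatment times. Periods are
    truncated at record_end; a record too short for the full pre-index window
    drops that period and flags the patient.
    """
    idx = patient.index_date
    flags: list[str] = []
    periods: dict[str, tuple] = {}

    pre_start = idx - PRE_INDEX_DAYS
    if pre_start >= patient.record_start:
        periods["pre_index"] = (pre_start, idx)
    else:
        flags.append("record shorter than pre-index window")

    if switcher:
        if patient.rux_first is None or patient.rux_last is None:
            raise ValueError(f"switcher {patient.patient_id} lacks ruxolitinib dates")
        bounds = [
            ("post_index", idx, patient.rux_first),
            ("switch_or_noswitch", patient.rux_first, patient.rux_last),
        ]
    else:
        t1 = idx + median_hu_time
        bounds = [
            ("post_index", idx, t1),
            ("switch_or_noswitch", t1, t1 + median_rux_time),
        ]
    for label, a, b in bounds:
        b = min(b, patient.record_end)
        if b > a:
            periods[label] = (int(a), int(b))
        else:
            flags.append(f"{label} empty after truncation")
    return PeriodSet(periods, flags)


def median_treatment_times(switchers: Cohort) -> tuple[float, float]:
    """Median HU course length and median ruxolitinib course length (days)
    in the switcher cohort."""
    hu = [p.hu_last - p.hu_first for p in switchers
          if p.hu_first is not None and p.hu_last is not None]
    rux = [p.rux_last - p.rux_first for p in switchers
           if p.rux_first is not None and p.rux_last is not None]
    if not hu or not rux:
        raise ValueError("switcher cohort lacks treatment-course dates")
    return float(np.median(hu)), float(np.median(rux))


def annualized_ir(
    cohort: Cohort,
    periods: dict,
    period_label: str,
    first_event_only: bool = False,
) -> IncidenceResult:
    """Annualized incidence per 100 patient-years over one labelled period.

    ``periods`` maps patient_id to :class:`PeriodSet`. All events in the
    interval are counted unless ``first_event_only``.
    """
    events = 0
    days = 0.0
    n_pat = 0
    for p in cohort:
        ps = periods.get(p.patient_id)
        if ps is None or period_label not in ps.periods:
            continue
        a, b = ps.periods[period_label]
        n_pat += 1
        days += b - a
        in_period = [t for t in p.te_times if a <= t < b]
        events += min(len(in_period), 1) if first_event_only else len(in_period)
    py = days / 365.25
    if py == 0:
        logger.warning("zero person-years for period %s; IR undefined", period_label)
        ir = None
    else:
        ir = 100.0 * events / py
    return IncidenceResult(cohort.label, period_label, n_pat, events, py, ir)


# ---------------------------------------------------------------------------
# propensity matching

MATCH_COVARIATES = ("total_treatment_time", "sex", "race", "age_at_index", "region")


def covariate_frame(cohort: Cohort, covariates=MATCH_COVARIATES) -> pd.DataFrame:
    rows = []
    for p in cohort:
        total = 0.0
        if p.hu_first is not None and p.hu_last is not None:
            total += p.hu_last - p.hu_first
        if p.rux_first is not None and p.rux_last is not None:
            total += p.rux_last - p.rux_first
        rows.append(
            {
                "patient_id": p.patient_id,
                "total_treatment_time": total,
                "sex": p.sex,
                "race": p.race,
                "region": p.region,
                "age_at_index": p.age_at_index,
            }
        )
    df = pd.DataFrame(rows).set_index("patient_id")[list(covariates)]
    return pd.get_dummies(df, drop_first=True, dtype=float)


def _smd(x_t: np.ndarray, x_c: np.ndarray) -> float:
    sd = np.sqrt((np.var(x_t, ddof=1) + np.var(x_c, ddof=1)) / 2.0) if (
        len(x_t) > 1 and len(x_c) > 1
    ) else 0.0
    if sd == 0:
        return 0.0
    return float(abs(np.mean(x_t) - np.mean(x_c)) / sd)


def propensity_match(
    treated: Cohort,
    controls: Cohort,
    covariates=MATCH_COVARIATES,
    caliper_sd: float = 0.2,
) -> MatchResult:
    """1:1 greedy nearest-neighbour matching on the propensity logit.

    Logistic propensity model on the covariates; greedy matching without
    replacement on the logit scale with caliper ``caliper_sd`` times the
    pooled SD of the logit. Treated patients are processed, and ties broken,
    in patient_id order. Reports absolute standardized mean differences per
    covariate column before and after matching.
    """
    if len(treated) == 0:
        return MatchResult([], {}, {}, {})
    Xt = covariate_frame(treated, covariates)
    Xc = covariate_frame(controls, covariates)
    X = pd.concat([Xt, Xc]).fillna(0.0)
    Xt = X.iloc[: len(Xt)]
    Xc = X.iloc[len(Xt):]
    y = np.r_[np.ones(len(Xt)), np.zeros(len(Xc))]

    from sklearn.linear_model import LogisticRegression

    # effectively unpenalized maximum likelihood
    model = LogisticRegression(C=1e12, solver="lbfgs", max_iter=2000)
    model.fit(X.values, y)
    logit = X.values @ model.coef_.ravel() + model.intercept_[0]
    if np.max(np.abs(logit)) > 30:
        raise ValueError(
            "propensity model shows complete separation; review the covariates"
        )
    lt = pd.Series(logit[: len(Xt)], index=Xt.index).sort_index()
    lc = pd.Series(logit[len(Xt):], index=Xc.index).sort_index()
    caliper = caliper_sd * float(np.std(logit, ddof=1))

    used: set[str] = set()
    pairs: list[tuple] = []
    for tid, lv in lt.items():
        best, best_d = None, np.inf
        for cid, cv in lc.items():
            if cid in used:
                continue
            d = abs(lv - cv)
            if d < best_d - 1e-12:
                best, best_d = cid, d
        if best is not None and best_d <= caliper:
            used.add(best)
            pairs.append((tid, best))

    coef = dict(zip(X.columns, model.coef_.ravel()))
    smd_pre = {c: _smd(Xt[c].values, Xc[c].values) for c in X.columns}
    if pairs:
        mt = Xt.loc[[a for a, _ in pairs]]
        mc = Xc.loc[[b for _, b in pairs]]
        smd_post = {c: _smd(mt[c].values, mc[c].values) for c in X.columns}
    else:
        smd_post = {}
    return MatchResult(pairs, coef, smd_pre, smd_post)


__all__ = [
    "IncidenceResult",
    "MATCH_COVARIATES",
    "MatchResult",
    "PERIOD_LABELS",
    "PRE_INDEX_DAYS",
    "PeriodSet",
    "annualized_ir",
    "build_periods",
    "covariate_frame",
    "median_treatment_times",
    "propensity_match",
]
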