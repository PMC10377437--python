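"""Kaplan-Meier estimation and k-group log-rank testing.

These primitives back every downstream stage (forest splitting, synergy
screening, landscape scans, validation), so they are implemented directly on
numpy arrays. The log-rank statistic is the standard one: at each distinct
event time the observed minus hypergeometric-expected events per group, with
the tie-corrected hypergeometric variance, referred to a chi-square with
(groups - 1) degrees of freedom. Censored subjects remain in the risk set at
their own time (right-continuous risk sets).

A batched two-group variant (:func:`logrank_chi2_masks`) evaluates many
candidate dichotomies of the same sample in one pass; the forest's split
search and the threshold-landscape scan are built on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class KaplanMeierCurve:
    """Product-limit estimate with risk/event counts at distinct event times."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time
    n_risk: np.ndarray
    n_event: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """S(t) as a right-continuous step function (S=1 before first event)."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.ones_like(t)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
            }
        )


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


def _check_times(time: np.ndarray) -> None:
    if time.size == 0:
        raise ValueError("at least one sample required")
    if not np.all(np.isfinite(time)) or np.any(time < 0):
        raise ValueError("times must be finite and >= 0")


def kaplan_meier(time, event) -> KaplanMeierCurve:
    """Product-limit survival estimate; ties decrement simultaneously."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    _check_times(time)

    etimes = np.unique(time[event])
    if etimes.size == 0:
        return KaplanMeierCurve(
            times=etimes,
            survival=np.ones(0),
            n_risk=np.zeros(0, dtype=int),
            n_event=np.zeros(0, dtype=int),
        )
    # risk set: subjects with time >= t (censored at t remain at risk at t)
    n_risk = (time[None, :] >= etimes[:, None]).sum(axis=1)
    n_event = ((time[None, :] == etimes[:, None]) & event[None, :]).sum(axis=1)
    surv = np.cumprod(1.0 - n_event / n_risk)
    return KaplanMeierCurve(etimes, surv, n_risk, n_event)


def logrank_test(time, event, group) -> LogRankResult:
    """k-group log-rank test.

    Groups with zero subjects are dropped with a warning and the degrees of
    freedom adjusted; fewer than two remaining groups is an error.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    _check_times(time)

    labels, ginv = np.unique(group, return_inverse=True)
    counts = np.bincount(ginv, minlength=labels.size)
    if np.any(counts == 0):  # can occur with categorical inputs
        logger.warning("dropping empty groups: %s", labels[counts == 0])
        keep = counts > 0
        labels = labels[keep]
    k = labels.size
    if k < 2:
        raise ValueError("log-rank requires at least two non-empty groups")

    etimes = np.unique(time[event])
    if etimes.size == 0:
        return LogRankResult(chi2=0.0, df=k - 1, p=1.0)

    # per (event time, group): at-risk and event counts
    at_risk = time[None, :] >= etimes[:, None]          # (K, n)
    is_event = (time[None, :] == etimes[:, None]) & event[None, :]
    gmat = group[None, :] == labels[:, None]            # (k, n)
    n_jk = at_risk.astype(float) @ gmat.T.astype(float)   # (K, k)
    d_jk = is_event.astype(float) @ gmat.T.astype(float)
    n_k = n_jk.sum(axis=1)
    d_k = d_jk.sum(axis=1)

    observed = d_jk.sum(axis=0)
    expected = (d_k[:, None] * n_jk / n_k[:, None]).sum(axis=0)

    # tie-corrected hypergeometric covariance, summed over event times
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = n_jk / n_k[:, None]                      # (K, k)
        mult = d_k * (n_k - d_k) / np.where(n_k > 1, n_k - 1, 1.0)
        mult = np.where(n_k > 1, mult, 0.0)
        V = np.einsum("t,tj,tl->jl", mult, frac, -frac)
        V[np.diag_indices(k)] += (mult[:, None] * frac).sum(axis=0)

    z = (observed - expected)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        chi2 = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    return LogRankResult(chi2=chi2, df=k - 1, p=max(p, np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# batched two-group machinery (forest split search, landscape scans)

@dataclass
class _RiskArrays:
    """Precomputed per-sample risk/event indicator matrices for one sample set."""

    etimes: np.ndarray   # (K,)
    R: np.ndarray        # (n, K) float32: time_i >= tau_k
    E: np.ndarray        # (n, K) float32: event at tau_k
    n_k: np.ndarray      # (K,)
    d_k: np.ndarray      # (K,)


def risk_arrays(time, event) -> _RiskArrays:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    etimes = np.unique(time[event])
    R = (time[:, None] >= etimes[None, :]).astype(np.float32)
    E = ((time[:, None] == etimes[None, :]) & event[:, None]).astype(np.float32)
    return _RiskArrays(etimes, R, E, R.sum(axis=0), E.sum(axis=0))


def logrank_chi2_masks(ra: _RiskArrays, masks: np.ndarray):
    """Two-group log-rank chi-square for many dichotomies of one sample.

    ``masks`` is (C, n) boolean, each row defining "group 1". Returns
    ``(chi2, p, events_in_group1)`` arrays of length C. Rows whose variance is
    zero (degenerate splits) get chi2 0 and p 1.
    """
    if ra.etimes.size == 0:
        c = masks.shape[0]
        return np.zeros(c), np.ones(c), np.zeros(c)
    M = masks.astype(np.float32)
    N1 = M @ ra.R            # (C, K) at-risk in group 1
    D1 = M @ ra.E            # (C, K) events in group 1
    n_k, d_k = ra.n_k, ra.d_k
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = N1 / n_k
        mult = d_k * (n_k - d_k) / np.where(n_k > 1, n_k - 1, 1.0)
        mult = np.where(n_k > 1, mult, 0.0)
        O1 = D1.sum(axis=1)
        E1 = (d_k * frac).sum(axis=1)
        V = (mult * frac * (1.0 - frac)).sum(axis=1)
    ok = V > 1e-12
    chi2 = np.zeros(masks.shape[0])
    chi2[ok] = (O1[ok] - E1[ok]) ** 2 / V[ok]
    p = np.ones(masks.shape[0])
    p[ok] = stats.chi2.sf(chi2[ok], 1)
    return chi2, np.maximum(p, np.finfo(float).tiny), O1


def te_window_outcome(cohort, window_start_days: float = 183, horizon_days: float | None = 365.25):
    """Time-to-first-TE outcome measured from the end of the feature window.

    For each patient whose record reaches ``index + window_start_days``:
    time runs from that point to the first subsequent TE, administratively
    censored at ``horizon_days`` (when given) or at record_end. Returns
    ``(subcohort, frame)`` where the frame has columns ``time`` (days),
    ``event`` (bool) and ``covered`` (follow-up reached the full horizon —
    the label set for windowed classification metrics).
    """
    import pandas as pd

    keep, rows = [], []
    for p in cohort:
        w0 = p.index_date + window_start_days
        if p.record_end <= w0:
            continue
        end = p.record_end if horizon_days is None else min(p.record_end, w0 + horizon_days)
        first_te = next((t for t in p.te_times if w0 <= t < end), None)
        if first_te is not None:
            t, ev = first_te - w0, True
        else:
            t, ev = end - w0, False
        covered = ev or horizon_days is None or (p.record_end >= w0 + horizon_days)
        keep.append(p)
        rows.append((p.patient_id, float(t), ev, covered))
    frame = pd.DataFrame(rows, columns=["patient_id", "time", "event", "covered"])
    frame = frame.set_index("patient_id")
    return cohort.subset(keep), frame


def nelson_aalen_total(time, event) -> float:
    """Nelson-Aalen cumulative hazard accumulated over all observed times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    etimes = np.unique(time[event])
    if etimes.size == 0:
        return 0.0
    n_risk = (time[None, :] >= etimes[:, None]).sum(axis=1)
    n_event = ((time[None, :] == etimes[:, None]) & event[None, :]).sum(axis=1)
    return float(np.sum(n_event / n_risk))


__all__ = [
    "KaplanMeierCurve",
    "LogRankResult",
    "kaplan_meier",
    "logrank_chi2_masks",
    "logrank_test",
    "nelson_aalen_total",
    "risk_arrays",
]
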