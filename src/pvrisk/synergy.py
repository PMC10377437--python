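"""Pairwise synergy screening of variable interactions.

For a pair of variables the "expected" significance is the product of the two
single-variable median-split log-rank p-values; the "observed" significance is
the log-rank p-value of the four-quadrant grouping formed by both median
splits together. The synergy score is expected / observed: a score well above
1 means the pair stratifies TE risk more sharply than its parts predict.

Screening runs over all unordered pairs within each TE-history stratum
(all / with / without history), using medians computed within the stratum.
No multiplicity correction is applied to the screening p-values; a Bonferroni
column is carried along for reference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, stratum_subset
from .survival import logrank_test, te_window_outcome

logger = logging.getLogger(__name__)

STRATA = ("all", "with_te_history", "without_te_history")
MIN_QUADRANT_SIZE = 10


@dataclass
class SynergyRecord:
    var1: str
    var2: str
    stratum: str
    p1: float | None
    p2: float | None
    expected_p: float | None
    observed_p: float | None
    score: float | None
    n: int
    valid: bool
    note: str = ""


def synergy_score(expected_p: float, observed_p: float) -> float:
    """expected / observed; both p-values must lie in (0, 1]."""
    for name, p in (("expected_p", expected_p), ("observed_p", observed_p)):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {p}")
    return expected_p / observed_p


def _median_split(x: np.ndarray) -> np.ndarray:
    """Boolean high/low split: >= median for continuous variables, value
    itself for binary flags (where the literal median would be degenerate)."""
    vals = np.unique(x)
    if vals.size <= 2 and set(vals).issubset({0.0, 1.0}):
        return x > 0.5
    return x >= np.median(x)


def pair_interaction(
    cohort: Cohort,
    var1: str,
    var2: str,
    stratum: str = "all",
    window_start_days: float = 183.0,
    horizon_days: float | None = 365.25,
    min_quadrant_size: int = MIN_QUADRANT_SIZE,
) -> SynergyRecord:
    """Synergy record for one variable pair within one stratum."""
    invalid = lambda note, n=0: SynergyRecord(  # noqa: E731
        var1, var2, stratum, None, None, None, None, None, n, False, note
    )
    if var1 == var2:
        return invalid("degenerate pair: var1 == var2")
    sub = stratum_subset(cohort, stratum)
    sub, frame = te_window_outcome(sub, window_start_days, horizon_days)
    x1 = sub.variable(var1)
    x2 = sub.variable(var2)
    ok = np.isfinite(x1) & np.isfinite(x2)
    n = int(ok.sum())
    if n < 4 * min_quadrant_size:
        return invalid(f"only {n} complete cases", n)
    time = frame["time"].values[ok]
    event = frame["event"].values[ok].astype(bool)
    hi1 = _median_split(x1[ok])
    hi2 = _median_split(x2[ok])
    if hi1.all() or (~hi1).all() or hi2.all() or (~hi2).all():
        return invalid("degenerate median split", n)

    p1 = logrank_test(time, event, hi1).p
    p2 = logrank_test(time, event, hi2).p

    quadrant = 2 * hi1.astype(int) + hi2.astype(int)
    sizes = np.bincount(quadrant, minlength=4)
    keep_q = sizes >= min_quadrant_size
    if keep_q.sum() < 2:
        return invalid("fewer than 2 quadrants of minimum size", n)
    if not keep_q.all():
        logger.warning(
            "%s x %s (%s): quadrants %s below size %d dropped from observed p",
            var1, var2, stratum, np.flatnonzero(~keep_q).tolist(), min_quadrant_size,
        )
    mask = keep_q[quadrant]
    observed = logrank_test(time[mask], event[mask], quadrant[mask]).p
    expected = p1 * p2
    return SynergyRecord(
        var1, var2, stratum, p1, p2, expected, observed,
        synergy_score(expected, observed), n, True,
        "" if keep_q.all() else "small quadrants dropped",
    )


def screen_all_pairs(
    cohort: Cohort,
    variables,
    strata=STRATA,
    **kwargs,
) -> list[SynergyRecord]:
    """All unordered pairs x strata, sorted by descending synergy score
    (invalid records last, then by name)."""
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("need at least two variables to screen")
    records = [
        pair_interaction(cohort, v1, v2, stratum, **kwargs)
        for stratum in strata
        for v1, v2 in itertools.combinations(sorted(variables), 2)
    ]
    records.sort(
        key=lambda r: (
            not r.valid,
            -(r.score if r.score is not None else -np.inf),
            r.var1,
            r.var2,
            r.stratum,
        )
    )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Tabular export mirroring the screening table's columns, with a
    reference Bonferroni-adjusted observed p over the valid comparisons."""
    df = pd.DataFrame([r.__dict__ for r in records])
    m = int(df["valid"].sum())
    df["observed_p_bonferroni"] = [
        min(p * m, 1.0) if p is not None else None for p in df["observed_p"]
    ]
    return df


__all__ = [
    "MIN_QUADRANT_SIZE",
    "STRATA",
    "SynergyRecord",
    "pair_interaction",
    "records_to_frame",
    "screen_all_pairs",
    "synergy_score",
]
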