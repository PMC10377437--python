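"""Two-variable threshold search ("risk landscape"), decision trees and
fixed-threshold external validation.

For a variable pair, every combination of candidate thresholds (by default
the 5th-95th percentiles in steps of 2.5) dichotomizes both variables and the
log-rank p-value of the induced grouping is recorded in a matrix. In
``risk_vs_rest`` mode the designated risk quadrant is compared against the
pooled remainder (two groups); in ``four_group`` mode all four quadrants
enter a k-group test. The matrix minimum identifies the optimal threshold
pair, from which a two-level clinical decision tree is built and then applied
unchanged to an independent cohort (fixed-threshold validation).

This module is deterministic for a fixed cohort: there is no randomness in
the scan, the tie-breaking or the tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, PatientRecord, stratum_subset
from .survival import (
    LogRankResult,
    kaplan_meier,
    logrank_chi2_masks,
    logrank_test,
    risk_arrays,
    te_window_outcome,
)

logger = logging.getLogger(__name__)

MIN_QUADRANT_SIZE = 10
HIGH, LOW = "high risk", "low risk"


def percentile_grid(x: np.ndarray, lo: float = 5.0, hi: float = 95.0, step: float = 2.5) -> np.ndarray:
    """Candidate thresholds at the percentiles of the observed values."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    qs = np.arange(lo, hi + 1e-9, step)
    return np.unique(np.percentile(x, qs))


@dataclass
class PValueMatrix:
    var1: str
    var2: str
    grid1: np.ndarray
    grid2: np.ndarray
    p: np.ndarray               # (len(grid1), len(grid2)); NaN = absent cell
    mode: str
    min_quadrant_size: int
    n_risk: np.ndarray          # designated risk-group size per cell
    risk_quadrant: np.ndarray   # per-cell quadrant code 2*hi1 + hi2
    n: int                      # complete-case sample size

    def as_frame(self):
        import pandas as pd

        t1, t2 = np.meshgrid(self.grid1, self.grid2, indexing="ij")
        return pd.DataFrame(
            {
                "t1": t1.ravel(),
                "t2": t2.ravel(),
                "p": self.p.ravel(),
                "n_risk": self.n_risk.ravel(),
                "risk_quadrant": self.risk_quadrant.ravel(),
            }
        )


@dataclass
class ThresholdPair:
    var1: str
    threshold1: float
    direction1: str
    var2: str
    threshold2: float
    direction2: str
    p: float
    n_risk: int

    @property
    def risk_label(self) -> str:
        return (
            f"{self.var1} {self.direction1} {self.threshold1:g} "
            f"and {self.var2} {self.direction2} {self.threshold2:g}"
        )


def _km_at_end(time: np.ndarray, event: np.ndarray) -> float:
    """KM survival at the last observed time of the subgroup (1.0 if no
    events)."""
    if event.sum() == 0:
        return 1.0
    km = kaplan_meier(time, event)
    return float(km.survival[-1])


def _code_from_directions(d1: str, d2: str) -> int:
    return 2 * int(d1 == ">=") + int(d2 == ">=")


def _directions_from_code(code: int) -> tuple[str, str]:
    return (">=" if code // 2 else "<", ">=" if code % 2 else "<")


def pvalue_matrix(
    cohort: Cohort,
    var1: str,
    var2: str,
    grids: tuple | None = None,
    mode: str = "risk_vs_rest",
    directions: tuple | None = None,
    stratum: str | None = None,
    window_start_days: float = 183.0,
    horizon_days: float | None = 365.25,
    min_quadrant_size: int = MIN_QUADRANT_SIZE,
) -> PValueMatrix:
    """Log-rank p-values over a grid of threshold pairs.

    ``directions`` fixes the risk quadrant (e.g. ``(">=", "<")`` for high
    var1 / low var2) in ``risk_vs_rest`` mode; when omitted, the quadrant
    with the worst KM survival at the horizon is designated per cell.
    Cells whose groups fall below ``min_quadrant_size`` are absent (NaN).
    """
    if mode not in ("risk_vs_rest", "four_group"):
        raise ValueError(f"unknown mode {mode!r}")
    sub = stratum_subset(cohort, stratum) if stratum else cohort
    sub, frame = te_window_outcome(sub, window_start_days, horizon_days)
    x1, x2 = sub.variable(var1), sub.variable(var2)
    ok = np.isfinite(x1) & np.isfinite(x2)
    x1, x2 = x1[ok], x2[ok]
    time = frame["time"].values[ok]
    event = frame["event"].values[ok].astype(bool)
    n = x1.size

    if grids is None:
        grids = (percentile_grid(x1), percentile_grid(x2))
    grid1 = np.asarray(grids[0], dtype=float)
    grid2 = np.asarray(grids[1], dtype=float)
    if grid1.size == 0 or grid2.size == 0:
        raise ValueError("grids must be non-empty")
    for g, x, name in ((grid1, x1, var1), (grid2, x2, var2)):
        if g.min() <= x.min() or g.max() > x.max():
            logger.warning(
                "grid for %s extends outside the observed range; edge cells will be absent",
                name,
            )

    hi1 = x1[None, :] >= grid1[:, None]   # (G1, n)
    hi2 = x2[None, :] >= grid2[:, None]   # (G2, n)
    G1, G2 = grid1.size, grid2.size
    p = np.full((G1, G2), np.nan)
    n_risk = np.zeros((G1, G2), dtype=int)
    risk_q = np.full((G1, G2), -1, dtype=int)

    if mode == "risk_vs_rest" and directions is not None:
        code = _code_from_directions(*directions)
        C1 = hi1 if directions[0] == ">=" else ~hi1
        C2 = hi2 if directions[1] == ">=" else ~hi2
        masks = (C1[:, None, :] & C2[None, :, :]).reshape(G1 * G2, n)
        sizes = masks.sum(axis=1)
        present = (sizes >= min_quadrant_size) & (n - sizes >= min_quadrant_size)
        ra = risk_arrays(time, event)
        _, pv, _ = logrank_chi2_masks(ra, masks[present])
        flat = np.full(G1 * G2, np.nan)
        flat[present] = pv
        p = flat.reshape(G1, G2)
        n_risk = sizes.reshape(G1, G2)
        risk_q[:] = code
        return PValueMatrix(
            var1, var2, grid1, grid2, p, mode, min_quadrant_size, n_risk, risk_q, n
        )

    # per-cell paths: four_group, or risk_vs_rest with direction discovery
    for i in range(G1):
        for j in range(G2):
            quadrant = 2 * hi1[i].astype(int) + hi2[j].astype(int)
            sizes = np.bincount(quadrant, minlength=4)
            if mode == "four_group":
                if (sizes < min_quadrant_size).any():
                    continue
                res = logrank_test(time, event, quadrant)
                surv = [
                    _km_at_end(time[quadrant == q], event[quadrant == q])
                    for q in range(4)
                ]
                q_risk = int(np.argmin(surv))
            else:
                occupied = np.flatnonzero(sizes >= min_quadrant_size)
                if occupied.size == 0:
                    continue
                surv = [
                    _km_at_end(time[quadrant == q], event[quadrant == q])
                    if sizes[q] >= min_quadrant_size
                    else np.inf
                    for q in range(4)
                ]
                q_risk = int(np.argmin(surv))
                mask = quadrant == q_risk
                if n - sizes[q_risk] < min_quadrant_size:
                    continue
                res = logrank_test(time, event, mask)
            p[i, j] = res.p
            n_risk[i, j] = sizes[q_risk]
            risk_q[i, j] = q_risk
    return PValueMatrix(
        var1, var2, grid1, grid2, p, mode, min_quadrant_size, n_risk, risk_q, n
    )


def optimal_thresholds(matrix: PValueMatrix) -> ThresholdPair:
    """Minimum-p cell; ties broken by larger risk-quadrant size, then lower
    var1 threshold, then lower var2 threshold."""
    if np.all(np.isnan(matrix.p)):
        raise ValueError("all landscape cells are absent")
    pmin = np.nanmin(matrix.p)
    cells = np.argwhere(matrix.p == pmin)
    order = sorted(
        (tuple(c) for c in cells),
        key=lambda c: (-matrix.n_risk[c], matrix.grid1[c[0]], matrix.grid2[c[1]]),
    )
    i, j = order[0]
    d1, d2 = _directions_from_code(int(matrix.risk_quadrant[i, j]))
    return ThresholdPair(
        matrix.var1, float(matrix.grid1[i]), d1,
        matrix.var2, float(matrix.grid2[j]), d2,
        float(pmin), int(matrix.n_risk[i, j]),
    )


def permutation_adjusted_p(
    cohort: Cohort,
    var1: str,
    var2: str,
    n_permutations: int = 500,
    seed: int = 0,
    **kwargs,
) -> dict:
    """Selection-adjusted minimum p: the landscape minimum is re-derived
    under event-label permutations, and the adjusted p is the fraction of
    permuted minima at least as extreme. This guards the selected threshold
    pair against multiple-testing optimism across cells (an addition beyond
    the raw matrix; clearly labelled in outputs)."""
    observed = optimal_thresholds(pvalue_matrix(cohort, var1, var2, **kwargs))
    rng = np.random.default_rng(seed)
    # permute event/time rows jointly against covariate rows via patient relabel
    sub = cohort.patients
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(sub))
        shuffled = []
        for p_rec, k in zip(sub, perm):
            q = sub[k]
            r = PatientRecord(**{**p_rec.__dict__})
            r.index_date = q.index_date
            r.record_start = q.record_start
            r.record_end = q.record_end
            r.te_times = q.te_times
            shuffled.append(r)
        mat = pvalue_matrix(Cohort(shuffled, cohort.label), var1, var2, **kwargs)
        if np.all(np.isnan(mat.p)):
            continue
        if np.nanmin(mat.p) <= observed.p:
            count += 1
    return {
        "min_p": observed.p,
        "permutation_adjusted_p": (count + 1) / (n_permutations + 1),
        "n_permutations": n_permutations,
    }


# ---------------------------------------------------------------------------
# decision trees and fixed-threshold validation

@dataclass
class DecisionTree:
    """Two-level threshold rules mapping a patient to high/low TE risk:
    high risk iff both risk-direction conditions hold."""

    var1: str
    threshold1: float
    direction1: str
    var2: str
    threshold2: float
    direction2: str

    def _cond(self, value: float, threshold: float, direction: str) -> bool:
        if not np.isfinite(value):
            return False  # unverifiable condition: defaults to low risk
        return value >= threshold if direction == ">=" else value < threshold

    def classify(self, patient: PatientRecord) -> str:
        c1 = self._cond(patient.variable(self.var1), self.threshold1, self.direction1)
        if not c1:
            return LOW
        c2 = self._cond(patient.variable(self.var2), self.threshold2, self.direction2)
        return HIGH if c2 else LOW

    def apply(self, cohort: Cohort) -> np.ndarray:
        return np.array([self.classify(p) for p in cohort])

    @property
    def rule(self) -> str:
        return (
            f"{HIGH} iff {self.var1} {self.direction1} {self.threshold1:g} "
            f"and {self.var2} {self.direction2} {self.threshold2:g}"
        )


def build_decision_tree(pair: ThresholdPair) -> DecisionTree:
    return DecisionTree(
        pair.var1, pair.threshold1, pair.direction1,
        pair.var2, pair.threshold2, pair.direction2,
    )


@dataclass
class ValidationResult:
    logrank: LogRankResult
    km_curves: dict        # leaf label -> KaplanMeierCurve
    n_per_leaf: dict
    n_excluded_missing: int


def validate_fixed_thresholds(
    tree: DecisionTree,
    cohort: Cohort,
    stratum: str = "without_te_history",
    window_start_days: float = 183.0,
    horizon_days: float | None = None,
) -> ValidationResult:
    """Apply fixed thresholds to an independent cohort and test
    thrombosis-free survival between the leaves (full follow-up by default).

    Patients missing either variable cannot be classified and are excluded
    (counted in the result). A leaf with zero patients raises, carrying the
    diagnostic forward."""
    sub = stratum_subset(cohort, stratum)
    sub, frame = te_window_outcome(sub, window_start_days, horizon_days)
    x1, x2 = sub.variable(tree.var1), sub.variable(tree.var2)
    ok = np.isfinite(x1) & np.isfinite(x2)
    classified = sub.subset([p for p, k in zip(sub, ok) if k])
    labels = tree.apply(classified)
    time = frame["time"].values[ok]
    event = frame["event"].values[ok].astype(bool)
    counts = {leaf: int((labels == leaf).sum()) for leaf in (HIGH, LOW)}
    empty = [leaf for leaf, c in counts.items() if c == 0]
    if empty:
        raise ValueError(
            f"decision-tree leaf {empty} is empty in cohort {cohort.label!r}; "
            "log-rank comparison impossible"
        )
    res = logrank_test(time, event, labels)
    km_curves = {
        leaf: kaplan_meier(time[labels == leaf], event[labels == leaf])
        for leaf in (HIGH, LOW)
    }
    return ValidationResult(res, km_curves, counts, int((~ok).sum()))


__all__ = [
    "DecisionTree",
    "HIGH",
    "LOW",
    "MIN_QUADRANT_SIZE",
    "PValueMatrix",
    "ThresholdPair",
    "ValidationResult",
    "build_decision_tree",
    "optimal_thresholds",
    "percentile_grid",
    "permutation_adjusted_p",
    "pvalue_matrix",
    "validate_fixed_thresholds",
]
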