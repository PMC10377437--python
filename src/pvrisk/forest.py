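"""Random survival forest with log-rank splitting and drop-column importance.

Each tree is grown on a without-replacement subsample; at every node a random
subset of features is tried, and for each feature a set of candidate
cutpoints; the split maximizing the two-group log-rank chi-square is taken.
Missing feature values are routed down the child that received more training
samples ("majority direction"). A terminal node's value is the Nelson-Aalen
cumulative hazard accumulated over its training samples, so a patient's risk
score is the tree-average cumulative hazard over the prediction horizon
(higher = earlier TE). Out-of-bag (OOB) scores average only trees whose
subsample excluded the patient.

The evaluation target is occurrence of a TE in the 6-18-month post-index
window: binary label = at least one TE within the horizon after the feature
window, restricted to patients whose follow-up covers the full horizon (or
who had an event); the metric is the Mann-Whitney ROC-AUC of risk scores
against that label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .cohort import Cohort, feature_matrix
from .survival import logrank_chi2_masks, nelson_aalen_total, risk_arrays, te_window_outcome

logger = logging.getLogger(__name__)

DEFAULT_FEATURES = (
    "te_history", "anticoag", "age",
    "NEP", "LYP", "RDW", "WBC", "Hct", "HGB", "Plt",
    "BMI", "DBP", "SBP", "weight", "HRT",
)


@dataclass
class RSFConfig:
    n_trees: int = 500
    mtry: int | None = None          # default ceil(sqrt(n_features))
    min_node_events: int = 3         # minimum events in each child
    max_depth: int | None = None
    bootstrap_fraction: float = 0.632  # without replacement
    seed: int = 0
    features: tuple = DEFAULT_FEATURES
    n_candidate_cutpoints: int = 24
    window_start_days: float = 183.0
    horizon_days: float = 365.25

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        k = len(self.features)
        if k == 0:
            raise ValueError("feature list must be non-empty")
        if self.mtry is not None and not 1 <= self.mtry <= k:
            raise ValueError("mtry must be in [1, n_features]")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")

    @property
    def effective_mtry(self) -> int:
        return self.mtry if self.mtry is not None else int(np.ceil(np.sqrt(len(self.features))))


@dataclass
class ImportanceEntry:
    variable: str
    score: float
    rank: int


class _Node:
    __slots__ = ("feature", "threshold", "missing_left", "left", "right", "value")

    def __init__(self, value=None, feature=None, threshold=None, missing_left=True,
                 left=None, right=None):
        self.value = value
        self.feature = feature
        self.threshold = threshold
        self.missing_left = missing_left
        self.left = left
        self.right = right

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _leaf(time, event) -> _Node:
    return _Node(value=nelson_aalen_total(time, event))


def _grow(X, time, event, idx, rng, cfg: RSFConfig, depth: int) -> _Node:
    t, e = time[idx], event[idx]
    d_tot = int(e.sum())
    if d_tot < 2 * cfg.min_node_events or (
        cfg.max_depth is not None and depth >= cfg.max_depth
    ):
        return _leaf(t, e)
    ra = risk_arrays(t, e)
    feats = rng.choice(len(cfg.features), size=cfg.effective_mtry, replace=False)

    best = None  # (chi2, feat, cutpoint, missing_left, mask)
    for f in feats:
        x = X[idx, f]
        finite = np.isfinite(x)
        xf = x[finite]
        uniq = np.unique(xf)
        if uniq.size < 2:
            continue
        if uniq.size - 1 > cfg.n_candidate_cutpoints:
            qs = np.quantile(xf, np.linspace(0, 1, cfg.n_candidate_cutpoints + 2)[1:-1])
            cand = np.unique(qs)
        else:
            cand = (uniq[:-1] + uniq[1:]) / 2.0
        base = x[:, None] < cand[None, :]            # NaN compares False
        n_left = base.sum(axis=0)
        n_right_finite = finite.sum() - n_left
        maj_left = n_left >= n_right_finite
        masks = base.T.copy()
        if not finite.all():
            masks[maj_left] |= ~finite
        chi2, _, d_left = logrank_chi2_masks(ra, masks)
        size_left = masks.sum(axis=1)
        valid = (
            (d_left >= cfg.min_node_events)
            & (d_tot - d_left >= cfg.min_node_events)
            & (size_left > 0)
            & (size_left < idx.size)
        )
        if not valid.any():
            continue
        j = int(np.flatnonzero(valid)[np.argmax(chi2[valid])])
        if best is None or chi2[j] > best[0]:
            best = (float(chi2[j]), int(f), float(cand[j]), bool(maj_left[j]), masks[j])

    if best is None or best[0] <= 0:
        return _leaf(t, e)
    _, f, cut, miss_left, mask = best
    node = _Node(feature=f, threshold=cut, missing_left=miss_left)
    node.left = _grow(X, time, event, idx[mask], rng, cfg, depth + 1)
    node.right = _grow(X, time, event, idx[~mask], rng, cfg, depth + 1)
    return node


def _route(node: _Node, X: np.ndarray, rows: np.ndarray, out: np.ndarray) -> None:
    if node.is_leaf:
        out[rows] = node.value
        return
    x = X[rows, node.feature]
    finite = np.isfinite(x)
    left = (x < node.threshold) & finite
    if node.missing_left:
        left |= ~finite
    _route(node.left, X, rows[left], out)
    _route(node.right, X, rows[~left], out)


@dataclass
class RandomSurvivalForest:
    config: RSFConfig
    trees: list
    oob_masks: np.ndarray        # (n_trees, n) True where sample was out-of-bag
    X_train: np.ndarray
    time: np.ndarray
    event: np.ndarray
    covered: np.ndarray
    patient_ids: list

    def predict_risk(self, X: np.ndarray) -> np.ndarray:
        """Tree-average cumulative hazard at the horizon for each row of X."""
        X = np.asarray(X, dtype=float)
        total = np.zeros(X.shape[0])
        buf = np.empty(X.shape[0])
        rows = np.arange(X.shape[0])
        for tree in self.trees:
            _route(tree, X, rows, buf)
            total += buf
        return total / len(self.trees)

    def predict_cohort(self, cohort: Cohort) -> np.ndarray:
        X = feature_matrix(cohort, self.config.features).values
        return self.predict_risk(X)

    def oob_risk(self) -> np.ndarray:
        """Per-training-sample risk averaged over trees not containing it."""
        n = self.X_train.shape[0]
        total = np.zeros(n)
        count = np.zeros(n)
        buf = np.empty(n)
        rows = np.arange(n)
        for tree, oob in zip(self.trees, self.oob_masks):
            _route(tree, self.X_train, rows, buf)
            total[oob] += buf[oob]
            count[oob] += 1
        with np.errstate(invalid="ignore"):
            out = total / count
        out[count == 0] = np.nan
        return out


def fit_rsf(cohort: Cohort, config: RSFConfig | None = None) -> RandomSurvivalForest:
    """Fit the forest on a cohort already filtered by the model eligibility
    rules; deterministic for a fixed config seed."""
    config = config or RSFConfig()
    sub, frame = te_window_outcome(cohort, config.window_start_days, config.horizon_days)
    if len(sub) < len(cohort):
        logger.warning(
            "%d patients lack follow-up past the feature window and were dropped",
            len(cohort) - len(sub),
        )
    time = frame["time"].values
    event = frame["event"].values.astype(bool)
    if event.sum() == 0:
        raise ValueError("no TE events in the training window; cannot fit")
    X = feature_matrix(sub, config.features).values.astype(float)

    n = X.shape[0]
    n_sub = max(2, int(round(config.bootstrap_fraction * n)))
    ss = np.random.SeedSequence(config.seed)
    trees, oob_masks = [], np.zeros((config.n_trees, n), dtype=bool)
    for b, child in enumerate(ss.spawn(config.n_trees)):
        rng = np.random.default_rng(child)
        idx = rng.choice(n, size=n_sub, replace=False)
        oob_masks[b] = True
        oob_masks[b, idx] = False
        trees.append(_grow(X, time, event, np.sort(idx), rng, config, 0))
    return RandomSurvivalForest(
        config=config,
        trees=trees,
        oob_masks=oob_masks,
        X_train=X,
        time=time,
        event=event,
        covered=frame["covered"].values.astype(bool),
        patient_ids=list(frame.index),
    )


def predict_risk(forest: RandomSurvivalForest, cohort: Cohort) -> np.ndarray:
    return forest.predict_cohort(cohort)


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Rank-based ROC-AUC; None when only one class is present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    ok = np.isfinite(scores)
    scores, labels = scores[ok], labels[ok]
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        logger.warning("single-class label set; AUC undefined")
        return None
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def windowed_auc(forest: RandomSurvivalForest, cohort: Cohort | None = None) -> float | None:
    """ROC-AUC for TE occurrence within the prediction window.

    Without a cohort, uses the training cohort's OOB scores. With a cohort,
    scores it with the full forest. Patients censored inside the window
    before any TE are excluded from the label set.
    """
    cfg = forest.config
    if cohort is None:
        scores = forest.oob_risk()
        event, covered = forest.event, forest.covered
    else:
        sub, frame = te_window_outcome(cohort, cfg.window_start_days, cfg.horizon_days)
        scores = forest.predict_cohort(sub)
        event = frame["event"].values.astype(bool)
        covered = frame["covered"].values.astype(bool)
    keep = covered
    return mann_whitney_auc(scores[keep], event[keep])


def drop_variable_importance(
    cohort: Cohort, config: RSFConfig | None = None
) -> list[ImportanceEntry]:
    """Drop-column importance: for each variable, refit without it (same
    seed) and score the OOB windowed-AUC degradation. Ranked descending,
    ties broken alphabetically."""
    config = config or RSFConfig()
    if len(config.features) < 2:
        raise ValueError("importance requires at least two features")
    full = fit_rsf(cohort, config)
    auc_full = windowed_auc(full)
    if auc_full is None:
        raise ValueError("baseline AUC undefined; cannot score importance")
    scores = {}
    for v in config.features:
        sub_cfg = replace(config, features=tuple(f for f in config.features if f != v))
        auc_v = windowed_auc(fit_rsf(cohort, sub_cfg))
        scores[v] = auc_full - (auc_v if auc_v is not None else 0.5)
    order = sorted(scores, key=lambda v: (-scores[v], v))
    return [ImportanceEntry(v, scores[v], r + 1) for r, v in enumerate(order)]


def permutation_importance(
    forest: RandomSurvivalForest, seed: int = 0
) -> list[ImportanceEntry]:
    """Comparison mode: OOB-AUC degradation when one feature column is
    permuted (no refits)."""
    rng = np.random.default_rng(seed)
    base = windowed_auc(forest)
    if base is None:
        raise ValueError("baseline AUC undefined")
    keep = forest.covered
    scores = {}
    for j, v in enumerate(forest.config.features):
        Xp = forest.X_train.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        n = Xp.shape[0]
        total, count = np.zeros(n), np.zeros(n)
        buf, rows = np.empty(n), np.arange(n)
        for tree, oob in zip(forest.trees, forest.oob_masks):
            _route(tree, Xp, rows, buf)
            total[oob] += buf[oob]
            count[oob] += 1
        with np.errstate(invalid="ignore"):
            s = total / count
        s[count == 0] = np.nan
        auc = mann_whitney_auc(s[keep], forest.event[keep])
        scores[v] = base - (auc if auc is not None else 0.5)
    order = sorted(scores, key=lambda v: (-scores[v], v))
    return [ImportanceEntry(v, scores[v], r + 1) for r, v in enumerate(order)]


__all__ = [
    "DEFAULT_FEATURES",
    "ImportanceEntry",
    "RandomSurvivalForest",
    "RSFConfig",
    "drop_variable_importance",
    "fit_rsf",
    "mann_whitney_auc",
    "permutation_importance",
    "predict_risk",
    "windowed_auc",
]
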