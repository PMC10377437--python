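"""Threshold risk landscapes, decision trees and fixed-threshold validation."""

import numpy as np
import pytest

from pvrisk import landscape, synthgen
from pvrisk.cohort import stratum_subset
from pvrisk.landscape import (
    HIGH,
    LOW,
    DecisionTree,
    PValueMatrix,
    ThresholdPair,
    build_decision_tree,
    optimal_thresholds,
    percentile_grid,
    pvalue_matrix,
    validate_fixed_thresholds,
)
from pvrisk.survival import logrank_test, te_window_outcome
from pvrisk.synthgen import GeneratorConfig


class TestPValueMatrix:
    def test_single_cell_reduces_to_one_logrank(self, small_cohort):
        sub = stratum_subset(small_cohort, "without_te_history")
        mat = pvalue_matrix(
            sub, "NEP", "RDW", grids=([70.0], [15.0]), directions=(">=", "<")
        )
        assert mat.p.shape == (1, 1)
        sub2, frame = te_window_outcome(sub)
        x1, x2 = sub2.variable("NEP"), sub2.variable("RDW")
        ok = np.isfinite(x1) & np.isfinite(x2)
        risk = (x1[ok] >= 70.0) & (x2[ok] < 15.0)
        ref = logrank_test(frame["time"].values[ok], frame["event"].values[ok], risk)
        # the scan accumulates in float32; agreement to ~1e-5 relative
        assert mat.p[0, 0] == pytest.approx(ref.p, rel=1e-5)

    def test_undersized_cells_absent(self, small_cohort):
        # a threshold beyond the observed range leaves an empty risk group
        mat = pvalue_matrix(
            small_cohort, "NEP", "RDW", grids=([1e6], [15.0]), directions=(">=", "<")
        )
        assert np.isnan(mat.p).all()

    def test_four_group_mode_matches_k_group_test(self, small_cohort):
        mat = pvalue_matrix(small_cohort, "NEP", "RDW", grids=([70.0], [15.0]), mode="four_group")
        sub, frame = te_window_outcome(small_cohort)
        x1, x2 = sub.variable("NEP"), sub.variable("RDW")
        ok = np.isfinite(x1) & np.isfinite(x2)
        quadrant = 2 * (x1[ok] >= 70.0).astype(int) + (x2[ok] >= 15.0).astype(int)
        ref = logrank_test(frame["time"].values[ok], frame["event"].values[ok], quadrant)
        assert mat.p[0, 0] == pytest.approx(ref.p, rel=1e-9)

    def test_deterministic_for_fixed_cohort(self, small_cohort):
        a = pvalue_matrix(small_cohort, "NEP", "RDW", directions=(">=", "<"))
        b = pvalue_matrix(small_cohort, "NEP", "RDW", directions=(">=", "<"))
        np.testing.assert_array_equal(a.p, b.p)

    def test_null_landscape_minimum_not_bonferroni_significant(self, null_config):
        # with no planted effect the selected minimum should almost never
        # survive a Bonferroni correction over the scanned cells
        hits = 0
        for seed in range(5):
            cohort = synthgen.generate_cohort(null_config(800, seed, baseline_hazard=0.12))
            mat = pvalue_matrix(cohort, "NEP", "RDW", directions=(">=", "<"))
            n_cells = int(np.sum(~np.isnan(mat.p)))
            hits += np.nanmin(mat.p) * n_cells >= 0.05
        assert hits >= 4

    def test_direction_discovery_finds_planted_quadrant(self):
        # with no directions supplied, the worst-KM quadrant per cell should
        # orient toward the planted high-NEP / low-RDW corner
        cohort = synthgen.generate_cohort(GeneratorConfig(n_patients=600, seed=2))
        mat = pvalue_matrix(
            cohort, "NEP", "RDW", grids=([68.0, 72.0], [14.3, 16.0]),
            mode="risk_vs_rest", directions=None, stratum="without_te_history",
        )
        pair = optimal_thresholds(mat)
        assert (pair.direction1, pair.direction2) == (">=", "<")
        assert pair.threshold1 == 72.0 and pair.threshold2 == 14.3

    def test_landscape_sharpens_on_single_median_splits(self):
        # planted-quadrant data: the scanned minimum p is at least as small
        # as either single median-split p
        cohort = synthgen.generate_cohort(GeneratorConfig(n_patients=2000, seed=3))
        sub = stratum_subset(cohort, "without_te_history")
        mat = pvalue_matrix(sub, "NEP", "RDW", directions=(">=", "<"))
        sub2, frame = te_window_outcome(sub)
        t, e = frame["time"].values, frame["event"].values
        for var in ("NEP", "RDW"):
            x = sub2.variable(var)
            ok = np.isfinite(x)
            p_med = logrank_test(t[ok], e[ok], x[ok] >= np.median(x[ok])).p
            assert np.nanmin(mat.p) <= p_med


class TestOptimalThresholds:
    def matrix(self, p, n_risk=None):
        p = np.asarray(p, float)
        return PValueMatrix(
            "A", "B", np.array([1.0, 2.0]), np.array([10.0, 20.0]), p,
            "risk_vs_rest", 1,
            np.ones_like(p, dtype=int) if n_risk is None else np.asarray(n_risk),
            np.full(p.shape, 3, dtype=int), 100,
        )

    def test_unique_minimum(self):
        pair = optimal_thresholds(self.matrix([[0.5, 0.01], [0.2, 0.9]]))
        assert (pair.threshold1, pair.threshold2) == (1.0, 20.0)
        assert pair.p == pytest.approx(0.01)

    def test_tie_broken_by_larger_risk_group(self):
        pair = optimal_thresholds(
            self.matrix([[0.01, 0.5], [0.5, 0.01]], n_risk=[[5, 1], [1, 50]])
        )
        assert (pair.threshold1, pair.threshold2) == (2.0, 20.0)

    def test_tie_then_lower_thresholds(self):
        pair = optimal_thresholds(self.matrix([[0.01, 0.01], [0.01, 0.5]]))
        assert (pair.threshold1, pair.threshold2) == (1.0, 10.0)

    def test_all_absent_errors(self):
        with pytest.raises(ValueError, match="absent"):
            optimal_thresholds(self.matrix([[np.nan, np.nan], [np.nan, np.nan]]))

    def test_directions_recovered_from_quadrant_code(self, small_cohort):
        mat = pvalue_matrix(small_cohort, "NEP", "RDW", grids=([70.0], [15.0]),
                            directions=(">=", "<"))
        pair = optimal_thresholds(mat)
        assert (pair.direction1, pair.direction2) == (">=", "<")


class TestDecisionTree:
    tree = DecisionTree("RDW", 14.3, "<", "NEP", 72.05, ">=")

    def patient(self, **kw):
        from test_cohort import make_patient

        labs = {"RDW": kw.pop("RDW", None), "NEP": kw.pop("NEP", None),
                "LYP": kw.pop("LYP", None)}
        return make_patient(lab_medians=labs, **kw)

    def test_high_risk_when_both_conditions_hold(self):
        assert self.tree.classify(self.patient(RDW=14.0, NEP=75.0)) == HIGH

    def test_boundary_value_fails_strict_less_than(self):
        assert self.tree.classify(self.patient(RDW=14.3, NEP=75.0)) == LOW

    def test_low_lyp_tree(self):
        tree = DecisionTree("RDW", 14.05, "<", "LYP", 19.3, "<")
        assert tree.classify(self.patient(RDW=13.9, LYP=18.0)) == HIGH
        assert tree.classify(self.patient(RDW=13.9, LYP=19.3)) == LOW

    def test_missing_value_defaults_to_low_risk(self):
        assert self.tree.classify(self.patient(RDW=None, NEP=80.0)) == LOW

    def test_pure_function_on_cohort(self, small_cohort):
        a = self.tree.apply(small_cohort)
        b = self.tree.apply(small_cohort)
        assert (a == b).all()

    def test_build_from_threshold_pair(self):
        pair = ThresholdPair("NEP", 72.05, ">=", "RDW", 14.3, "<", 1e-5, 40)
        tree = build_decision_tree(pair)
        assert tree.var1 == "NEP" and tree.direction2 == "<"
        assert "72.05" in tree.rule


class TestValidation:
    tree = DecisionTree("NEP", 72.05, ">=", "RDW", 14.3, "<")

    def test_planted_validation_cohort_separates(self):
        cohort = synthgen.generate_validation_cohort(n_patients=300, seed=0)
        res = validate_fixed_thresholds(self.tree, cohort)
        assert set(res.n_per_leaf) == {HIGH, LOW}
        assert res.logrank.df == 1
        assert HIGH in res.km_curves and LOW in res.km_curves

    def test_all_low_risk_leaf_errors(self):
        cohort = synthgen.generate_validation_cohort(n_patients=150, seed=1)
        impossible = DecisionTree("NEP", 1e6, ">=", "RDW", 14.3, "<")
        with pytest.raises(ValueError, match="empty"):
            validate_fixed_thresholds(impossible, cohort)

    def test_km_curves_are_step_functions(self):
        cohort = synthgen.generate_validation_cohort(n_patients=300, seed=2)
        res = validate_fixed_thresholds(self.tree, cohort)
        for km in res.km_curves.values():
            assert np.all(np.diff(km.survival) <= 1e-12)


def test_percentile_grid_strictly_increasing(small_cohort):
    g = percentile_grid(small_cohort.variable("NEP"))
    assert np.all(np.diff(g) > 0)
    assert g.size <= 37
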