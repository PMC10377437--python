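"""Random survival forest: determinism, calibration, oracles, invariances."""

import numpy as np
import pytest

from pvrisk import forest, synthgen
from pvrisk.cohort import feature_matrix
from pvrisk.forest import RSFConfig, fit_rsf, mann_whitney_auc, windowed_auc
from pvrisk.survival import te_window_outcome
from pvrisk.synthgen import GeneratorConfig, QuadrantEffect


@pytest.fixture(scope="module")
def planted_cohort():
    return synthgen.generate_cohort(GeneratorConfig(n_patients=800, seed=5))


class TestDeterminismAndStructure:
    def test_same_seed_identical_oob_scores(self, planted_cohort):
        cfg = RSFConfig(n_trees=30, seed=11)
        a = fit_rsf(planted_cohort, cfg).oob_risk()
        b = fit_rsf(planted_cohort, cfg).oob_risk()
        np.testing.assert_array_equal(a, b)

    def test_identical_patients_identical_scores(self, planted_cohort):
        f = fit_rsf(planted_cohort, RSFConfig(n_trees=20, seed=1))
        X = f.X_train[:5]
        twice = np.vstack([X, X])
        s = f.predict_risk(twice)
        np.testing.assert_allclose(s[:5], s[5:])

    def test_single_tree_single_split_two_scores(self):
        # one feature, depth 1: the tree partitions patients into exactly
        # two terminal hazard levels
        cfg = GeneratorConfig(
            n_patients=500, seed=3, missing_rate=0.0,
            interactions=(QuadrantEffect("RDW", 14.5, "<", "RDW", 100.0, "<", 1.5),),
            log_hr={"te_history": 0.0, "anticoag": 0.0, "age_per_decade": 0.0},
            baseline_hazard=0.15,
        )
        cohort = synthgen.generate_cohort(cfg)
        f = fit_rsf(cohort, RSFConfig(
            n_trees=1, seed=0, features=("RDW",), mtry=1, max_depth=1,
            bootstrap_fraction=1.0,
        ))
        scores = f.predict_risk(f.X_train)
        assert len(np.unique(scores)) == 2

    def test_unfitted_config_errors(self):
        with pytest.raises(ValueError):
            RSFConfig(n_trees=0)
        with pytest.raises(ValueError):
            RSFConfig(mtry=99)


class TestCalibration:
    def test_pure_noise_auc_near_half(self, null_config):
        # no planted signal: mean OOB windowed AUC over seeds ~ 0.5
        aucs = []
        for seed in range(10):
            cohort = synthgen.generate_cohort(
                null_config(400, seed, baseline_hazard=0.15)
            )
            f = fit_rsf(cohort, RSFConfig(n_trees=50, seed=seed))
            aucs.append(windowed_auc(f))
        assert abs(np.mean(aucs) - 0.5) <= 0.05

    def test_auc_within_tolerance_of_best_single_split(self):
        # one strong planted single-variable effect: the forest's OOB AUC
        # approaches the brute-force best single-split classifier
        cfg = GeneratorConfig(
            n_patients=1000, seed=11, missing_rate=0.0,
            log_hr={"te_history": 0.0, "anticoag": 0.0, "age_per_decade": 0.0},
            interactions=(QuadrantEffect("RDW", 14.5, "<", "RDW", 100.0, "<", 1.5),),
            baseline_hazard=0.12,
        )
        cohort = synthgen.generate_cohort(cfg)
        f = fit_rsf(cohort, RSFConfig(n_trees=150, seed=11, features=("RDW",), mtry=1))
        auc_forest = windowed_auc(f)
        sub, frame = te_window_outcome(cohort)
        keep = frame["covered"].values.astype(bool)
        x = sub.variable("RDW")[keep]
        label = frame["event"].values.astype(bool)[keep]
        best = 0.5
        for c in np.unique(x):
            for sgn in (1.0, -1.0):
                best = max(best, mann_whitney_auc(sgn * (x < c), label))
        assert auc_forest >= best - 0.05

    def test_against_independent_rsf_held_out(self):
        # cross-check against scikit-survival's forest on complete-case
        # data: held-out windowed AUCs agree closely
        from sksurv.ensemble import RandomSurvivalForest as SksurvRSF

        train = synthgen.generate_cohort(GeneratorConfig(n_patients=800, seed=5, missing_rate=0.0))
        test = synthgen.generate_cohort(GeneratorConfig(n_patients=800, seed=105, missing_rate=0.0))
        mine = fit_rsf(train, RSFConfig(n_trees=100, seed=5))
        auc_mine = windowed_auc(mine, test)

        sub_tr, fr_tr = te_window_outcome(train)
        X_tr = feature_matrix(sub_tr, forest.DEFAULT_FEATURES).values
        y_tr = np.array(
            list(zip(fr_tr["event"].values, fr_tr["time"].values)),
            dtype=[("e", bool), ("t", float)],
        )
        sub_te, fr_te = te_window_outcome(test)
        X_te = feature_matrix(sub_te, forest.DEFAULT_FEATURES).values
        sk = SksurvRSF(n_estimators=100, random_state=5, n_jobs=1, max_features="sqrt")
        sk.fit(X_tr, y_tr)
        keep = fr_te["covered"].values.astype(bool)
        auc_sk = mann_whitney_auc(
            sk.predict(X_te)[keep], fr_te["event"].values.astype(bool)[keep]
        )
        assert auc_mine == pytest.approx(auc_sk, abs=0.08)

    def test_full_model_beats_constant_score(self, planted_cohort):
        f = fit_rsf(planted_cohort, RSFConfig(n_trees=60, seed=2))
        auc = windowed_auc(f)
        keep = f.covered
        const = mann_whitney_auc(np.zeros(keep.sum()), f.event[keep])
        assert auc >= const  # constant scores give exactly 0.5


class TestInvariances:
    def test_monotone_feature_transform_preserves_predictions(self):
        cohort = synthgen.generate_cohort(GeneratorConfig(n_patients=500, seed=13))
        cfg = RSFConfig(n_trees=25, seed=13)
        base = fit_rsf(cohort, cfg)
        # log-transform one feature in place: split search depends only on
        # the ordering, so OOB risk ranks are unchanged
        import copy

        transformed = copy.deepcopy(cohort)
        for p in transformed:
            if p.lab_medians.get("WBC") is not None:
                p.lab_medians["WBC"] = float(np.log(p.lab_medians["WBC"]))
        other = fit_rsf(transformed, cfg)
        np.testing.assert_allclose(base.oob_risk(), other.oob_risk())

    def test_risk_increases_into_planted_quadrant(self, planted_cohort):
        # moving patients into the high-risk quadrant (high NEP, low RDW)
        # cannot lower the average predicted risk
        f = fit_rsf(planted_cohort, RSFConfig(n_trees=60, seed=4))
        X = f.X_train.copy()
        names = list(f.config.features)
        i_nep, i_rdw = names.index("NEP"), names.index("RDW")
        rows = np.where(np.isfinite(X[:, i_nep]) & np.isfinite(X[:, i_rdw]))[0][:100]
        before = f.predict_risk(X[rows]).mean()
        X2 = X[rows].copy()
        X2[:, i_nep] = 80.0
        X2[:, i_rdw] = 13.0
        after = f.predict_risk(X2).mean()
        assert after >= before


class TestImportance:
    def test_noise_variables_score_near_zero(self, null_config):
        scores = []
        for seed in range(3):
            cohort = synthgen.generate_cohort(null_config(350, seed, baseline_hazard=0.15))
            imp = forest.drop_variable_importance(
                cohort, RSFConfig(n_trees=40, seed=seed, features=("WBC", "Plt", "HGB", "Hct"))
            )
            scores.extend(e.score for e in imp)
        assert max(abs(s) for s in scores) <= 0.12

    def test_duplicated_variable_shares_credit(self):
        # duplicating a variable under two names shrinks each copy's
        # drop-column score relative to the unduplicated run
        cfg = GeneratorConfig(
            n_patients=800, seed=21, missing_rate=0.0,
            log_hr={"te_history": 0.0, "anticoag": 0.0, "age_per_decade": 0.0},
            interactions=(QuadrantEffect("RDW", 14.5, "<", "RDW", 100.0, "<", 1.2),),
            baseline_hazard=0.12,
        )
        cohort = synthgen.generate_cohort(cfg)
        # duplicate RDW into the (otherwise unused) PLS observation slot
        import copy

        dup = copy.deepcopy(cohort)
        for p in dup:
            p.obs_medians["PLS"] = p.lab_medians["RDW"]
        solo = forest.drop_variable_importance(
            cohort, RSFConfig(n_trees=60, seed=21, features=("RDW", "WBC", "Plt"))
        )
        shared = forest.drop_variable_importance(
            dup, RSFConfig(n_trees=60, seed=21, features=("RDW", "PLS", "WBC", "Plt"))
        )
        score_solo = {e.variable: e.score for e in solo}["RDW"]
        score_dup = {e.variable: e.score for e in shared}["RDW"]
        assert score_dup < score_solo

    def test_ranks_are_permutation_sorted_desc(self, planted_cohort):
        imp = forest.drop_variable_importance(
            planted_cohort, RSFConfig(n_trees=30, seed=2, features=("te_history", "RDW", "WBC"))
        )
        assert [e.rank for e in imp] == [1, 2, 3]
        assert all(a.score >= b.score for a, b in zip(imp, imp[1:]))


def test_mann_whitney_auc_degenerate_cases():
    assert mann_whitney_auc([1, 1, 1, 1], [1, 0, 1, 0]) == pytest.approx(0.5)
    assert mann_whitney_auc([3, 4, 1, 2], [1, 1, 0, 0]) == pytest.approx(1.0)
    assert mann_whitney_auc([1, 2], [1, 1]) is None
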