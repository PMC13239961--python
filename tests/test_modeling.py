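"""Grouped splitting, attribution ranking, selection, model search, statistics."""

import numpy as np
import pandas as pd
import pytest

from rotqa.modeling import (
    CandidateSearchRegressor,
    TwoStageSelector,
    direction_analysis,
    fit_evaluate,
    grouped_split,
    min_max_scale,
    pearson,
    rank_features,
    scenario_compare,
    tree_attributions,
    two_stage_select,
)
from rotqa.types import DegenerateInputError, ValidationError


class TestGroupedSplit:
    def test_sides_disjoint_and_complete(self):
        plans = [f"p{i}" for i in range(12)]
        split = grouped_split(plans, 0.7, seed=3)
        assert not (split.train_plan_ids & split.test_plan_ids)
        assert split.train_plan_ids | split.test_plan_ids == set(plans)

    def test_rounding_rule_10_plans(self):
        split = grouped_split([f"p{i}" for i in range(10)], 0.70, seed=0)
        assert len(split.train_plan_ids) == 7
        assert len(split.test_plan_ids) == 3

    def test_deterministic(self):
        plans = [f"p{i}" for i in range(9)]
        assert grouped_split(plans, seed=5) == grouped_split(plans, seed=5)

    def test_too_few_plans_rejected(self):
        with pytest.raises(ValidationError):
            grouped_split(["only"], 0.7, 0)


class TestMinMaxScale:
    def test_unit_interval(self):
        t = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        scaled, _ = min_max_scale(t)
        assert scaled["a"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_maps_to_zero(self):
        t = pd.DataFrame({"a": [3.0, 3.0, 3.0]})
        scaled, _ = min_max_scale(t)
        assert scaled["a"].tolist() == [0.0, 0.0, 0.0]

    def test_round_trip(self, rng):
        t = pd.DataFrame(rng.random((20, 4)), columns=list("abcd"))
        scaled, scaler = min_max_scale(t)
        back = scaler.inverse_transform(scaled.to_numpy())
        assert np.abs(back - t.to_numpy()).max() < 1e-12

    def test_test_rows_scaled_with_train_ranges(self):
        t = pd.DataFrame({"a": [0.0, 1.0, 2.0, 10.0]})
        fit_on = np.array([True, True, True, False])
        scaled, _ = min_max_scale(t, fit_on=fit_on)
        assert scaled["a"].iloc[3] == pytest.approx(5.0)  # may exceed [0, 1]


class TestRankFeatures:
    def test_planted_signal_ranked_first(self, rng):
        n = 200
        X = pd.DataFrame(rng.random((n, 6)), columns=[f"f{i}" for i in range(6)])
        y = 3.0 * X["f2"] + 0.05 * rng.standard_normal(n)
        hits = 0
        for seed in range(10):
            ranking = rank_features(X, y, seed=seed)
            hits += ranking[0][0] == "f2"
        assert hits >= 9

    def test_attribution_additivity(self, rng):
        import xgboost as xgb

        n = 100
        X = pd.DataFrame(rng.random((n, 4)), columns=list("abcd"))
        y = X["a"] * 2 + X["b"]
        model = xgb.XGBRegressor(n_estimators=50, max_depth=3, n_jobs=1, random_state=0).fit(
            X.to_numpy(), y
        )
        contribs, base = tree_attributions(model, X)
        pred = model.predict(X.to_numpy())
        assert np.abs(contribs.sum(axis=1) + base - pred).max() < 1e-4

    def test_constant_target_rejected(self, rng):
        X = pd.DataFrame(rng.random((30, 3)), columns=list("abc"))
        with pytest.raises(DegenerateInputError):
            rank_features(X, np.ones(30), seed=0)


class TestTwoStageSelect:
    def _tables(self, rng, n=120):
        rad = pd.DataFrame(rng.random((n, 8)), columns=[f"radiomics_r{i}" for i in range(8)])
        dos = pd.DataFrame(rng.random((n, 12)), columns=[f"dosiomics_d{i}" for i in range(12)])
        return rad, dos

    def test_planted_dosiomic_feature_recovered(self, rng):
        hits = 0
        for seed in range(10):
            rad, dos = self._tables(rng)
            y = 2.0 * dos["dosiomics_d5"] + 0.05 * rng.standard_normal(len(dos))
            res = two_stage_select(rad, dos, y, k=5, seed=seed)
            hits += "dosiomics_d5" in res.retained
        assert hits >= 9

    def test_per_group_cap(self, rng):
        rad, dos = self._tables(rng)
        y = rng.random(len(rad))
        res = two_stage_select(rad, dos, y, k=3, seed=0)
        assert len(res.group_retained["radiomics_"]) <= 3
        assert len(res.group_retained["dosiomics_"]) <= 3

    def test_k_zero_degenerates_to_empty_selection(self, rng):
        rad, dos = self._tables(rng, n=40)
        res = two_stage_select(rad, dos, rng.random(40), k=0, seed=0)
        assert res.retained == []

    def test_transformer_interface(self, rng):
        rad, dos = self._tables(rng)
        X = pd.concat([rad, dos], axis=1)
        y = 2.0 * dos["dosiomics_d5"].to_numpy()
        sel = TwoStageSelector(k=4, seed=1).fit(X, y)
        out = sel.transform(X)
        assert list(out.columns) == sel.retained_


def _linear_cohort(rng, n_plans=12, per_plan=8, noise=0.0):
    rows = []
    for p in range(n_plans):
        for _ in range(per_plan):
            x1, x2 = rng.random(2)
            rows.append(
                {"plan_id": f"p{p}", "x1": x1, "x2": x2,
                 "y": 2.0 * x1 - 1.0 * x2 + noise * rng.standard_normal()}
            )
    return pd.DataFrame(rows)


class TestFitEvaluate:
    def test_noise_free_linear_target_recovered(self, rng):
        df = _linear_cohort(rng)
        split = grouped_split(df["plan_id"], 0.7, seed=0)
        rep = fit_evaluate(df[["x1", "x2"]], df["y"], df["plan_id"], split, cv_folds=5, seed=0)
        assert rep.r2 > 1 - 1e-6
        assert rep.mae < 1e-6

    def test_pure_noise_target_has_no_skill(self, rng):
        fails = 0
        for seed in range(5):
            df = _linear_cohort(rng, noise=1.0)
            df["y"] = rng.standard_normal(len(df))
            split = grouped_split(df["plan_id"], 0.7, seed=seed)
            rep = fit_evaluate(df[["x1", "x2"]], df["y"], df["plan_id"], split, cv_folds=5, seed=seed)
            fails += rep.r2 > 0.1
        assert fails <= 1

    def test_rmse_at_least_mae(self, rng):
        df = _linear_cohort(rng, noise=0.3)
        split = grouped_split(df["plan_id"], 0.7, seed=1)
        rep = fit_evaluate(df[["x1", "x2"]], df["y"], df["plan_id"], split, cv_folds=5, seed=1)
        assert rep.rmse >= rep.mae >= 0

    def test_estimator_interface_deterministic(self, rng):
        df = _linear_cohort(rng, noise=0.2)
        X = df[["x1", "x2"]].to_numpy()
        a = CandidateSearchRegressor(cv_folds=4, seed=9).fit(X, df["y"], groups=df["plan_id"])
        b = CandidateSearchRegressor(cv_folds=4, seed=9).fit(X, df["y"], groups=df["plan_id"])
        assert a.best_name_ == b.best_name_
        assert np.array_equal(a.predict(X), b.predict(X))


class TestScenarioCompare:
    def test_rotation_only_uses_three_angles_and_shared_split(self, rng):
        n_plans, per_plan = 10, 6
        rows = []
        for p in range(n_plans):
            plan_eff = rng.random()
            for _ in range(per_plan):
                ang = rng.uniform(1.5, 4.5, size=3)
                rows.append(
                    {
                        "plan_id": f"p{p}",
                        "pitch_deg": ang[0],
                        "roll_deg": ang[1],
                        "yaw_deg": ang[2],
                        "radiomics_a": plan_eff + 0.01 * rng.standard_normal(),
                        "dosiomics_b": rng.random(),
                        "ssim": 1 - 0.02 * ang.sum() - 0.1 * plan_eff,
                    }
                )
        df = pd.DataFrame(rows)
        reports = scenario_compare(df, k=1, cv_folds=4, seed=0)
        assert set(reports) >= {"full", "rotation_only", "features_only"}
        assert reports["rotation_only"].scenario == "rotation_only"
        # deterministic reproduction
        again = scenario_compare(df, k=1, cv_folds=4, seed=0)
        assert again["full"].r2 == reports["full"].r2


class TestPearson:
    def test_perfect_negative_line(self):
        x = np.arange(10.0)
        res = pearson(x, -2 * x + 1)
        assert res.r == pytest.approx(-1.0)
        assert res.p < 1e-12

    def test_formula_oracle(self, rng):
        x = rng.random(50)
        y = rng.random(50)
        res = pearson(x, y)
        direct = ((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std())
        assert res.r == pytest.approx(direct, abs=1e-12)

    def test_independent_samples_near_zero(self, rng):
        big = 0
        for _ in range(20):
            r = pearson(rng.standard_normal(1000), rng.standard_normal(1000)).r
            big += abs(r) >= 0.1
        assert big <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson(np.ones(5), np.arange(5.0))


class TestDirectionAnalysis:
    def _table(self, rng):
        rows = []
        for lab, axis in (("UP", "pitch_deg"), ("RO", "roll_deg"), ("CW", "yaw_deg")):
            for a in (1.5, 2.25, 3.0, 3.75, 4.5):
                for p in range(4):
                    rows.append(
                        {
                            "plan_id": f"p{p}",
                            "direction_label": lab,
                            "n_directions": 1,
                            "angle_total_deg": a,
                            "ssim": 1 - 0.03 * a + 0.002 * rng.standard_normal(),
                            "gamma_rd_2%/2mm": 100 - a,
                        }
                    )
        for p in range(6):
            rows.append(
                {
                    "plan_id": f"m{p}",
                    "direction_label": "UP+RO",
                    "n_directions": 2,
                    "angle_total_deg": 6.0 + p,
                    "ssim": 0.9 - 0.01 * p,
                    "gamma_rd_2%/2mm": 96.0,
                }
            )
        return pd.DataFrame(rows)

    def test_one_row_per_group_and_metric(self, rng):
        out = direction_analysis(self._table(rng))
        # UP/RO/CW/multi on angle + multi on direction count
        assert set(out["group"]) == {"UP", "RO", "CW", "multi", "multi_ndir"}
        assert set(out["metric"]) == {"ssim", "gamma_rd_2%/2mm"}

    def test_negative_ssim_angle_correlation_detected(self, rng):
        out = direction_analysis(self._table(rng))
        row = out[(out.group == "UP") & (out.metric == "ssim")].iloc[0]
        assert row.r < -0.9 and row.p < 1e-3

    def test_pass_proportion_all_passing(self, rng):
        out = direction_analysis(self._table(rng))
        multi = out[(out.group == "multi") & (out.metric == "ssim")].iloc[0]
        assert multi.pass_proportion == 100.0

    def test_small_groups_skipped(self):
        t = pd.DataFrame(
            {
                "plan_id": ["a", "b"],
                "direction_label": ["UP", "UP"],
                "n_directions": [1, 1],
                "angle_total_deg": [1.5, 3.0],
                "ssim": [0.99, 0.95],
            }
        )
        out = direction_analysis(t, pass_col=None)
        assert out.empty
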