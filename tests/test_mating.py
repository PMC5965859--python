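"""Censoring rules, plasticity, contingency tests and line-level regressions."""

import numpy as np
import pandas as pd
import pytest

from coldsong import mating, synthetic
from coldsong.cold_tolerance import DataError
from conftest import make_obs


class TestCensoring:
    def test_non_courting_male_gets_screen_length_latency(self):
        obs = make_obs([{"courted": False, "latency_s": 0.0, "mated": False}])
        out = mating.apply_latency_censoring(obs)
        assert out.loc[0, "latency_s"] == 14_400.0

    def test_courting_latency_unchanged(self):
        obs = make_obs([{"latency_s": 300.0}])
        out = mating.apply_latency_censoring(obs)
        assert out.loc[0, "latency_s"] == 300.0

    def test_unmated_excluded_from_duration_table(self):
        obs = make_obs([{"mated": False, "duration_s": 50.0},
                        {"mated": True, "duration_s": 60.0}])
        dur = mating.duration_table(obs)
        assert list(dur["duration_s"]) == [60.0]

    def test_idempotent(self, courtship_table):
        once = mating.apply_latency_censoring(courtship_table)
        twice = mating.apply_latency_censoring(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_latency_beyond_screen_rejected(self):
        obs = make_obs([{"latency_s": 20_000.0}])
        with pytest.raises(DataError):
            mating.apply_latency_censoring(obs)


class TestPlasticity:
    def _obs(self, control_durs, acclim_durs):
        rows = [{"male_trt": "control", "duration_s": d} for d in control_durs]
        rows += [{"male_trt": "acclimated", "duration_s": d} for d in acclim_durs]
        return make_obs(rows)

    def test_sign_convention(self):
        res = mating.behavioral_plasticity(self._obs([100.0], [150.0]), "L1")
        assert res.plasticity == pytest.approx(-50.0)

    def test_equal_means_give_zero(self):
        res = mating.behavioral_plasticity(self._obs([120.0, 80.0],
                                                     [110.0, 90.0]), "L1")
        assert res.plasticity == pytest.approx(0.0)

    def test_sign_flips_under_arm_swap(self):
        obs = self._obs([100.0, 140.0], [200.0, 260.0])
        swapped = obs.copy()
        swapped["male_trt"] = swapped["male_trt"].map(
            {"control": "acclimated", "acclimated": "control"})
        a = mating.behavioral_plasticity(obs, "L1")
        b = mating.behavioral_plasticity(swapped, "L1")
        assert a.plasticity == pytest.approx(-b.plasticity)

    def test_acclimated_female_pairs_excluded(self):
        obs = self._obs([100.0], [150.0])
        extra = make_obs([{"male_trt": "acclimated",
                           "female_trt": "acclimated", "duration_s": 9000.0}])
        res = mating.behavioral_plasticity(pd.concat([obs, extra]), "L1")
        assert res.acclimated_mean_duration == pytest.approx(150.0)

    def test_empty_arm_flagged_missing_not_zero(self):
        obs = make_obs([{"male_trt": "control", "duration_s": 100.0}])
        res = mating.behavioral_plasticity(obs, "L1")
        assert res.missing
        assert np.isnan(res.plasticity)

    def test_recovers_simulated_multiplicative_effect(self):
        params = synthetic.CourtshipSimParams(
            lines=("A",), n_reps_per_cell=4000, courtship_prob=1.0,
            mating_prob_control=1.0, mating_prob_acclimated_male=1.0,
            duration_scale=0.3, male_acclimation_duration_effect=1.5, seed=7)
        obs = synthetic.gen_courtship_table(params)
        res = mating.behavioral_plasticity(obs, "A")
        assert res.plasticity == pytest.approx(
            -0.5 * res.control_mean_duration, rel=0.05)


class TestContingency:
    def test_counts_layout(self):
        obs = make_obs([
            {"male_trt": "acclimated", "mated": True},
            {"male_trt": "acclimated", "mated": False, "duration_s": np.nan},
            {"male_trt": "control", "mated": True},
            {"male_trt": "control", "mated": False, "duration_s": np.nan}])
        table = mating.mating_contingency(obs)
        assert table.values.tolist() == [[1, 1], [1, 1]]

    def test_all_mated_gives_degenerate_column(self):
        obs = make_obs([{"male_trt": "control"}, {"male_trt": "acclimated"}])
        table = mating.mating_contingency(obs)
        assert table["unmated"].sum() == 0
        with pytest.raises(DataError):
            mating.chi_square_test(table)

    def test_proportions_recover_simulated_rates(self):
        params = synthetic.CourtshipSimParams(
            lines=("A",), n_reps_per_cell=40, courtship_prob=1.0,
            mating_prob_control=0.7, mating_prob_acclimated_male=0.5, seed=3)
        obs = synthetic.gen_courtship_table(params)
        table = mating.mating_contingency(obs)
        props = table["mated"] / table.sum(axis=1)
        assert props["control"] == pytest.approx(0.7, abs=0.1)
        assert props["acclimated"] == pytest.approx(0.5, abs=0.1)


def pearson_2x2(a, b, c, d):
    """Closed-form Pearson statistic n(ad - bc)^2 / (row and column margins)."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return n * (a * d - b * c) ** 2 / denom


class TestChiSquare:
    def test_balanced_table_is_null(self):
        stat, df, p = mating.chi_square_test([[10, 10], [10, 10]],
                                             continuity=False)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        stat, df, p = mating.chi_square_test([[20, 10], [10, 20]],
                                             continuity=False)
        assert stat == pytest.approx(60 * (400 - 100) ** 2 / 810_000, abs=1e-9)
        assert df == 1

    def test_yates_correction_shrinks_statistic(self):
        uncorr, _, _ = mating.chi_square_test([[20, 10], [10, 20]],
                                              continuity=False)
        corr, _, _ = mating.chi_square_test([[20, 10], [10, 20]],
                                            continuity=True)
        assert corr < uncorr

    def test_matches_closed_form_on_random_tables(self, rng):
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 60, size=4)
            stat, _, _ = mating.chi_square_test([[a, b], [c, d]],
                                                continuity=False)
            assert stat == pytest.approx(pearson_2x2(a, b, c, d), abs=1e-9)


class TestModelsAndRegressions:
    def test_duration_model_flags_male_treatment_only(self):
        params = synthetic.CourtshipSimParams(
            n_reps_per_cell=12, courtship_prob=1.0,
            male_acclimation_duration_effect=2.0, duration_scale=0.3, seed=5)
        obs = synthetic.gen_courtship_table(params)
        report = mating.behavior_model_summary(obs, response="duration")
        fixed = report["fixed_effects"].set_index("term")
        male = [t for t in fixed.index if "male_trt" in t and ":" not in t][0]
        female = [t for t in fixed.index if "female_trt" in t and ":" not in t][0]
        assert fixed.loc[male, "p"] < 0.01
        assert fixed.loc[female, "p"] > 0.05

    def test_latency_model_includes_censored_rows(self):
        params = synthetic.CourtshipSimParams(courtship_prob=0.7, seed=6)
        obs = synthetic.gen_courtship_table(params)
        report = mating.behavior_model_summary(obs, response="latency")
        assert report["n_obs"] == len(obs)

    def test_exact_linear_relation(self):
        df = pd.DataFrame({"capacity": np.arange(10.0),
                           "basal_mean": np.arange(10.0) * 0.05 + 0.2,
                           "plasticity": 2.0 * np.arange(10.0)})
        reg = mating.plasticity_regressions(df, predictors=("capacity",),
                                            behaviors=("plasticity",))
        row = reg.iloc[0]
        assert row["slope"] == pytest.approx(2.0)
        assert row["r2"] == pytest.approx(1.0)

    def test_independent_predictor_gives_small_r2(self, rng):
        df = pd.DataFrame({"capacity": rng.normal(size=100),
                           "plasticity": rng.normal(size=100)})
        reg = mating.plasticity_regressions(df, predictors=("capacity",),
                                            behaviors=("plasticity",))
        assert reg.iloc[0]["r2"] < 0.1

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"capacity": np.ones(5),
                           "plasticity": np.arange(5.0)})
        with pytest.raises(DataError):
            mating.plasticity_regressions(df, predictors=("capacity",),
                                          behaviors=("plasticity",))

    def test_line_summaries_columns(self, courtship_table):
        summ = mating.line_behavior_summaries(courtship_table)
        assert set(summ.columns) >= {"line", "latency_control",
                                     "duration_control", "plasticity"}
        assert len(summ) == 19
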