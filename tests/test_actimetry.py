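import numpy as np
import pandas as pd
import pytest

from scmlab.actimetry import (
    PhaseConfig,
    adjust_fdr_by,
    code_sleep,
    fit_phase_effect,
    hourly_wheel_profile,
    select_last_days,
    split_phases,
    waking_probability,
)
from scmlab.io_formats import ActivityTable, FormatError
from scmlab.synthetic import default_actimetry_spec, gen_open_field, gen_wheel
from tests.conftest import make_activity_table


def uniform_table(value=1.0, n_days=5, bin_width_min=15, n_animals=1):
    bins_per_day = 24 * 60 // bin_width_min
    times = pd.Timestamp("2023-01-01 00:00") + pd.to_timedelta(
        np.arange(n_days * bins_per_day) * bin_width_min, unit="m"
    )
    rows = [
        pd.DataFrame(
            {
                "animal_id": f"m{a}",
                "genotype": "control",
                "bin_start": times,
                "bin_width_min": bin_width_min,
                "value": value,
            }
        )
        for a in range(n_animals)
    ]
    return ActivityTable(pd.concat(rows, ignore_index=True))


class TestSplitPhases:
    def test_uniform_activity_totals(self):
        # 1 cm per 15-min bin: 48 light bins and 48 dark bins per period
        summary = split_phases(uniform_table(1.0), PhaseConfig(), last_n_days=4)
        assert set(summary["phase"]) == {"light", "dark"}
        assert set(summary["period_index"]) == {1, 2, 3, 4}
        assert (summary["total"] == 48.0).all()

    def test_dark_only_activity(self):
        table = uniform_table(2.0)
        df = table.frame
        hours = df["bin_start"].dt.hour
        df.loc[(hours >= 6) & (hours < 18), "value"] = 0.0
        table = ActivityTable(df)
        summary = split_phases(table, PhaseConfig(), last_n_days=4)
        assert (summary.loc[summary["phase"] == "light", "total"] == 0).all()
        assert (summary.loc[summary["phase"] == "dark", "total"] == 96.0).all()

    def test_totals_conserved(self, rng):
        table = make_activity_table(rng, n_animals=3, n_days=5)
        summary = split_phases(table, PhaseConfig(), last_n_days=4)
        window = select_last_days(table, PhaseConfig(), 4)
        assert summary["total"].sum() == pytest.approx(window["value"].sum())

    def test_matches_groupby_oracle(self, rng):
        table = make_activity_table(rng, n_animals=2, n_days=5)
        cfg = PhaseConfig()
        summary = split_phases(table, cfg, last_n_days=4)
        window = select_last_days(table, cfg, 4)
        window["phase"] = np.where(
            (window["hour_of_day"] >= 6) & (window["hour_of_day"] < 18), "light", "dark"
        )
        oracle = (
            window.groupby(["animal_id", "phase", "period_index"])["value"].sum().to_dict()
        )
        for _, r in summary.iterrows():
            assert r["total"] == pytest.approx(
                oracle[(r["animal_id"], r["phase"], r["period_index"])]
            )

    def test_short_table_rejected(self):
        with pytest.raises(ValueError, match="spans less"):
            split_phases(uniform_table(n_days=2), PhaseConfig(), last_n_days=4)


class TestCodeSleep:
    def test_rule_forced_coding(self):
        table = uniform_table(0.0, n_days=1)
        df = table.frame
        df.loc[:3, "value"] = [0.0, 12.3, 0.0, 0.01]
        series = code_sleep(ActivityTable(df))
        assert list(series["awake"][:4]) == [0, 1, 0, 1]

    def test_all_zero_day(self):
        series = code_sleep(uniform_table(0.0, n_days=1))
        assert len(series) == 96
        assert (series["awake"] == 0).all()

    def test_hourly_bins_rejected(self):
        with pytest.raises(FormatError, match="15-min"):
            code_sleep(uniform_table(1.0, bin_width_min=60))

    def test_recoding_is_idempotent(self, rng):
        table = make_activity_table(rng, n_days=2)
        series = code_sleep(table)
        recoded_input = table.frame.copy()
        recoded_input["value"] = series["awake"].astype(float)
        series2 = code_sleep(ActivityTable(recoded_input))
        pd.testing.assert_series_equal(series["awake"], series2["awake"])

    def test_sample_index_within_hour(self, rng):
        series = code_sleep(make_activity_table(rng, n_days=1))
        assert set(series["sample_index"]) == {1, 2, 3, 4}
        one_hour = series[(series["animal_id"] == series["animal_id"].iloc[0])
                          & (series["hour_of_day"] == 3)
                          & (series["period_index"] == 1)]
        assert list(one_hour["sample_index"]) == [1, 2, 3, 4]


class TestHourlyWheel:
    def test_constant_rate_sums(self):
        spec = default_actimetry_spec(
            wheel_dark=10.0, wheel_light={"control": 10.0, "mutant": 10.0},
            n_animals={"control": 2, "mutant": 2}, seed=0,
        )
        table = gen_wheel(spec)
        df = table.frame
        df["value"] = 10.0
        profile = hourly_wheel_profile(ActivityTable(df), last_n_hours=96)
        assert (profile.profile["mean"] == 120.0).all()

    def test_identical_genotypes_give_p_one(self):
        spec = default_actimetry_spec(n_animals={"control": 2, "mutant": 2}, seed=0)
        table = gen_wheel(spec)
        df = table.frame
        df["value"] = 7.0
        profile = hourly_wheel_profile(ActivityTable(df), last_n_hours=96)
        assert (profile.hourly_tests["p_value"] == 1.0).all()

    def test_five_min_bins_required(self):
        with pytest.raises(FormatError, match="5-min"):
            hourly_wheel_profile(uniform_table(1.0), last_n_hours=96)

    def test_dark_phase_difference_detected(self):
        spec = default_actimetry_spec(
            wheel_dark=100.0, seed=42,
            n_animals={"control": 6, "mutant": 6},
        )
        # mutant runs 50% more in the dark only
        wheel = {}
        for (g, h), r in spec.wheel_rate_by_hour.items():
            wheel[(g, h)] = r * 1.5 if (g == "mutant" and not 6 <= h < 18) else r
        spec = default_actimetry_spec(seed=42, n_animals={"control": 6, "mutant": 6})
        object.__setattr__(spec, "wheel_rate_by_hour", wheel)
        profile = hourly_wheel_profile(gen_wheel(spec), last_n_hours=96)
        tests = profile.hourly_tests.set_index("hour_of_day")["p_value"]
        dark_hours = [h for h in range(24) if not 6 <= h < 18]
        light_hours = [h for h in range(24) if 6 <= h < 18]
        assert (tests.loc[dark_hours] < 0.05).mean() >= 0.75
        assert (tests.loc[light_hours] < 0.05).mean() <= 0.25


class TestWakingProbability:
    def test_all_awake(self):
        series = code_sleep(uniform_table(5.0, n_animals=4), last_n_days=4)
        res = waking_probability(series, "control", 18)
        assert (res.table["p_wake"] == 1.0).all()
        assert (res.table["relative_p_wake"] == 1.0).all()

    def test_ratio_forced_relative(self):
        series = code_sleep(uniform_table(5.0, n_animals=1), last_n_days=4)
        # control awake at reference, half-awake at hour 9
        series.loc[series["hour_of_day"] == 9, "awake"] = [0, 1] * 8
        res = waking_probability(series, "control", 18)
        tab = res.table.set_index("hour_of_day")
        assert tab.loc[9, "relative_p_wake"] == pytest.approx(0.5)
        assert tab.loc[18, "relative_p_wake"] == 1.0

    def test_degenerate_reference_rejected(self):
        series = code_sleep(uniform_table(5.0, n_animals=2), last_n_days=4)
        series.loc[series["hour_of_day"] == 18, "awake"] = 0
        with pytest.raises(ValueError, match="degenerate reference"):
            waking_probability(series, "control", 18)

    def test_invariant_to_animal_relabeling(self, rng):
        spec = default_actimetry_spec(n_animals={"control": 3, "mutant": 3}, seed=9)
        series = code_sleep(gen_open_field(spec), last_n_days=4)
        res1 = waking_probability(series, "control", 18)
        relabeled = series.copy()
        mapping = {a: f"x{i}" for i, a in enumerate(sorted(series["animal_id"].unique()))}
        relabeled["animal_id"] = relabeled["animal_id"].map(mapping)
        shuffled = relabeled.sample(frac=1.0, random_state=0)
        res2 = waking_probability(shuffled, "control", 18)
        pd.testing.assert_frame_equal(
            res1.table.drop(columns=[]), res2.table, check_exact=False, rtol=1e-12
        )


class TestPhaseEffect:
    def _summary(self, a_vals, b_vals):
        rows = []
        for g, vals in (("control", a_vals), ("mutant", b_vals)):
            for i, animal_vals in enumerate(vals):
                for p, v in enumerate(animal_vals, start=1):
                    rows.append(
                        {
                            "animal_id": f"{g}{i}",
                            "genotype": g,
                            "phase": "light",
                            "period_index": p,
                            "total": float(v),
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_groups_zero_effect(self):
        vals = [[10, 12, 11, 13], [11, 12, 10, 12], [12, 11, 13, 10]]
        res = fit_phase_effect(self._summary(vals, vals), "gamma")
        assert res.effect == pytest.approx(0.0, abs=1e-8)
        assert res.p_value > 0.9

    def test_gamma_requires_positive(self):
        bad = self._summary([[0, 1, 2, 3]] * 2, [[1, 2, 3, 4]] * 2)
        with pytest.raises(ValueError, match="positive"):
            fit_phase_effect(bad, "gamma")

    def test_binomial_requires_binary(self):
        bad = self._summary([[1, 2, 3, 4]] * 2, [[1, 2, 3, 4]] * 2)
        with pytest.raises(ValueError, match="0/1"):
            fit_phase_effect(bad, "binomial")

    def test_rate_ratio_direction(self):
        rng = np.random.default_rng(4)
        ctrl = rng.poisson(100, (6, 4))
        mut = rng.poisson(200, (6, 4))
        res = fit_phase_effect(
            self._summary(ctrl.tolist(), mut.tolist()), "negative_binomial",
            reference_genotype="control",
        )
        assert res.effect == pytest.approx(np.log(2.0), abs=0.15)
        assert res.p_value < 0.01


class TestFdrBy:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_fdr_by([0.03]), [0.03])

    def test_hand_computed_step_up(self):
        # m=4, c(4)=25/12: every adjusted value is 0.01*4*(25/12)/1 = 1/12
        out = adjust_fdr_by([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [1 / 12] * 4, atol=1e-12)

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_fdr_by([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_monotone_and_dominates_input(self, rng):
        p = rng.uniform(size=25)
        adj = adjust_fdr_by(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            adjust_fdr_by([])
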