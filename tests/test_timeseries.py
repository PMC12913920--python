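import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microgrid.timeseries import (
    Level,
    QCConfig,
    SensorCalibration,
    SummaryConfig,
    TemperatureSeries,
    annual_mean,
    apply_calibration,
    compute_offsets,
    daily_aggregate,
    gdd5,
    percentile_extreme,
    qc_screen,
    summarize_site,
)


def make_series(values, site="S1", sensor="X1", level=Level.air_200cm,
                start="2019-10-12"):
    ts = pd.date_range(start, periods=len(values), freq="15min")
    return TemperatureSeries(site, sensor, level, ts, np.asarray(values, dtype=float))


def year_series(values=None, fill=7.0, **kw):
    n = 365 * 96
    if values is None:
        values = np.full(n, fill)
    return make_series(values, **kw)


class TestOffsets:
    def test_constant_bias_recovered(self):
        # sensors at true+0.2, true-0.1, true-0.1 -> offsets +0.30, -0.15, -0.15
        n = 97  # just over 24 h
        true = np.zeros(n)
        group = [
            make_series(true + 0.2, sensor="A"),
            make_series(true - 0.1, sensor="B"),
            make_series(true - 0.1, sensor="C"),
        ]
        cals = compute_offsets(group)
        np.testing.assert_allclose([c.offset for c in cals], [0.30, -0.15, -0.15],
                                   atol=1e-12)

    def test_identical_sensors_zero_offsets(self):
        vals = np.sin(np.linspace(0, 10, 97))
        group = [make_series(vals, sensor=s) for s in "ABC"]
        assert all(abs(c.offset) < 1e-12 for c in compute_offsets(group))

    def test_offsets_sum_to_zero(self):
        rng = np.random.default_rng(0)
        group = [make_series(rng.normal(10, 1, 200) + b, sensor=s)
                 for s, b in zip("ABCD", [0.3, -0.1, 0.0, 0.2])]
        cals = compute_offsets(group)
        assert abs(sum(c.offset for c in cals)) < 1e-9

    def test_two_sensors_refused(self):
        group = [make_series(np.zeros(97), sensor=s) for s in "AB"]
        with pytest.raises(ValueError, match="3"):
            compute_offsets(group)

    def test_short_overlap_refused(self):
        group = [make_series(np.zeros(50), sensor=s) for s in "ABC"]
        with pytest.raises(ValueError, match="24"):
            compute_offsets(group)


class TestCalibration:
    def test_shift_and_identity(self):
        s = make_series(np.full(100, 10.0), sensor="A")
        out = apply_calibration(s, SensorCalibration("A", 0.3))
        np.testing.assert_allclose(out.values, 9.7)
        same = apply_calibration(s, SensorCalibration("A", 0.0))
        np.testing.assert_array_equal(same.values, s.values)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        s = make_series(rng.normal(8, 5, 300), sensor="A")
        cal = SensorCalibration("A", 0.237)
        back = apply_calibration(apply_calibration(s, cal),
                                 SensorCalibration("A", -0.237))
        np.testing.assert_allclose(back.values, s.values, rtol=0, atol=1e-12)

    def test_mismatched_sensor_refused(self):
        s = make_series(np.zeros(10), sensor="A")
        with pytest.raises(ValueError):
            apply_calibration(s, SensorCalibration("B", 0.1))

    def test_removed_readings_not_shifted(self):
        s = make_series(np.full(10, 10.0), sensor="A")
        s.qc_ok[3] = False
        out = apply_calibration(s, SensorCalibration("A", 1.0))
        assert out.values[3] == 10.0 and out.values[4] == 9.0


class TestQC:
    def test_spike_flagged(self):
        v = np.full(200, 12.0)
        v[50] = 85.0
        out = qc_screen(make_series(v))
        assert not out.qc_ok[50]
        assert out.qc_ok.sum() == 199

    def test_flatline_flagged(self):
        # 8 days constant embedded in varying data
        v = np.concatenate([np.sin(np.arange(100.0)), np.full(8 * 96, 3.0),
                            np.sin(np.arange(100.0))])
        out = qc_screen(make_series(v))
        assert not out.qc_ok[100 : 100 + 8 * 96].any()
        assert out.qc_ok[:100].all() and out.qc_ok[-100:].all()

    def test_clean_series_untouched(self):
        v = 10 + np.sin(np.arange(500) / 7.0)
        assert qc_screen(make_series(v)).qc_ok.all()

    def test_seven_day_flatline_kept(self):
        v = np.concatenate([np.sin(np.arange(10.0)), np.full(672, 3.0),
                            np.sin(np.arange(10.0))])
        assert qc_screen(make_series(v)).qc_ok.all()


class TestDailyAggregate:
    def test_constant_full_day(self):
        # start at 23:00 UTC = local midnight UTC+1
        s = make_series(np.full(96, 12.0), start="2019-10-11 23:00")
        out = daily_aggregate(s)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.daily_min, row.daily_max, row.daily_mean, row.n_readings) == \
            (12.0, 12.0, 12.0, 96)

    def test_sinusoid_extremes(self):
        t = np.arange(96) / 96.0
        v = 10 + 5 * np.sin(2 * np.pi * t)
        s = make_series(v, start="2019-10-11 23:00")
        out = daily_aggregate(s)
        assert out.iloc[0].daily_min == pytest.approx(v.min())
        assert out.iloc[0].daily_max == pytest.approx(v.max())

    def test_incomplete_day_dropped(self):
        s = make_series(np.full(50, 5.0), start="2019-10-11 23:00")
        assert len(daily_aggregate(s)) == 0

    def test_empty_series(self):
        s = make_series(np.zeros(1))
        s.qc_ok[:] = False
        assert len(daily_aggregate(s)) == 0


class TestAnnualStats:
    def test_constant_mean(self):
        assert annual_mean(year_series(fill=7.0)) == pytest.approx(7.0)

    def test_two_halves(self):
        v = np.concatenate([np.zeros(182 * 96 + 48), np.full(182 * 96 + 48, 10.0)])
        assert annual_mean(make_series(v)) == pytest.approx(5.0)

    def test_gaps_mean_of_remaining(self):
        v = np.full(365 * 96, 4.0)
        s = year_series(v)
        s.qc_ok[1000:3000] = False
        s.values[1000:3000] = 99.0  # ignored
        assert annual_mean(s) == pytest.approx(4.0)

    def test_low_coverage_refused(self):
        s = year_series(fill=3.0)
        s.qc_ok[: 60 * 96] = False
        with pytest.raises(ValueError, match="coverage"):
            annual_mean(s)


class TestPercentileExtreme:
    @staticmethod
    def sort_oracle(arr, p):
        """Linear-interpolation quantile by explicit rank arithmetic."""
        x = np.sort(np.asarray(arr, dtype=float))
        h = (len(x) - 1) * p / 100.0
        lo = int(np.floor(h))
        hi = min(lo + 1, len(x) - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    def daily_table(self, maxima=None, minima=None):
        n = len(maxima if maxima is not None else minima)
        return pd.DataFrame({
            "day": pd.date_range("2020-01-01", periods=n),
            "daily_max": maxima if maxima is not None else np.zeros(n),
            "daily_min": minima if minima is not None else np.zeros(n),
        })

    def test_all_equal(self):
        t = self.daily_table(maxima=np.full(365, 20.0))
        assert percentile_extreme(t, "max95p") == 20.0

    def test_ramp_values(self):
        t = self.daily_table(maxima=np.arange(1.0, 366.0))
        assert percentile_extreme(t, "max95p") == pytest.approx(346.8)
        t = self.daily_table(minima=np.arange(1.0, 366.0))
        assert percentile_extreme(t, "min5p") == pytest.approx(19.2)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-40, 50, allow_nan=False), min_size=30, max_size=400),
           st.sampled_from(["max95p", "min5p"]))
    def test_matches_sort_oracle(self, vals, which):
        arr = np.asarray(vals)
        t = self.daily_table(maxima=arr, minima=arr)
        p = 95 if which == "max95p" else 5
        assert percentile_extreme(t, which) == pytest.approx(
            self.sort_oracle(arr, p), abs=1e-9)

    def test_too_few_days_refused(self):
        t = self.daily_table(maxima=np.arange(10.0))
        with pytest.raises(ValueError):
            percentile_extreme(t, "max95p")


class TestGDD5:
    def test_constant_above_threshold(self):
        v = np.full(365 * 96, 5.0)
        v[:96] = 15.0
        # one day at 15 degC contributes (15-5)*96/96 = 10; rest at 5 contribute 0
        assert gdd5(make_series(v)) == pytest.approx(10.0)

    def test_at_threshold_is_zero(self):
        assert gdd5(year_series(fill=5.0)) == 0.0

    def test_mixed_day(self):
        v = np.full(365 * 96, 5.0)
        v[:48] = 25.0
        v[48:96] = -5.0
        assert gdd5(make_series(v)) == pytest.approx(48 * 20 / 96)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_under_warming(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(5, 8, 365 * 96)
        bump = rng.uniform(0, 2, 365 * 96)
        assert gdd5(make_series(base + bump)) >= gdd5(make_series(base))


class TestSummarizeSite:
    def three_levels(self):
        rng = np.random.default_rng(3)
        t = np.arange(365 * 96)
        base = 8 + 9 * np.sin(2 * np.pi * t / (365 * 96)) + \
            4 * np.sin(2 * np.pi * t / 96)
        return [
            make_series(base * 0.3 + rng.normal(0, .1, len(t)), sensor="a",
                        level=Level.soil_8cm),
            make_series(base + rng.normal(0, .1, len(t)), sensor="b",
                        level=Level.air_15cm),
            make_series(base * 0.9 + rng.normal(0, .1, len(t)), sensor="c",
                        level=Level.air_200cm),
        ]

    def test_nine_variables_all_levels(self):
        out = summarize_site(self.three_levels())
        assert len(out) == 9
        assert {s.variable for s in out} == {
            "T.soil_8_cm.mean", "T.air_15_cm.mean", "T.air_15_cm.max.95p",
            "T.air_15_cm.min.5p", "T.air_15_cm.GDD5", "T.air_200_cm.mean",
            "T.air_200_cm.max.95p", "T.air_200_cm.min.5p", "T.air_200_cm.GDD5",
        }

    def test_air_only_four(self):
        out = summarize_site([self.three_levels()[2]])
        assert len(out) == 4

    def test_soil_only_one(self):
        out = summarize_site([self.three_levels()[0]])
        assert len(out) == 1
        assert out[0].variable == "T.soil_8_cm.mean"

    def test_extremes_bracket_mean(self):
        out = {s.variable: s.value for s in summarize_site(self.three_levels())}
        for lvl in ("15", "200"):
            assert (out[f"T.air_{lvl}_cm.min.5p"] <= out[f"T.air_{lvl}_cm.mean"]
                    <= out[f"T.air_{lvl}_cm.max.95p"])
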