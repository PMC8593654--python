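"""Composite-sampling emulation, underestimation factors and exceedance
counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from streampulse.data_model import CompoundMeta, ConcentrationMatrix
from streampulse.exposure import (
    SamplingScheme,
    composite_average,
    exceedance_assessment,
    peak_vs_composite_assessment,
    start_offset_sweep,
    underestimation_factor,
    window_factors,
)


def _series(values, start="2019-06-01", freq="20min"):
    idx = pd.date_range(start, periods=len(values), freq=freq)
    return pd.Series(np.asarray(values, dtype=float), index=idx)


DAY_SCHEME = SamplingScheme(window=pd.Timedelta("1D"), below_loq_rule="set_to_loq")


class TestCompositeAverage:
    def test_constant_series_every_composite_equal(self):
        s = _series(np.full(72 * 4, 37.0))
        comp = composite_average(s, loq=1.0, scheme=DAY_SCHEME)
        assert (comp["composite"] == 37.0).all()
        assert comp["valid"].all()

    def test_six_sample_window_mean(self):
        s = _series([10, 10, 10, 10, 10, 70])
        scheme = SamplingScheme(window=pd.Timedelta("2h"), below_loq_rule="set_to_loq")
        comp = composite_average(s, loq=1.0, scheme=scheme)
        assert len(comp) == 1
        assert comp.iloc[0]["composite"] == 20.0

    def test_below_loq_rule_applied(self):
        s = _series([2.0, 2.0, 20.0, 20.0, 20.0, 20.0])
        scheme = SamplingScheme(window=pd.Timedelta("2h"), below_loq_rule="set_to_loq")
        comp = composite_average(s, loq=10.0, scheme=scheme)
        assert comp.iloc[0]["composite"] == (10 + 10 + 20 * 4) / 6

    def test_gap_fraction_invalidates_window(self):
        vals = np.full(72, 10.0)
        vals[:10] = np.nan  # ~14% gaps > 10%
        s = _series(vals)
        comp = composite_average(s, loq=1.0, scheme=DAY_SCHEME)
        assert not comp.iloc[0]["valid"]
        assert comp.iloc[0]["gap_fraction"] == pytest.approx(10 / 72)
        # mean still computed over the non-gap samples
        assert comp.iloc[0]["composite"] == 10.0

    def test_window_shorter_than_step_rejected(self):
        s = _series(np.full(10, 1.0))
        with pytest.raises(ValueError, match="window"):
            composite_average(
                s, 1.0, SamplingScheme(window=pd.Timedelta("10min"))
            )

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_window_means(self, seed):
        rng = np.random.default_rng(seed)
        n = 300
        vals = rng.uniform(0, 100, n)
        s = _series(vals)
        scheme = SamplingScheme(
            window=pd.Timedelta("7h"), below_loq_rule="zero", max_gap_fraction=0.0
        )
        comp = composite_average(s, loq=0.0, scheme=scheme)
        step_per_win = 21  # 7 h of 20-min steps
        for k, row in comp.iterrows():
            chunk = vals[k * step_per_win : (k + 1) * step_per_win]
            assert abs(row["composite"] - chunk.mean()) < 1e-12

    def test_mass_consistency_when_windows_tile(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(5, 50, 72 * 4)  # 4 exact day windows, no censoring
        s = _series(vals)
        comp = composite_average(s, loq=1.0, scheme=DAY_SCHEME)
        assert np.isclose(comp["composite"].mean(), vals.mean())


class TestUnderestimationFactor:
    def test_constant_series_factor_one(self):
        s = _series(np.full(72, 12.0))
        comp = composite_average(s, 1.0, DAY_SCHEME)
        f, bound = underestimation_factor(s, comp, 0)
        assert f == 1.0 and not bound

    def test_peak_over_mean(self):
        vals = np.full(72, 10.0)
        vals[30] = 730.0
        s = _series(vals)
        comp = composite_average(s, 1.0, DAY_SCHEME)
        f, bound = underestimation_factor(s, comp, 0)
        expected = 730.0 / ((71 * 10 + 730) / 72)
        assert f == pytest.approx(expected)

    def test_censored_composite_gives_lower_bound(self):
        vals = np.full(72, 1.0)
        vals[10] = 490.0
        s = _series(vals)
        scheme = SamplingScheme(window=pd.Timedelta("1D"), below_loq_rule="zero")
        comp = composite_average(s, 15.0, scheme)
        assert comp.iloc[0]["composite"] < 15.0
        f, bound = underestimation_factor(s, comp, 0, loq=15.0)
        assert bound
        assert f == pytest.approx(490.0 / 15.0)

    def test_zero_composite_undefined(self):
        s = _series(np.zeros(72))
        scheme = SamplingScheme(window=pd.Timedelta("1D"), below_loq_rule="zero")
        comp = composite_average(s, 1.0, scheme)
        f, flagged = underestimation_factor(s, comp, 0)
        assert np.isnan(f) and flagged

    @given(st.floats(0.1, 1000.0))
    def test_scale_invariance_without_substitution(self, c):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 100, 144)
        scheme = SamplingScheme(window=pd.Timedelta("1D"), below_loq_rule="zero")
        f1 = window_factors(_series(vals), composite_average(_series(vals), 0.0, scheme))
        f2 = window_factors(
            _series(vals * c), composite_average(_series(vals * c), 0.0, scheme)
        )
        np.testing.assert_allclose(f1["factor"], f2["factor"], rtol=1e-9)


class TestStartOffsetSweep:
    def test_constant_series_factor_one_everywhere(self):
        s = _series(np.full(72 * 3, 9.0))
        sweep = start_offset_sweep(
            s, DAY_SCHEME, [pd.Timedelta(minutes=20 * k) for k in range(12)], loq=1.0
        )
        np.testing.assert_allclose(sweep["max_factor"], 1.0)

    def test_single_spike_worst_case_matches_closed_form(self):
        """A lone spike of height h on baseline b: the worst offset places
        the spike in a window of W samples otherwise at baseline, giving
        h / ((h + (W-1) b) / W)."""
        W = 72
        h, b = 500.0, 2.0
        vals = np.full(72 * 3, b)
        vals[100] = h
        s = _series(vals)
        offsets = [pd.Timedelta(minutes=20 * k) for k in range(72)]
        sweep = start_offset_sweep(s, DAY_SCHEME, offsets, loq=0.5)
        closed_form = h / ((h + (W - 1) * b) / W)
        assert sweep["max_factor"].max() == pytest.approx(closed_form)

    def test_sweep_equals_brute_force_per_offset(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 50, 72 * 2)
        s = _series(vals)
        offsets = [pd.Timedelta(0), pd.Timedelta("100min"), pd.Timedelta("7h")]
        sweep = start_offset_sweep(s, DAY_SCHEME, offsets, loq=1.0)
        for off, expected in zip(offsets, sweep["max_factor"]):
            scheme = SamplingScheme(
                window=DAY_SCHEME.window, start_offset=off, below_loq_rule="set_to_loq"
            )
            comp = composite_average(s, 1.0, scheme)
            wf = window_factors(s, comp, 1.0)
            ok = wf[wf["valid"] & wf["factor"].notna()]
            assert expected == pytest.approx(ok["factor"].max())

    def test_longer_window_never_decreases_worst_case_for_single_spike(self):
        vals = np.full(72 * 8, 3.0)
        vals[200] = 300.0
        s = _series(vals)
        worst = []
        for days in (1, 2, 4):
            scheme = SamplingScheme(
                window=pd.Timedelta(days=days), below_loq_rule="set_to_loq"
            )
            offsets = [pd.Timedelta(minutes=20 * k) for k in range(0, 72 * days, 3)]
            sweep = start_offset_sweep(s, scheme, offsets, loq=1.0)
            worst.append(sweep["max_factor"].max())
        assert worst[0] <= worst[1] <= worst[2]


def _exceedance_matrix():
    idx = pd.date_range("2019-06-01", periods=144, freq="20min")
    meta = [
        CompoundMeta("hot", "insecticide", False, 2.0, 0.05, aqs=100.0, rac=400.0),
        CompoundMeta("cold", "herbicide", False, 2.0, 0.05, aqs=1e6, rac=1e6),
        CompoundMeta("nostd", "fungicide", False, 2.0, 0.05),
    ]
    hot = np.full(144, 10.0)
    hot[10:13] = 500.0  # episode 1 (also > rac)
    hot[40] = 150.0  # episode 2
    hot[90:92] = 120.0  # episode 3
    values = pd.DataFrame(
        {"hot": hot, "cold": np.full(144, 5.0), "nostd": np.full(144, 50.0)},
        index=idx,
    )
    return ConcentrationMatrix(values=values, compounds=meta)


class TestExceedanceAssessment:
    def test_three_pulses_three_episodes_one_ppp(self):
        m = _exceedance_matrix()
        comp = {
            c.compound_id: composite_average(m.values[c.compound_id], c.loq, DAY_SCHEME)
            for c in m.compounds
        }
        report = exceedance_assessment(m, comp)
        row = report.per_compound.set_index("compound_id").loc["hot"]
        assert row["n_aqs_episodes"] == 3
        assert row["n_aqs_samples"] == 6
        assert report.counts["ppp_aqs_highfreq"] == 1
        assert report.counts["ppp_rac_highfreq"] == 1
        assert report.unassessed == ["nostd"]

    def test_all_below_standards_zero_counts(self):
        m = _exceedance_matrix()
        sub = m.select(["cold"])
        comp = {"cold": composite_average(sub.values["cold"], 2.0, DAY_SCHEME)}
        report = exceedance_assessment(sub, comp)
        assert report.counts["ppp_aqs_highfreq"] == 0
        assert report.counts["episodes_aqs_highfreq"] == 0

    def test_composite_exceedance_detected(self):
        idx = pd.date_range("2019-06-01", periods=72, freq="20min")
        meta = [CompoundMeta("x", "fungicide", False, 2.0, 0.05, aqs=50.0)]
        values = pd.DataFrame({"x": np.full(72, 80.0)}, index=idx)
        m = ConcentrationMatrix(values=values, compounds=meta)
        comp = {"x": composite_average(m.values["x"], 2.0, DAY_SCHEME)}
        report = exceedance_assessment(m, comp)
        assert report.per_compound.iloc[0]["aqs_composite"]


class TestPeakVsCompositeTable:
    def test_factors_and_flags_from_reference_rows(self):
        table = pd.DataFrame(
            {
                "compound": ["a", "b"],
                "max_20min": [6300.0, 490.0],
                "composite": [490.0, np.nan],
                "composite_below_loq": [False, True],
                "loq": [np.nan, 15.0],
                "aqs": [550.0, 250.0],
                "rac": [3300.0, 1830.0],
            }
        )
        out = peak_vs_composite_assessment(table)
        assert out["underestimation"].iloc[0] == pytest.approx(6300 / 490)
        assert not out["is_bound"].iloc[0]
        assert out["underestimation"].iloc[1] == pytest.approx(490 / 15)
        assert out["is_bound"].iloc[1]
        assert out["aqs_highfreq"].all()
        assert list(out["rac_highfreq"]) == [True, False]
        assert not out["aqs_composite"].iloc[1]  # censored composite
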