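"""Energy-budget extraction from gas-exchange traces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dystroflux.calorimetry import (
    GasExchangeTrace,
    TraceValidationError,
    resting_ee,
    summarize_activity,
    summarize_trace,
    weir_ee,
)
from dystroflux.synthetic import TraceSpec, simulate_clams_trace

from conftest import trace_from_ee


class TestWeir:
    @pytest.mark.parametrize(
        "vo2, vco2, expected",
        [
            (0.0, 0.0, 0.0),
            (1.0, 1.0, 5.047),       # sum of the two Weir coefficients
            (1.0, 0.7, 4.7152),      # 3.941 + 0.7 × 1.106
        ],
    )
    def test_known_values(self, vo2, vco2, expected):
        assert weir_ee(vo2, vco2) == pytest.approx(expected, abs=1e-12)

    def test_rejects_negative_gas(self):
        with pytest.raises(ValueError):
            weir_ee(-0.1, 1.0)

    @given(
        a=st.tuples(st.floats(0, 10), st.floats(0, 10)),
        b=st.tuples(st.floats(0, 10), st.floats(0, 10)),
    )
    def test_linearity(self, a, b):
        """EE of summed gas volumes equals the sum of EEs."""
        joint = weir_ee(a[0] + b[0], a[1] + b[1])
        assert joint == pytest.approx(weir_ee(*a) + weir_ee(*b), rel=1e-12)


class TestSummarize:
    def test_flat_trace_totals_and_phases(self, flat_day_trace):
        """Constant EE: total is the daily sum, phases split evenly."""
        b = summarize_trace(flat_day_trace)
        assert b.ee_24h == pytest.approx(9.6, rel=1e-12)
        assert b.ee_dark == pytest.approx(4.8, rel=1e-12)
        assert b.ee_light == pytest.approx(4.8, rel=1e-12)
        assert b.rq_24h == pytest.approx(1.0, rel=1e-12)
        assert b.ee_resting == pytest.approx(9.6, rel=1e-12)

    def test_unit_rq_everywhere(self, flat_day_trace):
        b = summarize_trace(flat_day_trace)
        assert b.rq_dark == pytest.approx(1.0) and b.rq_light == pytest.approx(1.0)

    def test_balance_is_intake_minus_ee(self):
        """Energy conservation holds exactly, including spillage correction."""
        n = 960
        feeder = np.linspace(50.0, 46.0, n)        # 4 g removed
        spill = np.linspace(0.0, 0.5, n)           # 0.5 g spilled
        tr = trace_from_ee(np.full(n, 0.01), feeder=feeder, spill=spill)
        b = summarize_trace(tr, diet_energy_density=3.64)
        assert b.intake_kcal_d == pytest.approx(3.5 * 3.64, rel=1e-9)
        assert b.balance_kcal_d == pytest.approx(b.intake_kcal_d - b.ee_24h, abs=1e-12)

    def test_phase_additivity_on_simulated_trace(self):
        spec = TraceSpec(noise_cv=0.05, seed=7)
        b = summarize_trace(simulate_clams_trace(spec, 10.5))
        assert b.ee_dark + b.ee_light == pytest.approx(b.ee_24h, rel=1e-12)

    def test_simulated_round_trip_noiseless(self):
        """Noiseless generated trace returns the true EE to <0.1%."""
        spec = TraceSpec(noise_cv=0.0, circadian_amplitude=0.2, seed=1)
        b = summarize_trace(simulate_clams_trace(spec, 10.5))
        assert b.ee_24h == pytest.approx(10.5, rel=1e-3)
        assert b.intake_kcal_d == pytest.approx(spec.intake_kcal_d, rel=1e-9)

    def test_dark_phase_exceeds_light_with_circadian_drive(self):
        spec = TraceSpec(noise_cv=0.0, circadian_amplitude=0.3, seed=2)
        b = summarize_trace(simulate_clams_trace(spec, 11.0))
        assert b.ee_dark > b.ee_light

    def test_rejects_short_window(self, flat_day_trace):
        with pytest.raises(TraceValidationError):
            summarize_trace(flat_day_trace, days=2)


class TestRestingEE:
    def test_constant_trace_resting_equals_total(self, flat_day_trace):
        assert resting_ee(flat_day_trace) == pytest.approx(
            summarize_trace(flat_day_trace).ee_24h
        )

    def test_two_artificial_minima(self):
        """Two lowest 90-s readings of 0.008 and 0.010 → 0.009 × 960."""
        ee = np.full(960, 0.012)
        ee[100], ee[700] = 0.008, 0.010
        assert resting_ee(trace_from_ee(ee)) == pytest.approx(8.64, rel=1e-12)

    def test_resting_below_total_on_structured_trace(self):
        spec = TraceSpec(noise_cv=0.05, circadian_amplitude=0.2, seed=3)
        tr = simulate_clams_trace(spec, 11.0)
        assert resting_ee(tr) < summarize_trace(tr).ee_24h

    def test_monotone_under_positive_increment(self, rng):
        """Raising any epoch's EE never lowers resting EE."""
        ee = rng.uniform(0.008, 0.014, 960)
        base = resting_ee(trace_from_ee(ee))
        idx = rng.integers(0, 960, size=5)
        for i in idx:
            bumped = ee.copy()
            bumped[i] += 0.002
            assert resting_ee(trace_from_ee(bumped)) >= base - 1e-12

    def test_new_global_minimum_never_raises_resting(self, rng):
        ee = rng.uniform(0.008, 0.014, 960)
        base = resting_ee(trace_from_ee(ee))
        lowered = ee.copy()
        lowered[500] = 0.001
        assert resting_ee(trace_from_ee(lowered)) <= base + 1e-12

    def test_rejects_single_reading_window(self):
        df_ee = np.array([0.01, 0.01])
        tr = trace_from_ee(df_ee)
        with pytest.raises(TraceValidationError):
            resting_ee(tr)  # no full day available


class TestActivity:
    def test_all_zero_counts(self, flat_day_trace):
        act = summarize_activity(flat_day_trace)
        assert all(v == 0 for v in act.values())

    def test_dark_share_matches_injection(self):
        """Counts placed only in the dark phase land in the dark totals."""
        n = 960
        tr0 = trace_from_ee(np.full(n, 0.01))
        dark = ~tr0.is_light()
        x = np.where(dark, 5, 0)
        tr = trace_from_ee(np.full(n, 0.01), x_counts=x)
        act = summarize_activity(tr)
        assert act["activity_dark_x"] == 5 * dark.sum()
        assert act["activity_light_x"] == 0

    def test_mdx_pattern_reduced_nocturnal_rearing(self):
        """Lower burst rates (the mdx pattern) reduce dark-phase Z counts."""
        quiet = TraceSpec(burst_rate_dark=2.0, seed=5)
        active = TraceSpec(burst_rate_dark=8.0, seed=5)
        a_quiet = summarize_activity(simulate_clams_trace(quiet, 11.0))
        a_active = summarize_activity(simulate_clams_trace(active, 10.5))
        assert a_quiet["activity_dark_z"] < a_active["activity_dark_z"]


class TestTraceValidation:
    def test_negative_vo2_rejected(self, flat_day_trace):
        df = flat_day_trace.data.copy()
        df.loc[7, "vo2_ml_h"] = -1.0
        with pytest.raises(TraceValidationError, match="row 7"):
            GasExchangeTrace("bad", df, 90)

    def test_unflagged_feeder_rise_rejected(self, flat_day_trace):
        df = flat_day_trace.data.copy()
        df.loc[df.index[10:], "feeder_g"] = 55.0
        with pytest.raises(TraceValidationError, match="refill"):
            GasExchangeTrace("bad", df, 90)

    def test_flagged_refill_accepted(self, flat_day_trace):
        df = flat_day_trace.data.copy()
        df.loc[df.index[10:], "feeder_g"] = 55.0
        df["refill"] = False
        df.loc[10, "refill"] = True
        GasExchangeTrace("ok", df, 90)

    def test_nonuniform_timestamps_rejected(self, flat_day_trace):
        df = flat_day_trace.data.copy()
        df.loc[5, "timestamp"] = df.loc[5, "timestamp"] + pd.Timedelta(seconds=5)
        with pytest.raises(TraceValidationError):
            GasExchangeTrace("bad", df, 90)
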