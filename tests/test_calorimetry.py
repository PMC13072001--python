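"""Gas integration, the Brouwer equation, RQ and fasting heat production."""

import warnings
from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sowcal.calorimetry import (
    InsufficientDataError,
    brouwer_thp,
    fasting_heat_production,
    integrate_gas_day,
    respiratory_quotient,
)
from sowcal.constants import DEFAULT_CONSTANTS
from sowcal.datamodel import DataQualityWarning, GasExchangeRecord, State

T0 = datetime(2024, 1, 1, 8, 0)


def trace(concs, flows, minutes, state=State.FED, sow="S1"):
    return [
        GasExchangeRecord(sow, T0 + timedelta(minutes=float(m)), o2, o2 * 0.9, 0.0,
                          f, state)
        for m, o2, f in zip(minutes, concs, flows)
    ]


class TestIntegration:
    def test_constant_uptake_fraction_gives_exact_volume(self):
        # 0.005 differential fraction at 500 L/min over a full day
        minutes = np.arange(0, 1441, 10)
        recs = trace([0.005] * len(minutes), [500.0] * len(minutes), minutes)
        # half-open window: end just past the closing sample keeps it inside
        vol = integrate_gas_day(recs, (T0, T0 + timedelta(minutes=1441)))
        assert vol.vo2_l == pytest.approx(0.005 * 500 * 1440, rel=1e-12)

    def test_zero_flow_gives_zero_volumes(self):
        minutes = np.arange(0, 1441, 60)
        recs = trace([0.005] * len(minutes), [0.0] * len(minutes), minutes)
        vol = integrate_gas_day(recs, (T0, T0 + timedelta(minutes=1440)))
        assert (vol.vo2_l, vol.vco2_l, vol.vch4_l) == (0.0, 0.0, 0.0)

    def test_piecewise_linear_trace_matches_analytic_integral(self):
        # conc(t) = a + b t over [0, 240] min at constant flow F:
        # integral = F (a T + b T^2 / 2)
        a, b, F, T = 0.004, 1e-6, 400.0, 240
        minutes = np.arange(0, T + 1, 2)
        recs = trace(a + b * minutes, [F] * len(minutes), minutes)
        vol = integrate_gas_day(recs, (T0, T0 + timedelta(minutes=T + 1)))
        assert vol.vo2_l == pytest.approx(F * (a * T + b * T**2 / 2), rel=1e-9)

    def test_sampling_gap_and_short_span_are_warned(self):
        minutes = [0, 5, 300, 305]
        recs = trace([0.005] * 4, [500.0] * 4, minutes)
        with pytest.warns(DataQualityWarning):
            integrate_gas_day(recs, (T0, T0 + timedelta(minutes=1440)))

    def test_negative_volume_flagged_but_returned(self):
        minutes = [0, 10, 20]
        recs = trace([-0.001] * 3, [500.0] * 3, minutes)
        with pytest.warns(DataQualityWarning, match="calibration"):
            vol = integrate_gas_day(recs, (T0, T0 + timedelta(minutes=20)))
        assert vol.vo2_l < 0

    def test_empty_window_raises(self):
        recs = trace([0.005] * 3, [500.0] * 3, [0, 10, 20])
        with pytest.raises(InsufficientDataError):
            integrate_gas_day(recs, (T0, T0))
        with pytest.raises(InsufficientDataError):
            integrate_gas_day(recs, (T0 + timedelta(days=2), T0 + timedelta(days=3)))


class TestBrouwer:
    def test_zero_exchange_zero_heat(self):
        assert brouwer_thp(0, 0, 0, 0) == 0.0

    def test_printed_coefficient_evaluation(self):
        # 16.18*100 + 5.02*90 - 2.17*1 - 5.99*5
        assert brouwer_thp(100, 90, 1, 5) == pytest.approx(2037.68, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        vo2=st.floats(0, 5000), vco2=st.floats(0, 5000),
        vch4=st.floats(0, 50), un=st.floats(0, 30),
        scale=st.floats(0.1, 10),
    )
    def test_exact_linearity_and_superposition(self, vo2, vco2, vch4, un, scale):
        lhs = brouwer_thp(scale * vo2, scale * vco2, scale * vch4, scale * un)
        assert lhs == pytest.approx(scale * brouwer_thp(vo2, vco2, vch4, un), rel=1e-12, abs=1e-9)
        split = brouwer_thp(vo2, 0, 0, 0) + brouwer_thp(0, vco2, 0, 0) + \
            brouwer_thp(0, 0, vch4, 0) + brouwer_thp(0, 0, 0, un)
        assert split == pytest.approx(brouwer_thp(vo2, vco2, vch4, un), rel=1e-12, abs=1e-9)


class TestRQ:
    def test_equal_volumes_give_unity(self):
        assert respiratory_quotient(1234.5, 1234.5) == 1.0

    def test_zero_oxygen_rejected(self):
        with pytest.raises(ValueError):
            respiratory_quotient(0.0, 100.0)

    def test_published_fed_state_range_brackets_simulated_diets(self, noiseless_trial, noiseless_results):
        # study fed-state RQ spans 0.93-1.00 across diets
        from sowcal.calorimetry import integrate_gas_day, respiratory_quotient
        from sowcal.pipeline import _fed_windows

        for sp in noiseless_trial.sow_periods:
            recs = [g for g in noiseless_trial.gas if g.sow_id == sp.sow_id]
            window = _fed_windows(recs)[0]
            vol = integrate_gas_day(recs, window)
            rq = respiratory_quotient(vol.vo2_l, vol.vco2_l)
            assert 0.93 - 1e-9 <= rq <= 1.00 + 1e-9
            truth = noiseless_trial.truth.sows[sp.sow_id]
            assert rq == pytest.approx(truth.fed_rq, rel=1e-9)


class TestFHP:
    @staticmethod
    def fasting_records(fhp, bw, rq, un, start, vch4=1.0):
        mbw = bw**0.75
        b = DEFAULT_CONSTANTS.brouwer
        thp_window = fhp * mbw / 3.0
        un_window = un * 8.0 / 24.0
        vo2 = (thp_window + b.un * un_window + b.ch4 * vch4) / (b.o2 + b.co2 * rq)
        minutes = np.arange(0, 480, 1)
        span = float(minutes[-1])
        flow = 500.0
        return [
            GasExchangeRecord(
                "S1", start + timedelta(minutes=float(m)),
                vo2 / (flow * span), rq * vo2 / (flow * span),
                vch4 / (flow * span), flow, State.FASTED,
            )
            for m in minutes
        ]

    def test_generated_fhp_is_recovered_exactly(self):
        start = datetime(2024, 1, 4, 22, 0)
        recs = self.fasting_records(fhp=360.0, bw=213.0, rq=0.80, un=2.8, start=start)
        got = fasting_heat_production(
            recs, (start, start + timedelta(hours=8)), urinary_n_g=2.8, bw_kg=213.0
        )
        assert got == pytest.approx(360.0, rel=1e-9)

    def test_doubling_gas_volumes_doubles_fhp_at_zero_n(self):
        start = datetime(2024, 1, 4, 22, 0)
        one = self.fasting_records(fhp=300.0, bw=200.0, rq=0.80, un=0.0, start=start,
                                   vch4=0.0)
        double = [
            GasExchangeRecord(r.sow_id, r.timestamp, 2 * r.o2_conc, 2 * r.co2_conc,
                              2 * r.ch4_conc, r.flow_l_min, r.state)
            for r in one
        ]
        window = (start, start + timedelta(hours=8))
        f1 = fasting_heat_production(one, window, 0.0, 200.0)
        f2 = fasting_heat_production(double, window, 0.0, 200.0)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_insufficient_window_coverage_is_a_quality_error(self):
        start = datetime(2024, 1, 4, 22, 0)
        recs = self.fasting_records(360.0, 213.0, 0.80, 2.8, start)[:120]  # 2 h only
        with pytest.raises(InsufficientDataError, match="coverage"), warnings.catch_warnings():
            warnings.simplefilter("ignore", DataQualityWarning)
            fasting_heat_production(
                recs, (start, start + timedelta(hours=8)), 2.8, 213.0
            )

    def test_study_fhp_range_brackets_generator_default(self, diet_energy):
        lo, hi = diet_energy["fhp"].min(), diet_energy["fhp"].max()
        assert lo <= 360.0 <= hi  # generator centres FHP inside the study range
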