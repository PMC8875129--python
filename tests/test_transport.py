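"""Unit and property tests for the core permeability math."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cacoflux import (
    ACTIVE,
    AP_TO_BL,
    BL_TO_AP,
    PASSIVE,
    UNDETERMINED,
    WellTimeSeries,
    analyze_well,
    classify_mechanism,
    cumulative_amounts,
    efflux_ratio,
    papp,
    summarize_group,
    teer,
    teer_record,
    transport_rate,
)


def make_series(concs, times=None, vr=1.5, vs=0.2, c0=100.0, area=1.12,
                direction=AP_TO_BL, well_id="w1", **kw):
    concs = np.asarray(concs, dtype=float)
    if times is None:
        times = 30.0 * np.arange(1, concs.size + 1)
    return WellTimeSeries(well_id=well_id, compound="drug", direction=direction,
                          c0=c0, vr=vr, vs=vs, area=area, times=times,
                          concs=concs, **kw)


class TestTeer:
    @pytest.mark.parametrize("r1,r0,area,expected", [
        (500.0, 120.0, 1.12, 425.6),
        (300.0, 300.0, 1.12, 0.0),
        (300.0, 100.0, 1.12, 224.0),
    ])
    def test_arithmetic(self, r1, r0, area, expected):
        assert teer(r1, r0, area) == pytest.approx(expected)

    def test_below_integrity_threshold_is_flagged_not_rejected(self):
        rec = teer_record("w1", 300.0, 100.0, 1.12)
        assert rec.teer == pytest.approx(224.0)
        assert rec.flagged  # default advisory threshold 300 ohm*cm^2
        ok = teer_record("w2", 500.0, 120.0, 1.12)
        assert not ok.flagged

    def test_negative_teer_allowed_but_flagged(self):
        rec = teer_record("w1", 100.0, 300.0, 1.12)
        assert rec.teer < 0 and rec.flagged

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            teer(float("nan"), 0.0, 1.12)
        with pytest.raises(ValueError):
            teer(100.0, 0.0, -1.0)


class TestCumulativeAmounts:
    def test_single_point_reduces_to_receiver_content(self):
        s = make_series([2.0], vr=1.5, vs=0.2)
        assert cumulative_amounts(s) == pytest.approx([3.0])

    def test_two_point_hand_mass_balance(self):
        # dQ2 = C2*VR + VS*(C0 + C1) = 2*1.5 + 0.2*(0 + 1) = 3.2
        s = make_series([1.0, 2.0], vr=1.5, vs=0.2)
        assert cumulative_amounts(s) == pytest.approx([1.5, 3.2])

    def test_missing_concentration_poisons_the_tail(self):
        s = make_series([1.0, np.nan, 2.0])
        dq = cumulative_amounts(s)
        assert not np.isnan(dq[0])
        assert np.isnan(dq[1]) and np.isnan(dq[2])

    @given(st.lists(st.floats(min_value=0.0, max_value=500.0), min_size=1, max_size=12),
           st.floats(min_value=0.3, max_value=3.0),
           st.floats(min_value=0.01, max_value=0.29))
    def test_equals_event_by_event_bookkeeping(self, concs, vr, vs):
        """Eq.-4 correction == explicit withdraw-then-dilute ledger."""
        s = make_series(concs, vr=vr, vs=vs)
        dq = cumulative_amounts(s)
        removed = 0.0
        for n, c in enumerate(concs):
            expected = c * vr + removed   # receiver content + all prior samples
            assert dq[n] == pytest.approx(expected, rel=1e-12, abs=1e-15)
            removed += c * vs
    def test_no_withdrawal_limit(self):
        """As vs -> 0 the correction vanishes: dQ_n -> C_n * VR."""
        concs = [1.0, 2.0, 3.0]
        s = make_series(concs, vr=1.5, vs=1e-12)
        assert cumulative_amounts(s) == pytest.approx(np.array(concs) * 1.5, rel=1e-9)


class TestRateAndPapp:
    def test_exact_line(self):
        # 1 ug per 60 min = 1/3600 ug/s once time is converted to seconds
        rate, r2 = transport_rate(np.array([1.0, 2.0, 3.0]),
                                  np.array([60.0, 120.0, 180.0]))
        assert rate == pytest.approx(1.0 / 3600.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_dq_gives_zero_rate(self):
        rate, r2 = transport_rate(np.array([2.0, 2.0, 2.0]),
                                  np.array([30.0, 60.0, 90.0]))
        assert rate == 0.0
        assert r2 == pytest.approx(1.0)

    def test_window_restricts_points(self):
        dq = np.array([1.0, 2.0, 3.0, 10.0])
        t = np.array([30.0, 60.0, 90.0, 120.0])
        rate_all, _ = transport_rate(dq, t)
        rate_win, r2 = transport_rate(dq, t, window=(30.0, 90.0))
        assert rate_win == pytest.approx(1.0 / 30.0 / 60.0)
        assert r2 == pytest.approx(1.0)
        assert rate_all > rate_win

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            transport_rate(np.array([1.0]), np.array([30.0]))
        with pytest.raises(ValueError):
            transport_rate(np.array([1.0, 2.0]), np.array([30.0, 60.0]),
                           window=(100.0, 200.0))

    def test_papp_arithmetic(self):
        assert papp(0.001, 1.12, 100.0) == pytest.approx(8.929e-6, rel=1e-3)
        assert papp(0.0, 1.12, 100.0) == 0.0
        # homogeneity: doubling c0 at fixed rate halves papp
        assert papp(0.001, 1.12, 200.0) == pytest.approx(papp(0.001, 1.12, 100.0) / 2)
        with pytest.raises(ValueError):
            papp(0.001, 1.12, 0.0)


class TestEffluxRatioAndClassification:
    @pytest.mark.parametrize("ba,ab,expected", [
        (1.766, 1.225, 1.442),   # passive-range bidirectional condition
        (2.866, 2.407, 1.191),   # passive hydrophilic compound
        (3.0, 3.0, 1.0),
    ])
    def test_ratio_of_means(self, ba, ab, expected):
        assert efflux_ratio(ba, ab) == pytest.approx(expected, abs=5e-4)

    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, a, b, k):
        assert efflux_ratio(k * a, k * b) == pytest.approx(efflux_ratio(a, b), rel=1e-9)

    def test_missing_secretory_arm_gives_nan(self):
        assert math.isnan(efflux_ratio(float("nan"), 2.0))

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            efflux_ratio(2.0, 0.0)

    @pytest.mark.parametrize("er,label", [
        (1.442, PASSIVE),
        (3.531, ACTIVE),
        (1.5, PASSIVE),          # strictly greater-than rule at the boundary
        (float("nan"), UNDETERMINED),
        (None, UNDETERMINED),
    ])
    def test_classification(self, er, label):
        assert classify_mechanism(er) == label


class TestSummarizeGroup:
    def _results(self, papps_ab, papps_ba, c0=100.0):
        out = []
        for i, p in enumerate(papps_ab):
            # one concentration point per minute gives rate = p*A*c0 exactly
            rate = p * 1.12 * c0
            s = make_series([rate * 60.0 / 1.5, 2 * rate * 60.0 / 1.5],
                            times=np.array([1.0, 2.0]), vr=1.5, vs=1e-9,
                            c0=c0, well_id=f"ab{i}")
            out.append(analyze_well(s))
        for i, p in enumerate(papps_ba):
            rate = p * 1.12 * c0
            s = make_series([rate * 60.0 / 1.5, 2 * rate * 60.0 / 1.5],
                            times=np.array([1.0, 2.0]), vr=1.5, vs=1e-9,
                            c0=c0, direction=BL_TO_AP, well_id=f"ba{i}")
            out.append(analyze_well(s))
        return out

    def test_single_well_per_direction(self):
        res = self._results([2.0e-6], [3.0e-6])
        g = summarize_group(res, condition="x")
        assert g.papp_ab_mean == pytest.approx(2.0e-6, rel=1e-6)
        assert g.papp_ba_mean == pytest.approx(3.0e-6, rel=1e-6)
        assert g.er == pytest.approx(1.5, rel=1e-6)
        assert g.classification == PASSIVE   # strict > 1.5 rule

    def test_identical_wells_have_zero_sd(self):
        res = self._results([2e-6, 2e-6, 2e-6], [2e-6, 2e-6, 2e-6])
        g = summarize_group(res, condition="x")
        assert g.papp_ab_sd == pytest.approx(0.0, abs=1e-18)
        assert g.er_well_sd == pytest.approx(0.0, abs=1e-12)

    def test_missing_bl_ap_arm_reports_undetermined(self):
        res = self._results([2e-6, 2.5e-6], [])
        g = summarize_group(res, condition="x")
        assert math.isnan(g.er)
        assert g.classification == UNDETERMINED

    def test_no_absorptive_arm_is_invalid(self):
        res = self._results([], [2e-6])
        with pytest.raises(ValueError):
            summarize_group(res, condition="x")

    def test_er_is_exactly_ratio_of_means(self):
        res = self._results([1e-6, 3e-6], [2e-6, 6e-6])
        g = summarize_group(res, condition="x")
        assert g.er == pytest.approx(g.papp_ba_mean / g.papp_ab_mean, rel=1e-12)


class TestWellTimeSeriesValidation:
    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            make_series([1.0, 2.0], times=np.array([60.0, 30.0]))

    def test_sample_volume_must_fit_receiver(self):
        with pytest.raises(ValueError):
            make_series([1.0], vr=0.2, vs=0.2)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            make_series([-1.0])
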