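"""Tests for the mechanistic two-compartment transport simulator."""

import numpy as np
import pytest

from cacoflux import (
    AP_TO_BL,
    BL_TO_AP,
    SamplingSchedule,
    TransportSimParams,
    analyze_well,
    efflux_params,
    generate_standards,
    passive_params,
    simulate_condition,
    simulate_well,
    summarize_group,
)


def _group_er(params, c0, n_wells=1, seed=0, schedule=None):
    schedule = schedule or SamplingSchedule()
    ds = simulate_condition(params, schedule, [c0], n_wells, seed=seed)
    return summarize_group([analyze_well(w) for w in ds.wells])


class TestParameterValidation:
    @pytest.mark.parametrize("kw", [
        {"p_passive": -1e-6},
        {"p_passive": 1e-6, "vmax": -1.0},
        {"p_passive": 1e-6, "km": 0.0},
        {"p_passive": 1e-6, "inhibition": 1.5},
        {"p_passive": 1e-6, "vol_ap": 0.0},
        {"p_passive": 1e-6, "noise_cv": -0.1},
    ])
    def test_bad_params_rejected(self, kw):
        with pytest.raises(ValueError):
            TransportSimParams(**kw)

    def test_bad_schedule_rejected(self):
        with pytest.raises(ValueError):
            SamplingSchedule(times=(30.0, 30.0))
        with pytest.raises(ValueError):
            SamplingSchedule(times=(-10.0, 30.0))
        with pytest.raises(ValueError):
            SamplingSchedule(vs=0.0)

    def test_sample_volume_must_fit_receiver(self, schedule):
        params = passive_params(vol_ap=0.1)   # BL->AP receiver = apical 0.1 mL
        with pytest.raises(ValueError):
            simulate_well(params, schedule, BL_TO_AP, 100.0)


class TestPassiveSymmetry:
    def test_directions_identical_with_symmetric_volumes(self, schedule):
        """With no efflux and equal volumes the two directions coincide."""
        params = passive_params(p_passive=2e-6, vol_ap=1.5, vol_bl=1.5)
        _, ta = simulate_well(params, schedule, AP_TO_BL, 100.0)
        _, tb = simulate_well(params, schedule, BL_TO_AP, 100.0)
        np.testing.assert_allclose(ta.conc_true, tb.conc_true, rtol=1e-12)

    def test_full_inhibition_equals_no_efflux(self, schedule):
        """(1 - inhibition) = 0 zeroes the transporter term exactly."""
        blocked = efflux_params(inhibition=1.0)
        none = passive_params(p_passive=blocked.p_passive)
        for direction in (AP_TO_BL, BL_TO_AP):
            _, tb = simulate_well(blocked, schedule, direction, 100.0)
            _, tn = simulate_well(none, schedule, direction, 100.0)
            np.testing.assert_allclose(tb.conc_true, tn.conc_true, rtol=1e-12)

    def test_passive_er_near_unity(self, passive, schedule):
        """Noiseless symmetric passive run: ER within [0.95, 1.05]."""
        params = passive_params(p_passive=2e-6, vol_ap=1.5, vol_bl=1.5)
        g = _group_er(params, 100.0)
        assert 0.95 <= g.er <= 1.05


class TestMassConservation:
    @pytest.mark.parametrize("params", [
        passive_params(p_passive=1e-6),
        passive_params(p_passive=1e-5),
        efflux_params(),
        efflux_params(inhibition=0.5),
    ], ids=["passive-slow", "passive-fast", "efflux", "efflux-inhibited"])
    @pytest.mark.parametrize("direction", [AP_TO_BL, BL_TO_AP])
    @pytest.mark.parametrize("c0", [50.0, 200.0])
    def test_donor_receiver_withdrawn_sums_to_initial(self, params, direction,
                                                      c0, schedule):
        _, truth = simulate_well(params, schedule, direction, c0)
        assert truth.mass_balance_error() <= 1e-9

    def test_truth_cumulative_matches_eq4_on_noiseless_output(self, efflux,
                                                              schedule):
        """The analysis-side corrected dQ equals the simulator's exact
        cumulative transported mass when there is no noise."""
        from cacoflux import cumulative_amounts
        series, truth = simulate_well(efflux, schedule, AP_TO_BL, 100.0)
        dq = cumulative_amounts(series)
        np.testing.assert_allclose(dq, truth.cum_mass_true, rtol=1e-9)


class TestEffluxMechanism:
    def test_er_monotone_in_vmax(self, schedule):
        ers = [_group_er(efflux_params(vmax=v), 100.0).er
               for v in (0.0, 5e-5, 1.25e-4, 2e-4)]
        assert all(b >= a - 1e-9 for a, b in zip(ers, ers[1:]))

    def test_er_monotone_in_inhibition(self, schedule):
        ers = [_group_er(efflux_params(inhibition=i), 100.0).er
               for i in (0.0, 0.4, 0.8, 1.0)]
        assert all(b <= a + 1e-9 for a, b in zip(ers, ers[1:]))

    def test_saturation_reduces_er_at_high_concentration(self, efflux):
        """km << c0: doubling the donor concentration saturates the
        transporter and shrinks the efflux ratio."""
        er_100 = _group_er(efflux, 100.0).er
        er_200 = _group_er(efflux, 200.0).er
        assert er_100 > 3.0
        assert er_200 < er_100

    def test_efflux_direction_signs(self, efflux, passive, schedule):
        """Efflux slows AP->BL transport and speeds BL->AP transport."""
        base = passive_params(p_passive=efflux.p_passive)
        _, ab_eff = simulate_well(efflux, schedule, AP_TO_BL, 100.0)
        _, ab_pas = simulate_well(base, schedule, AP_TO_BL, 100.0)
        _, ba_eff = simulate_well(efflux, schedule, BL_TO_AP, 100.0)
        _, ba_pas = simulate_well(base, schedule, BL_TO_AP, 100.0)
        assert ab_eff.cum_mass_true[-1] < ab_pas.cum_mass_true[-1]
        assert ba_eff.cum_mass_true[-1] > ba_pas.cum_mass_true[-1]


class TestDeterminismAndNoise:
    def test_same_seed_same_dataset(self, schedule):
        params = efflux_params(noise_cv=0.05)
        a = simulate_condition(params, schedule, [100.0], 3, seed=42)
        b = simulate_condition(params, schedule, [100.0], 3, seed=42)
        assert a.wells_frame().equals(b.wells_frame())
        assert a.truth_frame().equals(b.truth_frame())

    def test_different_seeds_differ(self, schedule):
        params = efflux_params(noise_cv=0.05)
        a = simulate_condition(params, schedule, [100.0], 3, seed=1)
        b = simulate_condition(params, schedule, [100.0], 3, seed=2)
        assert not a.wells_frame().equals(b.wells_frame())

    def test_wells_are_independent_noise_draws(self, schedule):
        params = passive_params(p_passive=2e-6, noise_cv=0.05)
        ds = simulate_condition(params, schedule, [100.0], 4, seed=7)
        concs = np.array([w.concs for w in ds.wells if w.direction == AP_TO_BL])
        assert np.all(np.std(concs, axis=0) > 0)

    def test_replicate_papp_rsd_bounded_by_noise_model(self, schedule):
        """noise_cv=0.05, n=6: across-well Papp RSD lands in (0, 15%]."""
        params = passive_params(p_passive=2e-6, noise_cv=0.05)
        ds = simulate_condition(params, schedule, [100.0], 6, seed=11)
        papps = np.array([analyze_well(w).papp for w in ds.wells
                          if w.direction == AP_TO_BL])
        rsd = np.std(papps, ddof=1) / np.mean(papps) * 100.0
        assert 0.0 < rsd <= 15.0


class TestStandards:
    def test_noiseless_signal_from_known_line(self):
        # low-range puerarin curve: 1.8823 * 1 + 0.07998
        df = generate_standards(slope=1.8823, intercept=0.07998,
                                nominal_concs=[1.0], noise_cv=0.0)
        assert df["signal"].iloc[0] == pytest.approx(1.96228, abs=1e-9)

    def test_zero_concentration_returns_intercept(self):
        df = generate_standards(slope=1.8823, intercept=0.07998,
                                nominal_concs=[0.0], noise_cv=0.0)
        assert df["signal"].iloc[0] == pytest.approx(0.07998)

    def test_segmented_truth_uses_matching_segment(self):
        segs = [(0.025, 2.5, 1.8823, 0.07998), (2.5, 100.0, 1.8758, -0.3433)]
        df = generate_standards(None, segments=segs, nominal_concs=[1.0, 10.0],
                                noise_cv=0.0)
        assert df["signal"].iloc[0] == pytest.approx(1.8823 + 0.07998)
        assert df["signal"].iloc[1] == pytest.approx(1.8758 * 10 - 0.3433)

    def test_noise_is_seed_reproducible(self):
        a = generate_standards(1.0, 0.0, noise_cv=0.05, seed=3)
        b = generate_standards(1.0, 0.0, noise_cv=0.05, seed=3)
        assert a.equals(b)


class TestParameterRecovery:
    def test_sink_regime_recovers_p_passive(self, passive, schedule):
        """Noiseless passive sink-regime run: full-pipeline Papp within
        2% of the generating permeability."""
        series, truth = simulate_well(passive, schedule, AP_TO_BL, 100.0)
        # sink check: receiver concentration stays below 10% of donor
        assert np.all(truth.conc_true < 0.1 * 100.0)
        res = analyze_well(series)
        assert abs(res.papp - passive.p_passive) / passive.p_passive <= 0.02
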