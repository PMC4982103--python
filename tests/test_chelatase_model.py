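import math

import numpy as np
import pytest

from chelapower.catalytic_power import ThermoContext
from chelapower.chelatase_model import (
    DEFAULT_PARAMS,
    AssayConditions,
    KineticParameterSet,
    ModelState,
    ProgressCurve,
    atp_flux,
    chelation_velocity,
    displacement_factor,
    find_steady_state,
    simulate_progress,
    steady_state_maintenance_time,
)
from chelapower.synthetic_data import get_preset


def hand_velocity(D, Mg, ATP, E0=1e-7, kcat=1 / 75, Km=2e-6, K05=7e-3, h=2, KA=1e-4):
    """Independent hand evaluation of the separable rate law."""
    return (
        kcat * E0
        * (D / (Km + D))
        * (Mg**h / (K05**h + Mg**h))
        * (ATP / (KA + ATP))
    )


class TestRateLaw:
    def test_velocity_matches_hand_evaluation_at_assay_conditions(self):
        state = ModelState(D=8e-6, MgD=0.0, ATP=5e-3)
        v = chelation_velocity(state, DEFAULT_PARAMS, AssayConditions())
        assert v == pytest.approx(hand_velocity(8e-6, 1e-2, 5e-3), rel=1e-12)
        assert v == pytest.approx(7.02e-10, rel=1e-3)

    def test_no_enzyme_or_no_substrate_gives_zero_flux(self):
        cond = AssayConditions(conc_ChlI=0.0)
        state = ModelState(D=8e-6, MgD=0.0, ATP=5e-3)
        assert chelation_velocity(state, DEFAULT_PARAMS, cond) == 0.0
        state0 = ModelState(D=0.0, MgD=8e-6, ATP=5e-3)
        assert chelation_velocity(state0, DEFAULT_PARAMS, AssayConditions()) == 0.0

    def test_product_inhibition_factor(self):
        params = KineticParameterSet(K_i_product=1e-6)
        state = ModelState(D=8e-6, MgD=1e-6, ATP=5e-3)
        inhibited = chelation_velocity(state, params, AssayConditions())
        free = chelation_velocity(state, DEFAULT_PARAMS, AssayConditions())
        assert inhibited == pytest.approx(free / 2, rel=1e-12)

    def test_atp_flux_is_stoichiometric_plus_basal(self):
        cond = AssayConditions()
        state = ModelState(D=8e-6, MgD=0.0, ATP=5e-3)
        no_basal = KineticParameterSet(k_basal_ATPase=0.0)
        v = chelation_velocity(state, no_basal, cond)
        assert atp_flux(state, no_basal, cond) == pytest.approx(15 * v, rel=1e-12)
        # basal component ~0.7/s per 0.1 uM ChlI at saturating ATP
        basal = atp_flux(state, DEFAULT_PARAMS, cond) - atp_flux(state, no_basal, cond)
        assert basal == pytest.approx(0.7 * 1e-7 * (5e-3 / 5.1e-3), rel=1e-9)
        assert basal == pytest.approx(7e-8, rel=0.03)

    def test_atp_flux_zero_without_nucleotide(self):
        state = ModelState(D=8e-6, MgD=0.0, ATP=0.0)
        assert atp_flux(state, DEFAULT_PARAMS, AssayConditions()) == 0.0


class TestSimulation:
    def test_no_enzyme_limit_is_first_order_decay(self):
        cond = AssayConditions(conc_ChlI=0.0, D_total=2.5e-6)
        curve = simulate_progress(DEFAULT_PARAMS, cond, 36000, 121, MgD_0=2.5e-6)
        ref = 2.5e-6 * np.exp(-DEFAULT_PARAMS.k_dechel * curve.times)
        assert np.max(np.abs(curve.MgD - ref) / ref) < 1e-3

    @pytest.mark.parametrize("name", ["fig2a", "fig2b", "fig2a-noregen", "fig3b-low"])
    def test_porphyrin_conservation(self, name):
        p = get_preset(name)
        curve = simulate_progress(p.params, p.conditions, p.t_end, 241)
        total = curve.D + curve.MgD
        assert np.max(np.abs(total - p.conditions.D_total)) <= 1e-6 * p.conditions.D_total

    def test_atp_nonincreasing_without_regeneration(self, fig2a_noregen_curve):
        assert np.all(np.diff(fig2a_noregen_curve.ATP) <= 1e-18)

    def test_atp_clamped_while_pep_lasts(self, fig2b_curve):
        c = fig2b_curve
        pep_on = c.PEP > 1e-9
        assert np.all(np.diff(c.PEP) <= 1e-15)  # PEP only consumed
        assert np.allclose(c.ATP[pep_on], 1e-3, rtol=1e-9)  # clamp holds
        assert c.ATP[-1] < 1e-3  # and releases after exhaustion

    def test_clamped_atp_rise_is_monotone(self):
        p = get_preset("fig2b")
        cond = AssayConditions(
            ATP_0=1e-3, PEP_0=1.0, regeneration_on=True
        )  # effectively permanent clamp
        curve = simulate_progress(p.params, cond, 12 * 3600, 241)
        assert np.all(np.diff(curve.MgD) >= -1e-12 * curve.MgD.max())

    def test_plateau_matches_algebraic_steady_state(self):
        p = get_preset("fig2b")
        cond = AssayConditions(ATP_0=1e-3, PEP_0=1.0, regeneration_on=True)
        curve = simulate_progress(p.params, cond, 24 * 3600, 241)
        ss = find_steady_state(p.params, cond)
        assert curve.MgD[-1] == pytest.approx(ss.MgD_ss, rel=5e-3)

    def test_post_exhaustion_tail_decays_at_dechelation_rate(self, fig2a_noregen_curve):
        c = fig2a_noregen_curve
        tail = c.times > c.times[-1] - 7200
        slope = np.polyfit(c.times[tail], np.log(c.MgD[tail]), 1)[0]
        assert slope == pytest.approx(-DEFAULT_PARAMS.k_dechel, rel=0.01)

    def test_rise_and_fall_without_regeneration(self, fig2a_noregen_curve):
        mgd = fig2a_noregen_curve.MgD
        imax = int(mgd.argmax())
        assert 0 < imax < mgd.size - 1
        assert np.all(np.diff(mgd[: imax + 1]) > -1e-12 * mgd.max())
        assert np.all(np.diff(mgd[imax:]) < 1e-12 * mgd.max())
        assert mgd[-1] < 0.5 * mgd[imax]

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_progress(DEFAULT_PARAMS, AssayConditions(), -1.0, 10)
        with pytest.raises(ValueError):
            simulate_progress(DEFAULT_PARAMS, AssayConditions(), 100.0, 1)


class TestSteadyState:
    def test_no_loss_path_converts_completely(self):
        params = KineticParameterSet(k_dechel=0.0)
        ss = find_steady_state(params, AssayConditions())
        assert ss.MgD_ss == AssayConditions().D_total
        assert math.isinf(ss.ratio_ss)

    def test_no_formation_path_stays_free(self):
        ss = find_steady_state(DEFAULT_PARAMS, AssayConditions(conc_ChlD=0.0))
        assert ss.MgD_ss == 0.0
        assert ss.D_ss == AssayConditions().D_total

    def test_root_matches_independent_bisection(self):
        cond = AssayConditions(D_total=2.5e-6, ATP_0=5e-3)
        ss = find_steady_state(DEFAULT_PARAMS, cond)

        def balance(D):  # independent formulation of the balance equation
            return hand_velocity(D, 1e-2, 5e-3) - 3.17e-5 * (2.5e-6 - D)

        lo, hi = 0.0, 2.5e-6
        for _ in range(200):  # plain bisection oracle
            mid = 0.5 * (lo + hi)
            if balance(mid) > 0:
                hi = mid
            else:
                lo = mid
        assert ss.D_ss == pytest.approx(lo, rel=1e-9)
        assert ss.MgD_ss == pytest.approx(2.32e-6, rel=5e-3)
        assert ss.ratio_over_Mg == pytest.approx(1.27e3, rel=0.01)
        assert ss.velocity_ss == pytest.approx(3.17e-5 * ss.MgD_ss, rel=1e-9)

    def test_ratio_nondecreasing_in_clamped_atp(self):
        ratios = [
            find_steady_state(DEFAULT_PARAMS, AssayConditions(ATP_0=a)).ratio_ss
            for a in (1e-5, 5e-5, 1.5e-4, 1e-3, 5e-3)
        ]
        assert all(b >= a for a, b in zip(ratios, ratios[1:]))

    def test_conversion_nonincreasing_in_total_porphyrin(self):
        ratios = [
            find_steady_state(
                DEFAULT_PARAMS, AssayConditions(D_total=d)
            ).ratio_ss
            for d in (2.5e-6, 5e-6, 10e-6, 20e-6)
        ]
        assert all(b <= a for a, b in zip(ratios, ratios[1:]))

    def test_displacement_factor(self):
        thermo = ThermoContext(K_eq=1e-6)
        ss = find_steady_state(
            DEFAULT_PARAMS, AssayConditions(D_total=2.5e-6, ATP_0=5e-3)
        )
        assert displacement_factor(ss, thermo) == pytest.approx(1.27e9, rel=0.01)
        # at equilibrium the factor is 1 by construction
        from chelapower.chelatase_model import SteadyStateResult

        eq = SteadyStateResult(1e-6, 1e-6, 1.0, 1e-6, 0.0)
        assert displacement_factor(eq, thermo) == pytest.approx(1.0)


class TestMaintenanceTime:
    @staticmethod
    def _curve(t, mgd):
        z = np.zeros_like(np.asarray(t, float))
        return ProgressCurve(times=t, D=z, MgD=mgd, ATP=z, PEP=z)

    def test_constant_curve_spans_full_duration(self):
        t = np.linspace(0, 1000, 11)
        res = steady_state_maintenance_time(self._curve(t, np.full(11, 2e-6)))
        assert res.duration_s == pytest.approx(1000.0)
        assert res.censored and not res.no_plateau

    def test_pure_decay_flagged_no_plateau(self):
        t = np.linspace(0, 1000, 11)
        res = steady_state_maintenance_time(self._curve(t, 2e-6 * np.exp(-t / 100)))
        assert res.duration_s == 0.0
        assert res.no_plateau

    def test_regenerated_assay_holds_plateau_beyond_seven_hours(self, fig2b_curve):
        p = get_preset("fig2b")
        ss = find_steady_state(p.params, p.conditions)
        res = steady_state_maintenance_time(fig2b_curve, 0.10, plateau=ss.MgD_ss)
        assert res.duration_s >= 7 * 3600.0
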