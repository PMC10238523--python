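import numpy as np
import pytest
from scipy.integrate import solve_ivp

from coroflow.circuit import (
    chamber_pressure,
    coronary_branch_derivatives,
    coronary_branch_steady_flow,
    elastance,
    elastance_normalization,
    pack_parameters,
    system_derivatives,
    valve_pressure_gradient,
)
from coroflow.engine import integrate_to_periodic, measure_waveforms
from coroflow.errors import SimulationError
from coroflow.parameters import (
    ChamberElastanceParams,
    CoronaryBranchParameters,
    ValveParameters,
    build_model_parameters,
)

LV = ChamberElastanceParams(E_max=2.1, E_min=0.06, m1=1.32, m2=27.4,
                            tau1=0.269, tau2=0.452, V0=5.0)
BRANCH = CoronaryBranchParameters(R_p=22.1, R_m=36.0, R_d=11.1,
                                  C_p=0.0015, C_m=0.0121)


class TestElastance:
    def test_onset_value_is_emin(self):
        assert elastance(0.0, LV, 0.845) == pytest.approx(0.06)

    def test_cycle_max_is_emax(self):
        t = np.linspace(0, 0.845, 20001)
        assert elastance(t, LV, 0.845).max() == pytest.approx(2.1, rel=1e-6)

    def test_analytic_half_activation_at_tau1(self):
        """With a sharp descending limb far beyond tau1, E(tau1) is exactly
        E_min + (E_max - E_min)/(2N): the ascending Hill term equals 1/2."""
        ch = ChamberElastanceParams(E_max=2.0, E_min=0.1, m1=1.7, m2=200.0,
                                    tau1=0.2, tau2=0.9, V0=0.0)
        T = 1.0
        N = elastance_normalization(ch, T)
        assert elastance(0.2, ch, T) == pytest.approx(0.1 + 1.9 * 0.5 / N, rel=1e-9)

    def test_periodic_wrap(self):
        assert elastance(0.3 + 0.845, LV, 0.845) == pytest.approx(
            elastance(0.3, LV, 0.845))


class TestChamberPressure:
    def test_unstressed_volume_gives_zero(self):
        assert chamber_pressure(5.0, 2.1, 5.0) == 0.0

    def test_linear_in_volume(self):
        assert chamber_pressure(65.0, 2.1, 5.0) == pytest.approx(126.0)
        p1 = chamber_pressure(40.0, 1.3, 5.0)
        p2 = chamber_pressure(80.0, 1.3, 5.0)
        assert chamber_pressure(60.0, 1.3, 5.0) == pytest.approx((p1 + p2) / 2)


class TestValveLaw:
    VALVE = ValveParameters(name="aortic", EOA=0.7, ELCo=1.0, inertance_coeff=0.005)

    def test_zero_steady_flow(self):
        assert valve_pressure_gradient(0.0, 0.0, self.VALVE) == 0.0

    def test_convective_magnitude(self):
        """250 mL/s through ELCo 1 cm^2: 1.05/2 * 250^2 dyn/cm^2 = 24.6 mmHg."""
        dp = valve_pressure_gradient(250.0, 0.0, self.VALVE)
        assert dp == pytest.approx(24.61, abs=0.02)

    def test_quartic_scaling_in_elco(self):
        wide = ValveParameters(name="a", EOA=0.7, ELCo=4.0, inertance_coeff=0.005)
        assert valve_pressure_gradient(250.0, 0.0, self.VALVE) == pytest.approx(
            16 * valve_pressure_gradient(250.0, 0.0, wide))

    def test_signed_for_reverse_flow(self):
        assert valve_pressure_gradient(-100.0, 0.0, self.VALVE) < 0


def _integrate_branch(p_in, p_out, p_im, y0, t_end, params=BRANCH):
    def rhs(t, y):
        d = coronary_branch_derivatives(p_in, p_out, p_im, 0.0, (y[0], y[1]), params)
        return [d.dP_p_dt, d.dU_m_dt]

    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    return sol.y[:, -1]


class TestCoronaryBranch:
    def test_steady_state_matches_resistive_chain(self):
        """Constant imposed pressures: the branch relaxes to the closed-form
        series-resistance flow (the capacitors drop out)."""
        p_in, p_out, p_im = 95.0, 4.0, 20.0
        y = _integrate_branch(p_in, p_out, p_im, [0.0, 0.0], 20.0)
        d = coronary_branch_derivatives(p_in, p_out, p_im, 0.0, tuple(y), BRANCH)
        expected = coronary_branch_steady_flow(p_in, p_out, BRANCH)
        for q in (d.q_in, d.q_m, d.q_out):
            assert q == pytest.approx(expected, rel=1e-3)

    def test_equal_pressures_zero_flow(self):
        y = _integrate_branch(50.0, 50.0, 10.0, [20.0, 5.0], 20.0)
        d = coronary_branch_derivatives(50.0, 50.0, 10.0, 0.0, tuple(y), BRANCH)
        assert abs(d.q_in) < 1e-6 and abs(d.q_out) < 1e-6

    def test_kirchhoff_node_balance(self):
        """The derivative definitions satisfy the proximal node law
        q_in - q_m = C_p dP_p/dt identically."""
        d = coronary_branch_derivatives(90.0, 4.0, 35.0, 100.0, (60.0, 10.0), BRANCH)
        assert d.q_in - d.q_m == pytest.approx(BRANCH.C_p * d.dP_p_dt, rel=1e-12)
        assert d.q_m - d.q_out == pytest.approx(BRANCH.C_m * d.dU_m_dt, rel=1e-12)


class TestSystemAssembly:
    def test_derivative_finite_and_correct_length(self, tuned_mean):
        waves, _, params = tuned_mean
        y = waves.y_end
        dy = system_derivatives(0.1, y, params)
        assert dy.shape == y.shape
        assert np.all(np.isfinite(dy))

    def test_nan_state_names_component(self, tuned_mean):
        waves, _, params = tuned_mean
        y = waves.y_end.copy()
        y[2] = np.nan
        with pytest.raises(SimulationError, match="aortic root"):
            system_derivatives(0.1, y, params)

    def test_closed_valve_backflow_is_trickle(self, tuned_mean):
        waves, _, _ = tuned_mean
        assert waves["Q_AV"].min() > -1.0  # mL/s, smooth-diode leak only

    def test_removing_coronary_bed_barely_changes_loop(self, mean_patient):
        """Scaling every branch impedance out of reach (resistances x1e6 with
        time constants preserved) removes ~4% of the aortic outflow; the
        remaining loop shifts by less than 5%."""
        pre, _, anat = mean_patient
        params = build_model_parameters(pre, anat)
        base = measure_waveforms(integrate_to_periodic(params, rtol=1e-6,
                                                       residual_tol=1e-5))
        ablated = build_model_parameters(pre, anat)
        for cb in ablated.coronary.values():
            cb.R_p *= 1e6
            cb.R_m *= 1e6
            cb.R_d *= 1e6
            cb.C_p *= 1e-6
            cb.C_m *= 1e-6
        abl = measure_waveforms(integrate_to_periodic(ablated, rtol=1e-6,
                                                      residual_tol=1e-5))
        assert abl["total_coronary_flow"] < 0.01
        for key in ("SBP", "DBP", "forward_SV", "MAP_model"):
            assert abs(abl[key] - base[key]) / base[key] < 0.05

    def test_mean_la_inflow_equals_imposed_source(self, tuned_mean):
        waves, _, params = tuned_mean
        assert waves.cycle_mean("Q_LA_inflow") == pytest.approx(
            params.pulmonary.Q_MPV, rel=1e-3)

    def test_pack_parameters_deterministic(self, tuned_mean):
        _, _, params = tuned_mean
        assert np.array_equal(pack_parameters(params), pack_parameters(params))
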