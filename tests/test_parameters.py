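import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coroflow.errors import DomainError
from coroflow.parameters import (
    BRANCHES,
    allocate_branch_compliances,
    allocate_branch_resistances,
    build_model_parameters,
    compute_map,
    energy_loss_coefficient,
    total_coronary_resistance,
)
from coroflow.patients import CoronaryAnatomy

area = st.floats(min_value=0.02, max_value=0.5)


def _anatomy(a_lad, a_lcx, a_rca, **sten):
    return CoronaryAnatomy(A_LAD=a_lad, A_LCX=a_lcx, A_RCA=a_rca, **sten)


class TestMeanArterialPressure:
    @pytest.mark.parametrize(
        "sbp, dbp, hr, expected",
        [(133.0, 70.5, 71, 96.66), (142.0, 72.0, 73, 101.47)],
    )
    def test_cuff_formula(self, sbp, dbp, hr, expected):
        assert compute_map(sbp, dbp, hr) == pytest.approx(expected, abs=0.005)

    def test_zero_pulse_pressure(self):
        assert compute_map(100.0, 100.0, 60) == 100.0

    @given(st.floats(41, 100), st.floats(1, 40), st.floats(30, 200))
    def test_between_dbp_and_sbp(self, sbp, dbp, hr):
        assert dbp < compute_map(sbp, dbp, hr) < sbp

    def test_domain(self):
        with pytest.raises(DomainError):
            compute_map(80.0, 90.0, 60)
        with pytest.raises(DomainError):
            compute_map(120.0, 80.0, 0)


class TestTotalCoronaryResistance:
    def test_values(self):
        assert total_coronary_resistance(96.66, 83.33) == pytest.approx(29.00, abs=0.005)
        assert total_coronary_resistance(100.0, 100.0) == 25.0

    def test_doubling_co_halves(self):
        r1 = total_coronary_resistance(95.0, 80.0)
        assert total_coronary_resistance(95.0, 160.0) == pytest.approx(r1 / 2)

    def test_domain(self):
        with pytest.raises(DomainError):
            total_coronary_resistance(-1.0, 80.0)


class TestMurrayAllocation:
    def test_equal_areas_symmetric(self):
        rs = allocate_branch_resistances(_anatomy(0.1, 0.1, 0.1), 29.0)
        for b in BRANCHES:
            assert sum(rs[b]) == pytest.approx(3 * 29.0, rel=1e-12)

    def test_example_areas(self):
        rs = allocate_branch_resistances(_anatomy(0.10, 0.06, 0.09), 29.0)
        assert sum(rs["LAD"]) == pytest.approx(69.19, abs=0.05)

    @given(area, area, area, st.floats(1.0, 100.0))
    def test_parallel_sum_identity(self, a1, a2, a3, r_total):
        """The Murray weights make the three branch totals combine in
        parallel to exactly the pooled total (no stenosis)."""
        rs = allocate_branch_resistances(_anatomy(a1, a2, a3), r_total)
        parallel = 1.0 / sum(1.0 / sum(rs[b]) for b in BRANCHES)
        assert parallel == pytest.approx(r_total, rel=1e-12)

    @given(area, area, area, st.floats(1.0, 100.0))
    def test_split_fractions(self, a1, a2, a3, r_total):
        rs = allocate_branch_resistances(_anatomy(a1, a2, a3), r_total)
        for b in BRANCHES:
            total = sum(rs[b])
            assert rs[b][0] == pytest.approx(0.32 * total, rel=1e-12)
            assert rs[b][1] == pytest.approx(0.52 * total, rel=1e-12)
            assert rs[b][2] == pytest.approx(0.16 * total, rel=1e-12)

    def test_stenosis_example(self):
        """alpha = 0.5 quadruples the branch total before the 3-way split."""
        no_sten = allocate_branch_resistances(_anatomy(0.1, 0.1, 0.1), 100.0 / 3.0)
        sten = allocate_branch_resistances(
            _anatomy(0.1, 0.1, 0.1, A_sten_LAD=0.05), 100.0 / 3.0)
        assert sum(no_sten["LAD"]) == pytest.approx(100.0)
        assert np.allclose(sten["LAD"], (128.0, 208.0, 64.0))

    @given(area, st.floats(0.05, 1.0))
    def test_stenosis_identity_and_monotonicity(self, a, alpha):
        base = allocate_branch_resistances(_anatomy(a, a, a), 10.0)
        sten = allocate_branch_resistances(
            _anatomy(a, a, a, A_sten_LAD=alpha * a), 10.0)
        assert sum(sten["LAD"]) == pytest.approx(sum(base["LAD"]) / alpha**2, rel=1e-12)
        if alpha < 1.0:  # tighter stenosis -> strictly larger resistance
            assert sum(sten["LAD"]) > sum(base["LAD"])


class TestComplianceAllocation:
    def test_proportional_split(self):
        cs = allocate_branch_compliances(_anatomy(0.10, 0.06, 0.09), 0.020, 0.0125)
        assert sum(cs["LAD"]) == pytest.approx(0.0125, rel=1e-12)
        assert sum(cs["LCX"]) == pytest.approx(0.0075, rel=1e-12)
        assert sum(cs["RCA"]) == pytest.approx(0.0125, rel=1e-12)

    def test_capacitor_split(self):
        cs = allocate_branch_compliances(_anatomy(0.10, 0.06, 0.09), 0.020, 0.0125)
        assert cs["LAD"] == pytest.approx((0.001375, 0.011125), rel=1e-12)

    @given(area, area, area, st.floats(0.001, 0.1), st.floats(0.001, 0.1))
    def test_left_total_conserved(self, a1, a2, a3, c_left, c_right):
        cs = allocate_branch_compliances(_anatomy(a1, a2, a3), c_left, c_right)
        left_sum = sum(cs["LAD"]) + sum(cs["LCX"])
        assert left_sum == pytest.approx(c_left, rel=1e-12)
        for b in BRANCHES:
            assert cs[b][0] == pytest.approx(0.11 * sum(cs[b]), rel=1e-12)

    def test_domain(self):
        with pytest.raises(DomainError):
            allocate_branch_compliances(_anatomy(0.1, 0.1, 0.1), -0.01, 0.01)


class TestEnergyLossCoefficient:
    def test_values(self):
        assert energy_loss_coefficient(2.0, 4.0) == 4.0
        assert energy_loss_coefficient(0.84, 4.0) == pytest.approx(1.063, abs=5e-4)

    def test_large_area_limit(self):
        assert energy_loss_coefficient(1.5, 1e9) == pytest.approx(1.5, rel=1e-6)

    @given(st.floats(0.2, 3.0), st.floats(3.5, 12.0))
    def test_exceeds_eoa_and_monotone(self, eoa, a):
        elco = energy_loss_coefficient(eoa, a)
        assert elco > eoa
        assert energy_loss_coefficient(eoa + 0.05, a) > elco

    def test_diverges_at_equal_areas(self):
        with pytest.raises(DomainError):
            energy_loss_coefficient(4.0, 4.0)


class TestBuildModelParameters:
    def test_table_constants(self, mean_patient):
        pre, _, anat = mean_patient
        params = build_model_parameters(pre, anat)
        s = params.systemic
        assert (s.R_ao, s.R_SV, s.R_pda, s.P_CV0) == (0.05, 0.05, 0.05, 4.0)
        assert (s.C_ao, s.C_SAC, s.R_SA) == (0.5, 2.0, 0.8)
        pm = params.pulmonary
        assert (pm.L_PV, pm.R_PV, pm.R_PVC, pm.C_PVC) == (5e-4, 0.002, 0.001, 40.0)
        assert (pm.L_PC, pm.R_PC, pm.R_PA, pm.C_PA) == (3e-4, 0.21, 0.01, 4.0)
        assert (params.lv.E_max, params.lv.E_min) == (2.1, 0.06)
        assert (params.lv.m1, params.lv.m2) == (1.32, 27.4)
        assert (params.lv.tau1, params.lv.tau2) == (0.269, 0.452)
        assert (params.la.E_max, params.la.m2, params.la.tau2) == (0.17, 13.1, 0.18)
        assert params.rho == 1050.0

    def test_no_regurgitation_paths_absent(self, mean_patient):
        pre, _, anat = mean_patient
        params = build_model_parameters(pre, anat)
        assert params.valve_aortic_regurgitant is None
        assert params.valve_mitral_regurgitant is None
        assert params.leak_resistance is None

    def test_regurgitation_paths_present(self, mean_patient):
        pre, _, anat = mean_patient
        m = pre.model_copy(update={"EOA_AR": 0.2, "EOA_MR": 0.25, "V_leak": 8.0})
        params = build_model_parameters(m, anat)
        assert params.valve_aortic_regurgitant.direction == "regurgitant"
        assert params.valve_mitral_regurgitant.EOA == 0.25
        assert params.leak_resistance > 0

    def test_compliance_override_recomputes_splits(self, mean_patient):
        pre, _, anat = mean_patient
        x = 0.04
        params = build_model_parameters(pre, anat, {"C_cor_total_left": x})
        share = anat.A_LAD / (anat.A_LAD + anat.A_LCX)
        assert params.C_cor_total_left == x
        assert params.coronary["LAD"].C_p == pytest.approx(0.11 * share * x, rel=1e-12)
        assert params.coronary["LAD"].C_m == pytest.approx(0.89 * share * x, rel=1e-12)

    def test_unknown_override_rejected(self, mean_patient):
        pre, _, anat = mean_patient
        with pytest.raises(DomainError, match="nope"):
            build_model_parameters(pre, anat, {"nope": 1.0})

    def test_pure_function(self, mean_patient):
        pre, _, anat = mean_patient
        before = (pre.model_dump(), anat.model_dump())
        p1 = build_model_parameters(pre, anat)
        p2 = build_model_parameters(pre, anat)
        assert (pre.model_dump(), anat.model_dump()) == before
        assert p1 == p2

    def test_rca_intramyocardial_scale(self, mean_patient):
        pre, _, anat = mean_patient
        params = build_model_parameters(pre, anat)
        assert params.coronary["LAD"].im_pressure_scale == 1.0
        assert params.coronary["LCX"].im_pressure_scale == 1.0
        assert params.coronary["RCA"].im_pressure_scale == 0.5

    def test_elco_exceeds_eoa(self, mean_patient):
        pre, _, anat = mean_patient
        params = build_model_parameters(pre, anat)
        assert params.valve_aortic.ELCo > params.valve_aortic.EOA
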