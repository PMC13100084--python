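"""Single-beat elastance computations and their algebraic identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vacpih.elastance import (
    EchoMeasurements,
    aortic_mechanics,
    compute_ea,
    compute_ees,
    compute_end_est,
    compute_ratio,
    compute_table,
    compute_vac,
    derive_sv,
)
from vacpih.errors import DomainError, NonPhysiologicalElastance, SchemaError


def chen_end_est_oracle(ef, pep, tsp, sap, dap):
    """Independent transcription of the single-beat End(est) estimator.

    Evaluated term by term, exactly as printed in the source reference:
    a 7th-order polynomial in tNd = PEP/TSP averaged over the derivation
    cohort, plus linear corrections in EF and DAP/Pes.
    """
    t = pep / tsp
    end_avg = (0.35695 - 7.2266 * t + 74.376 * t**2 - 307.39 * t**3
               + 684.54 * t**4 - 856.92 * t**5 + 571.95 * t**6
               - 159.1 * t**7)
    return 0.0275 - 0.165 * ef + 0.3656 * (dap / (0.9 * sap)) + 0.515 * end_avg


class TestEa:
    @pytest.mark.parametrize("sap,sv,expected", [(120, 60, 1.8), (90, 50, 1.62)])
    def test_direct_substitution(self, sap, sv, expected):
        assert compute_ea(sap, sv) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("sap,sv", [(120, 0), (0, 60), (-5, 50)])
    def test_nonpositive_inputs_rejected(self, sap, sv):
        with pytest.raises(DomainError):
            compute_ea(sap, sv)

    def test_units_round_trip(self):
        # Ea * SV recovers the end-systolic pressure proxy exactly
        for sap, sv in [(118, 63.2), (140, 81.5), (95, 44.0)]:
            assert compute_ea(sap, sv) * sv == pytest.approx(0.9 * sap, rel=1e-15)


class TestEndEst:
    def test_matches_independent_transcription(self):
        val = compute_end_est(0.61, 80, 380, 120, 80)
        assert 0 < val < 1
        assert val == pytest.approx(chen_end_est_oracle(0.61, 80, 380, 120, 80),
                                    abs=1e-12)
        assert val == pytest.approx(0.3526806608, abs=1e-9)  # frozen

    def test_deterministic(self):
        a = compute_end_est(0.55, 95, 400, 130, 85)
        b = compute_end_est(0.55, 95, 400, 130, 85)
        assert a == b

    def test_pep_equal_tsp_rejected(self):
        with pytest.raises(DomainError):
            compute_end_est(0.61, 380, 380, 120, 80)

    def test_out_of_range_tnd_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="tNd"):
            clipped = compute_end_est(0.61, 10, 400, 120, 80)
        at_bound = compute_end_est(0.61, 0.05 * 400, 400, 120, 80)
        assert clipped == pytest.approx(at_bound, abs=1e-12)

    @pytest.mark.parametrize("args", [
        (1.2, 80, 380, 120, 80),   # ef not a fraction
        (0.61, 80, 380, 80, 120),  # sap < dap
        (0.61, -5, 380, 120, 80),  # negative pep
    ])
    def test_precondition_violations(self, args):
        with pytest.raises(DomainError):
            compute_end_est(*args)


class TestEes:
    @pytest.mark.parametrize("dap,sap,sv,end,expected", [
        (80, 120, 60, 0.30, (80 - 32.4) / 18.0),
        (70, 120, 70, 0.25, (70 - 27.0) / 17.5),
    ])
    def test_direct_substitution(self, dap, sap, sv, end, expected):
        assert compute_ees(dap, sap, sv, end) == pytest.approx(expected, rel=1e-12)

    def test_non_physiological_rejected(self):
        with pytest.raises(NonPhysiologicalElastance):
            compute_ees(30, 120, 60, 0.30)  # 30 < 0.30*0.9*120 = 32.4

    @settings(max_examples=200, derandomize=True)
    @given(
        sap=st.floats(90, 200),
        frac=st.floats(0.05, 0.95),
        sv=st.floats(20, 150),
        end=st.floats(0.1, 0.6),
    )
    def test_positive_whenever_precondition_holds(self, sap, frac, sv, end):
        # construct dap strictly between End(est)*Pes and sap
        x = end * 0.9 * sap
        dap = x + frac * (sap - x)
        if dap >= sap or dap <= x:
            return
        assert compute_ees(dap, sap, sv, end) > 0


class TestRatio:
    def test_cancellation_identity(self):
        ratio, unc = compute_ratio(120, 80, 60, 0.30)
        x = 0.30 * 0.9 * 120
        assert ratio == pytest.approx(x / (80 - x), rel=1e-12)
        assert ratio == pytest.approx(0.6807, abs=1e-4)
        assert unc is False

    @settings(max_examples=300, derandomize=True)
    @given(
        sap=st.floats(90, 200),
        frac=st.floats(0.05, 0.95),
        end=st.floats(0.1, 0.6),
        sv1=st.floats(20, 150),
        sv2=st.floats(20, 150),
    )
    def test_sv_cancels(self, sap, frac, end, sv1, sv2):
        x = end * 0.9 * sap
        dap = x + frac * (sap - x)
        if dap >= sap or dap <= x:
            return
        r1, u1 = compute_ratio(sap, dap, sv1, end)
        r2, u2 = compute_ratio(sap, dap, sv2, end)
        assert r1 == r2 and u1 == u2

    def test_boundary_ratio_one_is_coupled(self):
        # dap chosen so ratio == 1 exactly: dap = 2 * End(est)*0.9*SAP
        ratio, unc = compute_ratio(120, 64.8, 60, 0.30)
        assert ratio == pytest.approx(1.0, rel=1e-12)
        assert unc is False  # strict inequality

    def test_uncoupling_threshold_equivalence(self, rng):
        # uncoupled  <=>  End(est)*0.9*SAP > DAP/2
        for _ in range(1000):
            sap = rng.uniform(90, 200)
            end = rng.uniform(0.1, 0.6)
            x = end * 0.9 * sap
            dap = rng.uniform(x * 1.01, sap * 0.99)
            if dap >= sap:
                continue
            _, unc = compute_ratio(sap, dap, 60.0, end)
            assert unc == (x > dap / 2)


class TestDeriveSv:
    @pytest.mark.parametrize("lvot,vti,expected", [
        (2.0, 20, math.pi * 1.0**2 * 20),
        (1.8, 18, math.pi * 0.81 * 18),
    ])
    def test_cylinder_formula(self, lvot, vti, expected):
        assert derive_sv(lvot, vti) == pytest.approx(expected, rel=1e-12)

    def test_zero_rejected(self):
        with pytest.raises(DomainError):
            derive_sv(0, 20)


class TestAorticMechanics:
    def test_reference_values(self):
        m = aortic_mechanics(3.2, 3.0, 120, 80)
        assert m.strain == pytest.approx(100 * 0.2 / 3.0, rel=1e-12)
        assert m.stiffness_index == pytest.approx(
            math.log(1.5) / (0.2 / 3.0), rel=1e-9)
        # distensibility: 2*rel / (PP in dyn/cm^2), reported x1e-6
        assert m.distensibility == pytest.approx(
            2 * (0.2 / 3.0) / (40 * 1333.22) * 1e6, rel=1e-9)

    def test_rigid_aorta(self):
        m = aortic_mechanics(3.0, 3.0, 120, 80)
        assert m.strain == 0.0
        assert m.distensibility == 0.0
        assert math.isinf(m.stiffness_index)

    def test_systolic_smaller_than_diastolic_rejected(self):
        with pytest.raises(DomainError):
            aortic_mechanics(2.9, 3.0, 120, 80)


class TestEchoMeasurements:
    def test_direct_sv_wins_with_mismatch_warning(self):
        echo = EchoMeasurements(sap=120, dap=80, ef=0.6, pep=80, tsp=380,
                                sv=50, lvot_diameter=2.0, vti=25)
        with pytest.warns(UserWarning, match="differ by more than 20%"):
            assert echo.stroke_volume == 50

    def test_sv_derived_when_absent(self):
        echo = EchoMeasurements(sap=120, dap=80, ef=0.6, pep=80, tsp=380,
                                lvot_diameter=2.0, vti=20)
        assert echo.stroke_volume == pytest.approx(derive_sv(2.0, 20))

    def test_needs_some_volume_route(self):
        with pytest.raises(DomainError):
            EchoMeasurements(sap=120, dap=80, ef=0.6, pep=80, tsp=380)

    def test_vac_block_consistency(self):
        echo = EchoMeasurements(sap=120, dap=80, ef=0.61, pep=80, tsp=380, sv=60)
        vac = compute_vac(echo)
        assert vac.pes == pytest.approx(108.0)
        assert vac.ratio == pytest.approx(vac.ea / vac.ees, rel=1e-12)
        assert vac.uncoupled == (vac.ratio > 1)


class TestBatch:
    def test_roundtrip_columns(self, cohort405):
        out = compute_table(cohort405.head(20))
        for col in ["pes", "end_est", "ea", "ees", "ea_ees_ratio", "uncoupled"]:
            assert f"{col}_x" not in out  # appended, not duplicated
        # appended values agree with stored generator values
        np.testing.assert_allclose(out["ea"].iloc[:20],
                                   cohort405["ea"].iloc[:20], rtol=1e-10)

    def test_missing_columns_rejected(self, cohort405):
        with pytest.raises(SchemaError):
            compute_table(cohort405[["sap", "dap"]])
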