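import numpy as np
import pytest

from pdlmech.constitutive import (
    MaterialParams,
    StressStrainCurve,
    cauchy_stress_uniaxial,
    curve_predict,
    energy_diagnostics,
    exponents,
    pressure_term,
    strain_energy,
)
from pdlmech.synthetic import preset_by_name
from pdlmech.tensor_oracle import cauchy_via_finite_difference

from conftest import random_params

# frozen from the finite-difference oracle (independent route, step 1e-6)
NECK_CENTRAL_SIGMA_AT_1p15 = 0.5493137569192004


class TestMaterialParams:
    def test_matrix_fraction_defaults_to_complement(self):
        p = MaterialParams(1, 1, 1, 1, 1, 1, Vf=0.6)
        assert p.Vm == pytest.approx(0.4)

    def test_inconsistent_fractions_rejected(self):
        with pytest.raises(ValueError):
            MaterialParams(1, 1, 1, 1, 1, 1, Vf=0.6, Vm=0.6)

    @pytest.mark.parametrize("vf", [-0.1, 1.1])
    def test_fraction_bounds(self, vf):
        with pytest.raises(ValueError):
            MaterialParams(1, 1, 1, 1, 1, 1, Vf=vf)


class TestExponents:
    def test_zero_at_rest(self, param_rng):
        for _ in range(20):
            p = random_params(param_rng)
            assert exponents(1.0, p) == (0.0, 0.0)

    def test_zero_coefficients(self):
        p = MaterialParams(3.0, 4.0, 0, 0, 0, 0, Vf=0.5)
        assert exponents(1.37, p) == (0.0, 0.0)

    def test_matrix_exponent_value(self):
        p = MaterialParams(1, 1, c3=1.0, c4=0.0, c5=0.0, c6=0.0, Vf=0.5)
        i1m3 = 1.1**2 + 2 / 1.1 - 3
        assert exponents(1.1, p)[0] == pytest.approx(i1m3**2, rel=1e-12)
        assert exponents(1.1, p)[0] == pytest.approx(7.9421e-4, rel=1e-4)

    def test_overflow_guard_names_stretch(self):
        p = MaterialParams(1, 1, c3=1e6, c4=0, c5=0, c6=0, Vf=0.5)
        with pytest.raises(OverflowError, match="Q1"):
            exponents(3.0, p)


class TestStrainEnergy:
    def test_zero_at_rest(self, mixed_params):
        assert strain_energy(1.0, mixed_params) == 0.0

    def test_constant_energy_for_zero_exponents(self):
        p = MaterialParams(5.0, -2.0, 0, 0, 0, 0, Vf=0.3)
        assert strain_energy(1.2, p) == 0.0

    def test_mixed_phase_value(self, mixed_params):
        # e^{Q} - 1 with Q = (I1(1.1) - 3)^2 for both phases
        q = (1.1**2 + 2 / 1.1 - 3) ** 2
        assert strain_energy(1.1, mixed_params) == pytest.approx(
            np.expm1(q), rel=1e-12
        )
        assert strain_energy(1.1, mixed_params) == pytest.approx(7.9452e-4, rel=1e-4)


class TestPressure:
    def test_zero_at_rest(self, mixed_params):
        assert pressure_term(1.0, mixed_params) == 0.0

    def test_zero_when_isotropic_exponents_vanish(self):
        p = MaterialParams(2.0, 3.0, c3=0.0, c4=5.0, c5=0.0, c6=-1.0, Vf=0.4)
        for lam in (1.05, 1.1, 1.2):
            assert pressure_term(lam, p) == 0.0

    def test_mixed_phase_value(self, mixed_params):
        i1m3 = 1.1**2 + 2 / 1.1 - 3
        expected = 4.0 * i1m3 * np.exp(i1m3**2) / 1.1
        assert pressure_term(1.1, mixed_params) == pytest.approx(expected, rel=1e-12)


class TestCauchyStress:
    def test_stress_free_reference_state(self, param_rng):
        """σ11(1) = 0 for any parameter set: the rest state carries no stress."""
        for _ in range(200):
            p = random_params(param_rng)
            assert cauchy_stress_uniaxial(1.0, p) == 0.0

    def test_constant_energy_gives_zero_stress(self):
        p = MaterialParams(9.0, -4.0, 0, 0, 0, 0, Vf=0.7)
        assert cauchy_stress_uniaxial(1.2, p) == 0.0

    def test_mixed_phase_value_matches_energy_derivative(self, mixed_params):
        sigma = cauchy_stress_uniaxial(1.1, mixed_params)
        assert sigma == pytest.approx(0.033950, abs=5e-6)
        fd = cauchy_via_finite_difference(1.1, mixed_params)
        assert sigma == pytest.approx(fd, rel=1e-6)

    def test_regression_neck_central(self):
        p = preset_by_name("neck_central").params
        assert cauchy_stress_uniaxial(1.15, p) == pytest.approx(
            NECK_CENTRAL_SIGMA_AT_1p15, rel=1e-9
        )

    def test_phase_swap_symmetry(self, param_rng):
        """Matrix and fiber enter the stress symmetrically: swapping
        (c1,c3,c4,Vm) with (c2,c5,c6,Vf) leaves σ11 unchanged."""
        for _ in range(50):
            p = random_params(param_rng)
            lam = param_rng.uniform(1.0, 1.25)
            assert cauchy_stress_uniaxial(lam, p) == pytest.approx(
                cauchy_stress_uniaxial(lam, p.swapped_phases()), rel=1e-12, abs=1e-15
            )

    @pytest.mark.parametrize("vf", [0.0, 1.0])
    def test_degenerate_phase_limits(self, vf):
        p = MaterialParams(2.0, 3.0, 1.5, -0.5, 0.8, 2.0, Vf=vf)
        lam = 1.12
        i1m3 = lam**2 + 2 / lam - 3
        if vf == 0.0:  # pure matrix
            q1 = p.c3 * i1m3**2 + p.c4 * (lam - 1) ** 4
            expected = (lam**2 - 1 / lam) * 4 * p.c1 * np.exp(q1) * p.c3 * i1m3 + (
                4 * p.c4 * lam * (lam - 1) ** 3 * p.c1 * np.exp(q1)
            )
        else:  # pure fiber
            q2 = p.c5 * i1m3**2 + p.c6 * (lam - 1) ** 4
            expected = (lam**2 - 1 / lam) * 4 * p.c2 * np.exp(q2) * p.c5 * i1m3 + (
                4 * p.c6 * lam * (lam - 1) ** 3 * p.c2 * np.exp(q2)
            )
        assert cauchy_stress_uniaxial(lam, p) == pytest.approx(expected, rel=1e-12)


class TestCurvePredict:
    def test_rest_point_only(self, mixed_params):
        curve = curve_predict([1.0], mixed_params)
        np.testing.assert_array_equal(curve.stress, [0.0])

    def test_zero_exponents_flat(self):
        p = MaterialParams(5.0, 5.0, 0, 0, 0, 0, Vf=0.5)
        curve = curve_predict([1.0, 1.1, 1.2], p)
        np.testing.assert_array_equal(curve.stress, np.zeros(3))

    def test_elementwise_matches_scalar(self, mixed_params):
        curve = curve_predict([1.0, 1.1], mixed_params)
        assert curve.stress[0] == 0.0
        assert curve.stress[1] == pytest.approx(
            cauchy_stress_uniaxial(1.1, mixed_params), rel=1e-15
        )


class TestStressStrainCurve:
    def test_rejects_non_monotone(self):
        with pytest.raises(ValueError, match="increasing"):
            StressStrainCurve(stretch=[1.0, 1.2, 1.1], stress=[0, 1, 2])

    def test_rejects_substretch_start(self):
        with pytest.raises(ValueError, match=">= 1"):
            StressStrainCurve(stretch=[0.9, 1.1], stress=[0, 1])

    def test_rejects_empty(self):
        with pytest.raises(ValueError, match="empty"):
            StressStrainCurve(stretch=[], stress=[])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            StressStrainCurve(stretch=[1.0, 1.1], stress=[0.0])


def test_energy_diagnostics_flags_negative_energy():
    # a negative matrix stress-scale can produce W < 0 off the rest state
    p = MaterialParams(-7.13, 3.5, 40.93, 5.0, 2.0, 1.0, Vf=0.60312)
    report = energy_diagnostics(p)
    assert 0.0 <= report["negative_fraction"] <= 1.0
    assert report["n_grid"] == 101
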