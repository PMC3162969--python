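"""Unit and property tests of the GOH constitutive model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

import gelmech as g
from gelmech.errors import DomainError, FiberOverflowError
from gelmech.goh import biaxial_stress

from conftest import fd_biaxial_stress, random_admissible_draw


class TestKappaFromDensity:
    def test_uniform_density_is_isotropic_third(self):
        kappa = g.kappa_from_density(g.OrientationDensity.uniform())
        assert kappa == pytest.approx(1.0 / 3.0, abs=1e-9)

    @pytest.mark.parametrize("theta0, expected", [
        (math.pi / 2, 0.5),            # all fibers transverse to the mean axis
        (math.pi / 4, 0.25),           # sin^2(theta0)/2 closed form for a peak
        (0.02, math.sin(0.02) ** 2 / 2),  # near-perfect alignment -> ~0
    ])
    def test_narrow_peak_matches_delta_closed_form(self, theta0, expected):
        # normalized Gaussian peak of width s as a delta surrogate
        s = 0.005

        def bump(t, t0=theta0):
            return math.exp(-((t - t0) ** 2) / (2 * s * s))

        norm = 2.0 / quad(
            lambda t: bump(t) * math.sin(t), 0, math.pi, points=[theta0], limit=200
        )[0]
        rho = g.OrientationDensity(lambda t: norm * bump(t), quad_points=(theta0,))
        assert g.kappa_from_density(rho) == pytest.approx(expected, abs=1e-3)

    def test_unnormalized_density_rejected(self):
        with pytest.raises(DomainError, match="not normalized"):
            g.kappa_from_density(g.OrientationDensity(lambda t: 2.0))

    def test_negative_density_rejected(self):
        with pytest.raises(DomainError, match="non-negative"):
            g.kappa_from_density(g.OrientationDensity(lambda t: math.cos(t)))

    def test_any_valid_density_lies_in_bounds(self, rng):
        # mixture densities rho(t) = a + b*cos^2(t), renormalized
        from scipy.integrate import quad

        for _ in range(10):
            a, b = rng.uniform(0.1, 2.0, size=2)

            def rho(t, a=a, b=b):
                return a + b * math.cos(t) ** 2

            norm = 2.0 / quad(lambda t: rho(t) * math.sin(t), 0, math.pi)[0]
            kappa = g.kappa_from_density(g.OrientationDensity(lambda t: norm * rho(t)))
            assert 0.0 <= kappa <= 0.5


class TestFiberState:
    def test_identity_state_is_unstrained(self, scenario_params):
        state = g.fiber_state(scenario_params["aligned_0.03"], g.PlanarDeformation.identity())
        assert state.I1_bar == pytest.approx(3.0)
        assert state.I4_bar == pytest.approx([1.0, 1.0])
        assert state.E_bar == pytest.approx([0.0, 0.0])
        assert not state.active.any()

    @pytest.mark.parametrize("gamma", [0.0, 20.0, 45.0, 90.0])
    def test_equibiaxial_fiber_stretch_is_lambda_squared(self, gamma):
        params = g.MaterialParams(C10=1.0, k1=10.0, k2=5.0, gamma_deg=gamma, kappa=0.2)
        lam = 1.07
        state = g.fiber_state(params, g.PlanarDeformation.equibiaxial(lam))
        assert state.I4_bar == pytest.approx([lam**2, lam**2], rel=1e-14)

    def test_aligned_no_dispersion_matches_direct_substitution(self):
        # gamma = 0, kappa = 0: E = I4 - 1 = lambda_x^2 - 1
        params = g.MaterialParams(C10=1.0, k1=10.0, k2=5.0, gamma_deg=0.0, kappa=0.0)
        state = g.fiber_state(params, g.PlanarDeformation(1.05, 1.00))
        assert state.E_bar == pytest.approx([0.1025, 0.1025], abs=1e-12)

    def test_matches_brute_force_tensor_computation(self, rng):
        for _ in range(20):
            params, lx, ly = random_admissible_draw(rng)
            state = g.fiber_state(params, g.PlanarDeformation(lx, ly))
            # independent tensor route
            lz = 1.0 / (lx * ly)
            F = np.diag([lx, ly, lz])
            C = F.T @ F
            gam = math.radians(params.gamma_deg)
            for fam, sign in enumerate((1.0, -1.0)):
                a0 = np.array([math.cos(gam), sign * math.sin(gam), 0.0])
                I4 = a0 @ C @ a0
                E = params.kappa * (np.trace(C) - 3.0) + (1 - 3 * params.kappa) * (I4 - 1.0)
                assert state.I4_bar[fam] == pytest.approx(I4, rel=1e-13)
                assert state.E_bar[fam] == pytest.approx(E, rel=1e-12, abs=1e-14)


class TestStrainEnergy:
    def test_identity_energy_is_zero(self, scenario_params):
        for p in scenario_params.values():
            assert g.strain_energy(p, g.PlanarDeformation.identity()) == 0.0

    @pytest.mark.parametrize("lam", [1.01, 1.05, 1.2])
    def test_neo_hookean_closed_form(self, lam):
        params = g.MaterialParams(C10=7.3)
        expected = 7.3 * (2 * lam**2 + lam**-4 - 3)
        got = g.strain_energy(params, g.PlanarDeformation.equibiaxial(lam))
        assert got == pytest.approx(expected, rel=1e-14)

    def test_brute_force_oracle_published_params(self, scenario_params):
        # independent scalar-arithmetic evaluation of the energy density
        p = scenario_params["nonaligned_0.03"]
        lam = 1.05
        lz = 1.0 / lam**2
        I1 = 2 * lam**2 + lz**2
        gam = math.radians(p.gamma_deg)
        U_oracle = p.C10 * (I1 - 3.0)
        for sign in (1.0, -1.0):
            I4 = lam**2 * math.cos(gam) ** 2 + lam**2 * (sign * math.sin(gam)) ** 2
            E = p.kappa * (I1 - 3) + (1 - 3 * p.kappa) * (I4 - 1)
            U_oracle += p.k1 / (2 * p.k2) * (math.exp(p.k2 * max(E, 0.0) ** 2) - 1.0)
        got = g.strain_energy(p, g.PlanarDeformation.equibiaxial(lam))
        assert got == pytest.approx(U_oracle, rel=1e-13)

    def test_overflow_guard_names_family(self):
        params = g.MaterialParams(C10=1.0, k1=100.0, k2=2000.0, gamma_deg=0.0, kappa=0.0)
        with pytest.raises(FiberOverflowError, match="family"):
            g.strain_energy(params, g.PlanarDeformation(1.4, 1.0))


class TestCauchyStress:
    def test_unloaded_state_is_stress_free(self, scenario_params):
        for p in scenario_params.values():
            sxx, syy = g.cauchy_stress_biaxial(p, 1.0, 1.0)
            assert sxx == 0.0 and syy == 0.0

    @pytest.mark.parametrize("lam", [1.02, 1.1, 1.3])
    def test_neo_hookean_equibiaxial_closed_form(self, lam):
        params = g.MaterialParams(C10=5.0)
        expected = 2 * 5.0 * (lam**2 - lam**-4)
        sxx, syy = g.cauchy_stress_biaxial(params, lam, lam)
        assert sxx == pytest.approx(expected, rel=1e-14)
        assert syy == pytest.approx(expected, rel=1e-14)

    def test_isotropic_kappa_removes_direction_dependence(self, rng):
        # kappa = 1/3 kills the (1 - 3 kappa) term: equibiaxial stress is
        # axis-symmetric for any fiber angle, to machine precision
        for gamma in rng.uniform(0.0, 90.0, size=100):
            params = g.MaterialParams(C10=2.0, k1=500.0, k2=50.0,
                                      gamma_deg=float(gamma), kappa=1.0 / 3.0)
            sxx, syy = g.cauchy_stress_biaxial(params, 1.06, 1.06)
            assert sxx == pytest.approx(syy, rel=1e-14)

    def test_tensor_and_vectorized_routes_agree(self, rng):
        for _ in range(25):
            params, lx, ly = random_admissible_draw(rng)
            sxx, syy = g.cauchy_stress_biaxial(params, lx, ly)
            sigma = g.cauchy_stress(params, g.PlanarDeformation(lx, ly))
            assert sxx == pytest.approx(sigma[0, 0], rel=1e-12, abs=1e-12)
            assert syy == pytest.approx(sigma[1, 1], rel=1e-12, abs=1e-12)
            assert sigma[0, 1] == pytest.approx(0.0, abs=1e-12)
            assert sigma[2, 2] == 0.0

    def test_stress_is_energy_derivative(self, rng):
        # analytic stresses vs the finite-difference oracle under the
        # incompressibility constraint
        for _ in range(40):
            params, lx, ly = random_admissible_draw(rng)
            sxx, syy = g.cauchy_stress_biaxial(params, lx, ly)
            fxx, fyy = fd_biaxial_stress(params, lx, ly)
            scale = max(abs(sxx), abs(syy), 1.0)
            assert abs(sxx - fxx) <= 1e-6 * scale
            assert abs(syy - fyy) <= 1e-6 * scale

    def test_compressed_fibers_carry_no_load(self):
        # x-aligned fibers (gamma = 0, kappa = 0) see E = lambda_x^2 - 1 <= 0
        # when only y is stretched: the fiber term must not contribute
        fiber = g.MaterialParams(C10=3.0, k1=1000.0, k2=100.0, gamma_deg=0.0, kappa=0.0)
        matrix = g.MaterialParams(C10=3.0)
        for lx, ly in [(1.0, 1.05), (0.97, 1.08), (1.0, 1.2)]:
            assert g.cauchy_stress_biaxial(fiber, lx, ly) == pytest.approx(
                g.cauchy_stress_biaxial(matrix, lx, ly), rel=1e-14
            )


class TestEquibiaxialCurve:
    def test_single_point_grid_gives_zero_row(self, scenario_params):
        cx, cy = g.equibiaxial_curve(scenario_params["nonaligned_0.1"], [1.0])
        assert len(cx) == 1 and cx.strain[0] == 0.0 and cx.stress_kPa[0] == 0.0
        assert cy.stress_kPa[0] == 0.0

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(DomainError, match="increasing"):
            g.equibiaxial_curve(g.MaterialParams(C10=1.0), [1.0, 1.05, 1.02])
        with pytest.raises(DomainError, match="start at 1"):
            g.equibiaxial_curve(g.MaterialParams(C10=1.0), [1.01, 1.05])

    def test_neo_hookean_matches_closed_form_on_grid(self):
        grid = np.linspace(1.0, 1.3, 12)
        cx, _ = g.equibiaxial_curve(g.MaterialParams(C10=4.0), grid)
        np.testing.assert_allclose(cx.stress_kPa, 8.0 * (grid**2 - grid**-4), rtol=1e-14)

    def test_aligned_gels_are_stiffer_along_the_fibers(self, scenario_params):
        grid = np.linspace(1.0, 1.06, 30)
        for name in ("aligned_0.03", "aligned_0.1", "aligned_0.25"):
            cx, cy = g.equibiaxial_curve(scenario_params[name], grid)
            assert np.all(cx.stress_kPa[1:] > cy.stress_kPa[1:])


class TestSimpleShearAndModuli:
    def test_zero_shear_zero_stress(self, scenario_params):
        assert g.simple_shear_stress(scenario_params["aligned_0.1"], 0.0) == 0.0

    @given(st.floats(min_value=-0.5, max_value=0.5))
    def test_neo_hookean_shear_is_linear(self, s):
        assert g.simple_shear_stress(g.MaterialParams(C10=0.5), s) == pytest.approx(
            2 * 0.5 * s, rel=1e-12, abs=1e-15
        )

    @given(st.floats(min_value=1e-3, max_value=0.4))
    def test_isotropic_shear_antisymmetry(self, s):
        params = g.MaterialParams(C10=2.0, k1=300.0, k2=20.0, gamma_deg=30.0,
                                  kappa=1.0 / 3.0)
        assert g.simple_shear_stress(params, -s) == pytest.approx(
            -g.simple_shear_stress(params, s), rel=1e-10
        )

    def test_shear_bound_enforced(self):
        with pytest.raises(DomainError, match="shear"):
            g.simple_shear_stress(g.MaterialParams(C10=1.0), 1.5)

    def test_neo_hookean_moduli_closed_form(self):
        E0, G0 = g.small_strain_moduli(g.MaterialParams(C10=0.5))
        assert G0 == pytest.approx(1.0, rel=1e-9)       # mu = 2 C10
        assert E0 == pytest.approx(3.0, rel=1e-7)       # E = 3 mu
        assert E0 / G0 == pytest.approx(3.0, abs=1e-6)

    def test_isotropic_fiber_model_keeps_ratio_three(self):
        params = g.MaterialParams(C10=4.0, k1=2000.0, k2=100.0, gamma_deg=30.0,
                                  kappa=1.0 / 3.0)
        E0, G0 = g.small_strain_moduli(params)
        assert E0 / G0 == pytest.approx(3.0, abs=1e-4)


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(C10=0.0),
        dict(C10=1.0, k1=-1.0),
        dict(C10=1.0, k1=5.0, k2=0.0),
        dict(C10=1.0, gamma_deg=120.0),
        dict(C10=1.0, kappa=0.4),
        dict(C10=1.0, D=0.1),
        dict(C10=1.0, n_families=4),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(DomainError):
            g.MaterialParams(**kwargs)

    def test_deformation_preserves_volume(self):
        d = g.PlanarDeformation(1.3, 0.8, 0.2)
        assert d.J == pytest.approx(1.0, rel=1e-14)
        assert d.lambda_x * d.lambda_y * d.lambda_z == pytest.approx(1.0, rel=1e-14)
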