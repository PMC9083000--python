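"""Closed-form LPB field solutions: oracles and invariants.

The two load-bearing checks are independent of the implementation path:
a central-finite-difference oracle enforcing E = -dV/dcoordinate for
every geometry, and a separately derived screened-Coulomb (Yukawa)
closed form that the spherical solution must reproduce.
"""

import math

import numpy as np
import pytest

from ezmt import (
    ChargedSurface,
    CylinderField,
    DomainError,
    GeometryKind,
    PlaneField,
    SphereField,
    energy_variation,
    make_field,
    probe_energy,
    tubulin_probe,
    water_medium,
)
from ezmt.constants import CODATA
from ezmt.fields import (
    field_cylinder,
    field_plane,
    field_sphere,
    potential_cylinder,
    potential_plane,
    potential_sphere,
)
from ezmt.parameters import MT_OUTER_RADIUS, MT_SIGMA, STERN_THICKNESS, TUBULIN_SIGMA


def mt_surface():
    return ChargedSurface(kind="cylinder", R=MT_OUTER_RADIUS, d=STERN_THICKNESS,
                          sigma=MT_SIGMA)


def tubulin_sphere_surface():
    return ChargedSurface(kind="sphere", R=2.7144e-9, d=STERN_THICKNESS,
                          sigma=TUBULIN_SIGMA)


def sheet_surface():
    return ChargedSurface(kind="plane", d=STERN_THICKNESS, sigma=TUBULIN_SIGMA)


def yukawa_potential(r, surface, medium):
    """Independently derived screened-Coulomb solution for the sphere.

    V(r) = C exp(-(r-r0)/lambda)/r with C fixed by the Gauss-law
    boundary condition -dV/dr|_{r0} = sigma/(eps0 eps_r) R^2/r0^2.
    """
    lam = medium.debye_length
    r0 = surface.R + surface.d
    C = surface.sigma * surface.R**2 / (
        CODATA.epsilon_0 * medium.epsilon_r * (1.0 + r0 / lam)
    )
    return C * np.exp(-(r - r0) / lam) / r


def yukawa_field(r, surface, medium):
    lam = medium.debye_length
    r0 = surface.R + surface.d
    C = surface.sigma * surface.R**2 / (
        CODATA.epsilon_0 * medium.epsilon_r * (1.0 + r0 / lam)
    )
    return C * np.exp(-(r - r0) / lam) * (1.0 / lam + 1.0 / r) / r


class TestFiniteDifferenceOracle:
    """E must equal -dV/dcoordinate for every geometry and scenario."""

    def check(self, solution, rel_tol=1e-6):
        lam = solution.lambda_D
        h = 1e-4 * lam
        r = solution.x_min + h + np.geomspace(0.01 * lam, 10 * lam, 50)
        dV = (solution.potential(r + h) - solution.potential(r - h)) / (2 * h)
        E = solution.field(r)
        assert np.allclose(E, -dV, rtol=rel_tol)

    @pytest.mark.parametrize(
        "surface_factory", [mt_surface, tubulin_sphere_surface, sheet_surface]
    )
    @pytest.mark.parametrize("c_mM", [10.0, 160.0])
    def test_paper_surfaces(self, surface_factory, c_mM):
        self.check(make_field(surface_factory(), water_medium(c_mM)))

    def test_synthesized_scenarios(self, synthetic_scenarios):
        for sc in synthetic_scenarios:
            self.check(make_field(sc.surface, sc.medium))


class TestCylinder:
    def test_sign_and_prefactor_cancellation(self):
        sol = make_field(mt_surface(), water_medium(10))
        lam = sol.lambda_D
        r = sol.x_min + np.array([0.0, lam, 3 * lam])
        V = sol.potential(r)
        assert np.all(V < 0)  # sign follows sigma
        # prefactors cancel in ratios: V(r)/V(r') = K0(r/lam)/K0(r'/lam)
        from scipy.special import kv

        assert V[1] / V[2] == pytest.approx(
            kv(0, r[1] / lam) / kv(0, r[2] / lam), rel=1e-10
        )

    def test_contact_value_against_term_by_term_evaluation(self):
        # unscaled second Bessel implementation, term by term
        from scipy.special import kv

        surface, medium = mt_surface(), water_medium(10)
        sol = CylinderField(surface, medium)
        lam = medium.debye_length
        r0 = surface.R + surface.d
        expected = (
            surface.sigma * lam / (CODATA.epsilon_0 * medium.epsilon_r)
            * surface.R / r0 * kv(0, r0 / lam) / kv(1, r0 / lam)
        )
        assert float(sol.potential(r0)) == pytest.approx(expected, rel=1e-12)

    def test_contact_field_reduces_to_prefactor(self):
        surface, medium = mt_surface(), water_medium(10)
        sol = CylinderField(surface, medium)
        r0 = surface.R + surface.d
        expected = (
            surface.sigma / (CODATA.epsilon_0 * medium.epsilon_r) * surface.R / r0
        )
        assert float(sol.field(r0)) == pytest.approx(expected, rel=1e-12)

    def test_magnitude_strictly_decreasing(self):
        sol = make_field(mt_surface(), water_medium(10))
        r = sol.x_min + np.linspace(0, 20 * sol.lambda_D, 200)
        assert np.all(np.diff(np.abs(sol.potential(r))) < 0)
        assert np.all(np.diff(np.abs(sol.field(r))) < 0)

    def test_domain_error_inside_stern_layer(self):
        sol = make_field(mt_surface(), water_medium(10))
        with pytest.raises(DomainError):
            sol.potential(sol.x_min * 0.99)

    def test_overflow_control_far_from_surface(self):
        sol = make_field(mt_surface(), water_medium(160))
        r = sol.x_min + 650 * sol.lambda_D
        v = float(sol.potential(r))
        assert np.isfinite(v)
        assert v != 0.0

    def test_free_functions_match_class(self):
        surface, medium = mt_surface(), water_medium(10)
        sol = CylinderField(surface, medium)
        r = sol.x_min * 1.5
        assert potential_cylinder(r, surface, medium) == sol.potential(r)
        assert field_cylinder(r, surface, medium) == sol.field(r)


class TestSphere:
    @pytest.mark.parametrize("c_mM", [10.0, 160.0])
    def test_equivalent_to_yukawa_closed_form(self, c_mM):
        surface, medium = tubulin_sphere_surface(), water_medium(c_mM)
        sol = SphereField(surface, medium)
        lam = sol.lambda_D
        r = sol.x_min + np.linspace(0, 20 * lam, 300)
        assert np.allclose(sol.potential(r), yukawa_potential(r, surface, medium),
                           rtol=1e-10)
        assert np.allclose(sol.field(r), yukawa_field(r, surface, medium),
                           rtol=1e-10)

    def test_yukawa_on_synthesized_spheres(self, synthetic_scenarios):
        spheres = [sc for sc in synthetic_scenarios
                   if sc.surface.kind is GeometryKind.SPHERE]
        assert spheres, "sampler produced no spheres"
        for sc in spheres:
            sol = make_field(sc.surface, sc.medium)
            r = sol.x_min + np.linspace(0, 20 * sol.lambda_D, 64)
            assert np.allclose(sol.potential(r),
                               yukawa_potential(r, sc.surface, sc.medium),
                               rtol=1e-10)

    def test_gauss_law_boundary_condition(self):
        surface, medium = tubulin_sphere_surface(), water_medium(10)
        sol = SphereField(surface, medium)
        r0 = surface.R + surface.d
        expected = (
            surface.sigma / (CODATA.epsilon_0 * medium.epsilon_r)
            * surface.R**2 / r0**2
        )
        # field at contact is exactly the boundary value
        assert float(sol.field(r0)) == pytest.approx(expected, rel=1e-12)
        # and -dV/dr tends to it numerically
        h = 1e-6 * sol.lambda_D
        dV = (sol.potential(r0 + 2 * h) - sol.potential(r0)) / (2 * h)
        assert -float(dV) == pytest.approx(expected, rel=1e-4)

    def test_zero_charge_gives_zero_potential(self):
        surface = ChargedSurface(kind="sphere", R=2.7e-9, d=0.33e-9, sigma=0.0)
        sol = SphereField(surface, water_medium(10))
        r = sol.x_min + np.linspace(0, 5e-9, 10)
        assert np.all(np.asarray(sol.potential(r)) == 0.0)

    def test_yukawa_tail_structure(self):
        # E(r) * r * exp((r-r0)/lam) / (1/lam + 1/r) is constant (the
        # Yukawa amplitude), checked against the closed-form derivative
        surface, medium = tubulin_sphere_surface(), water_medium(10)
        sol = SphereField(surface, medium)
        lam = sol.lambda_D
        r = sol.x_min + np.linspace(5 * lam, 15 * lam, 40)
        amp = np.asarray(sol.field(r)) * r / (1 / lam + 1 / r) * np.exp(
            (r - sol.x_min) / lam
        )
        assert np.allclose(amp, amp[0], rtol=1e-9)

    def test_free_functions_match_class(self):
        surface, medium = tubulin_sphere_surface(), water_medium(10)
        sol = SphereField(surface, medium)
        r = sol.x_min * 1.2
        assert potential_sphere(r, surface, medium) == sol.potential(r)
        assert field_sphere(r, surface, medium) == sol.field(r)


class TestPlane:
    def test_contact_values_and_pure_exponential(self):
        surface, medium = sheet_surface(), water_medium(10)
        sol = PlaneField(surface, medium)
        lam = sol.lambda_D
        pref = surface.sigma / (2 * CODATA.epsilon_0 * medium.epsilon_r)
        assert float(sol.potential(surface.d)) == pytest.approx(pref * lam, rel=1e-14)
        assert float(sol.field(surface.d)) == pytest.approx(pref, rel=1e-14)
        # one Debye length out: e^-1
        assert float(sol.potential(surface.d + lam)) == pytest.approx(
            pref * lam * math.exp(-1), rel=1e-12
        )
        # E = V/lambda everywhere for a pure exponential
        x = surface.d + np.linspace(0, 10 * lam, 50)
        assert np.allclose(sol.field(x), sol.potential(x) / lam, rtol=1e-12)

    def test_debye_length_controls_decay(self):
        surface = sheet_surface()
        sol_10 = PlaneField(surface, water_medium(10))
        # quadrupling c_s halves lambda: decay at fixed x-d doubles in rate
        sol_40 = PlaneField(surface, water_medium(40))
        dx = 2e-9
        ratio_10 = float(sol_10.field(surface.d + dx) / sol_10.field(surface.d))
        ratio_40 = float(sol_40.field(surface.d + dx) / sol_40.field(surface.d))
        assert ratio_40 == pytest.approx(ratio_10**2, rel=1e-9)

    def test_free_functions_match_class(self):
        surface, medium = sheet_surface(), water_medium(160)
        sol = PlaneField(surface, medium)
        x = surface.d * 3
        assert potential_plane(x, surface, medium) == sol.potential(x)
        assert field_plane(x, surface, medium) == sol.field(x)


class TestSharedInvariants:
    @pytest.mark.parametrize(
        "surface_factory", [mt_surface, tubulin_sphere_surface, sheet_surface]
    )
    def test_vanishes_far_away(self, surface_factory):
        sol = make_field(surface_factory(), water_medium(10))
        v0 = abs(float(sol.potential(sol.x_min)))
        v_far = abs(float(sol.potential(sol.x_min + 20 * sol.lambda_D)))
        # geometry prefactors only sharpen the decay beyond e^-20
        assert v_far < v0 * math.exp(-19)

    @pytest.mark.parametrize(
        "surface_factory", [mt_surface, tubulin_sphere_surface, sheet_surface]
    )
    def test_stronger_screening_at_higher_concentration(self, surface_factory):
        surface = surface_factory()
        lo = make_field(surface, water_medium(10))
        hi = make_field(surface, water_medium(160))
        x = surface.contact_coordinate + np.linspace(1e-10, 10e-9, 30)
        assert np.all(np.abs(hi.potential(x)) < np.abs(lo.potential(x)))
        assert np.all(np.abs(hi.field(x)) < np.abs(lo.field(x)))

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CylinderField(sheet_surface(), water_medium(10))


class TestEnergy:
    def test_energy_is_charge_times_potential(self):
        probe = tubulin_probe(10)
        for factory in (mt_surface, tubulin_sphere_surface, sheet_surface):
            sol = make_field(factory(), water_medium(10))
            r = sol.x_min + np.linspace(0, 10e-9, 20)
            assert np.allclose(
                probe_energy(r, sol, probe.Q_eff),
                probe.Q_eff * np.asarray(sol.potential(r)),
                rtol=1e-14,
            )

    def test_repulsive_energy_positive_and_vanishing(self):
        sol = make_field(mt_surface(), water_medium(10))
        Q = tubulin_probe(10).Q_eff
        assert float(probe_energy(sol.x_min, sol, Q)) > 0
        assert float(probe_energy(sol.x_min + 30 * sol.lambda_D, sol, Q)) < 1e-3 * float(
            probe_energy(sol.x_min, sol, Q)
        )
        assert probe_energy(sol.x_min, sol, 0.0) == 0.0

    def test_energy_variation_properties(self):
        sol = make_field(mt_surface(), water_medium(10))
        Q = tubulin_probe(10).Q_eff
        start = sol.x_min
        assert energy_variation(start, start, sol, Q) == 0.0
        r = start + np.linspace(0, 15 * sol.lambda_D, 100)
        dU = np.asarray(energy_variation(r, start, sol, Q))
        assert np.all(np.diff(dU) < 0)  # monotone decreasing outward
        # dU(infinity) -> -U(start)
        far = start + 40 * sol.lambda_D
        assert float(energy_variation(far, start, sol, Q)) == pytest.approx(
            -float(probe_energy(start, sol, Q)), rel=1e-6
        )

    def test_linearization_warning_logged(self, caplog):
        import logging

        sol = make_field(mt_surface(), water_medium(10))
        logger = logging.getLogger("ezmt.fields")
        old_level = logger.level
        logger.setLevel(logging.WARNING)
        try:
            with caplog.at_level(logging.WARNING, logger="ezmt.fields"):
                assert sol.check_linearization() is False
            assert any("thermal voltage" in rec.message for rec in caplog.records)
        finally:
            logger.setLevel(old_level)
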