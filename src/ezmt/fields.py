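"""Closed-form linearized Poisson-Boltzmann (LPB) fields.

Solves nabla.(eps_r nabla V) = (2 e N_A c_s / eps0) sinh-linearized V for
the three geometries of interest, with a Neumann (Gauss-law) boundary
condition at the Stern boundary and V -> 0 at infinity:

* cylinder (microtubule): V(r) proportional to K0(r/lambda_D), the
  modified Bessel function of the second kind of order zero;
* sphere (tubulin dimer): half-integer-order Bessel solution, which is
  algebraically a screened-Coulomb (Yukawa) potential;
* plane (tubulin sheet): pure exponential decay.

All profiles decay on the Debye length lambda_D.  Bessel ratios are
evaluated through exponentially scaled functions so that coordinates
hundreds of Debye lengths from the surface stay finite.

The probe's electrostatic energy is U = Q_eff * V; the energy variation
along a trajectory is U(r) - U(start).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import k0e, k1e

from .constants import CODATA
from .parameters import ChargedSurface, GeometryKind, Medium, debye_length
from .units import thermal_voltage

logger = logging.getLogger(__name__)


class DomainError(ValueError):
    """Coordinate lies inside the Stern layer where the diffuse-layer
    solution is not defined."""


# -- half-integer-order modified Bessel functions, exponentially scaled ----
#
# K_{1/2}(x) = sqrt(pi/(2x)) e^{-x} and K_{3/2}(x) = K_{1/2}(x) (1 + 1/x)
# in closed form; the scaled variants below carry e^{+x} so ratios at large
# argument never overflow or underflow.


def k_half_e(x):
    """K_{1/2}(x) * e^x = sqrt(pi/(2x))."""
    return np.sqrt(np.pi / (2.0 * x))


def k_3half_e(x):
    """K_{3/2}(x) * e^x = sqrt(pi/(2x)) * (1 + 1/x)."""
    return np.sqrt(np.pi / (2.0 * x)) * (1.0 + 1.0 / x)


@dataclass(frozen=True)
class FieldSolution:
    """Base class: a solved LPB boundary-value problem.

    Subclasses implement ``potential`` (V, volts) and ``field``
    (E = -dV/dcoordinate, V/m) for coordinates at or beyond the Stern
    boundary ``x_min``.  Inputs may be scalars or arrays.
    """

    surface: ChargedSurface
    medium: Medium

    @property
    def lambda_D(self) -> float:
        """Debye screening length (m)."""
        return debye_length(self.medium)

    @property
    def x_min(self) -> float:
        """Innermost valid coordinate: R+d (cylinder/sphere) or d (plane)."""
        return self.surface.contact_coordinate

    def _check_domain(self, coord) -> np.ndarray:
        c = np.asarray(coord, dtype=float)
        # tiny negative slack absorbs roundoff from unit conversions
        if np.any(c < self.x_min * (1.0 - 1e-12)):
            raise DomainError(
                f"coordinate {np.min(c):.4e} m inside the Stern boundary "
                f"({self.x_min:.4e} m)"
            )
        return c

    def potential(self, coord):
        raise NotImplementedError

    def field(self, coord):
        raise NotImplementedError

    def energy(self, coord, Q_eff: float):
        """Probe electrostatic energy U = Q_eff * V(coord) (J).

        Positive (repulsive) when Q_eff and sigma share a sign.
        """
        return Q_eff * self.potential(coord)

    def energy_variation(self, coord, start, Q_eff: float):
        """dU(coord) = U(coord) - U(start) (J); zero at the start, negative
        and monotonically decreasing outward for repulsive scenarios."""
        return self.energy(coord, Q_eff) - self.energy(start, Q_eff)

    def contact_potential(self) -> float:
        """V at the Stern boundary (V); used for the linearization check."""
        return float(self.potential(self.x_min))

    def check_linearization(self) -> bool:
        """Log a warning when |V| at contact exceeds the thermal voltage
        k_B*T/e (~25 mV), where the linearized equation overestimates the
        magnitude of the potential.  Returns True when linearization is
        formally valid."""
        v0 = self.contact_potential()
        vt = thermal_voltage(self.medium.T)
        if abs(v0) > vt:
            logger.warning(
                "contact potential %.1f mV exceeds the thermal voltage "
                "%.1f mV: linearized PB overestimates |V| here",
                1e3 * v0, 1e3 * vt,
            )
            return False
        return True


@dataclass(frozen=True)
class CylinderField(FieldSolution):
    """Field around an infinite charged cylinder of radius R.

    V(r) = sigma*lambda_D/(eps0 eps_r) * R/(R+d) * K0(r/lambda_D)/K1((R+d)/lambda_D)
    E(r) = sigma/(eps0 eps_r)          * R/(R+d) * K1(r/lambda_D)/K1((R+d)/lambda_D)
    """

    def __post_init__(self) -> None:
        if self.surface.kind is not GeometryKind.CYLINDER:
            raise ValueError(f"CylinderField requires a cylinder surface, got {self.surface.kind}")

    def _prefactor(self) -> float:
        s, m = self.surface, self.medium
        return s.sigma / (CODATA.epsilon_0 * m.epsilon_r) * s.R / (s.R + s.d)

    def potential(self, coord):
        r = self._check_domain(coord)
        lam, r0 = self.lambda_D, self.x_min
        ratio = k0e(r / lam) / k1e(r0 / lam) * np.exp(-(r - r0) / lam)
        return self._prefactor() * lam * ratio

    def field(self, coord):
        r = self._check_domain(coord)
        lam, r0 = self.lambda_D, self.x_min
        ratio = k1e(r / lam) / k1e(r0 / lam) * np.exp(-(r - r0) / lam)
        return self._prefactor() * ratio


@dataclass(frozen=True)
class SphereField(FieldSolution):
    """Field around a charged sphere of radius R.

    V(r) = sigma/(eps0 eps_r) * R^2/(R+d)^2 * r^{-1/2} K_{1/2}(r/lambda_D) / g(R+d)
    E(r) = sigma/(eps0 eps_r) * R^2/(R+d)^2 * g(r)/g(R+d)

    with g(z) = -d/dz [ z^{-1/2} K_{1/2}(z/lambda_D) ]
              = z^{-3/2}/2 K_{1/2}(z/lambda_D)
                + z^{-1/2}/lambda_D [K_{3/2}(z/lambda_D) - lambda_D/(2z) K_{1/2}(z/lambda_D)]

    so that the Gauss-law condition -dV/dr = sigma/(eps0 eps_r) R^2/(R+d)^2
    holds exactly at r = R+d.  With the closed form of K_{1/2} this is the
    classical screened-Coulomb (Yukawa) potential.
    """

    def __post_init__(self) -> None:
        if self.surface.kind is not GeometryKind.SPHERE:
            raise ValueError(f"SphereField requires a sphere surface, got {self.surface.kind}")

    def _g_e(self, z):
        """g(z) * e^{z/lambda_D}, built from the scaled half-order Bessels."""
        lam = self.lambda_D
        x = z / lam
        return (
            0.5 * z**-1.5 * k_half_e(x)
            + z**-0.5 / lam * (k_3half_e(x) - (lam / (2.0 * z)) * k_half_e(x))
        )

    def _boundary_field(self) -> float:
        s, m = self.surface, self.medium
        return s.sigma / (CODATA.epsilon_0 * m.epsilon_r) * s.R**2 / (s.R + s.d) ** 2

    def potential(self, coord):
        r = self._check_domain(coord)
        lam, r0 = self.lambda_D, self.x_min
        num = r**-0.5 * k_half_e(r / lam) * np.exp(-(r - r0) / lam)
        return self._boundary_field() * num / self._g_e(r0)

    def field(self, coord):
        r = self._check_domain(coord)
        r0 = self.x_min
        return (
            self._boundary_field()
            * self._g_e(r) / self._g_e(r0)
            * np.exp(-(r - r0) / self.lambda_D)
        )


@dataclass(frozen=True)
class PlaneField(FieldSolution):
    """Field above an infinite charged plane.

    V(x) = sigma*lambda_D/(2 eps0 eps_r) * exp(-(x-d)/lambda_D)
    E(x) = sigma/(2 eps0 eps_r)          * exp(-(x-d)/lambda_D)
    """

    def __post_init__(self) -> None:
        if self.surface.kind is not GeometryKind.PLANE:
            raise ValueError(f"PlaneField requires a plane surface, got {self.surface.kind}")

    def _prefactor(self) -> float:
        return self.surface.sigma / (2.0 * CODATA.epsilon_0 * self.medium.epsilon_r)

    def potential(self, coord):
        x = self._check_domain(coord)
        lam = self.lambda_D
        return self._prefactor() * lam * np.exp(-(x - self.x_min) / lam)

    def field(self, coord):
        x = self._check_domain(coord)
        return self._prefactor() * np.exp(-(x - self.x_min) / self.lambda_D)


_FIELD_CLASSES = {
    GeometryKind.CYLINDER: CylinderField,
    GeometryKind.SPHERE: SphereField,
    GeometryKind.PLANE: PlaneField,
}


def make_field(surface: ChargedSurface, medium: Medium) -> FieldSolution:
    """Construct the LPB solution matching the surface geometry."""
    return _FIELD_CLASSES[GeometryKind(surface.kind)](surface, medium)


# -- free-function conveniences -------------------------------------------


def potential_cylinder(r, surface: ChargedSurface, medium: Medium):
    return CylinderField(surface, medium).potential(r)


def field_cylinder(r, surface: ChargedSurface, medium: Medium):
    return CylinderField(surface, medium).field(r)


def potential_sphere(r, surface: ChargedSurface, medium: Medium):
    return SphereField(surface, medium).potential(r)


def field_sphere(r, surface: ChargedSurface, medium: Medium):
    return SphereField(surface, medium).field(r)


def potential_plane(x, surface: ChargedSurface, medium: Medium):
    return PlaneField(surface, medium).potential(x)


def field_plane(x, surface: ChargedSurface, medium: Medium):
    return PlaneField(surface, medium).field(x)


def probe_energy(coord, solution: FieldSolution, Q_eff: float):
    """U = Q_eff * V(coord) (J)."""
    return solution.energy(coord, Q_eff)


def energy_variation(coord, start, solution: FieldSolution, Q_eff: float):
    """dU = U(coord) - U(start) (J)."""
    return solution.energy_variation(coord, start, Q_eff)
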