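"""Physical parameters of the exclusion-zone model.

Defines the electrolyte medium, the charged repelling surface (microtubule
cylinder, tubulin sphere or tubulin sheet), the repelled tubulin-dimer
probe, and the scenario bundle that ties them together, plus the small
closed-form derived quantities: Debye screening length, surface charge
densities, Stokes friction and the volume-equivalent sphere radius.

Everything is SI internally; see :mod:`ezmt.units` for the conversions
used at the config/report boundary.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

from .constants import CODATA
from . import units


class ParameterError(ValueError):
    """A physical parameter is outside its valid range."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Medium:
    """Electrolyte/solvent state.

    Parameters
    ----------
    epsilon_r : float
        Relative permittivity (dimensionless, > 1). Water: 78.3.
    T : float
        Absolute temperature (K).
    eta : float
        Dynamic viscosity (Pa s). Water: 1e-3.
    c_s : float
        Ionic concentration of the monovalent symmetric salt (mol/m^3;
        numerically equal to mM).
    """

    epsilon_r: float
    T: float
    eta: float
    c_s: float

    def __post_init__(self) -> None:
        if not self.epsilon_r > 1:
            raise ParameterError(f"epsilon_r must exceed 1, got {self.epsilon_r}")
        if not self.T > 0:
            raise ParameterError(f"T must be positive, got {self.T}")
        if not self.eta > 0:
            raise ParameterError(f"eta must be positive, got {self.eta}")
        if not self.c_s > 0:
            raise ParameterError(f"c_s must be positive, got {self.c_s}")

    @property
    def debye_length(self) -> float:
        """Debye screening length (m)."""
        return debye_length(self)

    @property
    def thermal_energy(self) -> float:
        """k_B*T (J)."""
        return units.thermal_energy(self.T)


class GeometryKind(str, enum.Enum):
    """Shape of the repelling body."""

    CYLINDER = "cylinder"
    SPHERE = "sphere"
    PLANE = "plane"


@dataclass(frozen=True)
class ChargedSurface:
    """The repelling body: geometry, size, Stern layer and charge.

    Parameters
    ----------
    kind : GeometryKind
        cylinder (microtubule), sphere (tubulin dimer) or plane (sheet).
    R : float or None
        Body radius (m); required for cylinder and sphere, ignored for the
        plane.
    d : float
        Stern-layer thickness (m) — one adsorbed-counterion radius offset
        before the diffuse-layer solution applies.
    sigma : float
        Surface charge density (C/m^2); negative for all tubulin surfaces.
    """

    kind: GeometryKind
    d: float
    sigma: float
    R: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", GeometryKind(self.kind))
        if self.kind is not GeometryKind.PLANE:
            if self.R is None or not self.R > 0:
                raise ParameterError(
                    f"{self.kind.value} surface requires R > 0, got {self.R}"
                )
        if not self.d > 0:
            raise ParameterError(f"Stern-layer thickness d must be positive, got {self.d}")

    @property
    def contact_coordinate(self) -> float:
        """Innermost coordinate where the diffuse-layer field is defined:
        r = R + d for cylinder/sphere, x = d for the plane."""
        if self.kind is GeometryKind.PLANE:
            return self.d
        return self.R + self.d  # type: ignore[operator]


@dataclass(frozen=True)
class Probe:
    """The repelled tubulin-dimer probe, modelled as a charged sphere.

    Parameters
    ----------
    a : float
        Effective sphere radius (m).
    Q_bare : float
        Bare (structural) charge (C).
    Q_eff : float
        Effective charge after counterion condensation (C);
        |Q_eff| <= |Q_bare|.
    m : float
        Mass (kg).
    """

    a: float
    Q_bare: float
    Q_eff: float
    m: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ParameterError(f"probe radius a must be positive, got {self.a}")
        if not self.m > 0:
            raise ParameterError(f"probe mass m must be positive, got {self.m}")
        if abs(self.Q_eff) > abs(self.Q_bare) * (1 + 1e-12):
            raise ParameterError(
                "effective charge cannot exceed the bare charge in magnitude: "
                f"|{self.Q_eff}| > |{self.Q_bare}|"
            )


@dataclass(frozen=True)
class MTSurfaceChargeBudget:
    """Area-weighted budget for the microtubule's surface charge density.

    The outer wall and the protruding C-termini contribute separately:
    sigma = sigma_out * A_out/A_tot + sigma_CT * 2*A_CT/A_tot.
    The area model is left open (A_out + 2*A_CT need not equal A_tot).
    """

    sigma_out: float
    sigma_CT: float
    A_out: float
    A_CT: float
    A_tot: float

    def __post_init__(self) -> None:
        if not (self.A_out > 0 and self.A_CT > 0 and self.A_tot > 0):
            raise ParameterError("all areas in the charge budget must be positive")


class StartRule(str, enum.Enum):
    """Initial probe position relative to the surface.

    stern_contact: the probe starts at the Stern boundary (r0 = R+d, or
    x0 = d for the plane) — a dimer detaching from the surface.
    probe_contact: the probe's centre starts one probe radius away
    (r0 = R+a, or x0 = a) — a dimer resting against the wall.
    """

    STERN_CONTACT = "stern_contact"
    PROBE_CONTACT = "probe_contact"


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: surface + medium + probe + initial rule.

    The initial velocity is always zero; ``t_max`` is the time horizon (s).
    """

    surface: ChargedSurface
    medium: Medium
    probe: Probe
    start_rule: StartRule
    t_max: float
    scenario_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_rule", StartRule(self.start_rule))
        if not self.t_max > 0:
            raise ParameterError(f"t_max must be positive, got {self.t_max}")
        if self.start_position < self.surface.contact_coordinate - 1e-30:
            raise ParameterError("start position lies inside the Stern layer")

    @property
    def start_position(self) -> float:
        """Initial coordinate (m) implied by the start rule."""
        if self.start_rule is StartRule.STERN_CONTACT:
            return self.surface.contact_coordinate
        if self.surface.kind is GeometryKind.PLANE:
            return self.probe.a
        return self.surface.R + self.probe.a  # type: ignore[operator]

    @property
    def friction_coefficient(self) -> float:
        """Stokes drag coefficient xi = 6*pi*eta*a (kg/s)."""
        return friction_coefficient(self.medium, self.probe)

    def with_(self, **changes) -> "Scenario":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def debye_length(medium: Medium) -> float:
    """Debye screening length of a monovalent symmetric electrolyte (m).

    lambda_D = sqrt(eps0 * eps_r * k_B * T / (2 * N_A * c_s * e^2));
    scales as c_s^(-1/2). About 3 nm at 10 mM and 7.5 Å at 160 mM in
    water at 20 °C.
    """
    c = CODATA
    return math.sqrt(
        c.epsilon_0 * medium.epsilon_r * c.k_B * medium.T
        / (2.0 * c.N_A * medium.c_s * c.e**2)
    )


def sphere_surface_charge(Q_bare: float, R: float) -> float:
    """Uniform surface charge density of a sphere, sigma = Q/(4*pi*R^2).

    Parameters in SI (C, m); the sign of sigma follows the sign of Q_bare.
    """
    if not R > 0:
        raise ParameterError(f"sphere radius must be positive, got {R}")
    return Q_bare / (4.0 * math.pi * R**2)


def mt_surface_charge(budget: MTSurfaceChargeBudget) -> float:
    """Area-weighted microtubule surface charge density (C/m^2).

    Combines the outer-wall contribution and the two C-termini per dimer:
    sigma_out*A_out/A_tot + sigma_CT*2*A_CT/A_tot.  The canonical value
    for the microtubule cylinder, ``MT_SIGMA`` = -0.102 C/m^2, is stored
    as a constant because the published area model does not tabulate the
    individual areas; this function serves users supplying their own
    budget.
    """
    return (
        budget.sigma_out * budget.A_out / budget.A_tot
        + budget.sigma_CT * 2.0 * budget.A_CT / budget.A_tot
    )


def equivalent_sphere_radius(s1: float, s2: float, s3: float) -> float:
    """Radius of the sphere with the same volume as an ellipsoid with
    semi-axes s1, s2, s3: the geometric mean (s1*s2*s3)^(1/3)."""
    if not (s1 > 0 and s2 > 0 and s3 > 0):
        raise ParameterError(f"semi-axes must be positive, got {(s1, s2, s3)}")
    return (s1 * s2 * s3) ** (1.0 / 3.0)


def friction_coefficient(medium: Medium, probe: Probe) -> float:
    """Stokes drag coefficient xi = 6*pi*eta*a (kg/s) of a sphere of
    radius a in a fluid of viscosity eta."""
    return 6.0 * math.pi * medium.eta * probe.a


# ---------------------------------------------------------------------------
# canonical tubulin / microtubule values
# ---------------------------------------------------------------------------

#: Microtubule external radius (m): 13 protofilaments, outer wall at 12.5 nm.
MT_OUTER_RADIUS = 12.5e-9

#: Stern-layer thickness (m): one K+ ionic radius, 0.33 nm, used for all
#: three geometries.
STERN_THICKNESS = 0.33e-9

#: Microtubule surface charge density (C/m^2), area-weighted combination of
#: the outer wall (-25 e) and the two C-termini (-11 e each) per dimer.
MT_SIGMA = -0.102

#: Tubulin-dimer bare charge at pH 7 (units of e).
TUBULIN_BARE_CHARGE_E = -52.0

#: Ellipsoid semi-axes of the tubulin dimer (m).
TUBULIN_SEMI_AXES = (2.0e-9, 2.5e-9, 4.0e-9)

#: Volume-equivalent sphere radius of the dimer (m), ~2.71 nm.
TUBULIN_RADIUS = equivalent_sphere_radius(*TUBULIN_SEMI_AXES)

#: Uniform surface charge density of the spherical dimer and of the tubulin
#: sheet (C/m^2), ~-0.090.
TUBULIN_SIGMA = sphere_surface_charge(
    units.e_to_coulomb(TUBULIN_BARE_CHARGE_E), TUBULIN_RADIUS
)

#: Tubulin-dimer mass (kg), ~110 kDa. The overdamped dynamics are
#: insensitive to this value.
TUBULIN_MASS = units.kda_to_kg(110.0)

#: Effective (counterion-corrected) dimer charge per KCl concentration,
#: in units of e: -17 e at 10 mM, -29 e at 160 mM.
Q_EFF_E_BY_MM = {10.0: -17.0, 160.0: -29.0}


def water_medium(c_mM: float, *, epsilon_r: float = 78.3, T: float = 293.15,
                 eta: float = 1e-3) -> Medium:
    """Water at 20 °C with a KCl concentration given in mM."""
    return Medium(epsilon_r=epsilon_r, T=T, eta=eta, c_s=units.mM_to_si(c_mM))


def tubulin_probe(c_mM: float) -> Probe:
    """The standard tubulin-dimer probe at a given KCl concentration.

    The effective charge interpolates nothing: only the two tabulated
    concentrations (10 and 160 mM) are supported.
    """
    try:
        q_eff_e = Q_EFF_E_BY_MM[float(c_mM)]
    except KeyError:
        raise ParameterError(
            f"no tabulated effective charge at {c_mM} mM; "
            f"known concentrations: {sorted(Q_EFF_E_BY_MM)}"
        ) from None
    return Probe(
        a=TUBULIN_RADIUS,
        Q_bare=units.e_to_coulomb(TUBULIN_BARE_CHARGE_E),
        Q_eff=units.e_to_coulomb(q_eff_e),
        m=TUBULIN_MASS,
    )
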