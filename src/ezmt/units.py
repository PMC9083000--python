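"""Hand-rolled unit conversions.

All model code works in SI internally (m, s, kg, C, V, J).  Config files
and reports use the field's customary units: lengths in nm or Å, charges
in units of the elementary charge e, concentrations in mM, times in µs,
energies in units of k_B*T.  These helpers are the only place conversions
happen, so round-trips are exact to floating precision.
"""

from __future__ import annotations

from .constants import CODATA

NM = 1e-9        # m per nm
ANGSTROM = 1e-10  # m per Å
US = 1e-6        # s per µs

# 1 mM of a solute = 1 mol/m^3: the two units are numerically identical.
MM_TO_MOL_PER_M3 = 1.0


def nm_to_m(x_nm: float) -> float:
    return x_nm * NM


def m_to_nm(x_m: float):
    return x_m / NM


def m_to_angstrom(x_m: float):
    return x_m / ANGSTROM


def us_to_s(t_us: float) -> float:
    return t_us * US


def s_to_us(t_s: float):
    return t_s / US


def e_to_coulomb(q_e: float) -> float:
    """Charge in units of the elementary charge -> coulombs."""
    return q_e * CODATA.e


def coulomb_to_e(q_c: float) -> float:
    return q_c / CODATA.e


def mM_to_si(c_mM: float) -> float:
    """Concentration in mM -> mol/m^3 (numerically the identity)."""
    return c_mM * MM_TO_MOL_PER_M3


def si_to_mM(c_si: float) -> float:
    return c_si / MM_TO_MOL_PER_M3


def kda_to_kg(m_kda: float) -> float:
    """Molecular mass in kDa -> kg."""
    return m_kda * 1e3 * CODATA.dalton


def thermal_energy(T: float) -> float:
    """k_B*T in joules at absolute temperature T (K)."""
    return CODATA.k_B * T


def joule_to_kbt(u_j, T: float):
    """Energy in joules -> units of k_B*T at temperature T (K)."""
    return u_j / thermal_energy(T)


def thermal_voltage(T: float) -> float:
    """k_B*T/e in volts (~25 mV at room temperature); the linearization
    threshold of the Poisson-Boltzmann equation."""
    return CODATA.k_B * T / CODATA.e
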