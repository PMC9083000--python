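"""Fundamental physical constants (CODATA, via scipy.constants).

These are fixed values, not user-configurable parameters: every derived
quantity in the package (Debye length, thermal energy, charge conversions)
is computed from this single set.
"""

from __future__ import annotations

from dataclasses import dataclass

import scipy.constants as _sc


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the CODATA constants the model uses.

    Attributes
    ----------
    e : float
        Elementary charge (C).
    N_A : float
        Avogadro constant (1/mol).
    k_B : float
        Boltzmann constant (J/K).
    epsilon_0 : float
        Vacuum permittivity (F/m).
    dalton : float
        Unified atomic mass unit (kg), used to convert protein masses
        quoted in kDa.
    """

    e: float = _sc.e
    N_A: float = _sc.N_A
    k_B: float = _sc.k
    epsilon_0: float = _sc.epsilon_0
    dalton: float = _sc.atomic_mass


#: The single shared instance; treat as read-only.
CODATA = PhysicalConstants()
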