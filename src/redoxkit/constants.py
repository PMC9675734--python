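"""Physical constants and unit helpers shared across the package.

All analysis modules work in the "bench" unit system of the experiments:
distances in nm, currents in nA, forces in pN, energies in pN·nm,
potentials in V (or thermal units kT/e), concentrations in mol/L.
"""

from __future__ import annotations

import numpy as np

# CODATA-2018 SI values
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
PLANCK = 6.62607015e-34  # J·s

#: Conductance quantum 2e^2/h, in siemens (~77.5 µS).
G0_SIEMENS = 2 * ELEMENTARY_CHARGE**2 / PLANCK

#: Thermal energy at 298 K in pN·nm (= 4.114 pN·nm), the working unit of
#: force spectroscopy.
KBT_298_PN_NM = 4.114

#: Default temperature (K) for all room-temperature experiments.
ROOM_TEMPERATURE = 298.0

#: Default relative permittivity of water at 298 K.
WATER_EPS_R = 78.5


def thermal_energy_pn_nm(temperature: float = ROOM_TEMPERATURE) -> float:
    """Thermal energy k_B·T in pN·nm at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return KBT_298_PN_NM * temperature / 298.0


def debye_length_nm(
    ionic_strength_M: float,
    temperature: float = ROOM_TEMPERATURE,
    eps_r: float = WATER_EPS_R,
) -> float:
    """Debye screening length (nm) of a 1:1 electrolyte.

    lambda_D = sqrt(eps0·eps_r·kB·T / (2·NA·e^2·I)), with the ionic
    strength I in mol/L.  At 50 mM, 298 K this is ~1.36 nm.
    Returns ``inf`` for zero ionic strength (unscreened Coulomb limit).
    """
    if ionic_strength_M < 0:
        raise ValueError("ionic strength must be non-negative")
    if ionic_strength_M == 0:
        return np.inf
    i_si = ionic_strength_M * 1e3 * AVOGADRO  # ions/m^3 per unit charge class
    lam = np.sqrt(
        VACUUM_PERMITTIVITY * eps_r * BOLTZMANN * temperature
        / (2 * i_si * ELEMENTARY_CHARGE**2)
    )
    return lam * 1e9


def bjerrum_length_nm(
    temperature: float = ROOM_TEMPERATURE, eps_r: float = WATER_EPS_R
) -> float:
    """Bjerrum length e^2/(4·pi·eps0·eps_r·kB·T) in nm (~0.70 nm in water)."""
    lb = ELEMENTARY_CHARGE**2 / (
        4 * np.pi * VACUUM_PERMITTIVITY * eps_r * BOLTZMANN * temperature
    )
    return lb * 1e9


def conductance_in_g0(current_nA: float | np.ndarray, bias_V: float):
    """Convert a (baseline-subtracted) current in nA at a bias in V to a
    junction conductance in multiples of G0."""
    if bias_V == 0:
        raise ZeroDivisionError("bias voltage must be non-zero")
    return (np.asarray(current_nA) * 1e-9 / bias_V) / G0_SIEMENS


def blink_amplitude_nA(conductance_g0: float, bias_V: float) -> float:
    """Current step (nA) of a junction of given conductance (G0 units)."""
    return conductance_g0 * G0_SIEMENS * bias_V * 1e9
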