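"""Physical constants and unit conversions.

Internal convention: all electronic-structure quantities are held in Hartree
atomic units (energy in hartree, length in bohr, charge in units of e,
dipoles in e*bohr, electric field in hartree/(e*bohr)).  Conversions to and
from the units used in input/output files (angstrom, eV, kJ/mol, volts,
M^-1 cm^-1) live here and nowhere else.
"""

from __future__ import annotations

import math

from scipy import constants as _c

# --- fundamental constants (SI, CODATA via scipy) ---
# length conversion pinned (CODATA 2018) so file round-trips are stable
# across scipy CODATA revisions
BOHR_M: float = 0.529177210903e-10                               # m
HARTREE_J: float = _c.physical_constants["Hartree energy"][0]    # J
E_CHARGE_C: float = _c.e                                         # C
PLANCK_J_S: float = _c.h
LIGHT_SPEED_M_S: float = _c.c
VACUUM_PERMITTIVITY: float = _c.epsilon_0
AVOGADRO: float = _c.N_A
BOLTZMANN_J_K: float = _c.k
FARADAY_C_MOL: float = 96485.332                                 # C/mol, fixed project-wide

# --- derived conversion factors ---
ANGSTROM_PER_BOHR: float = BOHR_M * 1e10          # 0.529177210903...
BOHR_PER_ANGSTROM: float = 1.0 / ANGSTROM_PER_BOHR
HARTREE_EV: float = HARTREE_J / E_CHARGE_C        # 27.2113862...
HARTREE_KJ_MOL: float = HARTREE_J * AVOGADRO / 1000.0   # 2625.4996...
KB_KJ_MOL_K: float = BOLTZMANN_J_K * AVOGADRO / 1000.0  # 0.00831446...
EV_KJ_MOL: float = E_CHARGE_C * AVOGADRO / 1000.0

# spectroscopy grid conversions (eV is the native grid unit)
EV_TO_HZ: float = E_CHARGE_C / PLANCK_J_S
EV_TO_CM1: float = E_CHARGE_C / (PLANCK_J_S * LIGHT_SPEED_M_S) / 100.0
NM_EV: float = PLANCK_J_S * LIGHT_SPEED_M_S / E_CHARGE_C * 1e9   # nm <-> eV via E = NM_EV / lambda

# default absolute potential of the standard hydrogen electrode (V)
E_SHE_DEFAULT_V: float = 4.281

# default Gaussian broadening for absorption spectra (eV)
SIGMA_DEFAULT_EV: float = 0.034

# default spectrum bin width (eV)
BIN_WIDTH_DEFAULT_EV: float = 0.002


def angstrom_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def bohr_to_angstrom(x):
    return x * ANGSTROM_PER_BOHR


def hartree_to_ev(x):
    return x * HARTREE_EV


def hartree_to_kj_mol(x):
    return x * HARTREE_KJ_MOL


def ev_to_nm(x):
    """Photon energy (eV) to wavelength (nm); vectorized, singular at 0."""
    return NM_EV / x


def cm1_to_ev(x):
    return x / EV_TO_CM1


def ev_to_cm1(x):
    return x * EV_TO_CM1


# Molar extinction prefactor: epsilon(nu) = EXTINCTION_PREFACTOR * nu_Hz
#   * |mu|^2_SI * rho(nu)_per_Hz  in M^-1 cm^-1.
# Derived from the absorption cross-section of a transition dipole mu with a
# normalized lineshape rho, sigma(nu) = 2 pi^2 nu |mu|^2 rho(nu) / (3 eps0 h c)
# (equivalent to the oscillator-strength sum rule), converted from m^2 per
# molecule to L mol^-1 cm^-1 via N_A / (ln 10 * 1e3 cm^3/L), with m^2 -> cm^2.
EXTINCTION_PREFACTOR: float = (
    2.0 * math.pi**2 / (3.0 * VACUUM_PERMITTIVITY * PLANCK_J_S * LIGHT_SPEED_M_S)
    * AVOGADRO / math.log(10.0) * 1e4 / 1e3
)

# squared dipole, atomic units (e*bohr)^2 -> SI (C*m)^2
DIPOLE_SQ_AU_TO_SI: float = (E_CHARGE_C * BOHR_M) ** 2
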