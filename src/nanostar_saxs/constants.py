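"""Physical constants and unit conversions.

All geometry is handled in Å, scattering lengths in Å, energies in k_BT
internally (converted from kJ/mol at the interface) and intensities in
absolute units (cm^-1).  Every conversion factor used by the package lives
in this table so the unit conventions can be audited in one place.
"""

from __future__ import annotations

import json

# CODATA 2018
R_ELECTRON_CM = 2.8179403262e-13  # classical electron radius [cm]
R_ELECTRON = R_ELECTRON_CM * 1e8  # [Å]
N_AVOGADRO = 6.02214076e23  # [1/mol]
K_BOLTZMANN = 1.380649e-23  # [J/K]
Q_ELEMENTARY = 1.602176634e-19  # [C]
EPSILON_0 = 8.8541878128e-12  # [F/m]
R_GAS = 8.314462618  # [J/(mol K)]

# reference solvent (liquid water)
T_REFERENCE = 298.15  # [K]
M_WATER = 18.0153  # [g/mol]
RHO_WATER_REF = 0.997047  # mass density at T_REFERENCE [g/cm^3]
N_ELECTRON_WATER = 10  # electrons per molecule
V_WATER = 29.9  # molecular volume of bulk water [Å^3]

# unit conversions
ANGSTROM_PER_CM = 1e8
CM_PER_ANGSTROM = 1e-8
L_PER_A3 = 1e-27  # litres per cubic ångström
KJMOL_PER_KBT = R_GAS * 1e-3  # multiply by T [K] to get kJ/mol per k_BT

# default expansivity model of bulk water (relative density about 25 °C)
ALPHA_W = 2.5e-4  # [1/K]
BETA_W = 9.8e-6  # [1/K^2]

#: default molar mass of the assembled four-strand nanostar [g/mol]
#: (sodium salt of the four 49-mers; see topology.molecular_weight)
M_NANOSTAR = 64700.0

#: default net charge number of the nanostar (one deprotonated phosphate
#: per residue, 196 residues)
Z_NANOSTAR = 196


def constants_table() -> dict:
    """Machine-readable table of the constants used by the package."""
    return {
        "r_e_cm": R_ELECTRON_CM,
        "N_A": N_AVOGADRO,
        "k_B": K_BOLTZMANN,
        "q_e": Q_ELEMENTARY,
        "epsilon_0": EPSILON_0,
        "R_gas": R_GAS,
        "T_o_K": T_REFERENCE,
        "M_w": M_WATER,
        "rho_m_w_ref": RHO_WATER_REF,
        "n_e_w": N_ELECTRON_WATER,
        "v_w_A3": V_WATER,
        "alpha_w": ALPHA_W,
        "beta_w": BETA_W,
        "M_nanostar": M_NANOSTAR,
        "Z_nanostar": Z_NANOSTAR,
    }


def export_constants(path) -> None:
    """Write the constants table as JSON key/value pairs for audit."""
    with open(path, "w") as fh:
        json.dump(constants_table(), fh, indent=2, sort_keys=True)
        fh.write("\n")
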