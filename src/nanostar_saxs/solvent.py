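"""Temperature-dependent solvent and electrolyte quantities.

Everything the scattering model needs to know about the aqueous buffer is
collected here: the relative mass density of bulk water d_w(T), the X-ray
scattering-length density rho_0(T), the relative dielectric constant
eps(T), the Debye-Hückel screening parameter kappa and the particle number
density n(T).

The density model is a two-parameter expansivity form about the reference
temperature T_o = 298.15 K,

    d_w(T) = exp[-alpha_w (T - T_o) - beta_w (T - T_o)^2 / 2],

in which ``alpha_w`` is the thermal expansivity at T_o and ``beta_w`` its
first temperature derivative.  The defaults (2.5e-4 1/K, 9.8e-6 1/K^2)
reproduce Kell's 1-atm water densities to better than 2e-4 over 5-45 °C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from . import constants as c

__all__ = [
    "SolventState",
    "relative_water_density",
    "kell_density_ratio",
    "fit_density_parameters",
    "electron_sld",
    "dielectric_constant",
    "ionic_strength",
    "counterion_molarity",
    "debye_kappa",
    "number_density",
    "solvent_state",
]

_T_MIN, _T_MAX = 273.15, 373.15


def _check_temperature(T) -> None:
    T = np.asarray(T, dtype=float)
    if np.any((T <= _T_MIN) | (T >= _T_MAX)):
        raise ValueError(
            f"temperature {T} K outside the liquid-water range; the density "
            f"model is validated on 5-45 °C (278.15-318.15 K)"
        )


def relative_water_density(
    T: float, alpha_w: float = c.ALPHA_W, beta_w: float = c.BETA_W
) -> float:
    """Relative mass density d_w(T) of bulk water w.r.t. T_o = 298.15 K."""
    _check_temperature(T)
    dT = np.asarray(T, dtype=float) - c.T_REFERENCE
    return np.exp(-alpha_w * dT - 0.5 * beta_w * dT**2)


def kell_density_ratio(T) -> np.ndarray:
    """Reference density ratio rho(T)/rho(T_o) from Kell's 1-atm formula.

    Kell's rational polynomial for the density of air-free water
    (0-150 °C, g/cm^3) serves as the experimental reference against which
    the two-parameter expansivity model is calibrated.
    """
    t = np.asarray(T, dtype=float) - 273.15

    def rho(t):
        num = (
            999.83952
            + 16.945176 * t
            - 7.9870401e-3 * t**2
            - 46.170461e-6 * t**3
            + 105.56302e-9 * t**4
            - 280.54253e-12 * t**5
        )
        return num / (1.0 + 16.879850e-3 * t) / 1000.0

    return rho(t) / rho(25.0)


def fit_density_parameters(reference_densities) -> tuple[float, float]:
    """Least-squares (alpha_w, beta_w) from a table of (T [K], d_w).

    Parameters
    ----------
    reference_densities : array-like, shape (n, 2)
        Rows of absolute temperature and relative density w.r.t. 298.15 K.
    """
    tab = np.atleast_2d(np.asarray(reference_densities, dtype=float))
    if tab.shape[0] < 3:
        raise ValueError("need at least 3 (T, density) points to fit")
    T, d = tab[:, 0], tab[:, 1]

    def model(T, a, b):
        dT = T - c.T_REFERENCE
        return np.exp(-a * dT - 0.5 * b * dT**2)

    popt, _ = curve_fit(model, T, d, p0=[2e-4, 1e-5])
    return float(popt[0]), float(popt[1])


def electron_sld(T: float, alpha_w: float = c.ALPHA_W, beta_w: float = c.BETA_W) -> float:
    """X-ray scattering-length density of bulk water [Å^-2].

    rho_0 = r_e n_e,w rho_m,w° N_A d_w(T) / M_w with n_e,w = 10 electrons
    per molecule.  About 9.4e-6 Å^-2 at 25 °C.
    """
    d_w = relative_water_density(T, alpha_w, beta_w)
    per_cm3 = c.N_ELECTRON_WATER * c.RHO_WATER_REF * c.N_AVOGADRO / c.M_WATER
    return c.R_ELECTRON * per_cm3 * 1e-24 * d_w  # e/cm^3 -> e/Å^3, times r_e[Å]


def dielectric_constant(T: float) -> float:
    """Relative dielectric constant of pure water (Malmberg & Maryott)."""
    _check_temperature(T)
    t = np.asarray(T, dtype=float) - 273.15
    return 87.740 - 0.40008 * t + 9.398e-4 * t**2 - 1.410e-6 * t**3


def counterion_molarity(concentration: float, T: float, M_DNA: float = c.M_NANOSTAR,
                        Z: int = c.Z_NANOSTAR) -> float:
    """Molar concentration of released monovalent counterions C' [mol/L].

    C' = |Z| c d_w(T) / M_DNA by electroneutrality.
    """
    if concentration < 0 or M_DNA <= 0:
        raise ValueError("concentration must be >= 0 and M_DNA > 0")
    return abs(Z) * concentration * relative_water_density(T) / M_DNA


def ionic_strength(
    concentration: float,
    T: float,
    I_S: float,
    Z: int = c.Z_NANOSTAR,
    M_DNA: float = c.M_NANOSTAR,
) -> float:
    """Total ionic strength I [mol/L] of added salt plus counterions.

    The monovalent counterions released by the nanostars enter the ionic
    strength with the standard 1/2 z'^2 C' weight,

        I = I_S + (1/2) C',   C' = |Z| c d_w(T) / M_DNA.

    The macroions themselves are excluded from the screening budget, as is
    conventional for Debye-Hückel screening between charged colloids.
    """
    if I_S < 0:
        raise ValueError("added-salt ionic strength must be >= 0")
    return I_S + 0.5 * counterion_molarity(concentration, T, M_DNA, Z)


def debye_kappa(I: float, T: float) -> float:
    """Reciprocal Debye-Hückel screening length kappa [Å^-1].

    kappa^2 = 2 e^2 N_A (10^3 I) / (eps_0 eps(T) k_B T) in SI units,
    converted to Å^-1.  About 0.09 Å^-1 for I = 77 mM at 25 °C.
    """
    if I < 0:
        raise ValueError("ionic strength must be >= 0")
    if I == 0:
        return 0.0
    eps = dielectric_constant(T)
    kappa_m = np.sqrt(
        2.0 * c.Q_ELEMENTARY**2 * c.N_AVOGADRO * 1e3 * I
        / (c.EPSILON_0 * eps * c.K_BOLTZMANN * T)
    )
    return float(kappa_m * 1e-10)


def bjerrum_length(T: float) -> float:
    """Bjerrum length e^2/(4 pi eps_0 eps(T) k_B T) [Å] (7.15 Å at 25 °C)."""
    eps = dielectric_constant(T)
    lam = c.Q_ELEMENTARY**2 / (
        4.0 * np.pi * c.EPSILON_0 * eps * c.K_BOLTZMANN * T
    )
    return float(lam * 1e10)


def number_density(concentration: float, T: float, M_DNA: float = c.M_NANOSTAR) -> float:
    """Particle number density n(T) = c N_A d_w(T) / M_DNA [Å^-3]."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    per_litre = concentration * c.N_AVOGADRO * relative_water_density(T) / M_DNA
    return float(per_litre * c.L_PER_A3)


@dataclass(frozen=True)
class SolventState:
    """Bundle of the solvent quantities at one temperature.

    Attributes
    ----------
    T : absolute temperature [K]
    d_w : relative mass density of bulk water w.r.t. 298.15 K
    rho0 : X-ray scattering-length density of bulk water [Å^-2]
    eps : relative dielectric constant
    kappa : Debye-Hückel screening parameter [Å^-1]
    I_total : total ionic strength [mol/L]
    """

    T: float
    d_w: float
    rho0: float
    eps: float
    kappa: float
    I_total: float


def solvent_state(
    T: float,
    concentration: float = 0.0,
    I_S: float = 0.0,
    Z: int = c.Z_NANOSTAR,
    M_DNA: float = c.M_NANOSTAR,
) -> SolventState:
    """Evaluate all solvent quantities for one sample condition."""
    I = ionic_strength(concentration, T, I_S, Z, M_DNA)
    return SolventState(
        T=float(T),
        d_w=float(relative_water_density(T)),
        rho0=float(electron_sld(T)),
        eps=float(dielectric_constant(T)),
        kappa=debye_kappa(I, T),
        I_total=float(I),
    )
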