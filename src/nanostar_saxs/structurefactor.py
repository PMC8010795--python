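"""Hard-sphere double-Yukawa structure factor in the PY + RPA scheme.

The radial nanostar-nanostar interaction is modeled as a hard core of
radius R plus two Yukawa tails,

    u_j(r) = B_j exp[-kappa_j (r - 2R)] / r,   j = C, A   (r > 2R)

* repulsion (C): screened-Coulomb DLVO form with contact amplitude
  B_C = Z^2 lambda_B / (1 + kappa R)^2 (in k_BT Å) and kappa the
  Debye-Hückel parameter of the buffer;
* attraction (A): B_A = -2R J and kappa_A = 1/d, so that u_A(2R) = -J
  exactly, with J the contact depth and d the range.

The particle-particle structure factor is the random-phase-approximation
perturbation of the analytic Percus-Yevick hard-sphere solution,

    S(q) = S0(q) / [1 + n S0(q) (u~_C(q) + u~_A(q)) / k_BT],

with u~_j the closed-form isotropic Fourier transform of the tail
restricted to r > 2R.  The measured structure factor couples S(q) to the
particle anisotropy through beta(q):  S_M(q) = 1 + beta(q) [S(q) - 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as cst
from . import solvent as sv

__all__ = [
    "HSDYParams",
    "PairPotentialCurve",
    "StructureFactorSet",
    "pair_potential",
    "py_structure_factor",
    "yukawa_transform",
    "rpa_structure_factor",
    "measured_structure_factor",
    "first_peak",
    "RPAInstabilityError",
    "PARTIAL_SPECIFIC_VOLUME_DNA",
]

#: partial specific volume of duplex DNA [cm^3/g] for the dry-volume
#: volume-fraction convention
PARTIAL_SPECIFIC_VOLUME_DNA = 0.55


class RPAInstabilityError(RuntimeError):
    """RPA denominator reached zero: parameters are past the spinodal."""


@dataclass(frozen=True)
class HSDYParams:
    """Pair-potential parameters of the HSDY model.

    R [Å] effective hard-sphere radius; Z net charge number; J [kJ/mol]
    attraction depth at contact r = 2R; d [Å] attraction range;
    ``n`` the particle number density [Å^-3]; ``solvent`` the buffer
    state (provides kappa, eps, T); ``phi_convention`` selects the volume
    fraction fed into the PY kernel ('effective-R' or 'dry-volume', the
    latter requiring ``concentration`` in g/L).
    """

    R: float
    J: float
    d: float
    solvent: sv.SolventState
    n: float
    Z: int = cst.Z_NANOSTAR
    phi_convention: str = "effective-R"
    concentration: float | None = None

    def __post_init__(self):
        if self.R <= 0 or self.d <= 0 or self.J < 0:
            raise ValueError("require R > 0, d > 0, J >= 0")
        phi = self.phi
        if not (0.0 <= phi < 0.25):
            raise ValueError(
                f"volume fraction {phi:.3f} outside [0, 0.25); the analytic "
                f"PY solution is not trusted at this packing"
            )

    @classmethod
    def from_conditions(
        cls,
        R: float,
        J: float,
        d: float,
        concentration: float,
        I_S: float,
        T: float,
        Z: int = cst.Z_NANOSTAR,
        M_DNA: float = cst.M_NANOSTAR,
        phi_convention: str = "effective-R",
    ) -> "HSDYParams":
        """Build parameters from sample conditions (c in g/L, I_S in M)."""
        solvent = sv.solvent_state(T, concentration, I_S, Z, M_DNA)
        n = sv.number_density(concentration, T, M_DNA)
        return cls(
            R=R, J=J, d=d, solvent=solvent, n=n, Z=Z,
            phi_convention=phi_convention, concentration=concentration,
        )

    @property
    def phi(self) -> float:
        if self.phi_convention == "effective-R":
            return self.n * 4.0 / 3.0 * np.pi * self.R**3
        if self.phi_convention == "dry-volume":
            if self.concentration is None:
                raise ValueError("dry-volume convention requires concentration")
            return self.concentration * PARTIAL_SPECIFIC_VOLUME_DNA / 1000.0
        raise ValueError(f"unknown phi convention {self.phi_convention!r}")

    @property
    def beta_J(self) -> float:
        """Attraction depth in k_BT."""
        return self.J * 1e3 / (cst.R_GAS * self.solvent.T)

    @property
    def B_C(self) -> float:
        """Screened-Coulomb contact amplitude [k_BT Å]."""
        lam_B = sv.bjerrum_length(self.solvent.T)
        return self.Z**2 * lam_B / (1.0 + self.solvent.kappa * self.R) ** 2

    @property
    def B_A(self) -> float:
        """Attractive Yukawa amplitude -2R J [k_BT Å]."""
        return -2.0 * self.R * self.beta_J


@dataclass
class PairPotentialCurve:
    """u(r) = u_C(r) + u_A(r) outside the hard core, in kJ/mol."""

    r: np.ndarray
    u: np.ndarray
    u_C: np.ndarray
    u_A: np.ndarray
    n_excluded: int = 0  # grid points inside the hard core (u = inf there)


@dataclass
class StructureFactorSet:
    q: np.ndarray
    S0: np.ndarray
    S: np.ndarray
    S_M: np.ndarray | None = None
    first_peak: tuple[float, float] | None = None


def pair_potential(params: HSDYParams, r) -> PairPotentialCurve:
    """Evaluate the HSDY tail potentials on an r-grid [Å], in kJ/mol."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    sigma = 2.0 * params.R
    kT_kJmol = cst.R_GAS * params.solvent.T * 1e-3
    inside = r < sigma
    rr = np.where(inside, sigma, r)
    u_C = params.B_C * np.exp(-params.solvent.kappa * (rr - sigma)) / rr * kT_kJmol
    u_A = params.B_A * np.exp(-(rr - sigma) / params.d) / rr * kT_kJmol
    u = u_C + u_A
    u_C[inside] = np.inf
    u_A[inside] = -params.J
    u[inside] = np.inf
    return PairPotentialCurve(
        r=r, u=u, u_C=u_C, u_A=u_A, n_excluded=int(inside.sum())
    )


def py_structure_factor(phi: float, R: float, q) -> np.ndarray:
    """Analytic Percus-Yevick structure factor of hard spheres (diam. 2R).

    Wertheim's closed-form direct correlation function; small-x limbs are
    evaluated by series to avoid catastrophic cancellation.
    """
    if not (0.0 <= phi < 0.25):
        raise ValueError(
            f"phi={phi} outside [0, 0.25), the validity range adopted for "
            f"the analytic PY solution"
        )
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if phi == 0.0:
        return np.ones_like(q)
    x = q * 2.0 * R
    a = (1.0 + 2.0 * phi) ** 2 / (1.0 - phi) ** 4
    b = -6.0 * phi * (1.0 + phi / 2.0) ** 2 / (1.0 - phi) ** 4
    g = phi * a / 2.0

    small = x < 0.1
    xs = np.where(small, 1.0, x)
    sin_x, cos_x = np.sin(xs), np.cos(xs)
    t1 = (sin_x - xs * cos_x) / xs**3
    t2 = (2.0 * xs * sin_x + (2.0 - xs**2) * cos_x - 2.0) / xs**4
    t3 = (
        -(xs**4) * cos_x
        + 4.0 * ((3.0 * xs**2 - 6.0) * cos_x + (xs**3 - 6.0 * xs) * sin_x + 6.0)
    ) / xs**6
    # series about x = 0 (t1 -> 1/3, t2 -> 1/4, t3 -> 1/6)
    x2 = x**2
    t1 = np.where(small, 1.0 / 3.0 - x2 / 30.0 + x2**2 / 840.0, t1)
    t2 = np.where(small, 1.0 / 4.0 - x2 / 36.0, t2)
    t3 = np.where(small, 1.0 / 6.0 - x2 / 48.0, t3)

    n_c = -24.0 * phi * (a * t1 + b * t2 + g * t3)
    return 1.0 / (1.0 - n_c)


def yukawa_transform(B: float, kappa_j: float, R: float, q) -> np.ndarray:
    """Closed-form 3-D Fourier transform of B e^{-kappa_j (r-2R)}/r, r > 2R.

    u~(q) = (4 pi B / q) Im[ e^{2iqR} / (kappa_j - i q) ], with the q -> 0
    limit 4 pi B (1 + 2 kappa_j R) / kappa_j^2.  Units: [B] Å^3.
    """
    if kappa_j <= 0:
        raise ValueError("kappa_j must be positive")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    out = np.empty_like(q)
    tiny = q < 1e-9
    qs = np.where(tiny, 1.0, q)
    out = 4.0 * np.pi * B * np.imag(np.exp(2j * qs * R) / (kappa_j - 1j * qs)) / qs
    limit = 4.0 * np.pi * B * (1.0 + 2.0 * kappa_j * R) / kappa_j**2
    return np.where(tiny, limit, out)


def rpa_structure_factor(params: HSDYParams, q) -> StructureFactorSet:
    """PY + RPA structure factor; raises on an unstable denominator."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    S0 = py_structure_factor(params.phi, params.R, q)
    u_t = np.zeros_like(q)
    if params.Z != 0 and params.solvent.kappa > 0:
        u_t = u_t + yukawa_transform(params.B_C, params.solvent.kappa, params.R, q)
    if params.J != 0:
        u_t = u_t + yukawa_transform(params.B_A, 1.0 / params.d, params.R, q)
    denom = 1.0 + params.n * S0 * u_t
    if np.any(denom <= 0):
        q_bad = q[np.argmin(denom)]
        raise RPAInstabilityError(
            f"RPA denominator non-positive at q = {q_bad:.4f} 1/Å: the "
            f"(R={params.R}, J={params.J}, d={params.d}) state is past the "
            f"RPA spinodal at this density"
        )
    S = S0 / denom
    return StructureFactorSet(q=q, S0=S0, S=S, first_peak=first_peak(q, S))


def first_peak(q, S, q_min: float = 0.02) -> tuple[float, float] | None:
    """Location and height of the first local maximum of S at q > q_min."""
    q = np.asarray(q)
    S = np.asarray(S)
    interior = (S[1:-1] > S[:-2]) & (S[1:-1] >= S[2:])
    idx = np.flatnonzero(interior) + 1
    idx = idx[q[idx] > q_min]
    if idx.size == 0:
        return None
    i = idx[0]
    return float(q[i]), float(S[i])


def measured_structure_factor(S, beta) -> np.ndarray:
    """Decoupling approximation: S_M(q) = 1 + beta(q) [S(q) - 1]."""
    S = np.asarray(S, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if S.shape != beta.shape:
        raise ValueError(
            f"S grid ({S.shape}) and beta grid ({beta.shape}) are not aligned"
        )
    return 1.0 + beta * (S - 1.0)
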