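"""Ensemble form factor of hydrated nanostars via multipole expansion.

The excess scattering amplitude of configuration m is the sum of the
united-atoms-in-water term and the hydration-shell term,

    F_m(q) = F_m,at(q) + (d_h - 1) G_m,sh(q),

with G_m,sh(q) = rho0 g_w(q) sum_k exp(i q . r_k) over the dummy-water
centres.  Both amplitudes are expanded in spherical harmonics about the
excess-scattering-length-weighted centroid of the configuration, which
makes the orientational averages over the direction of q exact sums over
multipole channels:

    <F>_Omega      = A_00 / sqrt(4 pi)
    <|F|^2>_Omega  = (1/4 pi) sum_lm |A_lm|^2,
    A_lm = 4 pi i^l sum_k w_k(q) j_l(q r_k) Y*_lm(r_k)

The ensemble form factor P(q) is the configuration mean of <|F|^2>, the
mean amplitude <F>(q) the configuration mean of <F>, and the coupling
function beta(q) = |<F>|^2 / P(q).  Because the shell enters linearly in
(d_h - 1), P decomposes exactly as

    P(q; d_h) = A(q) + (d_h - 1) B(q) + (d_h - 1)^2 C(q)

and the caches A, B, C (plus the complex amplitude parts) let d_h vary
without re-expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np
from scipy.special import spherical_jn, sph_harm_y

from . import constants as cst
from .hydration import ShellParams, hydrate
from .scattering import GroupScatteringTable

__all__ = [
    "FormFactorSet",
    "ensemble_form_factor",
    "coupling_function",
    "debye_direct_oracle",
    "scattering_center",
]

DEFAULT_LMAX = 30


@dataclass
class FormFactorSet:
    """q-grid with P(q), <F>(q), beta(q) and the d_h decomposition caches.

    ``P`` is in Å^2 per particle (multiply by the number density in Å^-3
    and by 1e8 to obtain a macroscopic cross section in cm^-1).
    """

    q: np.ndarray
    A: np.ndarray  # <|F_at|^2> ensemble mean
    B: np.ndarray  # 2 Re <F_at G*_sh> ensemble mean
    C: np.ndarray  # <|G_sh|^2> ensemble mean
    F0: np.ndarray  # complex <F_at> ensemble mean
    F1: np.ndarray  # complex <G_sh> ensemble mean
    d_h: float
    N: int
    Lmax: int

    def P_at(self, d_h: float | None = None) -> np.ndarray:
        x = (self.d_h if d_h is None else d_h) - 1.0
        return self.A + x * self.B + x**2 * self.C

    @property
    def P(self) -> np.ndarray:
        return self.P_at()

    def Fmean_at(self, d_h: float | None = None) -> np.ndarray:
        x = (self.d_h if d_h is None else d_h) - 1.0
        return self.F0 + x * self.F1

    @property
    def Fmean(self) -> np.ndarray:
        return self.Fmean_at()

    def beta_at(self, d_h: float | None = None) -> np.ndarray:
        P = self.P_at(d_h)
        num = np.abs(self.Fmean_at(d_h)) ** 2
        out = np.zeros_like(P)
        ok = P > 0
        out[ok] = num[ok] / P[ok]
        return out

    @property
    def beta(self) -> np.ndarray:
        return self.beta_at()

    def with_dh(self, d_h: float) -> "FormFactorSet":
        return replace(self, d_h=float(d_h))


def scattering_center(positions, weights) -> np.ndarray:
    """Excess-scattering-length-weighted centroid (the expansion origin)."""
    w = np.asarray(weights, dtype=float)
    return (w[:, None] * positions).sum(axis=0) / w.sum()


def _config_multipoles(at_pos, W_at, sh_pos, w_sh, q, Lmax, origin):
    """Multipole sums for one configuration.

    Returns (Pat, cross, Psh, Fat, Gsh): the orientational averages
    <|F_at|^2>, 2 Re <F_at G*>, <|G|^2> and the complex <F_at>, <G>.
    """
    nq = q.size
    Pat = np.zeros(nq)
    cross = np.zeros(nq)
    Psh = np.zeros(nq)

    def spherical(rel):
        r = np.linalg.norm(rel, axis=1)
        safe = np.where(r > 0, r, 1.0)
        theta = np.arccos(np.clip(rel[:, 2] / safe, -1.0, 1.0))
        phi = np.arctan2(rel[:, 1], rel[:, 0])
        return r, theta, phi

    r_at, th_at, ph_at = spherical(at_pos - origin)
    has_shell = sh_pos is not None and len(sh_pos) > 0
    if has_shell:
        r_sh, th_sh, ph_sh = spherical(sh_pos - origin)

    qr_at = q[None, :] * r_at[:, None]  # (na, nq)
    if has_shell:
        qr_sh = q[None, :] * r_sh[:, None]

    Fat = np.zeros(nq, dtype=complex)
    Gsh = np.zeros(nq, dtype=complex)

    for l in range(Lmax + 1):
        m = np.arange(0, l + 1)[:, None]
        T_at = W_at * spherical_jn(l, qr_at)  # (na, nq)
        Y_at = sph_harm_y(l, m, th_at[None, :], ph_at[None, :])  # (l+1, na)
        Xc = np.conj(Y_at) @ T_at  # m = 0..l
        Xp = Y_at @ T_at  # carries |X_{l,-m}| for m = 1..l
        contrib = np.abs(Xc) ** 2
        contrib[1:] += np.abs(Xp[1:]) ** 2
        Pat += 4.0 * np.pi * contrib.sum(axis=0)
        if l == 0:
            Fat = np.sqrt(4.0 * np.pi) * Xc[0]

        if has_shell:
            T_sh = w_sh[None, :] * spherical_jn(l, qr_sh)
            Y_sh = sph_harm_y(l, m, th_sh[None, :], ph_sh[None, :])
            Zc = np.conj(Y_sh) @ T_sh
            Zp = Y_sh @ T_sh
            sh_contrib = np.abs(Zc) ** 2
            sh_contrib[1:] += np.abs(Zp[1:]) ** 2
            Psh += 4.0 * np.pi * sh_contrib.sum(axis=0)
            x_contrib = (Xc * np.conj(Zc)).real
            x_contrib[1:] += (Xp[1:] * np.conj(Zp[1:])).real
            cross += 8.0 * np.pi * x_contrib.sum(axis=0)
            if l == 0:
                Gsh = np.sqrt(4.0 * np.pi) * Zc[0]

    return Pat, cross, Psh, Fat, Gsh


def ensemble_form_factor(
    ensemble,
    solvent,
    q,
    d_h: float = 1.0,
    Lmax: int = DEFAULT_LMAX,
    table: GroupScatteringTable | None = None,
    shells=None,
    shell_params: ShellParams | None = None,
    with_shell: bool = True,
) -> FormFactorSet:
    """Ensemble form factor, mean amplitude and coupling function.

    Parameters
    ----------
    ensemble : NanostarEnsemble (or any iterable of Configurations)
    solvent : SolventState providing rho0
    q : q-grid [Å^-1]
    d_h : relative mass density of the hydration water
    Lmax : multipole truncation order; should be at least q_max times the
        largest site distance from the origin (a warning is emitted below
        that bound)
    shells : optional precomputed list of HydrationShell, one per
        configuration; built on the fly when ``with_shell`` and absent
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    table = table or GroupScatteringTable(rho0=solvent.rho0)
    configs = list(ensemble)
    if not configs:
        raise ValueError("empty ensemble")

    if with_shell and shells is None:
        shells = [hydrate(conf, table, shell_params) for conf in configs]
    if not with_shell:
        shells = [None] * len(configs)

    # unit shell weight; the (d_h - 1) factor lives in the caches
    w_sh = solvent.rho0 * np.exp(
        -(q**2) * cst.V_WATER ** (2.0 / 3.0) / (4.0 * np.pi)
    ) * cst.V_WATER

    n = len(configs)
    A = np.zeros(q.size)
    B = np.zeros(q.size)
    C = np.zeros(q.size)
    F0 = np.zeros(q.size, dtype=complex)
    F1 = np.zeros(q.size, dtype=complex)

    for conf, shell in zip(configs, shells):
        W_at = table.site_lengths(conf.groups, q)  # (na, nq)
        w0 = table.site_lengths(conf.groups, np.array([0.0]))[:, 0]
        origin = scattering_center(conf.positions, w0)
        rmax = np.linalg.norm(conf.positions - origin, axis=1).max()
        if shell is not None and shell.N_h:
            rmax = max(rmax, np.linalg.norm(shell.centers - origin, axis=1).max())
        bound = int(np.ceil(q.max() * rmax))
        if Lmax < bound:
            warnings.warn(
                f"Lmax={Lmax} below the recommended bound ceil(q_max R_max)="
                f"{bound}; the high-q multipole truncation may be inaccurate",
                stacklevel=2,
            )
        sh_pos = shell.centers if shell is not None else None
        Pat, cross, Psh, Fat, Gsh = _config_multipoles(
            conf.positions, W_at, sh_pos, w_sh, q, Lmax, origin
        )
        A += Pat / n
        B += cross / n
        C += Psh / n
        F0 += Fat / n
        F1 += Gsh / n

    return FormFactorSet(
        q=q, A=A, B=B, C=C, F0=F0, F1=F1, d_h=float(d_h), N=n, Lmax=Lmax
    )


def coupling_function(ffset: FormFactorSet) -> np.ndarray:
    """beta(q) = |<F>(q)|^2 / P(q); zero (and flagged) where P vanishes."""
    return ffset.beta


def debye_direct_oracle(
    configuration,
    shell,
    solvent,
    d_h: float,
    q,
    table: GroupScatteringTable | None = None,
    chunk: int = 512,
) -> np.ndarray:
    """Orientationally averaged |F|^2 by the direct Debye double sum.

    Brute-force validator for the multipole path; O(n^2) in the number of
    sites, intended for small configurations.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    table = table or GroupScatteringTable(rho0=solvent.rho0)
    pos = np.asarray(configuration.positions, dtype=float)
    W = table.site_lengths(configuration.groups, q)
    if shell is not None and shell.N_h:
        pos = np.vstack([pos, shell.centers])
        w_sh = table.water_length(q, d_h)
        W = np.vstack([W, np.tile(w_sh, (shell.N_h, 1))])

    n = pos.shape[0]
    P = np.zeros(q.size)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = np.linalg.norm(pos[start:stop, None, :] - pos[None, :, :], axis=-1)
        for iq, qq in enumerate(q):
            j0 = np.sinc(qq * d / np.pi)
            P[iq] += W[start:stop, iq] @ j0 @ W[:, iq]
    return P
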