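"""Regularized global fitting of temperature batches of SAXS curves.

The model intensity of curve m (temperature T_m, concentration c,
added-salt ionic strength I_S) is

    I_m(q) = n(T_m) P(q; d_h(T_m)) S_M(q; R_m, J_m, d_m, T_m)   [cm^-1]

with the hydration density following the smooth law
d_h(T) = d_h° exp[-alpha_h (T - T_o)].  The common parameters of a batch
are (d_h°, alpha_h); each curve contributes (R_m, J_m, d_m).  The fit
minimizes the merit function

    M = chi2_bar + alpha L

where chi2_bar is the batch-averaged standard reduced chi-square and L a
regularization term that penalizes jumps of the per-curve parameters
between neighbouring temperatures,

    L = sum_k sum_m [ (X_{k,m+1} - X_{k,m}) / X_bar_k ]^2,

written with relative differences so that parameters of different units
share the single constant alpha.  By default alpha is set by the
~10% rule against a 1%-per-step roughness prior (see fit_batch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from . import constants as cst
from . import solvent as sv
from .formfactor import FormFactorSet
from .structurefactor import (
    HSDYParams,
    RPAInstabilityError,
    measured_structure_factor,
    rpa_structure_factor,
)

__all__ = [
    "SAXSCurve",
    "FitProblem",
    "FitResult",
    "BatchConditions",
    "sigmoid_trajectory",
    "default_trajectories",
    "model_intensity",
    "reduced_chi2",
    "regularization",
    "merit",
    "synthesize_batch",
    "fit_batch",
    "DEFAULT_TEMPERATURE_RAMP_C",
]

#: temperature steps of the experimental ramp (°C): 5 °C steps outside
#: 20-30 °C, 2 °C steps inside
DEFAULT_TEMPERATURE_RAMP_C = (5, 10, 15, 20, 22, 24, 26, 28, 30, 35, 40, 45)


@dataclass
class SAXSCurve:
    """One scattering curve with its sample metadata."""

    q: np.ndarray  # [Å^-1]
    I: np.ndarray  # [cm^-1]
    sigma: np.ndarray  # [cm^-1]
    T: float  # [K]
    c: float  # [g/L]
    I_S: float  # [mol/L]
    ramp: str = "heating"
    label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.I.shape == self.sigma.shape):
            raise ValueError("q, I, sigma must have equal shapes")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive everywhere")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")


def model_intensity(
    curve_T: float,
    curve_c: float,
    curve_I_S: float,
    R: float,
    J: float,
    d: float,
    dh0: float,
    alpha_h: float,
    ffset: FormFactorSet,
    Z: int = cst.Z_NANOSTAR,
    M_DNA: float = cst.M_NANOSTAR,
    phi_convention: str = "effective-R",
) -> np.ndarray:
    """Absolute model intensity [cm^-1] on the form-factor cache's q-grid."""
    d_h = dh0 * np.exp(-alpha_h * (curve_T - cst.T_REFERENCE))
    P = ffset.P_at(d_h)
    beta = ffset.beta_at(d_h)
    n = sv.number_density(curve_c, curve_T, M_DNA)
    if curve_c > 0:
        params = HSDYParams.from_conditions(
            R, J, d, curve_c, curve_I_S, curve_T, Z, M_DNA, phi_convention
        )
        S = rpa_structure_factor(params, ffset.q).S
        S_M = measured_structure_factor(S, beta)
    else:
        S_M = np.ones_like(ffset.q)
    return n * P * S_M * cst.ANGSTROM_PER_CM


def reduced_chi2(curve: SAXSCurve, model) -> float:
    """Mean squared sigma-normalized residual of one curve."""
    model = np.asarray(model, dtype=float)
    if model.shape != curve.I.shape:
        raise ValueError("model and data grids are not aligned")
    return float(np.mean(((curve.I - model) / curve.sigma) ** 2))


def regularization(per_curve_params) -> float:
    """L = sum_k sum_m [(X_{k,m+1} - X_{k,m}) / X_bar_k]^2.

    ``per_curve_params`` has shape (N_m, K), rows ordered along the ramp.
    """
    X = np.atleast_2d(np.asarray(per_curve_params, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("regularization needs at least 2 curves")
    scale = np.mean(np.abs(X), axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    steps = np.diff(X, axis=0) / scale[None, :]
    return float(np.sum(steps**2))


def merit(chi2_bar: float, L: float, alpha_reg: float) -> float:
    """Merit function chi2_bar + alpha L."""
    if alpha_reg < 0:
        raise ValueError("alpha_reg must be >= 0")
    return float(chi2_bar + alpha_reg * L)


def sigmoid_trajectory(T, low: float, high: float, T_mid: float = 298.15,
                       width: float = 3.0) -> np.ndarray:
    """Smooth sigmoidal parameter trajectory centred at the overhang melting.

    Goes from ``low`` at small T to ``high`` at large T (swap the two to
    obtain a decreasing trajectory); midpoint 25 °C, width in K.
    """
    T = np.asarray(T, dtype=float)
    return low + (high - low) / (1.0 + np.exp(-(T - T_mid) / width))


@dataclass(frozen=True)
class BatchConditions:
    """Sample conditions of one temperature batch."""

    concentration: float  # [g/L]
    I_S: float  # [mol/L]
    temperatures_K: tuple = tuple(t + 273.15 for t in DEFAULT_TEMPERATURE_RAMP_C)
    ramp: str = "heating"
    dh0: float = 1.05
    alpha_h: float = 0.0


def default_trajectories(conditions: BatchConditions):
    """The generating (R, J, d)(T) trajectories of the synthetic batches.

    Sigmoids centred at 25 °C: the effective radius grows with T (41-43.5 Å
    dilute, 49-53 Å dense), while the attraction weakens slightly
    (J: 280 -> 276 kJ/mol, d: 14.5 -> 13.5 Å).
    """
    T = np.asarray(conditions.temperatures_K)
    dense = conditions.concentration > 5.0
    R = sigmoid_trajectory(T, 49.0, 53.0) if dense else sigmoid_trajectory(T, 41.0, 43.5)
    J = sigmoid_trajectory(T, 280.0, 276.0)
    d = sigmoid_trajectory(T, 14.5, 13.5)
    return R, J, d


def synthesize_batch(
    ffset: FormFactorSet,
    conditions: BatchConditions,
    trajectories=None,
    noise_level: float = 0.02,
    seed: int = 0,
    Z: int = cst.Z_NANOSTAR,
    M_DNA: float = cst.M_NANOSTAR,
) -> tuple[list[SAXSCurve], np.ndarray]:
    """Forward-model a batch of curves with heteroscedastic Gaussian noise.

    sigma(q) = noise_level * I(q) * (1 + q/q_max); at noise_level = 0 the
    curves equal the forward model and a nominal 1e-4 relative sigma is
    recorded.  Returns (curves, true_params) with true_params of shape
    (N_m, 3) holding the generating (R, J, d) rows.

    The same seed always yields the same batch.
    """
    rng = np.random.default_rng(seed)
    q = ffset.q
    if trajectories is None:
        trajectories = default_trajectories(conditions)
    R_t, J_t, d_t = (np.asarray(a, dtype=float) for a in trajectories)
    curves = []
    for m, T in enumerate(conditions.temperatures_K):
        I = model_intensity(
            T, conditions.concentration, conditions.I_S,
            R_t[m], J_t[m], d_t[m], conditions.dh0, conditions.alpha_h,
            ffset, Z, M_DNA,
        )
        level = noise_level if noise_level > 0 else 1e-4
        sigma = level * I * (1.0 + q / q.max())
        noisy = I + sigma * rng.standard_normal(q.size) if noise_level > 0 else I
        curves.append(
            SAXSCurve(
                q=q, I=noisy, sigma=sigma, T=float(T),
                c=conditions.concentration, I_S=conditions.I_S,
                ramp=conditions.ramp, label=f"T{m:02d}",
            )
        )
    return curves, np.stack([R_t, J_t, d_t], axis=1)


@dataclass
class FitProblem:
    """Batch of curves plus the shared form-factor cache and fit settings.

    Curves must be ordered along the ramp (the regularizer couples
    neighbours) and share the cache's q-grid.
    """

    curves: list
    ffset: FormFactorSet
    alpha_reg: float | None = None  # None -> auto-tuned 10% rule
    x0_common: tuple = (1.02, 0.0)  # (d_h°, alpha_h)
    x0_per_curve: tuple | None = None  # (R, J, d); None -> physics init
    bounds_common: tuple = ((0.9, 1.2), (-1e-3, 1e-3))
    bounds_per_curve: tuple = ((30.0, 70.0), (150.0, 450.0), (5.0, 30.0))
    Z: int = cst.Z_NANOSTAR
    M_DNA: float = cst.M_NANOSTAR
    phi_convention: str = "effective-R"

    def __post_init__(self):
        if len(self.curves) < 2:
            raise ValueError("a global fit needs at least 2 curves")
        for c in self.curves:
            if c.q.shape != self.ffset.q.shape or not np.allclose(c.q, self.ffset.q):
                raise ValueError(
                    f"curve {c.label!r} q-grid differs from the form-factor cache"
                )
        if self.x0_per_curve is None:
            self.x0_per_curve = self._physics_init()

    def _physics_init(self, R0: float = 48.0) -> tuple:
        """Initial (R, J, d) at the charge-balance point of the mid curve.

        RPA with two sharp-cutoff Yukawa tails is only stable where the
        integrated repulsion and attraction nearly cancel, so the fit
        starts with J equal to the contact repulsion u_C(2R) and d equal
        to the Debye screening length of the mid-batch curve; both are
        computable from the sample conditions alone.
        """
        mid = self.curves[len(self.curves) // 2]
        params = HSDYParams.from_conditions(
            R0, 0.0, 10.0, mid.c, mid.I_S, mid.T, self.Z, self.M_DNA,
            self.phi_convention,
        )
        kT_kJmol = cst.R_GAS * mid.T * 1e-3
        J0 = params.B_C / (2.0 * R0) * kT_kJmol
        kappa = params.solvent.kappa
        d0 = 1.0 / kappa if kappa > 0 else 10.0
        lo, hi = self.bounds_per_curve[1]
        J0 = float(np.clip(J0, lo + 1.0, hi - 1.0))
        lo, hi = self.bounds_per_curve[2]
        d0 = float(np.clip(d0, lo + 0.1, hi - 0.1))
        return (R0, J0, d0)


@dataclass
class FitResult:
    dh0: float
    alpha_h: float
    per_curve: np.ndarray  # (N_m, 3): R, J, d
    dh0_err: float
    alpha_h_err: float
    per_curve_err: np.ndarray
    merit: float
    chi2_bar: float
    L: float
    alpha_reg: float
    model_curves: list
    converged: bool
    seed: int
    message: str = ""


def _unpack(x, n_curves):
    dh0, alpha_h = x[0], x[1]
    per = x[2:].reshape(n_curves, 3)
    return dh0, alpha_h, per


def _batch_chi2(problem: FitProblem, dh0, alpha_h, per) -> tuple[float, list]:
    models = []
    chi2 = 0.0
    for m, curve in enumerate(problem.curves):
        try:
            I = model_intensity(
                curve.T, curve.c, curve.I_S, per[m, 0], per[m, 1], per[m, 2],
                dh0, alpha_h, problem.ffset, problem.Z, problem.M_DNA,
                problem.phi_convention,
            )
        except RPAInstabilityError:
            I = np.zeros_like(curve.I)
        models.append(I)
        chi2 += reduced_chi2(curve, I)
    return chi2 / len(problem.curves), models


def fit_batch(
    problem: FitProblem,
    seed: int = 0,
    n_starts: int = 3,
    max_nfev: int | None = None,
) -> FitResult:
    """Minimize the merit function over common and per-curve parameters.

    Two-stage bounded trust-region least squares:

    1. a collapsed fit in which all curves share one (R, J, d) — a
       well-conditioned 5-parameter problem solved from ``n_starts``
       deterministic starting points (the physics-based initial guess
       plus seeded perturbations);
    2. the full per-curve fit, regularized, started from the collapsed
       optimum.  When ``alpha_reg`` is None the constant is tuned at the
       collapsed optimum against a roughness prior of one 1% neighbour
       step per parameter, which keeps alpha L at ~10% of the merit for
       chi2 near 1.

    Uncertainties are 1-sigma estimates from the Gauss-Newton curvature
    at the optimum.
    """
    n_curves = len(problem.curves)
    n_par = 2 + 3 * n_curves
    nq = problem.ffset.q.size
    norm = 1.0 / np.sqrt(n_curves * nq)

    x0 = np.empty(n_par)
    x0[0], x0[1] = problem.x0_common
    x0[2:] = np.tile(problem.x0_per_curve, n_curves)
    lo = np.empty(n_par)
    hi = np.empty(n_par)
    lo[0], hi[0] = problem.bounds_common[0]
    lo[1], hi[1] = problem.bounds_common[1]
    for k in range(3):
        lo[2 + k :: 3] = problem.bounds_per_curve[k][0]
        hi[2 + k :: 3] = problem.bounds_per_curve[k][1]

    def data_residuals(dh0, alpha_h, per, out):
        for m, curve in enumerate(problem.curves):
            try:
                I = model_intensity(
                    curve.T, curve.c, curve.I_S, per[m, 0], per[m, 1], per[m, 2],
                    dh0, alpha_h, problem.ffset, problem.Z, problem.M_DNA,
                    problem.phi_convention,
                )
                out[m * nq : (m + 1) * nq] = (curve.I - I) / curve.sigma * norm
            except RPAInstabilityError:
                out[m * nq : (m + 1) * nq] = 1e3
        return out

    # ---- stage 1: collapsed fit, one (R, J, d) for the whole batch
    def collapsed_residuals(x5):
        per = np.tile(x5[2:], (n_curves, 1))
        return data_residuals(x5[0], x5[1], per, np.empty(n_curves * nq))

    lo5 = np.array([lo[0], lo[1], lo[2], lo[3], lo[4]])
    hi5 = np.array([hi[0], hi[1], hi[2], hi[3], hi[4]])
    x5_0 = np.array([x0[0], x0[1], x0[2], x0[3], x0[4]])
    scale5 = np.array([0.01, 1e-5, 1.0, 5.0, 0.5])

    rng = np.random.default_rng(seed)
    starts = [x5_0]
    for _ in range(max(0, n_starts - 1)):
        pert = x5_0.copy()
        pert[0] += rng.uniform(-0.02, 0.02)
        pert[2:] *= 1.0 + rng.uniform(-0.08, 0.08, size=3)
        starts.append(np.clip(pert, lo5, hi5))

    best5 = None
    for x_start in starts:
        sol = least_squares(
            collapsed_residuals, x_start, bounds=(lo5, hi5), x_scale=scale5,
            max_nfev=max_nfev, method="trf", ftol=1e-14, xtol=1e-14, gtol=1e-14,
        )
        if best5 is None or sol.cost < best5.cost:
            best5 = sol

    if problem.alpha_reg is None:
        # 10% rule at the good-fit scale: for chi2 ~ 1 the penalty alpha L
        # should stay near 10% of the merit when the trajectories move by
        # ~1% between neighbouring curves (the roughness prior)
        L_probe = 3 * (n_curves - 1) * 1e-4
        alpha = 0.1 / L_probe
    else:
        alpha = float(problem.alpha_reg)

    # ---- stage 2: full per-curve fit from the collapsed optimum
    def residuals(x):
        dh0, alpha_h, per = _unpack(x, n_curves)
        res = np.empty(n_curves * nq + 3 * (n_curves - 1))
        data_residuals(dh0, alpha_h, per, res[: n_curves * nq])
        scale = np.mean(np.abs(per), axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        steps = np.diff(per, axis=0) / scale[None, :]
        res[n_curves * nq :] = np.sqrt(alpha) * steps.ravel()
        return res

    x_scale = np.empty(n_par)
    x_scale[0], x_scale[1] = 0.01, 1e-5
    x_scale[2::3], x_scale[3::3], x_scale[4::3] = 1.0, 5.0, 0.5

    x_full = np.empty(n_par)
    x_full[0], x_full[1] = best5.x[0], best5.x[1]
    x_full[2:] = np.tile(best5.x[2:], n_curves)
    best = least_squares(
        residuals, x_full, bounds=(lo, hi), x_scale=x_scale,
        max_nfev=max_nfev, method="trf", ftol=1e-12, xtol=1e-12, gtol=1e-14,
    )

    dh0, alpha_h, per = _unpack(best.x, n_curves)
    chi2_bar, models = _batch_chi2(problem, dh0, alpha_h, per)
    L = regularization(per)
    M = merit(chi2_bar, L, alpha)

    # 1-sigma uncertainties from the Gauss-Newton curvature
    J = best.jac
    dof = max(J.shape[0] - J.shape[1], 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = np.linalg.pinv(J.T @ J) * s2
        err = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        err = np.full(n_par, np.nan)

    return FitResult(
        dh0=float(dh0),
        alpha_h=float(alpha_h),
        per_curve=per,
        dh0_err=float(err[0]),
        alpha_h_err=float(err[1]),
        per_curve_err=err[2:].reshape(n_curves, 3),
        merit=M,
        chi2_bar=float(chi2_bar),
        L=float(L),
        alpha_reg=float(alpha),
        model_curves=models,
        converged=bool(best.status > 0),
        seed=seed,
        message=best.message,
    )
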