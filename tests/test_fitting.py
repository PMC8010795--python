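"""Merit function pieces, synthetic batches, and the global fit machinery.

These tests run on an analytic mock form-factor cache (fast); the full
end-to-end parameter-recovery study on the N = 29 ensemble lives in the
acceptance suite.
"""

import numpy as np
import pytest

import nanostar_saxs as ns
from nanostar_saxs.fitting import (
    BatchConditions,
    FitProblem,
    SAXSCurve,
    default_trajectories,
    fit_batch,
    merit,
    model_intensity,
    reduced_chi2,
    regularization,
    sigmoid_trajectory,
    synthesize_batch,
)


class TestSAXSCurve:
    def test_validation(self):
        q = np.linspace(0.02, 0.3, 10)
        with pytest.raises(ValueError, match="sigma"):
            SAXSCurve(q=q, I=np.ones(10), sigma=np.zeros(10), T=298.0, c=1.0, I_S=0.07)
        with pytest.raises(ValueError, match="increasing"):
            SAXSCurve(q=q[::-1], I=np.ones(10), sigma=np.ones(10), T=298.0, c=1.0, I_S=0.07)


class TestModelIntensity:
    def test_linear_in_number_density(self, mock_ffset):
        # at negligible volume fraction S_M ~ 1 and I is proportional to c
        kw = dict(R=45.0, J=200.0, d=12.0, dh0=1.05, alpha_h=0.0, ffset=mock_ffset)
        I1 = model_intensity(298.15, 0.002, 0.074, **kw)
        I2 = model_intensity(298.15, 0.004, 0.074, **kw)
        assert np.allclose(I2, 2.0 * I1, rtol=1e-3)

    def test_zero_concentration_is_dark(self, mock_ffset):
        I = model_intensity(298.15, 0.0, 0.074, 45.0, 200.0, 12.0, 1.05, 0.0, mock_ffset)
        assert np.allclose(I, 0.0)

    def test_dilute_high_T_approaches_form_factor_scattering(self, mock_ffset):
        """With weak correlations the curve approaches n P(q) (Guinier-like
        at low q)."""
        I = model_intensity(318.15, 1.0, 0.074, 43.5, 276.0, 13.5, 1.001, 0.0, mock_ffset)
        d_h = 1.001 * np.exp(-0.0 * 20.0)
        nP = (
            ns.number_density(1.0, 318.15)
            * mock_ffset.P_at(d_h)
            * ns.constants.ANGSTROM_PER_CM
        )
        assert np.allclose(I, nP, rtol=0.15)
        assert np.all(np.diff(np.log(I[:8])) < 0)


class TestReducedChi2:
    def _curve(self, n=10):
        q = np.linspace(0.02, 0.3, n)
        I = np.ones(n)
        return SAXSCurve(q=q, I=I, sigma=0.1 * I, T=298.0, c=1.0, I_S=0.07)

    def test_perfect_model(self):
        c = self._curve()
        assert reduced_chi2(c, c.I) == 0.0

    def test_one_sigma_offset(self):
        c = self._curve()
        assert reduced_chi2(c, c.I + c.sigma) == pytest.approx(1.0)

    def test_gaussian_calibration(self):
        n = 10_000
        rng = np.random.default_rng(42)
        q = np.linspace(0.02, 0.3, n)
        model = np.ones(n)
        sigma = 0.05 * np.ones(n)
        data = model + sigma * rng.standard_normal(n)
        curve = SAXSCurve(q=q, I=data, sigma=sigma, T=298.0, c=1.0, I_S=0.07)
        assert abs(reduced_chi2(curve, model) - 1.0) <= 3.0 * np.sqrt(2.0 / n)


class TestRegularization:
    def test_constant_trajectories(self):
        X = np.tile([50.0, 278.0, 14.0], (6, 1))
        assert regularization(X) == 0.0

    def test_single_one_percent_step(self):
        X = np.tile([50.0, 278.0, 14.0], (12, 1))
        X[6:, 0] *= 1.01
        assert regularization(X) == pytest.approx(1e-4, rel=2e-2)

    def test_order_matters(self):
        X = np.tile([50.0], (6, 1))
        X[:, 0] = [50, 50, 50, 51, 51, 51]
        Xperm = X[[0, 3, 1, 4, 2, 5]]
        assert regularization(Xperm) > regularization(X)

    def test_needs_two_curves(self):
        with pytest.raises(ValueError, match="2 curves"):
            regularization([[50.0, 278.0, 14.0]])


class TestMerit:
    def test_no_regularization(self):
        assert merit(1.3, 5.0, 0.0) == 1.3

    def test_zero_roughness(self):
        assert merit(1.3, 0.0, 100.0) == 1.3

    def test_decomposition(self):
        assert merit(1.1, 2e-3, 30.0) == pytest.approx(1.1 + 30.0 * 2e-3, rel=1e-15)

    def test_negative_alpha_raises(self):
        with pytest.raises(ValueError):
            merit(1.0, 1.0, -0.1)


class TestSynthesize:
    def test_seed_determinism(self, mock_ffset):
        cond = BatchConditions(concentration=18.0, I_S=0.022, dh0=1.0505)
        a, ta = synthesize_batch(mock_ffset, cond, noise_level=0.02, seed=5)
        b, tb = synthesize_batch(mock_ffset, cond, noise_level=0.02, seed=5)
        assert np.array_equal(ta, tb)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.I, cb.I)

    def test_noise_free_equals_forward_model(self, mock_ffset):
        cond = BatchConditions(concentration=1.0, I_S=0.074, dh0=1.001)
        curves, truth = synthesize_batch(mock_ffset, cond, noise_level=0.0, seed=5)
        R, J, d = truth[3]
        I = model_intensity(
            cond.temperatures_K[3], 1.0, 0.074, R, J, d, 1.001, 0.0, mock_ffset
        )
        assert np.allclose(curves[3].I, I, rtol=1e-14)

    def test_sigmoid_trajectories_bracket_limits(self):
        cond = BatchConditions(concentration=18.0, I_S=0.022)
        R, J, d = default_trajectories(cond)
        assert 49.0 < R[0] < R[-1] < 53.0
        assert J[0] > J[-1]
        assert d[0] > d[-1]
        mid = sigmoid_trajectory(np.array([298.15]), 0.0, 1.0)
        assert mid[0] == pytest.approx(0.5)


@pytest.fixture(scope="module")
def tiny_problem(mock_ffset):
    """Noise-free dense batch on the mock cache (full 12-step ramp)."""
    cond = BatchConditions(concentration=18.0, I_S=0.022, dh0=1.0505)
    curves, truth = synthesize_batch(mock_ffset, cond, noise_level=0.0, seed=2)
    return cond, curves, truth


class TestFitBatch:
    def test_noise_free_exact_recovery(self, mock_ffset, tiny_problem):
        cond, curves, truth = tiny_problem
        res = fit_batch(FitProblem(curves=curves, ffset=mock_ffset), seed=0, n_starts=2)
        assert res.converged
        assert res.dh0 == pytest.approx(cond.dh0, abs=1e-3)
        assert np.allclose(res.per_curve, truth, rtol=5e-3)
        assert res.chi2_bar < 1e-2  # merit -> ~0 in the perfect-model limit

    def test_merit_identity(self, mock_ffset, tiny_problem):
        _, curves, _ = tiny_problem
        res = fit_batch(FitProblem(curves=curves, ffset=mock_ffset), seed=0, n_starts=1)
        assert res.merit == pytest.approx(
            res.chi2_bar + res.alpha_reg * res.L, rel=1e-12
        )

    def test_refit_from_optimum_is_fixed_point(self, mock_ffset, tiny_problem):
        _, curves, _ = tiny_problem
        first = fit_batch(FitProblem(curves=curves, ffset=mock_ffset), seed=0, n_starts=1)
        again = fit_batch(
            FitProblem(
                curves=curves, ffset=mock_ffset,
                x0_common=(first.dh0, first.alpha_h),
                x0_per_curve=tuple(first.per_curve.mean(axis=0)),
                alpha_reg=first.alpha_reg,
            ),
            seed=0, n_starts=1,
        )
        assert np.allclose(again.per_curve, first.per_curve, rtol=1e-4)
        assert again.merit <= first.merit * (1.0 + 1e-9)

    def test_ramp_reversal_symmetry(self, mock_ffset, tiny_problem):
        _, curves, _ = tiny_problem
        forward = fit_batch(FitProblem(curves=curves, ffset=mock_ffset), seed=0, n_starts=1)
        backward = fit_batch(
            FitProblem(curves=list(reversed(curves)), ffset=mock_ffset),
            seed=0, n_starts=1,
        )
        assert np.allclose(backward.per_curve[::-1], forward.per_curve, rtol=1e-3)

    def test_grid_mismatch_raises(self, mock_ffset):
        q = np.linspace(0.02, 0.25, 20)
        c = SAXSCurve(q=q, I=np.ones(20), sigma=np.ones(20), T=298.0, c=18.0, I_S=0.022)
        with pytest.raises(ValueError, match="q-grid"):
            FitProblem(curves=[c, c], ffset=mock_ffset)
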