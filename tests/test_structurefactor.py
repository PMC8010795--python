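"""HSDY pair potential, Percus-Yevick + RPA structure factor."""

import numpy as np
import pytest
from scipy.integrate import quad

import nanostar_saxs as ns
from nanostar_saxs import constants as cst
from nanostar_saxs.structurefactor import (
    HSDYParams,
    RPAInstabilityError,
    first_peak,
    measured_structure_factor,
    pair_potential,
    py_structure_factor,
    rpa_structure_factor,
    yukawa_transform,
)


def dense_params(**kw):
    kw.setdefault("phi_convention", "effective-R")
    return HSDYParams.from_conditions(
        R=51.0, J=278.0, d=14.0, concentration=18.0, I_S=0.022, T=298.15, **kw
    )


def dilute_params():
    return HSDYParams.from_conditions(
        R=42.0, J=278.0, d=14.0, concentration=1.0, I_S=0.074, T=278.15
    )


class TestPairPotential:
    def test_contact_depth_is_minus_J(self):
        p = dense_params()
        curve = pair_potential(p, [2 * p.R])
        assert curve.u_A[0] == pytest.approx(-p.J, rel=1e-12)

    def test_sum_decomposition_and_core(self):
        p = dense_params()
        r = np.array([90.0, 110.0, 150.0, 300.0])
        curve = pair_potential(p, r)
        assert np.allclose(curve.u, curve.u_C + curve.u_A)
        inside = pair_potential(p, [50.0])
        assert np.isinf(inside.u[0])
        assert inside.n_excluded == 1

    def test_exponential_decay_to_zero(self):
        p = dense_params()
        far = 2 * p.R + 10.0 * max(1.0 / p.solvent.kappa, p.d)
        curve = pair_potential(p, [2 * p.R, far])
        contact_scale = max(abs(curve.u_C[0]), abs(curve.u_A[0]))
        assert abs(curve.u[1]) < 0.01 * contact_scale

    @pytest.mark.parametrize("params", [dense_params, dilute_params])
    def test_contact_repulsion_order_300_kJmol(self, params):
        p = params()
        curve = pair_potential(p, [2 * p.R])
        assert 200.0 < curve.u_C[0] < 400.0

    def test_near_cancellation_of_tails(self):
        """Repulsion and attraction almost compensate: |u| minimum is a few
        kJ/mol against ~300 kJ/mol contact magnitudes."""
        p = dilute_params()
        r = np.linspace(2 * p.R + 1e-3, 400.0, 4000)
        u = pair_potential(p, r).u
        assert -15.0 < u.min() < -3.0


class TestPercusYevick:
    def test_ideal_gas_limit(self):
        q = np.linspace(0.0, 0.3, 7)
        assert np.allclose(py_structure_factor(0.0, 42.0, q), 1.0)

    def test_compressibility_closed_form(self):
        # S0(0) = (1-phi)^4 / (1+2 phi)^2
        assert py_structure_factor(0.1, 40.0, [1e-12])[0] == pytest.approx(
            0.45563, abs=1e-5
        )

    @pytest.mark.parametrize("phi", [-0.01, 0.25, 0.4])
    def test_validity_domain(self, phi):
        with pytest.raises(ValueError, match="0.25"):
            py_structure_factor(phi, 40.0, [0.1])

    @pytest.mark.parametrize("phi", [0.01, 0.093, 0.2])
    def test_matches_quadrature_inversion(self, phi):
        """Closed form vs numerical transform of the PY direct correlation."""
        R = 51.0
        s = 2.0 * R
        a = (1 + 2 * phi) ** 2 / (1 - phi) ** 4
        b = -6 * phi * (1 + phi / 2) ** 2 / (1 - phi) ** 4
        g = phi * a / 2
        n = 6.0 * phi / (np.pi * s**3)
        q = np.array([0.001, 0.01, 0.05, 0.12, 0.3])
        closed = py_structure_factor(phi, R, q)
        for qq, Sc in zip(q, closed):
            val, _ = quad(
                lambda r: 4 * np.pi * r**2 * -(a + b * r / s + g * (r / s) ** 3)
                * np.sinc(qq * r / np.pi),
                0.0, s, limit=200,
            )
            assert Sc == pytest.approx(1.0 / (1.0 - n * val), abs=1e-6)


class TestYukawaTransform:
    @pytest.mark.parametrize("B", [1.0, -500.0, 14000.0])
    @pytest.mark.parametrize("kappa", [0.02, 0.0731, 0.3])
    def test_matches_quadrature(self, B, kappa):
        R = 48.0
        for qq in (1e-7, 0.01, 0.05, 0.15, 0.3):
            closed = yukawa_transform(B, kappa, R, [qq])[0]
            val, _ = quad(
                lambda r: 4 * np.pi * r * B * np.exp(-kappa * (r - 2 * R))
                * np.sinc(qq * r / np.pi),
                2 * R, 2 * R + 60.0 / kappa, limit=500,
            )
            scale = abs(4 * np.pi * B * (1 + 2 * kappa * R) / kappa**2)
            assert abs(closed - val) <= 1e-8 * scale

    def test_zero_mode_analytic(self):
        B, kappa, R = 7.0, 0.09, 42.0
        expected = 4 * np.pi * B * (1 + 2 * kappa * R) / kappa**2
        assert yukawa_transform(B, kappa, R, [0.0])[0] == pytest.approx(expected)

    def test_zero_amplitude(self):
        assert np.allclose(yukawa_transform(0.0, 0.1, 42.0, [0.0, 0.1]), 0.0)

    def test_nonpositive_kappa_raises(self):
        with pytest.raises(ValueError):
            yukawa_transform(1.0, 0.0, 42.0, [0.1])


class TestRPA:
    def test_no_perturbation_reduces_to_py(self):
        p = HSDYParams.from_conditions(
            R=51.0, J=0.0, d=14.0, concentration=18.0, I_S=0.022, T=298.15, Z=0
        )
        q = np.linspace(0.005, 0.3, 50)
        sf = rpa_structure_factor(p, q)
        assert np.allclose(sf.S, sf.S0, rtol=1e-12)

    def test_vanishing_density_gives_unity(self):
        p = HSDYParams.from_conditions(
            R=51.0, J=278.0, d=14.0, concentration=1e-6, I_S=0.022, T=298.15
        )
        sf = rpa_structure_factor(p, np.linspace(0.005, 0.3, 20))
        assert np.allclose(sf.S, 1.0, atol=1e-4)

    def test_instability_raises_with_offending_q(self):
        p = HSDYParams.from_conditions(
            R=51.0, J=400.0, d=20.0, concentration=18.0, I_S=0.022, T=298.15
        )
        with pytest.raises(RPAInstabilityError, match="q ="):
            rpa_structure_factor(p, np.linspace(0.002, 0.3, 400))

    def test_high_q_limits(self):
        p = dense_params()
        q = np.linspace(0.5, 0.7, 40)  # q 2R > 50
        sf = rpa_structure_factor(p, q)
        assert np.all(np.abs(sf.S0 - 1.0) < 0.01)
        assert np.all(np.abs(sf.S - 1.0) < 0.01)
        s_m = measured_structure_factor(sf.S, np.full_like(q, 0.5))
        assert np.all(np.abs(s_m - 1.0) < 0.01)

    def test_attraction_raises_compressibility(self):
        q0 = np.array([0.002])
        values = []
        for J in (0.0, 120.0, 200.0, 250.0):
            p = HSDYParams.from_conditions(
                R=42.0, J=J, d=14.0, concentration=2.0, I_S=0.074, T=298.15
            )
            values.append(rpa_structure_factor(p, q0).S[0])
        assert np.all(np.diff(values) > 0)

    def test_phi_conventions(self):
        eff = dense_params()
        dry = dense_params(phi_convention="dry-volume")
        assert eff.phi == pytest.approx(0.093, abs=0.002)
        assert dry.phi == pytest.approx(0.0099, abs=1e-4)  # < 0.02


class TestMeasuredStructureFactor:
    def test_unity_coupling(self):
        S = np.array([0.4, 1.2, 0.9])
        assert np.allclose(measured_structure_factor(S, np.ones(3)), S)

    def test_zero_coupling(self):
        S = np.array([0.4, 1.2, 0.9])
        assert np.allclose(measured_structure_factor(S, np.zeros(3)), 1.0)

    def test_unit_structure(self):
        beta = np.array([0.3, 0.7, 1.0])
        assert np.allclose(measured_structure_factor(np.ones(3), beta), 1.0)

    def test_damping_scales_with_beta(self):
        S = np.array([1.8, 1.4])
        beta = np.array([0.15, 0.05])
        s_m = measured_structure_factor(S, beta)
        assert np.allclose(np.abs(s_m - 1.0), beta * np.abs(S - 1.0))

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="aligned"):
            measured_structure_factor(np.ones(4), np.ones(3))


def test_first_peak_detection():
    q = np.linspace(0.001, 0.3, 300)
    S = 1.0 + 0.5 * np.exp(-((q - 0.05) ** 2) / 1e-4) + 0.2 * np.exp(
        -((q - 0.15) ** 2) / 1e-4
    )
    qs, height = first_peak(q, S)
    assert qs == pytest.approx(0.05, abs=0.002)
    assert height == pytest.approx(1.5, abs=0.01)
    assert first_peak(q, np.ones_like(q)) is None
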