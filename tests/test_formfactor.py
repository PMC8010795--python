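"""Multipole form factor: closed forms, decomposition, Guinier, bounds."""

import numpy as np
import pytest

import nanostar_saxs as ns
from nanostar_saxs.ensemble import Configuration, NanostarEnsemble
from nanostar_saxs.formfactor import debye_direct_oracle, scattering_center
from nanostar_saxs.hydration import HydrationShell


def _point_config(points, group="adenine"):
    pos = np.atleast_2d(np.asarray(points, dtype=float))
    return Configuration(
        positions=pos,
        groups=np.array([group] * len(pos), dtype=object),
        strand_index=np.zeros(len(pos), dtype=int),
        residue_index=np.arange(len(pos)),
    )


@pytest.fixture(scope="module")
def solvent():
    return ns.solvent_state(298.15)


@pytest.fixture(scope="module")
def q_grid():
    return np.linspace(0.0, 0.3, 31)


class TestClosedForms:
    def test_single_point_scatterer(self, solvent, table, q_grid):
        conf = _point_config([[3.0, -2.0, 1.0]])
        ens = NanostarEnsemble(configurations=[conf])
        ff = ns.ensemble_form_factor(
            ens, solvent, q_grid, Lmax=10, table=table, with_shell=False
        )
        b = table.group_length("adenine", q_grid)
        assert np.allclose(ff.P, b**2, rtol=1e-10)
        assert np.allclose(ff.beta, 1.0, atol=1e-10)

    def test_two_point_interference(self, solvent, table, q_grid):
        r = 8.0
        conf = _point_config([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
        ens = NanostarEnsemble(configurations=[conf])
        ff = ns.ensemble_form_factor(
            ens, solvent, q_grid, Lmax=30, table=table, with_shell=False
        )
        b = table.group_length("adenine", q_grid)
        expected = 2.0 * b**2 * (1.0 + np.sinc(q_grid * r / np.pi))
        assert np.allclose(ff.P, expected, rtol=1e-10)

    def test_forward_limit_is_squared_total_length(self, solvent, table, config, shell):
        ens = NanostarEnsemble(configurations=[config])
        q = np.array([0.0, 0.05])
        d_h = 1.05
        ff = ns.ensemble_form_factor(
            ens, solvent, q, d_h=d_h, Lmax=36, table=table, shells=[shell]
        )
        total = table.site_lengths(config.groups, np.array([0.0]))[:, 0].sum()
        total += shell.N_h * table.water_length(np.array([0.0]), d_h)[0]
        assert ff.P_at(d_h)[0] == pytest.approx(total**2, rel=1e-8)


class TestHydrationDecomposition:
    def test_quadratic_cache_matches_direct_debye(self, solvent, table):
        rng = np.random.default_rng(0)
        conf = _point_config(rng.uniform(-6, 6, size=(7, 3)), group="guanine")
        shell = HydrationShell(centers=rng.uniform(-8, 8, size=(5, 3)))
        ens = NanostarEnsemble(configurations=[conf])
        q = np.linspace(0.0, 0.3, 16)
        ff = ns.ensemble_form_factor(
            ens, solvent, q, Lmax=25, table=table, shells=[shell]
        )
        for d_h in (0.9, 1.0, 1.02, 1.05, 1.3):
            direct = debye_direct_oracle(conf, shell, solvent, d_h, q, table=table)
            assert np.allclose(ff.P_at(d_h), direct, rtol=1e-9)

    def test_shell_vanishes_at_unity_density(self, solvent, table):
        rng = np.random.default_rng(1)
        conf = _point_config(rng.uniform(-6, 6, size=(5, 3)))
        shell = HydrationShell(centers=rng.uniform(-8, 8, size=(4, 3)))
        ens = NanostarEnsemble(configurations=[conf])
        q = np.linspace(0.0, 0.3, 8)
        with_shell = ns.ensemble_form_factor(
            ens, solvent, q, d_h=1.0, Lmax=20, table=table, shells=[shell]
        )
        without = ns.ensemble_form_factor(
            ens, solvent, q, Lmax=20, table=table, with_shell=False
        )
        assert np.allclose(with_shell.P_at(1.0), without.P_at(1.0), rtol=1e-12)


@pytest.fixture(scope="module")
def small_ensemble_ff(solvent, table):
    ens = ns.build_ensemble(n_configurations=2, seed=21)
    q = np.linspace(0.014, 0.3, 30)
    ff = ns.ensemble_form_factor(ens, solvent, q, d_h=1.05, Lmax=36, table=table)
    return ens, ff


class TestEnsembleProperties:
    def test_low_truncation_order_warns(self, solvent, table):
        ens = ns.build_ensemble(n_configurations=1, seed=21)
        with pytest.warns(UserWarning, match="Lmax"):
            ns.ensemble_form_factor(
                ens, solvent, np.array([0.2, 0.3]), Lmax=5, table=table,
                with_shell=False,
            )

    def test_form_factor_positive(self, small_ensemble_ff):
        _, ff = small_ensemble_ff
        assert np.all(ff.P > 0)

    def test_beta_bounded(self, small_ensemble_ff):
        _, ff = small_ensemble_ff
        for d_h in (1.0, 1.05, 1.1):
            beta = ff.beta_at(d_h)
            assert np.all(beta >= 0.0)
            assert np.all(beta <= 1.0 + 1e-12)

    def test_coupling_function_alias(self, small_ensemble_ff):
        _, ff = small_ensemble_ff
        assert np.array_equal(ns.coupling_function(ff), ff.beta)

    def test_guinier_slope_matches_weighted_rg(self, solvent, table):
        ens = ns.build_ensemble(n_configurations=2, seed=13)
        shells = [ns.hydrate(c, table) for c in ens]
        d_h = 1.05
        q = np.linspace(1e-4, 0.008, 12)
        ff = ns.ensemble_form_factor(
            ens, solvent, q, d_h=d_h, Lmax=12, table=table, shells=shells
        )
        # scattering-weighted Rg^2, ensemble-averaged with F(0)^2 weights
        num = den = 0.0
        for conf, shell in zip(ens, shells):
            w = table.site_lengths(conf.groups, np.array([0.0]))[:, 0]
            pos = conf.positions
            w_sh = np.full(shell.N_h, table.water_length(np.array([0.0]), d_h)[0])
            w_all = np.concatenate([w, w_sh])
            pos_all = np.vstack([pos, shell.centers])
            centre = scattering_center(pos_all, w_all)
            rg2 = np.sum(w_all * np.sum((pos_all - centre) ** 2, axis=1)) / w_all.sum()
            f0 = w_all.sum()
            num += f0**2 * rg2
            den += f0**2
        rg2_eff = num / den
        slope = np.polyfit(q**2, np.log(ff.P), 1)[0]
        assert -3.0 * slope == pytest.approx(rg2_eff, rel=0.02)

    def test_empty_ensemble_raises(self, solvent, table):
        with pytest.raises(ValueError, match="empty"):
            ns.ensemble_form_factor(
                NanostarEnsemble(configurations=[]), solvent, [0.1], table=table
            )
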