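import numpy as np
import pytest

import nanostar_saxs as ns


@pytest.fixture(scope="session")
def solvent_ref():
    """Reference-temperature buffer of the dense sample."""
    return ns.solvent_state(298.15, 18.0, 0.022)


@pytest.fixture(scope="session")
def table(solvent_ref):
    return ns.GroupScatteringTable(rho0=solvent_ref.rho0)


@pytest.fixture(scope="session")
def topology():
    return ns.build_topology(ns.default_sequences())


@pytest.fixture(scope="session")
def config(topology):
    return ns.sample_configuration(topology, rng_seed=5)


@pytest.fixture(scope="session")
def shell(config, table):
    return ns.hydrate(config, table)


@pytest.fixture(scope="session")
def mock_ffset():
    """Analytic form-factor cache for exercising the fitting machinery.

    Smooth Guinier-like envelope with a weak shell channel; satisfies
    P > 0 and 0 <= beta <= 1 by construction.
    """
    q = np.linspace(0.014, 0.3, 48)
    env = np.exp(-((q * 40.0) ** 2) / 3.0)
    A = 0.12 * (env + 0.02 / (1.0 + (q / 0.1) ** 2))
    C = 0.004 * np.exp(-((q * 45.0) ** 2) / 3.0)
    decor = np.exp(-((q * 25.0) ** 2) / 2.0)
    F0 = np.sqrt(A) * decor
    F1 = np.sqrt(C) * decor * 0.95
    B = 2.0 * np.sqrt(A * C) * 0.9
    return ns.FormFactorSet(
        q=q, A=A, B=B, C=C, F0=F0.astype(complex), F1=F1.astype(complex),
        d_h=1.05, N=1, Lmax=0,
    )
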