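"""First-hydration-shell construction with dummy water spheres.

Dummy water centres are placed at contact with the united-atom surfaces:
candidate points are generated on spheres of radius (group radius + water
radius) around every site on a deterministic Fibonacci lattice, rejected
when they penetrate any united atom, and accepted greedily subject to a
hard-core exclusion between waters.  The accepted centres carry, in the
scattering model, the excess length (d_h - 1) rho0 g_w(q) of a water
molecule whose relative mass density d_h differs from bulk; the shell
vanishes identically at d_h = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import constants as c
from .scattering import GroupScatteringTable

__all__ = ["ShellParams", "HydrationShell", "hydrate"]

#: effective radius of one bulk water molecule [Å]
WATER_RADIUS = (3.0 * c.V_WATER / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class ShellParams:
    """Geometry of the dummy-water shell.

    ``hard_core`` is the minimum water-water distance (first-shell O-O
    distance); ``n_candidates`` the Fibonacci points per site sphere;
    ``contact_tolerance`` the numerical slack on the contact condition.
    """

    hard_core: float = 2.8
    n_candidates: int = 60
    contact_tolerance: float = 1e-6


@dataclass
class HydrationShell:
    """Dummy-water centres of the first hydration shell."""

    centers: np.ndarray  # (N_h, 3) [Å]
    v_w: float = c.V_WATER

    @property
    def N_h(self) -> int:
        return self.centers.shape[0]


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    theta = np.pi * (3.0 - np.sqrt(5.0)) * k
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def hydrate(
    configuration,
    table: GroupScatteringTable,
    params: ShellParams | None = None,
    rng=None,
) -> HydrationShell:
    """Place dummy waters at contact with a configuration's united atoms.

    Deterministic for a fixed configuration and parameter set; passing a
    seeded ``rng`` randomizes the candidate acceptance order (useful to
    probe the stability of the shell count).
    """
    p = params or ShellParams()
    pos = np.asarray(configuration.positions, dtype=float)
    radii = np.array([table.group_radius(g) for g in configuration.groups])

    sphere = _fibonacci_sphere(p.n_candidates)
    contact = radii[:, None, None] + WATER_RADIUS
    candidates = (pos[:, None, :] + contact * sphere[None, :, :]).reshape(-1, 3)

    # cull candidates that penetrate any united atom
    tree = cKDTree(pos)
    max_reach = radii.max() + WATER_RADIUS
    keep = np.ones(len(candidates), dtype=bool)
    neighbours = tree.query_ball_point(candidates, max_reach + p.contact_tolerance)
    for i, nb in enumerate(neighbours):
        if not nb:
            continue
        d = np.linalg.norm(candidates[i] - pos[nb], axis=1)
        if np.any(d < radii[nb] + WATER_RADIUS - p.contact_tolerance):
            keep[i] = False
    candidates = candidates[keep]

    order = np.arange(len(candidates))
    if rng is not None:
        order = rng.permutation(order)

    # greedy hard-core packing on a cell grid
    cell = p.hard_core
    grid: dict[tuple, list] = {}
    accepted = []
    hc2 = p.hard_core**2
    for idx in order:
        pt = candidates[idx]
        key = tuple((pt // cell).astype(int))
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for other in grid.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        if np.sum((pt - other) ** 2) < hc2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted.append(pt)
            grid.setdefault(key, []).append(pt)

    centers = np.asarray(accepted, dtype=float).reshape(-1, 3)
    return HydrationShell(centers=centers)
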