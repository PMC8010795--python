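"""Excess X-ray scattering lengths of united-atom groups.

Each united-atom group j (backbone, adenine, guanine, cytosine, thymine)
is assigned a q-dependent excess scattering length

    b_j(q) = sqrt( sum_{a,a'} db_a(q) db_a'(q) j0(q r_aa') ),

the square root of the orientationally averaged (Debye) squared amplitude
of the real atoms a belonging to the group, evaluated on idealized
crystal-geometry coordinates.  The per-atom excess length is

    db_a(q) = f_a(q) r_e - rho0 g_a(q),

the in-vacuum Thomson amplitude minus the amplitude of the water displaced
by the atom, with g_a(q) = nu_a exp(-q^2 nu_a^(2/3) / (4 pi)) the transform
of a spherical Gaussian normalized to the atomic van der Waals volume
nu_a.  Taking b_j as a non-negative scalar discards the internal phase of
the group; that loss is part of the united-atom approximation and is kept
deliberately.

All lengths are in Å (r_e = 2.818e-5 Å); q in Å^-1.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from . import constants as c

__all__ = [
    "thomson_amplitude",
    "displaced_solvent_transform",
    "excess_atom_length",
    "GroupScatteringTable",
    "VDW_VOLUMES",
    "FORM_FACTOR_COEFFS",
]

# International Tables for Crystallography vol. C (4-Gaussian) coefficients
# for neutral atoms: f(q) = sum_i a_i exp(-b_i s^2) + const, s = q / (4 pi).
FORM_FACTOR_COEFFS = {
    "H": {
        "a": (0.493002, 0.322912, 0.140191, 0.04081),
        "b": (10.5109, 26.1257, 3.14236, 57.7997),
        "c": 0.003038,
    },
    "C": {
        "a": (2.31000, 1.02000, 1.58860, 0.865000),
        "b": (20.8439, 10.2075, 0.568700, 51.6512),
        "c": 0.215600,
    },
    "N": {
        "a": (12.2126, 3.13220, 2.01250, 1.16630),
        "b": (0.005700, 9.89330, 28.9975, 0.582600),
        "c": -11.529,
    },
    "O": {
        "a": (3.04850, 2.28680, 1.54630, 0.867000),
        "b": (13.2771, 5.70110, 0.323900, 32.9089),
        "c": 0.250800,
    },
    "P": {
        "a": (6.43450, 4.17910, 1.78000, 1.49080),
        "b": (1.90670, 27.1570, 0.526000, 68.1645),
        "c": 1.11490,
    },
}

# atomic van der Waals volumes [Å^3] for the displaced-solvent dummy atoms
# (Fraser, MacRae & Suzuki set, as used by standard dummy-atom methods)
VDW_VOLUMES = {"H": 5.15, "C": 16.44, "N": 2.49, "O": 9.13, "P": 5.73}

_GROUP_RESNAME = {
    "BBN": "backbone",
    "ADE": "adenine",
    "GUA": "guanine",
    "CYT": "cytosine",
    "THY": "thymine",
}


def thomson_amplitude(element: str, q, coefficients=None) -> np.ndarray:
    """In-vacuum atomic scattering amplitude f(q) r_e [Å].

    ``f(q)`` is the Gaussian-sum parameterization of the atomic electron
    density transform; f(0) equals the atomic number.
    """
    coeffs = (coefficients or FORM_FACTOR_COEFFS).get(element)
    if coeffs is None:
        raise KeyError(f"no scattering-factor coefficients for element {element!r}")
    s2 = (np.asarray(q, dtype=float) / (4.0 * np.pi)) ** 2
    f = np.full_like(np.asarray(s2, dtype=float), coeffs["c"])
    for a, b in zip(coeffs["a"], coeffs["b"]):
        f = f + a * np.exp(-b * s2)
    return c.R_ELECTRON * f


def displaced_solvent_transform(q, volume: float) -> np.ndarray:
    """Spherical-Gaussian transform g(q) of a displaced volume [Å^3].

    Normalized so that g(0) = volume.
    """
    q = np.asarray(q, dtype=float)
    return volume * np.exp(-(q**2) * volume ** (2.0 / 3.0) / (4.0 * np.pi))


def excess_atom_length(element: str, q, rho0: float, volumes=None,
                       coefficients=None) -> np.ndarray:
    """Per-atom excess scattering length db_a(q) [Å].

    ``rho0`` is the solvent scattering-length density [Å^-2]; rho0 = 0
    gives the in-vacuum amplitude.
    """
    vols = volumes or VDW_VOLUMES
    if element not in vols:
        raise KeyError(f"no van der Waals volume registered for {element!r}")
    return thomson_amplitude(element, q, coefficients) - rho0 * displaced_solvent_transform(
        q, vols[element]
    )


def _load_templates(path=None):
    """Parse the idealized group-template PDB into {group: (elements, xyz)}."""
    if path is None:
        ref = resources.files("nanostar_saxs").joinpath("data/group_templates.pdb")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    groups: dict[str, tuple[list, list]] = {}
    for line in text.splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        res = line[17:20].strip()
        label = _GROUP_RESNAME.get(res, res.lower())
        el = line[76:78].strip()
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        groups.setdefault(label, ([], []))
        groups[label][0].append(el)
        groups[label][1].append(xyz)
    return {
        k: (tuple(els), np.asarray(xyz, dtype=float)) for k, (els, xyz) in groups.items()
    }


class GroupScatteringTable:
    """Tabulated excess scattering lengths of the united-atom groups.

    Parameters
    ----------
    rho0 : solvent scattering-length density [Å^-2]
    volumes, coefficients : overridable atomic tables
    template_path : optional PDB of group geometries (default: the
        idealized fixture shipped with the package)

    Besides the five elementary groups, combined single-site groups
    ``nt_<base>`` (backbone + base as one united atom) are available for
    coarse single-site ensembles; the base template is then displaced from
    the backbone template by the mean B-form backbone-base offset.
    """

    #: mean offset of the base centroid from the backbone centroid when a
    #: combined nucleotide group is assembled from the two templates [Å]
    COMBINED_OFFSET = 4.5

    def __init__(self, rho0: float, volumes=None, coefficients=None,
                 template_path=None):
        self.rho0 = float(rho0)
        self.volumes = dict(volumes or VDW_VOLUMES)
        self.coefficients = coefficients or FORM_FACTOR_COEFFS
        self._templates = _load_templates(template_path)
        self._cache: dict = {}
        self.clip_warnings = 0

    def groups(self):
        base = list(self._templates)
        return base + [f"nt_{g}" for g in base if g != "backbone"]

    def _atoms(self, group: str):
        if group.startswith("nt_"):
            els_b, xyz_b = self._templates["backbone"]
            els_x, xyz_x = self._templates[group[3:]]
            offset = np.array([self.COMBINED_OFFSET, 0.0, 0.0])
            return els_b + els_x, np.vstack([xyz_b, xyz_x + offset])
        if group not in self._templates:
            raise KeyError(f"unknown scattering group {group!r}")
        return self._templates[group]

    def group_volume(self, group: str) -> float:
        els, _ = self._atoms(group)
        return float(sum(self.volumes[e] for e in els))

    def group_radius(self, group: str) -> float:
        """Effective radius of the group's displaced volume [Å]."""
        return float((3.0 * self.group_volume(group) / (4.0 * np.pi)) ** (1.0 / 3.0))

    def group_length(self, group: str, q) -> np.ndarray:
        """Excess scattering length b_j(q) [Å] on a q-grid [Å^-1]."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        key = (group, q.tobytes())
        if key in self._cache:
            return self._cache[key]
        els, xyz = self._atoms(group)
        db = np.stack(
            [
                excess_atom_length(e, q, self.rho0, self.volumes, self.coefficients)
                for e in els
            ]
        )  # (n_atoms, nq)
        diff = xyz[:, None, :] - xyz[None, :, :]
        dist = np.sqrt(np.sum(diff**2, axis=-1))
        # Debye double sum; np.sinc(x/pi) = j0(x)
        j0 = np.sinc(q[None, None, :] * dist[:, :, None] / np.pi)
        sq = np.einsum("iq,jq,ijq->q", db, db, j0)
        neg = sq < 0
        if np.any(neg):
            self.clip_warnings += int(np.count_nonzero(neg))
            sq = np.where(neg, 0.0, sq)
        out = np.sqrt(sq)
        self._cache[key] = out
        return out

    def site_lengths(self, groups, q) -> np.ndarray:
        """Matrix of b(q) for a sequence of site group labels, (n, nq)."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        unique = {g: self.group_length(g, q) for g in set(groups)}
        return np.stack([unique[g] for g in groups])

    def water_length(self, q, d_h: float = 1.0) -> np.ndarray:
        """Excess length (d_h - 1) rho0 g_w(q) of one shell water [Å]."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        return (d_h - 1.0) * self.rho0 * displaced_solvent_transform(q, c.V_WATER)
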