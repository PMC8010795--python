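"""Coarse-grained nanostar configurations: builder and oxDNA reader.

The scattering model works on "united-atom" sites: each nucleotide is
represented by a backbone site (phosphate + deoxyribose) and a base site,
classified into the five scattering groups backbone/adenine/guanine/
cytosine/thymine.  Ensembles come from two sources:

* :func:`build_ensemble` — a geometric builder that stands in for a
  molecular-dynamics trajectory.  Arms are rigid ideal B-form duplexes
  (rise 3.4 Å/bp, twist 36°/bp, within a 10 Å duplex envelope) emanating
  from a flexible four-way junction; arm directions are drawn around
  tetrahedral axes with a configurable angular spread, and the unpaired
  spacer + overhang bases continue past each arm tip as a 6 Å/step random
  walk.  United-atom sites are placed at the coarse-grained interaction
  site radii (backbone 6.3 Å, base 1.8 Å from the duplex axis), matching
  the site convention of the oxDNA reader below, so ensembles from the
  two sources are interchangeable.  The builder reproduces realistic mass
  distributions, not DNA energetics.

* :func:`read_oxdna` — reads coarse-grained trajectory frames in the oxDNA
  configuration/topology format and maps each nucleotide to its backbone
  and base interaction sites.

All coordinates are Å, right handed, no periodic boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import NanostarTopology, build_topology, default_sequences

__all__ = [
    "BuilderParams",
    "Configuration",
    "NanostarEnsemble",
    "build_ensemble",
    "sample_configuration",
    "radius_of_gyration",
    "read_oxdna",
    "write_oxdna",
    "export_pdb",
    "SamplingError",
    "OxdnaParseError",
]

GROUP_OF_BASE = {
    "A": "adenine",
    "G": "guanine",
    "C": "cytosine",
    "T": "thymine",
}

#: 1 oxDNA length unit in Å
OXDNA_LENGTH = 8.518
#: offsets of the backbone and base interaction sites along the
#: backbone->base versor, in oxDNA length units
OXDNA_POS_BACK = -0.4
OXDNA_POS_BASE = 0.4

_TETRAHEDRAL = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
) / np.sqrt(3.0)


class SamplingError(RuntimeError):
    """Raised when the rejection budget of the builder is exhausted."""


class OxdnaParseError(ValueError):
    """Raised on malformed oxDNA configuration/topology input."""


@dataclass(frozen=True)
class BuilderParams:
    """Geometry knobs of the synthetic builder (lengths in Å, angles rad).

    ``arm_spread`` is the angular spread of the arm directions about the
    tetrahedral axes (the junction flexibility); ``overhang_wobble``
    controls the directional noise of the single-stranded walk past the
    arm tips.
    """

    rise: float = 3.4
    twist: float = np.deg2rad(36.0)
    backbone_radius: float = 6.3
    base_radius: float = 1.8
    duplex_radius: float = 10.0
    strand_offset: float = np.deg2rad(154.0)  # minor-groove azimuth offset
    junction_offset: float = 12.0
    arm_spread: float = 0.25
    overhang_wobble: float = 0.5
    ss_step: float = 6.0
    min_separation: float = 1.0
    max_attempts: int = 1000
    sites_per_nucleotide: int = 2  # 2 = backbone+base, 1 = combined


@dataclass
class Configuration:
    """One coarse-grained configuration of united-atom sites."""

    positions: np.ndarray  # (n_sites, 3) [Å]
    groups: np.ndarray  # (n_sites,) group labels
    strand_index: np.ndarray  # (n_sites,) provenance
    residue_index: np.ndarray  # (n_sites,)

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def n_nucleotides(self) -> int:
        return len({(s, r) for s, r in zip(self.strand_index, self.residue_index)})


@dataclass
class NanostarEnsemble:
    """A list of configurations sharing one topology.

    The origin convention for orientational averaging (applied downstream)
    is the excess-scattering-length-weighted centroid of each
    configuration.
    """

    configurations: list
    topology: NanostarTopology | None = None

    @property
    def N(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)


def radius_of_gyration(configuration: Configuration) -> float:
    """Mass-uniform radius of gyration about the site centroid [Å]."""
    pos = configuration.positions
    if pos.shape[0] < 1:
        raise ValueError("configuration has no sites")
    centred = pos - pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def _frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def _min_pair_distance(pos: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pos).query(pos, k=2)
    return float(d[:, 1].min())


def sample_configuration(
    topology: NanostarTopology,
    rng_seed: int,
    params: BuilderParams | None = None,
) -> Configuration:
    """Draw one nanostar configuration from the geometric builder.

    Deterministic for a given ``rng_seed`` and parameter set.  Draws whose
    minimum site-site distance falls below ``params.min_separation`` are
    rejected and resampled; a :class:`SamplingError` is raised when
    ``params.max_attempts`` draws have been rejected.
    """
    p = params or BuilderParams()
    if p.sites_per_nucleotide not in (1, 2):
        raise ValueError("sites_per_nucleotide must be 1 or 2")
    rng = np.random.default_rng(rng_seed)
    for _ in range(p.max_attempts):
        conf = _draw(topology, rng, p)
        if _min_pair_distance(conf.positions) > p.min_separation:
            return conf
    raise SamplingError(
        f"no overlap-free configuration within {p.max_attempts} attempts"
    )


def _nucleotide_sites(rng, p, bb_pos, base_pos):
    if p.sites_per_nucleotide == 2:
        return [(bb_pos, "backbone"), (base_pos, None)]
    # combined mode: single site at the midpoint, carrying a joint group
    return [(0.5 * (bb_pos + base_pos), "combined")]


def _draw(topology: NanostarTopology, rng, p: BuilderParams) -> Configuration:
    strands = topology.strands
    n_arms = 4

    # arm directions about tetrahedral axes
    axes = []
    for t in _TETRAHEDRAL:
        u = t + p.arm_spread * rng.normal(size=3)
        axes.append(u / np.linalg.norm(u))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_arms)

    # positions[strand][residue] -> (backbone xyz, base xyz)
    sites: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def place(strand, residue, u, e1, e2, z, phi):
        cb, sb = np.cos(phi), np.sin(phi)
        bb = z * u + p.backbone_radius * (cb * e1 + sb * e2)
        base = z * u + p.base_radius * (cb * e1 + sb * e2)
        sites[(strand, residue)] = (bb, base)

    # rigid duplex arms: arm k pairs section B of strand k (residues 21-40,
    # junction->tip) with section A of strand k+1 (residues 0-19, tip->junction)
    for k in range(n_arms):
        u = axes[k]
        e1, e2 = _frame(u)
        partner = (k + 1) % n_arms
        for t in range(20):
            z = p.junction_offset + p.rise * t
            phi = phases[k] + p.twist * t
            place(k, 21 + t, u, e1, e2, z, phi)
            place(partner, 19 - t, u, e1, e2, z, phi + p.strand_offset)

    # unpaired junction base of each strand, tucked between its two arms
    for k in range(n_arms):
        u_in = axes[(k - 1) % n_arms]  # arm carrying this strand's A section
        u_out = axes[k]  # arm carrying this strand's B section
        bisector = u_in + u_out
        nrm = np.linalg.norm(bisector)
        bisector = bisector / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
        centre = 0.6 * p.junction_offset * bisector + rng.normal(0.0, 1.5, 3)
        off = rng.normal(size=3)
        off *= 2.0 / np.linalg.norm(off)
        sites[(k, 20)] = (centre + off, centre - off)

    # spacers + overhang: freely jointed walk past the tip of the arm that
    # carries this strand's B section; the first step clears the duplex,
    # later steps are direction-uncorrelated apart from the wobble bias
    for k in range(n_arms):
        u = axes[k]
        tip = (p.junction_offset + p.rise * 19.5) * u
        prev = tip
        for step, residue in enumerate(range(41, 49)):
            if step == 0:
                direction = u + p.overhang_wobble * rng.normal(size=3)
            else:
                direction = p.overhang_wobble * u + rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            node = prev + p.ss_step * direction
            off = rng.normal(size=3)
            off *= 2.0 / np.linalg.norm(off)
            sites[(k, residue)] = (node + off, node - off)
            prev = node

    positions, groups, s_idx, r_idx = [], [], [], []
    for strand in range(n_arms):
        for residue, base_letter in enumerate(strands[strand]):
            bb, base = sites[(strand, residue)]
            for pos, tag in _nucleotide_sites(rng, p, bb, base):
                positions.append(pos)
                if tag == "backbone":
                    groups.append("backbone")
                elif tag == "combined":
                    groups.append("nt_" + GROUP_OF_BASE[base_letter])
                else:
                    groups.append(GROUP_OF_BASE[base_letter])
                s_idx.append(strand)
                r_idx.append(residue)
    return Configuration(
        positions=np.asarray(positions, dtype=float),
        groups=np.asarray(groups, dtype=object),
        strand_index=np.asarray(s_idx, dtype=int),
        residue_index=np.asarray(r_idx, dtype=int),
    )


def build_ensemble(
    n_configurations: int = 29,
    seed: int = 0,
    sequences=None,
    params: BuilderParams | None = None,
) -> NanostarEnsemble:
    """Build an ensemble of independent synthetic configurations."""
    topo = build_topology(sequences if sequences is not None else default_sequences())
    seeds = np.random.SeedSequence(seed).spawn(n_configurations)
    confs = [
        sample_configuration(topo, np.random.default_rng(s).integers(2**31), params)
        for s in seeds
    ]
    return NanostarEnsemble(configurations=confs, topology=topo)


# ---------------------------------------------------------------------------
# oxDNA format
# ---------------------------------------------------------------------------


def _read_topology_file(top_path):
    with open(top_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise OxdnaParseError(f"{top_path}: empty topology")
    head = lines[0].split()
    if len(head) < 2:
        raise OxdnaParseError(f"{top_path}:1: expected 'N_nt N_strands'")
    n_nt, _n_strands = int(head[0]), int(head[1])
    strand_ids, bases = [], []
    for i, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        parts = ln.split()
        if len(parts) < 4:
            raise OxdnaParseError(f"{top_path}:{i}: expected 'strand base n3 n5'")
        strand_ids.append(int(parts[0]))
        bases.append(parts[1].upper())
    if len(bases) != n_nt:
        raise OxdnaParseError(
            f"{top_path}: header declares {n_nt} nucleotides, found {len(bases)}"
        )
    return strand_ids, bases


def read_oxdna(conf_path, top_path) -> NanostarEnsemble:
    """Read an oxDNA trajectory into an ensemble of united-atom sites.

    Each nucleotide's centre of mass and backbone-base versor are mapped to
    a backbone site at -0.4 and a base site at +0.4 oxDNA length units
    along the versor (3.41 Å).  Coordinates are converted from oxDNA units
    to Å; box images are not unwrapped (single molecules are assumed to be
    whole in the frame).
    """
    strand_ids, bases = _read_topology_file(top_path)
    n_nt = len(bases)

    residue_index = []
    counters: dict[int, int] = {}
    for sid in strand_ids:
        residue_index.append(counters.get(sid, 0))
        counters[sid] = counters.get(sid, 0) + 1

    configurations = []
    with open(conf_path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].lstrip().startswith("t"):
            raise OxdnaParseError(f"{conf_path}:{i + 1}: expected 't = ...' header")
        if i + 2 >= len(lines) or not lines[i + 1].lstrip().startswith("b") or not lines[
            i + 2
        ].lstrip().startswith("E"):
            raise OxdnaParseError(
                f"{conf_path}:{i + 1}: malformed frame header (need t/b/E lines)"
            )
        i += 3
        com = np.empty((n_nt, 3))
        a1 = np.empty((n_nt, 3))
        for k in range(n_nt):
            if i + k >= len(lines) or lines[i + k].lstrip().startswith("t"):
                raise OxdnaParseError(
                    f"{conf_path}:{i + k + 1}: frame has {k} rows, topology "
                    f"declares {n_nt} nucleotides"
                )
            vals = lines[i + k].split()
            if len(vals) < 9:
                raise OxdnaParseError(
                    f"{conf_path}:{i + k + 1}: expected >= 9 columns, got {len(vals)}"
                )
            com[k] = [float(v) for v in vals[0:3]]
            a1[k] = [float(v) for v in vals[3:6]]
        i += n_nt

        positions, groups, s_idx, r_idx = [], [], [], []
        for k in range(n_nt):
            bb = (com[k] + OXDNA_POS_BACK * a1[k]) * OXDNA_LENGTH
            bs = (com[k] + OXDNA_POS_BASE * a1[k]) * OXDNA_LENGTH
            positions.extend([bb, bs])
            groups.extend(["backbone", GROUP_OF_BASE[bases[k]]])
            s_idx.extend([strand_ids[k]] * 2)
            r_idx.extend([residue_index[k]] * 2)
        configurations.append(
            Configuration(
                positions=np.asarray(positions),
                groups=np.asarray(groups, dtype=object),
                strand_index=np.asarray(s_idx),
                residue_index=np.asarray(r_idx),
            )
        )
    if not configurations:
        raise OxdnaParseError(f"{conf_path}: no frames found")
    return NanostarEnsemble(configurations=configurations)


def write_oxdna(ensemble: NanostarEnsemble, conf_path, top_path) -> None:
    """Write an ensemble in oxDNA configuration/topology format.

    Each nucleotide's two sites are reduced to a centre of mass (their
    midpoint) and a backbone->base versor; re-reading therefore restores
    the oxDNA convention of site offsets (±0.4 length units about the
    centre of mass), not any other intra-nucleotide separation.
    """
    first = ensemble.configurations[0]
    if first.n_sites != 2 * first.n_nucleotides:
        raise ValueError("write_oxdna requires two sites per nucleotide")

    inv_group = {v: k for k, v in GROUP_OF_BASE.items()}
    nt_order = []
    seen = set()
    for s, r in zip(first.strand_index, first.residue_index):
        if (s, r) not in seen:
            seen.add((s, r))
            nt_order.append((s, r))

    with open(top_path, "w") as fh:
        n_strands = len(set(s for s, _ in nt_order))
        fh.write(f"{len(nt_order)} {n_strands}\n")
        for s, r in nt_order:
            mask = (first.strand_index == s) & (first.residue_index == r)
            letters = [inv_group[g] for g in first.groups[mask] if g in inv_group]
            fh.write(f"{s} {letters[0]} -1 -1\n")

    with open(conf_path, "w") as fh:
        for it, conf in enumerate(ensemble):
            fh.write(f"t = {it}\n")
            fh.write("b = 0 0 0\n")
            fh.write("E = 0 0 0\n")
            for s, r in nt_order:
                mask = (conf.strand_index == s) & (conf.residue_index == r)
                pos = conf.positions[mask]
                grp = conf.groups[mask]
                bb = pos[list(grp).index("backbone")]
                bs = pos[[i for i, g in enumerate(grp) if g != "backbone"][0]]
                com = 0.5 * (bb + bs) / OXDNA_LENGTH
                a1 = bs - bb
                a1 = a1 / np.linalg.norm(a1)
                row = np.concatenate([com, a1, [0, 0, 1], [0, 0, 0], [0, 0, 0]])
                fh.write(" ".join(f"{v:.10f}" for v in row) + "\n")


_PDB_RESNAME = {
    "backbone": "BBN",
    "adenine": "ADE",
    "guanine": "GUA",
    "cytosine": "CYT",
    "thymine": "THY",
    "nt_adenine": "NTA",
    "nt_guanine": "NTG",
    "nt_cytosine": "NTC",
    "nt_thymine": "NTT",
    "water": "HOH",
}


def export_pdb(configuration: Configuration, path, shell=None) -> None:
    """Write united-atom sites (and optionally shell waters) as pseudo-atoms."""
    with open(path, "w") as fh:
        serial = 1
        for pos, grp, s, r in zip(
            configuration.positions,
            configuration.groups,
            configuration.strand_index,
            configuration.residue_index,
        ):
            res = _PDB_RESNAME.get(grp, "UNK")
            chain = chr(ord("A") + int(s) % 26)
            fh.write(
                f"ATOM  {serial % 100000:5d}  C   {res:<3s} {chain}{int(r) % 10000:4d}"
                f"    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00           C\n"
            )
            serial += 1
        if shell is not None:
            for pos in shell.centers:
                fh.write(
                    f"HETATM{serial % 100000:5d}  O   HOH W{serial % 10000:4d}"
                    f"    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00           O\n"
                )
                serial += 1
        fh.write("END\n")
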