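"""Four-strand nanostar topology: sequence design and validation.

A tetravalent DNA nanostar self-assembles from four 49-base strands.  Each
strand carries two 20-base sections that hybridize with sections on two
other strands (forming the four double-stranded arms), one unpaired base at
the junction, two unpaired spacer bases at the arm tip, and a terminal
six-base palindromic overhang (CGATCG) that provides the temperature-
controlled tip-to-tip attraction:

    5'-[A section, 20 nt]-[junction, 1 nt]-[B section, 20 nt]
       -[spacer, 2 nt]-[CGATCG]-3'

with B_i the reverse complement of A_{i+1} (indices mod 4), so that arm i
is the antiparallel duplex of B_i with A_{i+1}.  The full construct has
4 x 49 = 196 residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "NanostarTopology",
    "build_topology",
    "default_sequences",
    "reverse_complement",
    "molecular_weight",
    "TopologyError",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

STRAND_LENGTH = 49
SECTION_LENGTH = 20
OVERHANG_LENGTH = 6
_A_SLICE = slice(0, 20)
_JUNCTION_INDEX = 20
_B_SLICE = slice(21, 41)
_SPACER_SLICE = slice(41, 43)
_OVERHANG_SLICE = slice(43, 49)

# anhydrous monophosphate residue masses [g/mol], free-acid convention;
# a 5'-OH strand is the residue sum minus 61.96 (one HPO3 less, plus H2O)
_RESIDUE_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}
_STRAND_MASS_OFFSET = -61.96
_MASS_NA_MINUS_H = 21.9819  # Na replacing H on each internal phosphate


class TopologyError(ValueError):
    """Raised when four strands do not form a valid nanostar design."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# A synthetic default design: four 20-base arm sections (the B sections and
# all flanking bases follow from the layout above).  The sequences are this
# package's own stand-in, chosen with balanced composition; any four-strand
# set with the same layout is accepted by build_topology.
_DEFAULT_A_SECTIONS = (
    "CTACTATGGCGGGTGATAAC",
    "GGATTACCGCAGTCCATGCA",
    "CCTGATTGCGCATACGGTCA",
    "GTCAGGTAAGCGTACCTGAC",
)


def default_sequences() -> tuple[str, str, str, str]:
    """The package's default four 49-mer strands (synthetic design)."""
    strands = []
    for i, a in enumerate(_DEFAULT_A_SECTIONS):
        b = reverse_complement(_DEFAULT_A_SECTIONS[(i + 1) % 4])
        strands.append(a + "A" + b + "AA" + "CGATCG")
    return tuple(strands)


@dataclass(frozen=True)
class NanostarTopology:
    """Validated four-strand nanostar topology.

    Attributes
    ----------
    strands : the four 49-base sequences (5'->3')
    pairing : list of ((strand, section), (strand, section)) tuples, one per
        arm; section 'A' is residues 0-19, section 'B' residues 21-40
    spacers : per-strand indices of unpaired (junction + spacer) residues
    overhang : the palindromic 6-base terminal sequence
    """

    strands: tuple[str, str, str, str]
    pairing: tuple[tuple[tuple[int, str], tuple[int, str]], ...]
    spacers: tuple[tuple[int, ...], ...]
    overhang: str

    @property
    def n_residues(self) -> int:
        return sum(len(s) for s in self.strands)

    def residue_letters(self) -> list[tuple[int, int, str]]:
        """Flat (strand_index, residue_index, base) list, 196 entries."""
        return [
            (i, k, base)
            for i, s in enumerate(self.strands)
            for k, base in enumerate(s)
        ]


def build_topology(sequences) -> NanostarTopology:
    """Validate four strands against the nanostar layout.

    Raises
    ------
    TopologyError
        naming the offending strand or section when a strand has the wrong
        length or alphabet, the overhang is not palindromic, or a 20-base
        section lacks a complementary partner on a distinct strand.
    """
    strands = tuple(str(s).upper() for s in sequences)
    if len(strands) != 4:
        raise TopologyError(f"expected 4 strands, got {len(strands)}")
    for i, s in enumerate(strands):
        if len(s) != STRAND_LENGTH:
            raise TopologyError(f"strand {i}: length {len(s)} != {STRAND_LENGTH}")
        if set(s) - set("ACGT"):
            raise TopologyError(f"strand {i}: non-ACGT characters {set(s) - set('ACGT')}")

    overhangs = {s[_OVERHANG_SLICE] for s in strands}
    if len(overhangs) != 1:
        raise TopologyError(f"strands carry different overhangs: {sorted(overhangs)}")
    overhang = overhangs.pop()
    if reverse_complement(overhang) != overhang:
        raise TopologyError(
            f"overhang {overhang} is not palindromic "
            f"(reverse complement {reverse_complement(overhang)})"
        )

    # each B section must be the reverse complement of exactly one A
    # section on a distinct strand, and the matching must be a bijection
    a_sections = {i: s[_A_SLICE] for i, s in enumerate(strands)}
    pairing = []
    matched_a: set[int] = set()
    for i, s in enumerate(strands):
        b = s[_B_SLICE]
        target = reverse_complement(b)
        partners = [j for j, a in a_sections.items() if a == target and j != i]
        if not partners:
            raise TopologyError(
                f"strand {i} section B has no complementary A section on a "
                f"distinct strand"
            )
        j = partners[0]
        if j in matched_a:
            raise TopologyError(
                f"strand {j} section A matched by more than one B section"
            )
        matched_a.add(j)
        pairing.append(((i, "B"), (j, "A")))

    spacers = tuple(
        tuple([_JUNCTION_INDEX] + list(range(*_SPACER_SLICE.indices(STRAND_LENGTH))))
        for _ in strands
    )
    return NanostarTopology(
        strands=strands,
        pairing=tuple(pairing),
        spacers=spacers,
        overhang=overhang,
    )


def molecular_weight(sequences, counterion: str = "Na") -> float:
    """Molar mass of the assembled construct [g/mol].

    ``counterion='Na'`` gives the sodium salt (each internal phosphate
    carries Na+ instead of H), which is the convention behind the package
    default M_NANOSTAR; ``counterion='H'`` gives the free acid.
    """
    total = 0.0
    for s in sequences:
        s = str(s).upper()
        m = sum(_RESIDUE_MASS[b] for b in s) + _STRAND_MASS_OFFSET
        if counterion == "Na":
            m += _MASS_NA_MINUS_H * (len(s) - 1)
        elif counterion != "H":
            raise ValueError("counterion must be 'Na' or 'H'")
        total += m
    return total
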