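"""Ideal nucleotide atomic templates in the standard base reference frame.

Each template carries heavy-atom coordinates of one nucleotide expressed in
the standard base reference frame (origin at the pairing centre, x toward
the major groove, z along the helix axis; the template's own frame is the
identity).  Base-ring coordinates follow the published standard reference
geometry for the canonical bases; the sugar--phosphate moiety is a single
idealized, synthetic C2'-endo-like atom set attached rigidly to every base.
Because nucleotides are placed as rigid bodies, inter-residue O3'--P closure
is approximate -- a documented limitation of the builder.

Coordinates are stored in Angstrom below for legibility and exposed in nm.

The sequence alphabet covers thirteen codes; atomic templates exist for the
canonical five (A, T, G, C, U).  The synthetic codes (Hachimoji B/S/P/Z,
hydrophobic L/M, fluorescent E/D) are supported at the sequence/pairing
bookkeeping level only and raise when an atomic build is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import MissingTemplateError, UnknownBaseError

ALPHABET = "ATGCUEDBSZPLM"

#: canonical complement of each code (pairing partner on the antistrand).
#: A<->T, G<->C are mutual; U, E (2-aminopurine) pair with A-type partners
#: one-way; D (tricyclic cytosine analog) pairs G; Hachimoji B<->S, P<->Z;
#: hydrophobic d5SICS (L) <-> dNaM (M).
COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "U": "A", "E": "T", "D": "G",
    "B": "S", "S": "B", "P": "Z", "Z": "P",
    "L": "M", "M": "L",
}

#: residue names used on PDB output (and accepted on input).
RESIDUE_NAMES = {
    "A": "DA", "T": "DT", "G": "DG", "C": "DC", "U": "DU",
    "E": "2AP", "D": "TC1", "B": "HJB", "S": "HJS", "P": "HJP", "Z": "HJZ",
    "L": "5SI", "M": "NAM",
}
RESIDUE_CODES = {v: k for k, v in RESIDUE_NAMES.items()}
# methylated variants read back as their parent base
RESIDUE_CODES["5CM"] = "C"
RESIDUE_CODES["7MG"] = "G"

_PURINES = set("AGEB")  # glycosidic nitrogen N9
_PYRIMIDINES = set("TCUDSZP")


def is_purine(code: str) -> bool:
    return code in _PURINES


# -- standard-frame base ring coordinates (Angstrom) -------------------------

_ADENINE = {
    "N9": (-1.291, 4.498, 0.000), "C8": (0.024, 4.897, 0.000),
    "N7": (0.877, 3.902, 0.000), "C5": (0.071, 2.771, 0.000),
    "C6": (0.369, 1.398, 0.000), "N6": (1.611, 0.909, 0.000),
    "N1": (-0.668, 0.532, 0.000), "C2": (-1.912, 1.023, 0.000),
    "N3": (-2.320, 2.290, 0.000), "C4": (-1.267, 3.124, 0.000),
}
_GUANINE = {
    "N9": (-1.289, 4.551, 0.000), "C8": (0.023, 4.962, 0.000),
    "N7": (0.870, 3.969, 0.000), "C5": (0.071, 2.833, 0.000),
    "C6": (0.424, 1.460, 0.000), "O6": (1.554, 0.955, 0.000),
    "N1": (-0.700, 0.641, 0.000), "C2": (-1.999, 1.087, 0.000),
    "N2": (-2.949, 0.139, -0.001), "N3": (-2.342, 2.364, 0.001),
    "C4": (-1.265, 3.177, 0.000),
}
_THYMINE = {
    "N1": (-1.284, 4.500, 0.000), "C2": (-1.462, 3.135, 0.000),
    "O2": (-2.562, 2.608, 0.000), "N3": (-0.298, 2.407, 0.000),
    "C4": (0.994, 2.897, 0.000), "O4": (1.944, 2.119, 0.000),
    "C5": (1.106, 4.338, 0.000), "C7": (2.466, 4.961, 0.001),
    "C6": (-0.024, 5.057, 0.000),
}
_CYTOSINE = {
    "N1": (-1.285, 4.542, 0.000), "C2": (-1.472, 3.158, 0.000),
    "O2": (-2.628, 2.709, 0.001), "N3": (-0.391, 2.344, 0.000),
    "C4": (0.837, 2.868, 0.000), "N4": (1.875, 2.027, 0.001),
    "C5": (1.056, 4.275, 0.000), "C6": (-0.023, 5.068, 0.000),
}
_URACIL = {
    "N1": (-1.284, 4.500, 0.000), "C2": (-1.462, 3.131, 0.000),
    "O2": (-2.563, 2.608, 0.000), "N3": (-0.302, 2.397, 0.000),
    "C4": (0.989, 2.884, 0.000), "O4": (1.935, 2.094, -0.001),
    "C5": (1.089, 4.311, 0.000), "C6": (-0.024, 5.053, 0.000),
}

# idealized rigid sugar-phosphate moiety (synthetic geometry, Angstrom),
# shared by all bases; C1' matches the standard-frame glycosidic attachment.
_BACKBONE = {
    "C1'": (-2.479, 5.346, 0.000),
    "O4'": (-3.550, 5.070, 0.880),
    "C2'": (-3.200, 6.690, 0.200),
    "C3'": (-4.650, 6.470, 0.620),
    "O3'": (-5.350, 7.650, 0.950),
    "C4'": (-4.640, 5.480, 1.770),
    "C5'": (-5.260, 4.150, 1.550),
    "O5'": (-4.580, 3.400, 2.500),
    "P": (-4.990, 1.850, 2.570),
    "OP1": (-6.460, 1.770, 2.750),
    "OP2": (-4.180, 1.120, 3.570),
}

_RING_ATOMS = {
    True: ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    False: ("N1", "C2", "N3", "C4", "C5", "C6"),
}

_BASE_RINGS = {"A": _ADENINE, "G": _GUANINE, "T": _THYMINE, "C": _CYTOSINE, "U": _URACIL}


@dataclass(frozen=True)
class BaseTemplate:
    """Heavy atoms of one nucleotide in the standard base reference frame (nm)."""

    code: str
    atom_names: tuple
    elements: tuple
    positions: np.ndarray  # (n_atoms, 3), nm
    glycosidic_atoms: tuple  # (C1', ring nitrogen)
    ring_atoms: tuple

    def index(self, name: str) -> int:
        return self.atom_names.index(name)

    def ring_positions(self) -> np.ndarray:
        idx = [self.index(a) for a in self.ring_atoms]
        return self.positions[idx]

    def base_atom_mask(self) -> np.ndarray:
        """True for base (ring + substituent) atoms, False for sugar/phosphate."""
        return np.array([a not in _BACKBONE for a in self.atom_names])


def _element_of(name: str) -> str:
    return name.lstrip("0123456789")[0]


def _build(code: str) -> BaseTemplate:
    ring = _BASE_RINGS[code]
    names = list(_BACKBONE) + list(ring)
    pos = np.array([_BACKBONE.get(n, ring.get(n)) for n in names], dtype=float) / 10.0
    gly_n = "N9" if is_purine(code) else "N1"
    return BaseTemplate(
        code=code,
        atom_names=tuple(names),
        elements=tuple(_element_of(n) for n in names),
        positions=pos,
        glycosidic_atoms=("C1'", gly_n),
        ring_atoms=_RING_ATOMS[is_purine(code)],
    )


class TemplateLibrary:
    """Registry of atomic templates keyed by sequence code.

    Canonical bases are pre-registered; users may register templates for the
    non-canonical codes (which are otherwise bookkeeping-only).
    """

    def __init__(self) -> None:
        self._templates = {c: _build(c) for c in "ATGCU"}

    def register(self, template: BaseTemplate) -> None:
        if template.code not in ALPHABET:
            raise UnknownBaseError(f"unknown base code {template.code!r}")
        self._templates[template.code] = template

    def __contains__(self, code: str) -> bool:
        return code in self._templates

    def get(self, code: str) -> BaseTemplate:
        if code not in ALPHABET:
            raise UnknownBaseError(f"unknown base code {code!r}")
        try:
            return self._templates[code]
        except KeyError:
            raise MissingTemplateError(
                f"no atomic template for code {code!r}; this base is supported at "
                "the sequence level only (register a template to build atoms)"
            ) from None


DEFAULT_TEMPLATES = TemplateLibrary()


def methyl_position(template: BaseTemplate, site: str, bond_length: float = 0.149) -> np.ndarray:
    """Place a methyl carbon at ``site`` (e.g. C5 of cytosine, N7 of guanine),
    extended in the base plane away from the two ring neighbours."""
    names = template.atom_names
    ring = [n for n in template.ring_atoms]
    i = ring.index(site)
    nbrs = (ring[(i - 1) % len(ring)], ring[(i + 1) % len(ring)])
    p = template.positions[template.index(site)]
    mid = 0.5 * (template.positions[template.index(nbrs[0])]
                 + template.positions[template.index(nbrs[1])])
    d = p - mid
    nrm = np.linalg.norm(d)
    if nrm < 1e-9:  # pragma: no cover - rings are never this degenerate
        d = np.array([0.0, 1.0, 0.0])
        nrm = 1.0
    return p + d / nrm * bond_length
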