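"""The central double-stranded DNA object and its constructors.

:class:`NucleicStructure` holds the reference-strand sequence, the
complementary strand, a grid of base-pair reference frames over one or more
time frames, and the topology flag.  It is produced either by
:func:`make` (generation from sequence/shape inputs) or by the loaders in
:mod:`dnaforge.io`, and is the object every editing, relaxation and analysis
routine operates on.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import spline as _spline
from .exceptions import (
    DegenerateInputError,
    MissingTemplateError,
    UnknownBaseError,
)
from .geometry import Frame, rotvec_to_matrix, triad_is_valid
from .templates import (
    ALPHABET,
    COMPLEMENT,
    DEFAULT_TEMPLATES,
    RESIDUE_NAMES,
    TemplateLibrary,
)

logger = logging.getLogger(__name__)

#: classification rule: ends closer than this (nm) on a chain longer than
#: :data:`CIRCULAR_MIN_BP` base pairs means covalently closed.
CIRCULAR_DISTANCE_NM = 1.0
CIRCULAR_MIN_BP = 20

# 180-degree rotation about the frame x axis: the complementary-strand flip.
_FLIP_X = np.diag([1.0, -1.0, -1.0])


def complement(sequence: str) -> str:
    """Complementary strand of ``sequence``, returned 5'->3'.

    Pairing follows the canonical partner of each code (A<->T, G<->C, U->A,
    E->T, D->G, Hachimoji B<->S and P<->Z, d5SICS L <-> dNaM M).  Note that
    the map is one-way for U, E and D: their partners pair back to the
    canonical bases.
    """
    out = []
    for pos, c in enumerate(sequence):
        if c not in COMPLEMENT:
            raise UnknownBaseError(f"unknown base code {c!r} at position {pos}")
        out.append(COMPLEMENT[c])
    return "".join(reversed(out))


def classify_circular(frames: np.ndarray, n_bp: int | None = None) -> bool:
    """Proximity rule for covalent closure: first/last base-pair origins
    closer than 1 nm *and* more than 20 base pairs.  The length guard keeps
    short fragments with coincidentally close ends from being misclassified.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 3:  # (n_bp, 4, 3) single time frame
        frames = frames[None]
    if n_bp is None:
        n_bp = frames.shape[1]
    if n_bp < 1:
        raise DegenerateInputError("need at least one base pair")
    if n_bp <= CIRCULAR_MIN_BP:
        return False
    gap = float(np.linalg.norm(frames[0, 0, 0] - frames[0, -1, 0]))
    return gap < CIRCULAR_DISTANCE_NM


@dataclass
class AtomicModel:
    """Flat heavy-atom model of a duplex: two chains (A = sense, B = antisense),
    coordinates in nm, residues ordered 5'->3' within each chain."""

    atom_names: list
    elements: list
    residue_names: list
    residue_indices: np.ndarray  # 0-based, per chain
    chain_ids: list
    coordinates: np.ndarray  # (n_atoms, 3) nm

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def residue_count(self) -> int:
        return len({(c, int(r)) for c, r in zip(self.chain_ids, self.residue_indices)})

    def chain_residues(self, chain_id: str):
        """Yield (residue_index, residue_name, atom_slice) for one chain, in order."""
        mask = np.array([c == chain_id for c in self.chain_ids])
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            return
        res = self.residue_indices[idx]
        for r in np.unique(res):
            sel = idx[res == r]
            yield int(r), self.residue_names[sel[0]], sel

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        return AtomicModel(
            list(self.atom_names), list(self.elements), list(self.residue_names),
            self.residue_indices.copy(), list(self.chain_ids),
            self.coordinates @ np.asarray(rotation).T + np.asarray(translation),
        )

    def copy(self) -> "AtomicModel":
        return self.transformed(np.eye(3), np.zeros(3))


class NucleicStructure:
    """Sequence + base-pair frame grid + topology: the central DNA object.

    Parameters
    ----------
    sequence : str
        Reference-strand sequence, 5'->3', over the supported alphabet.
    frames : ndarray, shape (t, n_bp, 4, 3)
        Per time frame, per base pair: origin row plus x/y/z triad rows (nm).
    circular : bool, optional
        Explicit topology; by default the proximity classifier decides.
    dLk : int, optional
        Linking-number difference imposed at generation time (bookkeeping).
    """

    def __init__(self, sequence: str, frames: np.ndarray, circular: bool | None = None,
                 dLk: int | None = None, bp_per_turn: float = _spline.BP_PER_TURN):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim == 3:
            frames = frames[None]
        if frames.ndim != 4 or frames.shape[2:] != (4, 3):
            raise DegenerateInputError(
                f"frames must have shape (t, n_bp, 4, 3), got {frames.shape}"
            )
        if len(sequence) != frames.shape[1]:
            raise DegenerateInputError(
                f"sequence length {len(sequence)} != n_bp {frames.shape[1]}"
            )
        for c in sequence:
            if c not in ALPHABET:
                raise UnknownBaseError(f"unknown base code {c!r}")
        self.sequence = sequence
        self.frames = frames
        if circular is None:
            circular = classify_circular(frames)
            logger.info("topology auto-classified as %s", "circular" if circular else "linear")
        self.circular = bool(circular)
        self.dLk = dLk
        self.bp_per_turn = bp_per_turn
        # editing annotations
        self.hoogsteen: set = set()
        self.methylated: set = set()
        self.methylated_anti: set = set()  # antistrand positions (both-strand CpG)
        self.free_indices: set | None = None  # None = default fixing policy
        self._atomic: AtomicModel | None = None
        # explicit antistrand (non-complementary pairings); None = canonical
        self._anti_override: str | None = None
        # separate Watson/Crick base frames when fitted from atoms (t, n, 4, 3)
        self.watson_frames: np.ndarray | None = None
        self.crick_frames: np.ndarray | None = None

    # -- basic views ---------------------------------------------------------

    @property
    def n_bp(self) -> int:
        return self.frames.shape[1]

    @property
    def n_time_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def anti_sequence(self) -> str:
        if self._anti_override is not None:
            return self._anti_override
        return complement(self.sequence)

    def frame(self, bp: int, t: int = 0) -> Frame:
        return Frame.from_array(self.frames[t, bp])

    def origins(self, t: int = 0) -> np.ndarray:
        return self.frames[t, :, 0]

    def validate_frames(self, tol: float = 1e-6) -> None:
        for t in range(self.n_time_frames):
            for i in range(self.n_bp):
                if not triad_is_valid(self.frames[t, i, 1:], tol=tol):
                    raise DegenerateInputError(f"invalid triad at (t={t}, bp={i})")

    def copy(self) -> "NucleicStructure":
        out = NucleicStructure(self.sequence, self.frames.copy(), self.circular,
                               self.dLk, self.bp_per_turn)
        out.hoogsteen = set(self.hoogsteen)
        out.methylated = set(self.methylated)
        out.methylated_anti = set(self.methylated_anti)
        out.free_indices = None if self.free_indices is None else set(self.free_indices)
        out._atomic = None if self._atomic is None else self._atomic.copy()
        out._anti_override = self._anti_override
        if self.watson_frames is not None:
            out.watson_frames = self.watson_frames.copy()
        if self.crick_frames is not None:
            out.crick_frames = self.crick_frames.copy()
        return out

    def invalidate_atomic(self) -> None:
        self._atomic = None

    def atomic(self, templates: TemplateLibrary | None = None,
               frame_index: int = 0) -> AtomicModel:
        """Materialized atomic model (cached; rebuilt after frame edits)."""
        if self._atomic is None:
            self._atomic = to_atomic(self, templates=templates, frame_index=frame_index)
        return self._atomic

    # convenience delegates (wired up in __init__.py to avoid import cycles)
    def __repr__(self) -> str:
        topo = "circular" if self.circular else "linear"
        return (f"<NucleicStructure {self.n_bp} bp, {topo}, "
                f"{self.n_time_frames} time frame(s)>")


def random_sequence(n_bp: int, seed: int) -> str:
    """Uniform random sequence over A/C/G/T; the seed is mandatory."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n_bp))


def _linear_path_frames(n_bp: int, rise: float = _spline.RISE) -> _spline.PathFrames:
    """Straight line along +z at exact spacing; transported frames are all
    the identity triad (closed form for the default linear geometry)."""
    frames = [Frame(np.array([0.0, 0.0, i * rise]), np.eye(3)) for i in range(n_bp)]
    return _spline.PathFrames(frames, rise, closed=False)


def _circle_path_frames(n_bp: int, rise: float = _spline.RISE) -> _spline.PathFrames:
    """Planar circle of circumference n_bp * rise in the xy plane, sampled
    exactly equidistantly, with parallel-transported (twist-free) triads.

    For a planar curve the transported frame field has zero holonomy, and the
    radial normal is the transported image of the initial normal, so the
    closed-form triads below coincide with the parallel-transport rule."""
    radius = n_bp * rise / (2.0 * math.pi)
    frames = []
    for i in range(n_bp):
        phi = 2.0 * math.pi * i / n_bp
        origin = radius * np.array([math.cos(phi), math.sin(phi), 0.0])
        z = np.array([-math.sin(phi), math.cos(phi), 0.0])  # tangent
        x = np.array([math.cos(phi), math.sin(phi), 0.0])   # outward normal
        y = np.cross(z, x)
        frames.append(Frame(origin, np.vstack([x, y, z])))
    spacing = 2.0 * radius * math.sin(math.pi / n_bp)  # chord length
    return _spline.PathFrames(frames, spacing, closed=True,
                              writhe=_spline.compute_writhe(
                                  np.array([f.origin for f in frames]), closed=True))


def make(sequence: str | None = None, n_bp: int | None = None,
         control_points=None, circular: bool = False, dLk: int = 0,
         bp_per_turn: float = _spline.BP_PER_TURN, sequence_seed: int = 0,
         rise: float = _spline.RISE) -> NucleicStructure:
    """Generate a DNA structure from any combination of sequence, size and shape.

    All arguments are optional as long as one of ``sequence``/``n_bp``/
    ``control_points`` pins the size.  Defaults: a straight B-form duplex
    along +z; with ``circular=True`` and no shape, a planar circle of
    circumference ``n_bp * 0.34`` nm.  With control points (>= 4, nm) the
    full spline pipeline runs: fit, equidistant sampling, parallel transport,
    then twisting at ``bp_per_turn`` including the requested ``dLk`` via
    Tw_new = Tw0 + dLk - Wr (closed topology only).
    """
    if sequence is None and n_bp is None and control_points is None:
        raise DegenerateInputError("provide at least one of sequence, n_bp, control_points")
    if sequence is not None and n_bp is not None and len(sequence) != n_bp:
        raise DegenerateInputError(
            f"sequence length {len(sequence)} contradicts n_bp={n_bp}")
    if dLk and not circular:
        warnings.warn("dLk is ignored for linear DNA", stacklevel=2)
        dLk = 0

    if control_points is not None:
        path = _spline.fit_spline(control_points, closed=circular)
        if n_bp is None and sequence is not None:
            n_bp = len(sequence)
        origins, tangents, eff = _spline.sample_equidistant(path, spacing=rise, n_bp=n_bp)
        n_bp = len(origins)
        transported = _spline.transport_frames(origins, tangents, closed=circular, spacing=eff)
    else:
        if n_bp is None:
            n_bp = len(sequence)
        transported = (_circle_path_frames(n_bp, rise) if circular
                       else _linear_path_frames(n_bp, rise))

    twisted = _spline.apply_twist(transported, bp_per_turn=bp_per_turn,
                                  dLk=dLk if circular else 0, closed=circular)

    if sequence is None:
        sequence = random_sequence(n_bp, seed=sequence_seed)
        logger.info("random sequence of %d bp generated (seed=%d)", n_bp, sequence_seed)

    grid = np.array([f.as_array() for f in twisted.frames])[None]
    return NucleicStructure(sequence, grid, circular=circular,
                            dLk=dLk if circular else None, bp_per_turn=bp_per_turn)


#: atom name of the added methyl carbon and its ring site, per methylatable base
METHYL_SITES = {"C": ("C7", "C5"), "G": ("CM7", "N7")}
METHYLATED_RESNAMES = {"C": "5CM", "G": "7MG"}


def _template_atoms(templates: TemplateLibrary, code: str,
                    hoogsteen: bool = False, methyl: bool = False,
                    flip_angle: float = 180.0):
    """Template-frame atoms of one nucleotide with optional modifications.

    ``hoogsteen`` rotates the base (ring + substituent) atoms about the
    glycosidic bond; ``methyl`` appends the methyl carbon (C5 of cytosine,
    N7 of guanine) and switches the residue name.
    """
    from .templates import methyl_position as _mp

    tpl = templates.get(code)
    names = list(tpl.atom_names)
    elements = list(tpl.elements)
    positions = tpl.positions.copy()
    resname = RESIDUE_NAMES[code]

    if hoogsteen:
        c1 = positions[tpl.index(tpl.glycosidic_atoms[0])]
        ng = positions[tpl.index(tpl.glycosidic_atoms[1])]
        axis = ng - c1
        axis /= np.linalg.norm(axis)
        r = rotvec_to_matrix(axis * math.radians(flip_angle))
        mask = tpl.base_atom_mask()
        positions[mask] = (positions[mask] - c1) @ r.T + c1

    if methyl:
        if code not in METHYL_SITES:
            raise UnknownBaseError(f"no methylation geometry for code {code!r}")
        atom_name, site = METHYL_SITES[code]
        pos = _mp(tpl, site)
        if hoogsteen:
            pos = (pos - c1) @ r.T + c1
        names.append(atom_name)
        elements.append("C")
        positions = np.vstack([positions, pos])
        resname = METHYLATED_RESNAMES[code]

    return names, elements, resname, positions


def to_atomic(structure: NucleicStructure, templates: TemplateLibrary | None = None,
              frame_index: int = 0) -> AtomicModel:
    """Rigidly place nucleotide templates onto the base-pair frames.

    Sense residue ``i`` is the template of ``sequence[i]`` transformed by
    frame ``i``; the antisense residue is its pairing partner's template
    placed by the same frame composed with a 180-degree rotation about the
    frame x axis (the standard complementary-strand flip).  Chain A runs
    5'->3' with the frames; chain B is emitted 5'->3' on the antistrand
    (reverse order).  Hoogsteen and methylation annotations on the structure
    are materialized here.
    """
    if templates is None:
        templates = DEFAULT_TEMPLATES
    seq = structure.sequence
    anti = structure.anti_sequence
    for pos, c in enumerate(seq):
        if c not in templates:
            raise MissingTemplateError(
                f"no atomic template for code {c!r} (position {pos})")
    for pos, c in enumerate(anti):
        if c not in templates:
            raise MissingTemplateError(
                f"no atomic template for antistrand code {c!r} (position {pos})")

    names, elements, resnames, residx, chains, coords = [], [], [], [], [], []

    def _place(code: str, frame_block: np.ndarray, flip: bool, res_i: int,
               chain: str, hoogsteen: bool = False, methyl: bool = False):
        a_names, a_elems, resname, tpl_pos = _template_atoms(
            templates, code, hoogsteen=hoogsteen, methyl=methyl)
        origin, triad = frame_block[0], frame_block[1:]
        m = triad.T  # columns are the frame axes in world coordinates
        if flip:
            m = m @ _FLIP_X
        pts = tpl_pos @ m.T + origin
        names.extend(a_names)
        elements.extend(a_elems)
        resnames.extend([resname] * len(a_names))
        residx.extend([res_i] * len(a_names))
        chains.extend([chain] * len(a_names))
        coords.append(pts)

    fgrid = structure.frames[frame_index]
    for i, c in enumerate(seq):
        _place(c, fgrid[i], flip=False, res_i=i, chain="A",
               hoogsteen=i in structure.hoogsteen,
               methyl=i in structure.methylated)
    n = structure.n_bp
    for j in range(n):  # chain B residue j pairs chain A residue n-1-j
        i = n - 1 - j
        _place(anti[j], fgrid[i], flip=True, res_i=j, chain="B",
               methyl=j in structure.methylated_anti)

    return AtomicModel(names, elements, resnames, np.array(residx), chains,
                       np.vstack(coords))
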