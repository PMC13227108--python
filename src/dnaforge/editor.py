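"""Structure editing: mutate, Hoogsteen flip, methylate, extend, connect.

All editors return a new :class:`NucleicStructure`; the input is never
modified.  Frames are untouched by the sequence-level edits; ``extend`` and
``connect`` add frames and mark the new bases (plus a ``margin`` of adjacent
original bases, inclusive) as free for subsequent Monte Carlo relaxation,
leaving every other base pair fixed.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np

from .exceptions import EditError, NotMethylatableError, UnknownBaseError
from .geometry import Frame, StepVector, frames_from_step, rotation_vector, rotvec_to_matrix
from .spline import BP_PER_TURN, RISE, fit_spline, sample_equidistant, transport_frames
from .structure import NucleicStructure, complement, random_sequence
from .templates import ALPHABET, COMPLEMENT

logger = logging.getLogger(__name__)

_IDEAL_STEP = StepVector([0.0, 0.0, RISE], [0.0, 0.0, 360.0 / BP_PER_TURN])


def _check_positions(structure: NucleicStructure, positions) -> list:
    out = []
    for p in positions:
        p = int(p)
        if not (0 <= p < structure.n_bp):
            raise EditError(f"base-pair index {p} out of range [0, {structure.n_bp})")
        if p in out:
            raise EditError(f"duplicate index {p}")
        out.append(p)
    return out


def mutate(structure: NucleicStructure, mapping: dict,
           complementary: bool = True) -> NucleicStructure:
    """Change nucleobases at the given 0-based positions.

    With ``complementary`` (default) the paired antistrand base is set to
    the canonical partner of the new code; otherwise the partner is left
    untouched, producing a non-complementary pairing.
    """
    positions = _check_positions(structure, mapping.keys())
    for code in mapping.values():
        if code not in ALPHABET:
            raise UnknownBaseError(f"unknown base code {code!r}")

    out = structure.copy()
    n = out.n_bp
    seq = list(out.sequence)
    anti = list(out.anti_sequence)
    for p in positions:
        code = mapping[p]
        seq[p] = code
        if complementary:
            anti[n - 1 - p] = COMPLEMENT[code]
    out.sequence = "".join(seq)
    anti_str = "".join(anti)
    out._anti_override = None if anti_str == complement(out.sequence) else anti_str
    out.invalidate_atomic()
    return out


def flip(structure: NucleicStructure, positions, angle: float = 180.0) -> NucleicStructure:
    """Rotate reference-strand nucleobases about the glycosidic bond
    (C1'--N9 for purines, C1'--N1 for pyrimidines).

    The default 180-degree rotation converts a Watson--Crick--Franklin base
    into the Hoogsteen orientation; flipping the same position twice restores
    the original geometry (the pair's Hoogsteen tag is toggled).  Only the
    base atoms move; sugar and phosphate stay in place.  Other angles are
    applied to the materialized atomic model without tagging.
    """
    if not math.isfinite(angle):
        raise EditError("flip angle must be finite")
    positions = _check_positions(structure, positions)
    out = structure.copy()

    if abs(abs(angle) - 180.0) < 1e-12:
        for p in positions:
            out.hoogsteen ^= {p}
        out.invalidate_atomic()
        return out

    # arbitrary-angle geometric flip on the atomic model
    model = out.atomic().copy()
    from .templates import DEFAULT_TEMPLATES
    for p in positions:
        tpl = DEFAULT_TEMPLATES.get(out.sequence[p])
        sel = np.nonzero([(c == "A" and int(r) == p)
                          for c, r in zip(model.chain_ids, model.residue_indices)])[0]
        name_to_idx = {model.atom_names[k]: k for k in sel}
        c1 = model.coordinates[name_to_idx[tpl.glycosidic_atoms[0]]]
        ng = model.coordinates[name_to_idx[tpl.glycosidic_atoms[1]]]
        axis = ng - c1
        axis /= np.linalg.norm(axis)
        r = rotvec_to_matrix(axis * math.radians(angle))
        base_atoms = [name_to_idx[a] for a, keep in
                      zip(tpl.atom_names, tpl.base_atom_mask()) if keep]
        model.coordinates[base_atoms] = (
            model.coordinates[base_atoms] - c1) @ r.T + c1
    out._atomic = model
    return out


def methylate(structure: NucleicStructure, positions=None, cpg_auto: bool = False,
              both_strands: bool = False) -> NucleicStructure:
    """Methylate cytosines (5-methyl) or guanines (N7-methyl).

    Exactly one of ``positions`` / ``cpg_auto`` must be given; ``cpg_auto``
    scans the reference strand for CpG dinucleotides and methylates the C of
    each (with ``both_strands`` also the complementary-strand C of the same
    site).  Re-methylation is a warning no-op.
    """
    if (positions is None) == (not cpg_auto):
        raise EditError("provide exactly one of positions / cpg_auto")

    out = structure.copy()
    anti_targets: set = set()
    if cpg_auto:
        targets = [i for i in range(out.n_bp - 1)
                   if out.sequence[i] == "C" and out.sequence[i + 1] == "G"]
        if both_strands:
            # the complementary C pairs the G of the CpG: antistrand index n-2-i
            anti_targets = {out.n_bp - 2 - i for i in targets}
        logger.info("CpG auto-methylation: %d site(s) found", len(targets))
    else:
        targets = _check_positions(out, positions)
        for p in targets:
            if out.sequence[p] not in ("C", "G"):
                raise NotMethylatableError(
                    f"position {p} is {out.sequence[p]!r}; only C and G can be methylated")

    already = set(targets) & out.methylated
    if already:
        warnings.warn(f"positions {sorted(already)} already methylated; no-op",
                      stacklevel=2)
    out.methylated |= set(targets)
    out.methylated_anti |= anti_targets
    if targets or anti_targets:
        out.invalidate_atomic()
    return out


def extend(structure: NucleicStructure, n_bp: int | None = None,
           sequence: str | None = None, forward: bool = True, margin: int = 1,
           control_points=None, frame_index: int = 0,
           sequence_seed: int = 0) -> NucleicStructure:
    """Extend a linear duplex beyond one terminus.

    Exactly one of ``n_bp``/``sequence`` sets the length of the extension.
    The default shape is a straight continuation along the terminal frame's
    z axis at the ideal rise and twist; with ``control_points`` the extension
    follows a spline starting at the terminal origin.  Original frames are
    preserved bitwise; the new bases plus ``margin`` terminal bases of the
    original structure are marked free for minimization.
    """
    if structure.circular:
        raise EditError("cannot extend a circular structure")
    if (n_bp is None) == (sequence is None):
        raise EditError("provide exactly one of n_bp / sequence")
    if sequence is not None:
        n_new = len(sequence)
    else:
        n_new = int(n_bp)
        sequence = random_sequence(n_new, seed=sequence_seed)
    if n_new < 1:
        raise EditError("extension must add at least one base pair")
    if margin < 0:
        raise EditError("margin must be non-negative")

    grid = structure.frames[frame_index]
    n = structure.n_bp
    terminal = Frame.from_array(grid[-1 if forward else 0])

    if control_points is not None:
        new_frames = _frames_along_spline(terminal, control_points, n_new, forward)
    else:
        step = _IDEAL_STEP if forward else StepVector(-_IDEAL_STEP.translation,
                                                      -_IDEAL_STEP.rotation)
        new_frames = []
        f = terminal
        for _ in range(n_new):
            f = frames_from_step(f, step)
            new_frames.append(f)
        if not forward:
            new_frames.reverse()

    new_grid = np.array([f.as_array() for f in new_frames])
    if forward:
        frames = np.concatenate([grid[None], new_grid[None]], axis=1)
        new_seq = structure.sequence + sequence
        new_idx = set(range(n, n + n_new))
        margin_idx = set(range(max(0, n - margin), n))
        shift = 0
    else:
        frames = np.concatenate([new_grid[None], grid[None]], axis=1)
        new_seq = sequence + structure.sequence
        new_idx = set(range(0, n_new))
        margin_idx = set(range(n_new, min(n_new + margin, n_new + n)))
        shift = n_new

    out = NucleicStructure(new_seq, frames, circular=False,
                           bp_per_turn=structure.bp_per_turn)
    out.hoogsteen = {i + shift for i in structure.hoogsteen}
    out.methylated = {i + shift for i in structure.methylated}
    out.methylated_anti = ({j + (n_new if forward else 0)
                            for j in structure.methylated_anti})
    out.free_indices = new_idx | margin_idx
    return out


def _frames_along_spline(terminal: Frame, control_points, n_new: int,
                         forward: bool) -> list:
    """Extension frames along a user spline anchored at the terminal origin,
    transported from the terminal triad and twisted at the ideal rate."""
    pts = np.vstack([terminal.origin, np.asarray(control_points, float)])
    path = fit_spline(pts, closed=False)
    origins, tangents, _ = sample_equidistant(path, n_bp=n_new + 1)
    pf = transport_frames(origins, tangents, closed=False,
                          initial_normal=terminal.triad[0])
    out = []
    per_step = 360.0 / BP_PER_TURN
    for k, f in enumerate(pf.frames[1:], start=1):
        theta = math.radians(per_step * k)
        x, y, z = f.triad
        xn = math.cos(theta) * x + math.sin(theta) * y
        xn /= np.linalg.norm(xn)
        out.append(Frame(f.origin, np.vstack([xn, np.cross(z, xn), z])))
    if not forward:
        out.reverse()
    return out


def _wrap_angle(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def optimal_bridge_length(a_end: Frame, b_start: Frame, rise: float = RISE,
                          bp_per_turn: float = BP_PER_TURN) -> int:
    """Bridge length minimizing the helical twist-register penalty.

    Candidates lie near gap/rise; for each n the penalty is the squared
    wrapped deviation of the required net twist between the two fixed
    terminal frames from the relaxed twist n * 360/bp_per_turn.  Ties break
    toward the smaller n.
    """
    gap = float(np.linalg.norm(b_start.origin - a_end.origin))
    psi = float(rotation_vector(a_end.triad, b_start.triad)[2])
    lo = max(2, math.floor(gap / rise) - 5)
    hi = math.ceil(gap / rise) + 5
    best_n, best_pen = None, math.inf
    for n in range(lo, hi + 1):
        pen = _wrap_angle(psi - n * 360.0 / bp_per_turn) ** 2
        if pen < best_pen - 1e-12:
            best_n, best_pen = n, pen
    logger.info("bridge length %d bp chosen (gap %.3f nm, register penalty %.3g)",
                best_n, gap, best_pen)
    return best_n


def connect(a: NucleicStructure, b: NucleicStructure, n_bp: int | None = None,
            control_points=None, margin: int = 1, frame_index: int = 0,
            sequence_seed: int = 0) -> NucleicStructure:
    """Join two linear duplexes with a bridge from a's 3' end to b's 5' end.

    Without ``n_bp`` the bridge length is chosen by the twist-register
    penalty of :func:`optimal_bridge_length`.  Bridge frames are seeded on
    the straight segment between the termini (orientation interpolated);
    the bridge plus ``margin`` bases on each side are marked free for
    minimization, everything else fixed.
    """
    if a.circular or b.circular:
        raise EditError("cannot connect circular structures")
    ga, gb = a.frames[frame_index], b.frames[frame_index]
    a_end = Frame.from_array(ga[-1])
    b_start = Frame.from_array(gb[0])
    gap = float(np.linalg.norm(b_start.origin - a_end.origin))
    if n_bp is None:
        if gap < RISE:
            raise EditError(
                f"termini overlap (gap {gap:.3f} nm < {RISE} nm); pass n_bp explicitly")
        n_bridge = optimal_bridge_length(a_end, b_start)
    else:
        n_bridge = int(n_bp)
        if n_bridge < 1:
            raise EditError("bridge must contain at least one base pair")

    if control_points is not None:
        # spline runs from a's terminus through the user points to b's start;
        # the endpoint sample coincides with b's first base pair and is dropped
        bridge = _frames_along_spline(
            a_end, np.vstack([np.asarray(control_points, float),
                              b_start.origin]),
            n_bridge + 1, forward=True)[:-1]
    else:
        rv = np.radians(rotation_vector(a_end.triad, b_start.triad))
        bridge = []
        for k in range(1, n_bridge + 1):
            frac = k / (n_bridge + 1)
            origin = a_end.origin + frac * (b_start.origin - a_end.origin)
            triad = rotvec_to_matrix(rv * frac).T @ a_end.triad
            bridge.append(Frame(origin, triad))

    bridge_grid = np.array([f.as_array() for f in bridge]).reshape(n_bridge, 4, 3)
    frames = np.concatenate([ga, bridge_grid, gb], axis=0)[None]
    seq = a.sequence + random_sequence(n_bridge, seed=sequence_seed) + b.sequence

    out = NucleicStructure(seq, frames, circular=False, bp_per_turn=a.bp_per_turn)
    na = a.n_bp
    out.hoogsteen = set(a.hoogsteen) | {i + na + n_bridge for i in b.hoogsteen}
    out.methylated = set(a.methylated) | {i + na + n_bridge for i in b.methylated}
    out.free_indices = (set(range(na, na + n_bridge))
                        | set(range(max(0, na - margin), na))
                        | set(range(na + n_bridge,
                                    min(na + n_bridge + margin, out.n_bp))))
    return out
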