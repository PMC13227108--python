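"""Rigid-base geometric analysis.

Implements the Curves+-style rigid parameter set (six intra-base-pair and
six step coordinates per base pair), base-frame fitting from atomic
coordinates, the White--Fuller linking-number decomposition Lk = Tw + Wr,
the persistence length from tangent--tangent correlations, and total
curvature.

Twist for the linking number is the polygonal ribbon twist: the rotation of
the base-pair x axis about the centre line, referenced to discrete parallel
transport of the segment tangents.  Together with the exact polygonal Gauss
writhe this makes Lk = Tw + Wr an integer invariant of closed chains, exact
under any deformation that does not pass the chain through itself.  (The sum
of step-parameter twists agrees with this ribbon twist only to ~1e-3 turns
on curved chains and would break the topological identity.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, IOFormatError, TopologyError
from .geometry import Frame, step_from_frames, rotvec_to_matrix
from .spline import compute_writhe
from .structure import AtomicModel, NucleicStructure
from .templates import DEFAULT_TEMPLATES, RESIDUE_CODES, TemplateLibrary

PARAMETER_NAMES = (
    "shear", "stretch", "stagger", "buckle", "propeller", "opening",
    "shift", "slide", "rise", "tilt", "roll", "twist",
)

_FLIP_X = np.diag([1.0, -1.0, -1.0])


@dataclass
class RigidParameterSet:
    """(t, n_bp, 12) grid of rigid parameters.

    Slot order: intra translations (shear, stretch, stagger; nm), intra
    rotations (buckle, propeller, opening; degrees), step translations
    (shift, slide, rise; nm), step rotations (tilt, roll, twist; degrees).
    Step slot ``i`` holds the step i -> i+1; for open chains the final step
    slot is NaN (absent), for circular chains it is the wrap step.
    """

    values: np.ndarray
    sequence: str
    circular: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 12:
            raise DegenerateInputError(
                f"rigid parameter grid must be (t, n_bp, 12), got {self.values.shape}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[:, :, PARAMETER_NAMES.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        t, n, _ = self.values.shape
        tt, bb = np.meshgrid(np.arange(t), np.arange(n), indexing="ij")
        df = pd.DataFrame(self.values.reshape(t * n, 12), columns=list(PARAMETER_NAMES))
        df.insert(0, "bp", bb.ravel())
        df.insert(0, "time_frame", tt.ravel())
        return df


@dataclass
class TopologyNumbers:
    """White--Fuller decomposition: Lk = Tw + Wr (turns)."""

    Lk: float
    Tw: float
    Wr: float


def kabsch(template_points: np.ndarray, observed_points: np.ndarray):
    """Least-squares rigid superposition: rotation R and translation t with
    observed ~ template @ R.T + t (standard SVD solution)."""
    p = np.asarray(template_points, float)
    q = np.asarray(observed_points, float)
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    h = (p - cp).T @ (q - cq)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    return r, cq - r @ cp


def sequence_from_atomic(atomic: AtomicModel, chain: str = "A") -> str:
    codes = []
    for _, resname, _ in atomic.chain_residues(chain):
        if resname not in RESIDUE_CODES:
            raise IOFormatError(f"unknown residue name {resname!r}")
        codes.append(RESIDUE_CODES[resname])
    return "".join(codes)


def fit_base_frames(atomic: AtomicModel, templates: TemplateLibrary | None = None,
                    sense_chain: str = "A", anti_chain: str = "B"):
    """Base reference frames from atomic coordinates by ring-atom superposition.

    Each base frame is the template frame carried by the optimal rigid
    superposition of the template's ring atoms onto the observed ones.
    Antisense frames are flipped 180 degrees about their own x axis so both
    frames of a pair are co-oriented.  Returns ``(watson, crick, sequence)``
    with frame grids of shape (n_bp, 4, 3); crick grid index i pairs watson
    index i (antisense residue n_bp-1-i).
    """
    if templates is None:
        templates = DEFAULT_TEMPLATES

    def _fit_chain(chain_id: str):
        frames = []
        for res_i, resname, sel in atomic.chain_residues(chain_id):
            if resname not in RESIDUE_CODES:
                raise IOFormatError(f"unknown residue name {resname!r} "
                                    f"(chain {chain_id}, residue {res_i})")
            code = RESIDUE_CODES[resname]
            tpl = templates.get(code)
            name_to_pos = {atomic.atom_names[k]: atomic.coordinates[k] for k in sel}
            missing = [a for a in tpl.ring_atoms if a not in name_to_pos]
            if missing:
                raise IOFormatError(
                    f"residue {res_i} ({resname}, chain {chain_id}) lacks ring "
                    f"atoms {missing}")
            obs = np.array([name_to_pos[a] for a in tpl.ring_atoms])
            r, t = kabsch(tpl.ring_positions(), obs)
            frames.append(np.vstack([t, r.T]))  # triad rows = R columns
        return np.array(frames)

    watson = _fit_chain(sense_chain)
    anti = _fit_chain(anti_chain)
    if len(watson) != len(anti):
        raise IOFormatError(
            f"strand lengths differ: {len(watson)} vs {len(anti)} residues")
    # chain B residue j pairs chain A residue n-1-j; flip about own x axis
    crick = anti[::-1].copy()
    crick[:, 1:] = _FLIP_X @ crick[:, 1:]
    sequence = sequence_from_atomic(atomic, sense_chain)
    return watson, crick, sequence


def _pair_frame_and_intra(watson_block: np.ndarray, crick_block: np.ndarray):
    """Base-pair mid-frame plus the six intra parameters (Watson relative to
    the co-oriented Crick frame, resolved in the pair mid-frame)."""
    c = Frame.from_array(crick_block)
    w = Frame.from_array(watson_block)
    s = step_from_frames(c, w)
    half = rotvec_to_matrix(np.radians(s.rotation) / 2.0)
    mid_triad = half.T @ c.triad
    mid_origin = (c.origin + w.origin) / 2.0
    return np.vstack([mid_origin, mid_triad]), np.concatenate([s.translation, s.rotation])


def compute_rigid_parameters(structure: NucleicStructure) -> RigidParameterSet:
    """The 12 rigid parameters per base pair per time frame.

    When the structure was generated (single frame per base pair), Watson and
    Crick base frames coincide with the base-pair frame and the intra
    parameters are zero by construction; structures fitted from atoms carry
    distinct strand frames and yield non-trivial intra parameters.
    """
    t_frames, n, _, _ = structure.frames.shape
    out = np.full((t_frames, n, 12), np.nan)

    for t in range(t_frames):
        if structure.watson_frames is not None and structure.crick_frames is not None:
            pair_frames = np.empty((n, 4, 3))
            for i in range(n):
                pair_frames[i], out[t, i, :6] = _pair_frame_and_intra(
                    structure.watson_frames[t, i], structure.crick_frames[t, i])
        else:
            pair_frames = structure.frames[t]
            out[t, :, :6] = 0.0

        n_steps = n if structure.circular else n - 1
        for i in range(n_steps):
            a = Frame.from_array(pair_frames[i])
            b = Frame.from_array(pair_frames[(i + 1) % n])
            s = step_from_frames(a, b)
            out[t, i, 6:9] = s.translation
            out[t, i, 9:12] = s.rotation

    return RigidParameterSet(out, structure.sequence, structure.circular)


def ribbon_twist(origins: np.ndarray, x_axes: np.ndarray, closed: bool) -> float:
    """Total twist (turns) of the material x axis about the polygonal centre
    line, referenced to discrete parallel transport of the segment tangents."""
    o = np.asarray(origins, float)
    x = np.asarray(x_axes, float)
    n = len(o)
    if n < 3:
        raise DegenerateInputError("need at least 3 vertices for ribbon twist")
    if closed:
        tangents = np.roll(o, -1, axis=0) - o
    else:
        tangents = np.diff(o, axis=0)
    norms = np.linalg.norm(tangents, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateInputError("coincident consecutive origins")
    tangents = tangents / norms[:, None]
    m = len(tangents)

    def _proj(v, t):
        w = v - (v @ t) * t
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise DegenerateInputError("material axis parallel to the tangent")
        return w / nw

    def _transport(v, t_from, t_to):
        axis = np.cross(t_from, t_to)
        s = np.linalg.norm(axis)
        if s < 1e-14:
            return v if (t_from @ t_to) > 0 else -v
        ang = math.atan2(s, float(np.clip(t_from @ t_to, -1, 1)))
        return rotvec_to_matrix(axis / s * ang) @ v

    total = 0.0
    a_prev = _proj(x[0], tangents[0])
    for k in range(1, n + 1 if closed else n):
        j = k % n
        t_prev = tangents[(k - 1) % m]
        t_here = tangents[j] if j < m else tangents[m - 1]
        carried = _transport(a_prev, t_prev, t_here)
        a_here = _proj(x[j], t_here)
        ang = math.atan2(float(np.cross(carried, a_here) @ t_here),
                         float(np.clip(carried @ a_here, -1, 1)))
        total += ang
        a_prev = a_here
    return total / (2.0 * math.pi)


def compute_linking_number(structure: NucleicStructure, frame_index: int = 0,
                           allow_open: bool = False) -> TopologyNumbers:
    """Lk = Tw + Wr over the base-pair centre line.

    Tw is the ribbon twist of the base-pair x axes, Wr the exact polygonal
    Gauss writhe of the origins.  For closed chains Lk is an integer to
    numerical precision; for open chains only Tw is well defined unless
    ``allow_open`` requests the open-chain Gauss integral.
    """
    origins = structure.frames[frame_index, :, 0]
    x_axes = structure.frames[frame_index, :, 1]
    if not structure.circular and not allow_open:
        raise TopologyError(
            "linking number of an open chain is undefined; pass allow_open=True "
            "to obtain the open-chain Gauss-integral analogues")
    tw = ribbon_twist(origins, x_axes, closed=structure.circular)
    wr = compute_writhe(origins, closed=structure.circular, allow_open=allow_open)
    return TopologyNumbers(Lk=tw + wr, Tw=tw, Wr=wr)


def persistence_length(frames: np.ndarray | NucleicStructure,
                       max_lag: int | None = None,
                       correlation_floor: float = 0.05) -> float:
    """Bending persistence length (nm) from tangent correlations.

    Fits <z_i . z_{i+m}>, averaged over positions and the ensemble, to
    exp(-m h / l_p) with h the mean rise, by log-linear least squares on
    lags with correlation above ``correlation_floor`` and m <= n_bp/2.
    A perfectly straight, rigid chain returns ``math.inf``.
    """
    if isinstance(frames, NucleicStructure):
        frames = frames.frames
    frames = np.asarray(frames, float)
    if frames.ndim == 3:
        frames = frames[None]
    t, n = frames.shape[:2]
    if n < 20:
        raise DegenerateInputError("persistence length needs at least 20 bp")
    z = frames[:, :, 3, :]
    origins = frames[:, :, 0, :]
    h = float(np.mean(np.linalg.norm(np.diff(origins, axis=1), axis=2)))

    if max_lag is None:
        max_lag = n // 2
    lags = np.arange(1, max_lag + 1)
    corr = np.array([np.mean(np.einsum("tij,tij->ti", z[:, :-m], z[:, m:]))
                     for m in lags])

    usable = corr > correlation_floor
    if not np.any(usable):
        raise DegenerateInputError("correlations decay below the floor at lag 1")
    lags_u, corr_u = lags[usable], corr[usable]
    if np.all(corr_u > 1.0 - 1e-12):
        return math.inf
    slope = np.polyfit(lags_u, np.log(corr_u), 1)[0]
    if slope >= 0:
        return math.inf
    return float(-h / slope)


def total_curvature(params: RigidParameterSet) -> np.ndarray:
    """Per time frame: sum over steps of sqrt(tilt^2 + roll^2), degrees."""
    tilt = params["tilt"]
    roll = params["roll"]
    return np.nansum(np.sqrt(tilt ** 2 + roll ** 2), axis=1)
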