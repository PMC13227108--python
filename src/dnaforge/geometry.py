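"""Frame algebra for rigid base-pair geometry.

A :class:`Frame` is an origin (nm) together with a right-handed orthonormal
triad (x, y, z unit vectors).  By convention z points along the helix axis
toward the 3' end of the reference strand and x toward the major groove
(the standard base reference frame).  The relative geometry of two frames is
expressed as a six-component step vector -- translations (shift, slide,
rise) in nm and rotations (tilt, roll, twist) in degrees -- resolved in the
half-rotation mid-frame, following the Curves+ convention.

All rotations are parameterized as rotation vectors (axis--angle).  The
conversions here are hand-rolled numpy (they sit on the Monte Carlo hot
path); scipy's Rotation class is deliberately *not* used so that it can act
as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    AmbiguousRotationError,
    InvalidFrameError,
    RotationOutOfRangeError,
)

_ORTHO_TOL = 1e-9
# Re-orthonormalize composed frames after this many chained applications.
REORTHONORMALIZE_EVERY = 100


def orthonormalize(triad: np.ndarray) -> np.ndarray:
    """Project a nearly-orthonormal 3x3 row-triad back onto SO(3) (via SVD)."""
    u, _, vt = np.linalg.svd(triad)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def triad_is_valid(triad: np.ndarray, tol: float = _ORTHO_TOL) -> bool:
    triad = np.asarray(triad, dtype=float)
    if triad.shape != (3, 3) or not np.all(np.isfinite(triad)):
        return False
    if not np.allclose(triad @ triad.T, np.eye(3), atol=tol):
        return False
    return abs(np.linalg.det(triad) - 1.0) < 10 * tol


def _require_valid_triad(triad: np.ndarray, tol: float = 1e-8) -> None:
    if not triad_is_valid(triad, tol=tol):
        raise InvalidFrameError("triad is not right-handed orthonormal")


@dataclass
class Frame:
    """Origin (nm) plus right-handed orthonormal triad (rows: x, y, z)."""

    origin: np.ndarray
    triad: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.triad = np.asarray(self.triad, dtype=float).reshape(3, 3)

    @classmethod
    def identity(cls) -> "Frame":
        return cls(np.zeros(3), np.eye(3))

    def validate(self, tol: float = 1e-8) -> "Frame":
        if not np.all(np.isfinite(self.origin)):
            raise InvalidFrameError("non-finite origin")
        _require_valid_triad(self.triad, tol=tol)
        return self

    def copy(self) -> "Frame":
        return Frame(self.origin.copy(), self.triad.copy())

    def as_array(self) -> np.ndarray:
        """(4, 3) block: row 0 the origin, rows 1-3 the x, y, z vectors."""
        return np.vstack([self.origin, self.triad])

    @classmethod
    def from_array(cls, block: np.ndarray) -> "Frame":
        block = np.asarray(block, dtype=float)
        if block.shape != (4, 3):
            raise InvalidFrameError(f"expected (4, 3) frame block, got {block.shape}")
        return cls(block[0], block[1:])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Frame":
        """Rigid-body transform of the frame (world-fixed rotation matrix)."""
        return Frame(rotation @ self.origin + translation, self.triad @ rotation.T)


@dataclass
class StepVector:
    """Six step coordinates: translation (shift, slide, rise) in nm and
    rotation (tilt, roll, twist) in degrees, resolved in the mid-frame."""

    translation: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "StepVector":
        v = np.asarray(v, dtype=float).reshape(6)
        return cls(v[:3], v[3:])

    def as_vector(self) -> np.ndarray:
        """[shift, slide, rise, tilt, roll, twist]."""
        return np.concatenate([self.translation, self.rotation])

    def validate(self) -> "StepVector":
        v = self.as_vector()
        if not np.all(np.isfinite(v)):
            raise RotationOutOfRangeError("non-finite step components")
        if np.linalg.norm(self.rotation) >= 180.0:
            raise RotationOutOfRangeError(
                "step rotation magnitude must be < 180 degrees (principal rotation)"
            )
        return self


# -- rotation-vector <-> matrix conversions ---------------------------------

def rotvec_to_matrix(v: np.ndarray) -> np.ndarray:
    """Rodrigues formula; ``v`` in radians."""
    v = np.asarray(v, dtype=float)
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        k = _skew(v)
        return np.eye(3) + k + 0.5 * (k @ k)
    u = v / angle
    k = _skew(u)
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def matrix_to_rotvec(r: np.ndarray) -> np.ndarray:
    """Principal rotation vector (radians) of a rotation matrix.

    Accurate for all angles in [0, pi]; at exactly pi the axis sign is
    conventional (largest-diagonal column, skew-disambiguated when possible).
    """
    r = np.asarray(r, dtype=float)
    cos = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.arccos(cos)
    skew = 0.5 * np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
    if angle < 1e-7:
        # sin(x)/x ~ 1 - x^2/6
        return skew * (1.0 + angle * angle / 6.0)
    if np.pi - angle < 1e-7:
        # R ~ 2 uu^T - I near pi: read the axis off (R + I)/2.
        a = (r + np.eye(3)) / 2.0
        i = int(np.argmax(np.diag(a)))
        u = a[:, i] / np.sqrt(max(a[i, i], 1e-300))
        u /= np.linalg.norm(u)
        if skew @ u < 0:
            u = -u
        return u * angle
    return skew * (angle / np.sin(angle))


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


# -- the four frame-pair operations -----------------------------------------

def rotation_vector(a_triad: np.ndarray, b_triad: np.ndarray) -> np.ndarray:
    """Axis-angle (degrees) of the relative rotation carrying triad ``a``
    onto triad ``b``, with components expressed in the ``a``-frame basis.

    Triads are stored as rows; with column matrices Ma, Mb the relative
    rotation in the a basis is Ma^T Mb = a_rows @ b_rows^T ... transposed;
    concretely ``R = a_triad @ b_triad.T`` maps b-components to a-components,
    and its transpose rotates a onto b.
    """
    a_triad = np.asarray(a_triad, dtype=float)
    b_triad = np.asarray(b_triad, dtype=float)
    _require_valid_triad(a_triad)
    _require_valid_triad(b_triad)
    r_ab = a_triad @ b_triad.T  # Ma^T @ Mb with rows-as-axes storage
    return np.degrees(matrix_to_rotvec(r_ab))


def midframe(a: Frame, b: Frame) -> Frame:
    """Half-rotation mid-frame: a's triad composed with R(u, phi/2); origin
    the midpoint of the two origins.  Raises for phi = 180 degrees exactly
    (ambiguous axis)."""
    rv_deg = rotation_vector(a.triad, b.triad)
    angle = np.linalg.norm(rv_deg)
    if abs(angle - 180.0) < 1e-9:
        raise AmbiguousRotationError(
            "mid-frame of a 180-degree rotation is ambiguous; perturb one frame"
        )
    half = rotvec_to_matrix(np.radians(rv_deg) / 2.0)
    # Column matrices: Mmid = Ma @ Rhalf; row storage: rows = (Ma @ Rhalf)^T.
    mid_triad = half.T @ a.triad
    return Frame((a.origin + b.origin) / 2.0, mid_triad)


def step_from_frames(a: Frame, b: Frame) -> StepVector:
    """Step coordinates of frame pair (a, b) in the mid-frame basis.

    The rotation vector's components are identical in the a, b and
    mid-frame bases (the axis is invariant under the rotation itself), so
    only the translation needs re-expression.
    """
    rv_deg = rotation_vector(a.triad, b.triad)
    mid = midframe(a, b)
    translation = mid.triad @ (b.origin - a.origin)
    return StepVector(translation, rv_deg)


def frames_from_step(a: Frame, s: StepVector) -> Frame:
    """Unique frame ``b`` with ``step_from_frames(a, b) == s``."""
    s.validate()
    rv = np.radians(s.rotation)
    full = rotvec_to_matrix(rv)
    half = rotvec_to_matrix(rv / 2.0)
    b_triad = full.T @ a.triad
    mid_triad = half.T @ a.triad
    origin_b = a.origin + mid_triad.T @ s.translation
    return Frame(origin_b, b_triad)


def chain_frames(start: Frame, steps) -> list:
    """Compose a chain of steps from a starting frame, re-orthonormalizing
    every :data:`REORTHONORMALIZE_EVERY` applications to cap float drift."""
    frames = [start.copy()]
    for i, s in enumerate(steps, start=1):
        nxt = frames_from_step(frames[-1], s)
        if i % REORTHONORMALIZE_EVERY == 0:
            nxt.triad = orthonormalize(nxt.triad)
        frames.append(nxt)
    return frames
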