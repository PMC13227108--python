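"""Metropolis Monte Carlo relaxation of base-pair frame chains.

The energy is a quadratic rigid-base-step elastic Hamiltonian: for each step
x_i (six coordinates from :func:`dnaforge.geometry.step_from_frames`),
E = 1/2 sum_i (x_i - x_0)^T K (x_i - x_0) in units of kT at 300 K, plus a
hard-sphere excluded volume between base-pair origins.  The default
stiffness is diagonal, derived from a bending persistence length of 50 nm
and a torsional persistence length of 100 nm at 0.34 nm rise, with stiff
translations (rise fluctuation ~0.01 nm); all entries are overridable.

Moves: (i) crankshaft -- rotate the frames strictly between two chain points
about the axis joining their origins (endpoints untouched; the only move
needed for closed chains); (ii) terminal pivot for open chains -- rotate a
terminal segment about a hinge; (iii) a local single-frame perturbation of
one origin and triad, which equips the sampler with translational degrees of
freedom.  Proposals are symmetric; moves touching fixed indices are rejected
outright.  A hard-wall rejection on the excluded volume together with a
per-move displacement cap of half the hard-sphere diameter prevents chain
passage, so the linking number of closed chains is conserved exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import DegenerateInputError, MinimizationError
from .geometry import (
    Frame,
    frames_from_step,
    matrix_to_rotvec,
    orthonormalize,
    rotvec_to_matrix,
    step_from_frames,
    StepVector,
)
from .spline import BP_PER_TURN, RISE, compute_writhe
from .structure import NucleicStructure
from .analysis import compute_linking_number

logger = logging.getLogger(__name__)

_DEG2 = (180.0 / math.pi) ** 2
_MC_BASES = set("ATGCU")  # the MC elastic model covers canonical bases only


def default_stiffness(bend_persistence_nm: float = 50.0,
                      twist_persistence_nm: float = 100.0,
                      rise: float = RISE,
                      translational_sigma_nm: float = 0.01) -> np.ndarray:
    """Diagonal 6x6 stiffness (kT units: nm^-2 and deg^-2).

    Bending: <tilt^2> = <roll^2> = rise / l_p (radians^2); twist likewise from
    the torsional persistence length.  Translations are stiff springs with the
    given fluctuation."""
    k_bend = 1.0 / (rise / bend_persistence_nm * _DEG2)
    k_twist = 1.0 / (rise / twist_persistence_nm * _DEG2)
    k_trans = 1.0 / translational_sigma_nm ** 2
    return np.diag([k_trans, k_trans, k_trans, k_bend, k_bend, k_twist])


@dataclass
class ElasticModel:
    """Equilibrium step plus stiffness matrix driving the MC energy."""

    equilibrium_step: StepVector = field(
        default_factory=lambda: StepVector([0.0, 0.0, RISE], [0.0, 0.0, 360.0 / BP_PER_TURN]))
    stiffness: np.ndarray = field(default_factory=default_stiffness)

    def __post_init__(self) -> None:
        self.stiffness = np.asarray(self.stiffness, dtype=float)
        if self.stiffness.shape != (6, 6):
            raise DegenerateInputError("stiffness must be 6x6")
        if not np.allclose(self.stiffness, self.stiffness.T, atol=1e-9):
            raise DegenerateInputError("stiffness must be symmetric")
        if np.any(np.linalg.eigvalsh(self.stiffness) < -1e-9):
            raise DegenerateInputError("stiffness must be positive semidefinite")

    @property
    def x0(self) -> np.ndarray:
        return self.equilibrium_step.as_vector()

    def step_energy(self, step6: np.ndarray) -> float:
        d = step6 - self.x0
        return 0.5 * float(d @ self.stiffness @ d)

    def covariance(self) -> np.ndarray:
        """Thermal step covariance K^-1 (kT = 1)."""
        return np.linalg.inv(self.stiffness)


@dataclass
class MCConfig:
    """Knobs of the Metropolis sampler.  The seed is mandatory."""

    seed: int
    temperature: float = 300.0
    ev_diameter: float = 2.0  # nm, hard-sphere diameter of the duplex
    # chain separation below which the hard sphere is exempt; 8 steps is the
    # smallest exemption for which ideal B-DNA (0.34 nm stacking) clears a
    # 2.0 nm diameter with margin (8 x 0.34 = 2.72 nm)
    ev_min_separation: int = 8
    fixed_indices: set | None = None
    conserve_topology: bool | None = None  # default: closed chains conserve
    max_sweeps: int = 500
    check_every: int = 50
    crank_angle: float = 0.3  # rad, crankshaft amplitude
    crank_max_span: int = 60  # longest block a crankshaft may rotate
    pivot_angle: float = 0.15  # rad, terminal-pivot amplitude
    local_translation: float = 0.01  # nm
    local_rotation: float = 4.0  # degrees

    def __post_init__(self) -> None:
        if self.seed is None:
            raise MinimizationError("MCConfig.seed is required for reproducibility")
        for amp in (self.crank_angle, self.pivot_angle,
                    self.local_translation, self.local_rotation):
            if amp <= 0:
                raise DegenerateInputError("move amplitudes must be positive")


@dataclass
class MinimizationResult:
    structure: NucleicStructure
    energy_trace: np.ndarray
    writhe_trace: np.ndarray | None
    tau: float
    converged: bool
    acceptance_rate: float
    lk_before: float | None = None
    lk_after: float | None = None


def _chain_separation(i: np.ndarray, j: np.ndarray, n: int, circular: bool):
    d = np.abs(i - j)
    return np.minimum(d, n - d) if circular else d


def excluded_volume_ok(origins: np.ndarray, config: MCConfig,
                       circular: bool = False) -> bool:
    """True iff all origin pairs with chain separation >= ev_min_separation
    are at least ev_diameter apart."""
    o = np.asarray(origins, float)
    n = len(o)
    ii, jj = np.triu_indices(n, k=config.ev_min_separation)
    if circular:
        keep = _chain_separation(ii, jj, n, True) >= config.ev_min_separation
        ii, jj = ii[keep], jj[keep]
    if len(ii) == 0:
        return True
    d2 = np.sum((o[ii] - o[jj]) ** 2, axis=1)
    return bool(np.all(d2 >= config.ev_diameter ** 2))


def elastic_energy(structure: NucleicStructure, model: ElasticModel,
                   frame_index: int = 0, config: MCConfig | None = None) -> float:
    """Total elastic energy (kT); ``inf`` if a supplied config's excluded
    volume is violated."""
    if structure.n_bp < 2:
        raise DegenerateInputError("energy needs at least 2 bp")
    grid = structure.frames[frame_index]
    if config is not None and not excluded_volume_ok(
            grid[:, 0], config, structure.circular):
        return math.inf
    return sum(
        model.step_energy(_step6(grid, i, (i + 1) % structure.n_bp))
        for i in range(structure.n_bp if structure.circular else structure.n_bp - 1)
    )


def _step6(grid: np.ndarray, i: int, j: int) -> np.ndarray:
    """Step 6-vector between grid blocks i and j (hot path: same math as
    :func:`dnaforge.geometry.step_from_frames` without object wrapping)."""
    oa, ta = grid[i, 0], grid[i, 1:]
    ob, tb = grid[j, 0], grid[j, 1:]
    rv = matrix_to_rotvec(ta @ tb.T)
    mid = rotvec_to_matrix(rv / 2.0).T @ ta
    return np.concatenate([mid @ (ob - oa), np.degrees(rv)])


def fit_convergence(trace, require_plateau: bool = False):
    """Fit c + a exp(-t/tau) to a per-sweep trace.

    Returns ``(tau, converged)``; converged means the trace spans at least
    five decay times and the fitted plateau is stable between the first and
    second half of the trace (relative change < 5%).  With
    ``require_plateau`` (barrier-crossing runs) the last 20% of the trace
    must additionally fluctuate around a fixed value.
    """
    y = np.asarray(trace, dtype=float)
    if len(y) < 20:
        raise DegenerateInputError("convergence fit needs at least 20 points")
    if not np.all(np.isfinite(y)):
        raise DegenerateInputError("non-finite trace values")
    scale = float(np.ptp(y))
    if scale < 1e-12 * max(1.0, abs(y[0])):
        return 0.0, True

    def _fit(yy):
        t = np.arange(len(yy), dtype=float)
        c0 = float(np.mean(yy[-max(len(yy) // 10, 1):]))
        a0 = float(yy[0] - c0) or scale
        try:
            popt, _ = curve_fit(
                lambda t, c, a, tau: c + a * np.exp(-t / tau),
                t, yy, p0=[c0, a0, max(len(yy) / 5.0, 1.0)],
                bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000)
        except RuntimeError:
            return None
        return popt

    full = _fit(y)
    if full is None:
        return math.inf, False
    c, _, tau = full
    converged = len(y) >= 5 * tau

    half = len(y) // 2
    f1, f2 = _fit(y[:half]), _fit(y[half:])
    if f1 is None or f2 is None:
        converged = False
    else:
        ref = max(abs(c), scale)
        converged = converged and abs(f2[0] - f1[0]) <= 0.05 * ref

    if require_plateau and converged:
        k = max(len(y) // 5, 5)
        tail, prev = y[-k:], y[-2 * k:-k]
        ref = max(abs(c), scale)
        converged = abs(np.mean(tail) - np.mean(prev)) <= 0.05 * ref

    return float(tau), bool(converged)


class _MCState:
    """Working state for one relaxation run (single time frame)."""

    def __init__(self, structure: NucleicStructure, model: ElasticModel,
                 config: MCConfig, frame_index: int):
        self.grid = structure.frames[frame_index].copy()
        self.n = structure.n_bp
        self.circular = structure.circular
        self.model = model
        self.config = config
        self.beta = 300.0 / config.temperature
        n_steps = self.n if self.circular else self.n - 1
        self.step_e = np.array([
            model.step_energy(_step6(self.grid, i, (i + 1) % self.n))
            for i in range(n_steps)])
        if structure.free_indices is not None:
            self.fixed = set(range(self.n)) - set(structure.free_indices)
        elif config.fixed_indices is not None:
            self.fixed = {i % self.n for i in config.fixed_indices}
        elif not self.circular:
            self.fixed = {0, self.n - 1}  # default: pin the ends of open chains
        else:
            self.fixed = set()
        if len(self.fixed) >= self.n:
            raise MinimizationError("no movable indices")
        self.accepted = 0
        self.proposed = 0

    # steps adjacent to a vertex index (existing ones only)
    def _steps_at(self, idx):
        out = set()
        for v in idx:
            if self.circular:
                out.add((v - 1) % self.n)
                out.add(v % self.n)
            else:
                if v - 1 >= 0:
                    out.add(v - 1)
                if v <= self.n - 2:
                    out.add(v)
        return sorted(out)

    def _try_move(self, moved, new_blocks, rng, affected=None) -> bool:
        """Metropolis-accept a proposed update of the ``moved`` vertices.

        ``affected`` lists the step indices whose geometry the move can
        change; rigid block moves only alter the two boundary steps, which
        keeps the energy update O(1) per move."""
        self.proposed += 1
        if any(v in self.fixed for v in moved):
            return False
        cap = self.config.ev_diameter / 2.0
        old = self.grid[moved]
        disp = np.linalg.norm(new_blocks[:, 0] - old[:, 0], axis=1)
        if np.any(disp > cap):
            return False  # displacement cap: no chain passage possible

        # excluded volume: moved beads vs the unmoved rest (moved-moved
        # distances are preserved by rigid block moves; the local move has
        # a single bead)
        moved_arr = np.asarray(moved)
        keep = np.ones(self.n, dtype=bool)
        keep[moved_arr] = False
        others = np.nonzero(keep)[0]
        if len(others):
            sep = _chain_separation(moved_arr[:, None], others[None, :],
                                    self.n, self.circular)
            mask = sep >= self.config.ev_min_separation
            if np.any(mask):
                d2 = np.sum((new_blocks[:, None, 0, :] - self.grid[others][None, :, 0, :]) ** 2,
                            axis=2)
                if np.any(d2[mask] < self.config.ev_diameter ** 2):
                    return False

        if affected is None:
            affected = self._steps_at(moved)
        saved = self.grid[moved].copy()
        self.grid[moved] = new_blocks
        new_e = np.array([
            self.model.step_energy(_step6(self.grid, s, (s + 1) % self.n))
            for s in affected])
        delta = float(new_e.sum() - self.step_e[affected].sum())
        if delta <= 0 or rng.random() < math.exp(-delta * self.beta):
            self.step_e[affected] = new_e
            self.accepted += 1
            return True
        self.grid[moved] = saved
        return False

    # -- move generators -----------------------------------------------------

    def crankshaft(self, rng) -> bool:
        n = self.n
        max_span = min(max(n // 2, 3), self.config.crank_max_span)
        if self.circular:
            i = int(rng.integers(0, n))
            span = int(rng.integers(2, max(max_span, 3)))
            j = (i + span) % n
            moved = [(i + k) % n for k in range(1, span)]
        else:
            if n < 3:
                return False
            i = int(rng.integers(0, n - 2))
            j = int(rng.integers(i + 2, min(i + 1 + max_span, n)))
            moved = list(range(i + 1, j))
        axis = self.grid[j, 0] - self.grid[i, 0]
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            return False
        theta = rng.normal(0.0, self.config.crank_angle)
        r = rotvec_to_matrix(axis / nrm * theta)
        blocks = self.grid[moved].copy()
        blocks[:, 0] = (blocks[:, 0] - self.grid[i, 0]) @ r.T + self.grid[i, 0]
        blocks[:, 1:] = blocks[:, 1:] @ r.T
        affected = sorted({i % self.n, (j - 1) % self.n})
        return self._try_move(moved, blocks, rng, affected=affected)

    def pivot(self, rng) -> bool:
        n = self.n
        if self.circular or n < 2:
            return False
        hinge = int(rng.integers(0, n - 1))
        if rng.random() < 0.5:
            moved = list(range(hinge + 1, n))
            anchor = self.grid[hinge, 0]
        else:
            moved = list(range(0, hinge + 1))
            anchor = self.grid[hinge + 1, 0]
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        theta = rng.normal(0.0, self.config.pivot_angle)
        r = rotvec_to_matrix(v * theta)
        blocks = self.grid[moved].copy()
        blocks[:, 0] = (blocks[:, 0] - anchor) @ r.T + anchor
        blocks[:, 1:] = blocks[:, 1:] @ r.T
        return self._try_move(moved, blocks, rng, affected=[hinge])

    def local(self, rng) -> bool:
        i = int(rng.integers(0, self.n))
        block = self.grid[[i]].copy()
        block[0, 0] += rng.normal(0.0, self.config.local_translation, size=3)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        theta = math.radians(rng.normal(0.0, self.config.local_rotation))
        r = rotvec_to_matrix(v * theta)
        block[0, 1:] = block[0, 1:] @ r.T
        return self._try_move([i], block, rng)

    def sweep(self, rng) -> None:
        for _ in range(self.n):
            u = rng.random()
            if self.circular:
                (self.crankshaft if u < 0.7 else self.local)(rng)
            else:
                if u < 0.5:
                    self.crankshaft(rng)
                elif u < 0.75:
                    self.pivot(rng)
                else:
                    self.local(rng)

    def reorthonormalize(self) -> None:
        for i in range(self.n):
            self.grid[i, 1:] = orthonormalize(self.grid[i, 1:])


def minimize(structure: NucleicStructure, model: ElasticModel | None = None,
             config: MCConfig | None = None, frame_index: int = 0) -> MinimizationResult:
    """Relax a structure by Metropolis MC under the elastic + hard-sphere
    energy.  Closed chains conserve their linking number exactly (verified
    after the run when ``conserve_topology`` applies).  Non-canonical bases
    are incompatible with the elastic model and raise."""
    bad = {c for c in structure.sequence if c not in _MC_BASES}
    if bad:
        raise MinimizationError(
            f"non-canonical bases {sorted(bad)} are incompatible with MC minimization")
    if model is None:
        model = ElasticModel()
    if config is None:
        raise MinimizationError("an MCConfig with a seed is required")

    rng = np.random.default_rng(config.seed)
    state = _MCState(structure, model, config, frame_index)

    conserve = config.conserve_topology
    if conserve is None:
        conserve = structure.circular
    lk_before = (compute_linking_number(structure, frame_index).Lk
                 if structure.circular else None)

    energy_trace = []
    writhe_trace = [] if structure.circular else None
    tau, converged = math.inf, False
    require_plateau = bool(structure.circular and (structure.dLk or 0) != 0)

    for sweep in range(1, config.max_sweeps + 1):
        state.sweep(rng)
        energy_trace.append(float(state.step_e.sum()))
        if writhe_trace is not None:
            writhe_trace.append(compute_writhe(state.grid[:, 0], closed=True))
        if sweep % 100 == 0:
            state.reorthonormalize()
        if sweep % config.check_every == 0 and sweep >= 20:
            tau, converged = fit_convergence(energy_trace)
            if converged and require_plateau:
                # barrier-crossing runs: the writhe must also have settled
                _, converged = fit_convergence(writhe_trace, require_plateau=True)
            if converged:
                logger.info("converged after %d sweeps (tau = %.1f)", sweep, tau)
                break

    state.reorthonormalize()
    out = structure.copy()
    out.frames = structure.frames.copy()
    out.frames[frame_index] = state.grid
    out.invalidate_atomic()

    lk_after = (compute_linking_number(out, frame_index).Lk
                if structure.circular else None)
    if conserve and lk_before is not None and abs(lk_after - lk_before) > 0.5:
        raise MinimizationError(
            f"linking number changed during minimization: {lk_before:.3f} -> "
            f"{lk_after:.3f} (chain passage should be impossible)")

    acc = state.accepted / max(state.proposed, 1)
    return MinimizationResult(
        structure=out,
        energy_trace=np.asarray(energy_trace),
        writhe_trace=None if writhe_trace is None else np.asarray(writhe_trace),
        tau=tau, converged=converged, acceptance_rate=acc,
        lk_before=lk_before, lk_after=lk_after,
    )


def sample_ensemble(model: ElasticModel, n_bp: int, n_samples: int, seed: int,
                    start: Frame | None = None) -> np.ndarray:
    """Draw equilibrium conformations of a *linear* chain by direct Gaussian
    sampling of the steps (exact for the quadratic Hamiltonian without
    excluded volume): steps ~ N(x0, K^-1 kT).  Returns (n_samples, n_bp, 4, 3)."""
    if n_bp < 2:
        raise DegenerateInputError("need at least 2 bp")
    rng = np.random.default_rng(seed)
    cov = model.covariance()
    chol = np.linalg.cholesky(cov + 1e-15 * np.eye(6))
    x0 = model.x0
    if start is None:
        start = Frame.identity()
    out = np.empty((n_samples, n_bp, 4, 3))
    for s in range(n_samples):
        draws = x0 + rng.normal(size=(n_bp - 1, 6)) @ chol.T
        f = start.copy()
        out[s, 0] = f.as_array()
        for i in range(n_bp - 1):
            f = frames_from_step(f, StepVector.from_vector(draws[i]))
            if (i + 1) % 100 == 0:
                f.triad = orthonormalize(f.triad)
            out[s, i + 1] = f.as_array()
    return out
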