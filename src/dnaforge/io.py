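"""Readers, writers and fixture generation.

Formats:

* frame-array text -- one line per base pair, 12 floats (``%.9f``): origin
  then the x, y, z triad vectors (nm); time frames separated by blank lines;
  a header comment carries the sequence and the circular flag.  The format
  round-trips bit-exactly.
* PDB -- read and written through Biopython (multi-model PDB is treated as a
  trajectory).  PDB coordinates are Angstrom; the API is nm and the factor 10
  is applied only at this boundary.
* CSV -- rigid parameters and minimization traces, via pandas.
"""

from __future__ import annotations

import logging
import os
import warnings

import numpy as np
import pandas as pd

from .analysis import compute_rigid_parameters, fit_base_frames, _pair_frame_and_intra
from .exceptions import IOFormatError
from .geometry import orthonormalize, triad_is_valid
from .structure import AtomicModel, NucleicStructure, make
from .templates import RESIDUE_CODES, TemplateLibrary

logger = logging.getLogger(__name__)

NM_PER_ANGSTROM = 0.1


# -- frame-array text format -------------------------------------------------

def write_frames(structure: NucleicStructure, path) -> None:
    """Write the (t, n_bp, 4, 3) frame grid as diff-able plain text."""
    with open(path, "w") as fh:
        fh.write("# dnaforge frame array\n")
        fh.write(f"# sequence={structure.sequence}\n")
        fh.write(f"# circular={int(structure.circular)}\n")
        for t in range(structure.n_time_frames):
            if t:
                fh.write("\n")
            for bp in range(structure.n_bp):
                row = structure.frames[t, bp].reshape(12)
                fh.write(" ".join(f"{v:.9f}" for v in row) + "\n")


def _parse_frame_text(path):
    sequence, circular = None, None
    blocks, current = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("sequence="):
                    sequence = body[len("sequence="):]
                elif body.startswith("circular="):
                    circular = bool(int(body[len("circular="):]))
                continue
            if not line.strip():
                if current:
                    blocks.append(current)
                    current = []
                continue
            vals = [float(x) for x in line.split()]
            if len(vals) != 12:
                raise IOFormatError(f"expected 12 floats per line, got {len(vals)}")
            current.append(vals)
    if current:
        blocks.append(current)
    if not blocks:
        raise IOFormatError(f"no frame data found in {path}")
    n_bp = len(blocks[0])
    if any(len(b) != n_bp for b in blocks):
        raise IOFormatError("time frames have inconsistent base-pair counts")
    arr = np.array(blocks, dtype=float).reshape(len(blocks), n_bp, 4, 3)
    return arr, sequence, circular


def load_frames(source, sequence: str | None = None,
                circular: bool | None = None) -> NucleicStructure:
    """Build a structure from a frame array (path or ndarray) plus sequence.

    Validates the (t, n_bp, 4, 3) shape, the sequence length, and triad
    orthonormality: deviations below 1e-6 pass, up to 1e-3 are silently
    repaired by re-orthonormalization (logged), anything worse is an error.
    Topology is auto-classified from end proximity unless given explicitly.
    """
    if isinstance(source, (str, os.PathLike)):
        arr, file_seq, file_circ = _parse_frame_text(source)
        sequence = sequence if sequence is not None else file_seq
        circular = circular if circular is not None else file_circ
    else:
        arr = np.asarray(source, dtype=float)
        if arr.ndim == 3:
            arr = arr[None]
    if arr.ndim != 4 or arr.shape[2:] != (4, 3):
        raise IOFormatError(f"frame array must be (t, n_bp, 4, 3), got {arr.shape}")
    if sequence is None:
        raise IOFormatError("a sequence is required alongside a frame array")
    if len(sequence) != arr.shape[1]:
        raise IOFormatError(
            f"sequence length {len(sequence)} does not match n_bp {arr.shape[1]}")

    repaired = 0
    for t in range(arr.shape[0]):
        for i in range(arr.shape[1]):
            triad = arr[t, i, 1:]
            if triad_is_valid(triad, tol=1e-6):
                continue
            if triad_is_valid(triad, tol=1e-3):
                arr[t, i, 1:] = orthonormalize(triad)
                repaired += 1
            else:
                raise IOFormatError(
                    f"triad at (t={t}, bp={i}) is not orthonormal within 1e-3")
    if repaired:
        logger.info("re-orthonormalized %d triads (drift between 1e-6 and 1e-3)",
                    repaired)
    return NucleicStructure(sequence, arr, circular=circular)


# -- PDB ----------------------------------------------------------------------

def _atomic_to_biopython(models: list, structure_id: str = "dna"):
    from Bio.PDB.StructureBuilder import StructureBuilder

    builder = StructureBuilder()
    builder.init_structure(structure_id)
    for m, atomic in enumerate(models):
        builder.init_model(m)
        seen_chains = []
        for chain_id in ("A", "B"):
            if chain_id not in atomic.chain_ids:
                continue
            builder.init_chain(chain_id)
            builder.init_seg("    ")
            seen_chains.append(chain_id)
            for res_i, resname, sel in atomic.chain_residues(chain_id):
                builder.init_residue(resname, " ", res_i + 1, " ")
                for k in sel:
                    coord = atomic.coordinates[k] / NM_PER_ANGSTROM
                    builder.init_atom(
                        atomic.atom_names[k], coord.astype(float), 0.0, 1.0,
                        " ", atomic.atom_names[k], element=atomic.elements[k])
    return builder.get_structure()


def write_pdb(structure_or_models, path, templates: TemplateLibrary | None = None) -> None:
    """Write a structure (all time frames -> models) or AtomicModel list as PDB."""
    from Bio.PDB import PDBIO

    if isinstance(structure_or_models, NucleicStructure):
        from .structure import to_atomic
        models = [to_atomic(structure_or_models, templates=templates, frame_index=t)
                  for t in range(structure_or_models.n_time_frames)]
    elif isinstance(structure_or_models, AtomicModel):
        models = [structure_or_models]
    else:
        models = list(structure_or_models)
    bio = _atomic_to_biopython(models)
    io = PDBIO()
    io.set_structure(bio)
    io.save(str(path))


def _biopython_to_atomic(model, chain_map: dict) -> AtomicModel:
    names, elements, resnames, residx, chains, coords = [], [], [], [], [], []
    for orig_id, new_id in chain_map.items():
        chain = model[orig_id]
        residues = [r for r in chain if r.id[0] == " "]
        for j, res in enumerate(residues):
            for atom in res:
                names.append(atom.get_name())
                elements.append(atom.element or atom.get_name()[0])
                resnames.append(res.get_resname().strip())
                residx.append(j)
                chains.append(new_id)
                coords.append(atom.get_coord() * NM_PER_ANGSTROM)
    return AtomicModel(names, elements, resnames, np.array(residx), chains,
                       np.array(coords, dtype=float))


def load_structure_file(path, chains=None,
                        templates: TemplateLibrary | None = None) -> NucleicStructure:
    """Load a (multi-model) PDB file into a structure.

    Base frames are fitted per residue by ring-atom superposition; the two
    strands are paired by index complementarity (chain A residue i with
    chain B residue n_bp-1-i).  ``chains`` selects the (sense, antisense)
    chain IDs when the file contains more than one duplex.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        bio = parser.get_structure("dna", str(path))

    models = list(bio)
    if not models:
        raise IOFormatError(f"no models in {path}")

    nucleic_chains = []
    for chain in models[0]:
        resnames = {r.get_resname().strip() for r in chain if r.id[0] == " "}
        if resnames and resnames <= set(RESIDUE_CODES):
            nucleic_chains.append(chain.id)
    if chains is not None:
        chain_pair = list(chains)
    elif len(nucleic_chains) == 2:
        chain_pair = nucleic_chains
    elif len(nucleic_chains) < 2:
        raise IOFormatError(f"no nucleic duplex found in {path}")
    else:
        raise IOFormatError(
            f"multiple nucleic chains {nucleic_chains} in {path}; "
            "specify the (sense, antisense) chain IDs")
    chain_map = {chain_pair[0]: "A", chain_pair[1]: "B"}

    pair_grids, watson_all, crick_all = [], [], []
    sequence = None
    for model in models:
        atomic = _biopython_to_atomic(model, chain_map)
        watson, crick, seq = fit_base_frames(atomic, templates=templates)
        if sequence is None:
            sequence = seq
        elif seq != sequence:
            raise IOFormatError("sequence differs between models")
        n = len(watson)
        pair = np.empty((n, 4, 3))
        for i in range(n):
            pair[i], _ = _pair_frame_and_intra(watson[i], crick[i])
        pair_grids.append(pair)
        watson_all.append(watson)
        crick_all.append(crick)

    frames = np.array(pair_grids)
    structure = NucleicStructure(sequence, frames)
    structure.watson_frames = np.array(watson_all)
    structure.crick_frames = np.array(crick_all)
    logger.info("loaded %d bp, %d time frame(s) from %s (circular=%s)",
                structure.n_bp, structure.n_time_frames, path, structure.circular)
    return structure


# -- parameter / trace CSV -----------------------------------------------------

def write_parameters_csv(structure: NucleicStructure, path) -> None:
    params = compute_rigid_parameters(structure)
    params.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def write_trace_csv(result, path) -> None:
    """Minimization traces as CSV (sweep, energy[, writhe])."""
    data = {"sweep": np.arange(1, len(result.energy_trace) + 1),
            "energy_kT": result.energy_trace}
    if result.writhe_trace is not None:
        data["writhe"] = result.writhe_trace
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


# -- deterministic fixtures ----------------------------------------------------

def make_fixture(kind: str, n_bp: int, seed: int, outdir) -> dict:
    """Emit a deterministic test fixture: PDB + frame-array + parameter CSV.

    Kinds: ``linear``, ``circle``, ``supercoiled`` (circle with dLk=3), and
    ``noisy-trajectory`` (5 time frames of a linear duplex with seeded
    Gaussian frame noise, sigma = 0.01 nm / 1 degree).
    """
    os.makedirs(outdir, exist_ok=True)
    if kind == "linear":
        structure = make(n_bp=n_bp, sequence_seed=seed)
    elif kind == "circle":
        structure = make(n_bp=n_bp, circular=True, sequence_seed=seed)
    elif kind == "supercoiled":
        structure = make(n_bp=n_bp, circular=True, dLk=3, sequence_seed=seed)
    elif kind == "noisy-trajectory":
        structure = make(n_bp=n_bp, sequence_seed=seed)
        rng = np.random.default_rng(seed)
        t_frames = 5
        grids = np.repeat(structure.frames, t_frames, axis=0)
        from .geometry import rotvec_to_matrix
        for t in range(t_frames):
            for i in range(n_bp):
                grids[t, i, 0] += rng.normal(0.0, 0.01, size=3)
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                ang = np.radians(rng.normal(0.0, 1.0))
                grids[t, i, 1:] = grids[t, i, 1:] @ rotvec_to_matrix(v * ang).T
        structure = NucleicStructure(structure.sequence, grids, circular=False)
    else:
        raise IOFormatError(f"unknown fixture kind {kind!r}")

    paths = {
        "pdb": os.path.join(outdir, f"{kind}_{n_bp}.pdb"),
        "frames": os.path.join(outdir, f"{kind}_{n_bp}.frames.txt"),
        "params": os.path.join(outdir, f"{kind}_{n_bp}.params.csv"),
    }
    write_pdb(structure, paths["pdb"])
    write_frames(structure, paths["frames"])
    write_parameters_csv(structure, paths["params"])
    return paths
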