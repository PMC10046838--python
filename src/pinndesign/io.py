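"""File I/O: C-alpha traces and trajectories from PDB, sequences from
FASTA, energy tables and summaries from CSV.

All structure parsing goes through biotite; tables through pandas.  PDB
residue numbering (1-based, author-assigned) is preserved in the trace
metadata while internal indexing stays 0-based.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile
from biotite.sequence.io.fasta import FastaFile

from .geometry import CaTrace, InvalidInputError
from .trajectory import TrajectoryEnsemble, TrajectorySummary

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def _ca_mask(atoms) -> np.ndarray:
    return (atoms.atom_name == "CA") & np.isin(atoms.res_name, list(_THREE_TO_ONE))


def read_ca_trace(path, chain: str | None = None, model: int = 1) -> CaTrace:
    """Read the C-alpha trace of one chain from a PDB file."""
    structure = PDBFile.read(str(path)).get_structure(model=model)
    if chain is not None:
        structure = structure[structure.chain_id == chain]
    ca = structure[_ca_mask(structure)]
    if ca.array_length() == 0:
        raise InvalidInputError(f"no CA atoms found in {path}")
    seq = "".join(_THREE_TO_ONE[r] for r in ca.res_name)
    return CaTrace(
        sequence=seq,
        coords=np.asarray(ca.coord, dtype=float),
        id=str(path),
        residue_numbers=np.asarray(ca.res_id),
    )


def read_trajectory(path, chain: str | None = None) -> tuple[TrajectoryEnsemble, str]:
    """Read a multi-model PDB as a trajectory of C-alpha frames.

    Returns the ensemble and the (model-1) sequence.
    """
    stack = PDBFile.read(str(path)).get_structure()
    if isinstance(stack, AtomArray):  # single model
        stack = stack[None]
    if chain is not None:
        stack = stack[..., stack.chain_id == chain]
    mask = _ca_mask(stack[0])
    ca = stack[..., mask]
    seq = "".join(_THREE_TO_ONE[r] for r in ca[0].res_name)
    return TrajectoryEnsemble(frames=np.asarray(ca.coord, dtype=float), id=str(path)), seq


def _ca_atom_array(trace: CaTrace, coords: np.ndarray) -> AtomArray:
    n = len(trace)
    arr = AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.full(n, "A")
    arr.res_id = (
        trace.residue_numbers
        if trace.residue_numbers is not None
        else np.arange(1, n + 1)
    )
    arr.res_name = np.array([_ONE_TO_THREE[c] for c in trace.sequence])
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    return arr


def write_ca_trace(trace: CaTrace, path) -> None:
    """Write a trace as a single-model CA-only PDB file."""
    f = PDBFile()
    f.set_structure(_ca_atom_array(trace, trace.coords))
    f.write(str(path))


def write_trajectory(traj: TrajectoryEnsemble, sequence: str, path) -> None:
    """Write an ensemble as a multi-model CA-only PDB file."""
    trace = CaTrace(sequence=sequence, coords=traj.frames[0], id=traj.id)
    frames = [_ca_atom_array(trace, f).coord for f in traj.frames]
    template = _ca_atom_array(trace, traj.frames[0])
    stack = AtomArrayStack(len(frames), len(sequence))
    stack.coord = np.stack(frames)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    f = PDBFile()
    f.set_structure(stack)
    f.write(str(path))


# -- sequences --------------------------------------------------------------


def read_fasta(path) -> dict:
    """Read sequences from FASTA as an ordered {header: sequence} dict."""
    return dict(FastaFile.read(str(path)).items())


def write_fasta(sequences: dict, path) -> None:
    """Write {header: sequence} to FASTA."""
    f = FastaFile()
    for header, seq in sequences.items():
        f[header] = str(seq)
    f.write(str(path))


# -- tables -----------------------------------------------------------------


def read_energy_table(path, n_residues: int | None = None) -> np.ndarray:
    """Read a per-frame per-residue energy CSV into a (T, n) array.

    Expected columns: ``frame``, ``residue_index`` (0-based), ``energy``.
    """
    df = pd.read_csv(path)
    required = {"frame", "residue_index", "energy"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"energy CSV must have columns {sorted(required)}")
    wide = df.pivot(index="frame", columns="residue_index", values="energy").sort_index()
    arr = wide.to_numpy(dtype=float)
    if n_residues is not None and arr.shape[1] != n_residues:
        raise InvalidInputError(
            f"energy table has {arr.shape[1]} residues, expected {n_residues}"
        )
    if np.any(np.isnan(arr)):
        raise InvalidInputError("energy table has missing (frame, residue) entries")
    return arr


def write_energy_table(frame_energies: np.ndarray, path) -> None:
    """Write a (T, n) per-frame per-residue energy array to long CSV."""
    t, n = frame_energies.shape
    frames, residues = np.meshgrid(np.arange(t), np.arange(n), indexing="ij")
    pd.DataFrame(
        {
            "frame": frames.ravel(),
            "residue_index": residues.ravel(),
            "energy": frame_energies.ravel(),
        }
    ).to_csv(path, index=False)


def write_summary(summary: TrajectorySummary, path) -> None:
    """Write a trajectory summary (per-residue rows + aggregate header) to CSV."""
    n = len(summary.per_residue_rmsd)
    df = pd.DataFrame(
        {
            "residue_index": np.arange(n),
            "per_residue_rmsd": summary.per_residue_rmsd,
            "per_residue_energy": (
                summary.per_residue_energy
                if summary.has_energy
                else np.full(n, np.nan)
            ),
        }
    )
    df.attrs["rmsd_total"] = summary.rmsd_total
    with open(path, "w") as fh:
        fh.write(f"# rmsd_total={summary.rmsd_total!r} energy_total={summary.energy_total!r}\n")
        df.to_csv(fh, index=False)


def read_summary(path) -> TrajectorySummary:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh)
    parts = dict(p.split("=") for p in header.lstrip("# ").split())
    energy = df["per_residue_energy"].to_numpy()
    has_energy = not np.all(np.isnan(energy))
    return TrajectorySummary(
        per_residue_rmsd=df["per_residue_rmsd"].to_numpy(),
        rmsd_total=float(parts["rmsd_total"]),
        per_residue_energy=energy if has_energy else None,
        energy_total=float(parts["energy_total"]) if parts["energy_total"] != "None" else None,
    )
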