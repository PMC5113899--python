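"""PDB reading and writing for Cα traces.

Reading uses Biopython's PDB parser and extracts the Cα trace of the first
chain of the first model, honouring altloc A and rejecting insertion codes
(renumber upstream if a model uses them).  Writing emits a minimal
CA-only PDB; pseudo-centroids, when present, are written as pseudo-atoms in
a separate chain so they can be inspected alongside the trace.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .evaluate import CaTrace


def read_ca_trace(path: str | Path, model_id: str | None = None) -> CaTrace:
    """Read the Cα trace of the first chain / first model of a PDB file."""
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate rough, non-conformant models
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    model = next(structure.get_models())
    chain = next(model.get_chains())
    residue_ids: list[int] = []
    coords: list[np.ndarray] = []
    for residue in chain:
        hetflag, resseq, icode = residue.id
        if hetflag.strip():
            continue
        if icode.strip():
            raise ValueError(
                f"{path}: insertion code {icode!r} at residue {resseq}; "
                "renumber the model before use")
        if "CA" not in residue:
            continue
        atom = residue["CA"]
        if atom.is_disordered():
            atom = atom.disordered_get("A")
        residue_ids.append(resseq)
        coords.append(atom.get_coord().astype(float))
    if not coords:
        raise ValueError(f"{path}: no Cα atoms found in the first chain")
    return CaTrace(model_id or path.stem, residue_ids, np.array(coords))


def write_ca_trace(trace: CaTrace, path: str | Path,
                   with_centroids: bool = False) -> None:
    """Write a CA-only PDB file; centroids (if any) go in chain ``B``."""
    lines: list[str] = []
    serial = 1

    def atom_line(serial: int, name: str, resname: str, chain: str,
                  resseq: int, xyz: np.ndarray) -> str:
        return (f"ATOM  {serial:5d} {name:^4s}{resname:>4s} {chain}{resseq:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C")

    for resid, xyz in zip(trace.residue_ids, trace.coords):
        lines.append(atom_line(serial, "CA", "ALA", "A", resid, xyz))
        serial += 1
    lines.append("TER")
    if with_centroids:
        if trace.centroids is None:
            raise ValueError("trace has no centroids to write")
        for resid, xyz in zip(trace.residue_ids, trace.centroids):
            lines.append(atom_line(serial, "CB", "ALA", "B", resid, xyz))
            serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
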