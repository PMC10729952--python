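"""Backbone structure I/O: PDB/mmCIF reading, PDB and FASTA writing.

Parsing is delegated to gemmi. One entry is produced per polymer residue in
author order; alternate locations are resolved to the highest occupancy
(ties toward the lexicographically smallest altloc id); residues missing any
of N/CA/C/O are kept but masked. Selenomethionine (MSE) is read as
methionine; other non-standard residues become 'X'. Only the first model of
multi-model files is considered.
"""

from __future__ import annotations

import os

import gemmi
import numpy as np

from .constants import ONE_TO_THREE, THREE_TO_ONE
from .structures import BackboneStructure, DesignRecord

_BACKBONE_ATOMS = ("N", "CA", "C", "O")


def read_backbone(path: str | os.PathLike, chain: str | None = None,
                  ) -> BackboneStructure:
    """Read one chain of a PDB or mmCIF file as a :class:`BackboneStructure`.

    ``chain`` defaults to the first polymer chain. Raises ``ValueError``
    naming the available chains when the requested chain is absent, and
    ``ValueError`` with the parser diagnostic for unreadable files.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path!r}: {exc}") from exc
    structure.setup_entities()
    if len(structure) == 0:
        raise ValueError(f"no models in {path!r}")
    model = structure[0]
    names = [ch.name for ch in model]
    if chain is None:
        if not names:
            raise ValueError(f"no chains in {path!r}")
        chain = names[0]
    if chain not in names:
        raise KeyError(
            f"chain {chain!r} not found in {path!r}; available chains: "
            f"{{{', '.join(sorted(names))}}}")

    coords = {name: [] for name in _BACKBONE_ATOMS}
    mask, seq_letters, residue_ids = [], [], []
    for residue in model[chain]:
        if residue.is_water():
            continue
        info = gemmi.find_tabulated_residue(residue.name)
        is_peptide = info is not None and info.is_amino_acid()
        if not is_peptide and residue.name not in THREE_TO_ONE:
            continue  # ligands, nucleic acids
        atom_xyz: dict[str, np.ndarray] = {}
        for name in _BACKBONE_ATOMS:
            best = None
            for atom in residue:
                if atom.name != name:
                    continue
                key = (-atom.occ, atom.altloc or "")
                if best is None or key < best[0]:
                    best = (key, atom.pos)
            if best is not None:
                atom_xyz[name] = np.array(
                    [best[1].x, best[1].y, best[1].z])
        complete = all(name in atom_xyz for name in _BACKBONE_ATOMS)
        for name in _BACKBONE_ATOMS:
            coords[name].append(atom_xyz.get(name, np.full(3, np.nan)))
        mask.append(complete)
        seq_letters.append(THREE_TO_ONE.get(residue.name, "X"))
        seqid = residue.seqid
        residue_ids.append(f"{seqid.num}{(seqid.icode or '').strip()}")
    if not mask:
        raise ValueError(f"chain {chain!r} of {path!r} has no polymer residues")
    return BackboneStructure(
        coords_N=np.array(coords["N"]),
        coords_CA=np.array(coords["CA"]),
        coords_C=np.array(coords["C"]),
        coords_O=np.array(coords["O"]),
        mask=np.array(mask, dtype=bool),
        native_seq="".join(seq_letters),
        chain_id=chain,
        name=os.path.splitext(os.path.basename(path))[0],
        residue_ids=residue_ids,
    )


def write_pdb(structure: BackboneStructure, path: str | os.PathLike) -> None:
    """Write the backbone (present atoms only) as a minimal PDB file."""
    lines = []
    serial = 1
    seq = structure.native_seq or "X" * structure.length
    for i in range(structure.length):
        resname = ONE_TO_THREE.get(seq[i], "UNK")
        for name, xyz in zip(_BACKBONE_ATOMS,
                             (structure.coords_N[i], structure.coords_CA[i],
                              structure.coords_C[i], structure.coords_O[i])):
            if not np.isfinite(xyz).all():
                continue
            element = name[0]
            padded = name if len(name) == 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {padded} {resname:>3s} "
                f"{structure.chain_id[:1] or 'A'}{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")
            serial += 1
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_fasta(records: list[DesignRecord], path: str | os.PathLike,
                width: int = 60) -> None:
    """Write sampled sequences as FASTA, one entry per sample.

    Headers carry the structure id, sample index, sampling temperature and
    seed; sequences wrap at 60 columns.
    """
    if not records:
        raise ValueError("no design records to write")
    lines = []
    for record in records:
        for s_idx, seq in enumerate(record.sequences):
            lines.append(f">{record.structure_id} sample={s_idx} "
                         f"T={record.temperature:g} seed={record.seed}")
            for start in range(0, len(seq), width):
                lines.append(seq[start:start + width])
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read (header, sequence) pairs from a FASTA file."""
    entries: list[tuple[str, str]] = []
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    entries.append((header, "".join(chunks)))
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line.strip())
    if header is not None:
        entries.append((header, "".join(chunks)))
    return entries
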