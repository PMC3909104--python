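"""Multi-model PDB input/output (via biotite).

Ensembles and trajectories are written as MODEL/ENDMDL stacks, one model per
snapshot, chain IDs A.., residue numbers in human prion numbering (the acetyl
cap takes the number before the first residue, the amide cap the number after
the last). A CRYST1 record carries the cubic box side when present.
"""

from __future__ import annotations

import logging
import string
import warnings

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .builder import AtomicStructure
from .sequences import PeptideSequence

log = logging.getLogger(__name__)

CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _element_of(name: str) -> str:
    return name[0]


def _to_atom_array(s: AtomicStructure) -> bst.AtomArray:
    n = s.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(s.coords, dtype=np.float32)
    arr.atom_name = np.array([nm if nm != "CH3" else "CH3" for nm in s.atom_names])
    arr.res_name = np.asarray(s.res_names)
    arr.res_id = s.res_numbers
    arr.chain_id = np.array([CHAIN_IDS[c] for c in s.chain_index])
    arr.element = np.array([_element_of(nm) for nm in s.atom_names])
    arr.hetero = np.zeros(n, dtype=bool)
    if s.box:
        arr.box = np.eye(3, dtype=np.float32) * s.box
    return arr


def write_pdb(structures, path) -> None:
    """Write one or more AtomicStructures as a multi-model PDB file."""
    if isinstance(structures, AtomicStructure):
        structures = [structures]
    structures = list(structures)
    if not structures:
        raise ValueError("nothing to write")
    for s in structures:
        if s.n_chains > len(CHAIN_IDS):
            raise ValueError(f"more than {len(CHAIN_IDS)} chains: chain IDs exhausted")
    arrays = [_to_atom_array(s) for s in structures]
    stack = bst.stack(arrays)
    f = PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def read_pdb(path, sequences: list[PeptideSequence] | None = None) -> list[AtomicStructure]:
    """Read a multi-model PDB into a list of AtomicStructures.

    Without an explicit ``sequences`` hint the one-letter sequence and the
    numbering offset are reconstructed from the residue records. Structures
    read this way carry no covalent template (``topology is None``); the
    measurement layer works on them, the energy model does not.
    """
    try:
        f = PDBFile.read(str(path))
        n_models = f.get_model_count()
    except Exception as exc:
        _report_malformed(path, exc)
        raise
    if n_models == 0:
        warnings.warn(f"{path}: empty PDB file, no models read")
        return []
    out = []
    for m in range(1, n_models + 1):
        arr = f.get_structure(model=m)
        arr = arr[~arr.hetero]
        if arr.array_length() == 0:
            raise ValueError(f"{path}: no peptide atoms (HETATM-only content)")
        out.append(_from_atom_array(arr, sequences))
    return out


THREE_TO_ONE = {
    "ALA": "A", "GLY": "G", "LEU": "L", "LYS": "K", "HIS": "H",
    "VAL": "V", "THR": "T", "ASN": "N", "CYS": "C", "ASP": "D",
    "GLU": "E", "PHE": "F", "ILE": "I", "MET": "M", "PRO": "P",
    "GLN": "Q", "ARG": "R", "SER": "S", "TRP": "W", "TYR": "Y",
}


def _from_atom_array(arr: bst.AtomArray, sequences) -> AtomicStructure:
    chain_labels = []
    for cid in arr.chain_id:
        if cid not in chain_labels:
            chain_labels.append(cid)
    chain_index = np.array([chain_labels.index(c) for c in arr.chain_id])
    seqs = []
    res_slots = np.zeros(arr.array_length(), dtype=np.int64)
    for c, cid in enumerate(chain_labels):
        m = chain_index == c
        rids = arr.res_id[m]
        rnames = arr.res_name[m]
        first = int(rids.min())
        # cap-aware: ACE occupies the first number, NH2 the last
        letters = []
        offset = first
        for rid in np.unique(rids):
            name = str(rnames[rids == rid][0])
            if name == "ACE":
                offset = rid + 1
                continue
            if name == "NH2":
                continue
            letters.append(THREE_TO_ONE.get(name, "X"))
        if sequences is not None:
            seq = sequences[c] if len(sequences) > 1 else sequences[0]
        else:
            seq = PeptideSequence("".join(letters), numbering_offset=int(offset))
        seqs.append(seq)
        res_slots[m] = rids - seq.numbering_offset + 1
    box = None
    if arr.box is not None:
        side = float(arr.box[0, 0])
        if side > 0:
            box = side
    return AtomicStructure(
        coords=np.asarray(arr.coord, dtype=float),
        atom_names=np.asarray(arr.atom_name),
        res_slots=res_slots,
        res_names=np.asarray(arr.res_name),
        chain_index=chain_index,
        sequences=seqs,
        box=box,
        topology=None,
    )


def _report_malformed(path, exc) -> None:
    """Best-effort line diagnosis for malformed ATOM records."""
    try:
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38])
                        float(line[38:46])
                        float(line[46:54])
                    except ValueError:
                        log.error("%s: malformed ATOM record at line %d", path, ln)
                        raise ValueError(
                            f"{path}: malformed ATOM record at line {ln}") from exc
    except OSError:
        pass
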