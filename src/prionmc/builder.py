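"""Torsion state -> Cartesian structure conversion and the structure container.

Coordinates are Angstrom. A chain is built in a canonical local frame from
its internal coordinates and then placed by a rigid-body
:class:`Frame` (rotation + translation), so multi-chain systems are a list of
torsion states plus frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geom import build_coords, dihedral
from .sequences import PeptideSequence
from .topology import ChainTopology, Conformation, get_topology, wrap_angle


@dataclass
class Frame:
    """Rigid-body placement: x -> rotation @ x + translation."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ np.asarray(self.rotation).T + np.asarray(self.translation)

    @staticmethod
    def from_rotvec(rotvec, translation=(0.0, 0.0, 0.0)) -> "Frame":
        from scipy.spatial.transform import Rotation

        return Frame(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                     np.asarray(translation, float))

    @staticmethod
    def random(rng: np.random.Generator, box: float | None = None) -> "Frame":
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
        t = rng.uniform(0.0, box, size=3) if box else rng.normal(0.0, 10.0, size=3)
        return Frame(rot.as_matrix(), t)


@dataclass
class AtomicStructure:
    """Heavy atoms + amide hydrogens of one or more chains.

    ``res_slots`` uses template slot numbering (0 = acetyl cap, 1..n residues,
    n+1 = amide cap); ``res_numbers`` is human prion numbering per atom.
    """

    coords: np.ndarray
    atom_names: np.ndarray
    res_slots: np.ndarray
    res_names: np.ndarray
    chain_index: np.ndarray
    sequences: list[PeptideSequence]
    box: float | None = None
    topology: ChainTopology | None = None

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_chains(self) -> int:
        return len(self.sequences)

    def chain_mask(self, c: int) -> np.ndarray:
        return self.chain_index == c

    def chain_coords(self, c: int) -> np.ndarray:
        return self.coords[self.chain_index == c]

    @property
    def res_numbers(self) -> np.ndarray:
        out = np.empty(self.n_atoms, dtype=np.int64)
        for c, seq in enumerate(self.sequences):
            m = self.chain_index == c
            out[m] = seq.numbering_offset + self.res_slots[m] - 1
        return out

    def copy(self) -> "AtomicStructure":
        return AtomicStructure(
            self.coords.copy(), self.atom_names, self.res_slots, self.res_names,
            self.chain_index, list(self.sequences), self.box, self.topology,
        )

    def atom_index(self, chain: int, slot: int, name: str) -> int:
        hit = np.flatnonzero(
            (self.chain_index == chain) & (self.res_slots == slot) & (self.atom_names == name)
        )
        if hit.size != 1:
            raise KeyError(f"atom chain={chain} slot={slot} name={name}: {hit.size} matches")
        return int(hit[0])


def _res_name_array(topo: ChainTopology) -> np.ndarray:
    seq = topo.sequence
    three = {
        "A": "ALA", "G": "GLY", "L": "LEU", "K": "LYS", "H": "HIS",
        "V": "VAL", "T": "THR", "N": "ASN", "C": "CYS", "D": "ASP",
        "E": "GLU", "F": "PHE", "I": "ILE", "M": "MET", "P": "PRO",
        "Q": "GLN", "R": "ARG", "S": "SER", "W": "TRP", "Y": "TYR",
    }
    names = np.empty(topo.n_atoms, dtype="U3")
    for k in range(topo.n_atoms):
        s = topo.atom_slots[k]
        if s == 0:
            names[k] = "ACE"
        elif s == topo.n_residues + 1:
            names[k] = "NH2"
        else:
            names[k] = three[seq.residues[s - 1]]
    return names


def build_chain_coords(topo: ChainTopology, dof: np.ndarray) -> np.ndarray:
    """Canonical-frame coordinates from a dof vector (radians)."""
    out = np.empty((topo.n_atoms, 3))
    build_coords(topo.parent, topo.grand, topo.ggrand, topo.bond, topo.angle,
                 topo.torsion_values(dof), out)
    return out


def build_structure(
    seq: PeptideSequence,
    conf: Conformation,
    frame: Frame | None = None,
    box: float | None = None,
) -> AtomicStructure:
    """Deterministically realize a torsion state as Cartesian coordinates."""
    topo = get_topology(seq)
    dof = topo.conformation_to_dof(conf)
    coords = build_chain_coords(topo, dof)
    if frame is not None:
        coords = frame.apply(coords)
    return AtomicStructure(
        coords=coords,
        atom_names=topo.atom_names,
        res_slots=topo.atom_slots.astype(np.int64),
        res_names=_res_name_array(topo),
        chain_index=np.zeros(topo.n_atoms, dtype=np.int64),
        sequences=[seq],
        box=box,
        topology=topo,
    )


def assemble(
    seq: PeptideSequence,
    confs: list[Conformation],
    frames: list[Frame],
    box: float | None = None,
) -> AtomicStructure:
    """Multi-chain system: one sequence, one torsion state + frame per chain."""
    topo = get_topology(seq)
    if len(confs) != len(frames):
        raise ValueError("need one frame per conformation")
    n_local = topo.n_atoms
    n_ch = len(confs)
    coords = np.empty((n_ch * n_local, 3))
    for c, (conf, fr) in enumerate(zip(confs, frames)):
        local = build_chain_coords(topo, topo.conformation_to_dof(conf))
        coords[c * n_local:(c + 1) * n_local] = fr.apply(local)
    return AtomicStructure(
        coords=coords,
        atom_names=np.tile(topo.atom_names, n_ch),
        res_slots=np.tile(topo.atom_slots.astype(np.int64), n_ch),
        res_names=np.tile(_res_name_array(topo), n_ch),
        chain_index=np.repeat(np.arange(n_ch), n_local),
        sequences=[seq] * n_ch,
        box=box,
        topology=topo,
    )


def measure_conformation(structure: AtomicStructure, chain: int = 0) -> Conformation:
    """Recover the torsion state of one chain from coordinates.

    Inverse of :func:`build_structure` up to numerical precision. Requires a
    template-compatible structure (topology attached or rebuildable from the
    sequence).
    """
    topo = structure.topology or get_topology(structure.sequences[chain])
    idx = np.flatnonzero(structure.chain_index == chain)
    if idx.size != topo.n_atoms:
        raise ValueError("chain does not match its covalent template")
    c = structure.coords[idx]
    dof = np.zeros(topo.n_dof)
    found = np.zeros(topo.n_dof, dtype=bool)
    for k in range(topo.n_atoms):
        d = topo.atom_dof[k]
        if d < 0 or found[d] or abs(topo.tor_off[k]) > 1e-12:
            continue
        a, b, p = topo.ggrand[k], topo.grand[k], topo.parent[k]
        dof[d] = dihedral(c[a], c[b], c[p], c[k])
        found[d] = True
    if not found.all():
        raise ValueError("could not measure every torsion")
    return topo.dof_to_conformation(dof)


def measure_phi_psi(structure: AtomicStructure, chain: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Backbone phi/psi (degrees) of one chain, using atom names only.

    Works for structures read from PDB files without a template, as long as
    backbone atoms N/CA/C are present and the caps provide the terminal
    reference atoms.
    """
    m = structure.chain_index == chain
    names = structure.atom_names[m]
    slots = structure.res_slots[m]
    xyz = structure.coords[m]

    def get(slot, name):
        hit = np.flatnonzero((slots == slot) & (names == name))
        return xyz[hit[0]] if hit.size else None

    n_res = int(slots.max()) - 1
    phi = np.full(n_res, np.nan)
    psi = np.full(n_res, np.nan)
    for i in range(1, n_res + 1):
        N, CA, C = get(i, "N"), get(i, "CA"), get(i, "C")
        Cprev = get(i - 1, "C")
        Nnext = get(i + 1, "N")
        if all(x is not None for x in (Cprev, N, CA, C)):
            phi[i - 1] = np.rad2deg(dihedral(Cprev, N, CA, C))
        if all(x is not None for x in (N, CA, C, Nnext)):
            psi[i - 1] = np.rad2deg(dihedral(N, CA, C, Nnext))
    return wrap_angle(phi), wrap_angle(psi)
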