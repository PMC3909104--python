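"""Fixed covalent geometry of capped peptide chains.

The model is torsion-space: bond lengths, bond angles and the peptide bond
torsion (omega = 180 deg) are constants; the degrees of freedom are the
Ramachandran angles phi/psi of every residue plus a conventional set of
sidechain chi torsions. A :class:`ChainTopology` compiles a peptide sequence
into flat internal-coordinate arrays that the numba builder consumes, plus
all the bookkeeping the energy model and the analysis layer need (hydrogen
bond donors/acceptors, excluded-volume radii, bond-separation table,
backbone-dipole pair lists, hydrophobic sidechain groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .sequences import PeptideSequence

# --- covalent constants (Angstrom / degrees) ---------------------------------
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
B_N_H = 1.000
B_CA_CB = 1.530

A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.8
A_C_N_H = 119.5
A_N_CA_CB = 110.5

OMEGA = 180.0
#: Offset of the CB torsion relative to phi about the N-CA axis; the sign
#: selects L-chirality (the improper dihedral N-C-CA-CB comes out at +122.8
#: deg, the canonical value for L-amino acids).
DELTA_CB = -122.6

#: Excluded-volume radii per element (Angstrom). The amide hydrogen radius is
#: kept small so that excluded volume does not punish proper N-H...O=C
#: hydrogen-bond geometry (H...O around 2.0-2.2 A).
ELEMENT_SIGMA = {"C": 1.75, "N": 1.53, "O": 1.42, "H": 0.75}

#: Backbone partial charges for the local-electrostatics term (units of e).
Q_C, Q_O, Q_N, Q_H = 0.42, -0.42, -0.20, 0.20

#: Number of rotatable chi torsions per residue type (standard convention;
#: only types occurring in the prion fragments are listed).
CHI_COUNT = {"A": 0, "G": 0, "L": 2, "K": 4, "H": 2, "V": 1, "T": 1, "N": 2}

#: Modal rotamer values (degrees) used as fixture / starting chi angles;
#: all-trans sidechains produce syn-pentane-like clashes for L/H/T.
DEFAULT_CHI = {
    "L": [-65.0, 175.0],
    "K": [-67.0, 180.0, 180.0, 180.0],
    "H": [-63.0, -74.0],
    "V": [175.0],
    "T": [-60.0],
    "N": [-65.0, -20.0],
}

# Sidechain internal coordinates: (name, parent, grand, ggrand, bond, angle, tor)
# where tor is ("chi", local_chi_index, offset_deg) or ("fixed", deg).
# References are atom names in the same residue ("-C" = previous slot's C).
_SIDECHAINS: dict[str, list] = {
    "A": [],
    "G": [],
    "V": [
        ("CG1", "CB", "CA", "N", 1.521, 110.5, ("chi", 0, 0.0)),
        ("CG2", "CB", "CA", "N", 1.521, 110.5, ("chi", 0, 122.0)),
    ],
    "L": [
        ("CG", "CB", "CA", "N", 1.530, 116.3, ("chi", 0, 0.0)),
        ("CD1", "CG", "CB", "CA", 1.521, 110.7, ("chi", 1, 0.0)),
        ("CD2", "CG", "CB", "CA", 1.521, 110.7, ("chi", 1, 122.0)),
    ],
    "K": [
        ("CG", "CB", "CA", "N", 1.520, 114.1, ("chi", 0, 0.0)),
        ("CD", "CG", "CB", "CA", 1.520, 111.3, ("chi", 1, 0.0)),
        ("CE", "CD", "CG", "CB", 1.520, 111.3, ("chi", 2, 0.0)),
        ("NZ", "CE", "CD", "CG", 1.489, 111.9, ("chi", 3, 0.0)),
    ],
    "H": [
        ("CG", "CB", "CA", "N", 1.497, 113.8, ("chi", 0, 0.0)),
        ("ND1", "CG", "CB", "CA", 1.378, 122.7, ("chi", 1, 0.0)),
        ("CD2", "CG", "CB", "CA", 1.356, 131.1, ("chi", 1, 180.0)),
        ("CE1", "ND1", "CG", "CB", 1.321, 109.3, ("fixed", 180.0)),
        ("NE2", "CD2", "CG", "CB", 1.374, 107.2, ("fixed", 180.0)),
    ],
    "T": [
        ("OG1", "CB", "CA", "N", 1.433, 109.6, ("chi", 0, 0.0)),
        ("CG2", "CB", "CA", "N", 1.521, 110.5, ("chi", 0, -120.0)),
    ],
    "N": [
        ("CG", "CB", "CA", "N", 1.516, 112.6, ("chi", 0, 0.0)),
        ("OD1", "CG", "CB", "CA", 1.231, 120.8, ("chi", 1, 0.0)),
        ("ND2", "CG", "CB", "CA", 1.328, 116.4, ("chi", 1, 180.0)),
    ],
}

#: Hydrophobic / charged sidechain groups for the contact potential:
#: residue type -> (category, atom names). Categories: 0 = aliphatic,
#: 1 = positively charged (Lys ammonium), 2 = His ring.
SC_GROUPS = {
    "A": (0, ["CB"]),
    "V": (0, ["CB", "CG1", "CG2"]),
    "L": (0, ["CB", "CG", "CD1", "CD2"]),
    "T": (0, ["CG2"]),
    "K": (1, ["CE", "NZ"]),
    "H": (2, ["CG", "ND1", "CD2", "CE1", "NE2"]),
}

TOR_FIXED, TOR_PHI, TOR_PSI, TOR_CHI = 0, 1, 2, 3


@dataclass
class Conformation:
    """Torsional state of one chain (degrees): phi/psi per residue and the
    flattened chi list in residue order."""

    phi: np.ndarray
    psi: np.ndarray
    chi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.chi = np.asarray(self.chi, dtype=float)
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi must have equal length")

    def copy(self) -> "Conformation":
        return Conformation(self.phi.copy(), self.psi.copy(), self.chi.copy())


def wrap_angle(a):
    """Wrap degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -((-a + 180.0) % 360.0 - 180.0)
    return w


class ChainTopology:
    """Compiled covalent template of one capped chain.

    Atom slots: slot 0 is the acetyl cap (CH3, C, O), slots 1..n the residues
    (N, H, CA, C, O, sidechain...), slot n+1 the C-terminal amide (N, H1, H2).
    """

    def __init__(self, sequence: PeptideSequence):
        self.sequence = sequence
        n = len(sequence)
        self.n_residues = n

        names: list[str] = []
        slots: list[int] = []
        parent: list[int] = []
        grand: list[int] = []
        ggrand: list[int] = []
        bond: list[float] = []
        angle: list[float] = []
        tor_kind: list[int] = []
        tor_res: list[int] = []  # 0-based residue index for phi/psi, chi dof idx for chi
        tor_off: list[float] = []

        index: dict[tuple[int, str], int] = {}

        def add(slot, name, p, g, gg, b, a, kind, tres, toff):
            k = len(names)
            names.append(name)
            slots.append(slot)
            parent.append(p)
            grand.append(g)
            ggrand.append(gg)
            bond.append(b)
            angle.append(np.deg2rad(a))
            tor_kind.append(kind)
            tor_res.append(tres)
            tor_off.append(np.deg2rad(toff))
            index[(slot, name)] = k
            return k

        # acetyl cap (seed frame)
        add(0, "CH3", -1, -1, -1, 0.0, 0.0, TOR_FIXED, 0, 0.0)
        add(0, "C", index[(0, "CH3")], -1, -1, 1.520, 0.0, TOR_FIXED, 0, 0.0)
        add(0, "O", index[(0, "C")], index[(0, "CH3")], -1, B_C_O, 121.0, TOR_FIXED, 0, 0.0)

        # chi dof layout
        self.chi_counts = [CHI_COUNT[r] for r in sequence.residues]
        chi_base = np.concatenate([[0], np.cumsum(self.chi_counts)])[:-1]
        self.n_chi = int(sum(self.chi_counts))

        for i, res in enumerate(sequence.residues, start=1):
            prev = i - 1
            pC = index[(prev, "C")]
            if prev == 0:
                pCA = index[(0, "CH3")]  # cap methyl plays the CA role
                pN = index[(0, "O")]
            else:
                pCA = index[(prev, "CA")]
                pN = index[(prev, "N")]
            # N from psi of previous residue; residue 1 from the cap plane
            if prev == 0:
                iN = add(i, "N", pC, index[(0, "O")], index[(0, "CH3")],
                         B_C_N, 122.7, TOR_FIXED, 0, 180.0)
            else:
                iN = add(i, "N", pC, pCA, pN, B_C_N, A_CA_C_N, TOR_PSI, prev - 1, 0.0)
            iH = add(i, "H", iN, pC, pCA, B_N_H, A_C_N_H, TOR_FIXED, 0, 0.0)
            iCA = add(i, "CA", iN, pC, pCA, B_N_CA, A_C_N_CA, TOR_FIXED, 0, OMEGA)
            iC = add(i, "C", iCA, iN, pC, B_CA_C, A_N_CA_C, TOR_PHI, i - 1, 0.0)
            add(i, "O", iC, iCA, iN, B_C_O, A_CA_C_O, TOR_PSI, i - 1, 180.0)
            if res != "G":
                add(i, "CB", iCA, iN, pC, B_CA_CB, A_N_CA_CB, TOR_PHI, i - 1, DELTA_CB)
            for (nm, p, g, gg, b, a, tor) in _SIDECHAINS[res]:
                pi = index[(i, p)]
                gi = index[(i, g)]
                ggi = index[(i, gg)]
                if tor[0] == "chi":
                    add(i, nm, pi, gi, ggi, b, a, TOR_CHI,
                        int(chi_base[i - 1] + tor[1]), tor[2])
                else:
                    add(i, nm, pi, gi, ggi, b, a, TOR_FIXED, 0, tor[1])

        # C-terminal amide cap
        last = n
        iNt = add(last + 1, "N", index[(last, "C")], index[(last, "CA")],
                  index[(last, "N")], B_C_N, A_CA_C_N, TOR_PSI, last - 1, 0.0)
        add(last + 1, "H1", iNt, index[(last, "C")], index[(last, "CA")],
            B_N_H, A_C_N_H, TOR_FIXED, 0, 0.0)
        add(last + 1, "H2", iNt, index[(last, "C")], index[(last, "CA")],
            B_N_H, A_C_N_H, TOR_FIXED, 0, 180.0)

        self.atom_names = np.array(names)
        self.atom_slots = np.array(slots, dtype=np.int32)
        self.n_atoms = len(names)
        self._index = index
        self.parent = np.array(parent, dtype=np.int32)
        self.grand = np.array(grand, dtype=np.int32)
        self.ggrand = np.array(ggrand, dtype=np.int32)
        self.bond = np.array(bond, dtype=np.float64)
        self.angle = np.array(angle, dtype=np.float64)
        self.tor_kind = np.array(tor_kind, dtype=np.int32)
        self.tor_res = np.array(tor_res, dtype=np.int32)
        self.tor_off = np.array(tor_off, dtype=np.float64)

        self.elements = np.array([nm[0] for nm in names])
        self.sigma = np.array([ELEMENT_SIGMA[e] for e in self.elements])

        # degrees of freedom: phi_0..phi_{n-1}, psi_0.., chi flattened
        self.n_dof = 2 * n + self.n_chi
        self._compile_dof()
        self._compile_bondsep()
        self._compile_hbond_sites()
        self._compile_local_pairs()
        self._compile_sc_groups()
        self.backbone_idx = np.array(
            [index[(i, nm)] for i in range(1, n + 1) for nm in ("N", "CA", "C", "O")],
            dtype=np.int32,
        )

    # -- helpers -------------------------------------------------------------
    def atom(self, slot: int, name: str) -> int:
        return self._index[(slot, name)]

    def dof_phi(self, i0: int) -> int:
        return i0

    def dof_psi(self, i0: int) -> int:
        return self.n_residues + i0

    def _compile_dof(self):
        n = self.n_residues
        kind = self.tor_kind
        # dof index per atom (-1 fixed)
        dof = np.full(self.n_atoms, -1, dtype=np.int32)
        dof[kind == TOR_PHI] = self.tor_res[kind == TOR_PHI]
        dof[kind == TOR_PSI] = n + self.tor_res[kind == TOR_PSI]
        dof[kind == TOR_CHI] = 2 * n + self.tor_res[kind == TOR_CHI]
        self.atom_dof = dof
        # transitive dependency: which atoms move when a dof changes
        deps: list[set[int]] = []
        aff = np.zeros((self.n_dof, self.n_atoms), dtype=bool)
        for k in range(self.n_atoms):
            s: set[int] = set()
            for r in (self.parent[k], self.grand[k], self.ggrand[k]):
                if r >= 0:
                    s |= deps[r]
            if dof[k] >= 0:
                s.add(int(dof[k]))
            deps.append(s)
            for d in s:
                aff[d, k] = True
        self.affected = aff

    def _compile_bondsep(self):
        # bond graph over atoms of one chain
        nbrs: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for k in range(1, self.n_atoms):
            p = self.parent[k]
            if p >= 0:
                nbrs[k].append(p)
                nbrs[p].append(k)
        # close the His ring (CE1-NE2 bond is not in the tree)
        for i in range(1, self.n_residues + 1):
            if self.sequence.residues[i - 1] == "H":
                a = self.atom(i, "CE1")
                b = self.atom(i, "NE2")
                nbrs[a].append(b)
                nbrs[b].append(a)
        sep = np.full((self.n_atoms, self.n_atoms), 255, dtype=np.uint8)
        for s in range(self.n_atoms):
            sep[s, s] = 0
            frontier = [s]
            for d in (1, 2, 3):
                nxt = []
                for u in frontier:
                    for v in nbrs[u]:
                        if sep[s, v] == 255:
                            sep[s, v] = d
                            nxt.append(v)
                frontier = nxt
        self.bondsep = sep

    def _compile_hbond_sites(self):
        """Backbone amide donors (N,H) and carbonyl acceptors (C,O), caps included."""
        dn, dh, dres = [], [], []
        for i in range(1, self.n_residues + 1):
            dn.append(self.atom(i, "N"))
            dh.append(self.atom(i, "H"))
            dres.append(i)
        t = self.n_residues + 1
        for h in ("H1", "H2"):
            dn.append(self.atom(t, "N"))
            dh.append(self.atom(t, h))
            dres.append(t)
        ac, ao, ares = [], [], []
        for i in range(0, self.n_residues + 1):
            ac.append(self.atom(i, "C"))
            ao.append(self.atom(i, "O"))
            ares.append(i)
        self.don_n = np.array(dn, dtype=np.int32)
        self.don_h = np.array(dh, dtype=np.int32)
        self.don_res = np.array(dres, dtype=np.int32)
        self.acc_c = np.array(ac, dtype=np.int32)
        self.acc_o = np.array(ao, dtype=np.int32)
        self.acc_res = np.array(ares, dtype=np.int32)

    def _compile_local_pairs(self):
        """Adjacent backbone peptide-unit charge pairs for the local term.

        Unit j (j = 0..n) carries C_j, O_j and N_{j+1}, H_{j+1}(,H2); the
        dipole-dipole interaction of units j and j+1 depends on phi/psi of
        residue j+1 and encodes the intrinsic torsion preference.
        """
        n = self.n_residues
        units = []
        for j in range(0, n + 1):
            atoms = [(self.atom(j, "C"), Q_C), (self.atom(j, "O"), Q_O)]
            if j + 1 <= n:
                atoms += [(self.atom(j + 1, "N"), Q_N), (self.atom(j + 1, "H"), Q_H)]
            else:
                atoms += [
                    (self.atom(n + 1, "N"), 2 * Q_N),
                    (self.atom(n + 1, "H1"), Q_H),
                    (self.atom(n + 1, "H2"), Q_H),
                ]
            units.append(atoms)
        pi, pj, qq = [], [], []
        for j in range(len(units) - 1):
            for (a, qa) in units[j]:
                for (b, qb) in units[j + 1]:
                    if a == b:
                        continue
                    pi.append(a)
                    pj.append(b)
                    qq.append(qa * qb)
        self.loc_i = np.array(pi, dtype=np.int32)
        self.loc_j = np.array(pj, dtype=np.int32)
        self.loc_qq = np.array(qq, dtype=np.float64)

    def _compile_sc_groups(self):
        starts, lens, cats, res = [], [], [], []
        flat: list[int] = []
        for i, r in enumerate(self.sequence.residues, start=1):
            if r not in SC_GROUPS:
                continue
            cat, atoms = SC_GROUPS[r]
            starts.append(len(flat))
            lens.append(len(atoms))
            cats.append(cat)
            res.append(i)
            flat.extend(self.atom(i, nm) for nm in atoms)
        self.sc_atom = np.array(flat, dtype=np.int32)
        self.sc_start = np.array(starts, dtype=np.int32)
        self.sc_len = np.array(lens, dtype=np.int32)
        self.sc_cat = np.array(cats, dtype=np.int32)
        self.sc_res = np.array(res, dtype=np.int32)

    # -- dof vector <-> Conformation ------------------------------------------
    def conformation_to_dof(self, conf: Conformation) -> np.ndarray:
        n = self.n_residues
        if conf.phi.shape[0] != n:
            raise ValueError(f"conformation has {conf.phi.shape[0]} residues, template {n}")
        if conf.chi.shape[0] != self.n_chi:
            raise ValueError(f"chi count mismatch: got {conf.chi.shape[0]}, template {self.n_chi}")
        return np.deg2rad(np.concatenate([conf.phi, conf.psi, conf.chi]))

    def dof_to_conformation(self, dof: np.ndarray) -> Conformation:
        n = self.n_residues
        deg = wrap_angle(np.rad2deg(dof))
        return Conformation(deg[:n], deg[n:2 * n], deg[2 * n:])

    def torsion_values(self, dof: np.ndarray) -> np.ndarray:
        """Resolve the per-atom torsion array (radians) for the builder."""
        tor = self.tor_off.copy()
        has = self.atom_dof >= 0
        tor[has] += dof[self.atom_dof[has]]
        return tor

    def default_chi(self) -> np.ndarray:
        """Modal rotamer chi angles for the whole chain (degrees)."""
        vals: list[float] = []
        for r in self.sequence.residues:
            vals.extend(DEFAULT_CHI.get(r, []))
        return np.array(vals, dtype=float)

    def default_conformation(self) -> Conformation:
        """Extended chain with modal-rotamer sidechains."""
        n = self.n_residues
        return Conformation(np.full(n, 180.0), np.full(n, 180.0), self.default_chi())


@lru_cache(maxsize=32)
def _topology_cached(residues: str, offset: int, label: str) -> ChainTopology:
    return ChainTopology(PeptideSequence(residues, label=label, numbering_offset=offset))


def get_topology(sequence: PeptideSequence) -> ChainTopology:
    """Topology for a sequence (cached: compiling the template is not free)."""
    return _topology_cached(sequence.residues, sequence.numbering_offset, sequence.label)
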