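"""Per-residue secondary structure, hydrogen-bond census, beta-turn typing
and beta-hairpin detection.

Geometric hydrogen bonds follow the classic donor-hydrogen criterion:
H...O distance at most 2.4 A and N-H...O no more than 35 deg from linear.
Secondary structure is assigned from backbone torsions with rectangular
Ramachandran windows (helix: phi in [-90,-30], psi in [-77,-17]; strand:
phi in [-150,-90], psi in [90,150]), which keeps the assignment defined for
torsion-space snapshots without any Cartesian heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .builder import AtomicStructure, measure_phi_psi
from .sequences import PeptideSequence
from .topology import Conformation, wrap_angle

HELIX_PHI = (-90.0, -30.0)
HELIX_PSI = (-77.0, -17.0)
STRAND_PHI = (-150.0, -90.0)
STRAND_PSI = (90.0, 150.0)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric gate for a hydrogen bond.

    ``distance_atom`` selects whether ``d_max`` applies to the H...O distance
    (the classic reading, default) or to N...O.
    """

    d_max: float = 2.4
    angle_max: float = 35.0
    distance_atom: str = "H"

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.angle_max < 90:
            raise ValueError("angle_max must be in (0, 90)")
        if self.distance_atom not in ("H", "N"):
            raise ValueError("distance_atom must be 'H' or 'N'")


@dataclass(frozen=True)
class HBondRecord:
    donor_chain: int
    donor_res: int       # human numbering
    acceptor_chain: int
    acceptor_res: int    # human numbering
    distance: float
    angle: float

    @property
    def intra_chain(self) -> bool:
        return self.donor_chain == self.acceptor_chain


@dataclass
class SSLabels:
    """Per-residue H/E/C labels of one chain plus the derived fractions."""

    labels: np.ndarray
    residue_numbers: np.ndarray

    @property
    def helix_fraction(self) -> float:
        return float(np.mean(self.labels == "H"))

    @property
    def sheet_fraction(self) -> float:
        return float(np.mean(self.labels == "E"))


@dataclass(frozen=True)
class TurnRecord:
    span: tuple[int, int]    # residue-number span of the turn residues
    turn_type: str           # I, I', II, II', VIII, alpha, irregular
    anchor: HBondRecord | None = None


@dataclass(frozen=True)
class HairpinRecord:
    chain: int
    order: int                           # 1 single, 2 double, 3 triple
    turn_spans: tuple[tuple[int, int], ...]  # human numbering, inclusive
    strand_registers: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    n_cross_bonds: int

    @property
    def order_name(self) -> str:
        return {1: "single", 2: "double", 3: "triple"}.get(self.order, str(self.order))


def ss_label_from_phi_psi(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Vectorized window assignment; NaN torsions label as coil."""
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    lab = np.full(phi.shape, "C", dtype="U1")
    h = ((phi >= HELIX_PHI[0]) & (phi <= HELIX_PHI[1])
         & (psi >= HELIX_PSI[0]) & (psi <= HELIX_PSI[1]))
    e = ((phi >= STRAND_PHI[0]) & (phi <= STRAND_PHI[1])
         & (psi >= STRAND_PSI[0]) & (psi <= STRAND_PSI[1]))
    lab[h] = "H"
    lab[e] = "E"
    return lab


def assign_secondary_structure(obj, sequence: PeptideSequence | None = None,
                               chain: int = 0) -> SSLabels:
    """H/E/C labels for one chain of a structure, or for a Conformation."""
    if isinstance(obj, Conformation):
        if sequence is None:
            raise ValueError("a Conformation needs its PeptideSequence")
        phi, psi = obj.phi, obj.psi
        nums = np.asarray(sequence.residue_numbers)
    else:
        phi, psi = measure_phi_psi(obj, chain=chain)
        nums = np.asarray(obj.sequences[chain].residue_numbers)
    return SSLabels(ss_label_from_phi_psi(phi, psi), nums)


def _hb_sites(structure: AtomicStructure):
    """Donor (N,H) and acceptor (C,O) atom indices with chain/slot tags."""
    names = structure.atom_names
    slots = structure.res_slots
    chains = structure.chain_index
    don, acc = [], []
    for c in range(structure.n_chains):
        m = np.flatnonzero(chains == c)
        key = {}
        for k in m:
            key[(int(slots[k]), str(names[k]))] = int(k)
        max_slot = int(slots[m].max())
        for s in range(0, max_slot + 1):
            if (s, "N") in key:
                for h in ("H", "H1", "H2"):
                    if (s, h) in key:
                        don.append((c, s, key[(s, "N")], key[(s, h)]))
            if (s, "C") in key and (s, "O") in key:
                acc.append((c, s, key[(s, "C")], key[(s, "O")]))
    return don, acc


def detect_hbonds(structure: AtomicStructure,
                  criteria: HBondCriteria = HBondCriteria()) -> list[HBondRecord]:
    """Geometric backbone hydrogen-bond census.

    Pairs within the same or adjacent residue slot of one chain are excluded;
    inter-chain pairs use the minimum-image convention when the structure
    carries a periodic box.
    """
    don, acc = _hb_sites(structure)
    if not don or not acc:
        return []
    xyz = structure.coords
    box = structure.box or 0.0
    dN = np.array([d[2] for d in don])
    dH = np.array([d[3] for d in don])
    dC = np.array([d[0] for d in don])
    dS = np.array([d[1] for d in don])
    aC = np.array([a[2] for a in acc])
    aO = np.array([a[3] for a in acc])
    aCh = np.array([a[0] for a in acc])
    aS = np.array([a[1] for a in acc])

    # O - H displacement with minimum image across chains
    v = xyz[aO][None, :, :] - xyz[dH][:, None, :]
    same = dC[:, None] == aCh[None, :]
    if box > 0.0:
        shift = box * np.rint(v / box)
        shift[same] = 0.0
        v = v - shift
    else:
        shift = np.zeros_like(v)
    dist = np.linalg.norm(v, axis=-1)
    measure = dist
    if criteria.distance_atom == "N":
        vn = xyz[aO][None, :, :] - shift - xyz[dN][:, None, :]
        measure = np.linalg.norm(vn, axis=-1)

    u = (xyz[dH] - xyz[dN])[:, None, :]
    cosa = np.sum(u * v, axis=-1) / (np.linalg.norm(u, axis=-1) * np.maximum(dist, 1e-12))
    ang = np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0)))

    ok = (measure <= criteria.d_max) & (ang <= criteria.angle_max)
    ok &= ~(same & (np.abs(dS[:, None] - aS[None, :]) < 2))

    out = []
    seen = set()
    for i, j in zip(*np.nonzero(ok)):
        c_d, s_d = int(dC[i]), int(dS[i])
        c_a, s_a = int(aCh[j]), int(aS[j])
        rd = structure.sequences[c_d].numbering_offset + s_d - 1
        ra = structure.sequences[c_a].numbering_offset + s_a - 1
        key = (c_d, s_d, c_a, s_a)
        if key in seen:  # NH2 cap offers two hydrogens; report the bond once
            continue
        seen.add(key)
        out.append(HBondRecord(c_d, rd, c_a, ra, float(dist[i, j]), float(ang[i, j])))
    return out


def per_residue_frequency(labelled: list[tuple[SSLabels, int]]) -> dict[str, pd.DataFrame]:
    """H/E/C frequency tables (residue number x temperature rung).

    ``labelled`` pairs each chain's labels with its temperature rung. Rungs
    with no snapshots are simply absent from the columns.
    """
    rows = []
    for lab, rung in labelled:
        for num, l in zip(lab.residue_numbers, lab.labels):
            rows.append((int(num), int(rung), l))
    df = pd.DataFrame(rows, columns=["residue", "rung", "label"])
    out = {}
    for state in "HEC":
        tab = (df.assign(hit=(df["label"] == state).astype(float))
               .pivot_table(index="residue", columns="rung", values="hit", aggfunc="mean"))
        out[state] = tab
    return out


# canonical (phi_{i+1}, psi_{i+1}, phi_{i+2}, psi_{i+2}) centroids
TURN_CENTROIDS = {
    "I": (-60.0, -30.0, -90.0, 0.0),
    "I'": (60.0, 30.0, 90.0, 0.0),
    "II": (-60.0, 120.0, 80.0, 0.0),
    "II'": (60.0, -120.0, -80.0, 0.0),
    "VIII": (-60.0, -30.0, -120.0, 120.0),
}
TURN_TOLERANCE = 45.0


def classify_turn(window, hbonds: list[HBondRecord] | None = None,
                  residue_numbers: tuple[int, ...] | None = None) -> TurnRecord:
    """Type a turn from the two central residues' torsions.

    ``window`` is the (phi, psi) sequence of 4 consecutive residues (or 5 for
    an alpha-turn candidate). A 5-residue window anchored by an i->i+4
    hydrogen bond is typed "alpha"; 4-residue windows are matched against the
    canonical beta-turn centroids with a 45 deg circular tolerance per angle
    and fall back to "irregular".
    """
    window = np.asarray(window, float)
    if residue_numbers is None:
        residue_numbers = tuple(range(1, len(window) + 1))
    if len(window) == 5:
        anchor = None
        if hbonds:
            i, j = residue_numbers[0], residue_numbers[4]
            for hb in hbonds:
                if hb.intra_chain and {hb.donor_res, hb.acceptor_res} == {i, j}:
                    anchor = hb
                    break
        span = (residue_numbers[1], residue_numbers[3])
        return TurnRecord(span, "alpha", anchor)
    if len(window) != 4:
        raise ValueError("window must cover 4 (beta) or 5 (alpha) residues")
    if np.isnan(window[1:3]).any():
        raise ValueError("central residues of the window have undefined torsions")
    angles = np.array([window[1, 0], window[1, 1], window[2, 0], window[2, 1]])
    best, best_type = np.inf, "irregular"
    for name, cent in TURN_CENTROIDS.items():
        d = np.abs(wrap_angle(angles - np.asarray(cent)))
        if d.max() <= TURN_TOLERANCE and d.max() < best:
            best, best_type = d.max(), name
    anchor = None
    if hbonds:
        i, j = residue_numbers[0], residue_numbers[3]
        for hb in hbonds:
            if hb.intra_chain and {hb.donor_res, hb.acceptor_res} == {i, j}:
                anchor = hb
                break
    return TurnRecord((residue_numbers[1], residue_numbers[2]), best_type, anchor)


def detect_hairpins(structure: AtomicStructure | None = None,
                    hbonds: list[HBondRecord] | None = None,
                    criteria: HBondCriteria = HBondCriteria()) -> list[HairpinRecord]:
    """Find beta-hairpins from nested antiparallel cross-strand H-bonds.

    A hairpin turn shows up as a family of intra-chain bonds pairing residues
    i and j with (nearly) constant i+j: the bonds nest around the loop. Each
    group of >= 2 such bonds whose innermost pair encloses a loop of 2-5
    residues is one turn; a chain's hairpin order is the number of such turns
    (single/double/triple). Spans are reported in human numbering.
    """
    if hbonds is None:
        if structure is None:
            raise ValueError("need a structure or a precomputed bond list")
        hbonds = detect_hbonds(structure, criteria)
    by_chain: dict[int, set[tuple[int, int]]] = {}
    for hb in hbonds:
        if not hb.intra_chain:
            continue
        i, j = sorted((hb.donor_res, hb.acceptor_res))
        if j - i >= 3:
            by_chain.setdefault(hb.donor_chain, set()).add((i, j))
    out: list[HairpinRecord] = []
    for chain, pairs in sorted(by_chain.items()):
        groups: dict[int, list[tuple[int, int]]] = {}
        for (i, j) in sorted(pairs):
            s = i + j
            # merge with an existing register within +-1
            key = None
            for g in groups:
                if abs(g - s) <= 1:
                    key = g
                    break
            if key is None:
                groups[s] = [(i, j)]
            else:
                groups[key].append((i, j))
        spans = []
        registers = []
        n_bonds = 0
        for g, members in sorted(groups.items()):
            if len(members) < 2:
                continue
            a, b = min(members, key=lambda p: p[1] - p[0])
            loop_len = b - a - 1
            if not 2 <= loop_len <= 5:
                continue
            spans.append((a + 1, b - 1))
            lo = min(p[0] for p in members)
            hi = max(p[1] for p in members)
            registers.append(((lo, a), (b, hi)))
            n_bonds += len(members)
        if spans:
            out.append(HairpinRecord(chain, len(spans), tuple(spans),
                                     tuple(registers), n_bonds))
    return out
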