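"""RMSD conformational clustering and structural-family tables.

Ensembles are clustered on backbone heavy atoms (N, CA, C, O) with the
greedy neighbour-count (medoid-removal) algorithm at a peptide-dependent
cutoff (2.5 A for the 14-mers, 3.5 A for the 21-mers). Clusters are then
amalgamated by explicit structural predicates into the families used for
wildtype-vs-mutant comparison: helix, single hairpins binned by turn
location, double (and for the 21-mer triple) hairpins, and coil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geom import kabsch_rmsd, pairwise_rmsd_matrix
from .builder import AtomicStructure
from .metrics import HairpinRecord, assign_secondary_structure, detect_hairpins

#: Clustering cutoff (Angstrom) by peptide length.
CLUSTER_CUTOFF = {14: 2.5, 21: 3.5}

#: Turn-location bins (human numbering) defining the single-hairpin families.
SINGLE_HAIRPIN_BINS = {
    14: {"hairpin_113_116": (113, 116), "hairpin_117_119": (117, 119)},
    21: {"hairpin_112_117": (112, 117), "hairpin_118_120": (118, 120)},
}

FAMILY_SETS = {
    14: ["helix", "hairpin_113_116", "hairpin_117_119", "double_hairpin", "coil"],
    21: ["helix", "hairpin_112_117", "hairpin_118_120", "double_hairpin",
         "triple_hairpin", "coil"],
}


@dataclass
class ClusterSet:
    assignments: np.ndarray   # structure index -> cluster id
    representatives: np.ndarray  # cluster id -> medoid structure index
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return int(self.representatives.size)

    def members(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cid)


@dataclass
class FamilyAssignment:
    families: np.ndarray        # structure index -> family name
    superclusters: np.ndarray   # structure index -> (family, exact spans) id
    family_set: list[str]


def backbone_coords(structure: AtomicStructure, chain: int = 0) -> np.ndarray:
    """(4n, 3) backbone heavy-atom coordinates of one chain."""
    m = structure.chain_index == chain
    names = structure.atom_names[m]
    slots = structure.res_slots[m]
    xyz = structure.coords[m]
    n = len(structure.sequences[chain])
    rows = []
    for i in range(1, n + 1):
        for nm in ("N", "CA", "C", "O"):
            hit = np.flatnonzero((slots == i) & (names == nm))
            if hit.size != 1:
                raise ValueError(f"missing backbone atom {nm} in residue slot {i}")
            rows.append(hit[0])
    return xyz[rows]


def pairwise_rmsd(a, b) -> float:
    """Backbone RMSD after optimal superposition (Angstrom).

    Accepts AtomicStructures or pre-extracted (m,3) coordinate arrays.
    """
    ca = backbone_coords(a) if isinstance(a, AtomicStructure) else np.asarray(a, float)
    cb = backbone_coords(b) if isinstance(b, AtomicStructure) else np.asarray(b, float)
    if ca.shape != cb.shape:
        raise ValueError(f"atom selections differ: {ca.shape} vs {cb.shape}")
    return float(kabsch_rmsd(np.ascontiguousarray(ca), np.ascontiguousarray(cb)))


def cluster_structures(ensemble, cutoff: float) -> ClusterSet:
    """Greedy neighbour-count clustering.

    Repeatedly picks the structure with the most unassigned neighbours within
    the cutoff as a medoid (ties to the lowest index), assigns the
    neighbourhood to it, removes it, and recurses. Deterministic and
    independent of input permutation up to the documented tie-break.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(ensemble, np.ndarray):
        coords = ensemble
    else:
        ensemble = list(ensemble)
        if not ensemble:
            raise ValueError("empty ensemble")
        coords = np.stack([backbone_coords(s) for s in ensemble])
    m = coords.shape[0]
    condensed = pairwise_rmsd_matrix(np.ascontiguousarray(coords))
    neigh = np.zeros((m, m), dtype=bool)
    iu = np.triu_indices(m, k=1)
    neigh[iu] = condensed <= cutoff
    neigh |= neigh.T
    np.fill_diagonal(neigh, True)

    counts = neigh.sum(axis=1).astype(np.int64)
    alive = np.ones(m, dtype=bool)
    assignments = np.full(m, -1, dtype=np.int64)
    reps = []
    cid = 0
    while alive.any():
        masked = np.where(alive, counts, -1)
        medoid = int(np.argmax(masked))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neigh[medoid] & alive)
        assignments[members] = cid
        reps.append(medoid)
        alive[members] = False
        counts -= neigh[:, members].sum(axis=1)
        cid += 1
    return ClusterSet(assignments, np.array(reps, dtype=np.int64), float(cutoff))


def classify_structure(structure: AtomicStructure,
                       hairpins: list[HairpinRecord] | None = None) -> tuple[str, tuple]:
    """Family predicate for a single chain: (family, exact turn spans).

    Precedence: triple hairpin, double hairpin, single hairpin binned by
    turn location, helix (helix fraction >= 0.5), coil.
    """
    seq = structure.sequences[0]
    n = len(seq)
    if hairpins is None:
        hairpins = detect_hairpins(structure)
    hp = next((h for h in hairpins if h.chain == 0), None)
    bins = SINGLE_HAIRPIN_BINS[n] if n in SINGLE_HAIRPIN_BINS else {}
    if hp is not None:
        if hp.order >= 3 and n == 21:
            return "triple_hairpin", hp.turn_spans
        if hp.order == 2 or (hp.order >= 3 and n != 21):
            return "double_hairpin", hp.turn_spans
        span = hp.turn_spans[0]
        for fam, (lo, hi) in bins.items():
            if span[0] >= lo and span[1] <= hi:
                return fam, hp.turn_spans
        # a single hairpin outside the tabulated turn ranges
        return "coil", hp.turn_spans
    ss = assign_secondary_structure(structure)
    if ss.helix_fraction >= 0.5:
        return "helix", ()
    return "coil", ()


def assign_families(clusters: ClusterSet, ensemble,
                    vote_size: int = 5) -> FamilyAssignment:
    """Map every structure to a family via its cluster's representative.

    A lone medoid with marginal hydrogen-bond geometry can misread a whole
    cluster (e.g. a double hairpin whose first loop sits a hundredth of an
    Angstrom past the bond cutoff reads as single), so the predicate is
    evaluated on the medoid plus up to ``vote_size - 1`` evenly spaced
    members and the modal family wins; ties go to the medoid.
    """
    ensemble = list(ensemble)
    n_pep = len(ensemble[0].sequences[0])
    fam_by_cluster = {}
    super_by_cluster = {}
    for cid, rep in enumerate(clusters.representatives):
        rep_fam, rep_spans = classify_structure(ensemble[int(rep)])
        members = clusters.members(cid)
        votes = {rep_fam: 1}
        span_of = {rep_fam: rep_spans}
        if members.size > 1 and vote_size > 1:
            extra = members[np.linspace(0, members.size - 1,
                                        min(vote_size, members.size),
                                        dtype=int)]
            for m in extra:
                if int(m) == int(rep):
                    continue
                f, sp = classify_structure(ensemble[int(m)])
                votes[f] = votes.get(f, 0) + 1
                span_of.setdefault(f, sp)
        fam = max(votes, key=lambda f: (votes[f], f == rep_fam))
        fam_by_cluster[cid] = fam
        super_by_cluster[cid] = (fam, span_of[fam])
    sup_ids = {}
    families = np.empty(len(ensemble), dtype=object)
    superclusters = np.empty(len(ensemble), dtype=np.int64)
    for i, cid in enumerate(clusters.assignments):
        families[i] = fam_by_cluster[int(cid)]
        key = super_by_cluster[int(cid)]
        superclusters[i] = sup_ids.setdefault(key, len(sup_ids))
    return FamilyAssignment(families, superclusters, FAMILY_SETS[n_pep])


def family_percentages(assignment: FamilyAssignment) -> pd.Series:
    fams = pd.Series(assignment.families)
    pct = fams.value_counts(normalize=True) * 100.0
    return pct.reindex(assignment.family_set, fill_value=0.0)


def family_table(wildtype, mutant,
                 family_set: list[str] | None = None) -> pd.DataFrame:
    """Wildtype-vs-mutant family table with fold changes.

    ``wildtype`` / ``mutant`` are lists of per-replicate family percentage
    Series (or FamilyAssignments). Percentages are unweighted means over
    replicates; fold changes divide the unrounded means and are left
    undefined (NaN) where the wildtype percentage is zero.
    """
    def prep(reps):
        series = []
        for r in reps:
            series.append(family_percentages(r) if isinstance(r, FamilyAssignment) else r)
        return pd.concat(series, axis=1).mean(axis=1)

    wt = prep(wildtype if isinstance(wildtype, (list, tuple)) else [wildtype])
    mt = prep(mutant if isinstance(mutant, (list, tuple)) else [mutant])
    if family_set is not None:
        wt = wt.reindex(family_set, fill_value=0.0)
        mt = mt.reindex(family_set, fill_value=0.0)
    fold = mt / wt.where(wt > 0, np.nan)
    df = pd.DataFrame({"wildtype_pct": wt, "mutant_pct": mt, "fold_change": fold})
    df.index.name = "family"
    return df
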