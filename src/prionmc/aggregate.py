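"""Multi-chain trajectory analysis: oligomer detection, aggregation time
series, hydrogen-bond occupancy fold-change tables, pairwise-interaction
persistence and (helix, sheet) energy landscapes.

A pair of chains is *linked* when it satisfies all three oligomerization
criteria at once: at least 3 inter-chain hydrogen bonds, both chains at
least 50% beta-strand by residue labels, and strand axes parallel or
antiparallel within 30 degrees. Oligomers are connected components of
linked pairs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .builder import AtomicStructure
from .metrics import (HBondCriteria, HBondRecord, assign_secondary_structure,
                      detect_hairpins, detect_hbonds)

MIN_LINK_HBONDS = 3
MIN_SHEET_FRACTION = 0.5
ORIENTATION_TOL = 30.0  # degrees


@dataclass(frozen=True)
class OligomerRecord:
    frame: int
    members: tuple[int, ...]
    links: tuple[tuple[int, int, str], ...]   # (chain_a, chain_b, orientation)
    sheet_fractions: dict[int, float]
    pair_hbond_counts: dict[tuple[int, int], int]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PersistenceRun:
    pair: tuple[int, int]
    start_frame: int
    length: int
    min_hbonds: int
    max_hbonds: int
    hairpin_flags: tuple[tuple[bool, bool], ...]  # per frame, per chain
    persistent: bool

    @property
    def any_hairpin(self) -> bool:
        return any(a or b for a, b in self.hairpin_flags)


@dataclass
class LandscapeGrid:
    helix_edges: np.ndarray
    sheet_edges: np.ndarray
    mean_energy: np.ndarray   # NaN where empty
    counts: np.ndarray
    minima: list[tuple[int, int]] = field(default_factory=list)
    saddle: tuple[int, int] | None = None


def _strand_vector(structure: AtomicStructure, chain: int) -> np.ndarray | None:
    """Unit vector along the chain's longest strand-labelled segment
    (first to last CA), falling back to the whole chain."""
    ss = assign_secondary_structure(structure, chain=chain)
    lab = ss.labels
    best = None
    run = None
    for i, l in enumerate(lab):
        if l == "E":
            run = (run[0], i) if run else (i, i)
        else:
            if run and run[1] > run[0] and (best is None or run[1] - run[0] > best[1] - best[0]):
                best = run
            run = None
    if run and run[1] > run[0] and (best is None or run[1] - run[0] > best[1] - best[0]):
        best = run
    lo, hi = best if best else (0, len(lab) - 1)
    m = structure.chain_index == chain
    names = structure.atom_names[m]
    slots = structure.res_slots[m]
    xyz = structure.coords[m]
    ca = {int(s): xyz[k] for k, (nm, s) in enumerate(zip(names, slots)) if nm == "CA"}
    p0, p1 = ca.get(lo + 1), ca.get(hi + 1)
    if p0 is None or p1 is None:
        return None
    v = p1 - p0
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else None


def classify_pair_orientation(structure: AtomicStructure, chain_a: int,
                              chain_b: int) -> str:
    """'parallel' / 'antiparallel' / 'neither' from strand-axis vectors."""
    va = _strand_vector(structure, chain_a)
    vb = _strand_vector(structure, chain_b)
    if va is None or vb is None:
        return "neither"
    cosang = float(np.clip(np.dot(va, vb), -1.0, 1.0))
    ang = np.degrees(np.arccos(cosang))
    if ang <= ORIENTATION_TOL:
        return "parallel"
    if ang >= 180.0 - ORIENTATION_TOL:
        return "antiparallel"
    return "neither"


def interchain_hbond_counts(hbonds: list[HBondRecord]) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = defaultdict(int)
    for hb in hbonds:
        if not hb.intra_chain:
            key = tuple(sorted((hb.donor_chain, hb.acceptor_chain)))
            counts[key] += 1
    return dict(counts)


def detect_oligomers(structure: AtomicStructure, frame: int = 0,
                     criteria: HBondCriteria = HBondCriteria()) -> list[OligomerRecord]:
    """Oligomers of one snapshot: connected components of qualifying links."""
    hbonds = detect_hbonds(structure, criteria)
    pair_counts = interchain_hbond_counts(hbonds)
    sheet = {c: assign_secondary_structure(structure, chain=c).sheet_fraction
             for c in range(structure.n_chains)}
    links = []
    for (a, b), cnt in sorted(pair_counts.items()):
        if cnt < MIN_LINK_HBONDS:
            continue
        if sheet[a] < MIN_SHEET_FRACTION or sheet[b] < MIN_SHEET_FRACTION:
            continue
        ori = classify_pair_orientation(structure, a, b)
        if ori == "neither":
            continue
        links.append((a, b, ori))
    # connected components
    parent = list(range(structure.n_chains))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in links:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[int, list[int]] = defaultdict(list)
    for a, b, _ in links:
        comps[find(a)]  # touch
    for c in range(structure.n_chains):
        comps[find(c)].append(c)
    out = []
    linked_chains = {x for a, b, _ in links for x in (a, b)}
    for root, members in sorted(comps.items()):
        members = [m for m in members if m in linked_chains]
        if len(members) < 2:
            continue
        mem = tuple(sorted(members))
        mylinks = tuple(l for l in links if l[0] in mem and l[1] in mem)
        out.append(OligomerRecord(
            frame, mem, mylinks,
            {m: sheet[m] for m in mem},
            {(a, b): pair_counts[(a, b)] for a, b, _ in mylinks},
        ))
    return out


def chains_by_orientation(oligomers: list[OligomerRecord]) -> tuple[int, int]:
    """Number of chains involved in parallel / antiparallel links (a chain in
    both kinds of link counts toward both; this package counts chains, not
    links)."""
    par, anti = set(), set()
    for o in oligomers:
        for a, b, ori in o.links:
            (par if ori == "parallel" else anti).update((a, b))
    return len(par), len(anti)


def aggregation_time_series(trajectory, stride: int = 1,
                            criteria: HBondCriteria = HBondCriteria()) -> pd.DataFrame:
    """Per-frame helix/sheet fraction, total energy and oligomerized chains."""
    rows = []
    for i in range(0, len(trajectory), stride):
        snap = trajectory.snapshots[i]
        s = trajectory.structure(i)
        oligs = detect_oligomers(s, frame=i, criteria=criteria)
        npar, nanti = chains_by_orientation(oligs)
        rows.append({
            "frame": i, "cycle": snap.cycle,
            "helix_fraction": snap.helix_fraction,
            "sheet_fraction": snap.sheet_fraction,
            "e_total": snap.energy.e_total,
            "chains_parallel": npar,
            "chains_antiparallel": nanti,
            "n_oligomers": len(oligs),
            "largest_oligomer": max((o.size for o in oligs), default=0),
        })
    return pd.DataFrame(rows)


def _bond_key(hb: HBondRecord) -> tuple[int, int]:
    return (hb.donor_res, hb.acceptor_res)


def infer_turn_span(donor_res: int, acceptor_res: int,
                    first_res: int, last_res: int) -> str:
    """Turn location implied by an intra-chain bond's antiparallel register.

    The bond pairing residues i and j nests inside registers of constant
    i+j; the innermost strand pair encloses a 2-residue loop (odd |i-j|) or
    a 3-residue loop (even |i-j|). When the register cannot be nested by a
    second cross-strand pair inside the chain (terminal bonds), no hairpin
    can account for the bond and 'n/a' is reported.
    """
    i, j = sorted((donor_res, acceptor_res))
    if j - i < 3:
        return "n/a"
    s = i + j
    if (j - i) % 2 == 1:
        a, b = (s - 3) // 2, (s + 3) // 2
    else:
        a, b = (s - 4) // 2, (s + 4) // 2
    if a - 1 < first_res or b + 1 > last_res:
        return "n/a"
    return f"{a + 1}-{b - 1}"


def hbond_occupancy(wildtype_reps, mutant_reps, sequence=None,
                    criteria: HBondCriteria = HBondCriteria(),
                    fold_filter: float = 2.0) -> pd.DataFrame:
    """Hydrogen-bond occupancy table with mutant/wildtype fold changes.

    ``wildtype_reps`` / ``mutant_reps`` are lists of replicates, each a list
    of single-chain structures (or precomputed per-structure bond lists).
    Occupancy of a (donor residue, acceptor residue) bond is the percentage
    of structures containing it, averaged over replicates; rows are filtered
    to fold change >= ``fold_filter`` (rows with zero wildtype occupancy are
    kept and flagged undefined).
    """
    def occupancies(reps):
        per_rep = []
        for rep in reps:
            counts: dict[tuple[int, int], int] = defaultdict(int)
            nstruct = 0
            for item in rep:
                if isinstance(item, AtomicStructure):
                    bonds = detect_hbonds(item, criteria)
                else:
                    bonds = item
                nstruct += 1
                for key in {_bond_key(hb) for hb in bonds if hb.intra_chain}:
                    counts[key] += 1
            per_rep.append(pd.Series({k: 100.0 * v / nstruct for k, v in counts.items()},
                                     dtype=float))
        return pd.concat(per_rep, axis=1).fillna(0.0).mean(axis=1)

    wt = occupancies(wildtype_reps)
    mt = occupancies(mutant_reps)
    all_keys = wt.index.union(mt.index)
    wt = wt.reindex(all_keys, fill_value=0.0)
    mt = mt.reindex(all_keys, fill_value=0.0)
    fold = mt / wt.replace(0.0, np.nan)
    keep = (fold >= fold_filter) | (wt == 0.0) & (mt > 0.0)
    rows = []
    for (d, a) in all_keys[keep]:
        span = "n/a"
        if sequence is not None:
            first = sequence.numbering_offset
            last = first + len(sequence) - 1
            span = infer_turn_span(d, a, first, last)
        rows.append({
            "donor_res": d, "acceptor_res": a,
            "wildtype_pct": wt[(d, a)], "mutant_pct": mt[(d, a)],
            "fold_change": fold[(d, a)],
            "turn_span": span,
        })
    df = pd.DataFrame(rows, columns=["donor_res", "acceptor_res", "wildtype_pct",
                                     "mutant_pct", "fold_change", "turn_span"])
    return df.sort_values("fold_change", ascending=False, na_position="last").reset_index(drop=True)


def pair_persistence(pair_counts_by_frame, hbond_threshold: int = 3,
                     run_min: int = 5,
                     hairpin_by_frame=None) -> list[PersistenceRun]:
    """Maximal runs of consecutive frames where a chain pair keeps >=
    ``hbond_threshold`` inter-chain hydrogen bonds.

    ``pair_counts_by_frame`` is a sequence (one entry per frame) of
    ``{(a, b): count}`` dicts; ``hairpin_by_frame`` optionally provides per
    frame the set of chains in beta-hairpin conformation, recorded per run in
    support of the observation that persistent pairs involve a hairpin chain.
    """
    pairs = sorted({p for frame in pair_counts_by_frame for p in frame})
    out: list[PersistenceRun] = []
    nf = len(pair_counts_by_frame)
    for pair in pairs:
        f = 0
        while f < nf:
            if pair_counts_by_frame[f].get(pair, 0) >= hbond_threshold:
                start = f
                counts = []
                flags = []
                while f < nf and pair_counts_by_frame[f].get(pair, 0) >= hbond_threshold:
                    counts.append(pair_counts_by_frame[f][pair])
                    if hairpin_by_frame is not None:
                        hp = hairpin_by_frame[f]
                        flags.append((pair[0] in hp, pair[1] in hp))
                    else:
                        flags.append((False, False))
                    f += 1
                out.append(PersistenceRun(
                    pair, start, len(counts), min(counts), max(counts),
                    tuple(flags), persistent=len(counts) >= run_min))
            else:
                f += 1
    return out


def trajectory_pair_counts(trajectory, stride: int = 1,
                           criteria: HBondCriteria = HBondCriteria()):
    """Per-frame inter-chain H-bond counts and hairpin chain sets."""
    counts = []
    hairpins = []
    for i in range(0, len(trajectory), stride):
        s = trajectory.structure(i)
        bonds = detect_hbonds(s, criteria)
        counts.append(interchain_hbond_counts(bonds))
        hairpins.append({h.chain for h in detect_hairpins(s, hbonds=bonds)})
    return counts, hairpins


def energy_landscape(helix_fraction, sheet_fraction, energy,
                     n_bins: int = 20, min_count: int = 10) -> LandscapeGrid:
    """Mean total energy binned over the (helix, sheet) fraction plane.

    Local minima are occupied bins (>= ``min_count`` members) lower than all
    occupied neighbours; when two or more minima exist, the saddle between
    the two deepest is the lowest level at which they become connected
    through occupied bins (found by a union-find flood).
    """
    hf = np.asarray(helix_fraction, float)
    sf = np.asarray(sheet_fraction, float)
    en = np.asarray(energy, float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    ih = np.clip(np.digitize(hf, edges) - 1, 0, n_bins - 1)
    isf = np.clip(np.digitize(sf, edges) - 1, 0, n_bins - 1)
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    sums = np.zeros((n_bins, n_bins))
    np.add.at(counts, (ih, isf), 1)
    np.add.at(sums, (ih, isf), en)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    occupied = counts > 0
    minima = []
    for i in range(n_bins):
        for j in range(n_bins):
            if counts[i, j] < min_count:
                continue
            val = mean[i, j]
            is_min = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < n_bins and 0 <= b < n_bins and occupied[a, b]:
                        if mean[a, b] <= val:
                            is_min = False
                if not is_min:
                    break
            if is_min:
                minima.append((i, j))
    minima.sort(key=lambda ij: mean[ij])
    saddle = None
    if len(minima) >= 2:
        m1, m2 = minima[0], minima[1]
        order = sorted(((mean[i, j], i, j) for i in range(n_bins)
                        for j in range(n_bins) if occupied[i, j]))
        parent: dict[tuple[int, int], tuple[int, int]] = {}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        added = set()
        for val, i, j in order:
            parent[(i, j)] = (i, j)
            added.add((i, j))
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    nb = (i + di, j + dj)
                    if nb != (i, j) and nb in added:
                        ra, rb = find((i, j)), find(nb)
                        if ra != rb:
                            parent[ra] = rb
            if m1 in added and m2 in added and find(m1) == find(m2):
                saddle = (i, j)
                break
    return LandscapeGrid(edges, edges, mean, counts, minima, saddle)
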