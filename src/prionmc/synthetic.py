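"""Labelled synthetic conformers, ensembles and multi-chain assemblies.

Every analysis stage of the package (secondary structure, hairpin detection,
clustering, family tables, oligomer criteria, persistence) is validated on
fixtures built here with known ground truth, so the full pipeline is testable
without long simulations. Fixtures are seed-deterministic and are constructed
to *pass the detectors they target and fail the ones they should not*:
helix fixtures yield no hairpins, dispersed snapshots no oligomers.

Hairpins are built in torsion space (strands at (-120, 130), loop residues at
the canonical turn centroid) and then refined by a short local optimization
of the torsions around each loop so that the nested cross-strand H-bonds
actually meet the 2.4 A / 35 deg geometric criterion; beta-sheet assemblies
dock rigid extended chains at the canonical ~4.8 A inter-strand spacing by
maximizing a soft hydrogen-bond score over the 6 rigid-body parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.spatial.transform import Rotation

from .builder import AtomicStructure, Frame, assemble, build_chain_coords, build_structure
from .engine import Snapshot, Trajectory
from .forcefield import EnergyModel, ForceFieldParams
from .metrics import TURN_CENTROIDS, ss_label_from_phi_psi
from .sequences import PeptideSequence, get_peptide
from .topology import Conformation, get_topology

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 130.0)
COIL_PHI_PSI = (-70.0, 160.0)  # polyproline-ish backbone outside both windows

#: Default turn locations (human numbering) for multi-hairpin fixtures.
DEFAULT_DOUBLE_SPANS = {14: ((113, 114), (117, 118)), 21: ((113, 114), (119, 120))}
DEFAULT_TRIPLE_SPANS = {21: ((112, 113), (117, 118), (122, 123))}


def _as_seq(seq) -> PeptideSequence:
    return seq if isinstance(seq, PeptideSequence) else get_peptide(seq)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def make_ideal_helix(seq, noise_sigma: float = 0.0, seed=0) -> AtomicStructure:
    """All-residue alpha-helix with optional Gaussian torsional noise (deg)."""
    seq = _as_seq(seq)
    topo = get_topology(seq)
    rng = _rng(seed)
    n = topo.n_residues
    phi = np.full(n, HELIX_PHI_PSI[0]) + rng.normal(0, noise_sigma, n)
    psi = np.full(n, HELIX_PHI_PSI[1]) + rng.normal(0, noise_sigma, n)
    return build_structure(seq, Conformation(phi, psi, topo.default_chi()))


def make_coil(seq, seed=0) -> AtomicStructure:
    """Random-coil conformer: torsions from the uniform prior."""
    seq = _as_seq(seq)
    topo = get_topology(seq)
    rng = _rng(seed)
    n = topo.n_residues
    return build_structure(seq, Conformation(
        rng.uniform(-180, 180, n), rng.uniform(-180, 180, n),
        rng.uniform(-180, 180, topo.n_chi)))


def _hairpin_targets(seq: PeptideSequence, spans) -> list[tuple[int, int]]:
    """Target (donor_slot, acceptor_slot) H-bonds for the requested loops.

    Narrow bridge pairs of an antiparallel hairpin carry bonds in both
    directions at register offsets 0, 2, 4 from the loop.
    """
    n = len(seq)
    spans = sorted(spans)
    targets = []
    for li, (t1, t2) in enumerate(spans):
        p1 = seq.position_of(t1)
        p2 = seq.position_of(t2)
        # registers may not extend past the neighbouring loops of a meander;
        # the outer residue of an adjacent loop may still carry one bond
        strict_lo = seq.position_of(spans[li - 1][1]) + 1 if li > 0 else 1
        strict_hi = seq.position_of(spans[li + 1][0]) - 1 if li + 1 < len(spans) else n
        ext_lo = seq.position_of(spans[li - 1][0]) + 1 if li > 0 else 1
        ext_hi = seq.position_of(spans[li + 1][1]) - 1 if li + 1 < len(spans) else n
        for k in (0, 2, 4):
            a, b = p1 - 1 - k, p2 + 1 + k
            if a < ext_lo or b > ext_hi:
                break
            if k == 0:
                targets.append(("fixed", b, a))  # the i->i+3 turn anchor N(b)->O(a)
            elif a >= strict_lo and b <= strict_hi:
                targets.append(("fixed", a, b))
                targets.append(("fixed", b, a))
            else:
                # borrowed narrow pair: let refinement pick the direction the
                # local geometry favours
                targets.append(("either", a, b))
    return targets


def _hairpin_base_conformation(seq: PeptideSequence, spans, turn_types,
                               coil_tails: int = 0) -> Conformation:
    topo = get_topology(seq)
    n = topo.n_residues
    phi = np.full(n, STRAND_PHI_PSI[0])
    psi = np.full(n, STRAND_PHI_PSI[1])
    for (t1, t2), ttype in zip(spans, turn_types):
        cen = TURN_CENTROIDS[ttype]
        p1 = seq.position_of(t1) - 1
        p2 = seq.position_of(t2) - 1
        phi[p1], psi[p1] = cen[0], cen[1]
        phi[p2], psi[p2] = cen[2], cen[3]
    for k in range(coil_tails):
        phi[k], psi[k] = COIL_PHI_PSI
        phi[n - 1 - k], psi[n - 1 - k] = COIL_PHI_PSI
    return Conformation(phi, psi, topo.default_chi())


def _refine_hairpin(seq: PeptideSequence, conf: Conformation, spans,
                    window: int = 2, max_loop_dev: float = 30.0) -> Conformation:
    """Refine a (multi-)hairpin: cascade over loops, re-optimizing jointly
    with each newly added loop so earlier registers act as anchors."""
    for i in range(len(spans)):
        conf = _refine_pass(seq, conf, spans[:i + 1], window, max_loop_dev)
    return conf


def _refine_pass(seq: PeptideSequence, conf: Conformation, spans,
                 window: int = 2, max_loop_dev: float = 30.0,
                 max_nfev: int = 400) -> Conformation:
    """Locally optimize torsions around each loop until the nested
    cross-strand bonds meet the H-bond geometry; loop angles are tethered to
    their centroid so the turn type survives refinement."""
    topo = get_topology(seq)
    n = topo.n_residues
    dof0 = topo.conformation_to_dof(conf)
    free: list[int] = []
    loop_dofs: set[int] = set()
    for (t1, t2) in spans:
        p1 = seq.position_of(t1)
        p2 = seq.position_of(t2)
        for p in range(max(1, p1 - window), min(n, p2 + window) + 1):
            free.append(topo.dof_phi(p - 1))
            free.append(topo.dof_psi(p - 1))
            if p1 <= p <= p2:
                loop_dofs.add(topo.dof_phi(p - 1))
                loop_dofs.add(topo.dof_psi(p - 1))
    free = sorted(set(free))
    loop_sel = np.array([d in loop_dofs for d in free])
    targets = _hairpin_targets(seq, spans)
    # each target contributes one (H, N, O) triple; "either"-direction pairs
    # contribute both and the better one is scored
    dirs = []  # (donor_slot, acceptor_slot) rows; "either" pairs add both
    row_of = []
    for kind, a, b in targets:
        row_of.append(len(dirs))
        dirs.append((a, b))
        if kind == "either":
            dirs.append((b, a))
    dH = np.array([topo.atom(d, "H") for (d, _) in dirs])
    dN = np.array([topo.atom(d, "N") for (d, _) in dirs])
    dO = np.array([topo.atom(a, "O") for (_, a) in dirs])
    base = dof0.copy()
    max_dev = np.deg2rad(max_loop_dev)

    nca = topo.backbone_idx[1::4].size

    def residuals(x):
        dof = base.copy()
        dof[free] = x
        c = build_chain_coords(topo, dof)
        v = c[dO] - c[dH]
        d = np.linalg.norm(v, axis=1)
        u = c[dH] - c[dN]
        cosa = np.sum(u * v, axis=1) / (np.linalg.norm(u, axis=1) * np.maximum(d, 1e-9))
        ang = np.degrees(np.arccos(np.clip(cosa, -1, 1)))
        # collapse "either"-direction rows to the closer direction
        keep = []
        for (kind, _, _), r in zip(targets, row_of):
            if kind == "fixed":
                keep.append(r)
            else:
                keep.append(r if d[r] <= d[r + 1] else r + 1)
        d = d[keep]
        ang = ang[keep]
        # keep the loop near its centroid (turn type must survive)
        dev = np.abs(x[loop_sel] - base[free][loop_sel])
        # soft steric guard: no pair of CA atoms closer than 3.6 A
        ca = c[topo.backbone_idx[1::4]]
        dd = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
        iu = np.triu_indices(nca, k=2)
        return np.concatenate([
            d - 2.0,
            0.15 * np.maximum(ang - 15.0, 0.0),
            4.0 * np.maximum(dev - max_dev, 0.0),
            1.5 * np.maximum(3.6 - dd[iu], 0.0),
        ])

    res = least_squares(residuals, base[free], method="trf",
                        diff_step=1e-3, max_nfev=max_nfev, xtol=1e-8)
    dof = base.copy()
    dof[free] = res.x
    return topo.dof_to_conformation(dof)


def make_hairpin(seq, turn_span=(115, 116), turn_type: str = "II'",
                 noise_sigma: float = 0.0, seed=0, refine: bool = True,
                 coil_tails: int = 0) -> AtomicStructure:
    """Single beta-hairpin with the loop at ``turn_span`` (human numbering)."""
    return make_multi_hairpin(seq, [turn_span], [turn_type], noise_sigma,
                              seed, refine, coil_tails)


_TEMPLATE_CACHE: dict = {}


def make_multi_hairpin(seq, spans, turn_types=None, noise_sigma: float = 0.0,
                       seed=0, refine: bool = True,
                       coil_tails: int = 0) -> AtomicStructure:
    """Single/double/triple hairpin: one loop per span, meander topology.

    The noiseless refined conformation is cached per (sequence, spans, types)
    and used as the template; noisy samples perturb the template and are
    re-refined with a single joint pass, so the cross-strand bonds survive
    the noise while the rest of the backbone keeps it.
    """
    seq = _as_seq(seq)
    topo = get_topology(seq)
    if turn_types is None:
        turn_types = ["II'"] * len(spans)
    spans = tuple(tuple(s) for s in spans)
    for (t1, t2) in spans:
        p1, p2 = seq.position_of(t1), seq.position_of(t2)
        if p1 < 3 or p2 > len(seq) - 2:
            raise ValueError(f"turn span {t1}-{t2} too close to the termini "
                             "to form two cross-strand bonds")
    key = (seq.residues, spans, tuple(turn_types), coil_tails, refine)
    if key not in _TEMPLATE_CACHE:
        conf = _hairpin_base_conformation(seq, spans, turn_types, coil_tails)
        if refine:
            conf = _refine_hairpin(seq, conf, spans)
        _TEMPLATE_CACHE[key] = conf
    conf = _TEMPLATE_CACHE[key].copy()
    if noise_sigma > 0:
        rng = _rng(seed)
        n = topo.n_residues
        conf.phi += rng.normal(0, noise_sigma, n)
        conf.psi += rng.normal(0, noise_sigma, n)
        if refine:
            # starting near the refined template: a short polish suffices
            conf = _refine_pass(seq, conf, spans, max_nfev=150)
    return build_structure(seq, conf)


# --- labelled ensembles ------------------------------------------------------

@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for a labelled conformer ensemble.

    ``components`` maps family names to proportions (must sum to 1):
    ``helix``, ``coil``, ``hairpin_<t1>_<t2>`` (e.g. ``hairpin_115_116``),
    ``double_hairpin``, ``triple_hairpin`` (21-mer only).
    """

    sequence: str
    components: tuple
    noise_sigma: float = 5.0
    n_structures: int = 1000
    seed: int = 0

    def proportions(self) -> dict[str, float]:
        d = dict(self.components)
        total = sum(d.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"component proportions sum to {total}, not 1")
        return d


@dataclass
class LabelledEnsemble:
    spec: EnsembleSpec
    structures: list[AtomicStructure]
    labels: list[str]
    turn_spans: list[tuple]
    counts: dict[str, int]

    def __len__(self):
        return len(self.structures)


def _component_builder(name: str, seq: PeptideSequence):
    n = len(seq)
    if name == "helix":
        return lambda s, r: (make_ideal_helix(seq, s, r), ())
    if name == "coil":
        return lambda s, r: (make_coil(seq, r), ())
    if name.startswith("hairpin_"):
        _, t1, t2 = name.split("_")
        span = (int(t1), int(t2))
        return lambda s, r: (make_hairpin(seq, span, "II'", s, r), (span,))
    if name == "double_hairpin":
        spans = DEFAULT_DOUBLE_SPANS[n]
        return lambda s, r: (make_multi_hairpin(seq, spans, None, s, r), spans)
    if name == "triple_hairpin":
        if n not in DEFAULT_TRIPLE_SPANS:
            raise ValueError(f"a triple hairpin does not fit a {n}-mer")
        spans = DEFAULT_TRIPLE_SPANS[n]
        return lambda s, r: (make_multi_hairpin(seq, spans, None, s, r), spans)
    raise ValueError(f"unknown ensemble component {name!r}")


def make_labelled_ensemble(spec: EnsembleSpec) -> LabelledEnsemble:
    """Draw component counts multinomially and build every structure."""
    seq = _as_seq(spec.sequence)
    rng = np.random.default_rng(spec.seed)
    props = spec.proportions()
    names = list(props)
    counts = rng.multinomial(spec.n_structures, [props[k] for k in names])
    builders = {k: _component_builder(k, seq) for k in names}
    labels = np.repeat(names, counts)
    rng.shuffle(labels)
    structures, spans = [], []
    for lab in labels:
        s, sp = builders[lab](spec.noise_sigma, rng)
        structures.append(s)
        spans.append(sp)
    return LabelledEnsemble(spec, structures, list(labels), spans,
                            dict(zip(names, map(int, counts))))


# --- beta-sheet assemblies ---------------------------------------------------

def _pair_score(cH, cN, cO):
    v = cO[None, :, :] - cH[:, None, :]
    d = np.linalg.norm(v, axis=-1)
    u = cH - cN
    un = np.linalg.norm(u, axis=-1)
    cosa = np.einsum("ik,ijk->ij", u, v) / (un[:, None] * np.maximum(d, 1e-9))
    w = np.exp(-((d - 2.0) ** 2) / 0.18) * np.maximum(cosa, 0.0) ** 2
    return float(w.sum())


_DOCK_CACHE: dict = {}


def _dock_transform(topo, local, anti: bool, tag: str = "strand") -> Frame:
    """Rigid transform placing a second extended chain next to the first in
    (anti)parallel cross-beta registry, found by maximizing a soft H-bond
    score over several geometric initial guesses."""
    key = (topo.sequence.residues, anti, tag)
    if key in _DOCK_CACHE:
        return _DOCK_CACHE[key]
    bb = topo.backbone_idx
    ca = local[bb[1::4]]
    u = ca[-1] - ca[0]
    u /= np.linalg.norm(u)
    # N->H directions alternate sides along a strand: average one parity only
    nh_all = local[topo.don_h[:-2]] - local[topo.don_n[:-2]]
    nh = nh_all[::2].mean(axis=0)
    nh -= u * np.dot(nh, u)
    nh /= np.linalg.norm(nh)
    w = np.cross(u, nh)
    w /= np.linalg.norm(w)
    cen = local.mean(axis=0)

    def frame_from(x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        return Frame(rot, x[3:] + cen - rot @ cen)

    dH = local[topo.don_h[:-2]]
    dN = local[topo.don_n[:-2]]
    aO = local[topo.acc_o]

    def objective(x):
        fr = frame_from(x)
        bH, bN, bO = fr.apply(dH), fr.apply(dN), fr.apply(aO)
        s = _pair_score(dH, dN, bO) + _pair_score(bH, bN, aO)
        bca = fr.apply(ca)
        dd = np.linalg.norm(ca[:, None] - bca[None, :], axis=-1)
        clash = np.sum(np.maximum(4.0 - dd, 0.0) ** 2)
        return -s + 1.0 * clash

    starts = []
    for axis in ((nh, w) if anti else ((np.zeros(3),),)):
        rv = axis * np.pi if anti else np.zeros(3)
        for sgn in (1.0, -1.0):
            for shift in (-3.4, 0.0, 3.4):
                starts.append(np.concatenate([rv, sgn * 4.8 * nh + shift * u]))
    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": 1200, "xatol": 1e-3, "fatol": 1e-4})
        if best is None or res.fun < best.fun:
            best = res
    fr = frame_from(best.x)
    _DOCK_CACHE[key] = fr
    return fr


def make_sheet_assembly(seq, n_chains: int = 3, architecture: str = "antiparallel",
                        seed=0, box: float | None = None,
                        hairpin_edge: bool = False) -> AtomicStructure:
    """Multi-stranded beta-sheet of extended chains at cross-beta spacing.

    ``architecture`` is 'parallel' or 'antiparallel'; with ``hairpin_edge``
    one extra chain in (low-sheet-fraction) hairpin conformation is docked
    at the sheet edge, emulating the hairpin-capped fibril ends.
    """
    seq = _as_seq(seq)
    if n_chains < 2:
        raise ValueError("an assembly needs at least 2 chains")
    if architecture not in ("parallel", "antiparallel"):
        raise ValueError("architecture must be 'parallel' or 'antiparallel'")
    topo = get_topology(seq)
    n = topo.n_residues
    conf = Conformation(np.full(n, STRAND_PHI_PSI[0]), np.full(n, STRAND_PHI_PSI[1]),
                        topo.default_chi())
    dof = topo.conformation_to_dof(conf)
    local = build_chain_coords(topo, dof)
    D = _dock_transform(topo, local, anti=(architecture == "antiparallel"))
    frames = [Frame()]
    for _ in range(1, n_chains):
        prev = frames[-1]
        frames.append(Frame(prev.rotation @ D.rotation,
                            prev.rotation @ D.translation + prev.translation))
    confs = [Conformation(conf.phi.copy(), conf.psi.copy(), conf.chi.copy())
             for _ in range(n_chains)]
    if hairpin_edge:
        mid = (min(seq.residue_numbers) + max(seq.residue_numbers)) // 2
        hp = make_hairpin(seq, (mid, mid + 1), "II'", 0.0, seed, coil_tails=max(3, n // 3))
        from .builder import measure_conformation
        hconf = measure_conformation(hp)
        edge = frames[-1]
        off = edge.rotation @ (D.translation * 1.6)
        frames.append(Frame(edge.rotation, edge.translation + off))
        confs.append(hconf)
    return assemble(seq, confs, frames, box=box)


def make_pseudo_extended_pair(seq, seed=0) -> AtomicStructure:
    """Two H-bonded chains whose torsions sit just outside the strand window.

    The geometry is extended enough for >= 3 inter-chain bonds and the chains
    are antiparallel, but every residue labels coil: of the three
    oligomerization criteria only the 50%-sheet one fails.
    """
    seq = _as_seq(seq)
    topo = get_topology(seq)
    n = topo.n_residues
    conf = Conformation(np.full(n, -160.0), np.full(n, 150.0), topo.default_chi())
    dof = topo.conformation_to_dof(conf)
    local = build_chain_coords(topo, dof)
    fr = _dock_transform(topo, local, anti=True, tag="pseudo")
    return assemble(seq, [conf, conf], [Frame(), fr])


def make_crossed_pair(seq, seed=0) -> AtomicStructure:
    """A strand chain plus an L-shaped mostly-strand chain bonded through its
    *short* arm, so the pair is >= 3 H-bonds and >= 50% sheet on both sides
    but the strand axes cross at roughly 90 deg: only the orientation
    criterion fails."""
    seq = _as_seq(seq)
    topo = get_topology(seq)
    n = topo.n_residues
    straight = Conformation(np.full(n, STRAND_PHI_PSI[0]), np.full(n, STRAND_PHI_PSI[1]),
                            topo.default_chi())
    bent = Conformation(np.full(n, STRAND_PHI_PSI[0]), np.full(n, STRAND_PHI_PSI[1]),
                        topo.default_chi())
    arm = max(4, n // 3)          # short bonded arm
    kink = arm + 1                # single non-strand residue at the corner
    bent.phi[kink - 1], bent.psi[kink - 1] = -70.0, -40.0
    localA = build_chain_coords(topo, topo.conformation_to_dof(straight))
    localB = build_chain_coords(topo, topo.conformation_to_dof(bent))

    # dock B's short arm against A's matching stretch (soft H-bond score)
    arm_don = [i for i, r in enumerate(topo.don_res[:-2]) if r <= arm]
    arm_acc = [i for i, r in enumerate(topo.acc_res) if 1 <= r <= arm]
    dHa, dNa = localA[topo.don_h[:-2][arm_don]], localA[topo.don_n[:-2][arm_don]]
    aOa = localA[topo.acc_o[arm_acc]]
    dHb_idx, dNb_idx = topo.don_h[:-2][arm_don], topo.don_n[:-2][arm_don]
    aOb_idx = topo.acc_o[arm_acc]
    ca = localA[topo.backbone_idx[1::4]]
    u = ca[arm] - ca[0]
    u /= np.linalg.norm(u)
    nh = (localA[topo.don_h[:-2]] - localA[topo.don_n[:-2]])[::2].mean(axis=0)
    nh -= u * np.dot(nh, u)
    nh /= np.linalg.norm(nh)
    cenB = localB.mean(axis=0)

    def frame_from(x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        return Frame(rot, x[3:] + cenB - rot @ cenB)

    caB = localB[topo.backbone_idx[1::4]]

    def objective(x):
        fr = frame_from(x)
        bH, bN, bO = fr.apply(localB[dHb_idx]), fr.apply(localB[dNb_idx]), fr.apply(localB[aOb_idx])
        s = _pair_score(dHa, dNa, bO) + _pair_score(bH, bN, aOa)
        dd = np.linalg.norm(ca[:, None] - fr.apply(caB)[None, :], axis=-1)
        return -s + np.sum(np.maximum(4.0 - dd, 0.0) ** 2)

    w = np.cross(u, nh)
    best = None
    for rv in (np.pi * nh, np.pi * w, np.zeros(3)):
        for sgn in (1.0, -1.0):
            for shift in (-3.4, 0.0, 3.4):
                x0 = np.concatenate([rv, sgn * 4.8 * nh + shift * u])
                res = minimize(objective, x0, method="Nelder-Mead",
                               options={"maxiter": 1500, "xatol": 1e-3, "fatol": 1e-4})
                if best is None or res.fun < best.fun:
                    best = res
    return assemble(seq, [straight, bent], [Frame(), frame_from(best.x)])


def make_dispersed(seq, n_chains: int, seed=0, spacing: float = 30.0,
                   component: str = "coil", box: float | None = None) -> AtomicStructure:
    """Well-separated chains (no inter-chain contacts): the null fixture."""
    seq = _as_seq(seq)
    rng = _rng(seed)
    confs, frames = [], []
    side = int(np.ceil(n_chains ** (1 / 3)))
    k = 0
    for c in range(n_chains):
        s = make_ideal_helix(seq, 0.0, rng) if component == "helix" else make_coil(seq, rng)
        from .builder import measure_conformation
        confs.append(measure_conformation(s))
        pos = spacing * np.array([k % side, (k // side) % side, k // side ** 2], float)
        frames.append(Frame(np.eye(3), pos))
        k += 1
    return assemble(seq, confs, frames, box=box)


# --- scripted trajectories ---------------------------------------------------

@dataclass(frozen=True)
class Stage:
    """A scripted span of frames in one collective state.

    kind: 'dispersed' | 'dimer' | 'sheet'; for 'dimer' ``pair`` names the
    bonded chains, for 'sheet' ``size`` is the number of sheet chains.
    """

    kind: str
    n_frames: int
    pair: tuple[int, int] = (0, 1)
    size: int = 2


def make_assembly_trajectory(seq, stages: list[Stage], n_chains: int = 4,
                             seed=0, params: ForceFieldParams | None = None) -> Trajectory:
    """Scripted aggregation time course with per-frame ground truth.

    Frames realize the scripted states (dispersed coil, transient dimer,
    growing extended sheet); the trajectory's ``meta['truth']`` records the
    expected oligomer sizes and bonded pairs per frame.
    """
    seq = _as_seq(seq)
    topo = get_topology(seq)
    rng = _rng(seed)
    params = params or ForceFieldParams()
    model = EnergyModel(topo, n_chains, params, None)
    if not stages:
        return Trajectory(seq, [], output_interval=1, seed=seed if isinstance(seed, int) else 0,
                          nu=0, n_chains=n_chains, meta={"truth": []})

    from .builder import measure_conformation

    def state_chains(stage: Stage):
        if stage.kind == "dispersed":
            s = make_dispersed(seq, n_chains, rng)
            return s, set()
        if stage.kind == "dimer":
            a, b = stage.pair
            sheet = make_sheet_assembly(seq, 2, "antiparallel", 0)
            disp = make_dispersed(seq, n_chains, rng)
            confs = [measure_conformation(disp, c) for c in range(n_chains)]
            frames = [_frame_for(disp, c) for c in range(n_chains)]
            # place chains a,b as the docked dimer, shifted away from the rest
            off = np.array([90.0, 90.0, 90.0])
            for c, src in ((a, 0), (b, 1)):
                confs[c] = measure_conformation(sheet, src)
                frames[c] = _frame_for(sheet, src, extra=off)
            return assemble(seq, confs, frames), {tuple(sorted((a, b)))}
        if stage.kind == "sheet":
            k = min(stage.size, n_chains)
            sheet = make_sheet_assembly(seq, k, "antiparallel", 0)
            confs = [measure_conformation(sheet, c) for c in range(k)]
            frames = [_frame_for(sheet, c) for c in range(k)]
            if k < n_chains:
                disp = make_dispersed(seq, n_chains - k, rng, spacing=30.0)
                for c in range(n_chains - k):
                    confs.append(measure_conformation(disp, c))
                    frames.append(_frame_for(disp, c, extra=np.array([120.0, 120.0, 120.0])))
            pairs = {(c, c + 1) for c in range(k - 1)}
            return assemble(seq, confs, frames), pairs
        raise ValueError(f"unknown stage kind {stage.kind!r}")

    snaps = []
    truth = []
    frame_no = 0
    for stage in stages:
        struct, bonded = state_chains(stage)
        dofs = np.stack([topo.conformation_to_dof(measure_conformation(struct, c))
                         for c in range(n_chains)])
        frames = [_frame_for(struct, c) for c in range(n_chains)]
        for _ in range(stage.n_frames):
            coords = struct.coords
            energy = model.total(coords)
            n = topo.n_residues
            phi = np.rad2deg(dofs[:, :n]).ravel()
            psi = np.rad2deg(dofs[:, n:2 * n]).ravel()
            lab = ss_label_from_phi_psi((phi + 180) % 360 - 180, (psi + 180) % 360 - 180)
            snaps.append(Snapshot(frame_no + 1, -1, 300.0, energy,
                                  float(np.mean(lab == "H")), float(np.mean(lab == "E")),
                                  dofs.copy(), [Frame(f.rotation.copy(), f.translation.copy())
                                                for f in frames]))
            truth.append({"frame": frame_no, "kind": stage.kind,
                          "bonded_pairs": sorted(bonded)})
            frame_no += 1
    return Trajectory(seq, snaps, output_interval=1,
                      seed=seed if isinstance(seed, int) else 0,
                      nu=0, n_chains=n_chains, meta={"truth": truth})


def _centroid_frame(struct, c):
    return struct.coords[struct.chain_index == c].mean(axis=0)


def _frame_for(struct: AtomicStructure, c: int, extra=None) -> Frame:
    """Frame reproducing chain c's placement from its canonical build."""
    topo = struct.topology or get_topology(struct.sequences[c])
    from .builder import measure_conformation
    conf = measure_conformation(struct, c)
    local = build_chain_coords(topo, topo.conformation_to_dof(conf))
    world = struct.coords[struct.chain_index == c]
    lc = local - local.mean(axis=0)
    wc = world - world.mean(axis=0)
    m = lc.T @ wc
    u, s, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = world.mean(axis=0) - rot @ local.mean(axis=0)
    if extra is not None:
        t = t + extra
    return Frame(rot, t)
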