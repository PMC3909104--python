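"""Metropolis Monte Carlo in torsion space: simulated tempering for monomers
and fixed-temperature multi-chain simulation in a periodic box.

One *cycle* is nu elementary Metropolis steps, with nu equal to the number of
degrees of freedom of the system (torsions, plus six rigid-body degrees per
chain in multi-chain runs), so run lengths quoted in cycles scale with system
size the way the underlying sampler does. Every run is driven by a single
seeded 64-bit generator and is bit-for-bit reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .builder import Frame, assemble, build_chain_coords, AtomicStructure
from .forcefield import EnergyBreakdown, EnergyModel, ForceFieldParams, StericCatastrophe
from .metrics import ss_label_from_phi_psi
from .sequences import PeptideSequence
from .topology import get_topology

#: Default monomer box sides (Angstrom), taken as given constants.
MONOMER_BOX = {14: 65.3, 21: 91.9}
MULTICHAIN_BOX = 100.0


@dataclass(frozen=True)
class TemperatureLadder:
    temperatures: np.ndarray  # Kelvin, ascending

    def __post_init__(self):
        t = np.asarray(self.temperatures, float)
        if t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)

    @property
    def n_rungs(self) -> int:
        return int(self.temperatures.size)

    @property
    def rounded(self) -> np.ndarray:
        """Temperatures rounded to the nearest Kelvin (for reporting)."""
        return np.rint(self.temperatures).astype(int)


def make_temperature_ladder(t_min: float = 277.0, t_max: float = 333.0,
                            n: int = 8) -> TemperatureLadder:
    """Geometric (equal-ratio) ladder; reproduces the printed 277..333 K set."""
    if n < 2:
        raise ValueError("a ladder needs at least 2 rungs")
    if not t_min < t_max:
        raise ValueError("t_min must be below t_max")
    k = np.arange(n)
    return TemperatureLadder(t_min * (t_max / t_min) ** (k / (n - 1)))


@dataclass
class SimulationBox:
    side: float
    periodic: bool = True

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("box side must be positive")


@dataclass
class TemperingState:
    current_rung: int
    weights: np.ndarray
    visit_counts: np.ndarray
    attempt_interval: int = 1
    converged: bool = False
    occupancy_ratio: float = math.inf


@dataclass
class Snapshot:
    cycle: int
    rung: int               # -1 for fixed-temperature runs
    temperature: float
    energy: EnergyBreakdown
    helix_fraction: float
    sheet_fraction: float
    dofs: np.ndarray        # (n_chains, n_dof) radians
    frames: list[Frame]


@dataclass
class Trajectory:
    sequence: PeptideSequence
    snapshots: list[Snapshot]
    output_interval: int
    seed: int
    nu: int
    box: float | None = None
    n_chains: int = 1
    meta: dict = field(default_factory=dict)

    def structure(self, i: int) -> AtomicStructure:
        snap = self.snapshots[i]
        topo = get_topology(self.sequence)
        confs = [topo.dof_to_conformation(d) for d in snap.dofs]
        return assemble(self.sequence, confs, snap.frames, box=self.box)

    def __len__(self) -> int:
        return len(self.snapshots)


def expected_snapshots(n_cycles: int, output_interval: int) -> int:
    """Bookkeeping: snapshots written for a run of ``n_cycles``."""
    if output_interval <= 0:
        raise ValueError("output interval must be positive")
    return n_cycles // output_interval


def peptide_concentration_mm(n_chains: int, box_side: float) -> float:
    """Molar concentration (mM) of n chains in a cubic box of side Angstrom."""
    avogadro = 6.02214076e23
    litres = (box_side * 1e-9 / 10.0) ** 3 * 1e3  # A^3 -> dm^3
    return n_chains / (avogadro * litres) * 1e3


# --- system state ------------------------------------------------------------

PIVOT, SEMILOCAL, SIDECHAIN, RIGID = 0, 1, 2, 3


def move_mix(temperature: float, multichain: bool,
             t_lo: float = 277.0, t_hi: float = 333.0) -> np.ndarray:
    """Move-type probabilities, shifted toward small-step moves at low T."""
    x = min(max((temperature - t_lo) / (t_hi - t_lo), 0.0), 1.0)
    if multichain:
        w = np.array([0.3 * (0.6 + 0.4 * x), 0.2, 0.2, 0.3])
    else:
        w = np.array([0.4 * (0.6 + 0.4 * x), 0.3, 0.3, 0.0])
    return w / w.sum()


class SystemState:
    """Coordinates + energies of one or more chains of a single peptide."""

    def __init__(self, seq: PeptideSequence, n_chains: int = 1,
                 params: ForceFieldParams | None = None,
                 box: float | None = None,
                 frozen_dofs: np.ndarray | None = None):
        self.seq = seq
        self.topo = get_topology(seq)
        self.n_chains = n_chains
        self.params = params or ForceFieldParams()
        self.box = box
        self.model = EnergyModel(self.topo, n_chains, self.params, box)
        nd = self.topo.n_dof
        self.dofs = np.zeros((n_chains, nd))
        self.frames = [Frame() for _ in range(n_chains)]
        self.local = np.zeros((n_chains, self.topo.n_atoms, 3))
        self.coords = np.zeros((n_chains * self.topo.n_atoms, 3))
        # dofs that moves may touch (all by default); freezing a subset turns
        # the system into a low-dimensional testbed (e.g. one torsion)
        self.free_dofs = np.arange(nd) if frozen_dofs is None else \
            np.setdiff1d(np.arange(nd), frozen_dofs)
        self.energy = EnergyBreakdown(0, 0, 0, 0)

    @property
    def n_dof_total(self) -> int:
        per_chain = len(self.free_dofs) + (6 if self.n_chains > 1 else 0)
        return per_chain * self.n_chains

    def set_chain(self, c: int, dof: np.ndarray, frame: Frame | None = None):
        self.dofs[c] = dof
        if frame is not None:
            self.frames[c] = frame
        self.local[c] = build_chain_coords(self.topo, self.dofs[c])
        nl = self.topo.n_atoms
        self.coords[c * nl:(c + 1) * nl] = self.frames[c].apply(self.local[c])

    def randomize(self, rng: np.random.Generator, placement_tries: int = 1000):
        """Random torsions from the uniform prior; non-overlapping placement."""
        nl = self.topo.n_atoms
        for c in range(self.n_chains):
            dof = rng.uniform(-np.pi, np.pi, self.topo.n_dof)
            if len(self.free_dofs) < self.topo.n_dof:
                keep = np.setdiff1d(np.arange(self.topo.n_dof), self.free_dofs)
                base = self.topo.conformation_to_dof(self.topo.default_conformation())
                dof[keep] = base[keep]
            if self.n_chains == 1:
                self.set_chain(c, dof)
                continue
            placed = False
            for _ in range(placement_tries):
                fr = Frame.random(rng, box=self.box)
                local = build_chain_coords(self.topo, dof)
                world = fr.apply(local)
                ok = True
                for c2 in range(c):
                    d = world[:, None, :] - self.coords[c2 * nl:(c2 + 1) * nl][None, :, :]
                    if self.box:
                        d -= self.box * np.rint(d / self.box)
                    if np.min(np.sum(d * d, axis=-1)) < 1.5 ** 2:
                        ok = False
                        break
                if ok:
                    self.dofs[c] = dof
                    self.frames[c] = fr
                    self.local[c] = local
                    self.coords[c * nl:(c + 1) * nl] = world
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    "could not place chains without steric overlap; use a larger box")
        self.refresh_energy()

    def refresh_energy(self) -> EnergyBreakdown:
        self.energy = self.model.total(self.coords)
        return self.energy

    def fractions(self) -> tuple[float, float]:
        """Helix / sheet fraction over all residues of all chains."""
        n = self.topo.n_residues
        phi = np.rad2deg(self.dofs[:, :n]).ravel()
        psi = np.rad2deg(self.dofs[:, n:2 * n]).ravel()
        phi = (phi + 180.0) % 360.0 - 180.0
        psi = (psi + 180.0) % 360.0 - 180.0
        lab = ss_label_from_phi_psi(phi, psi)
        return float(np.mean(lab == "H")), float(np.mean(lab == "E"))


def _propose(state: SystemState, rng: np.random.Generator, temperature: float,
             mix: np.ndarray):
    """Draw a move; returns (chain, new_dof or None, new_frame or None, mask_local)."""
    topo = state.topo
    c = int(rng.integers(state.n_chains))
    kind = int(rng.choice(4, p=mix))
    x = min(max((temperature - 277.0) / 56.0, 0.0), 1.0)
    n = topo.n_residues
    if kind == RIGID:
        dt = rng.normal(0.0, 1.0, 3)
        axis = rng.normal(0.0, 1.0, 3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(-np.pi / 6, np.pi / 6)
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_rotvec(axis * ang).as_matrix()
        old = state.frames[c]
        # rotate about the chain centroid, then translate
        nl = topo.n_atoms
        cen = state.coords[c * nl:(c + 1) * nl].mean(axis=0)
        newR = rot @ old.rotation
        newt = rot @ (old.translation - cen) + cen + dt
        if state.box:
            newt = newt % state.box
        return c, None, Frame(newR, newt), np.ones(topo.n_atoms, dtype=bool)
    dof = state.dofs[c].copy()
    free = state.free_dofs
    if kind == PIVOT:
        bb = free[free < 2 * n]
        target = free if bb.size == 0 else bb
        d = int(target[rng.integers(target.size)])
        if rng.random() < 0.5:
            dof[d] = rng.uniform(-np.pi, np.pi)
        else:
            dof[d] += rng.normal(0.0, np.deg2rad(15.0 + 25.0 * x))
        mask = topo.affected[d].copy()
    elif kind == SEMILOCAL:
        bb = free[free < 2 * n]
        target = free if bb.size == 0 else bb
        d0 = int(target[rng.integers(target.size)])
        picked = [d for d in range(d0, d0 + 4) if d in set(target.tolist())]
        mask = np.zeros(topo.n_atoms, dtype=bool)
        for d in picked:
            dof[d] += rng.normal(0.0, np.deg2rad(8.0))
            mask |= topo.affected[d]
    else:  # SIDECHAIN
        sc = free[free >= 2 * n]
        target = sc if sc.size else free
        d = int(target[rng.integers(target.size)])
        dof[d] = rng.uniform(-np.pi, np.pi)
        mask = topo.affected[d].copy()
    return c, dof, None, mask


def mc_step(state: SystemState, rng: np.random.Generator, beta: float,
            temperature: float, mix: np.ndarray) -> bool:
    """One elementary Metropolis step; returns acceptance."""
    c, dof, frame, mask_local = _propose(state, rng, temperature, mix)
    nl = state.topo.n_atoms
    sl = slice(c * nl, (c + 1) * nl)
    mask = np.zeros(state.n_chains * nl, dtype=bool)
    mask[sl] = mask_local

    if frame is not None:
        new_local = state.local[c]
        new_world = frame.apply(new_local)
    else:
        new_local = build_chain_coords(state.topo, dof)
        new_world = state.frames[c].apply(new_local)

    old_chunk = state.coords[sl].copy()
    try:
        e_before = state.model.involving(state.coords, mask)
        state.coords[sl] = new_world
        e_after = state.model.involving(state.coords, mask)
    except StericCatastrophe:
        state.coords[sl] = old_chunk
        return False
    delta = e_after - e_before
    if delta.e_total <= 0.0 or rng.random() < math.exp(-beta * delta.e_total):
        if frame is not None:
            state.frames[c] = frame
        else:
            state.dofs[c] = dof
            state.local[c] = new_local
        state.energy = state.energy + delta
        return True
    state.coords[sl] = old_chunk
    return False


def mc_cycle(state: SystemState, rng: np.random.Generator,
             temperature: float) -> float:
    """One cycle = nu elementary steps at the given temperature.

    Returns the acceptance fraction of the cycle.
    """
    beta = state.params.beta(temperature)
    mix = move_mix(temperature, state.n_chains > 1)
    nu = state.n_dof_total
    acc = 0
    for _ in range(nu):
        acc += mc_step(state, rng, beta, temperature, mix)
    return acc / nu


# --- simulated tempering -----------------------------------------------------

def _attempt_rung_change(state: SystemState, tempering: TemperingState,
                         ladder: TemperatureLadder, rng: np.random.Generator):
    k = tempering.current_rung
    k2 = k + (1 if rng.random() < 0.5 else -1)
    if not 0 <= k2 < ladder.n_rungs:
        return
    b1 = state.params.beta(ladder.temperatures[k])
    b2 = state.params.beta(ladder.temperatures[k2])
    g = tempering.weights
    logp = (b1 - b2) * state.energy.e_total + (g[k2] - g[k])
    if logp >= 0.0 or rng.random() < math.exp(logp):
        tempering.current_rung = k2


def _tempering_run(state: SystemState, ladder: TemperatureLadder,
                   weights: np.ndarray, n_cycles: int,
                   rng: np.random.Generator, attempt_prob: float = 0.1,
                   on_snapshot=None, output_interval: int | None = None,
                   start_rung: int | None = None) -> np.ndarray:
    """Core tempering loop; returns per-rung cycle occupancy counts."""
    tempering = TemperingState(
        current_rung=int(start_rung if start_rung is not None
                         else rng.integers(ladder.n_rungs)),
        weights=np.asarray(weights, float),
        visit_counts=np.zeros(ladder.n_rungs, dtype=np.int64),
    )
    for cycle in range(1, n_cycles + 1):
        t = ladder.temperatures[tempering.current_rung]
        mc_cycle(state, rng, t)
        if rng.random() < attempt_prob:
            _attempt_rung_change(state, tempering, ladder, rng)
        tempering.visit_counts[tempering.current_rung] += 1
        if output_interval and cycle % output_interval == 0 and on_snapshot:
            state.energy = state.refresh_energy()
            on_snapshot(cycle, tempering.current_rung)
    return tempering.visit_counts


def tune_tempering_weights(seq: PeptideSequence, ladder: TemperatureLadder,
                           pilot_cycles: int, max_iterations: int,
                           seed: int, params: ForceFieldParams | None = None,
                           occupancy_target: float = 2.0,
                           f_floor: float = 1e-3) -> TemperingState:
    """Iteratively tune tempering weights toward uniform rung occupancy.

    Runs short pilot simulations and applies ``g_k <- g_k - ln(max(f_k,
    f_floor))`` (recentred to mean zero) until the occupancy ratio max f /
    min f drops to ``occupancy_target``, or ``max_iterations`` is exhausted
    (then the best weights seen are returned with a warning).
    """
    if ladder.n_rungs == 1:
        return TemperingState(0, np.zeros(1), np.zeros(1, dtype=np.int64),
                              converged=True, occupancy_ratio=1.0)
    if pilot_cycles < ladder.n_rungs * 100:
        raise ValueError("pilot_cycles must be at least 100 per rung")
    rng = np.random.default_rng(seed)
    state = SystemState(seq, params=params)
    state.randomize(rng)
    g = np.zeros(ladder.n_rungs)
    best = (math.inf, g.copy(), np.zeros(ladder.n_rungs, dtype=np.int64))
    for _ in range(max_iterations):
        visits = _tempering_run(state, ladder, g, pilot_cycles, rng)
        f = visits / visits.sum()
        ratio = f.max() / max(f.min(), f_floor)
        if ratio < best[0]:
            best = (ratio, g.copy(), visits.copy())
        if ratio <= occupancy_target:
            return TemperingState(0, g, visits, converged=True,
                                  occupancy_ratio=float(ratio))
        g = g - np.log(np.maximum(f, f_floor))
        g -= g.mean()
    warnings.warn(
        f"tempering weights did not reach occupancy ratio {occupancy_target}; "
        f"best ratio {best[0]:.2f}", RuntimeWarning)
    return TemperingState(0, best[1], best[2], converged=False,
                          occupancy_ratio=float(best[0]))


def run_simulated_tempering(seq: PeptideSequence, ladder: TemperatureLadder,
                            weights: np.ndarray | None, n_cycles: int,
                            output_interval: int, seed: int,
                            params: ForceFieldParams | None = None,
                            attempt_prob: float = 0.1) -> Trajectory:
    """Production tempering run of one monomer.

    Tuned weights are mandatory: without them the walker camps on one rung
    and the temperature ladder is pointless, so this mirrors the tune-first
    protocol.
    """
    if weights is None:
        raise ValueError("tempering weights are required; run tune_tempering_weights first")
    rng = np.random.default_rng(seed)
    box = MONOMER_BOX.get(len(seq))
    state = SystemState(seq, params=params)
    state.randomize(rng)
    traj = Trajectory(seq, [], output_interval, seed, nu=state.n_dof_total,
                      box=box, n_chains=1,
                      meta={"kind": "tempering",
                            "ladder": ladder.temperatures.tolist(),
                            "weights": list(map(float, weights))})

    def snap(cycle, rung):
        hf, sf = state.fractions()
        traj.snapshots.append(Snapshot(
            cycle, rung, float(ladder.temperatures[rung]), state.energy,
            hf, sf, state.dofs.copy(), [Frame(f.rotation.copy(), f.translation.copy())
                                        for f in state.frames]))

    _tempering_run(state, ladder, np.asarray(weights, float), n_cycles, rng,
                   attempt_prob=attempt_prob, on_snapshot=snap,
                   output_interval=output_interval)
    return traj


def run_multichain(seq: PeptideSequence, n_chains: int, box: float,
                   temperature: float, n_cycles: int, output_interval: int,
                   seed: int, params: ForceFieldParams | None = None) -> Trajectory:
    """Fixed-temperature multi-chain run in a periodic cube."""
    if n_chains < 2:
        raise ValueError("a multi-chain run needs at least 2 chains")
    rng = np.random.default_rng(seed)
    state = SystemState(seq, n_chains=n_chains, params=params, box=box)
    state.randomize(rng)
    traj = Trajectory(seq, [], output_interval, seed, nu=state.n_dof_total,
                      box=box, n_chains=n_chains,
                      meta={"kind": "multichain", "temperature": temperature,
                            "concentration_mM": peptide_concentration_mm(n_chains, box)})
    for cycle in range(1, n_cycles + 1):
        mc_cycle(state, rng, temperature)
        if cycle % output_interval == 0:
            state.refresh_energy()
            hf, sf = state.fractions()
            traj.snapshots.append(Snapshot(
                cycle, -1, temperature, state.energy, hf, sf,
                state.dofs.copy(),
                [Frame(f.rotation.copy(), f.translation.copy()) for f in state.frames]))
    return traj
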