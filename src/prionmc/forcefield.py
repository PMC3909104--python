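"""The four-term implicit-solvent interaction potential.

``E = E_loc + E_ev + E_hb + E_sc``: local backbone electrostatics (the
intrinsic phi/psi preference), excluded volume, backbone hydrogen bonding and
a sidechain contact potential over hydrophobic/charged groups. Energies are
kcal/mol; the functional forms are this package's concrete choices, with
every constant configurable, and the default scales are calibrated so that
the ideal helix of the 109-122 peptide is the lowest-energy conformer among
helix/hairpin/coil fixtures at the coldest ladder temperature.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .builder import AtomicStructure
from .topology import ChainTopology

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872041

#: Sidechain contact categories (see topology.SC_GROUPS).
CAT_ALIPHATIC, CAT_POSITIVE, CAT_HIS = 0, 1, 2


def _default_m_table() -> np.ndarray:
    m = np.zeros((3, 3))
    m[CAT_ALIPHATIC, CAT_ALIPHATIC] = 0.8   # hydrophobic attraction
    m[CAT_POSITIVE, CAT_POSITIVE] = -0.5    # like-charge repulsion
    m[CAT_ALIPHATIC, CAT_HIS] = 0.3
    m[CAT_HIS, CAT_ALIPHATIC] = 0.3
    return m


@dataclass(frozen=True)
class ForceFieldParams:
    """All tunable constants of the potential (kcal/mol, Angstrom, e)."""

    kappa_loc: float = 25.0        # scale of q_a q_b / r between adjacent units
    kappa_ev: float = 0.10         # excluded-volume prefactor
    lambda_bonded: float = 0.75    # EV radius reduction for 3-bond pairs
    epsilon_hb: float = 3.0        # H-bond well depth
    sigma_hb: float = 2.0          # H-bond distance at the minimum
    m_table: np.ndarray = field(default_factory=_default_m_table)
    temperature_scale: float = 1.0  # nominal K per model K
    version: str = "1"

    def __post_init__(self):
        if self.epsilon_hb < 0 or self.kappa_ev < 0:
            raise ValueError("epsilon_hb and kappa_ev must be non-negative")
        m = np.asarray(self.m_table, dtype=float)
        if m.shape != (3, 3) or not np.allclose(m, m.T):
            raise ValueError("m_table must be a symmetric 3x3 matrix")
        object.__setattr__(self, "m_table", m)

    def beta(self, temperature_kelvin: float) -> float:
        """Inverse temperature in model units."""
        return 1.0 / (KB * temperature_kelvin / self.temperature_scale)

    @staticmethod
    def from_toml(path) -> "ForceFieldParams":
        """Read a ``[forcefield]`` section from a TOML config file."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        sec = data.get("forcefield", {})
        kwargs = {}
        for key in ("kappa_loc", "kappa_ev", "lambda_bonded", "epsilon_hb",
                    "sigma_hb", "temperature_scale", "version"):
            if key in sec:
                kwargs[key] = sec[key]
        if "m_table" in sec:
            kwargs["m_table"] = np.asarray(sec["m_table"], dtype=float)
        return ForceFieldParams(**kwargs)


@dataclass(frozen=True)
class EnergyBreakdown:
    e_loc: float
    e_ev: float
    e_hb: float
    e_sc: float

    @property
    def e_total(self) -> float:
        return self.e_loc + self.e_ev + self.e_hb + self.e_sc

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(self.e_loc + other.e_loc, self.e_ev + other.e_ev,
                               self.e_hb + other.e_hb, self.e_sc + other.e_sc)

    def __sub__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(self.e_loc - other.e_loc, self.e_ev - other.e_ev,
                               self.e_hb - other.e_hb, self.e_sc - other.e_sc)


class StericCatastrophe(ValueError):
    """Two atoms are (numerically) on top of each other."""


class EnergyModel:
    """Prepared pair lists for one topology replicated over ``n_chains``.

    The heavy lifting lives in numba kernels; this class tiles the per-chain
    bookkeeping (H-bond sites, charge pairs, contact groups) across chains and
    exposes total and move-local (masked) evaluations.
    """

    def __init__(self, topo: ChainTopology, n_chains: int,
                 params: ForceFieldParams | None = None, box: float | None = None):
        self.topo = topo
        self.n_chains = n_chains
        self.params = params or ForceFieldParams()
        self.box = float(box) if box else 0.0
        nl = topo.n_atoms
        self.n_atoms = nl * n_chains
        self.chain_id = np.repeat(np.arange(n_chains, dtype=np.int32), nl)
        self.local_id = np.tile(np.arange(nl, dtype=np.int32), n_chains)
        self.sigma = np.tile(topo.sigma, n_chains)

        offs = np.arange(n_chains, dtype=np.int32)[:, None] * nl

        def tile_idx(a):
            return (a[None, :] + offs).ravel().astype(np.int32)

        self.loc_i = tile_idx(topo.loc_i)
        self.loc_j = tile_idx(topo.loc_j)
        self.loc_qq = np.tile(topo.loc_qq, n_chains)

        self.don_n = tile_idx(topo.don_n)
        self.don_h = tile_idx(topo.don_h)
        self.don_res = np.tile(topo.don_res, n_chains)
        self.don_chain = np.repeat(np.arange(n_chains, dtype=np.int32), topo.don_n.size)
        self.acc_c = tile_idx(topo.acc_c)
        self.acc_o = tile_idx(topo.acc_o)
        self.acc_res = np.tile(topo.acc_res, n_chains)
        self.acc_chain = np.repeat(np.arange(n_chains, dtype=np.int32), topo.acc_c.size)

        ng = topo.sc_start.size
        self.grp_atom = tile_idx(topo.sc_atom)
        starts = (topo.sc_start[None, :] + np.arange(n_chains)[:, None] * topo.sc_atom.size)
        self.grp_start = starts.ravel().astype(np.int32)
        self.grp_len = np.tile(topo.sc_len, n_chains)
        self.grp_cat = np.tile(topo.sc_cat, n_chains)
        self.grp_res = np.tile(topo.sc_res, n_chains)
        self.grp_chain = np.repeat(np.arange(n_chains, dtype=np.int32), ng)

        self._no_mask = np.zeros(self.n_atoms, dtype=bool)

    def _terms(self, coords: np.ndarray, mask, use_mask: bool) -> EnergyBreakdown:
        p = self.params
        if mask is None:
            mask = self._no_mask
        e_ev, minr2 = _kernels.ev_energy(
            coords, self.sigma, self.chain_id, self.local_id, self.topo.bondsep,
            p.lambda_bonded, p.kappa_ev, self.box, mask, use_mask)
        if minr2 < 1e-12:
            raise StericCatastrophe(
                f"steric catastrophe: atom pair at distance {np.sqrt(minr2):.2e} A")
        e_loc = _kernels.loc_energy(coords, self.loc_i, self.loc_j, self.loc_qq,
                                    p.kappa_loc, mask, use_mask)
        e_hb = _kernels.hb_energy(
            coords, self.don_n, self.don_h, self.don_res, self.don_chain,
            self.acc_c, self.acc_o, self.acc_res, self.acc_chain,
            p.epsilon_hb, p.sigma_hb, self.box, mask, use_mask)
        e_sc = _kernels.sc_energy(
            coords, self.grp_atom, self.grp_start, self.grp_len, self.grp_cat,
            self.grp_res, self.grp_chain, p.m_table, self.box, mask, use_mask)
        return EnergyBreakdown(e_loc, e_ev, e_hb, e_sc)

    def total(self, coords: np.ndarray) -> EnergyBreakdown:
        return self._terms(coords, None, False)

    def involving(self, coords: np.ndarray, mask: np.ndarray) -> EnergyBreakdown:
        """Pair terms with at least one atom in ``mask`` (for move deltas)."""
        return self._terms(coords, mask, True)


def energy_breakdown(structure: AtomicStructure,
                     params: ForceFieldParams | None = None,
                     box: float | None = None) -> EnergyBreakdown:
    """Full energy of a built structure (uses ``structure.box`` by default)."""
    if structure.topology is None:
        raise ValueError("energy requires a template-built structure")
    model = EnergyModel(structure.topology, structure.n_chains, params,
                        box if box is not None else structure.box)
    return model.total(structure.coords)
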