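import numpy as np
import pytest

from prionmc import (Conformation, EnergyModel, Frame, ForceFieldParams,
                     SystemState, assemble, build_structure, energy_breakdown,
                     get_topology)
from prionmc._kernels import hb_energy
from prionmc.engine import mc_step, move_mix

from conftest import random_conformation


def test_terms_sum_to_total(helix14):
    eb = energy_breakdown(helix14)
    assert eb.e_total == eb.e_loc + eb.e_ev + eb.e_hb + eb.e_sc
    assert eb.e_ev >= 0.0


def test_rigid_invariance(seq14, topo14):
    rng = np.random.default_rng(0)
    conf = topo14.default_conformation()
    e0 = energy_breakdown(build_structure(seq14, conf))
    fr = Frame.random(rng)
    e1 = energy_breakdown(build_structure(seq14, conf, frame=fr))
    for term in ("e_loc", "e_ev", "e_hb", "e_sc"):
        assert getattr(e0, term) == pytest.approx(getattr(e1, term), abs=1e-9)


def test_interchain_terms_vanish_at_separation(seq14, topo14):
    """Every term is short-ranged: two chains > 20 A apart contribute no
    inter-chain energy."""
    conf = topo14.default_conformation()
    iso = energy_breakdown(build_structure(seq14, conf))
    pair = assemble(seq14, [conf, conf],
                    [Frame(), Frame(np.eye(3), np.array([80.0, 0, 0]))])
    both = energy_breakdown(pair)
    for term in ("e_loc", "e_ev", "e_hb", "e_sc"):
        assert getattr(both, term) == pytest.approx(2 * getattr(iso, term), abs=1e-6)


def test_helix_hb_below_extended(seq14, topo14):
    helix = build_structure(seq14, Conformation(
        np.full(14, -57.0), np.full(14, -47.0), topo14.default_chi()))
    ext = build_structure(seq14, Conformation(
        np.full(14, 180.0), np.full(14, 180.0), topo14.default_chi()))
    assert energy_breakdown(helix).e_hb < energy_breakdown(ext).e_hb
    assert energy_breakdown(ext).e_hb == 0.0


def test_ev_monotone_nonincreasing_in_pair_distance():
    """One inter-chain atom pair: excluded volume is non-negative and
    non-increasing as the pair distance grows."""
    from prionmc._kernels import ev_energy
    sigma = np.array([1.75, 1.75])
    chain = np.array([0, 1], np.int32)
    local = np.array([0, 0], np.int32)
    bondsep = np.zeros((1, 1), np.uint8)
    mask = np.zeros(2, bool)
    prev = np.inf
    for r in np.linspace(1.0, 6.0, 60):
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        e, _ = ev_energy(coords, sigma, chain, local, bondsep, 0.75, 0.1,
                         0.0, mask, False)
        assert 0.0 <= e <= prev + 1e-12
        prev = e


class TestHBondWell:
    def _geometry(self, r, alpha_deg=0.0, beta_deg=0.0):
        """Collinear N-H...O=C geometry with controlled deviations."""
        N = np.array([0.0, 0.0, 0.0])
        H = np.array([1.0, 0.0, 0.0])
        a = np.deg2rad(alpha_deg)
        O = H + r * np.array([np.cos(a), np.sin(a), 0.0])
        b = np.deg2rad(beta_deg)
        direction = (O - N) / np.linalg.norm(O - N)
        rot = np.array([[np.cos(b), -np.sin(b), 0], [np.sin(b), np.cos(b), 0], [0, 0, 1]])
        C = O + 1.23 * (rot @ direction)
        coords = np.vstack([N, H, O, C])
        return hb_energy(coords,
                         np.array([0], np.int32), np.array([1], np.int32),
                         np.array([0], np.int32), np.array([0], np.int32),
                         np.array([3], np.int32), np.array([2], np.int32),
                         np.array([5], np.int32), np.array([1], np.int32),
                         1.0, 2.0, 0.0, np.zeros(4, bool), False)

    def test_minimum_at_sigma(self):
        rs = np.linspace(1.6, 4.4, 200)
        es = np.array([self._geometry(r) for r in rs])
        assert rs[np.argmin(es)] == pytest.approx(2.0, abs=0.05)
        assert self._geometry(2.0) == pytest.approx(-1.0, abs=1e-9)

    @pytest.mark.parametrize("alpha,beta", [(95.0, 0.0), (0.0, 95.0), (120.0, 0.0)])
    def test_gated_off_beyond_90deg(self, alpha, beta):
        assert self._geometry(2.0, alpha, beta) == 0.0

    def test_beyond_cutoff_zero(self):
        assert self._geometry(4.6) == 0.0


class TestDeltaEnergy:
    def test_null_and_rigid_moves(self, seq14):
        state = SystemState(seq14)
        rng = np.random.default_rng(0)
        state.randomize(rng)
        e0 = state.energy.e_total
        # rigid translation of an isolated chain in free space changes nothing
        state.frames[0] = Frame(np.eye(3), np.array([5.0, -3.0, 1.0]))
        state.set_chain(0, state.dofs[0])
        assert state.refresh_energy().e_total == pytest.approx(e0, rel=1e-9)

    def test_500_random_moves_match_full_recompute(self, seq14):
        """Incremental move-local deltas agree with full recomputation."""
        state = SystemState(seq14)
        rng = np.random.default_rng(1)
        state.randomize(rng)
        beta = state.params.beta(350.0)
        mix = move_mix(350.0, False)
        for _ in range(500):
            mc_step(state, rng, beta, 350.0, mix)
            full = state.model.total(state.coords).e_total
            running = state.energy.e_total
            assert abs(running - full) <= 1e-6 * max(1.0, abs(full))


def test_helix_is_global_minimum_among_fixtures(seq14, topo14):
    """Calibration: at the default constants the ideal helix beats hairpin
    and coil fixtures in total energy (coldest-rung ordering)."""
    from prionmc import make_hairpin, make_coil, make_ideal_helix
    e_helix = energy_breakdown(make_ideal_helix(seq14, 0, 0)).e_total
    e_hairpin = energy_breakdown(make_hairpin(seq14, (115, 116), "II'", 0, 0)).e_total
    rng = np.random.default_rng(0)
    e_coils = [energy_breakdown(make_coil(seq14, s)).e_total for s in range(5)]
    assert e_helix < e_hairpin
    assert e_helix < min(e_coils)


def test_steric_catastrophe_reported(seq14, topo14):
    from prionmc import StericCatastrophe
    conf = topo14.default_conformation()
    pair = assemble(seq14, [conf, conf], [Frame(), Frame()])  # exact overlap
    with pytest.raises(StericCatastrophe):
        energy_breakdown(pair)
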