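import math

import numpy as np
import pytest

from prionmc import (ForceFieldParams, SystemState, Trajectory,
                     expected_snapshots, make_temperature_ladder, mc_cycle,
                     peptide_concentration_mm, run_multichain,
                     run_simulated_tempering, tune_tempering_weights)
from prionmc.engine import TemperatureLadder, SimulationBox, mc_step, move_mix


class TestLadder:
    def test_printed_ladder_reproduced(self):
        """Geometric spacing between 277 and 333 K reproduces the printed
        8-rung ladder after rounding to the nearest K."""
        lad = make_temperature_ladder(277.0, 333.0, 8)
        assert lad.rounded.tolist() == [277, 284, 292, 300, 308, 316, 324, 333]

    def test_endpoints_preserved(self):
        lad = make_temperature_ladder(300.0, 300.0 * 1.37, 2)
        assert lad.temperatures[0] == pytest.approx(300.0)
        assert lad.temperatures[1] == pytest.approx(411.0)

    def test_three_rung_middle_is_geometric_mean(self):
        lad = make_temperature_ladder(277.0, 333.0, 3)
        assert lad.temperatures[1] == pytest.approx(math.sqrt(277 * 333), rel=1e-12)
        assert lad.rounded[1] == 304

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_temperature_ladder(277, 333, 1)
        with pytest.raises(ValueError):
            make_temperature_ladder(333, 277, 4)
        with pytest.raises(ValueError):
            TemperatureLadder(np.array([300.0, 290.0]))
        with pytest.raises(ValueError):
            SimulationBox(-1.0)


def test_snapshot_bookkeeping():
    assert expected_snapshots(10**8, 1000) == 100_000
    assert expected_snapshots(10**8, 1000) // 20 == 5_000
    assert expected_snapshots(2 * 10**7, 500) == 40_000
    assert expected_snapshots(1234, 100) == 12


def test_concentration_20_chains_100A_box():
    assert peptide_concentration_mm(20, 100.0) == pytest.approx(33.0, abs=0.3)


def test_metropolis_accepts_everything_at_infinite_temperature(seq14):
    state = SystemState(seq14)
    rng = np.random.default_rng(0)
    state.randomize(rng)
    for _ in range(30):
        mc_cycle(state, rng, 300.0)  # relax out of clashes first
    acc = [mc_cycle(state, rng, 1e12) for _ in range(5)]
    assert np.mean(acc) > 0.95


def test_seeded_runs_bit_identical(seq14):
    lad = make_temperature_ladder(277, 333, 4)
    w = np.zeros(4)
    t1 = run_simulated_tempering(seq14, lad, w, 200, 50, seed=9)
    t2 = run_simulated_tempering(seq14, lad, w, 200, 50, seed=9)
    assert len(t1) == len(t2) == 4
    for a, b in zip(t1.snapshots, t2.snapshots):
        assert np.array_equal(a.dofs, b.dofs)
        assert a.energy.e_total == b.energy.e_total
        assert a.rung == b.rung


def test_different_seeds_decorrelate(seq14):
    lad = make_temperature_ladder(277, 333, 4)
    w = np.zeros(4)
    t1 = run_simulated_tempering(seq14, lad, w, 200, 50, seed=9)
    t2 = run_simulated_tempering(seq14, lad, w, 200, 50, seed=10)
    assert any(a.energy.e_total != b.energy.e_total
               for a, b in zip(t1.snapshots, t2.snapshots))


def test_missing_weights_refused(seq14):
    lad = make_temperature_ladder(277, 333, 4)
    with pytest.raises(ValueError, match="weights"):
        run_simulated_tempering(seq14, lad, None, 100, 10, seed=1)


class TestTuning:
    def test_flat_landscape_converges_immediately(self, seq14):
        """With every energy term off, rung occupancy is uniform under zero
        weights already."""
        params = ForceFieldParams(kappa_loc=0.0, kappa_ev=0.0, epsilon_hb=0.0,
                                  m_table=np.zeros((3, 3)))
        lad = make_temperature_ladder(277, 333, 4)
        ts = tune_tempering_weights(seq14, lad, pilot_cycles=1500,
                                    max_iterations=3, seed=2, params=params)
        assert ts.converged
        assert np.allclose(ts.weights, 0.0)

    def test_single_rung_trivial(self, seq14):
        lad = TemperatureLadder(np.array([300.0]))
        ts = tune_tempering_weights(seq14, lad, 10, 1, seed=0)
        assert ts.converged and ts.weights.tolist() == [0.0]

    def test_pilot_too_short_rejected(self, seq14):
        lad = make_temperature_ladder(277, 333, 8)
        with pytest.raises(ValueError):
            tune_tempering_weights(seq14, lad, pilot_cycles=100,
                                   max_iterations=1, seed=0)


def test_multichain_additivity_at_separation(seq14):
    """Two chains placed far apart have the sum of isolated energies."""
    from prionmc import Conformation, Frame, assemble, energy_breakdown, build_structure, get_topology
    topo = get_topology(seq14)
    conf = topo.default_conformation()
    iso = energy_breakdown(build_structure(seq14, conf)).e_total
    pair = assemble(seq14, [conf, conf],
                    [Frame(), Frame(np.eye(3), np.array([45.0, 0, 0]))], box=200.0)
    assert energy_breakdown(pair).e_total == pytest.approx(2 * iso, abs=1e-6)


def test_multichain_run_bookkeeping(seq14):
    traj = run_multichain(seq14, n_chains=2, box=50.0, temperature=293.0,
                          n_cycles=120, output_interval=50, seed=4)
    assert len(traj) == 2
    assert [s.cycle for s in traj.snapshots] == [50, 100]
    assert traj.meta["concentration_mM"] == pytest.approx(
        peptide_concentration_mm(2, 50.0))
    with pytest.raises(ValueError):
        run_multichain(seq14, 1, 50.0, 293.0, 10, 5, 0)


def test_periodic_wrap_keeps_energy_finite(seq14):
    """Rigid moves wrap translations into the box; an isolated chain's
    energy is unchanged by the wrap."""
    state = SystemState(seq14, n_chains=2, box=40.0)
    rng = np.random.default_rng(8)
    state.randomize(rng)
    e0 = state.energy.e_total
    for _ in range(50):
        mc_step(state, rng, state.params.beta(300), 300.0,
                np.array([0.0, 0.0, 0.0, 1.0]))  # rigid moves only
        for f in state.frames:
            assert np.all(f.translation >= -1e-9) and np.all(f.translation <= 40.0 + 1e-9)
    assert np.isfinite(state.refresh_energy().e_total)
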