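import numpy as np
import pandas as pd
import pytest

from prionmc import (Frame, Stage, aggregation_time_series, assemble,
                     classify_pair_orientation, detect_oligomers,
                     energy_landscape, hbond_occupancy, infer_turn_span,
                     make_assembly_trajectory, make_dispersed, make_hairpin,
                     make_ideal_helix, make_sheet_assembly, pair_persistence)
from prionmc.aggregate import interchain_hbond_counts, trajectory_pair_counts
from prionmc.metrics import detect_hbonds
from prionmc.synthetic import make_crossed_pair, make_pseudo_extended_pair


class TestOrientation:
    def test_translated_copy_parallel(self, seq14, topo14):
        conf = topo14.default_conformation()
        s = assemble(seq14, [conf, conf],
                     [Frame(), Frame(np.eye(3), np.array([0, 30.0, 0]))])
        assert classify_pair_orientation(s, 0, 1) == "parallel"

    def test_flipped_copy_antiparallel(self, seq14, topo14):
        from scipy.spatial.transform import Rotation
        conf = topo14.default_conformation()
        s0 = assemble(seq14, [conf], [Frame()])
        from prionmc.aggregate import _strand_vector
        v = _strand_vector(s0, 0)
        perp = np.cross(v, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        rot = Rotation.from_rotvec(np.pi * perp).as_matrix()
        s = assemble(seq14, [conf, conf],
                     [Frame(), Frame(rot, np.array([0, 40.0, 0]))])
        assert classify_pair_orientation(s, 0, 1) == "antiparallel"

    def test_right_angle_neither(self, seq14, topo14):
        from scipy.spatial.transform import Rotation
        conf = topo14.default_conformation()
        s0 = assemble(seq14, [conf], [Frame()])
        from prionmc.aggregate import _strand_vector
        v = _strand_vector(s0, 0)
        perp = np.cross(v, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        rot = Rotation.from_rotvec(np.pi / 2 * perp).as_matrix()
        s = assemble(seq14, [conf, conf],
                     [Frame(), Frame(rot, np.array([0, 40.0, 0]))])
        assert classify_pair_orientation(s, 0, 1) == "neither"


class TestOligomerCriteria:
    def test_three_chain_antiparallel_sheet(self, seq14):
        s = make_sheet_assembly(seq14, 3, "antiparallel", 0)
        oligs = detect_oligomers(s)
        assert len(oligs) == 1
        assert oligs[0].members == (0, 1, 2)
        assert all(ori == "antiparallel" for _, _, ori in oligs[0].links)

    def test_parallel_sheet_labelled_parallel(self, seq14):
        s = make_sheet_assembly(seq14, 2, "parallel", 0)
        oligs = detect_oligomers(s)
        assert len(oligs) == 1
        assert all(ori == "parallel" for _, _, ori in oligs[0].links)

    def test_hbond_count_gate(self, seq14, topo14):
        """Shearing the sheet dimer along the strand axis until at most 2
        inter-chain bonds remain: sheet and orientation still pass, the
        bond-count criterion alone rejects the pair."""
        base = make_sheet_assembly(seq14, 2, "antiparallel", 0)
        from prionmc.synthetic import _frame_for
        fr = _frame_for(base, 1)
        conf = topo14.default_conformation()
        conf.phi[:] = -120.0
        conf.psi[:] = 130.0
        ca = base.coords[base.chain_index == 0]
        bb = topo14.backbone_idx[1::4]
        u = ca[bb[-1]] - ca[bb[0]]
        u /= np.linalg.norm(u)
        found = None
        for shift in np.arange(8.0, 30.0, 1.0):
            s = assemble(seq14, [conf, conf],
                         [Frame(), Frame(fr.rotation, fr.translation + shift * u)])
            n = sum(interchain_hbond_counts(detect_hbonds(s)).values())
            if 1 <= n <= 2:
                found = s
                break
        assert found is not None, "no shear produced a 1-2 bond pair"
        assert detect_oligomers(found) == []
        assert classify_pair_orientation(found, 0, 1) == "antiparallel"

    def test_sheet_fraction_gate(self, seq14):
        s = make_pseudo_extended_pair(seq14)
        assert sum(interchain_hbond_counts(detect_hbonds(s)).values()) >= 3
        assert classify_pair_orientation(s, 0, 1) in ("parallel", "antiparallel")
        assert detect_oligomers(s) == []

    def test_orientation_gate(self, seq14):
        s = make_crossed_pair(seq14)
        from prionmc.metrics import assign_secondary_structure
        assert sum(interchain_hbond_counts(detect_hbonds(s)).values()) >= 3
        assert all(assign_secondary_structure(s, chain=c).sheet_fraction >= 0.5
                   for c in (0, 1))
        assert detect_oligomers(s) == []

    def test_dispersed_helices_no_oligomer(self, seq14):
        s = make_dispersed(seq14, 6, 0, component="helix")
        assert detect_oligomers(s) == []

    def test_membership_invariant_under_rigid_motion(self, seq14):
        rng = np.random.default_rng(3)
        s = make_sheet_assembly(seq14, 3, "antiparallel", 0)
        fr = Frame.random(rng)
        moved = s.copy()
        moved.coords = fr.apply(s.coords)
        a = detect_oligomers(s)
        b = detect_oligomers(moved)
        assert [o.members for o in a] == [o.members for o in b]


class TestTimeSeries:
    def test_static_helix_trajectory_constant(self, seq14):
        traj = make_assembly_trajectory(seq14, [Stage("dispersed", 4)],
                                        n_chains=3, seed=0)
        ts = aggregation_time_series(traj)
        assert len(ts) == 4
        assert (ts["chains_antiparallel"] == 0).all()
        assert (ts["n_oligomers"] == 0).all()

    def test_scripted_growth_monotone_sheet(self, seq14):
        traj = make_assembly_trajectory(
            seq14, [Stage("dispersed", 2), Stage("sheet", 2, size=2),
                    Stage("sheet", 2, size=3)], n_chains=3, seed=1)
        ts = aggregation_time_series(traj)
        sf = ts["sheet_fraction"].to_numpy()
        assert np.all(np.diff(sf) >= -1e-9)
        assert ts["chains_antiparallel"].iloc[-1] == 3

    def test_energy_column_matches_recomputation(self, seq14):
        from prionmc import energy_breakdown
        traj = make_assembly_trajectory(seq14, [Stage("sheet", 2, size=2)],
                                        n_chains=2, seed=2)
        ts = aggregation_time_series(traj)
        for i in range(len(traj)):
            ref = energy_breakdown(traj.structure(i)).e_total
            assert ts["e_total"].iloc[i] == pytest.approx(ref, rel=1e-9)


class TestOccupancy:
    def _ensembles(self, seq, bond_rates, n, seed):
        """Replicates where a hairpin (carrying its signature bonds) appears
        at a controlled rate; brute-force occupancies are known."""
        rng = np.random.default_rng(seed)
        reps = []
        for rep_rate in bond_rates:
            structures = []
            k = round(n * rep_rate)
            for i in range(n):
                if i < k:
                    structures.append(make_hairpin(seq, (114, 115), "II'", 0.0, 0))
                else:
                    structures.append(make_ideal_helix(seq, 0.0, rng))
            reps.append(structures)
        return reps

    def test_occupancy_arithmetic_and_filter(self, seq14):
        wt = self._ensembles(seq14, [0.02], 100, 0)
        mt = self._ensembles(seq14, [0.05], 100, 1)
        tab = hbond_occupancy(wt, mt, sequence=seq14)
        sig = tab[(tab.donor_res == 116) & (tab.acceptor_res == 113)]
        assert len(sig) == 1
        row = sig.iloc[0]
        assert row.wildtype_pct == pytest.approx(2.0)
        assert row.mutant_pct == pytest.approx(5.0)
        assert row.fold_change == pytest.approx(2.5)
        assert row.turn_span == "114-115"
        # helix bonds are present in both at ~equal rates: filtered out
        assert not ((tab.donor_res - tab.acceptor_res == 4) & tab.fold_change.lt(2)).any()

    def test_identical_ensembles_empty(self, seq14):
        wt = self._ensembles(seq14, [0.05], 40, 0)
        tab = hbond_occupancy(wt, [list(wt[0])], sequence=seq14)
        assert tab[tab.fold_change.notna()].empty

    def test_enumeration_oracle(self, seq14):
        """Occupancies equal brute-force per-structure counts / N * 100."""
        wt = self._ensembles(seq14, [0.10, 0.20], 20, 3)
        mt = self._ensembles(seq14, [0.50, 0.30], 20, 4)
        tab = hbond_occupancy(wt, mt, sequence=seq14)
        sig = tab[(tab.donor_res == 116) & (tab.acceptor_res == 113)].iloc[0]
        assert sig.wildtype_pct == pytest.approx(15.0)
        assert sig.mutant_pct == pytest.approx(40.0)


class TestTurnSpanInference:
    @pytest.mark.parametrize("donor,acceptor,span", [
        (110, 118, "113-115"),
        (113, 116, "114-115"),
        (122, 117, "119-120"),
        (110, 117, "113-114"),
        (117, 109, "112-114"),
        (120, 109, "114-115"),
        (119, 122, "n/a"),      # terminal: no second nested pair fits
    ])
    def test_printed_registers(self, donor, acceptor, span):
        """The innermost-loop rule reproduces the published turn-location
        column for the 14-mer occupancy table."""
        assert infer_turn_span(donor, acceptor, 109, 122) == span


class TestPersistence:
    def test_run_arithmetic(self):
        counts = [{(0, 1): c} for c in [0, 3, 3, 3, 0]]
        runs = pair_persistence(counts, hbond_threshold=3, run_min=5)
        assert len(runs) == 1
        assert runs[0].start_frame == 1 and runs[0].length == 3
        assert not runs[0].persistent

    def test_empty(self):
        assert pair_persistence([{}, {}, {}]) == []

    def test_runs_partition_qualifying_frames(self):
        rng = np.random.default_rng(0)
        counts = [{(0, 1): int(c)} for c in rng.integers(0, 6, 60)]
        runs = pair_persistence(counts, hbond_threshold=3, run_min=4)
        covered = sorted(f for r in runs for f in range(r.start_frame,
                                                        r.start_frame + r.length))
        qualifying = [i for i, c in enumerate(counts) if c[(0, 1)] >= 3]
        assert covered == qualifying

    def test_implanted_dimer_found(self, seq14):
        traj = make_assembly_trajectory(
            seq14, [Stage("dispersed", 2), Stage("dimer", 12, pair=(0, 3)),
                    Stage("dispersed", 2)], n_chains=4, seed=7)
        counts, hairpins = trajectory_pair_counts(traj)
        runs = pair_persistence(counts, 3, 5, hairpins)
        persistent = [r for r in runs if r.persistent]
        assert len(persistent) == 1
        assert persistent[0].pair == (0, 3)
        assert persistent[0].length == 12


class TestLandscape:
    def test_constructed_functional_minimum(self):
        rng = np.random.default_rng(0)
        hf = rng.uniform(0, 1, 4000)
        sf = rng.uniform(0, 0.2, 4000)
        grid = energy_landscape(hf, sf, -hf)
        hi, si = grid.minima[0]
        assert hi == 19  # highest occupied helix bin

    def test_two_basin_saddle(self):
        rng = np.random.default_rng(1)
        n = 6000
        hf = rng.uniform(0, 1, n)
        sf = rng.uniform(0, 1, n)
        energy = -3.0 * np.exp(-((hf - 0.9) ** 2 + sf ** 2) / 0.02) \
                 - 2.0 * np.exp(-((sf - 0.9) ** 2 + hf ** 2) / 0.02) \
                 + 0.5 * rng.normal(0, 0.01, n)
        grid = energy_landscape(hf, sf, energy)
        assert len(grid.minima) >= 2
        assert grid.saddle is not None
        h1, s1 = grid.minima[0]
        h2, s2 = grid.minima[1]
        assert {(h1 > 15, s1 > 15), (h2 > 15, s2 > 15)} == {(True, False), (False, True)}

    def test_single_structure_no_saddle(self):
        grid = energy_landscape([0.5], [0.5], [1.0], min_count=1)
        assert grid.counts.sum() == 1
        assert grid.saddle is None
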