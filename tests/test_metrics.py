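import numpy as np
import pytest

from prionmc import (Conformation, HBondCriteria, assign_secondary_structure,
                     build_structure, classify_turn, detect_hairpins,
                     detect_hbonds, make_hairpin, make_ideal_helix,
                     make_multi_hairpin, per_residue_frequency)
from prionmc.builder import AtomicStructure
from prionmc.sequences import PeptideSequence


def _two_residue_probe(d, angle_deg):
    """Minimal donor/acceptor geometry: one N-H, one C=O, controllable
    H...O distance and N-H...O deviation."""
    a = np.deg2rad(angle_deg)
    N = np.array([0.0, 0.0, 0.0])
    H = np.array([1.0, 0.0, 0.0])
    O = H + d * np.array([np.cos(a), np.sin(a), 0.0])
    C = O + 1.23 * np.array([np.cos(a), np.sin(a), 0.0])
    seq = PeptideSequence("AAAAAA", numbering_offset=1)
    coords = np.vstack([N, H, O, C])
    return AtomicStructure(
        coords=coords,
        atom_names=np.array(["N", "H", "O", "C"]),
        res_slots=np.array([2, 2, 5, 5]),
        res_names=np.array(["ALA"] * 4),
        chain_index=np.zeros(4, dtype=int),
        sequences=[seq],
    )


class TestHBondCriteria:
    def test_qualifying_pair_reported(self):
        bonds = detect_hbonds(_two_residue_probe(2.1, 10.0))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.1)
        assert bonds[0].angle == pytest.approx(10.0, abs=1e-6)

    def test_distance_gate_at_2_4(self):
        assert detect_hbonds(_two_residue_probe(2.5, 10.0)) == []
        assert len(detect_hbonds(_two_residue_probe(2.4, 10.0))) == 1

    def test_angle_gate_at_35(self):
        assert detect_hbonds(_two_residue_probe(2.1, 36.0)) == []
        assert len(detect_hbonds(_two_residue_probe(2.1, 34.9))) == 1

    def test_adjacent_residues_excluded(self):
        s = _two_residue_probe(2.1, 10.0)
        s.res_slots = np.array([2, 2, 3, 3])
        assert detect_hbonds(s) == []

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HBondCriteria(d_max=-1)
        with pytest.raises(ValueError):
            HBondCriteria(angle_max=95)


def test_helix_bonds_are_all_i_to_i4(helix14):
    bonds = detect_hbonds(helix14)
    assert bonds
    assert all(b.donor_res - b.acceptor_res == 4 for b in bonds)


def test_extended_chain_has_no_intrachain_bonds(strand14):
    assert [b for b in detect_hbonds(strand14) if b.intra_chain] == []


class TestSSWindows:
    @pytest.mark.parametrize("phi,psi,label", [
        (-57.0, -47.0, "H"), (-120.0, 120.0, "E"), (60.0, 60.0, "C"),
        (-90.0, -17.0, "H"), (-150.0, 150.0, "E"), (0.0, 0.0, "C")])
    def test_window_membership(self, seq14, topo14, phi, psi, label):
        conf = Conformation(np.full(14, phi), np.full(14, psi), topo14.default_chi())
        lab = assign_secondary_structure(conf, seq14)
        assert set(lab.labels) == {label}

    def test_fractions_recomputable(self, helix14):
        lab = assign_secondary_structure(helix14)
        assert lab.helix_fraction == np.mean(lab.labels == "H")
        assert lab.helix_fraction >= 12 / 14


def test_per_residue_frequency_mixture(seq14):
    helix = assign_secondary_structure(make_ideal_helix(seq14, 0, 0))
    from prionmc import make_coil
    coil = assign_secondary_structure(make_coil(seq14, 1))
    labelled = [(helix, 0)] * 5 + [(coil, 0)] * 5 + [(helix, 2)] * 4
    freq = per_residue_frequency(labelled)
    # rung 0: 50/50 helix/coil; rung 2 pure helix; rung 1 absent
    assert freq["H"].loc[112, 0] == pytest.approx(0.5)
    assert freq["H"].loc[112, 2] == pytest.approx(1.0)
    assert 1 not in freq["H"].columns
    total = freq["H"].loc[112, 0] + freq["E"].loc[112, 0] + freq["C"].loc[112, 0]
    assert total == pytest.approx(1.0)


class TestTurnTyping:
    @pytest.mark.parametrize("angles,expected", [
        ((0, 0, -60, 120, 80, 0, 0, 0), "II"),
        ((0, 0, 60, -120, -80, 0, 0, 0), "II'"),
        ((0, 0, -60, -30, -90, 0, 0, 0), "I"),
        ((0, 0, 60, 30, 90, 0, 0, 0), "I'"),
    ])
    def test_centroid_cases(self, angles, expected):
        window = np.array(angles).reshape(4, 2)
        assert classify_turn(window).turn_type == expected

    def test_large_deviation_is_irregular(self):
        window = np.array([(0, 0), (-60, 120 + 50), (80, 0), (0, 0)], float)
        assert classify_turn(window).turn_type == "irregular"

    def test_alpha_turn_window(self):
        window = np.zeros((5, 2))
        rec = classify_turn(window, residue_numbers=(113, 114, 115, 116, 117))
        assert rec.turn_type == "alpha"
        assert rec.span == (114, 116)


class TestHairpins:
    def test_constructed_single_hairpin(self, seq14):
        hp = make_hairpin(seq14, (115, 116), "II'", 0.0, 0)
        recs = detect_hairpins(hp)
        assert len(recs) == 1
        assert recs[0].order == 1
        assert recs[0].turn_spans == ((115, 116),)

    def test_turn_type_survives_refinement(self, seq14):
        from prionmc import measure_conformation
        hp = make_hairpin(seq14, (115, 116), "II'", 0.0, 0)
        conf = measure_conformation(hp)
        p = seq14.position_of(114) - 1
        window = [(conf.phi[p + k], conf.psi[p + k]) for k in range(4)]
        assert classify_turn(window).turn_type == "II'"

    def test_helix_has_no_hairpins(self, helix14):
        assert detect_hairpins(helix14) == []

    def test_double_hairpin_two_spans(self, seq21):
        d = make_multi_hairpin(seq21, [(113, 114), (119, 120)], None, 0.0, 0)
        recs = detect_hairpins(d)
        assert len(recs) == 1
        assert recs[0].order == 2
        assert recs[0].turn_spans == ((113, 114), (119, 120))

    def test_triple_hairpin(self, seq21):
        t = make_multi_hairpin(seq21, [(112, 113), (117, 118), (122, 123)],
                               None, 0.0, 0)
        recs = detect_hairpins(t)
        assert recs and recs[0].order == 3

    def test_order_equals_span_count_and_loops_inside(self, seq21):
        for spans in ([(113, 114)], [(113, 114), (119, 120)]):
            s = make_multi_hairpin(seq21, spans, None, 0.0, 1)
            recs = detect_hairpins(s)
            assert recs[0].order == len(recs[0].turn_spans)
            for (a, b), ((lo, ia), (ib, hi)) in zip(recs[0].turn_spans,
                                                    recs[0].strand_registers):
                assert ia < a <= b < ib  # loop strictly between the strands
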