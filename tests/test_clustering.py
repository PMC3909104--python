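import numpy as np
import pytest

from prionmc import (CLUSTER_CUTOFF, Frame, assign_families,
                     cluster_structures, family_percentages, family_table,
                     make_coil, make_hairpin, make_ideal_helix, pairwise_rmsd)
from prionmc.clustering import backbone_coords, classify_structure


class TestPairwiseRMSD:
    def test_identity_zero(self, helix14):
        assert pairwise_rmsd(helix14, helix14) == 0.0

    def test_rigid_motion_removed(self, seq14, helix14):
        rng = np.random.default_rng(0)
        from prionmc import measure_conformation, build_structure
        conf = measure_conformation(helix14)
        moved = build_structure(seq14, conf, frame=Frame.random(rng))
        assert pairwise_rmsd(helix14, moved) < 1e-6

    def test_agrees_with_mdtraj_oracle(self, seq14):
        """Independent superposition oracle on 100 random structure pairs."""
        md = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(5)
        structures = [make_coil(seq14, s) for s in range(20)]
        coords = np.stack([backbone_coords(s) for s in structures])
        top = md.Topology()
        ch = top.add_chain()
        res = top.add_residue("ALA", ch)
        for i in range(coords.shape[1]):
            top.add_atom(f"C{i}", md.element.carbon, res)
        traj = md.Trajectory(coords / 10.0, top)  # mdtraj uses nm
        pairs = [(int(a), int(b)) for a, b in
                 rng.integers(0, 20, size=(100, 2)) if a != b]
        for a, b in pairs:
            ours = pairwise_rmsd(coords[a], coords[b])
            ref = float(md.rmsd(traj[a], traj[b])[0]) * 10.0
            assert ours == pytest.approx(ref, abs=1e-4)

    def test_length_mismatch_rejected(self, seq14, seq21):
        with pytest.raises(ValueError):
            pairwise_rmsd(make_coil(seq14, 0), make_coil(seq21, 0))


class TestGreedyClustering:
    def test_identical_structures_one_cluster(self, helix14):
        coords = np.stack([backbone_coords(helix14)] * 10)
        cs = cluster_structures(coords, 2.5)
        assert cs.n_clusters == 1
        assert np.all(cs.assignments == 0)
        assert cs.representatives[0] == 0

    def test_isolated_structures_singletons(self, seq14):
        structures = [make_coil(seq14, s) for s in range(8)]
        coords = np.stack([backbone_coords(s) for s in structures])
        d = min(pairwise_rmsd(coords[i], coords[j])
                for i in range(8) for j in range(i + 1, 8))
        cutoff = 0.5 * d
        cs = cluster_structures(coords, cutoff)
        assert cs.n_clusters == 8

    def test_three_component_ensemble(self, seq14):
        """Helix/hairpin/coil centroids with small noise recover 3 dominant
        clusters holding >= 95% of members."""
        rng = np.random.default_rng(1)
        structures = []
        for s in range(30):
            structures.append(make_ideal_helix(seq14, 3.0, rng))
        for s in range(30):
            structures.append(make_hairpin(seq14, (115, 116), "II'", 3.0, rng))
        base = make_coil(seq14, 77)
        from prionmc import measure_conformation, build_structure
        conf0 = measure_conformation(base)
        for s in range(30):
            c = conf0.copy()
            c.phi += rng.normal(0, 3.0, 14)
            c.psi += rng.normal(0, 3.0, 14)
            structures.append(build_structure(seq14, c))
        coords = np.stack([backbone_coords(s) for s in structures])
        cs = cluster_structures(coords, 2.5)
        sizes = sorted(np.bincount(cs.assignments), reverse=True)
        assert sum(sizes[:3]) >= 0.95 * 90

    def test_invalid_cutoff(self, helix14):
        with pytest.raises(ValueError):
            cluster_structures(np.stack([backbone_coords(helix14)]), 0.0)


class TestFamilies:
    def test_helix_predicate(self, helix14):
        fam, spans = classify_structure(helix14)
        assert fam == "helix" and spans == ()

    def test_hairpin_binned_by_turn_location(self, seq14):
        fam, spans = classify_structure(make_hairpin(seq14, (114, 115), "II'", 0, 0))
        assert fam == "hairpin_113_116"
        fam, _ = classify_structure(make_hairpin(seq14, (117, 118), "II'", 0, 1))
        assert fam == "hairpin_117_119"

    def test_double_hairpin_predicate(self, seq21):
        from prionmc import make_multi_hairpin
        s = make_multi_hairpin(seq21, [(113, 114), (119, 120)], None, 0, 0)
        fam, spans = classify_structure(s)
        assert fam == "double_hairpin"
        assert len(spans) == 2

    def test_assign_families_via_representatives(self, seq14):
        structures = ([make_ideal_helix(seq14, 2.0, s) for s in range(10)]
                      + [make_coil(seq14, s) for s in range(10)])
        coords = np.stack([backbone_coords(s) for s in structures])
        cs = cluster_structures(coords, CLUSTER_CUTOFF[14])
        fa = assign_families(cs, structures)
        pct = family_percentages(fa)
        assert pct["helix"] == pytest.approx(50.0)
        assert pct["coil"] == pytest.approx(50.0)
        assert set(fa.family_set) == {"helix", "hairpin_113_116",
                                      "hairpin_117_119", "double_hairpin", "coil"}


class TestFamilyTable:
    def test_printed_row_arithmetic(self):
        """Worked example from the published 14-mer family table: 2.84% vs
        7.09% gives a 2.50-fold enrichment."""
        import pandas as pd
        fams = ["helix", "hairpin_113_116", "hairpin_117_119",
                "double_hairpin", "coil"]
        wt = pd.Series({"helix": 45.07, "hairpin_113_116": 2.84,
                        "hairpin_117_119": 2.38, "double_hairpin": 1.15,
                        "coil": 48.56})
        mt = pd.Series({"helix": 38.05, "hairpin_113_116": 7.09,
                        "hairpin_117_119": 2.07, "double_hairpin": 2.15,
                        "coil": 50.63})
        tab = family_table([wt], [mt], family_set=fams)
        assert tab.loc["hairpin_113_116", "fold_change"] == pytest.approx(2.50, abs=0.005)
        assert tab.loc["helix", "fold_change"] == pytest.approx(0.84, abs=0.005)
        assert tab["wildtype_pct"].sum() == pytest.approx(100.0, abs=0.01)

    def test_identical_ensembles_unit_fold(self):
        import pandas as pd
        p = pd.Series({"helix": 60.0, "coil": 40.0})
        tab = family_table([p], [p.copy()])
        assert np.allclose(tab["fold_change"], 1.0)

    def test_zero_wildtype_undefined(self):
        import pandas as pd
        wt = pd.Series({"helix": 100.0, "coil": 0.0})
        mt = pd.Series({"helix": 90.0, "coil": 10.0})
        tab = family_table([wt], [mt])
        assert np.isnan(tab.loc["coil", "fold_change"])
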