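"""Cluster contact maps, secondary structure, descriptors and reporting."""

import json

import numpy as np
import pytest

from omegamap.cluster import ClusterAssignment, NOISE
from omegamap.characterize import (characterize, characterize_ensemble,
                                   cluster_contact_map, cluster_descriptors,
                                   collapse_ss, end_to_end_distance,
                                   hydrogen_bond_energy, radius_of_gyration,
                                   report, secondary_structure)
from omegamap.featurize import FeatureMatrix, pair_columns
from omegamap.io import ATOM_MASSES, Conformation, Ensemble
from omegamap.fixtures import (FamilySpec, HELIX_PHI_PSI, build_chain,
                               make_ensemble)


def _random_feature_matrix(rng, n, L):
    return FeatureMatrix(rng.uniform(size=(n, L * (L - 1) // 2)),
                         pair_columns(L), "omega", "A" * L)


class TestClusterContactMap:
    def test_mean_of_two_members(self, rng):
        F = _random_feature_matrix(rng, 4, 5)
        F.values[1, 0], F.values[3, 0] = 0.2, 0.4
        m = cluster_contact_map(F, [1, 3], n=4)
        assert m.values[0, 1] == pytest.approx(0.3)
        assert m.weight == 0.5 and m.occupancy == 2
        m.validate()

    def test_identical_members_reproduce_row(self, rng):
        F = _random_feature_matrix(rng, 1, 6)
        F.values = np.repeat(F.values, 3, axis=0)
        m = cluster_contact_map(F, [0, 1, 2], n=3)
        np.testing.assert_allclose(m.values, F.row_as_map(0), atol=1e-15)
        assert m.weight == 1.0

    def test_empty_members_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            cluster_contact_map(_random_feature_matrix(rng, 3, 5), [], n=3)

    def test_requires_omega_features(self, rng):
        F = _random_feature_matrix(rng, 3, 5)
        F.feature_kind = "distance"
        with pytest.raises(ValueError, match="omega"):
            cluster_contact_map(F, [0], n=3)


class TestCharacterize:
    def test_single_cluster_weight_one(self, rng):
        F = _random_feature_matrix(rng, 8, 5)
        char = characterize(F, ClusterAssignment(np.ones(8, dtype=int)))
        assert char.K == 1
        assert char.maps[0].weight == 1.0 and char.noise_fraction == 0.0

    def test_mass_conservation_with_noise(self, rng):
        F = _random_feature_matrix(rng, 10, 5)
        labels = np.array([1, 1, 1, 1, 2, 2, 2, NOISE, NOISE, NOISE])
        char = characterize(F, ClusterAssignment(labels))
        assert sum(m.weight for m in char.maps) + char.noise_fraction == 1.0
        assert [m.occupancy for m in char.maps] == [4, 3]

    def test_merging_clusters_is_weighted_mean(self, rng):
        """The map of a merged cluster equals the occupancy-weighted mean
        of its parts (algebraic identity of the row mean)."""
        F = _random_feature_matrix(rng, 12, 6)
        a = cluster_contact_map(F, range(0, 5), n=12)
        b = cluster_contact_map(F, range(5, 12), n=12)
        merged = cluster_contact_map(F, range(0, 12), n=12)
        expected = (a.weight * a.values + b.weight * b.values) / (a.weight + b.weight)
        np.testing.assert_allclose(merged.values, expected, atol=1e-12)

    def test_mismatched_n_rejected(self, rng):
        F = _random_feature_matrix(rng, 6, 5)
        with pytest.raises(ValueError, match="disagree"):
            characterize(F, ClusterAssignment(np.ones(7, dtype=int)))


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_helix(self, helix15):
        ss = secondary_structure(helix15)
        assert set(ss[2:-2]) == {"H"}
        assert all(s == "helix" for s in collapse_ss(ss)[2:-2])

    def test_extended_chain_is_coil(self):
        ss = secondary_structure(build_chain([(-139, 135)] * 15))
        assert set(collapse_ss(ss)) == {"coil"}

    def test_hairpin_strands_and_bond_energies(self):
        """The fixture hairpin gets strand labels on its paired arms, and
        the underlying cross-strand H-bonds check out by direct evaluation
        of the electrostatic energy formula."""
        ens, _ = make_ensemble(
            [FamilySpec("hairpin", count=1, segment=(4, 17), noise=0.02)],
            "A" * 20, seed=1)
        conf = ens.conformations[0]
        ss = secondary_structure(conf)
        arms = ss[3:9] + ss[12:17]
        assert arms.count("E") >= 6
        E = hydrogen_bond_energy(conf)
        bonded = np.argwhere(E < -0.5)
        cross = [(i, j) for i, j in bonded if abs(i - j) >= 5]
        assert len(cross) >= 2
        # oracle: recompute one bond energy from atom positions
        i, j = cross[0]
        O, C, N = conf.atom("O")[i], conf.atom("C")[i], conf.atom("N")[j]
        # reconstruct H as the implementation documents
        u = conf.atom("N")[j] - conf.atom("C")[j - 1]
        v = conf.atom("N")[j] - conf.atom("CA")[j]
        u, v = u / np.linalg.norm(u), v / np.linalg.norm(v)
        H = conf.atom("N")[j] + 1.01 * (u + v) / np.linalg.norm(u + v)
        expected = 0.084 * 332 * (1 / np.linalg.norm(O - N)
                                  + 1 / np.linalg.norm(C - H)
                                  - 1 / np.linalg.norm(O - H)
                                  - 1 / np.linalg.norm(C - N))
        assert E[i, j] == pytest.approx(expected, abs=1e-12)
        assert expected < -0.5

    def test_short_chain_all_coil_with_warning(self):
        conf = build_chain([(-60, -45)] * 5)
        short = Conformation("AAAA", conf.coords[:4])
        with pytest.warns(UserWarning, match="shorter"):
            assert secondary_structure(short) == "----"

    def test_matches_independent_dssp_on_helix(self, helix15):
        """Cross-check against MDAnalysis's independent DSSP port (3-state)
        on an ideal helix written to PDB."""
        pytest.importorskip("MDAnalysis.analysis.dssp")
        import MDAnalysis as mda
        from MDAnalysis.analysis.dssp import DSSP

        from omegamap.io import write_ensemble_pdb
        import tempfile, warnings
        ens = Ensemble(helix15.sequence, [helix15])
        with tempfile.NamedTemporaryFile(suffix=".pdb") as fh:
            write_ensemble_pdb(ens, fh.name)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = mda.Universe(fh.name)
                ref = DSSP(u, guess_hydrogens=True).run().results.dssp[0]
        ours = collapse_ss(secondary_structure(helix15))
        for k in range(2, 13):
            if ref[k] == "H":
                assert ours[k] == "helix"


class TestDescriptors:
    def test_rg_matches_hand_formula(self):
        """Straight three-atom toy: mass-weighted rg from the closed form."""
        coords = np.full((5, 5, 3), np.nan)
        conf = build_chain([(-120, 120)] * 5)
        coords = conf.coords
        xyz, mass = [], []
        for slot, name in enumerate(("N", "CA", "C", "O", "CB")):
            for r in range(5):
                if np.isfinite(coords[r, slot]).all():
                    xyz.append(coords[r, slot])
                    mass.append(ATOM_MASSES[name])
        xyz, mass = np.array(xyz), np.array(mass)
        com = (mass[:, None] * xyz).sum(0) / mass.sum()
        expected = np.sqrt((mass * ((xyz - com) ** 2).sum(1)).sum() / mass.sum())
        assert radius_of_gyration(conf) == pytest.approx(expected, abs=1e-12)

        three = np.full((3, 5, 3), np.nan)
        three[:, 1, :] = [[0, 0, 0], [2, 0, 0], [4, 0, 0]]  # CA-only line
        three[:, 0], three[:, 2], three[:, 3] = three[:, 1], three[:, 1], three[:, 1]
        lineconf = Conformation("AAA", three)
        # equal masses on a 0/2/4 line, com at 2 -> rg = sqrt(8/3)
        assert radius_of_gyration(lineconf) == pytest.approx(np.sqrt(8 / 3))

    def test_identical_members_zero_spread(self, helix15):
        ens = Ensemble(helix15.sequence, [helix15] * 4)
        d = cluster_descriptors(ens, [0, 1, 2, 3])
        assert d.rg_sd == 0.0
        assert d.end_to_end_mean == pytest.approx(end_to_end_distance(helix15))
        np.testing.assert_allclose(d.ss_propensity.sum(axis=1), 1.0, atol=1e-9)

    def test_family_propensities_separate(self, table):
        """Planted helical family: > 0.8 helix propensity on its segment;
        coil family: < 0.2 there (ground-truth labels, no clustering)."""
        ens, labels = make_ensemble(
            [FamilySpec("coil", count=40),
             FamilySpec("helix_segment", count=40, segment=(8, 20))],
            "A" * 24, seed=11)
        helix_members = np.flatnonzero(labels == 1)
        coil_members = np.flatnonzero(labels == 0)
        d_helix = cluster_descriptors(ens, helix_members)
        d_coil = cluster_descriptors(ens, coil_members)
        seg = slice(8, 19)  # interior of the planted segment (1-based 9..19)
        assert d_helix.ss_propensity[seg, 0].mean() > 0.8
        assert d_coil.ss_propensity[seg, 0].mean() < 0.2


class TestReport:
    def test_report_writes_consistent_summary(self, tmp_path, table, rng):
        ens, labels = make_ensemble(
            [FamilySpec("helix_segment", count=12, segment=(5, 13)),
             FamilySpec("coil", count=8)], "A" * 16, seed=2)
        from omegamap.featurize import featurize_omega
        F = featurize_omega(ens, table)
        assignment = ClusterAssignment(np.where(labels == 0, 1, 2))
        char = characterize_ensemble(ens, F, assignment)
        summary = report(char, ens, assignment, tmp_path, n_representatives=3,
                         seed=0)
        reloaded = json.loads((tmp_path / "summary.json").read_text())
        weights = [c["weight"] for c in reloaded["clusters"]]
        assert sum(weights) + reloaded.get("noise_fraction", 0.0) == \
            pytest.approx(1.0)
        assert (tmp_path / "cluster_01_map.png").exists()
        assert (tmp_path / "cluster_01_representatives.pdb").exists()
        assert (tmp_path / "naive_binary_map.png").exists()
        # noise section omitted when there is no noise
        assert "noise_fraction" not in reloaded
        assert summary["K"] == 2
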