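"""Dataset I/O, similarity-capped and random splits, augmentation, and the
synthetic attenuation-model generator."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.DataStructs import BulkTanimotoSimilarity

from graphpka.chemgraph import bond_distances
from graphpka.data_pipeline import (
    DatasetRecord,
    Scaffold,
    Substituent,
    SyntheticSpec,
    augment,
    cluster_split,
    generate_synthetic_library,
    morgan_fingerprints,
    random_split,
    read_records,
    records_to_graphs,
    write_records,
)


class TestRecordsIO:
    def test_round_trip(self, tmp_path):
        records = [
            DatasetRecord("CCO", 15.9, None, "train"),
            DatasetRecord("CC(=O)O", 4.76, 3, "test"),
            DatasetRecord("NCC(=O)O", 2.35, 4, "none"),
        ]
        path = tmp_path / "set.csv"
        write_records(records, path)
        back, rejects = read_records(path)
        assert back == records and rejects == []

    def test_bad_smiles_rejected_not_dropped_silently(self, tmp_path):
        path = tmp_path / "set.csv"
        path.write_text(
            "smiles,pka\nCCO,15.9\nnot_a_smiles,1.0\nCN,10.6\nCS,10.5\nCO,15.5\n"
        )
        records, rejects = read_records(path)
        assert len(records) == 4
        assert len(rejects) == 1 and rejects[0]["smiles"] == "not_a_smiles"

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("smiles,pka\n")
        records, rejects = read_records(path)
        assert records == [] and rejects == []

    def test_conflicting_duplicate_keeps_first(self, tmp_path, caplog):
        path = tmp_path / "dup.csv"
        path.write_text("smiles,pka\nCCO,4.3\nOCC,4.5\n")
        with caplog.at_level("WARNING"):
            records, _ = read_records(path)
        assert len(records) == 1 and records[0].pka == 4.3
        assert "conflicting" in caplog.text


class TestClusterSplit:
    def test_near_duplicates_co_assigned(self):
        # long homologs are near-identical on circular fingerprints
        records = [DatasetRecord(s, 4.0, 0) for s in
                   ("OC(=O)CCCCCCCC", "OC(=O)CCCCCCCCC",
                    "NCCCCCCCC", "NCCCCCCCCC",
                    "SCC(F)CC", "Oc1ccc(CCl)cc1", "OC(=O)C(Br)CC(F)CF",
                    "NC(C#N)CCBr", "SC(Cl)CCC#N", "Oc1ccc(CC(F)CF)cc1")]
        fps = morgan_fingerprints([r.smiles for r in records])
        sim = BulkTanimotoSimilarity(fps[0], fps)
        assert sim[1] > 0.65  # precondition of the scenario
        labeled, _ = cluster_split(records, 0.65, 0.3, seed=0)
        assert labeled[0].split == labeled[1].split
        assert labeled[2].split == labeled[3].split

    def test_no_cross_pair_above_cap(self, small_library):
        labeled, report = cluster_split(small_library, 0.65, 0.2, seed=1)
        fps = morgan_fingerprints([r.smiles for r in labeled])
        test_i = [i for i, r in enumerate(labeled) if r.split == "test"]
        train_i = [i for i, r in enumerate(labeled) if r.split == "train"]
        worst = max(
            max(BulkTanimotoSimilarity(fps[i], [fps[j] for j in train_i]))
            for i in test_i
        )
        assert worst <= 0.65
        assert report["max_cross_similarity"] == pytest.approx(worst)

    def test_singleton_library_hits_fraction(self):
        # mutually dissimilar molecules -> split fraction ~ requested
        smiles = [
            "OC(=O)c1ccccc1", "NCCCCN", "SCC(=O)NC", "Oc1ccc(F)cc1",
            "OC(=O)C(N)CC(=O)O", "c1ccncc1", "CS(=O)(=O)N", "O=C1CCC(=O)N1",
            "BrCC(Br)CBr", "N#CCC#N", "CC(C)(C)CO", "FC(F)(F)CF",
            "c1ccc2[nH]ccc2c1", "OCC1CCCCO1", "CC1CCCC1", "ClCCl",
            "O=S(=O)(O)CC", "NC(=N)N", "CCOP(=O)(O)O", "CC(=O)CC(C)=O",
        ]
        records = [DatasetRecord(s, 5.0) for s in smiles]
        labeled, report = cluster_split(records, 0.65, 0.25, seed=0)
        assert abs(report["achieved_fraction"] - 0.25) <= 0.05

    def test_cap_bounds_rejected(self, small_library):
        with pytest.raises(ValueError):
            cluster_split(small_library, 1.0, 0.2)
        with pytest.raises(ValueError):
            cluster_split(small_library, 0.0, 0.2)

    def test_blocking_cluster_reported(self):
        # all near-duplicates: one giant cluster, 0.2 unreachable
        records = [DatasetRecord("OC(=O)" + "C" * k, 4.0) for k in range(8, 14)]
        with pytest.raises(ValueError, match="blocking cluster"):
            cluster_split(records, 0.3, 0.2, seed=0)


class TestRandomSplit:
    def test_extreme_fractions(self, small_library):
        assert all(r.split == "train"
                   for r in random_split(small_library, 0.0))
        assert all(r.split == "test"
                   for r in random_split(small_library, 1.0))

    def test_seeded_determinism(self, small_library):
        a = random_split(small_library, 0.3, seed=5)
        b = random_split(small_library, 0.3, seed=5)
        assert [r.split for r in a] == [r.split for r in b]


class TestAugment:
    def test_default_yields_fifty_copies_plus_original(self, small_graphs):
        out = augment(small_graphs[:2])
        assert len(out) == 2 * 51

    def test_zero_copies_is_identity(self, small_graphs):
        assert augment(small_graphs[:3], n_copies=0) == small_graphs[:3]

    def test_copies_carry_label_and_center(self, small_graphs):
        g = small_graphs[0]
        for copy in augment([g], n_copies=10, seed=2):
            assert copy.label == g.label
            assert copy.bond_distance[0] == 0
            assert copy.n_atoms == g.n_atoms and copy.n_edges == g.n_edges


class TestSyntheticLibrary:
    def test_unsubstituted_molecules_hit_base_pka(self):
        spec = SyntheticSpec(substituents=(), noise_sd=0.0, n_molecules=50,
                             seed=0, max_substituents=0)
        for rec in generate_synthetic_library(spec):
            heads = [s for s in spec.scaffolds
                     if rec.pka == pytest.approx(s.base_pka)]
            assert heads, f"{rec.smiles} has pKa {rec.pka} matching no scaffold"

    def test_attenuated_shift_hand_value(self):
        # one amine scaffold, one substituent of delta -1.0 at distance 3:
        # shift = -1.0 * 0.4**2 = -0.16
        spec = SyntheticSpec(
            scaffolds=(Scaffold("amine", "N", 10.6),),
            substituents=(Substituent("F", -1.0),),
            chain_lengths=(2,), attenuation=0.4, noise_sd=0.0,
            n_molecules=100, seed=0, max_substituents=1,
        )
        recs = {Chem.CanonSmiles(r.smiles): r.pka
                for r in generate_synthetic_library(spec)}
        assert recs[Chem.CanonSmiles("NCCF")] == pytest.approx(10.6 - 0.16)

    def test_shift_magnitude_decays_with_distance(self):
        spec = SyntheticSpec(
            scaffolds=(Scaffold("amine", "N", 10.6),),
            substituents=(Substituent("F", -3.0),),
            chain_lengths=(1, 2, 3, 4, 5, 6), attenuation=0.4, noise_sd=0.0,
            n_molecules=500, seed=0, max_substituents=1,
        )
        recs = {Chem.CanonSmiles(r.smiles): r.pka
                for r in generate_synthetic_library(spec)}
        shifts = [10.6 - recs[Chem.CanonSmiles("N" + "C" * k + "F")]
                  for k in range(1, 7)]
        assert all(a > b > 0 for a, b in zip(shifts, shifts[1:]))

    def test_covers_distances_one_to_seven(self):
        lib = generate_synthetic_library(SyntheticSpec(n_molecules=500, seed=3))
        seen = set()
        for rec in lib:
            mol = Chem.MolFromSmiles(rec.smiles)
            dist = bond_distances(mol, rec.center)
            for atom in mol.GetAtoms():
                if atom.GetSymbol() in ("F", "Cl", "Br"):
                    seen.add(int(dist[atom.GetIdx()]))
        assert seen.issuperset(set(range(1, 8)))

    def test_center_is_detected_ionizable_site(self, small_library):
        graphs = records_to_graphs(small_library[:30])
        assert all(g.bond_distance[0] == 0 for g in graphs)

    def test_bad_attenuation_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(attenuation=1.5)

    def test_seeded_determinism(self):
        a = generate_synthetic_library(SyntheticSpec(n_molecules=50, seed=4))
        b = generate_synthetic_library(SyntheticSpec(n_molecules=50, seed=4))
        assert a == b
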