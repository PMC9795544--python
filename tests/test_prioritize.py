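import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from oatpscreen import prioritize as pr

from .oracles import mcs_distance_oracle


def dock_frame(rows):
    return pd.DataFrame(rows, columns=["compound_id", "target", "score"])


class TestTopNByDock:
    def test_sort_order(self):
        dock = dock_frame(
            [("x", "OATP1B1", -9.0), ("y", "OATP1B1", -8.0), ("z", "OATP1B1", -9.5)]
        )
        assert pr.top_n_by_dock(dock, "G1", n=2) == ["z", "x"]

    def test_fewer_than_n_returns_all(self):
        dock = dock_frame([("x", "OATP1B3", -5.0)])
        assert pr.top_n_by_dock(dock, "G2", n=30) == ["x"]

    def test_duplicate_poses_deduped_to_best(self):
        dock = dock_frame(
            [("x", "OATP2B1", -6.0), ("x", "OATP2B1", -9.0), ("y", "OATP2B1", -8.0)]
        )
        assert pr.top_n_by_dock(dock, "G3", n=2) == ["x", "y"]

    def test_members_restriction(self):
        dock = dock_frame([("x", "OATP1B1", -9.0), ("y", "OATP1B1", -9.5)])
        assert pr.top_n_by_dock(dock, "G1", members=["x"], n=5) == ["x"]


class TestPropertyFilter:
    def test_out_of_range_removed_and_bounds_closed(self):
        ref = ["CCCCCCCCCC", "CCO"]  # AMW range spans ~46..142
        ranges = pr.property_ranges(ref)
        lo, hi = ranges["amw"]
        compounds = {
            "small": "C",                       # AMW below range -> removed
            "edge": "CCO",                      # exactly on bound -> retained
            "big": "CCCCCCCCCCCCCCCCCCCCCCCC",  # above -> removed
        }
        kept = pr.property_range_filter(compounds, ranges)
        assert kept == ["edge"]

    def test_all_inside_retained(self):
        ref = ["CCO", "CCCO", "CCCCO"]
        ranges = pr.property_ranges(ref)
        kept = pr.property_range_filter({"a": "CCCO"}, ranges)
        assert kept == ["a"]

    def test_unparseable_excluded(self):
        ranges = pr.property_ranges(["CCO"])
        assert pr.property_range_filter({"bad": "q(("}, ranges) == []


class TestMCSDistance:
    def test_identical_molecules_zero(self):
        m = Chem.MolFromSmiles("Cc1ccccc1O")
        assert pr.mcs_distance(m, Chem.MolFromSmiles("Oc1ccccc1C")) == 0.0

    def test_propane_butane(self):
        d = pr.mcs_distance(Chem.MolFromSmiles("CCC"), Chem.MolFromSmiles("CCCC"))
        assert d == pytest.approx(0.25)

    def test_dissimilar_approaches_one(self):
        d = pr.mcs_distance(Chem.MolFromSmiles("FC(F)(F)F"), Chem.MolFromSmiles("c1ccccc1"))
        assert d >= 0.8

    def test_symmetry_and_identity_on_panel(self, small_compounds):
        mols = [Chem.MolFromSmiles(c.smiles_std) for c in small_compounds[:8]]
        for i in range(len(mols)):
            assert pr.mcs_distance(mols[i], mols[i]) == 0.0
            for j in range(i + 1, len(mols)):
                dij = pr.mcs_distance(mols[i], mols[j])
                dji = pr.mcs_distance(mols[j], mols[i])
                assert dij == pytest.approx(dji)
                assert 0.0 <= dij <= 1.0

    def test_matches_bruteforce_oracle_small_pairs(self):
        pairs = [
            ("CCC", "CCCC"),
            ("CCO", "CCN"),
            ("c1ccccc1", "c1ccncc1"),
            ("c1ccccc1", "C1CCCCC1"),
        ]
        for sa, sb in pairs:
            ma, mb = Chem.MolFromSmiles(sa), Chem.MolFromSmiles(sb)
            assert pr.mcs_distance(ma, mb) == pytest.approx(mcs_distance_oracle(ma, mb))


class TestClustering:
    def test_all_close_one_cluster(self):
        D = np.full((3, 3), 0.2)
        np.fill_diagonal(D, 0)
        ca = pr.cluster_compounds(["a", "b", "c"], D, 0.5)
        assert len(ca.clusters) == 1

    def test_two_triplets(self):
        D = np.full((6, 6), 0.9)
        np.fill_diagonal(D, 0)
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i in grp:
                for j in grp:
                    if i != j:
                        D[i, j] = 0.1
        ca = pr.cluster_compounds(list("abcdef"), D, 0.5)
        assert sorted(map(sorted, ca.clusters.values())) == [list("abc"), list("def")]

    def test_all_at_point_six_singletons(self):
        D = np.full((4, 4), 0.6)
        np.fill_diagonal(D, 0)
        ca = pr.cluster_compounds(list("abcd"), D, 0.5)
        assert len(ca.clusters) == 4

    def test_nan_rejected(self):
        D = np.zeros((2, 2))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            pr.cluster_compounds(["a", "b"], D, 0.5)

    def test_cut_bounds_within_cluster_distance(self):
        """Complete linkage cut at h: every within-cluster distance <= h."""
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = int(rng.integers(4, 16))
            M = rng.random((n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0)
            ids = [f"c{i}" for i in range(n)]
            ca = pr.cluster_compounds(ids, D, 0.5)
            idx = {cid: i for i, cid in enumerate(ids)}
            for members in ca.clusters.values():
                for a in members:
                    for b in members:
                        assert D[idx[a], idx[b]] <= 0.5 + 1e-12


class TestRepresentatives:
    def test_best_dock_score_wins(self):
        dock = dock_frame([("a", "OATP1B1", -9.5), ("b", "OATP1B1", -9.0)])
        ca = pr.ClusterAssignment(labels={"a": 1, "b": 1}, cut=0.5)
        out = pr.pick_representatives(ca, dock, "G1")
        assert out.compound_ids == ["a"]

    def test_tie_broken_by_selectivity_gap(self):
        dock = dock_frame(
            [
                ("a", "OATP1B1", -9.0), ("a", "OATP1B3", -7.8),  # gap 1.2
                ("b", "OATP1B1", -9.0), ("b", "OATP1B3", -8.7),  # gap 0.3
            ]
        )
        ca = pr.ClusterAssignment(labels={"a": 1, "b": 1}, cut=0.5)
        out = pr.pick_representatives(ca, dock, "G1")
        assert out.compound_ids == ["a"]

    def test_quota_truncates_by_score(self):
        rows = [(f"c{i:02d}", "OATP2B1", -10.0 + 0.1 * i) for i in range(20)]
        dock = dock_frame(rows)
        ca = pr.ClusterAssignment(labels={f"c{i:02d}": i for i in range(20)}, cut=0.5)
        out = pr.pick_representatives(ca, dock, "G3", per_class_quota=15)
        assert len(out.compound_ids) == 15
        assert out.compound_ids[0] == "c00"  # best score first

    def test_quota_above_cluster_count_returns_all(self):
        dock = dock_frame([("a", "OATP1B1", -9.0), ("b", "OATP1B1", -8.0)])
        ca = pr.ClusterAssignment(labels={"a": 1, "b": 2}, cut=0.5)
        out = pr.pick_representatives(ca, dock, "G1", per_class_quota=15)
        assert sorted(out.compound_ids) == ["a", "b"]


class TestTanimoto:
    def test_identity_and_disjoint(self):
        a = np.zeros(16, dtype=int); a[[1, 2, 3]] = 1
        b = np.zeros(16, dtype=int); b[[2, 3, 4]] = 1
        c = np.zeros(16, dtype=int); c[[8, 9]] = 1
        assert pr.mean_tanimoto_to_reference([a], [a]) == 1.0
        assert pr.mean_tanimoto_to_reference([a], [c]) == 0.0
        assert pr.mean_tanimoto_to_reference([a], [b]) == pytest.approx(0.5)

    def test_conventions_agree_for_rectangular_sets(self):
        rng = np.random.default_rng(6)
        refs = [(rng.random(64) > 0.7).astype(int) for _ in range(5)]
        queries = [(rng.random(64) > 0.7).astype(int) for _ in range(3)]
        mom = pr.mean_tanimoto_to_reference(refs, queries, "mean_of_means")
        pooled = pr.mean_tanimoto_to_reference(refs, queries, "pooled")
        assert mom == pytest.approx(pooled)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pr.mean_tanimoto_to_reference([], [np.ones(4)])


class TestDockIO:
    def test_reader_checks_columns(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("compound_id\ttarget\tscore\nx\tOATP1B1\t-9.1\n")
        df = pr.read_dock_tsv(p)
        assert df.iloc[0]["score"] == -9.1
        p2 = tmp_path / "bad.tsv"
        p2.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError):
            pr.read_dock_tsv(p2)
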