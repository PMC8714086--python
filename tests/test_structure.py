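import dendropy
import numpy as np
import pandas as pd
import pytest

from conftest import make_ped, random_pedigree
from pedlion import (
    ar_heatmap_matrix,
    fst_dendrogram,
    pairwise_fst,
    relationship_matrix,
    relationship_pca,
    subpop_coancestry,
)
from pedlion.pedigree import PedigreeError


@pytest.fixture
def two_singleton_groups():
    ped = make_ped([("A", "0", "0", "male"), ("B", "0", "0", "female")])
    return ped, {"A": "g1", "B": "g2"}


class TestSubpopCoancestry:
    def test_unrelated_singletons(self, two_singleton_groups):
        ped, grouping = two_singleton_groups
        f = subpop_coancestry(ped, grouping)
        assert f.loc["g1", "g1"] == pytest.approx(0.5)   # self-co-ancestry (1+F)/2
        assert f.loc["g1", "g2"] == pytest.approx(0.0)

    def test_duplicated_group_labels_are_identical(self, full_sib_ped):
        grouping = {a: "x" for a in ("C", "D")} | {a + "": "x" for a in ()}
        f1 = subpop_coancestry(full_sib_ped, {"C": "x", "D": "x"})
        # the same animals under two labels: all means equal
        f2 = subpop_coancestry(full_sib_ped, {"C": "x", "D": "y"})
        assert f2.loc["x", "y"] == pytest.approx(0.25)   # full-sib kinship
        del grouping, f1

    def test_fixture_means_match_hand_average(self, full_sib_ped):
        grouping = {"C": "kids", "D": "kids", "A": "old", "B": "old"}
        f = subpop_coancestry(full_sib_ped, grouping)
        # kids: [1, .5; .5, 1]/2 mean = 0.375; cross: all a=0.5 -> c=0.25
        assert f.loc["kids", "kids"] == pytest.approx(0.375)
        assert f.loc["old", "kids"] == pytest.approx(0.25)
        assert f.loc["old", "old"] == pytest.approx(0.25)

    def test_location_column_grouping(self):
        ped = make_ped([("A", "0", "0"), ("B", "0", "0")])
        with pytest.raises(PedigreeError):
            subpop_coancestry(ped)  # no locations recorded


class TestFst:
    def test_identical_groups_have_zero_fst(self, full_sib_ped):
        # one group duplicated under two labels: f_11 = f_22 = f_12, FST = 0
        means = pd.DataFrame([[0.375, 0.375], [0.375, 0.375]],
                             index=["x", "y"], columns=["x", "y"])
        assert pairwise_fst(means).loc["x", "y"] == pytest.approx(0.0)
        # distinct full sibs differentiate slightly
        f = subpop_coancestry(full_sib_ped, {"C": "x", "D": "y"})
        assert pairwise_fst(f).loc["x", "y"] > 0

    def test_unrelated_singletons_fully_differentiated(self, two_singleton_groups):
        ped, grouping = two_singleton_groups
        fst = pairwise_fst(subpop_coancestry(ped, grouping))
        assert fst.loc["g1", "g2"] == pytest.approx(1.0)
        assert fst.loc["g1", "g1"] == 0.0

    def test_fst_decreases_as_cross_coancestry_rises(self):
        vals = []
        for f12 in (0.0, 0.2, 0.4, 0.5):
            means = pd.DataFrame([[0.5, f12], [f12, 0.5]],
                                 index=["x", "y"], columns=["x", "y"])
            vals.append(pairwise_fst(means).loc["x", "y"])
        assert vals == sorted(vals, reverse=True)
        assert vals[-1] == pytest.approx(0.0)

    def test_group_size_duplication_invariance(self, full_sib_ped):
        base = subpop_coancestry(full_sib_ped, {"C": "x", "D": "y"})
        # duplicating every animal within a group leaves the mean co-ancestry
        # matrix unchanged, hence FST unchanged: simulate via identical means
        assert pairwise_fst(base).equals(pairwise_fst(base.copy()))


class TestDendrogram:
    def test_closest_pair_joins_first(self):
        fst = pd.DataFrame(
            [[0.0, 0.02, 0.3], [0.02, 0.0, 0.3], [0.3, 0.3, 0.0]],
            index=["A", "B", "C"], columns=["A", "B", "C"])
        newick, Z = fst_dendrogram(fst)
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 rooting="force-rooted")
        ab = tree.mrca(taxon_labels=["A", "B"])
        assert {t.taxon.label for t in ab.leaf_iter()} == {"A", "B"}

    def test_zero_matrix_gives_star_at_height_zero(self):
        fst = pd.DataFrame(np.zeros((3, 3)), index=list("ABC"), columns=list("ABC"))
        _, Z = fst_dendrogram(fst)
        assert np.allclose(Z[:, 2], 0.0)

    def test_permutation_gives_isomorphic_tree(self):
        fst = pd.DataFrame(
            [[0.0, 0.02, 0.3, 0.25], [0.02, 0.0, 0.31, 0.26],
             [0.3, 0.31, 0.0, 0.05], [0.25, 0.26, 0.05, 0.0]],
            index=list("ABCD"), columns=list("ABCD"))
        n1, _ = fst_dendrogram(fst)
        perm = ["C", "A", "D", "B"]
        n2, _ = fst_dendrogram(fst.loc[perm, perm])
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions(); t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_ultrametric_heights_non_decreasing(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0.05, 0.5, size=(5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        fst = pd.DataFrame(m, index=list("ABCDE"), columns=list("ABCDE"))
        _, Z = fst_dendrogram(fst)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_missing_entries_error_names_pairs(self):
        fst = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]],
                           index=["x", "y"], columns=["x", "y"])
        with pytest.raises(PedigreeError, match="x"):
            fst_dendrogram(fst)


class TestPca:
    def test_eigen_reconstruction(self, full_sib_ped):
        ids = list(full_sib_ped.real_ids)
        pca = relationship_pca(full_sib_ped, ids, k=len(ids))
        _, A = relationship_matrix(full_sib_ped, ids)
        n = len(ids)
        J = np.eye(n) - np.ones((n, n)) / n
        B = J @ A @ J
        rec = pca.coords.to_numpy() @ pca.coords.to_numpy().T
        assert np.abs(rec - B).max() <= 1e-8

    def test_variance_fractions_sum_to_one(self, full_sib_ped):
        pca = relationship_pca(full_sib_ped, list(full_sib_ped.real_ids), k=2)
        assert pca.explained.sum() == pytest.approx(1.0)
        assert (pca.explained >= 0).all()

    def test_full_sibs_are_exchangeable_in_the_embedding(self, full_sib_ped):
        # C and D have identical ancestry, so swapping them leaves every
        # distance to a third animal unchanged (their own rows differ only in
        # the self vs sib entry, so the coordinates themselves need not match)
        pca = relationship_pca(full_sib_ped, ["A", "B", "C", "D"], k=4)
        X = pca.coords
        for other in ("A", "B"):
            d_c = np.linalg.norm(X.loc["C"] - X.loc[other])
            d_d = np.linalg.norm(X.loc["D"] - X.loc[other])
            assert d_c == pytest.approx(d_d, abs=1e-9)

    def test_two_families_separate_on_pc1(self):
        ped = make_ped([
            ("A", "0", "0", "male"), ("B", "0", "0", "female"),
            ("X", "0", "0", "male"), ("Y", "0", "0", "female"),
            ("C1", "A", "B", "male"), ("C2", "A", "B", "female"),
            ("K1", "X", "Y", "male"), ("K2", "X", "Y", "female"),
        ])
        pca = relationship_pca(ped, ["C1", "C2", "K1", "K2"], k=1)
        pc1 = pca.coords["PC1"]
        assert np.sign(pc1["C1"]) == np.sign(pc1["C2"])
        assert np.sign(pc1["K1"]) == np.sign(pc1["K2"])
        assert np.sign(pc1["C1"]) == -np.sign(pc1["K1"])

    def test_oversized_k_truncated(self, full_sib_ped):
        pca = relationship_pca(full_sib_ped, ["C", "D"], k=10)
        assert pca.k == 2


class TestHeatmap:
    def test_unrelated_founders_identity_pattern(self):
        ped = make_ped([("A", "0", "0"), ("B", "0", "0"), ("Q", "0", "0")])
        M, order = ar_heatmap_matrix(ped, ["A", "B", "Q"])
        assert np.allclose(M.to_numpy(), np.eye(3))

    def test_ordering_is_permutation_and_values_match_kinship(self, full_sib_ped):
        ids = list(full_sib_ped.real_ids)
        M, order = ar_heatmap_matrix(full_sib_ped, ids)
        assert sorted(order) == sorted(ids)
        got, A = relationship_matrix(full_sib_ped, ids)
        ref = pd.DataFrame(A, index=got, columns=got)
        assert np.allclose(M.to_numpy(), ref.loc[list(order), list(order)].to_numpy())
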