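import math

import numpy as np
import pytest

from conftest import make_ped, random_pedigree
from oracles import PathOracle
from pedlion import (
    average_relatedness,
    delta_f_from_means,
    inbreeding,
    inbreeding_classes,
    kinship_summary,
    ne_from_coancestry,
    ne_from_delta_f,
    relationship_matrix,
)
import pandas as pd

from pedlion.pedigree import PedigreeError


class TestClassicInbreedingValues:
    def test_full_sib_offspring(self, full_sib_ped):
        assert inbreeding(full_sib_ped)["E"] == pytest.approx(0.25)

    def test_half_sib_offspring(self):
        ped = make_ped([
            ("S", "0", "0", "male"), ("D1", "0", "0", "female"),
            ("D2", "0", "0", "female"), ("C", "S", "D1", "male"),
            ("K", "S", "D2", "female"), ("X", "C", "K"),
        ])
        assert inbreeding(ped)["X"] == pytest.approx(0.125)

    def test_parent_offspring_mating(self):
        ped = make_ped([
            ("S", "0", "0", "male"), ("D", "0", "0", "female"),
            ("G", "S", "D", "female"), ("X", "S", "G"),
        ])
        assert inbreeding(ped)["X"] == pytest.approx(0.25)

    def test_sire_by_inbred_daughter_matches_path_counting(self):
        # daughter's parents are full sibs, so the common-ancestor correction
        # (1 + F_a) is exercised
        ped = make_ped([
            ("A", "0", "0", "male"), ("B", "0", "0", "female"),
            ("C", "A", "B", "male"), ("D", "A", "B", "female"),
            ("E", "C", "D", "female"), ("X", "C", "E"),
        ])
        oracle = PathOracle(ped)
        F = inbreeding(ped)
        for a in ped.real_ids:
            assert F[a] == pytest.approx(oracle.F(ped.index(a)), abs=1e-12)

    def test_relationship_matrix_values(self, full_sib_ped):
        ids, A = relationship_matrix(full_sib_ped)
        pos = {a: i for i, a in enumerate(ids)}
        assert A[pos["C"], pos["A"]] == pytest.approx(0.5)
        assert A[pos["C"], pos["D"]] == pytest.approx(0.5)
        assert A[pos["E"], pos["E"]] == pytest.approx(1.25)


class TestStructuralIdentities:
    @pytest.mark.parametrize("seed", range(12))
    def test_offspring_f_equals_parental_coancestry(self, seed):
        ped = random_pedigree(np.random.default_rng(seed))
        ids, A = relationship_matrix(ped, list(ped.ids))
        pos = {a: i for i, a in enumerate(ids)}
        F = inbreeding(ped, list(ped.ids))
        for i, rec in enumerate(ped.records):
            s, d = int(ped.sire_idx[i]), int(ped.dam_idx[i])
            if s >= 0 and d >= 0:
                c = A[pos[ped.records[s].id], pos[ped.records[d].id]] / 2.0
                assert F[rec.id] == pytest.approx(c, abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matrix_is_positive_semidefinite(self, seed):
        ped = random_pedigree(np.random.default_rng(seed))
        _, A = relationship_matrix(ped)
        assert np.linalg.eigvalsh(A).min() >= -1e-8

    def test_mean_ar_equals_half_mean_of_matrix(self, full_sib_ped):
        ids, A = relationship_matrix(full_sib_ped)
        ar = average_relatedness(full_sib_ped)
        assert ar.mean() == pytest.approx(A.mean() / 2.0)


class TestAverageRelatedness:
    def test_lone_founder_only_self_term(self):
        ped = make_ped([("A", "0", "0")])
        assert average_relatedness(ped)["A"] == pytest.approx(0.5)

    def test_trio_values(self):
        ped = make_ped([("A", "0", "0", "male"), ("B", "0", "0", "female"),
                        ("C", "A", "B")])
        ar = average_relatedness(ped)
        assert ar["A"] == pytest.approx((1 + 0 + 0.5) / 6)
        assert ar["C"] == pytest.approx((0.5 + 0.5 + 1) / 6)


class TestRatesAndNe:
    def test_delta_f_zero_for_non_inbred(self):
        ped = make_ped([
            ("A", "0", "0", "male"), ("B", "0", "0", "female"),
            ("C", "0", "0", "male"), ("D", "0", "0", "female"),
            ("S", "A", "B", "male"), ("M", "C", "D", "female"),
            ("X", "S", "M"),
        ])
        s = kinship_summary(ped)
        assert s.t["X"] == pytest.approx(2.0)
        assert s.dF["X"] == pytest.approx(0.0)   # F = 0 at t > 1

    def test_delta_f_undefined_below_two_generations(self, full_sib_ped):
        s = kinship_summary(full_sib_ped)
        assert np.isnan(s.dF["C"])  # t = 1: excluded from averages

    def test_delta_f_closed_form(self):
        # F = 0.25 at t = 3: dF = 1 - 0.75^(1/2)
        assert 1 - (1 - 0.25) ** (1 / 2) == pytest.approx(0.1339746)
        ped = make_ped([
            ("A", "0", "0", "male"), ("B", "0", "0", "female"),
            ("C", "A", "B", "male"), ("D", "A", "B", "female"),
            ("E", "C", "D", "male"), ("F2", "C", "D", "female"),
            ("X", "E", "F2"),
        ])
        s = kinship_summary(ped)
        assert s.t["X"] == pytest.approx(3.0)
        assert s.dF["X"] == pytest.approx(1 - (1 - s.F["X"]) ** (1 / 2))

    def test_generation_mean_form(self):
        assert delta_f_from_means([0.0, 0.1])[0] == pytest.approx(0.1)
        steps = delta_f_from_means([0.0, 0.1, 0.19])
        assert steps[1] == pytest.approx((0.19 - 0.1) / 0.9)

    def test_ne_arithmetic(self):
        # mean dF = 0.025 -> Ne = 20; verified through a constructed pedigree
        # is exercised in the recovery tests; here the closed forms:
        assert 1.0 / (2 * 0.025) == 20.0

    def test_ne_infinite_when_no_inbreeding_accumulates(self):
        ped = make_ped([
            ("A", "0", "0", "male"), ("B", "0", "0", "female"),
            ("C", "0", "0", "male"), ("D", "A", "B", "female"),
            ("E", "C", "D", "male"),
        ], reference={"E"})
        ne, n = ne_from_delta_f(ped)
        assert math.isinf(ne) and n == 1

    def test_ne_coancestry_closed_form(self):
        # two full sibs at g=2 with c=0.25: dc = 1 - 0.75^(1/2) -> Ne
        ped = make_ped([
            ("A", "0", "0", "male"), ("B", "0", "0", "female"),
            ("C", "A", "B", "male"), ("D", "A", "B", "female"),
            ("E", "C", "D", "male"), ("G", "C", "D", "female"),
        ], reference={"E", "G"})
        ne, n_pairs = ne_from_coancestry(ped)
        c = 0.25 + 0.25 / 2  # full sibs of full-sib parents: a_EG/2 = 0.375
        dc = 1 - (1 - c) ** (1 / 2.0)
        assert n_pairs == 1
        assert ne == pytest.approx(1 / (2 * dc))

    def test_founder_pairs_excluded_from_coancestry_ne(self):
        ped = make_ped([("A", "0", "0", "male"), ("B", "0", "0", "female")],
                       reference={"A", "B"})
        with pytest.raises(PedigreeError):
            ne_from_coancestry(ped)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_ne_invariant_to_relabeling_and_row_order(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng, n_max=12)
        ids = list(ped.real_ids)
        ref = ids[len(ids) // 2:]
        mapping = {a: f"Z{k:02d}" for k, a in enumerate(reversed(ids))}

        def remap(pid):  # phantom parents stay unrecorded after relabeling
            if pid is None or ped.record(pid).is_phantom:
                return "0"
            return mapping[pid]

        rows = [(mapping[r.id], remap(r.sire), remap(r.dam), r.sex)
                for r in reversed(ped.records) if not r.is_phantom]
        ped2 = make_ped(rows, reference={mapping[a] for a in ref})
        ref2 = [mapping[a] for a in ref]
        try:
            ne1 = ne_from_delta_f(ped, ref)[0]
            ne2 = ne_from_delta_f(ped2, ref2)[0]
            assert ne1 == pytest.approx(ne2)
        except PedigreeError:
            with pytest.raises(PedigreeError):
                ne_from_delta_f(ped2, ref2)
        try:
            nc1 = ne_from_coancestry(ped, ref)[0]
            nc2 = ne_from_coancestry(ped2, ref2)[0]
            assert nc1 == pytest.approx(nc2)
        except PedigreeError:
            pass


class TestInbreedingClasses:
    def test_default_three_way_split(self):
        F = pd.Series({"a": 0.0, "b": 0.05, "c": 0.25})
        counts = inbreeding_classes(F)
        assert list(counts["count"]) == [1, 1, 1]

    def test_founders_all_in_first_class(self, full_sib_ped):
        F = inbreeding(full_sib_ped, ["A", "B", "C", "D"])
        counts = inbreeding_classes(F)
        assert counts["count"].iloc[0] == 4

    def test_by_sex_split(self):
        F = pd.Series({"a": 0.0, "b": 0.2})
        sex = pd.Series({"a": "male", "b": "female"})
        out = inbreeding_classes(F, sex)
        assert out.loc[out.index[0], "male"] == 1
        assert out.loc[out.index[-1], "female"] == 1

    def test_bad_bounds_rejected(self):
        with pytest.raises(PedigreeError):
            inbreeding_classes(pd.Series({"a": 0.1}), edges=(0.0, 0.5, 0.3, 1.0))
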