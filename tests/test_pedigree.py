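"""Pedigree construction, the circulant design, and the A matrix."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gmatrixlab.pedigree import (
    UNKNOWN,
    Pedigree,
    PedigreeError,
    additive_relationship_matrix,
    average_relatedness,
    count_pair_relationships,
    inbreeding_coefficients,
    make_circulant_design,
)

from conftest import kinship_oracle, random_pedigree


def nuclear_family(n_off=2):
    rows = [
        {"id": "S", "sire": UNKNOWN, "dam": UNKNOWN, "sex": "male",
         "generation": 0, "line": "L", "family": "p"},
        {"id": "D", "sire": UNKNOWN, "dam": UNKNOWN, "sex": "female",
         "generation": 0, "line": "L", "family": "p"},
    ]
    for k in range(n_off):
        rows.append({"id": f"O{k}", "sire": "S", "dam": "D", "sex": "unknown",
                     "generation": 1, "line": "L", "family": "f"})
    return Pedigree(pd.DataFrame(rows))


class TestCirculantDesign:
    def test_eight_families_three_matings_gives_24_crosses(self):
        plan = make_circulant_design([f"f{i}" for i in range(8)], [1, 2, 3])
        assert len(plan) == 24

    def test_each_parent_used_exactly_k_times(self):
        plan = make_circulant_design([f"f{i}" for i in range(8)], [1, 2, 3])
        # brute-force tally over the emitted plan
        dams = plan.dam_counts()
        sires = plan.sire_counts()
        assert all(dams[f"f{i}"] == 3 for i in range(8))
        assert all(sires[f"f{i}"] == 3 for i in range(8))
        assert not any(c.dam_family == c.sire_family for c in plan)

    def test_single_offset_is_pure_cycle(self):
        plan = make_circulant_design(["a", "b", "c", "d"], [1])
        assert len(plan) == 4
        assert [(c.dam_family, c.sire_family) for c in plan] == [
            ("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")
        ]

    @pytest.mark.parametrize(
        "families,offsets",
        [(3, [1, 2, 3]), (4, [1, 1]), (4, [0]), (2, [2])],
    )
    def test_infeasible_or_invalid_designs_rejected(self, families, offsets):
        with pytest.raises(PedigreeError):
            make_circulant_design([f"f{i}" for i in range(families)], offsets)


class TestPedigreeValidation:
    def test_half_specified_parentage_rejected(self):
        rows = pd.DataFrame(
            [{"id": "A", "sire": UNKNOWN, "dam": UNKNOWN, "sex": "male",
              "generation": 0, "line": "L", "family": "x"},
             {"id": "B", "sire": "A", "dam": UNKNOWN, "sex": "female",
              "generation": 1, "line": "L", "family": "y"}]
        )
        with pytest.raises(PedigreeError, match="half-specified"):
            Pedigree(rows)

    def test_cycle_rejected(self):
        rows = pd.DataFrame(
            [{"id": "A", "sire": "B", "dam": "C", "sex": "male",
              "generation": 0, "line": "L", "family": "x"},
             {"id": "B", "sire": "A", "dam": "C", "sex": "male",
              "generation": 0, "line": "L", "family": "x"},
             {"id": "C", "sire": UNKNOWN, "dam": UNKNOWN, "sex": "female",
              "generation": 0, "line": "L", "family": "x"}]
        )
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree(rows)

    def test_input_order_does_not_matter(self):
        ped = nuclear_family()
        shuffled = Pedigree(ped.table.sample(frac=1, random_state=7))
        A1, ids1 = additive_relationship_matrix(ped)
        A2, ids2 = additive_relationship_matrix(shuffled)
        lookup = {iid: k for k, iid in enumerate(ids2)}
        perm = [lookup[i] for i in ids1]
        assert np.allclose(A1, A2[np.ix_(perm, perm)])


class TestRelationshipMatrix:
    def test_founders_give_identity(self):
        rows = pd.DataFrame(
            [{"id": f"F{k}", "sire": UNKNOWN, "dam": UNKNOWN, "sex": "unknown",
              "generation": 0, "line": "L", "family": f"f{k}"} for k in range(5)]
        )
        A, _ = additive_relationship_matrix(Pedigree(rows))
        assert np.array_equal(A, np.eye(5))

    def test_textbook_nuclear_family_entries(self):
        A, ids = additive_relationship_matrix(nuclear_family())
        idx = {i: k for k, i in enumerate(ids)}
        assert A[idx["O0"], idx["O1"]] == 0.5
        assert A[idx["S"], idx["O0"]] == 0.5
        assert A[idx["O0"], idx["O0"]] == 1.0

    def test_fullsib_mating_offspring_is_inbred(self):
        ped = nuclear_family()
        t = ped.table
        t2 = pd.concat(
            [t, pd.DataFrame([{"id": "I", "sire": "O0", "dam": "O1",
                               "sex": "unknown", "generation": 2, "line": "L",
                               "family": "g"}])],
            ignore_index=True,
        )
        # O1 must be female to be a dam
        t2.loc[t2["id"] == "O1", "sex"] = "female"
        t2.loc[t2["id"] == "O0", "sex"] = "male"
        ped2 = Pedigree(t2)
        A, ids = additive_relationship_matrix(ped2)
        idx = {i: k for k, i in enumerate(ids)}
        assert A[idx["I"], idx["I"]] == pytest.approx(1.25)
        assert inbreeding_coefficients(ped2)["I"] == pytest.approx(0.25)
        f = kinship_oracle(ped2)
        assert 2 * f("I", "I") == pytest.approx(1.25)  # A_ii = 2 f(i,i)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_tabular_equals_twice_recursive_coancestry(self, seed):
        ped = random_pedigree(np.random.default_rng(seed))
        A, ids = additive_relationship_matrix(ped)
        f = kinship_oracle(ped)
        for a in range(0, len(ids), 7):
            for b in range(a, len(ids), 5):
                assert A[a, b] == pytest.approx(2 * f(ids[a], ids[b]), abs=1e-12)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_A_is_psd_with_bounded_entries(self, seed):
        ped = random_pedigree(np.random.default_rng(seed), n_gens=4)
        A, _ = additive_relationship_matrix(ped)
        assert np.linalg.eigvalsh(A).min() >= -1e-8
        assert np.all(np.diag(A) >= 1.0)
        assert A.min() >= 0.0 and A.max() <= 2.0


def circulant_two_offspring_pedigree():
    """8 founder pairs, 24 circulant crosses, 2 offspring each."""
    rows = []
    for k in range(8):
        for sex, tag in (("male", "M"), ("female", "F")):
            rows.append({"id": f"{tag}{k}", "sire": UNKNOWN, "dam": UNKNOWN,
                         "sex": sex, "generation": 0, "line": "L",
                         "family": f"fam{k}"})
    plan = make_circulant_design([str(i) for i in range(8)], [1, 2, 3])
    offspring = []
    for j, cross in enumerate(plan):
        for k in range(2):
            iid = f"c{j}o{k}"
            rows.append({"id": iid, "sire": f"M{cross.sire_family}",
                         "dam": f"F{cross.dam_family}", "sex": "unknown",
                         "generation": 1, "line": "L", "family": f"c{j}"})
            offspring.append(iid)
    return Pedigree(pd.DataFrame(rows)), offspring


class TestRelationshipCounts:
    def test_circulant_offspring_pair_counts(self):
        ped, offspring = circulant_two_offspring_pedigree()
        full, mat, pat = count_pair_relationships(ped, offspring)
        # independent brute-force enumeration over all pairs
        t = ped.table.set_index("id")
        bf = bm = bp = 0
        for a, b in itertools.combinations(offspring, 2):
            sd = t.loc[a, "dam"] == t.loc[b, "dam"]
            ss = t.loc[a, "sire"] == t.loc[b, "sire"]
            bf += sd and ss
            bm += sd and not ss
            bp += ss and not sd
        assert (full, mat, pat) == (bf, bm, bp) == (24, 96, 96)

    def test_founder_set_has_no_sib_pairs(self):
        ped, _ = circulant_two_offspring_pedigree()
        founders = [i for i in ped.ids if i.startswith(("M", "F"))]
        assert count_pair_relationships(ped, founders) == (0, 0, 0)

    def test_counts_invariant_to_id_order(self):
        ped, offspring = circulant_two_offspring_pedigree()
        assert count_pair_relationships(ped, offspring) == \
            count_pair_relationships(ped, offspring[::-1])


class TestAverageRelatedness:
    def test_two_founders(self):
        rows = pd.DataFrame(
            [{"id": "A", "sire": UNKNOWN, "dam": UNKNOWN, "sex": "male",
              "generation": 0, "line": "L", "family": "x"},
             {"id": "B", "sire": UNKNOWN, "dam": UNKNOWN, "sex": "female",
              "generation": 0, "line": "L", "family": "x"}]
        )
        assert average_relatedness(Pedigree(rows)) == 0.0

    def test_single_individual_undefined(self):
        rows = pd.DataFrame(
            [{"id": "A", "sire": UNKNOWN, "dam": UNKNOWN, "sex": "male",
              "generation": 0, "line": "L", "family": "x"}]
        )
        with pytest.raises(PedigreeError):
            average_relatedness(Pedigree(rows))

    def test_matches_kinship_oracle_on_circulant_pedigree(self):
        ped, _ = circulant_two_offspring_pedigree()
        f = kinship_oracle(ped)
        ids = ped.ids
        vals = [2 * f(a, b) for a, b in itertools.combinations(ids, 2)]
        assert average_relatedness(ped) == pytest.approx(np.mean(vals), abs=1e-12)
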