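"""Single-locus Mendel checking against an exhaustive gamete-enumeration oracle."""

import itertools

import numpy as np
import pytest

from mendelqc.io_formats import PedigreeIndividual
from mendelqc.mendel_engine import (
    check_trio,
    count_mies,
    extract_nuclear_families,
)
from mendelqc.io_formats import VariantRecord

GT_STATES = [0, 1, 2, None]


def oracle_check(father, mother, child, duo_checking=True):
    """Brute-force verdict by enumerating one gamete per parent.

    A missing parent contributes any gamete; the verdict is "unchecked"
    when the child is missing, both parents are missing, or (with duo
    checking off) either parent is missing.
    """
    if child is None:
        return "unchecked"
    if father is None and mother is None:
        return "unchecked"
    if not duo_checking and (father is None or mother is None):
        return "unchecked"
    gametes = {0: (0,), 1: (0, 1), 2: (1,), None: (0, 1)}
    possible = {
        a + b for a in gametes[father] for b in gametes[mother]
    }
    return "consistent" if child in possible else "error"


def ped(fam, iid, f, m, sex="male", col=None):
    p = PedigreeIndividual(fam, iid, f, m, sex)
    p.sample_column = col
    return p


def biallelic(pos, genotypes, info_mie=None):
    return VariantRecord(
        chrom="3",
        pos=pos,
        ref_allele="A",
        alt_alleles=["G"],
        filter_status={"PASS"},
        svm_score=None,
        info_mie=info_mie,
        genotypes=genotypes,
    )


DOSAGE_TO_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), None: None}


class TestCheckTrio:
    @pytest.mark.parametrize("duo", [True, False])
    def test_matches_enumeration_on_all_64_combinations(self, duo):
        for f, m, c in itertools.product(GT_STATES, repeat=3):
            assert check_trio(f, m, c, duo_checking=duo) == oracle_check(
                f, m, c, duo_checking=duo
            ), (f, m, c, duo)

    def test_textbook_cases(self):
        # hom-ref x hom-ref cannot produce an alt-carrying child
        assert check_trio(0, 0, 2) == "error"
        assert check_trio(0, 0, 1) == "error"
        # opposite homozygotes force a heterozygous child
        assert check_trio(0, 2, 1) == "consistent"
        assert check_trio(0, 2, 0) == "error"
        assert check_trio(0, 2, 2) == "error"
        # het x het allows anything
        for c in (0, 1, 2):
            assert check_trio(1, 1, c) == "consistent"

    def test_duo_opposite_homozygote_rule(self):
        assert check_trio(0, None, 2) == "error"
        assert check_trio(2, None, 0) == "error"
        assert check_trio(None, 2, 0) == "error"
        assert check_trio(0, None, 1) == "consistent"
        assert check_trio(1, None, 0) == "consistent"

    def test_parent_symmetry(self):
        for f, m, c in itertools.product(GT_STATES, repeat=3):
            assert check_trio(f, m, c) == check_trio(m, f, c)

    def test_masking_never_creates_error(self):
        """Setting any genotype to missing never turns consistent into error."""
        for f, m, c in itertools.product(GT_STATES, repeat=3):
            before = check_trio(f, m, c)
            for masked in ((None, m, c), (f, None, c), (f, m, None)):
                after = check_trio(*masked)
                if before == "consistent":
                    assert after != "error", (f, m, c, masked)

    def test_rejects_invalid_dosage(self):
        with pytest.raises(ValueError):
            check_trio(3, 0, 0)


class TestExtractNuclearFamilies:
    def test_trio(self):
        pedigree = [
            ped("F1", "P1", None, None, col=0),
            ped("F1", "M1", None, None, "female", col=1),
            ped("F1", "C1", "P1", "M1", col=2),
        ]
        (fam,) = extract_nuclear_families(pedigree)
        assert (fam.father, fam.mother, fam.children) == (0, 1, [2])

    def test_three_generation_splits_into_two(self):
        pedigree = [
            ped("F1", "G1", None, None, col=0),
            ped("F1", "G2", None, None, "female", col=1),
            ped("F1", "P1", "G1", "G2", col=2),
            ped("F1", "S1", None, None, "female", col=3),
            ped("F1", "C1", "P1", "S1", col=4),
        ]
        fams = extract_nuclear_families(pedigree)
        assert len(fams) == 2
        # the middle individual is child in one family and parent in the other
        children = {tuple(f.children) for f in fams}
        parents = {f.father for f in fams}
        assert (2,) in children and 2 in parents

    def test_all_founders_yield_nothing(self):
        pedigree = [ped("F1", "A", None, None, col=0),
                    ped("F1", "B", None, None, col=1)]
        assert extract_nuclear_families(pedigree) == []

    def test_ungenotyped_family_dropped(self):
        pedigree = [
            ped("F1", "P1", None, None),
            ped("F1", "M1", None, None, "female"),
            ped("F1", "C1", "P1", "M1"),
        ]
        assert extract_nuclear_families(pedigree) == []

    def test_siblings_grouped_into_one_family(self):
        pedigree = [
            ped("F1", "P1", None, None, col=0),
            ped("F1", "M1", None, None, "female", col=1),
            ped("F1", "C1", "P1", "M1", col=2),
            ped("F1", "C2", "P1", "M1", col=3),
        ]
        (fam,) = extract_nuclear_families(pedigree)
        assert fam.children == [2, 3]


class TestCountMies:
    def trio_family(self):
        pedigree = [
            ped("F1", "P1", None, None, col=0),
            ped("F1", "M1", None, None, "female", col=1),
            ped("F1", "C1", "P1", "M1", col=2),
        ]
        return extract_nuclear_families(pedigree)

    def test_single_inconsistent_variant(self):
        fams = self.trio_family()
        variants = [
            biallelic(100, [(0, 0), (0, 0), (0, 0)]),
            biallelic(200, [(0, 0), (0, 0), (1, 1)]),  # impossible child
            biallelic(300, [(0, 1), (0, 1), (1, 1)]),
        ]
        table = count_mies(variants, fams)
        assert table.native_mie.tolist() == [0, 1, 0]
        assert table.n_checked.tolist() == [1, 1, 1]

    def test_two_children_count_separately(self):
        pedigree = [
            ped("F1", "P1", None, None, col=0),
            ped("F1", "M1", None, None, "female", col=1),
            ped("F1", "C1", "P1", "M1", col=2),
            ped("F1", "C2", "P1", "M1", col=3),
        ]
        fams = extract_nuclear_families(pedigree)
        v = biallelic(100, [(0, 0), (0, 0), (1, 1), (0, 1)])
        table = count_mies([v], fams)
        assert table.native_mie.tolist() == [2]
        capped = count_mies([v], fams, per_family_cap=True)
        assert capped.native_mie.tolist() == [1]

    def test_external_counts_copied_not_recomputed(self):
        fams = self.trio_family()
        v = biallelic(100, [(0, 0), (0, 0), (0, 0)], info_mie=5)
        table = count_mies([v], fams)
        assert table.native_mie.tolist() == [0]
        assert table.counts("external").tolist() == [5]

    def test_multiallelic_input_fatal(self):
        fams = self.trio_family()
        v = VariantRecord(
            chrom="3", pos=1, ref_allele="A", alt_alleles=["G", "T"],
            filter_status={"PASS"}, svm_score=None, info_mie=None,
            genotypes=[(0, 0)] * 3,
        )
        with pytest.raises(ValueError, match="multi-allelic"):
            count_mies([v], fams)

    def test_missing_parent_column_checks_as_duo(self):
        pedigree = [
            ped("F1", "P1", None, None, col=0),
            ped("F1", "M1", None, None, "female", col=None),  # not genotyped
            ped("F1", "C1", "P1", "M1", col=1),
        ]
        fams = extract_nuclear_families(pedigree)
        v = biallelic(100, [(0, 0), (1, 1)])  # opposite homozygotes
        table = count_mies([v], fams)
        assert table.native_mie.tolist() == [1]
        trio_only = count_mies([v], fams, duo_checking=False)
        assert trio_only.native_mie.tolist() == [0]
        assert trio_only.n_checked.tolist() == [0]

    def test_details_list_flagged_pairs(self):
        fams = self.trio_family()
        variants = [
            biallelic(100, [(0, 0), (0, 0), (1, 1)]),
            biallelic(200, [(0, 1), (0, 1), (0, 0)]),
        ]
        table = count_mies(variants, fams, keep_details=True)
        assert len(table.details) == 1
        row = table.details.iloc[0]
        assert (row.variant_index, row.family_id, row.child_id) == (0, "F1", "C1")


class TestAgainstSimulatorTruth:
    def test_flagged_set_equals_obligate_truth(self, small_bundle):
        """The engine flags exactly the variants whose observed genotypes
        contain a single-locus inconsistency (per the simulator's own
        independent enumeration), and only at sites with injected errors."""
        truth = small_bundle["truth_binary"]
        flagged = small_bundle["mie"].native_mie > 0
        obligate = truth["obligate_error"].to_numpy()
        injected = truth["n_errors_injected"].to_numpy() > 0
        assert np.array_equal(flagged, obligate)
        assert not np.any(flagged & ~injected)

    def test_counts_bounded_by_checked_pairs(self, small_bundle):
        table = small_bundle["mie"]
        assert np.all(table.native_mie <= table.n_checked)
        assert np.all(table.native_mie >= 0)
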