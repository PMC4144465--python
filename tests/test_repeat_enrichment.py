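"""Repeat-membership classification, enrichment testing, and coverage."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mendelqc.io_formats import RepeatTrack, VariantRecord
from mendelqc.repeat_enrichment import (
    ContingencyTable,
    build_contingency,
    classify_variants,
    enrichment_test,
    repeat_class_composition,
    repeat_coverage,
)


def variants_at(positions, chrom="3"):
    return [
        VariantRecord(
            chrom=chrom, pos=p, ref_allele="A", alt_alleles=["G"],
            filter_status={"PASS"}, svm_score=None, info_mie=None,
            genotypes=[],
        )
        for p in positions
    ]


def track_of(*ivs):
    return RepeatTrack(
        intervals=[("3", s, e, "SINE", "AluY") for s, e in ivs]
    )


class TestClassifyVariants:
    def test_interior_and_boundaries(self):
        track = track_of((100, 200))
        flags = classify_variants(variants_at([150, 200, 201, 100]), track)
        # 1-based 200 is 0-based 199 < 200: inside; 201 is outside;
        # 1-based 100 is 0-based 99 < 100: outside
        assert flags.tolist() == [True, True, False, False]

    def test_chr_prefix_normalized_with_warning(self):
        track = RepeatTrack(intervals=[("chr3", 100, 200, "SINE", "AluY")])
        with pytest.warns(UserWarning, match="normalized"):
            flags = classify_variants(variants_at([150]), track)
        assert flags.tolist() == [True]

    @given(
        intervals=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=500),
                st.integers(min_value=1, max_value=80),
            ),
            min_size=0,
            max_size=10,
        ),
        positions=st.lists(
            st.integers(min_value=1, max_value=600), min_size=1, max_size=30
        ),
    )
    def test_matches_per_base_scan(self, intervals, positions):
        ivs = [(s, s + ln) for s, ln in intervals]
        track = track_of(*ivs)
        covered = {b for s, e in ivs for b in range(s, e)}
        flags = classify_variants(variants_at(sorted(positions)), track)
        expected = [(p - 1) in covered for p in sorted(positions)]
        assert flags.tolist() == expected


class TestEnrichmentTest:
    def test_headline_contingency_from_printed_counts(self):
        """26,745 / 13,205 / 836,713 / 728,768 gives an overwhelming
        association (p far below 2.2e-16) with OR > 1."""
        table = ContingencyTable(a=26_745, b=13_205, c=836_713, d=728_768)
        result = enrichment_test(table, method="chi_square")
        assert result.method == "chi_square"
        assert result.p_value < 2.2e-16
        assert result.odds_ratio > 1
        fisher = enrichment_test(table, method="fisher")
        assert fisher.p_value < 2.2e-16
        assert fisher.odds_ratio == result.odds_ratio

    def test_proportional_table_is_null(self):
        result = enrichment_test(ContingencyTable(10, 10, 100, 100))
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)
        assert result.odds_ratio == pytest.approx(1.0)

    def test_small_table_switches_to_fisher(self):
        table = ContingencyTable(3, 1, 2, 4)
        with pytest.warns(UserWarning, match="Fisher"):
            result = enrichment_test(table, method="chi_square")
        assert result.method == "fisher"

    def test_fisher_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals the sum of hypergeometric point
        probabilities no larger than the observed one."""
        for a, b, c, d in [(3, 1, 2, 4), (5, 0, 1, 6), (2, 8, 7, 3)]:
            result = enrichment_test(
                ContingencyTable(a, b, c, d), method="fisher"
            )
            n, row1, col1 = a + b + c + d, a + b, a + c
            dist = stats.hypergeom(n, row1, col1)
            p_obs = dist.pmf(a)
            exact = sum(
                dist.pmf(k)
                for k in range(max(0, col1 - (c + d)), min(row1, col1) + 1)
                if dist.pmf(k) <= p_obs * (1 + 1e-9)
            )
            assert result.p_value == pytest.approx(exact, rel=1e-6)

    def test_zero_margin_degenerate(self):
        result = enrichment_test(ContingencyTable(0, 0, 5, 5))
        assert result.status.startswith("degenerate")
        assert result.p_value == 1.0

    def test_chi_square_matches_scipy_reference(self):
        arr_table = ContingencyTable(120, 80, 300, 500)
        result = enrichment_test(arr_table)
        chi2, p, _, _ = stats.chi2_contingency(
            arr_table.as_array(), correction=False
        )
        assert result.statistic == pytest.approx(chi2)
        assert result.p_value == pytest.approx(p)


class TestContingencyConstruction:
    def test_margins_consistent(self):
        rng = np.random.default_rng(3)
        in_repeat = rng.random(500) < 0.4
        counts = rng.poisson(0.1, 500)
        table = build_contingency(in_repeat, counts)
        assert table.total == 500
        assert table.a + table.b == (counts > 0).sum()
        assert table.a + table.c == in_repeat.sum()

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestRepeatCoverage:
    def test_region_fully_covered(self):
        assert repeat_coverage(("3", 120, 180), track_of((100, 200))) == 100.0

    def test_union_arithmetic(self):
        track = track_of((0, 200), (100, 400))
        assert repeat_coverage(("3", 0, 1000), track) == pytest.approx(40.0)

    def test_inverted_region_fatal(self):
        with pytest.raises(ValueError):
            repeat_coverage(("3", 10, 10), track_of((0, 5)))

    @given(
        intervals=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=300),
                st.integers(min_value=1, max_value=60),
            ),
            min_size=0,
            max_size=8,
        ),
        region=st.tuples(
            st.integers(min_value=0, max_value=200),
            st.integers(min_value=1, max_value=150),
        ),
    )
    def test_matches_per_base_count(self, intervals, region):
        ivs = [(s, s + ln) for s, ln in intervals]
        start, width = region
        end = start + width
        covered = {b for s, e in ivs for b in range(s, e)}
        expected = 100.0 * len(covered & set(range(start, end))) / width
        got = repeat_coverage(("3", start, end), track_of(*ivs))
        assert got == pytest.approx(expected)

    @given(
        start=st.integers(min_value=0, max_value=100),
        length=st.integers(min_value=2, max_value=100),
        cut=st.integers(min_value=1, max_value=99),
    )
    def test_invariant_to_splitting_intervals(self, start, length, cut):
        """Splitting an interval into abutting pieces leaves coverage fixed."""
        end = start + length
        mid = start + max(1, min(length - 1, cut * length // 100))
        whole = track_of((start, end))
        split = track_of((start, mid), (mid, end))
        region = ("3", 0, 300)
        assert repeat_coverage(region, whole) == pytest.approx(
            repeat_coverage(region, split)
        )


class TestClassComposition:
    def test_single_class_is_all(self):
        track = RepeatTrack(intervals=[("3", 0, 100, "SINE", "AluY")])
        df = repeat_class_composition(track)
        assert df.loc[0, "pct_of_repeat_bases"] == 100.0

    def test_two_equal_classes(self):
        track = RepeatTrack(
            intervals=[
                ("3", 0, 100, "SINE", "AluY"),
                ("3", 200, 300, "LINE", "L1"),
            ]
        )
        df = repeat_class_composition(track)
        assert sorted(df["pct_of_repeat_bases"]) == [50.0, 50.0]

    def test_same_class_overlaps_counted_once(self):
        track = RepeatTrack(
            intervals=[
                ("3", 0, 100, "SINE", "AluY"),
                ("3", 50, 150, "SINE", "AluSx"),
                ("3", 300, 350, "LINE", "L1"),
            ]
        )
        df = repeat_class_composition(track).set_index("repeat_class")
        assert df.loc["SINE", "bases"] == 150
        assert df.loc["LINE", "bases"] == 50
        assert df.loc["SINE", "pct_of_repeat_bases"] == 75.0

    def test_unlabeled_pooled_as_other(self):
        track = RepeatTrack(intervals=[("3", 0, 10, "", ".")])
        df = repeat_class_composition(track)
        assert df.loc[0, "repeat_class"] == "other"


class TestDetectionMethodRobustness:
    def test_enrichment_direction_holds_for_both_sources(self, small_bundle):
        """Errors planted preferentially in repeats enrich both the
        native single-locus counts and the external INFO counts."""
        in_repeat = classify_variants(
            small_bundle["binary"], small_bundle["sim"].repeat_track
        )
        for source in ("native", "external"):
            table = build_contingency(
                in_repeat, small_bundle["mie"].counts(source)
            )
            result = enrichment_test(table)
            assert result.odds_ratio > 1, source
            assert result.p_value < 0.05, source
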