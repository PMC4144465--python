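"""Association of Mendelian errors with repetitive sequence.

Each analyzed variant is classified by whether its position falls inside
any repeat-track interval (point-in-interval on the VCF POS; class is
ignored for the membership call), a 2x2 contingency table of MIE status
by repeat membership is built, and independence is tested with a Pearson
chi-square (no continuity correction) or Fisher's exact test.  Helpers
compute the repeat-covered fraction of arbitrary regions (e.g. called
peaks) and the class composition of a track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import round_half_up
from .io_formats import RepeatTrack, VariantRecord, merge_intervals, normalize_chrom


def classify_variants(
    variants: Sequence[VariantRecord], track: RepeatTrack
) -> np.ndarray:
    """Boolean per-variant flag: does the site fall inside any repeat?

    A 1-based variant position p overlaps a 0-based half-open interval
    [s, e) iff s <= p-1 < e.  Chromosome labels are normalized so "3"
    and "chr3" match; a mismatch in conventions triggers a warning once.
    """
    track_chroms = {normalize_chrom(c) for c, *_ in track.intervals}
    variant_chroms = {v.chrom for v in variants}
    raw_overlap = variant_chroms & {c for c, *_ in track.intervals}
    if (
        track.intervals
        and variants
        and not raw_overlap
        and ({normalize_chrom(c) for c in variant_chroms} & track_chroms)
    ):
        warnings.warn(
            "chromosome naming differs between variants and repeat track "
            "('chr' prefix); labels were normalized for matching",
            stacklevel=2,
        )
    return np.array([track.contains(v.chrom, v.pos) for v in variants], dtype=bool)


@dataclass
class ContingencyTable:
    """2x2 table: MIE status (rows) by repeat membership (columns).

    a: variants with MIEs inside repeats;  b: with MIEs outside;
    c: without MIEs inside repeats;        d: without MIEs outside.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "in_repeat": [self.a, self.c],
                "outside_repeat": [self.b, self.d],
            },
            index=["with_mie", "without_mie"],
        )


def build_contingency(
    in_repeat: np.ndarray, mie_counts: np.ndarray
) -> ContingencyTable:
    """Cross-tabulate per-variant repeat membership with MIE presence."""
    in_repeat = np.asarray(in_repeat, dtype=bool)
    has_mie = np.asarray(mie_counts) > 0
    if len(in_repeat) != len(has_mie):
        raise ValueError("flag vectors differ in length")
    return ContingencyTable(
        a=int((has_mie & in_repeat).sum()),
        b=int((has_mie & ~in_repeat).sum()),
        c=int((~has_mie & in_repeat).sum()),
        d=int((~has_mie & ~in_repeat).sum()),
    )


@dataclass
class EnrichmentResult:
    method: str
    statistic: float  # chi-square statistic; NaN for Fisher
    p_value: float
    odds_ratio: float
    status: str = "ok"

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "odds_ratio": self.odds_ratio,
            "status": self.status,
        }


def enrichment_test(
    table: ContingencyTable,
    method: Literal["chi_square", "fisher"] = "chi_square",
) -> EnrichmentResult:
    """Test MIE status against repeat membership on a 2x2 table.

    Chi-square is Pearson's without continuity correction; when any
    expected cell falls below 5 the test auto-switches to Fisher's exact
    with a warning.  The odds ratio is (a*d)/(b*c) (inf when b*c = 0).
    A zero margin returns a no-test result with explanatory status.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return EnrichmentResult(
            method=method,
            statistic=float("nan"),
            p_value=1.0,
            odds_ratio=float("nan"),
            status="degenerate: zero margin, association untestable",
        )
    odds_ratio = (
        float("inf")
        if table.b * table.c == 0
        else (table.a * table.d) / (table.b * table.c)
    )
    if method == "chi_square":
        expected = stats.contingency.expected_freq(arr)
        if (expected < 5).any():
            warnings.warn(
                "expected cell count below 5; switching to Fisher's exact test",
                stacklevel=2,
            )
            method = "fisher"
        else:
            chi2, p, _dof, _exp = stats.chi2_contingency(arr, correction=False)
            return EnrichmentResult(
                method="chi_square",
                statistic=float(chi2),
                p_value=float(p),
                odds_ratio=odds_ratio,
            )
    _or, p = stats.fisher_exact(arr, alternative="two-sided")
    return EnrichmentResult(
        method="fisher",
        statistic=float("nan"),
        p_value=float(p),
        odds_ratio=odds_ratio,
    )


def repeat_coverage(
    region: tuple[str, int, int],
    track: RepeatTrack,
    decimals: int | None = None,
) -> float:
    """Percent of bases of a 0-based half-open region covered by repeats.

    Overlapping track intervals are merged first, so double-annotated
    bases count once.
    """
    chrom, start, end = region
    if start >= end:
        raise ValueError(f"region start {start} >= end {end}")
    covered = 0
    for _c, s, e in track.merged_intervals(chrom):
        covered += max(0, min(e, end) - max(s, start))
    pct = 100.0 * covered / (end - start)
    return round_half_up(pct, decimals) if decimals is not None else pct


def repeat_class_composition(
    track: RepeatTrack, decimals: int = 1
) -> pd.DataFrame:
    """Per-class repeat base totals and percents of all repeat bases.

    Bases are merged within each class (overlapping same-class intervals
    count once); unlabeled intervals pool under "other".  Percents are of
    the summed per-class base totals and add to 100 within rounding.
    """
    by_class: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for chrom, start, end, cls, _name in track.intervals:
        cls = cls or "other"
        by_class.setdefault(cls, {}).setdefault(
            normalize_chrom(chrom), []
        ).append((start, end))
    rows = []
    for cls in sorted(by_class):
        bases = sum(
            e - s
            for per_chrom in [by_class[cls]]
            for ivs in per_chrom.values()
            for s, e in merge_intervals(ivs)
        )
        rows.append({"repeat_class": cls, "bases": bases})
    df = pd.DataFrame(rows, columns=["repeat_class", "bases"])
    total = df["bases"].sum()
    df["pct_of_repeat_bases"] = [
        round_half_up(100.0 * b / total, decimals) if total else 0.0
        for b in df["bases"]
    ]
    return df.sort_values("bases", ascending=False, ignore_index=True)
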