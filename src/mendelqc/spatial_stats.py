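"""Spatial distribution of Mendelian errors along a chromosome.

Variants are grouped into fixed-size bins of consecutive variants
(1000 per bin by default — bins are defined by variant count, not by
basepair width), the per-bin MIE sums are tested for randomness with the
Wald-Wolfowitz runs test, and contiguous stretches of unusually high
bins are merged into peaks.

Runs test
---------
The bin sums are dichotomized around a center (median by default),
values exactly at the center are dropped, and R, the number of maximal
same-sign runs, is compared with its null distribution given n1 values
above and n2 below:

    E[R]   = 1 + 2 n1 n2 / (n1 + n2)
    Var[R] = 2 n1 n2 (2 n1 n2 - n1 - n2) / ((n1+n2)^2 (n1+n2-1))

z = (R - E[R]) / sqrt(Var[R]) is referred to the standard normal, two
sided, without continuity correction.  Few runs (z < 0) indicates
clustering.  An exact-enumeration mode is available for short series as
a verification of the normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import VariantRecord
from .mendel_engine import MieTable


@dataclass
class Bin:
    start_pos: int  # 1-based position of the first variant in the bin
    end_pos: int  # 1-based position of the last variant
    n_variants: int
    mie_sum: int


@dataclass
class BinSeries:
    chrom: str
    bin_size: int
    bins: list[Bin]

    def mie_sums(self) -> np.ndarray:
        return np.array([b.mie_sum for b in self.bins], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start_pos": [b.start_pos for b in self.bins],
                "end_pos": [b.end_pos for b in self.bins],
                "n_variants": [b.n_variants for b in self.bins],
                "mie_sum": [b.mie_sum for b in self.bins],
            }
        )


def bin_mies(
    variants: Sequence[VariantRecord],
    mie_table: MieTable,
    bin_size: int = 1000,
    source: str = "native",
    indices: np.ndarray | None = None,
) -> BinSeries:
    """Sum MIEs over consecutive blocks of ``bin_size`` variants.

    All bins except possibly the last hold exactly ``bin_size`` variants;
    each bin's genomic span is [first variant pos, last variant pos].
    The input must be position-sorted and from a single chromosome.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    variants = list(variants)
    if not variants:
        return BinSeries(chrom="", bin_size=bin_size, bins=[])
    chroms = {v.chrom for v in variants}
    if len(chroms) > 1:
        raise ValueError(f"variants span multiple chromosomes: {sorted(chroms)}")
    positions = [v.pos for v in variants]
    if positions != sorted(positions):
        raise ValueError("variants are not position-sorted")
    counts = mie_table.counts(source)
    if indices is not None:
        counts = counts[np.asarray(indices, dtype=np.int64)]
    if len(counts) != len(variants):
        raise ValueError("MIE table does not cover the variant list")
    bins = []
    for start in range(0, len(variants), bin_size):
        block = slice(start, min(start + bin_size, len(variants)))
        bins.append(
            Bin(
                start_pos=positions[block.start],
                end_pos=positions[block.stop - 1],
                n_variants=block.stop - block.start,
                mie_sum=int(counts[block].sum()),
            )
        )
    return BinSeries(chrom=variants[0].chrom, bin_size=bin_size, bins=bins)


@dataclass
class RunsTestResult:
    n_runs: int
    n_above: int
    n_below: int
    expected_runs: float
    variance_runs: float
    z_score: float
    p_value: float
    status: str = "ok"  # "degenerate" when all values fall on one side

    @property
    def valid(self) -> bool:
        return self.status == "ok"

    def as_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "n_above": self.n_above,
            "n_below": self.n_below,
            "expected_runs": self.expected_runs,
            "variance_runs": self.variance_runs,
            "z_score": self.z_score,
            "p_value": self.p_value,
            "status": self.status,
        }


def _count_runs(signs: np.ndarray) -> int:
    return int(1 + np.sum(signs[1:] != signs[:-1])) if len(signs) else 0


def runs_test(
    series: Sequence[float],
    center: Literal["median", "mean"] = "median",
) -> RunsTestResult:
    """Wald-Wolfowitz runs test for randomness of a numeric series.

    Values equal to the center are dropped before dichotomizing.  Returns
    a degenerate no-test result (p = 1, status set) when fewer than two
    values remain or all fall on one side of the center.
    """
    x = np.asarray(series, dtype=float)
    c = np.median(x) if center == "median" else np.mean(x)
    x = x[x != c]
    signs = x > c
    n1 = int(signs.sum())
    n2 = int(len(signs) - n1)
    if n1 == 0 or n2 == 0:
        return RunsTestResult(
            n_runs=_count_runs(signs),
            n_above=n1,
            n_below=n2,
            expected_runs=float("nan"),
            variance_runs=float("nan"),
            z_score=float("nan"),
            p_value=1.0,
            status="degenerate: all values on one side of the center",
        )
    r = _count_runs(signs)
    n = n1 + n2
    expected = 1.0 + 2.0 * n1 * n2 / n
    variance = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1))
    if variance <= 0:  # only for n1 = n2 = 1: the null is a point mass
        return RunsTestResult(
            n_runs=r, n_above=n1, n_below=n2, expected_runs=expected,
            variance_runs=variance, z_score=float("nan"), p_value=1.0,
            status="degenerate: null run-count distribution has no spread",
        )
    z = (r - expected) / np.sqrt(variance)
    p = 2.0 * stats.norm.sf(abs(z))
    return RunsTestResult(
        n_runs=r,
        n_above=n1,
        n_below=n2,
        expected_runs=expected,
        variance_runs=variance,
        z_score=float(z),
        p_value=float(min(p, 1.0)),
    )


def runs_pmf(n1: int, n2: int) -> dict[int, float]:
    """Exact null distribution of the run count given n1 above / n2 below.

    Closed-form combinatorial probabilities; useful for verifying the
    normal approximation on short series (and exactly matches brute-force
    enumeration of all C(n1+n2, n1) arrangements).
    """
    total = comb(n1 + n2, n1)
    pmf: dict[int, float] = {}
    for r in range(2, n1 + n2 + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * comb(n1 - 1, k - 1) * comb(n2 - 1, k - 1)
        else:
            k = (r - 1) // 2
            ways = comb(n1 - 1, k) * comb(n2 - 1, k - 1) + comb(
                n1 - 1, k - 1
            ) * comb(n2 - 1, k)
        if ways:
            pmf[r] = ways / total
    return pmf


def runs_test_exact_p(n_runs: int, n1: int, n2: int) -> float:
    """Two-sided exact p-value: P(|R - E[R]| >= |observed - E[R]|)."""
    pmf = runs_pmf(n1, n2)
    expected = 1.0 + 2.0 * n1 * n2 / (n1 + n2)
    dev = abs(n_runs - expected)
    return float(
        min(1.0, sum(p for r, p in pmf.items() if abs(r - expected) >= dev - 1e-12))
    )


@dataclass
class Peak:
    peak_id: int
    bin_start: int  # first qualifying bin index (0-based, inclusive)
    bin_end: int  # last qualifying bin index (inclusive)
    start_pos: int
    end_pos: int
    total_mie: int
    threshold_used: float

    def as_dict(self) -> dict:
        return {
            "peak": self.peak_id,
            "bin_start": self.bin_start,
            "bin_end": self.bin_end,
            "start_pos": self.start_pos,
            "end_pos": self.end_pos,
            "total_mie": self.total_mie,
            "threshold": self.threshold_used,
        }


def call_peaks(series: BinSeries, k_sd: float = 3.0) -> list[Peak]:
    """Merge adjacent bins whose MIE sum exceeds mean + k_sd * SD into peaks.

    Peaks are ordered by genomic position and numbered from 1.  A flat
    series (SD = 0) yields no peaks for any positive ``k_sd``.
    """
    if not series.bins:
        return []
    sums = series.mie_sums().astype(float)
    threshold = float(sums.mean() + k_sd * sums.std(ddof=0))
    above = sums > threshold
    peaks: list[Peak] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            peaks.append(
                Peak(
                    peak_id=len(peaks) + 1,
                    bin_start=i,
                    bin_end=j,
                    start_pos=series.bins[i].start_pos,
                    end_pos=series.bins[j].end_pos,
                    total_mie=int(sums[i : j + 1].sum()),
                    threshold_used=threshold,
                )
            )
            i = j + 1
        else:
            i += 1
    return peaks


_PEAK_COLUMNS = [
    "peak", "bin_start", "bin_end", "start_pos", "end_pos",
    "total_mie", "threshold",
]


def peaks_table(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame([p.as_dict() for p in peaks], columns=_PEAK_COLUMNS)
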