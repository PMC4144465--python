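"""The QC filter cascade and SVM-threshold sweep.

Filtering runs in a fixed order, tracking a count after every stage:

1. FILTER-column gate — drop records whose FILTER lists a failing filter
   (e.g. a caller's ``SVM`` flag, set when the score is negative, or an
   ``INDEL5`` proximity flag);
2. multi-allelic exclusion — drop sites with more than one ALT allele
   (these carry an inherently high Mendelian-error load);
3. score threshold — keep records with quality score strictly above a
   configurable cutoff (the threshold-sweep mechanism; distinct from the
   FILTER-column gate, which encodes the caller's own score<0 rule).

Summaries mirror the standard per-dataset QC table: variant count, total
MIE count, mean MIEs per variant, per-variant MIE range, and the count and
percent of variants carrying at least one MIE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .io_formats import VariantRecord
from .mendel_engine import MieTable

MieSource = Literal["native", "external"]


@dataclass
class FilterConfig:
    require_pass: bool = True
    drop_multiallelic: bool = True
    svm_threshold: float | None = None  # keep svm_score > threshold (strict)
    mie_source: MieSource = "native"
    drop_missing_svm: bool = True  # under an active threshold, records with
    # no score fail the gate (unknown quality fails a quality gate)


@dataclass
class FilterStage:
    label: str
    n_after: int
    n_removed: int
    pct_reduction: float  # percent removed relative to the previous stage


@dataclass
class FilterResult:
    variants: list[VariantRecord]
    kept_indices: np.ndarray  # positions in the input list
    stages: list[FilterStage]

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.label,
                    "n_after": s.n_after,
                    "n_removed": s.n_removed,
                    "pct_reduction": s.pct_reduction,
                }
                for s in self.stages
            ]
        )


def percent_reduction(n_before: int, n_after: int, decimals: int = 1) -> float:
    """Percent of records removed going from ``n_before`` to ``n_after``."""
    if n_before == 0:
        return 0.0
    return round_half_up(100.0 * (n_before - n_after) / n_before, decimals)


def apply_filters(
    variants: Sequence[VariantRecord],
    config: FilterConfig,
    pct_decimals: int = 1,
) -> FilterResult:
    """Run the filter cascade, logging a count after every stage."""
    idx = np.arange(len(variants))
    current = list(variants)
    stages = [FilterStage("input", len(current), 0, 0.0)]

    def _apply(label: str, keep_mask: list[bool]) -> None:
        nonlocal current, idx
        n_before = len(current)
        keep = np.asarray(keep_mask, dtype=bool)
        current = [v for v, k in zip(current, keep) if k]
        idx = idx[keep]
        stages.append(
            FilterStage(
                label,
                len(current),
                n_before - len(current),
                percent_reduction(n_before, len(current), pct_decimals),
            )
        )

    if config.require_pass:
        _apply("pass_filters", [v.passes_filters for v in current])
    if config.drop_multiallelic:
        _apply("binary_only", [v.is_binary for v in current])
    if config.svm_threshold is not None:
        scores = [v.svm_score for v in current]
        if current and all(s is None for s in scores):
            raise ValueError(
                "svm_threshold is set but no record carries a score; "
                "the threshold cannot act"
            )
        t = config.svm_threshold
        if config.drop_missing_svm:
            keep = [s is not None and s > t for s in scores]
        else:
            keep = [s is None or s > t for s in scores]
        _apply(f"svm_gt_{t:g}", keep)
    return FilterResult(variants=current, kept_indices=idx, stages=stages)


@dataclass
class QcSummaryRow:
    """One row of the per-dataset MIE summary table.

    ``mie_per_variant`` and ``pct_variants_with_mie`` are half-up rounded
    at the precision requested from :func:`summarize`.
    """

    label: str
    n_variants: int
    n_mie: int
    mie_per_variant: float
    mie_range: tuple[int, int]
    n_variants_with_mie: int
    pct_variants_with_mie: float

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "n_variants": self.n_variants,
            "n_mie": self.n_mie,
            "mie_per_variant": self.mie_per_variant,
            "mie_min": self.mie_range[0],
            "mie_max": self.mie_range[1],
            "n_variants_with_mie": self.n_variants_with_mie,
            "pct_variants_with_mie": self.pct_variants_with_mie,
        }


def summary_from_counts(
    label: str,
    n_variants: int,
    n_mie: int,
    n_variants_with_mie: int = 0,
    mie_range: tuple[int, int] = (0, 0),
    ratio_decimals: int = 2,
    pct_decimals: int = 2,
) -> QcSummaryRow:
    """Build a summary row from pre-tallied integers (exact arithmetic).

    mean MIEs/variant = n_mie / n_variants and
    percent with MIE = 100 * n_variants_with_mie / n_variants,
    both half-up rounded; zero variants yields a row of zeros.
    """
    if n_variants == 0:
        return QcSummaryRow(label, 0, 0, 0.0, (0, 0), 0, 0.0)
    return QcSummaryRow(
        label=label,
        n_variants=n_variants,
        n_mie=n_mie,
        mie_per_variant=round_half_up(n_mie / n_variants, ratio_decimals),
        mie_range=mie_range,
        n_variants_with_mie=n_variants_with_mie,
        pct_variants_with_mie=round_half_up(
            100.0 * n_variants_with_mie / n_variants, pct_decimals
        ),
    )


def summarize(
    variants: Sequence[VariantRecord],
    mie_table: MieTable,
    label: str,
    source: MieSource = "native",
    indices: np.ndarray | None = None,
    ratio_decimals: int = 2,
    pct_decimals: int = 2,
) -> QcSummaryRow:
    """Tally MIE content over ``variants`` using one detection source.

    ``mie_table`` must be aligned with the original variant list the table
    was computed from; ``indices`` selects the surviving subset (defaults
    to all rows, i.e. ``variants`` is that original list).
    """
    counts = mie_table.counts(source)
    if indices is not None:
        counts = counts[np.asarray(indices, dtype=np.int64)]
    if len(counts) != len(variants):
        raise ValueError(
            f"MIE table covers {len(counts)} variants but {len(variants)} given"
        )
    n_variants = len(variants)
    if n_variants == 0:
        return summary_from_counts(label, 0, 0)
    return summary_from_counts(
        label=label,
        n_variants=n_variants,
        n_mie=int(counts.sum()),
        n_variants_with_mie=int((counts > 0).sum()),
        mie_range=(int(counts.min()), int(counts.max())),
        ratio_decimals=ratio_decimals,
        pct_decimals=pct_decimals,
    )


def svm_sweep(
    variants: Sequence[VariantRecord],
    mie_table: MieTable,
    thresholds: Sequence[float],
    source: MieSource = "native",
    drop_missing_svm: bool = True,
    ratio_decimals: int = 2,
    pct_decimals: int = 2,
) -> list[QcSummaryRow]:
    """Summarize MIE content after each score threshold in turn.

    Per-variant MIE counts are subset, not recomputed, at each threshold.
    ``n_variants`` is guaranteed weakly decreasing across ascending
    thresholds (subset law); the error metrics usually follow when the
    score is informative, but that is a property of the data.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in thresholds:
        config = FilterConfig(
            require_pass=False,
            drop_multiallelic=False,
            svm_threshold=float(t),
            drop_missing_svm=drop_missing_svm,
        )
        result = apply_filters(variants, config)
        rows.append(
            summarize(
                result.variants,
                mie_table,
                label=f"SVM >{t:g}",
                source=source,
                indices=result.kept_indices,
                ratio_decimals=ratio_decimals,
                pct_decimals=pct_decimals,
            )
        )
    return rows


def summary_table(rows: Sequence[QcSummaryRow]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in rows])
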