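"""Small shared helpers: half-up rounding and transparent gzip I/O."""

from __future__ import annotations

import gzip
import io
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties going away from zero, as printed tables do.

    Python's builtin ``round`` is banker's rounding; published tables
    use half-up, so 2.5% style percents must not fall to 2.4.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def open_text(path: str | Path, mode: str = "rt"):
    """Open plain or gzip-compressed text transparently (by suffix)."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return io.open(path, mode)
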