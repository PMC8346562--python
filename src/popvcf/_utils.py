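"""Small shared helpers: rounding and chromosome naming conventions."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables).

    Python's built-in ``round`` is banker's rounding; frequencies and
    percentages reported at a fixed number of decimals use half-up instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up_int(x: float) -> int:
    """Nearest integer, ties rounded up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def normalize_chrom(chrom: str) -> str:
    """Strip common chromosome-name prefixes (``chr``, ``ECA``)."""
    c = chrom
    for prefix in ("chr", "Chr", "CHR", "ECA", "eca"):
        if c.startswith(prefix):
            c = c[len(prefix):]
            break
    return c


def is_autosome(chrom: str) -> bool:
    """True for numerically named chromosomes (1..N); X/Y/MT are not."""
    return normalize_chrom(chrom).isdigit()


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Natural chromosome order: numeric ascending, then X, Y, MT, then others."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 0, "Y": 1, "MT": 2, "M": 2}
    if c.upper() in special:
        return (1, special[c.upper()], "")
    return (2, 0, c)
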