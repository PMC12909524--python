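"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

MISSING_TOKEN = "NA"


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero, as diversity tables are printed.

    Python's built-in ``round`` is banker's rounding; report layers here use
    half-up so 0.3745 prints as 0.375.
    """
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def spawn_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Accept a seed or a Generator and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def normalize_genotype(cell: object) -> str | None:
    """Canonicalise a genotype cell to a sorted two-letter string or None.

    Unordered allele pairs: "GA" and "AG" are the same call. Missing values
    (None, NaN, "", "NA", "./.") map to None.
    """
    if cell is None:
        return None
    if isinstance(cell, float) and np.isnan(cell):
        return None
    s = str(cell).strip().upper()
    if s in ("", MISSING_TOKEN, "NAN", "./.", ".", "--"):
        return None
    s = s.replace("/", "").replace("|", "")
    if len(s) != 2 or not s.isalpha():
        raise ValueError(f"malformed genotype cell: {cell!r}")
    return "".join(sorted(s))
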