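"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Python's built-in ``round`` uses banker's rounding; published
    pharmacovigilance tables conventionally round half up, so displayed
    statistics go through this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fold(s: str) -> str:
    """Case-fold and collapse internal whitespace, for name/PT matching."""
    return " ".join(s.split()).casefold()
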