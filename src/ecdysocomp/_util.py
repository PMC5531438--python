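"""Small numeric helpers with the package's fixed rounding conventions."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, the convention used for every printed
    ratio and percentage (Python's builtin round is banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(n: int, total: int, ndigits: int = 1) -> float:
    """100*n/total rounded half-up to `ndigits` decimals."""
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    return round_half_up(100.0 * n / total, ndigits)
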