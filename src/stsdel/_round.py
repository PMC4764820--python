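"""Half-up decimal rounding used for every reported mean and percentage."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` half-up to ``ndigits`` decimal places.

    Python's builtin ``round`` is banker's rounding; reported one-decimal
    summary figures use the conventional half-up rule instead (0.25 -> 0.3).
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
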