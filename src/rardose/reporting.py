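"""Report-layer number formatting.

Computation never rounds; rounding happens once, here, when a table is
rendered.  Values are rounded half-away-from-zero on their shortest
decimal representation, so a factor that is exactly 0.485 in decimal
arithmetic prints as 0.49 even though the nearest binary double sits a
hair below the tie.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away", "fmt"]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals.

    Operates on ``repr(x)`` (the shortest decimal string that round-trips
    to ``x``) so decimal ties arising from decimal inputs round the way a
    hand calculation would.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt(x: float, ndigits: int = 2) -> str:
    """Format with half-away-from-zero rounding at ``ndigits`` decimals."""
    return f"{round_half_away(x, ndigits):.{ndigits}f}"
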