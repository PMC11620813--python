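"""Display rounding used at the reporting boundary.

All index computations run at full float precision; rounding happens only
when a value is *reported* (tables, CSV output, summaries).  Two conventions
are provided:

``round_half_up``
    Conventional decimal half-up rounding (0.6545… -> 0.655 at 3 decimals),
    as opposed to the round-half-even used by Python's builtin ``round``.

``round_chain``
    Sequential half-up rounding through a chain of precisions, e.g.
    ``round_chain(25.4545, 1, 0) == 26`` (25.4545 -> 25.5 -> 26).  Percentage
    columns in legacy spreadsheet workflows are frequently produced this way:
    the value is first formatted to one decimal and the *displayed* value is
    then rounded to an integer, which differs from direct integer rounding
    for inputs ending in .45–.49.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero."""
    if value != value:  # NaN propagates
        return value
    quantum = Decimal(1).scaleb(-ndigits)
    out = Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(out)


def round_chain(value: float, *ndigits: int) -> float:
    """Apply :func:`round_half_up` repeatedly through decreasing precisions."""
    out = float(value)
    for nd in ndigits:
        out = round_half_up(out, nd)
    return out
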