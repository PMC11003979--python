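"""Half-up decimal rounding used for report rendering.

Summary tables print values at one decimal with conventional (half-up)
rounding; Python's built-in ``round`` rounds half to even and cannot
reproduce them. Internal computation always stays at full precision —
rounding is applied only at the reporting edge.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` half away from zero at ``ndigits`` decimal places.

    The shortest-repr decimalisation of the float is rounded, so values
    that print as exact halves (e.g. ``1.175``) round up the way a table
    typeset from decimal data would.
    """
    x = float(x)
    if x != x or x in (float("inf"), float("-inf")):  # NaN/inf pass through
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
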