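"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away_from_zero(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (2.5 -> 3, -2.5 -> -3).

    Python's built-in ``round`` uses banker's rounding, which does not match
    how the summary tables in this package display values.
    """
    factor = 10.0**decimals
    scaled = x * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor
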