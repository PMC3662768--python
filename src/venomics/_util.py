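"""Small shared helpers."""

from __future__ import annotations

import math


def percent(numerator: float, denominator: float) -> int:
    """Integer percentage, rounding half away from zero.

    Matches the presentation of the report tables (e.g. 21625/49972 -> 43).
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))
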