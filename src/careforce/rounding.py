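"""Rounding conventions for person counts.

All head-count quantities are rounded *half-up* at the operation boundary
(2.5 -> 3, never banker's rounding); internal FTE arithmetic stays in
floating point so that the yearly state fold does not accumulate drift.
"""

from __future__ import annotations

import math

__all__ = ["round_half_up"]


def round_half_up(x: float) -> int:
    """Round a non-negative quantity to the nearest integer, halves up.

    Python's built-in ``round`` uses banker's rounding (76.5 -> 76), which
    does not match workforce accounting practice; ``floor(x + 0.5)`` does.
    """
    if x < 0:
        raise ValueError(f"person counts must be non-negative, got {x}")
    return math.floor(x + 0.5)
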