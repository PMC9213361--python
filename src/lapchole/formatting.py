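"""Publication-style rendering helpers.

The source report's tables are consistent with truncation (floor) to two
decimals rather than rounding — e.g. 2/123 is printed 1.62% and 4/162 is
printed 2.46%.  Renderers here truncate; computations elsewhere always keep
full precision.
"""

from __future__ import annotations

import math

__all__ = ["trunc2", "pct2", "format_p"]

_EPS = 1e-9  # guards against 0.57*100 == 56.999999999999996


def trunc2(x: float) -> float:
    """Truncate toward zero to two decimals (0.6303 -> 0.63, 8.0246 -> 8.02)."""
    return math.floor(x * 100.0 + _EPS) / 100.0 if x >= 0 else -trunc2(-x)


def pct2(count: int, denom: int) -> float:
    """100*count/denom truncated to two decimals."""
    return trunc2(100.0 * count / denom)


def format_p(p: float, floor: float = 0.001) -> str:
    """Render a p-value the way clinical tables do: '< 0.001' below the floor."""
    if p < floor:
        return f"< {floor:g}"
    return f"{p:.3f}"
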