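"""Small shared helpers."""

from __future__ import annotations


def percent(count: int, total: int, ndigits: int = 0) -> float:
    """Percentage of ``count`` out of ``total`` at the requested rounding.

    ``percent(598, 3723)`` -> 16.0; ``percent(12, 3723, 1)`` -> 0.3.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    return round(100.0 * count / total, ndigits)
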