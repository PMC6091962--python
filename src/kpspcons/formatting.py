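"""Proportion rendering matching the published tables.

Percentages are truncated (not rounded) at the printed precision — e.g.
8/9 renders "88.8%", 1951/3059 renders "63.7%" — computed in integer
arithmetic so the rendering is exact.  A zero denominator renders "N/A".
"""

from __future__ import annotations


def truncate_percent(numerator: int, denominator: int, decimals: int = 1) -> str:
    """``100 * numerator / denominator`` truncated to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    if numerator < 0 or denominator < 0:
        raise ValueError("counts must be non-negative")
    scale = 10 ** decimals
    units = (100 * scale * numerator) // denominator
    if decimals == 0:
        return str(units)
    whole, frac = divmod(units, scale)
    return f"{whole}.{frac:0{decimals}d}"


def format_proportion(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Render ``"X/Y (P%)"``; ``0/0`` (or any Y=0) renders ``"0/0 (N/A)"``."""
    if denominator == 0:
        return f"{numerator}/{denominator} (N/A)"
    return f"{numerator}/{denominator} ({truncate_percent(numerator, denominator, decimals)}%)"
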