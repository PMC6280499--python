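"""Rounding and formatting helpers shared by report tables.

Percents are rounded half-up, sequentially: first to two decimals, then to
one. Study reports in this domain are typically assembled from spreadsheets
that display hundredths of a percent, so the published one-decimal figure is
the half-up rounding of that two-decimal intermediate rather than of the raw
ratio (e.g. 144/508 = 28.3465% -> 28.35 -> 28.4). Sequential rounding
reproduces such tables exactly; plain one-step rounding does not.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "round_percent", "fmt_percent", "fmt_ci"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` half away from zero (ties up) to ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_percent(pct: float) -> float:
    """Round a percent to one decimal via the two-decimal intermediate."""
    return round_half_up(round_half_up(pct, 2), 1)


def fmt_percent(pct: float) -> str:
    return f"{round_percent(pct):.1f}"


def fmt_ci(low_pct: float, high_pct: float) -> str:
    return f"{round_percent(low_pct):.1f}–{round_percent(high_pct):.1f}"
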