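"""Small shared reporting helpers."""

from __future__ import annotations

__all__ = ["percent"]


def percent(numerator: float, denominator: float) -> float:
    """100 x numerator / denominator (the pipeline's summary-ratio form)."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator in percentage")
    return 100.0 * numerator / denominator
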