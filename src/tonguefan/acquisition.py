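"""Acquisition-timing helpers (metadata-level; no signal processing)."""

from __future__ import annotations

__all__ = ["worst_case_frame_misalignment_ms"]


def worst_case_frame_misalignment_ms(scan_rate_hz: float, ndigits: int = 2) -> float:
    """Worst-case within-frame temporal misalignment ("tearing"), in ms.

    Content grabbed from the top versus the bottom of a frame can differ
    in time by at most one acquisition period, ``1000 / scan_rate_hz``
    milliseconds, rounded to ``ndigits`` decimals.
    """
    if scan_rate_hz <= 0:
        raise ValueError("scan rate must be positive")
    return round(1000.0 / scan_rate_hz, ndigits)
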