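"""Small shared helpers."""

from __future__ import annotations

import math


def round_sig(x: float, n: int = 2) -> float:
    """Round ``x`` to ``n`` significant figures (0 and non-finite pass through)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, n - 1 - int(math.floor(math.log10(abs(x)))))
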