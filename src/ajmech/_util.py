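"""Small shared numerics helpers."""

from __future__ import annotations

import numpy as np


def sanitize_f(F, p) -> tuple[float, float]:
    """Clamp a one-way-ANOVA result against floating-point cancellation.

    Identical groups can yield a tiny negative F (and NaN p) from the
    between-group sum of squares cancelling; that is F = 0, p = 1.
    """
    F = float(F)
    p = float(p)
    if F < 0.0 and F > -1e-9:
        F = 0.0
    if not np.isfinite(p) and F == 0.0:
        p = 1.0
    return F, p
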