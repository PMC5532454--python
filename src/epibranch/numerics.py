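"""Shared numerical primitives."""

from __future__ import annotations

import numpy as np

__all__ = ["exp_diff"]


def exp_diff(a, b, t):
    """Divided exponential difference ``(e^{at} - e^{bt}) / (a - b)``.

    Every "denominator equals zero" limit in the closed-form moment
    formulas is an instance of this function at ``a = b``, where the value
    is ``t e^{at}``.  Evaluated in the numerically stable form

        t * exp((a+b)t/2) * sinh(x)/x,   x = (a-b)t/2,

    which is continuous in (a, b) and loses no precision as ``a -> b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t = np.asarray(t, dtype=float)
    x = 0.5 * (a - b) * t
    # sinh(x)/x with its removable singularity at 0; overflow to inf for
    # extreme rate combinations is deliberate (callers reject non-finite
    # variances), so the warnings are silenced
    small = np.abs(x) < 1e-4
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratio = np.where(small, 1.0 + x * x / 6.0 * (1.0 + x * x / 20.0),
                         np.sinh(np.where(small, 1.0, x)) / np.where(small, 1.0, x))
        out = t * np.exp(0.5 * (a + b) * t) * ratio
    if out.ndim == 0:
        return float(out)
    return out
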