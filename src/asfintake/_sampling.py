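"""Shared MCMC utilities: slice sampling and seed fan-out."""

from __future__ import annotations

import zlib
from typing import Callable

import numpy as np


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 (stage re-runs keep their stream
    even when other stages change)."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


def slice_sample(x0: float, logpdf: Callable[[float], float],
                 rng: np.random.Generator, width: float = 1.0,
                 max_steps: int = 64) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage).

    Robust for the low-dimensional variance-component conditionals here;
    no tuning beyond an initial bracket width.
    """
    logy = logpdf(x0) + np.log(rng.random())
    lo = x0 - width * rng.random()
    hi = lo + width
    for _ in range(max_steps):
        if logpdf(lo) <= logy:
            break
        lo -= width
    for _ in range(max_steps):
        if logpdf(hi) <= logy:
            break
        hi += width
    for _ in range(max_steps):
        x1 = lo + (hi - lo) * rng.random()
        if logpdf(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # degenerate slice; keep current point
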