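"""Posterior-draw summaries: medians, 95% uncertainty intervals, differences.

All uncertainty in this package is carried as draws; summaries are the
50th / 2.5th / 97.5th percentiles computed by linear interpolation between
order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Estimate:
    """Median and 95% uncertainty interval of a posterior quantity."""

    median: float
    lower95: float
    upper95: float
    n_draws: int

    def __post_init__(self):
        if not (self.lower95 <= self.median <= self.upper95):
            raise ValueError("estimate must satisfy lower95 <= median <= upper95")

    def to_dict(self) -> dict:
        return {"median": self.median, "lower95": self.lower95,
                "upper95": self.upper95, "n_draws": self.n_draws}


@dataclass(frozen=True)
class DiffResult:
    """Absolute and relative difference between two aggregated quantities.

    ``significant`` is exactly the rule that the 95% UI of the absolute
    difference excludes zero.
    """

    absolute: Estimate
    relative_pct: Estimate
    significant: bool
    unit: str = "g/day"

    def to_dict(self) -> dict:
        return {"absolute": self.absolute.to_dict(),
                "relative_pct": self.relative_pct.to_dict(),
                "significant": self.significant, "unit": self.unit}


def summarize_draws(draws: np.ndarray, min_draws: int = 100) -> Estimate:
    """Summarise a draw vector as (median, 2.5th, 97.5th percentile).

    Percentiles use linear interpolation between order statistics
    (so 1..100 has median 50.5).
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < min_draws:
        raise ValueError(
            f"need at least {min_draws} draws to summarise, got {draws.size}")
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return Estimate(float(med), float(lo), float(hi), int(draws.size))


def difference_from_draws(draws_a: np.ndarray, draws_b: np.ndarray,
                          unit: str = "g/day",
                          min_draws: int = 100) -> DiffResult:
    """Paired draw-level difference A - B with B as the relative denominator."""
    draws_a = np.asarray(draws_a, dtype=float).ravel()
    draws_b = np.asarray(draws_b, dtype=float).ravel()
    if draws_a.shape != draws_b.shape:
        raise ValueError("draw vectors must be paired (same length)")
    diff = draws_a - draws_b
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 100.0 * diff / draws_b
    absolute = summarize_draws(diff, min_draws)
    relative = summarize_draws(rel[np.isfinite(rel)], min_draws)
    significant = bool(absolute.lower95 > 0 or absolute.upper95 < 0)
    return DiffResult(absolute, relative, significant, unit)
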