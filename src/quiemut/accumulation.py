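"""Least-squares fit of mutant frequency against days of quiescence."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

__all__ = ["AccumulationPoint", "AccumulationSeries", "LinearFit", "fit_slope"]


class AccumulationPoint(NamedTuple):
    day: float
    frequency: float
    experiment_id: str = ""


class LinearFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class AccumulationSeries:
    """Frequency-vs-day observations, optionally pooled across experiments."""

    points: list[AccumulationPoint]
    fit: Optional[LinearFit] = None

    def fit_line(self) -> LinearFit:
        self.fit = fit_slope(self.points)
        return self.fit


def fit_slope(points: Sequence[tuple]) -> LinearFit:
    """Ordinary least squares with intercept over (day, frequency[, experiment]).

    Points from different experiments are pooled into one joint fit.
    R^2 = 1 - SS_res / SS_tot; on noiseless collinear input it is exactly 1.

    Raises
    ------
    ValueError
        With fewer than 2 points, on a negative frequency, or when all day
        values coincide (the slope would be undefined).
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points to fit a slope")
    days = np.asarray([p[0] for p in points], dtype=float)
    freqs = np.asarray([p[1] for p in points], dtype=float)
    if np.any(freqs < 0):
        raise ValueError("frequencies must be non-negative")
    if np.ptp(days) == 0:
        raise ValueError("all day values identical; slope undefined")
    slope, intercept = np.polyfit(days, freqs, 1)
    resid = freqs - (slope * days + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((freqs - freqs.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    # Guard against float dust on exactly collinear input.
    if ss_tot > 0 and ss_res / ss_tot < 1e-12:
        r2 = 1.0
    return LinearFit(float(slope), float(intercept), r2, len(points))
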