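"""Hydrolytic degradation tracking from GPC molar-mass time series.

Retention expresses the number-average molar mass Mn at each storage day as
a percentage of the day-0 value.  An optional first-order rate fit treats
hydrolysis as a random-scission-like process, Mn(t) = Mn(0) exp(-k t), and
estimates k by ordinary least squares on ln Mn versus day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .io_schema import GpcSeries

__all__ = ["RetentionSeries", "retention", "hydrolysis_rate"]


@dataclass
class RetentionSeries:
    """Percent of day-0 Mn remaining at each day; 100 at day 0 by construction."""

    polymer_label: str
    points: list[tuple[float, float]] = field(default_factory=list)


def retention(series: GpcSeries) -> RetentionSeries:
    """Molar-mass retention: 100 * Mn(day)/Mn(0) per observation.

    Scale-invariant in Mn.  The series must contain a day-0 entry (enforced
    by :class:`~gelphys.io_schema.GpcSeries`).
    """
    mn0 = series.observations[0][1]
    return RetentionSeries(
        polymer_label=series.polymer_label,
        points=[(day, 100.0 * mn / mn0) for day, mn in series.observations],
    )


def hydrolysis_rate(series: GpcSeries) -> tuple[float, float]:
    """First-order degradation rate from a log-linear least-squares fit.

    Fits ln Mn(t) = ln Mn(0) - k t and returns ``(k, r_squared)`` with k in
    day⁻¹ (0 for a perfectly flat series) and r² the coefficient of
    determination of the fit.
    """
    if len(series.observations) < 2:
        raise ValueError("need at least 2 points to fit a rate")
    days = [d for d, _ in series.observations]
    log_mn = [math.log(mn) for _, mn in series.observations]
    fit = stats.linregress(days, log_mn)
    r_squared = fit.rvalue**2
    if math.isnan(r_squared):  # zero-variance response: flat line fits exactly
        r_squared = 1.0
    return float(-fit.slope), float(r_squared)
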