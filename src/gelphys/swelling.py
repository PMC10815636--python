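"""Dynamic and equilibrium swelling degrees from gravimetric time series.

The swelling degree of a gel disc weighed wet at time t is

    Q(t) = (m_t - m_0) / m_0

with ``m_0`` the dry mass.  Equilibrium is detected by a plateau criterion:
the first observation after which every successive relative change in Q
stays below a tolerance (default 1%).  No smoothing is applied first, so the
estimator is transparent about measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .io_schema import GravimetricSeries

__all__ = [
    "SwellingCurve",
    "swelling_degree",
    "analyze_curve",
    "temperature_profile",
    "DEFAULT_PLATEAU_REL_TOL",
]

DEFAULT_PLATEAU_REL_TOL = 0.01


@dataclass
class SwellingCurve:
    """Q(t) for one sample plus its detected equilibrium point.

    ``q_eq`` always equals the Q of some observed point and ``t_eq`` is that
    point's time.
    """

    sample_id: str
    points: list[tuple[float, float]] = field(default_factory=list)
    q_eq: float = math.nan
    t_eq: float = math.nan


def swelling_degree(mt_mg: float, m0_mg: float) -> float:
    """Gravimetric swelling degree Q = (mt - m0)/m0 (dimensionless).

    Scale-invariant: Q(c*mt, c*m0) == Q(mt, m0) for any c > 0.
    """
    if m0_mg <= 0:
        raise ValueError(f"dry mass must be positive, got {m0_mg}")
    if mt_mg <= 0:
        raise ValueError(f"wet mass must be positive, got {mt_mg}")
    return (mt_mg - m0_mg) / m0_mg


def _plateau_index(qs: list[float], rel_tol: float) -> int:
    """Index of the first observation inside the plateau.

    A point is inside the plateau when the relative change arriving at it
    and every later change stay below ``rel_tol``; the very first point
    qualifies only when the entire series is settled.  Falls back to the
    final index when the curve never settles.
    """
    n = len(qs)
    # rel[i-1] is the change arriving at point i; 0/0 counts as no change
    rel = []
    for i in range(1, n):
        dq = abs(qs[i] - qs[i - 1])
        base = abs(qs[i - 1])
        rel.append(0.0 if dq == 0 else (math.inf if base == 0 else dq / base))
    for j in range(n):
        if all(r < rel_tol for r in rel[max(j, 1) - 1 :]):
            return j
    return n - 1


def analyze_curve(
    series: GravimetricSeries, plateau_rel_tol: float = DEFAULT_PLATEAU_REL_TOL
) -> SwellingCurve:
    """Compute Q at every observation and locate the equilibrium plateau.

    Parameters
    ----------
    series:
        Validated gravimetric series (dry mass + timed wet masses).
    plateau_rel_tol:
        Relative-change threshold below which the curve counts as settled.

    Returns
    -------
    SwellingCurve with ``q_eq`` the Q at the first settled observation (the
    final Q when the curve never settles) and ``t_eq`` its time.
    """
    if plateau_rel_tol <= 0:
        raise ValueError(f"plateau_rel_tol must be positive, got {plateau_rel_tol}")
    points = [(t, swelling_degree(mt, series.m0_mg)) for t, mt in series.observations]
    qs = [q for _, q in points]
    j = _plateau_index(qs, plateau_rel_tol)
    return SwellingCurve(
        sample_id=series.sample_id, points=points, q_eq=qs[j], t_eq=points[j][0]
    )


def temperature_profile(
    entries: Iterable[tuple[str, float, float]]
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Tabulate equilibrium swelling versus temperature per crosslinker.

    Parameters
    ----------
    entries:
        ``(crosslinker_label, temperature_c, q_eq)`` triples, at least two
        temperatures per crosslinker.

    Returns
    -------
    (table, flags):
        ``table`` sorted by crosslinker then temperature with columns
        ``crosslinker_label, temperature_c, q_eq``; ``flags`` maps each
        crosslinker to True iff its Q_eq is non-increasing in temperature
        (the thermo-shrinking behaviour these PEG-crosslinked gels show).
    """
    df = pd.DataFrame(
        list(entries), columns=["crosslinker_label", "temperature_c", "q_eq"]
    )
    dup = df.duplicated(subset=["crosslinker_label", "temperature_c"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["crosslinker_label", "temperature_c"]]
        raise ValueError(
            f"duplicate (crosslinker, temperature) pair: "
            f"({pair.crosslinker_label!r}, {pair.temperature_c})"
        )
    counts = df.groupby("crosslinker_label")["temperature_c"].nunique()
    short = counts[counts < 2]
    if not short.empty:
        raise ValueError(
            f"need >= 2 temperatures per crosslinker; "
            f"{short.index[0]!r} has {int(short.iloc[0])}"
        )
    df = df.sort_values(["crosslinker_label", "temperature_c"]).reset_index(drop=True)
    flags = {
        label: bool(g["q_eq"].is_monotonic_decreasing)
        for label, g in df.groupby("crosslinker_label")
    }
    return df, flags
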