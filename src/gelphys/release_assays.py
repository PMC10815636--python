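"""Fluorescence calibration, solute loading and release, and viability.

Release quantification follows standard dissolution-testing accounting for
a protocol in which each sampled aliquot of volume v is replaced by fresh
medium (sink conditions).  The raw back-calculated concentration at the
k-th sampling time underestimates cumulative release because earlier
aliquots physically removed solute; the corrected concentration

    C_corr(t_k) = C_raw(t_k) + (v/V) * sum_{i<k} C_raw(t_i)

restores the mass balance exactly: C_corr(t_k) * V equals the total mass
released up to t_k, including the mass carried away in aliquots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_schema import CalibrationPoint, PlateReadings, ReleaseExperiment

__all__ = [
    "CalibrationCurve",
    "ReleaseProfile",
    "fit_calibration",
    "intensity_to_conc",
    "cumulative_release",
    "loading_efficiency",
    "viability_pct",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map intensity = slope * conc + intercept.

    slope in a.u. per (µg/mL), intercept in a.u., r_squared in [0, 1].
    """

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        if not 0 <= self.r_squared <= 1:
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")


@dataclass
class ReleaseProfile:
    """Cumulative-release table for one experiment.

    ``points`` columns: t_h, conc_raw, conc_corrected, mass_cum (µg),
    release_pct (%).  ``capped`` flags release_pct values truncated at 100
    (calibration extrapolation can overshoot); ``n_clamped`` counts
    negative back-calculated concentrations clamped to zero.
    """

    sample_id: str
    points: pd.DataFrame = field(default_factory=pd.DataFrame)
    capped: bool = False
    n_clamped: int = 0


def fit_calibration(points: list[CalibrationPoint] | list[tuple[float, float]]) -> CalibrationCurve:
    """Ordinary least-squares calibration line through standard points.

    Requires at least 3 points spanning at least 2 distinct concentrations.
    """
    pts = [
        (p.conc_ug_ml, p.intensity_au) if isinstance(p, CalibrationPoint) else p
        for p in points
    ]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 calibration points, got {len(pts)}")
    concs = [c for c, _ in pts]
    if len(set(concs)) < 2:
        raise ValueError("calibration points must span >= 2 distinct concentrations")
    fit = stats.linregress(concs, [i for _, i in pts])
    r_squared = fit.rvalue**2
    if np.isnan(r_squared):
        r_squared = 1.0
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(min(r_squared, 1.0)),
    )


def intensity_to_conc(intensity, cal: CalibrationCurve):
    """Back-calculate concentration (µg/mL) from fluorescence intensity.

    Negative results (intensity below the intercept, i.e. within blank
    noise) are clamped to zero; a RuntimeWarning reports how many values
    were clamped.  Accepts a scalar or an array; returns the same shape.
    """
    arr = np.asarray(intensity, dtype=float)
    conc = (arr - cal.intercept) / cal.slope
    n_neg = int(np.count_nonzero(conc < 0))
    if n_neg:
        warnings.warn(
            f"{n_neg} back-calculated concentration(s) below zero clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        conc = np.clip(conc, 0.0, None)
    return float(conc) if np.isscalar(intensity) else conc


def cumulative_release(exp: ReleaseExperiment, cal: CalibrationCurve) -> ReleaseProfile:
    """Cumulative release profile with aliquot-replacement correction.

    Converts each aliquot intensity to a raw concentration, applies the
    replacement correction (module docstring), and reports cumulative
    released mass and percent of the loaded dose.  release_pct is capped at
    100 with ``capped`` set when the back-calculation overshoots.
    """
    times = np.array([t for t, _ in exp.observations], dtype=float)
    intensities = np.array([i for _, i in exp.observations], dtype=float)
    n_clamped = int(np.count_nonzero(intensities < cal.intercept))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        conc_raw = np.atleast_1d(intensity_to_conc(intensities, cal))
    # prior-aliquot make-up term: (v/V) * running sum of earlier raw concs
    prior = np.concatenate([[0.0], np.cumsum(conc_raw)[:-1]])
    conc_corr = conc_raw + (exp.aliquot_ml / exp.volume_ml) * prior
    mass_cum = conc_corr * exp.volume_ml
    release_pct = 100.0 * mass_cum / exp.loaded_mass_ug
    capped = bool(np.any(release_pct > 100.0))
    df = pd.DataFrame(
        dict(
            t_h=times,
            conc_raw=conc_raw,
            conc_corrected=conc_corr,
            mass_cum=mass_cum,
            release_pct=np.minimum(release_pct, 100.0),
        )
    )
    return ReleaseProfile(
        sample_id=exp.sample_id, points=df, capped=capped, n_clamped=n_clamped
    )


def loading_efficiency(
    c0_ug_ml: float, c_end_ug_ml: float, v_load_ml: float
) -> tuple[float, float]:
    """Loading by depletion of the soaking solution.

    A gel soaked in volume ``v_load_ml`` of solution depletes it from
    ``c0_ug_ml`` to ``c_end_ug_ml``; the difference is the mass taken up.

    Returns
    -------
    (mass_loaded_ug, pct_loaded):
        mass_loaded = (c0 - c_end) * V_load; pct_loaded = 100 (c0 - c_end)/c0.
    """
    if c0_ug_ml <= 0:
        raise ValueError(f"initial concentration must be positive, got {c0_ug_ml}")
    if v_load_ml <= 0:
        raise ValueError(f"loading volume must be positive, got {v_load_ml}")
    if not 0 <= c_end_ug_ml <= c0_ug_ml:
        raise ValueError(
            f"final concentration must lie in [0, c0], got {c_end_ug_ml} "
            f"with c0 = {c0_ug_ml}"
        )
    mass = (c0_ug_ml - c_end_ug_ml) * v_load_ml
    return mass, 100.0 * (c0_ug_ml - c_end_ug_ml) / c0_ug_ml


def viability_pct(readings: PlateReadings) -> list[float]:
    """Percent viability per sample well from a resazurin plate.

    viability = 100 (F_sample - F_blank)/(F_negative - F_blank).  Values
    above 100 are reported as-is (metabolically stimulated wells exceed the
    untreated control).
    """
    denom = readings.f_negative - readings.f_blank
    return [100.0 * (f - readings.f_blank) / denom for f in readings.f_samples]
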