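import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gelphys import (
    CalibrationCurve,
    PlateReadings,
    ReleaseExperiment,
    cumulative_release,
    fit_calibration,
    intensity_to_conc,
    loading_efficiency,
    viability_pct,
)


def _line_points(slope=2000.0, intercept=50.0, concs=(0.1, 0.5, 1.0, 2.0)):
    return [(c, slope * c + intercept) for c in concs]


# --- calibration ---------------------------------------------------------------

def test_fit_exact_line():
    cal = fit_calibration(_line_points())
    assert cal.slope == pytest.approx(2000.0)
    assert cal.intercept == pytest.approx(50.0)
    assert cal.r_squared == pytest.approx(1.0)


def test_fit_requires_spread_in_concentration():
    with pytest.raises(ValueError):
        fit_calibration([(1.0, 100.0), (1.0, 101.0), (1.0, 102.0)])
    with pytest.raises(ValueError):
        fit_calibration([(1.0, 100.0), (2.0, 200.0)])


def test_back_calculation_is_inverse_on_exact_line():
    """fit then invert is the identity on the calibration points."""
    pts = _line_points()
    cal = fit_calibration(pts)
    for conc, intensity in pts:
        assert intensity_to_conc(intensity, cal) == pytest.approx(conc, abs=1e-12)


def test_back_calculation_clamps_below_blank():
    cal = CalibrationCurve(slope=2000.0, intercept=50.0, r_squared=1.0)
    assert intensity_to_conc(50.0, cal) == 0.0
    assert intensity_to_conc(4050.0, cal) == pytest.approx(2.0)
    with pytest.warns(RuntimeWarning, match="clamped"):
        assert intensity_to_conc(40.0, cal) == 0.0


# --- cumulative release ---------------------------------------------------------

def _exp_from_concs(concs, volume=10.0, aliquot=0.5, loaded=10.0,
                    slope=1.0, intercept=0.0):
    obs = [(float(k + 1), slope * c + intercept) for k, c in enumerate(concs)]
    return ReleaseExperiment("r", volume, aliquot, loaded, obs)


def test_correction_hand_computed_running_sum():
    """Constant 1 µg/mL raw readings with v/V = 0.05 correct to
    1, 1.05, 1.10 µg/mL."""
    cal = CalibrationCurve(slope=1.0, intercept=0.0, r_squared=1.0)
    profile = cumulative_release(_exp_from_concs([1.0, 1.0, 1.0]), cal)
    assert profile.points["conc_corrected"].tolist() == pytest.approx([1.0, 1.05, 1.10])


def test_no_aliquot_means_no_correction():
    cal = CalibrationCurve(slope=1.0, intercept=0.0, r_squared=1.0)
    profile = cumulative_release(
        _exp_from_concs([0.3, 0.5, 0.8], aliquot=0.0), cal
    )
    assert (profile.points["conc_corrected"] == profile.points["conc_raw"]).all()


def test_blank_intensities_give_zero_release():
    cal = CalibrationCurve(slope=2000.0, intercept=50.0, r_squared=1.0)
    exp = ReleaseExperiment("r", 10.0, 0.5, 10.0, [(1.0, 50.0), (2.0, 50.0)])
    profile = cumulative_release(exp, cal)
    assert (profile.points["release_pct"] == 0.0).all()
    assert profile.n_clamped == 0


def test_overshoot_is_capped_and_flagged():
    cal = CalibrationCurve(slope=1.0, intercept=0.0, r_squared=1.0)
    profile = cumulative_release(_exp_from_concs([1.5], loaded=10.0), cal)
    assert profile.capped
    assert profile.points["release_pct"].iloc[-1] == 100.0


def test_clamped_negative_concentrations_are_counted():
    cal = CalibrationCurve(slope=1.0, intercept=10.0, r_squared=1.0)
    exp = ReleaseExperiment("r", 10.0, 0.5, 10.0, [(1.0, 5.0), (2.0, 12.0)])
    profile = cumulative_release(exp, cal)
    assert profile.n_clamped == 1
    assert profile.points["conc_raw"].iloc[0] == 0.0


@given(
    concs=st.lists(st.floats(0.0, 5.0), min_size=2, max_size=12),
    ratio=st.floats(0.0, 0.5),
)
def test_correction_nonnegative_and_growing(concs, ratio):
    """The replacement correction only ever adds mass, and the added term
    is non-decreasing over the sampling sequence."""
    cal = CalibrationCurve(slope=1.0, intercept=0.0, r_squared=1.0)
    exp = _exp_from_concs(concs, volume=10.0, aliquot=10.0 * ratio, loaded=1e6)
    profile = cumulative_release(exp, cal)
    delta = profile.points["conc_corrected"] - profile.points["conc_raw"]
    assert (delta >= 0).all()
    assert (np.diff(delta) >= -1e-12).all()
    assert profile.points["mass_cum"].iloc[-1] >= 0


# --- loading and viability -------------------------------------------------------

def test_loading_by_depletion():
    """A 0.1 mg/mL soak depleted to 0.09 mg/mL over 1 mL loads 10 µg = 10%,
    the scale of the protein-loading experiment."""
    assert loading_efficiency(100.0, 90.0, 1.0) == pytest.approx((10.0, 10.0))


@pytest.mark.parametrize(
    "c_end,expected", [(100.0, (0.0, 0.0)), (0.0, (100.0, 100.0))]
)
def test_loading_limits(c_end, expected):
    assert loading_efficiency(100.0, c_end, 1.0) == pytest.approx(expected)


def test_loading_rejects_enrichment():
    with pytest.raises(ValueError):
        loading_efficiency(100.0, 101.0, 1.0)


def test_viability_controls_and_stimulated_wells():
    readings = PlateReadings(
        f_blank=100.0, f_negative=1100.0, f_positive=150.0,
        f_samples=[1100.0, 100.0, 1500.0],
    )
    assert viability_pct(readings) == pytest.approx([100.0, 0.0, 140.0])
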