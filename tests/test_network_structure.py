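import math

import mpmath
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gelphys import (
    NetworkParams,
    characterize_network,
    mesh_size,
    molar_mass_between_crosslinks,
    polymer_volume_fraction,
    stretched_peg_length,
)


def mc_oracle(v2s, chi1, mn, v1=18.1, nu1=1 / 1.2, phi=2.0):
    """Arbitrary-precision evaluation of the modified Flory–Rehner relation,
    fully independent of the float64 implementation path."""
    with mpmath.workdps(50):
        v = mpmath.mpf(v2s)
        mixing = mpmath.log(1 - v) + v + mpmath.mpf(chi1) * v**2
        elastic = v ** mpmath.mpf("1/3") - (2 / mpmath.mpf(phi)) * v
        inv = 2 / mpmath.mpf(mn) - (mpmath.mpf(nu1) / mpmath.mpf(v1)) * mixing / elastic
        return float(1 / inv)


# --- polymer volume fraction -------------------------------------------------

@pytest.mark.parametrize(
    "q,expected",
    [(0.0, 1.0), (11.81, 1.0 / (11.81 * 1.2 + 1.0)), (3.84, 1.0 / (3.84 * 1.2 + 1.0))],
)
def test_polymer_volume_fraction_values(q, expected):
    assert polymer_volume_fraction(q, 1.2, 1.0) == pytest.approx(expected, rel=1e-12)


def test_polymer_volume_fraction_rejects_negative_swelling():
    with pytest.raises(ValueError):
        polymer_volume_fraction(-0.1, 1.2, 1.0)


# --- molar mass between crosslinks -------------------------------------------

def test_mc_phantom_limit_without_solvent_term():
    """With the solvent term switched off (nu1 = 0) the relation collapses
    to 1/Mc = 2/Mn."""
    p = NetworkParams(nu1=0.0)
    assert molar_mass_between_crosslinks(0.1, p) == pytest.approx(17_500 / 2)


@pytest.mark.parametrize(
    "v2s,approx",
    [(0.0657, 5.82e3), (0.1779, 1.53e3)],
)
def test_mc_against_independent_oracle(v2s, approx, default_params):
    mc = molar_mass_between_crosslinks(v2s, default_params)
    assert mc == pytest.approx(approx, rel=5e-3)
    assert mc == pytest.approx(mc_oracle(v2s, 0.426, 17_500), rel=1e-12)


def test_mc_rejects_degenerate_volume_fractions(default_params):
    for v2s in (0.0, 1.0, 1.5):
        with pytest.raises(ValueError):
            molar_mass_between_crosslinks(v2s, default_params)


def test_mc_oracle_agreement_on_grid(default_params):
    """Float64 implementation matches the 50-digit oracle to 10 significant
    digits across the physically relevant (v2s, chi1, Mn) box."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        v2s = rng.uniform(0.02, 0.6)
        chi1 = rng.uniform(0.1, 0.49)
        mn = rng.uniform(5e3, 5e4)
        p = NetworkParams(mn=mn, chi1=chi1)
        got = molar_mass_between_crosslinks(v2s, p)
        want = mc_oracle(v2s, chi1, mn)
        assert math.isclose(got, want, rel_tol=1e-10)


# --- mesh size ----------------------------------------------------------------

def test_mesh_size_single_link_dry_limit():
    p = NetworkParams(mr=640.0)
    n, r0, xi = mesh_size(320.0, 1.0, p)
    assert n == pytest.approx(1.0)
    assert r0 == pytest.approx(1.51 * math.sqrt(6.1))
    assert xi == pytest.approx(r0)


@pytest.mark.parametrize(
    "mc,v2s,xi_expected",
    [(5824.0, 0.0657, 39.4), (1529.0, 0.1779, 14.5)],
)
def test_mesh_size_reference_values(mc, v2s, xi_expected, default_params):
    _, _, xi = mesh_size(mc, v2s, default_params)
    assert xi == pytest.approx(xi_expected, rel=5e-3)


def test_characterize_network_chains_the_stages(default_params):
    r = characterize_network(3.84, default_params)
    v2s = polymer_volume_fraction(3.84, 1.2, 1.0)
    mc = molar_mass_between_crosslinks(v2s, default_params)
    n, r0, xi = mesh_size(mc, v2s, default_params)
    assert (r.v2s, r.mc, r.n_links, r0, r.xi) == (v2s, mc, n, r0, xi)
    assert r.xi >= r.r0
    assert 0 < r.v2s <= 1


def test_dry_limit_mesh_approaches_end_to_end_distance(default_params):
    """As Q -> 0+, v2s -> 1 and xi -> r0."""
    r = characterize_network(1e-9, default_params)
    assert r.v2s == pytest.approx(1.0, rel=1e-8)
    assert r.xi == pytest.approx(r.r0, rel=1e-8)


def test_structure_monotone_in_swelling(default_params):
    """v2s strictly decreases and xi strictly increases with Q."""
    qs = np.linspace(0.5, 20.0, 200)
    results = [characterize_network(q, default_params) for q in qs]
    v2s = np.array([r.v2s for r in results])
    xi = np.array([r.xi for r in results])
    assert np.all(np.diff(v2s) < 0)
    assert np.all(np.diff(xi) > 0)


def test_mesh_recompute_round_trip(default_params):
    """Recomputing xi from a result's (Mc, v2s) reproduces the stored xi."""
    for q in (0.7, 3.84, 6.73, 11.81, 18.0):
        r = characterize_network(q, default_params)
        assert mesh_size(r.mc, r.v2s, default_params)[2] == r.xi


# --- stretched PEG spacers ----------------------------------------------------

def test_stretched_peg_length_unit_case():
    assert stretched_peg_length(n_units=1) == 1.5


@pytest.mark.parametrize("n,expected", [(9, 13.5), (23, 34.5), (45, 67.5)])
def test_stretched_peg_length_by_units(n, expected):
    assert stretched_peg_length(n_units=n) == pytest.approx(expected)


def test_stretched_peg_length_by_molar_mass():
    assert stretched_peg_length(peg_molar_mass=1000.0) == pytest.approx(
        1.5 * 1000.0 / 44.05
    )


def test_stretched_peg_length_argument_exclusivity():
    with pytest.raises(ValueError):
        stretched_peg_length()
    with pytest.raises(ValueError):
        stretched_peg_length(n_units=9, peg_molar_mass=400.0)


# --- parameter validation ------------------------------------------------------

def test_params_reject_theta_solvent_and_inconsistent_density():
    with pytest.raises(ValueError, match="chi1"):
        NetworkParams(chi1=0.55)
    with pytest.raises(ValueError, match="inconsistent"):
        NetworkParams(nu1=1.0, rho_p=1.2)


def test_params_from_yaml_file(tmp_path):
    f = tmp_path / "p.yaml"
    f.write_text("Mn: 17250\nrho_p: 1.1\nnu1: 0.909\n")
    p = NetworkParams.from_file(f)
    assert (p.mn, p.rho_p, p.nu1) == (17_250.0, 1.1, 0.909)


def test_params_from_file_rejects_unknown_keys(tmp_path):
    f = tmp_path / "q.yaml"
    f.write_text("Mx: 1\n")
    with pytest.raises(ValueError, match="unknown parameter"):
        NetworkParams.from_file(f)


@given(q=st.floats(0.1, 50.0))
def test_mesh_always_at_least_end_to_end(q):
    r = characterize_network(q, NetworkParams())
    assert r.xi >= r.r0
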