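"""Gas-chemistry checks against standalone solubility oracles and exact
mass-balance round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sedshuttle.gas_chemistry import (
    GAS_CONSTANT_L_ATM,
    HeadspaceSample,
    diffusive_flux,
    equilibrium_concentration,
    excess_gas,
    gas_transfer_velocity,
    headspace_original_concentration,
    n2_from_n2ar,
    n2o_solubility_coefficient,
)

# ---------------------------------------------------------------------------
# Standalone oracle implementations of the published fits (kept independent
# of the package code on purpose).
# ---------------------------------------------------------------------------


def oracle_n2o_k0(t_k, s):
    """Weiss & Price N2O solubility polynomial, re-coded from the published
    coefficients."""
    t100 = t_k / 100.0
    ln_k0 = (
        -62.7062
        + 97.3066 / t100
        + 24.1406 * math.log(t100)
        + s * (-0.058420 + 0.033193 * t100 - 0.0051313 * t100 ** 2)
    )
    return math.exp(ln_k0)


_HE = {
    "N2": ((6.42931, 2.92704, 4.32531, 4.69149),
           (-7.44129e-3, -8.02566e-3, -1.46775e-2), 0.780840),
    "Ar": ((2.79150, 3.17609, 4.13116, 4.90379),
           (-6.96233e-3, -7.66670e-3, -1.16888e-2), 0.009332),
}


def oracle_saturation(gas, t_k, s, x=None):
    """Hamme-Emerson saturation fit, re-coded from the published
    coefficients; rescaled for a non-standard mole fraction."""
    a, b, x_std = _HE[gas]
    t_c = t_k - 273.15
    ts = math.log((298.15 - t_c) / (273.15 + t_c))
    ln_c = (
        a[0] + a[1] * ts + a[2] * ts ** 2 + a[3] * ts ** 3
        + s * (b[0] + b[1] * ts + b[2] * ts ** 2)
    )
    c = math.exp(ln_c)
    return c if x is None else c * x / x_std


@pytest.mark.parametrize("t_k,s", [
    (298.15, 0.0), (278.15, 0.0), (298.15, 35.0), (283.15, 10.0),
])
def test_n2o_solubility_matches_oracle(t_k, s):
    assert n2o_solubility_coefficient(t_k, s) == pytest.approx(
        oracle_n2o_k0(t_k, s), rel=1e-6
    )


def test_n2o_solubility_monotonicity():
    # colder water and fresher water both dissolve more N2O
    assert n2o_solubility_coefficient(278.15) > n2o_solubility_coefficient(298.15)
    assert (
        n2o_solubility_coefficient(298.15, 0.0)
        > n2o_solubility_coefficient(298.15, 35.0)
    )


@pytest.mark.parametrize("bad_t,bad_s", [(250.0, 0.0), (330.0, 0.0), (298.15, 50.0)])
def test_solubility_domain_errors(bad_t, bad_s):
    with pytest.raises(ValueError, match="range"):
        n2o_solubility_coefficient(bad_t, bad_s)


@pytest.mark.parametrize("gas,x", [("N2", 0.7808), ("Ar", 0.00934)])
def test_equilibrium_concentration_matches_oracle(gas, x):
    got = equilibrium_concentration(gas, 298.15, 0.0, x)
    assert got == pytest.approx(oracle_saturation(gas, 298.15, 0.0, x), rel=1e-6)


def test_equilibrium_concentration_henry_linearity():
    base = equilibrium_concentration("N2O", 288.15, 0.0, 200e-9)
    assert equilibrium_concentration("N2O", 288.15, 0.0, 400e-9) == pytest.approx(
        2.0 * base, rel=1e-12
    )
    assert equilibrium_concentration("N2O", 288.15, 0.0, 200e-9, pressure=2.0) \
        == pytest.approx(2.0 * base, rel=1e-12)


def test_equilibrium_concentration_rejects_unknown_gas():
    with pytest.raises(ValueError, match="N2, Ar, N2O"):
        equilibrium_concentration("CH4", 298.15)


def _sample(cg, cair, k0=0.0247, t=298.15, vg=40.0, vl=160.0):
    return HeadspaceSample(
        headspace_conc=cg, air_conc=cair, gas_volume=vg, liquid_volume=vl,
        temperature=t, solubility_coeff=k0,
    )


def test_headspace_equilibrium_fixed_point():
    # headspace composition unchanged by shaking -> water was at equilibrium
    s = _sample(cg=0.0135, cair=0.0135)
    res = headspace_original_concentration(s)
    k0rt = 0.0247 * GAS_CONSTANT_L_ATM * 298.15
    assert res.cw == pytest.approx(0.0135 * k0rt, rel=1e-12)
    assert res.flags == ()


def test_headspace_field_geometry_round_trip():
    # forward partition with the 40/160 mL field geometry, then invert
    cw0, cair, ratio, k0rt = 0.0200, 0.0135, 0.25, 0.586
    cg = (cw0 + cair * ratio) / (ratio + k0rt)
    k0 = k0rt / (GAS_CONSTANT_L_ATM * 298.15)
    res = headspace_original_concentration(_sample(cg, cair, k0=k0))
    assert res.cw == pytest.approx(cw0, rel=1e-12)


@given(
    cw0=st.floats(0.0, 1.0),
    cair=st.floats(0.0, 0.1),
    ratio=st.floats(0.05, 2.0),
    k0=st.floats(0.01, 0.06),
    t=st.floats(273.15, 310.0),
)
def test_headspace_round_trip_property(cw0, cair, ratio, k0, t):
    """Forward mass balance followed by inversion is exact."""
    k0rt = k0 * GAS_CONSTANT_L_ATM * t
    cg = (cw0 + cair * ratio) / (ratio + k0rt)
    s = HeadspaceSample(
        headspace_conc=cg, air_conc=cair, gas_volume=100.0 * ratio,
        liquid_volume=100.0, temperature=t, solubility_coeff=k0,
    )
    res = headspace_original_concentration(s)
    assert res.cw == pytest.approx(cw0, rel=1e-10, abs=1e-12)


def test_headspace_negative_cw_flagged_not_clamped():
    s = _sample(cg=0.0, cair=0.5)
    res = headspace_original_concentration(s)
    assert res.cw < 0
    assert "negative_cw" in res.flags


def test_excess_gas_sign_convention():
    assert excess_gas(500.0, 480.0) == pytest.approx(20.0)
    assert excess_gas(0.010, 0.0135) == pytest.approx(-0.0035)
    assert excess_gas(3.2, 3.2) == 0.0
    eq = equilibrium_concentration("N2", 290.0)
    assert excess_gas(eq, eq) == 0.0


def test_n2ar_method_self_consistency():
    t, s = 291.15, 0.0
    n2_eq = equilibrium_concentration("N2", t, s)
    ar_eq = equilibrium_concentration("Ar", t, s)
    assert n2_from_n2ar(n2_eq / ar_eq, t, s) == pytest.approx(n2_eq, rel=1e-12)
    # linearity in the measured ratio
    assert n2_from_n2ar(80.0, t, s) == pytest.approx(
        2.0 * n2_from_n2ar(40.0, t, s), rel=1e-12
    )


def test_n2ar_oracle_composition():
    got = n2_from_n2ar(40.0, 298.15, 0.0)
    assert got == pytest.approx(
        40.0 * oracle_saturation("Ar", 298.15, 0.0, 0.00934), rel=1e-6
    )


def test_diffusive_flux_values_and_bilinearity():
    assert diffusive_flux(0.5, 2.0) == pytest.approx(1000.0)
    assert diffusive_flux(1.0, -0.004) == pytest.approx(-4.0)
    assert diffusive_flux(0.7, 0.0) == 0.0
    assert diffusive_flux(2 * 0.3, 2.0) == pytest.approx(2 * diffusive_flux(0.3, 2.0))
    with pytest.raises(ValueError):
        diffusive_flux(-0.1, 1.0)


def test_gas_transfer_velocity_wind_law():
    assert gas_transfer_velocity(0.0) == 0.0
    assert gas_transfer_velocity(10.0, 298.15) == pytest.approx(
        4.0 * gas_transfer_velocity(5.0, 298.15), rel=1e-12
    )
    # independent evaluation of k600 (Sc/600)^-0.5 at u10 = 5, 25 degC
    t = 25.0
    sc = 2141.2 - 152.56 * t + 5.8963 * t**2 - 0.12411 * t**3 + 0.0010655 * t**4
    expected = 0.251 * 25.0 * (sc / 600.0) ** -0.5 * 0.24
    assert gas_transfer_velocity(5.0, 298.15) == pytest.approx(expected, rel=1e-9)
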