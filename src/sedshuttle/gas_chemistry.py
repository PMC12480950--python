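"""Dissolved-gas chemistry: solubility, headspace inversion, excess gas, flux.

The headspace-equilibrium method recovers the original dissolved
concentration of a sparingly soluble gas (here N₂O) from the gas-phase
concentration measured after shaking a water sample against an ambient-air
headspace.  The mass balance over the two phases gives

    Cw = Cg * (K0 * R * T + Vg/Vl) - Cair * (Vg/Vl)

with ``K0`` the Bunsen-type solubility coefficient (mol L^-1 atm^-1),
``R = 0.082`` L atm mol^-1 K^-1, ``T`` the equilibration temperature (K) and
``Vg/Vl`` the headspace-to-water volume ratio.  Excess ("Δ") gas is the
measured dissolved concentration minus the concentration in equilibrium with
the atmosphere, and the diffusive air-water flux is ``F = k * ΔN₂O`` with
``k`` the gas transfer velocity.

Solubility parameterizations
----------------------------
* N₂O: Weiss & Price (1980) polynomial for K0 in mol L^-1 atm^-1.
* N₂ and Ar: Hamme & Emerson (2004) atmospheric-saturation fits
  (µmol kg^-1 at standard atmospheric mole fraction and 1 atm total
  pressure including saturated water vapour).

Freshwater density is taken as 1 kg L^-1 so µmol kg^-1 is used
interchangeably with µmol L^-1; the survey sites are a freshwater lake and
the error is < 0.3 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GAS_CONSTANT_L_ATM",
    "DEFAULT_ATM_MOLE_FRACTIONS",
    "HeadspaceSample",
    "HeadspaceResult",
    "DissolvedGasProfile",
    "n2o_solubility_coefficient",
    "equilibrium_concentration",
    "headspace_original_concentration",
    "excess_gas",
    "n2_from_n2ar",
    "diffusive_flux",
    "gas_transfer_velocity",
    "read_gas_table",
    "process_gas_table",
]

#: Ideal gas constant in the units the headspace mass balance uses.
GAS_CONSTANT_L_ATM = 0.082  # L atm mol^-1 K^-1

#: Atmospheric mole fractions (dry air).  Config values, overridable
#: everywhere they are consumed; N2O default is a modern ~335 ppb.
DEFAULT_ATM_MOLE_FRACTIONS = {"N2": 0.78084, "Ar": 0.00934, "N2O": 335e-9}

# Standard mole fractions assumed by the Hamme & Emerson (2004) saturation
# fits; outputs are rescaled linearly for user-supplied mole fractions.
_HAMME_EMERSON_X_STD = {"N2": 0.780840, "Ar": 0.009332}

# ln(C/umol kg^-1) = A0 + A1 Ts + A2 Ts^2 + A3 Ts^3 + S (B0 + B1 Ts + B2 Ts^2)
# with Ts = ln((298.15 - t)/(273.15 + t)), t in degC.
_HAMME_EMERSON_COEFFS = {
    "N2": ((6.42931, 2.92704, 4.32531, 4.69149),
           (-7.44129e-3, -8.02566e-3, -1.46775e-2)),
    "Ar": ((2.79150, 3.17609, 4.13116, 4.90379),
           (-6.96233e-3, -7.66670e-3, -1.16888e-2)),
}

# Weiss & Price (1980) N2O solubility, K0 in mol L^-1 atm^-1:
# ln K0 = A1 + A2 (100/T) + A3 ln(T/100) + S [B1 + B2 (T/100) + B3 (T/100)^2]
_WEISS_PRICE_A = (-62.7062, 97.3066, 24.1406)
_WEISS_PRICE_B = (-0.058420, 0.033193, -0.0051313)

# Fit validity ranges (K / practical salinity).
_SOLUBILITY_T_RANGE = (273.15, 313.15)
_SOLUBILITY_S_RANGE = (0.0, 40.0)


def _check_ts(temperature: float, salinity: float) -> None:
    tlo, thi = _SOLUBILITY_T_RANGE
    slo, shi = _SOLUBILITY_S_RANGE
    if not tlo <= temperature <= thi:
        raise ValueError(
            f"temperature {temperature} K outside the solubility-fit range "
            f"[{tlo}, {thi}] K"
        )
    if not slo <= salinity <= shi:
        raise ValueError(
            f"salinity {salinity} outside the solubility-fit range "
            f"[{slo}, {shi}]"
        )


def n2o_solubility_coefficient(temperature: float, salinity: float = 0.0) -> float:
    """Weiss & Price N₂O solubility coefficient K0 (mol L^-1 atm^-1).

    Parameters
    ----------
    temperature : float
        Absolute temperature (K); valid 273.15-313.15 K.
    salinity : float
        Practical salinity; valid 0-40.  Default 0 (freshwater).
    """
    _check_ts(temperature, salinity)
    a1, a2, a3 = _WEISS_PRICE_A
    b1, b2, b3 = _WEISS_PRICE_B
    t100 = temperature / 100.0
    ln_k0 = a1 + a2 / t100 + a3 * math.log(t100) + salinity * (
        b1 + b2 * t100 + b3 * t100 * t100
    )
    return math.exp(ln_k0)


def _hamme_emerson_saturation(gas: str, temperature: float, salinity: float) -> float:
    """Saturation concentration (µmol kg^-1) at standard mole fraction."""
    a, b = _HAMME_EMERSON_COEFFS[gas]
    t_c = temperature - 273.15
    ts = math.log((298.15 - t_c) / (273.15 + t_c))
    ln_c = (
        a[0] + a[1] * ts + a[2] * ts ** 2 + a[3] * ts ** 3
        + salinity * (b[0] + b[1] * ts + b[2] * ts ** 2)
    )
    return math.exp(ln_c)


def equilibrium_concentration(
    gas: str,
    temperature: float,
    salinity: float = 0.0,
    atm_mole_fraction: float | None = None,
    pressure: float = 1.0,
) -> float:
    """Atmospheric-equilibrium dissolved concentration (µmol L^-1).

    ``gas`` is one of ``N2``, ``Ar``, ``N2O``.  The output is linear in
    ``atm_mole_fraction`` and ``pressure`` (Henry's law); mole fraction
    defaults to :data:`DEFAULT_ATM_MOLE_FRACTIONS`.
    """
    if gas not in ("N2", "Ar", "N2O"):
        raise ValueError(
            f"unsupported gas {gas!r}; supported gases: N2, Ar, N2O"
        )
    if atm_mole_fraction is None:
        atm_mole_fraction = DEFAULT_ATM_MOLE_FRACTIONS[gas]
    if not 0.0 < atm_mole_fraction <= 1.0:
        raise ValueError("atm_mole_fraction must be in (0, 1]")
    if pressure <= 0:
        raise ValueError("pressure must be positive")
    _check_ts(temperature, salinity)
    if gas == "N2O":
        k0 = n2o_solubility_coefficient(temperature, salinity)
        # mol L^-1 atm^-1 * atm -> mol L^-1 -> umol L^-1
        return k0 * atm_mole_fraction * pressure * 1e6
    c_std = _hamme_emerson_saturation(gas, temperature, salinity)
    return c_std * (atm_mole_fraction / _HAMME_EMERSON_X_STD[gas]) * pressure


@dataclass(frozen=True)
class HeadspaceSample:
    """One equilibrated water/headspace pair (inputs to the mass balance).

    Concentrations in µmol L^-1, volumes in mL, temperature in K,
    ``solubility_coeff`` in mol L^-1 atm^-1.
    """

    headspace_conc: float
    air_conc: float
    gas_volume: float
    liquid_volume: float
    temperature: float
    solubility_coeff: float

    def __post_init__(self) -> None:
        if self.gas_volume <= 0 or self.liquid_volume <= 0:
            raise ValueError("gas_volume and liquid_volume must be positive")
        if not 270.0 <= self.temperature <= 330.0:
            raise ValueError("temperature must be within [270, 330] K")
        if self.solubility_coeff <= 0:
            raise ValueError("solubility_coeff must be positive")
        if self.headspace_conc < 0 or self.air_conc < 0:
            raise ValueError("concentrations must be nonnegative")

    @property
    def volume_ratio(self) -> float:
        return self.gas_volume / self.liquid_volume


@dataclass(frozen=True)
class HeadspaceResult:
    """Recovered original dissolved concentration with quality flags."""

    cw: float  # umol L^-1
    flags: tuple[str, ...] = ()


def headspace_original_concentration(
    sample: HeadspaceSample, negative_tolerance: float = 1e-9
) -> HeadspaceResult:
    """Invert the headspace mass balance to the pre-equilibration Cw.

    ``Cw = Cg (K0 R T + Vg/Vl) - Cair (Vg/Vl)``.  A recovered concentration
    more negative than ``-negative_tolerance`` is physically inconsistent
    with the inputs and is flagged (``"negative_cw"``), never clamped.
    """
    r = sample.volume_ratio
    k0rt = sample.solubility_coeff * GAS_CONSTANT_L_ATM * sample.temperature
    cw = sample.headspace_conc * (k0rt + r) - sample.air_conc * r
    flags: tuple[str, ...] = ()
    if cw < -abs(negative_tolerance):
        flags = ("negative_cw",)
    return HeadspaceResult(cw=cw, flags=flags)


def excess_gas(measured: float, equilibrium: float) -> float:
    """Excess dissolved gas Δ = measured - equilibrium (sign preserved)."""
    if not (np.isfinite(measured) and np.isfinite(equilibrium)):
        raise ValueError("measured and equilibrium must be finite")
    return measured - equilibrium


def n2_from_n2ar(
    n2ar_ratio: float,
    temperature: float,
    salinity: float = 0.0,
    ar_mole_fraction: float | None = None,
    pressure: float = 1.0,
) -> float:
    """Dissolved N₂ (µmol L^-1) from a measured N₂:Ar ratio.

    Membrane-inlet mass spectrometry measures the N₂:Ar ratio precisely;
    multiplying by the well-constrained equilibrium Ar concentration yields
    absolute dissolved N₂.
    """
    if n2ar_ratio <= 0:
        raise ValueError("n2ar_ratio must be positive")
    ar_eq = equilibrium_concentration(
        "Ar", temperature, salinity, ar_mole_fraction, pressure
    )
    return n2ar_ratio * ar_eq


def diffusive_flux(k: float, delta_n2o: float) -> float:
    """Diffusive flux F (µmol m^-2 d^-1) from k (m d^-1) and ΔN₂O (µmol L^-1).

    1 µmol L^-1 = 1000 µmol m^-3, applied here; a negative excess gives a
    negative flux (influx from the atmosphere).
    """
    if k < 0:
        raise ValueError("gas transfer velocity k must be nonnegative")
    return k * delta_n2o * 1000.0


# Schmidt-number polynomial for N2O in fresh water (0-40 degC),
# Sc = a + b t + c t^2 + d t^3 + e t^4 (Wanninkhof-2014-type fit).
_SCHMIDT_N2O_FRESH = (2141.2, -152.56, 5.8963, -0.12411, 0.0010655)


def gas_transfer_velocity(wind_u10: float, temperature: float = 293.15) -> float:
    """Optional quadratic wind-speed parameterization of k (m d^-1).

    ``k600 = 0.251 u10^2`` (cm h^-1), scaled by ``(Sc/600)^-0.5`` with the
    freshwater N₂O Schmidt number.  k is otherwise a user-supplied input.
    """
    if wind_u10 < 0:
        raise ValueError("wind speed must be nonnegative")
    t_c = temperature - 273.15
    a, b, c, d, e = _SCHMIDT_N2O_FRESH
    sc = a + b * t_c + c * t_c ** 2 + d * t_c ** 3 + e * t_c ** 4
    k600_cm_h = 0.251 * wind_u10 ** 2
    k_cm_h = k600_cm_h * (sc / 600.0) ** -0.5
    return k_cm_h * 0.24  # cm h^-1 -> m d^-1


@dataclass
class DissolvedGasProfile:
    """Per-site dissolved-gas summary (all concentrations µmol L^-1)."""

    site_id: str
    n2_measured: float
    n2_equilibrium: float
    n2o_measured: float
    n2o_equilibrium: float
    delta_n2: float = field(init=False)
    delta_n2o: float = field(init=False)
    gas_transfer_velocity: float = 0.0
    flux: float = field(init=False)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.delta_n2 = excess_gas(self.n2_measured, self.n2_equilibrium)
        self.delta_n2o = excess_gas(self.n2o_measured, self.n2o_equilibrium)
        self.flux = diffusive_flux(self.gas_transfer_velocity, self.delta_n2o)


GAS_TABLE_COLUMNS = [
    "site_id", "T_insitu_C", "T_equil_C", "salinity", "Cg_umol_L",
    "Cair_umol_L", "Vg_mL", "Vl_mL", "n2ar_ratio", "k_m_d",
]


def read_gas_table(path) -> pd.DataFrame:
    """Read a site gas-survey CSV (see :data:`GAS_TABLE_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = [c for c in GAS_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gas table missing columns: {missing}")
    return df


def process_gas_table(
    df: pd.DataFrame, mole_fractions: dict[str, float] | None = None
) -> pd.DataFrame:
    """Run the full dissolved-gas chain on a site survey table.

    Per site: N₂O K0 at the equilibration temperature, headspace inversion
    to dissolved N₂O, equilibrium N₂/N₂O at the in-situ temperature,
    dissolved N₂ from the N₂:Ar ratio, excess gases, and diffusive N₂O
    flux.
    """
    xf = dict(DEFAULT_ATM_MOLE_FRACTIONS)
    if mole_fractions:
        xf.update(mole_fractions)
    rows = []
    for rec in df.itertuples(index=False):
        t_equil = rec.T_equil_C + 273.15
        t_insitu = rec.T_insitu_C + 273.15
        k0 = n2o_solubility_coefficient(t_equil, rec.salinity)
        sample = HeadspaceSample(
            headspace_conc=rec.Cg_umol_L,
            air_conc=rec.Cair_umol_L,
            gas_volume=rec.Vg_mL,
            liquid_volume=rec.Vl_mL,
            temperature=t_equil,
            solubility_coeff=k0,
        )
        hs = headspace_original_concentration(sample)
        n2o_eq = equilibrium_concentration(
            "N2O", t_insitu, rec.salinity, xf["N2O"]
        )
        n2_eq = equilibrium_concentration(
            "N2", t_insitu, rec.salinity, xf["N2"]
        )
        n2_meas = n2_from_n2ar(
            rec.n2ar_ratio, t_insitu, rec.salinity, xf["Ar"]
        )
        prof = DissolvedGasProfile(
            site_id=str(rec.site_id),
            n2_measured=n2_meas,
            n2_equilibrium=n2_eq,
            n2o_measured=hs.cw,
            n2o_equilibrium=n2o_eq,
            gas_transfer_velocity=rec.k_m_d,
            flags=hs.flags,
        )
        rows.append({
            "site_id": prof.site_id,
            "n2_umol_L": prof.n2_measured,
            "n2_eq_umol_L": prof.n2_equilibrium,
            "delta_n2_umol_L": prof.delta_n2,
            "n2o_umol_L": prof.n2o_measured,
            "n2o_eq_umol_L": prof.n2o_equilibrium,
            "delta_n2o_umol_L": prof.delta_n2o,
            "n2o_flux_umol_m2_d": prof.flux,
            "flags": ";".join(prof.flags),
        })
    return pd.DataFrame(rows)
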