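"""Microbial fuel cell polarization: power-density curves and MPD.

A polarization sweep steps the external resistance of a sediment MFC and
records the cell voltage.  Per point, ``I = V/R_ext``; dividing by the anode
projected area gives current density (A m^-2) and ``P = V·I/area`` the power
density, reported in µW m^-2.  The maximum power density (MPD) over the
sweep is the sediment's electron-transfer-capacity proxy.  For a Thevenin
cell ``V = Voc·R/(R + Rint)``, power peaks at ``R = Rint`` with
``MPD = Voc²/(4·Rint·area)`` — used as the analytic oracle and as a
diagnostic fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PolarizationSweep",
    "power_density_curve",
    "max_power_density",
    "estimate_internal_resistance",
    "read_sweep_table",
    "sweeps_from_table",
]


@dataclass(frozen=True)
class PolarizationSweep:
    """External-resistance/voltage pairs with the anode projected area (m²)."""

    external_resistance: tuple[float, ...]  # ohm
    voltage: tuple[float, ...]  # V
    anode_area: float  # m^2
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.external_resistance) != len(self.voltage):
            raise ValueError("resistance and voltage lists must match")
        if len(self.external_resistance) == 0:
            raise ValueError("sweep must contain at least one point")
        if min(self.external_resistance) <= 0:
            raise ValueError("external resistances must be positive")
        if self.anode_area <= 0:
            raise ValueError("anode_area must be positive")
        if min(self.voltage) < 0:
            raise ValueError("voltages must be nonnegative")


def power_density_curve(sweep: PolarizationSweep) -> pd.DataFrame:
    """Per-point current density (A m^-2) and power density (µW m^-2)."""
    r = np.asarray(sweep.external_resistance, dtype=float)
    v = np.asarray(sweep.voltage, dtype=float)
    current = v / r  # A
    i_density = current / sweep.anode_area
    p_density_uw = v * current / sweep.anode_area * 1e6
    return pd.DataFrame({
        "R_ohm": r,
        "V_volt": v,
        "current_density_A_m2": i_density,
        "power_density_uW_m2": p_density_uw,
    })


def max_power_density(sweep: PolarizationSweep) -> tuple[float, float]:
    """Empirical MPD (µW m^-2) and the external resistance attaining it.

    No interpolation between resistance steps; ties break toward the larger
    external resistance.
    """
    curve = power_density_curve(sweep)
    p = curve["power_density_uW_m2"].to_numpy()
    r = curve["R_ohm"].to_numpy()
    pmax = p.max()
    at_max = r[np.isclose(p, pmax, rtol=0.0, atol=0.0) | (p == pmax)]
    return float(pmax), float(at_max.max())


@dataclass(frozen=True)
class TheveninFit:
    """Least-squares Thevenin model fit of a sweep."""

    voc: float
    rint: float
    voc_stderr: float
    rint_stderr: float
    flags: tuple[str, ...] = ()


def estimate_internal_resistance(sweep: PolarizationSweep) -> TheveninFit:
    """Fit ``V = Voc·R/(R + Rint)`` to the sweep (quality diagnostic).

    Requires >= 3 points.  A sweep whose voltage is not monotone
    nondecreasing in R (after sorting) is flagged ``nonmonotone_voltage``;
    fit failure returns NaN estimates with ``fit_failed``.
    """
    r = np.asarray(sweep.external_resistance, dtype=float)
    v = np.asarray(sweep.voltage, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 sweep points to fit")
    order = np.argsort(r)
    flags: list[str] = []
    if np.any(np.diff(v[order]) < -1e-12):
        flags.append("nonmonotone_voltage")

    def model(rr, voc, rint):
        return voc * rr / (rr + rint)

    try:
        p0 = (float(v.max()) or 0.1, float(np.median(r)))
        popt, pcov = curve_fit(
            model, r, v, p0=p0,
            bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=10000,
        )
        perr = np.sqrt(np.diag(pcov))
        if not np.all(np.isfinite(popt)) or popt[1] <= 0:
            raise RuntimeError("degenerate fit")
        return TheveninFit(
            voc=float(popt[0]), rint=float(popt[1]),
            voc_stderr=float(perr[0]), rint_stderr=float(perr[1]),
            flags=tuple(flags),
        )
    except (RuntimeError, ValueError):
        return TheveninFit(
            voc=float("nan"), rint=float("nan"),
            voc_stderr=float("nan"), rint_stderr=float("nan"),
            flags=tuple(flags) + ("fit_failed",),
        )


SWEEP_COLUMNS = ["sample_id", "R_ohm", "V_volt", "area_m2"]


def read_sweep_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sweep table missing columns: {missing}")
    return df


def sweeps_from_table(df: pd.DataFrame) -> list[PolarizationSweep]:
    out = []
    for sample, sub in df.groupby("sample_id", sort=True):
        out.append(PolarizationSweep(
            external_resistance=tuple(sub["R_ohm"]),
            voltage=tuple(sub["V_volt"]),
            anode_area=float(sub["area_m2"].iloc[0]),
            sample_id=str(sample),
        ))
    return out
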