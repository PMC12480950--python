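"""¹⁵N isotope pairing: N₂ isotopologue production rates and partitioning.

In a ¹⁵NO₃⁻-amended sediment incubation, denitrification draws pairs of N
atoms at random from a nitrate pool with ¹⁵N atom fraction ``FN``, while
anammox pairs one pool-derived atom with one ambient ¹⁴NH₄⁺-derived atom.
Writing ``D`` for total denitrification N₂ production and ``A`` for anammox
N₂ production, the forward model for the accumulation slopes of the two
labeled isotopologues is

    p30 = D * FN**2
    p29 = 2 * D * FN * (1 - FN) + A * FN

The (revised) isotope-pairing inversion used here is the exact inverse:

    D = p30 / FN**2
    A = p29 / FN - 2 * (1 - FN) / FN**2 * p30

Slopes come from ordinary least-squares regression of isotopologue
concentration on time across sacrificial vials (replicates pooled, not
averaged, to preserve degrees of freedom).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LabeledIncubation",
    "RateFit",
    "RateResult",
    "fit_production_rate",
    "ipt_partition",
    "normalize_rate",
    "fn_from_nitrate",
    "analyze_incubation",
    "read_incubation_table",
    "incubations_from_table",
]


@dataclass(frozen=True)
class LabeledIncubation:
    """A ¹⁵N-amended vial time series (sacrificial design, replicates flat).

    ``times`` (h), ``conc29``/``conc30`` (µmol L^-1) are parallel arrays with
    one entry per vial.
    """

    times: tuple[float, ...]
    conc29: tuple[float, ...]
    conc30: tuple[float, ...]
    fn: float
    sediment_dry_mass: float = 2.0  # g
    liquid_volume: float = 11.0  # mL
    group_label: str = "Blank"
    pair_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) < 2 or len(set(self.times)) < 2:
            raise ValueError("need at least 2 distinct time points")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be nondecreasing")
        if not 0.0 < self.fn <= 1.0:
            raise ValueError("fn must be in (0, 1]")
        if len(self.conc29) != len(t) or len(self.conc30) != len(t):
            raise ValueError("times/conc29/conc30 lengths must match")
        if min(self.conc29) < 0 or min(self.conc30) < 0:
            raise ValueError("concentrations must be nonnegative")


@dataclass(frozen=True)
class RateFit:
    """An OLS slope with its inference summary."""

    slope: float
    stderr: float
    r_squared: float
    pvalue: float
    intercept: float
    n: int
    flags: tuple[str, ...] = ()


def fit_production_rate(times, conc) -> RateFit:
    """OLS slope of concentration vs time (µmol L^-1 h^-1).

    With exactly two points the slope is returned but SE and p are flagged
    unavailable (NaN).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size != c.size:
        raise ValueError("times and conc must have equal length")
    if t.size < 2:
        raise ValueError("need at least 2 points")
    if np.allclose(t, t[0]):
        raise ValueError("all times identical; slope undefined")
    if t.size == 2:
        slope = (c[1] - c[0]) / (t[1] - t[0])
        return RateFit(
            slope=slope, stderr=math.nan, r_squared=1.0, pvalue=math.nan,
            intercept=c[0] - slope * t[0], n=2,
            flags=("inference_unavailable_n2",),
        )
    res = stats.linregress(t, c)
    return RateFit(
        slope=res.slope, stderr=res.stderr,
        r_squared=res.rvalue ** 2, pvalue=res.pvalue,
        intercept=res.intercept, n=int(t.size),
    )


@dataclass(frozen=True)
class IptPartition:
    """Denitrification/anammox split of total N₂ production."""

    d_rate: float
    a_rate: float
    fraction_denitrification: float
    d_rate_clamped: float
    a_rate_clamped: float
    flags: tuple[str, ...] = ()


def ipt_partition(p29: float, p30: float, fn: float) -> IptPartition:
    """Partition isotopologue production into denitrification and anammox.

    ``D = p30/FN²``; ``A = p29/FN − 2(1−FN)/FN² · p30``.  Negative rates are
    reported raw with a flag (``negative_a_rate`` / ``negative_d_rate``);
    clamped-to-zero copies are provided for downstream summaries.  The
    denitrification fraction is ``D/(D+A)``, computed from the raw rates
    when both are nonnegative and from the clamped rates (with a flag)
    otherwise; it is NaN with ``fraction_undefined`` when D+A = 0.
    """
    if not np.isfinite(p29) or not np.isfinite(p30):
        raise ValueError("rates must be finite")
    if not 0.0 < fn <= 1.0:
        raise ValueError("fn must be in (0, 1]")
    d = p30 / fn ** 2
    a = p29 / fn - 2.0 * (1.0 - fn) / fn ** 2 * p30
    flags: list[str] = []
    if d < 0:
        flags.append("negative_d_rate")
    if a < 0:
        flags.append("negative_a_rate")
    d_cl, a_cl = max(d, 0.0), max(a, 0.0)
    if d >= 0 and a >= 0:
        total = d + a
        frac = d / total if total > 0 else math.nan
    else:
        total = d_cl + a_cl
        frac = d_cl / total if total > 0 else math.nan
        flags.append("fraction_from_clamped")
    if total == 0:
        flags.append("fraction_undefined")
    return IptPartition(
        d_rate=d, a_rate=a, fraction_denitrification=frac,
        d_rate_clamped=d_cl, a_rate_clamped=a_cl, flags=tuple(flags),
    )


def normalize_rate(
    slope: float,
    liquid_volume: float,
    sediment_dry_mass: float,
    per_n_atom: bool = False,
) -> float:
    """Convert a volumetric slope to a per-gram rate (nmol g^-1 h^-1).

    ``rate = slope [µmol L⁻¹ h⁻¹] × (V/1000) [L] / m [g] × 1000 [nmol/µmol]``.
    By default the unit is nmol N₂ g^-1 h^-1; ``per_n_atom=True`` multiplies
    by 2 to express nmol N g^-1 h^-1.
    """
    if liquid_volume <= 0 or sediment_dry_mass <= 0:
        raise ValueError("liquid_volume and sediment_dry_mass must be positive")
    rate = slope * liquid_volume / sediment_dry_mass
    return 2.0 * rate if per_n_atom else rate


def fn_from_nitrate(
    added_15no3: float, ambient_no3: float, label_atom_fraction: float = 0.99
) -> float:
    """¹⁵N atom fraction of the nitrate pool after tracer addition.

    ``FN = f_label * added / (added + ambient)`` for a ¹⁵N-enriched tracer
    with atom fraction ``label_atom_fraction`` diluted by ambient (natural
    abundance ≈ 0) nitrate; concentrations in any common unit.
    """
    if added_15no3 <= 0:
        raise ValueError("added tracer concentration must be positive")
    if ambient_no3 < 0:
        raise ValueError("ambient nitrate must be nonnegative")
    if not 0.0 < label_atom_fraction <= 1.0:
        raise ValueError("label_atom_fraction must be in (0, 1]")
    return label_atom_fraction * added_15no3 / (added_15no3 + ambient_no3)


@dataclass
class RateResult:
    """Full per-vial-set result: slopes, partition, per-gram rates."""

    p29: RateFit
    p30: RateFit
    partition: IptPartition
    d_rate_per_g: float
    a_rate_per_g: float
    group_label: str = ""
    pair_id: str = ""
    quality_flags: tuple[str, ...] = field(default_factory=tuple)


def analyze_incubation(inc: LabeledIncubation) -> RateResult:
    """Fit both isotopologue slopes and partition the N₂ production."""
    f29 = fit_production_rate(inc.times, inc.conc29)
    f30 = fit_production_rate(inc.times, inc.conc30)
    part = ipt_partition(f29.slope, f30.slope, inc.fn)
    d_g = normalize_rate(part.d_rate, inc.liquid_volume, inc.sediment_dry_mass)
    a_g = normalize_rate(part.a_rate, inc.liquid_volume, inc.sediment_dry_mass)
    return RateResult(
        p29=f29, p30=f30, partition=part,
        d_rate_per_g=d_g, a_rate_per_g=a_g,
        group_label=inc.group_label, pair_id=inc.pair_id,
        quality_flags=f29.flags + f30.flags + part.flags,
    )


INCUBATION_COLUMNS = [
    "pair_id", "group", "time_h", "n29_umol_L", "n30_umol_L",
    "fn", "dry_mass_g", "vol_mL",
]


def read_incubation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in INCUBATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"incubation table missing columns: {missing}")
    return df


def incubations_from_table(df: pd.DataFrame) -> list[LabeledIncubation]:
    """Group a long vial table into LabeledIncubation objects."""
    out = []
    for (pair, group), sub in df.groupby(["pair_id", "group"], sort=True):
        sub = sub.sort_values("time_h")
        out.append(LabeledIncubation(
            times=tuple(sub["time_h"]),
            conc29=tuple(sub["n29_umol_L"]),
            conc30=tuple(sub["n30_umol_L"]),
            fn=float(sub["fn"].iloc[0]),
            sediment_dry_mass=float(sub["dry_mass_g"].iloc[0]),
            liquid_volume=float(sub["vol_mL"].iloc[0]),
            group_label=str(group),
            pair_id=str(pair),
        ))
    return out
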