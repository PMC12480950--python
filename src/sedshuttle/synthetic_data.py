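"""Seeded generators for every input the analysis chain consumes.

Each generator is a pure function of its configuration and seed, and each
has an exact noise-free inversion by its paired analysis stage: the
headspace generator runs the forward two-phase mass balance, the
incubation generator the forward isotope-pairing model, the polarization
generator a Thevenin cell, and the qPCR generator shifts target Ct by
−log₂(fold) in the treated group.  The survey generator reproduces the
field study's statistical structure: 12 sites, humic substances (HS)
log-uniform over 9.5–230.1 mg g⁻¹, humic acid ≈ 92.8 ± 9.4 % of HS,
maximum power density (MPD) linearly coupled to HS (target R² ≈ 0.7355),
excess N₂ driven by MPD alone (target R² ≈ 0.7926), excess N₂O negatively
coupled to MPD, and independent physicochemical nuisance columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gas_chemistry import (
    GAS_CONSTANT_L_ATM,
    DEFAULT_ATM_MOLE_FRACTIONS,
    HeadspaceSample,
    equilibrium_concentration,
    n2o_solubility_coefficient,
)
from .isotope_pairing import LabeledIncubation
from .mfc_power import PolarizationSweep

__all__ = [
    "SurveyGeneratorConfig",
    "IncubationGeneratorConfig",
    "generate_survey",
    "gas_table_from_survey",
    "generate_incubation",
    "generate_headspace",
    "generate_polarization",
    "generate_qpcr",
    "DEFAULT_QPCR_FOLDS",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _noise_sd_for_r2(signal: np.ndarray, r2_target: float) -> float:
    """Noise s.d. giving the target R² for a linear signal-plus-noise model.

    R² = var(signal) / (var(signal) + σ²)  ⇒  σ = sd(signal)·√((1−R²)/R²).
    """
    if not 0.0 < r2_target <= 1.0:
        raise ValueError("R² target must be in (0, 1]")
    sd_sig = float(np.std(signal, ddof=1))
    if sd_sig == 0 and r2_target < 1.0:
        raise ValueError(
            "infeasible coupling: zero signal span cannot reach R² < 1"
        )
    if r2_target == 1.0:
        return 0.0
    return sd_sig * np.sqrt((1.0 - r2_target) / r2_target)


@dataclass(frozen=True)
class SurveyGeneratorConfig:
    """Ground-truth structure of the synthetic 12-site survey."""

    seed: int
    n_sites: int = 12
    hs_range: tuple[float, float] = (9.5, 230.1)  # mg g^-1 sediment
    ha_fraction_mean: float = 0.928
    ha_fraction_sd: float = 0.094
    mpd_hs_slope: float = 0.33  # uW m^-2 per mg g^-1
    mpd_hs_r2: float = 0.7355
    n2_mpd_slope: float = 0.5  # umol L^-1 per uW m^-2
    n2_mpd_r2: float = 0.7926
    n2o_mpd_slope: float = -4e-4  # umol L^-1 per uW m^-2 (negative coupling)
    n2o_base: float = 0.045  # umol L^-1 excess at MPD = 0
    n2o_noise_sd: float = 0.008
    t_equil_c: float = 25.0
    salinity: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sites < 4:
            raise ValueError("need at least 4 sites")
        if self.hs_range[0] <= 0 or self.hs_range[1] <= self.hs_range[0]:
            raise ValueError("hs_range must be positive and increasing")


def generate_survey(config: SurveyGeneratorConfig) -> pd.DataFrame:
    """Synthetic per-site survey table (one row per site)."""
    rng = _rng(config.seed)
    n = config.n_sites
    lo, hi = config.hs_range
    hs = np.exp(rng.uniform(np.log(lo), np.log(hi), n))

    frac = rng.normal(config.ha_fraction_mean, config.ha_fraction_sd, n)
    while np.any((frac <= 0) | (frac > 1)):  # truncate to (0, 1]
        bad = (frac <= 0) | (frac > 1)
        frac[bad] = rng.normal(
            config.ha_fraction_mean, config.ha_fraction_sd, int(bad.sum())
        )
    ha = frac * hs
    fa = hs - ha

    mpd_signal = config.mpd_hs_slope * hs
    mpd = mpd_signal + rng.normal(
        0, _noise_sd_for_r2(mpd_signal, config.mpd_hs_r2), n
    )

    n2_signal = config.n2_mpd_slope * mpd
    delta_n2 = n2_signal + rng.normal(
        0, _noise_sd_for_r2(n2_signal, config.n2_mpd_r2), n
    )

    delta_n2o = (
        config.n2o_base + config.n2o_mpd_slope * mpd
        + rng.normal(0, config.n2o_noise_sd, n)
    )

    temp_w = rng.normal(18.0, 2.0, n)
    n2_eq = np.array([
        equilibrium_concentration("N2", t + 273.15, config.salinity)
        for t in temp_w
    ])
    n2o_eq = np.array([
        equilibrium_concentration("N2O", t + 273.15, config.salinity)
        for t in temp_w
    ])
    n2 = n2_eq + delta_n2
    n2o = n2o_eq + delta_n2o

    ratio_total = delta_n2o + delta_n2
    n2o_ratio = np.where(ratio_total != 0, delta_n2o / ratio_total, np.nan)

    return pd.DataFrame({
        "site_id": [f"S{i + 1:02d}" for i in range(n)],
        "HS_mg_g": hs,
        "HA_mg_g": ha,
        "FA_mg_g": fa,
        "MPD_uW_m2": mpd,
        "DO_mg_L": rng.normal(8.0, 1.5, n),
        "pH": rng.normal(7.8, 0.4, n),
        "T_water_C": temp_w,
        "NO3_mg_kg": np.exp(rng.normal(0.8, 0.5, n)),
        "NH4_mg_kg": np.exp(rng.normal(0.2, 0.5, n)),
        "NO2_mg_kg": np.exp(rng.normal(-1.5, 0.5, n)),
        "n2_umol_L": n2,
        "n2_eq_umol_L": n2_eq,
        "delta_n2_umol_L": delta_n2,
        "n2o_umol_L": n2o,
        "n2o_eq_umol_L": n2o_eq,
        "delta_n2o_umol_L": delta_n2o,
        "n2o_over_n2o_plus_n2": n2o_ratio,
    })


def gas_table_from_survey(
    survey: pd.DataFrame,
    config: SurveyGeneratorConfig,
    cg_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Raw gas-measurement table whose processing recovers the survey gases.

    Headspace N₂O concentrations come from the forward two-phase mass
    balance at the equilibration temperature; the N₂:Ar ratio from the
    site's dissolved N₂ over the equilibrium Ar concentration.
    """
    rng = _rng(config.seed + 1)
    t_eq = config.t_equil_c + 273.15
    k0 = n2o_solubility_coefficient(t_eq, config.salinity)
    k0rt = k0 * GAS_CONSTANT_L_ATM * t_eq
    vg, vl = 40.0, 160.0
    r = vg / vl
    # ambient-air N2O gas-phase concentration (umol per liter of air)
    x_n2o = DEFAULT_ATM_MOLE_FRACTIONS["N2O"]
    cair = x_n2o / (GAS_CONSTANT_L_ATM * t_eq) * 1e6
    rows = []
    for rec in survey.itertuples(index=False):
        cg = (rec.n2o_umol_L + cair * r) / (r + k0rt)
        if cg_noise_sd > 0:
            cg = max(cg + rng.normal(0, cg_noise_sd), 0.0)
        ar_eq = equilibrium_concentration(
            "Ar", rec.T_water_C + 273.15, config.salinity
        )
        rows.append({
            "site_id": rec.site_id,
            "T_insitu_C": rec.T_water_C,
            "T_equil_C": config.t_equil_c,
            "salinity": config.salinity,
            "Cg_umol_L": cg,
            "Cair_umol_L": cair,
            "Vg_mL": vg,
            "Vl_mL": vl,
            "n2ar_ratio": rec.n2_umol_L / ar_eq,
            "k_m_d": rng.uniform(0.3, 1.5),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class IncubationGeneratorConfig:
    """Ground truth for paired Blank/HS_C vial incubations."""

    seed: int
    d_rate: float = 0.5  # umol L^-1 h^-1 total denitrification N2 production
    a_rate: float = 0.2  # umol L^-1 h^-1 anammox N2 production
    fn: float = 0.8
    timepoints: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0)
    replicates: int = 3
    noise_sd: float = 0.05  # umol L^-1 on each vial concentration
    hs_effect: float = 2.6  # multiplier on d_rate in HS_C vials
    n_pairs: int = 8
    pair_sd_log: float = 0.15  # between-pair lognormal spread of the rates
    baseline29: float = 0.5  # umol L^-1 background at t = 0
    baseline30: float = 0.1
    sediment_dry_mass: float = 2.0  # g
    liquid_volume: float = 11.0  # mL

    def __post_init__(self) -> None:
        if self.d_rate < 0 or self.a_rate < 0:
            raise ValueError("rates must be nonnegative")
        if not 0.0 < self.fn <= 1.0:
            raise ValueError("fn must be in (0, 1]")


def generate_incubation(
    config: IncubationGeneratorConfig,
) -> list[tuple[LabeledIncubation, LabeledIncubation]]:
    """Paired (Blank, HS_C) vial time series from the forward pairing model.

    ``p30 = D·FN²`` and ``p29 = 2D·FN(1−FN) + A·FN`` accumulate linearly in
    time with Gaussian measurement noise; HS_C vials multiply D by the
    configured enhancement.
    """
    rng = _rng(config.seed)
    fn = config.fn
    times = tuple(
        t for t in config.timepoints for _ in range(config.replicates)
    )
    pairs = []
    for i in range(config.n_pairs):
        scale = (
            np.exp(rng.normal(0.0, config.pair_sd_log))
            if config.pair_sd_log > 0 else 1.0
        )
        d_pair = config.d_rate * scale
        a_pair = config.a_rate * scale
        vials = {}
        for group, d in (("Blank", d_pair), ("HS_C", d_pair * config.hs_effect)):
            p30 = d * fn ** 2
            p29 = 2.0 * d * fn * (1.0 - fn) + a_pair * fn
            t_arr = np.asarray(times)
            c29 = config.baseline29 + p29 * t_arr
            c30 = config.baseline30 + p30 * t_arr
            if config.noise_sd > 0:
                c29 = c29 + rng.normal(0, config.noise_sd, c29.size)
                c30 = c30 + rng.normal(0, config.noise_sd, c30.size)
            vials[group] = LabeledIncubation(
                times=times,
                conc29=tuple(np.clip(c29, 0.0, None)),
                conc30=tuple(np.clip(c30, 0.0, None)),
                fn=fn,
                sediment_dry_mass=config.sediment_dry_mass,
                liquid_volume=config.liquid_volume,
                group_label=group,
                pair_id=f"P{i + 1:02d}",
            )
        pairs.append((vials["Blank"], vials["HS_C"]))
    return pairs


def incubation_table(
    pairs: list[tuple[LabeledIncubation, LabeledIncubation]],
) -> pd.DataFrame:
    """Flatten generated pairs to the long CSV layout the readers expect."""
    rows = []
    for blank, hs in pairs:
        for inc in (blank, hs):
            for t, c29, c30 in zip(inc.times, inc.conc29, inc.conc30):
                rows.append({
                    "pair_id": inc.pair_id,
                    "group": inc.group_label,
                    "time_h": t,
                    "n29_umol_L": c29,
                    "n30_umol_L": c30,
                    "fn": inc.fn,
                    "dry_mass_g": inc.sediment_dry_mass,
                    "vol_mL": inc.liquid_volume,
                })
    return pd.DataFrame(rows)


def generate_headspace(
    true_cw: float,
    cair: float,
    vg_ml: float = 40.0,
    vl_ml: float = 160.0,
    k0: float = 0.0247,
    temperature: float = 298.15,
    n: int = 1,
    noise_sd: float = 0.0,
    seed=0,
) -> list[HeadspaceSample]:
    """Forward-partitioned headspace samples for a known dissolved Cw.

    ``Cg = (Cw + Cair·(Vg/Vl)) / (Vg/Vl + K0·R·T)`` plus optional Gaussian
    measurement noise on Cg (clipped at zero).
    """
    rng = _rng(seed)
    r = vg_ml / vl_ml
    k0rt = k0 * GAS_CONSTANT_L_ATM * temperature
    cg_true = (true_cw + cair * r) / (r + k0rt)
    samples = []
    for _ in range(n):
        cg = cg_true + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        samples.append(HeadspaceSample(
            headspace_conc=max(cg, 0.0),
            air_conc=cair,
            gas_volume=vg_ml,
            liquid_volume=vl_ml,
            temperature=temperature,
            solubility_coeff=k0,
        ))
    return samples


def generate_polarization(
    voc: float = 0.4,
    rint: float = 800.0,
    r_grid: tuple[float, ...] = (
        5000.0, 3000.0, 2000.0, 1500.0, 1000.0, 800.0, 600.0, 400.0,
        200.0, 100.0,
    ),
    area: float = 0.01,
    noise_sd: float = 0.0,
    seed=0,
    sample_id: str = "synthetic",
) -> PolarizationSweep:
    """Thevenin-cell sweep ``V = Voc·R/(R + Rint)`` with optional noise."""
    rng = _rng(seed)
    r = np.asarray(r_grid, dtype=float)
    v = voc * r / (r + rint)
    if noise_sd > 0:
        v = v + rng.normal(0, noise_sd, v.size)
    return PolarizationSweep(
        external_resistance=tuple(r),
        voltage=tuple(np.clip(v, 0.0, None)),
        anode_area=area,
        sample_id=sample_id,
    )


#: Fold changes (HS_C/Blank) used as generator defaults, one per panel gene.
DEFAULT_QPCR_FOLDS = {
    "nirS": 6.0, "nirK": 4.6, "nosZI": 7.7, "nosZII": 31.5,
    "omcB": 31.5, "omcS": 2.0, "pilA": 3.3,
}


def generate_qpcr(
    true_folds: dict[str, float] | None = None,
    n_pairs: int = 8,
    ct_noise_sd: float = 0.2,
    biomass_sd: float = 1.0,
    seed=0,
    efficiency: float = 2.0,
    timepoint: float = 24.0,
) -> pd.DataFrame:
    """Synthetic paired Ct table with known treatment fold changes.

    Each physical sample carries a biomass offset (s.d. ``biomass_sd``
    cycles) applied to both its 16S reference Ct (around 15 cycles) and its
    target Ct (around a per-pair baseline near 25) — exactly the nuisance
    the 16S normalization cancels.  The treated group's target Ct is
    additionally shifted by ``−log₂(fold)`` so the efficiency-2 normalized
    expression ratio equals the configured fold.  Independent Gaussian read
    noise (``ct_noise_sd`` cycles) applies to every Ct.
    """
    rng = _rng(seed)
    folds = dict(DEFAULT_QPCR_FOLDS if true_folds is None else true_folds)
    rows = []
    for gene, fold in folds.items():
        if fold <= 0:
            raise ValueError(f"fold for {gene!r} must be positive")
        shift = np.log2(fold)
        for i in range(n_pairs):
            pair = f"P{i + 1:02d}"
            base_target = rng.normal(25.0, 1.0)
            for group, delta in (("Blank", 0.0), ("HS_C", -shift)):
                biomass = rng.normal(0.0, biomass_sd)
                rows.append({
                    "target_gene": gene,
                    "ct_target": base_target + biomass + delta
                    + rng.normal(0, ct_noise_sd),
                    "ct_reference": 15.0 + biomass
                    + rng.normal(0, ct_noise_sd),
                    "group": group,
                    "pair_id": pair,
                    "efficiency": efficiency,
                    "timepoint": timepoint,
                })
    return pd.DataFrame(rows)
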