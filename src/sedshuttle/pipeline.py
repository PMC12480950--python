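"""Pipeline orchestration: stage wiring, config, logging, report assembly.

Stages (any subset): ``simulate`` writes synthetic CSV inputs,
``gas`` processes the site gas table, ``ipt`` the vial incubations,
``mfc`` the polarization sweeps, ``qpcr`` the Ct table, ``drivers`` the
merged site survey.  Every run is a pure function of (config, seed): the
JSON summary embeds the config hash and per-stage outputs, and re-running
a single stage on the saved intermediates reproduces the full-run result
for that stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    driver_stats,
    expression_qpcr,
    gas_chemistry,
    isotope_pairing,
    mfc_power,
    synthetic_data,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

ALL_STAGES = ("simulate", "gas", "ipt", "mfc", "qpcr", "drivers")


@dataclass
class PipelineConfig:
    """Everything a run needs; YAML-loadable via :func:`load_config`."""

    seed: int = 0
    outdir: str = "sedshuttle_out"
    stages: tuple[str, ...] = ALL_STAGES
    # input CSVs; ignored for any table the simulate stage writes
    gas_table: str | None = None
    incubation_table: str | None = None
    sweep_table: str | None = None
    ct_table: str | None = None
    site_table: str | None = None
    # statistical options
    alpha: float = 0.05
    criterion: str = "aicc"
    spearman_screen: bool = True
    transform_policy: bool = True
    ratio_summary: str = "geometric"
    # generator overrides (field name -> value)
    survey: dict = field(default_factory=dict)
    incubation: dict = field(default_factory=dict)
    qpcr: dict = field(default_factory=dict)
    atm_mole_fractions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if "simulate" not in self.stages:
            needed = {
                "gas": self.gas_table, "ipt": self.incubation_table,
                "mfc": self.sweep_table, "qpcr": self.ct_table,
                "drivers": self.site_table,
            }
            for stage, path in needed.items():
                if stage in self.stages and (
                    path is None or not Path(path).exists()
                ):
                    raise ValueError(
                        f"stage {stage!r} enabled without simulate but its "
                        f"input table is missing: {path!r}"
                    )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(**raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


DRIVER_CANDIDATES = [
    "HS_mg_g", "HA_mg_g", "FA_mg_g", "MPD_uW_m2", "DO_mg_L", "pH",
    "T_water_C", "NO3_mg_kg", "NH4_mg_kg", "NO2_mg_kg",
]


def _stage_simulate(config: PipelineConfig, outdir: Path, log) -> dict:
    survey_cfg = synthetic_data.SurveyGeneratorConfig(
        seed=config.seed, **config.survey
    )
    survey = synthetic_data.generate_survey(survey_cfg)
    gas = synthetic_data.gas_table_from_survey(survey, survey_cfg)
    inc_cfg = synthetic_data.IncubationGeneratorConfig(
        seed=config.seed + 10, **config.incubation
    )
    pairs = synthetic_data.generate_incubation(inc_cfg)
    inc_table = synthetic_data.incubation_table(pairs)
    sweep_rows = []
    rng = np.random.default_rng(config.seed + 20)
    for rec in survey.itertuples(index=False):
        rint = float(rng.uniform(500, 1500))
        area = 0.01
        voc = float(np.sqrt(max(rec.MPD_uW_m2, 0.05) * 1e-6 * 4 * rint * area))
        sweep = synthetic_data.generate_polarization(
            voc=voc, rint=rint, area=area, noise_sd=0.002,
            seed=rng.integers(2 ** 31), sample_id=str(rec.site_id),
        )
        for r, v in zip(sweep.external_resistance, sweep.voltage):
            sweep_rows.append({
                "sample_id": sweep.sample_id, "R_ohm": r,
                "V_volt": v, "area_m2": sweep.anode_area,
            })
    sweeps = pd.DataFrame(sweep_rows)
    ct = synthetic_data.generate_qpcr(seed=config.seed + 30, **config.qpcr)

    paths = {}
    for name, df in (
        ("site_table", survey), ("gas_table", gas),
        ("incubation_table", inc_table), ("sweep_table", sweeps),
        ("ct_table", ct),
    ):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
        setattr(config, name, str(p))
    log(f"simulate: wrote {len(paths)} tables")
    return {"tables": paths, "n_sites": len(survey)}


def _stage_gas(config: PipelineConfig, outdir: Path, log) -> dict:
    df = gas_chemistry.read_gas_table(config.gas_table)
    out = gas_chemistry.process_gas_table(
        df, mole_fractions=config.atm_mole_fractions or None
    )
    path = outdir / "gas_results.csv"
    out.to_csv(path, index=False)
    log(f"gas: processed {len(out)} sites")
    return {
        "output": str(path),
        "n_sites": len(out),
        "mean_delta_n2o_umol_L": float(out["delta_n2o_umol_L"].mean()),
        "mean_n2o_flux_umol_m2_d": float(out["n2o_flux_umol_m2_d"].mean()),
    }


def _stage_ipt(config: PipelineConfig, outdir: Path, log) -> dict:
    df = isotope_pairing.read_incubation_table(config.incubation_table)
    incs = isotope_pairing.incubations_from_table(df)
    rows = []
    for inc in incs:
        res = isotope_pairing.analyze_incubation(inc)
        rows.append({
            "pair_id": res.pair_id,
            "group": res.group_label,
            "p29_slope": res.p29.slope,
            "p30_slope": res.p30.slope,
            "d_rate_umol_L_h": res.partition.d_rate,
            "a_rate_umol_L_h": res.partition.a_rate,
            "fraction_denitrification": res.partition.fraction_denitrification,
            "d_rate_nmol_g_h": res.d_rate_per_g,
            "a_rate_nmol_g_h": res.a_rate_per_g,
            "flags": ";".join(res.quality_flags),
        })
    out = pd.DataFrame(rows)
    path = outdir / "ipt_rates.csv"
    out.to_csv(path, index=False)
    wide = out.pivot(index="pair_id", columns="group", values="d_rate_umol_L_h")
    ratio = float((wide["HS_C"] / wide["Blank"]).median()) \
        if {"HS_C", "Blank"} <= set(wide.columns) else float("nan")
    summary = {
        "output": str(path),
        "mean_fraction_denitrification": float(
            out["fraction_denitrification"].mean()
        ),
        "median_d_rate_enhancement": ratio,
    }
    log(f"ipt: {len(out)} vial sets; median HS_C/Blank d-ratio {ratio:.2f}")
    return summary


def _stage_mfc(config: PipelineConfig, outdir: Path, log) -> dict:
    df = mfc_power.read_sweep_table(config.sweep_table)
    sweeps = mfc_power.sweeps_from_table(df)
    rows = []
    for sweep in sweeps:
        mpd, r_at = mfc_power.max_power_density(sweep)
        fit = mfc_power.estimate_internal_resistance(sweep)
        rows.append({
            "sample_id": sweep.sample_id,
            "mpd_uW_m2": mpd,
            "r_at_mpd_ohm": r_at,
            "rint_ohm": fit.rint,
            "voc_V": fit.voc,
            "flags": ";".join(fit.flags),
        })
    out = pd.DataFrame(rows)
    path = outdir / "mfc_results.csv"
    out.to_csv(path, index=False)
    log(f"mfc: {len(out)} sweeps")
    return {
        "output": str(path),
        "mpd_range_uW_m2": [
            float(out["mpd_uW_m2"].min()), float(out["mpd_uW_m2"].max())
        ],
    }


def _stage_qpcr(config: PipelineConfig, outdir: Path, log) -> dict:
    df = expression_qpcr.read_ct_table(config.ct_table)
    genes = sorted(df["target_gene"].unique())
    rows, pvals = [], []
    for gene in genes:
        tr = expression_qpcr.treatment_ratio(
            df, gene, summary=config.ratio_summary
        )
        expr = expression_qpcr.expression_table(
            df[df["target_gene"] == gene]
        )
        wide = expr.pivot_table(
            index="pair_id", columns="group", values="expression",
            aggfunc="mean",
        ).dropna()
        test = expression_qpcr.paired_test(
            np.log10(wide["HS_C"]), np.log10(wide["Blank"]),
            alpha=config.alpha,
        )
        rows.append({
            "gene": gene, "fold_ratio": tr.ratio, "n_pairs": tr.n_pairs,
            "test": test.test, "statistic": test.statistic,
            "pvalue": test.pvalue,
        })
        pvals.append(test.pvalue)
    out = pd.DataFrame(rows)
    out["qvalue"] = expression_qpcr.bh_fdr(np.asarray(pvals))
    path = outdir / "qpcr_results.csv"
    out.to_csv(path, index=False)
    summary = {
        "output": str(path),
        "fold_ratios": {r["gene"]: r["fold_ratio"] for r in rows},
    }
    folds = summary["fold_ratios"]
    if "nosZII" in folds and "nosZI" in folds:
        summary["nosZII_over_nosZI"] = expression_qpcr.ratio_of_ratios(
            folds["nosZII"], folds["nosZI"]
        )
    log(f"qpcr: {len(genes)} genes tested")
    return summary


def _stage_drivers(config: PipelineConfig, outdir: Path, log) -> dict:
    table = pd.read_csv(config.site_table)
    candidates = [c for c in DRIVER_CANDIDATES if c in table.columns]
    results = {}
    for response in ("n2_umol_L", "delta_n2_umol_L"):
        if response not in table.columns:
            continue
        work, cands = table, candidates
        if config.transform_policy:
            work, cands, _ = driver_stats.apply_transform_policy(
                table, response, candidates
            )
        if config.spearman_screen:
            screened = driver_stats.screen_candidates(
                work, response, cands, alpha=config.alpha
            )
        else:
            screened = cands
        report = driver_stats.stepwise_aic_mlr(
            work, response, screened, criterion=config.criterion
        )
        results[response] = report.to_dict()
        results[response]["screened_candidates"] = screened
    path = outdir / "driver_report.json"
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, default=str)
    log(
        "drivers: "
        + "; ".join(
            f"{resp} -> {res['selected']}" for resp, res in results.items()
        )
    )
    return {
        "output": str(path),
        "selected": {r: res["selected"] for r, res in results.items()},
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "gas": _stage_gas,
    "ipt": _stage_ipt,
    "mfc": _stage_mfc,
    "qpcr": _stage_qpcr,
    "drivers": _stage_drivers,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order; return (and write) the summary.

    A stage failure halts the pipeline with the failing stage named;
    outputs of completed stages remain on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    summary: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            result = _STAGE_FUNCS[stage](config, outdir, log)
        except Exception as exc:
            log(f"{stage}: FAILED ({exc})")
            (outdir / "pipeline_log.txt").write_text("\n".join(log_lines))
            raise RuntimeError(f"pipeline stage {stage!r} failed") from exc
        result["elapsed_s"] = round(time.perf_counter() - t0, 3)
        summary["stages"][stage] = result
    (outdir / "pipeline_log.txt").write_text("\n".join(log_lines) + "\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
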