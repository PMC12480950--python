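"""16S-normalized qPCR expression, paired treatment ratios, and BH-FDR.

Relative expression is the efficiency-corrected ΔCt form
``E^(Ct_ref − Ct_target)`` against the 16S rRNA reference (default
amplification efficiency 2.0, i.e. perfect doubling → 2^−ΔΔCt behaviour
across groups).  Treatment effects are summarized as HS_C/Blank fold
ratios per matched pair, combined with a geometric mean (ratios are
multiplicative), and group comparisons use a normality-routed paired
test: Shapiro–Wilk on the paired differences at α = 0.05 routes to a
paired t-test (normal) or the Wilcoxon matched-pairs signed-rank test
(otherwise).  Families of tests are corrected with Benjamini–Hochberg
step-up q-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KNOWN_GENES",
    "CtRecord",
    "relative_expression",
    "expression_table",
    "treatment_ratio",
    "ratio_of_ratios",
    "paired_test",
    "bh_fdr",
    "read_ct_table",
]

#: Target genes of the denitrification / N2O-reduction / EET panels.
KNOWN_GENES = ("nirS", "nirK", "nosZI", "nosZII", "omcB", "omcS", "pilA")


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement with its 16S reference Ct."""

    target_gene: str
    ct_target: float
    ct_reference: float
    group: str  # "Blank" | "HS_C"
    pair_id: str
    efficiency: float = 2.0
    timepoint: float = 24.0

    def __post_init__(self) -> None:
        if not 0.0 < self.ct_target < 45.0 or not 0.0 < self.ct_reference < 45.0:
            raise ValueError("Ct values must lie in (0, 45)")
        if not 1.0 < self.efficiency <= 2.2:
            raise ValueError("efficiency must be in (1, 2.2]")


def relative_expression(record: CtRecord) -> float:
    """Expression normalized to 16S: ``efficiency**(ct_reference − ct_target)``."""
    return record.efficiency ** (record.ct_reference - record.ct_target)


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["target_gene", "ct_target", "ct_reference", "group", "pair_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if "efficiency" not in df.columns:
        df = df.assign(efficiency=2.0)
    return df


def expression_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a 16S-normalized ``expression`` column to a Ct table."""
    eff = df["efficiency"] if "efficiency" in df.columns else 2.0
    expr = np.power(eff, df["ct_reference"] - df["ct_target"])
    return df.assign(expression=expr)


@dataclass(frozen=True)
class TreatmentRatio:
    """HS_C/Blank fold change for one gene, summarized across pairs."""

    gene: str
    ratio: float  # geometric (default) or arithmetic mean of per-pair ratios
    per_pair: tuple[float, ...]
    n_pairs: int
    dropped_pairs: tuple[str, ...] = ()


def treatment_ratio(
    df: pd.DataFrame,
    gene: str,
    treatment: str = "HS_C",
    control: str = "Blank",
    summary: str = "geometric",
) -> TreatmentRatio:
    """Per-pair treatment/control expression ratios for one gene.

    Pairs missing either partner are dropped (recorded in
    ``dropped_pairs``).  The cross-pair summary is the geometric mean by
    default; ``summary="arithmetic"`` is available behind the flag.
    """
    if summary not in ("geometric", "arithmetic"):
        raise ValueError("summary must be 'geometric' or 'arithmetic'")
    sub = expression_table(df[df["target_gene"] == gene])
    if sub.empty:
        raise ValueError(f"no records for gene {gene!r}")
    wide = sub.pivot_table(
        index="pair_id", columns="group", values="expression", aggfunc="mean"
    )
    for col in (treatment, control):
        if col not in wide.columns:
            wide[col] = np.nan
    complete = wide.dropna(subset=[treatment, control])
    dropped = tuple(str(p) for p in wide.index.difference(complete.index))
    if complete.empty:
        raise ValueError(f"no complete {treatment}/{control} pairs for {gene!r}")
    ratios = (complete[treatment] / complete[control]).to_numpy(dtype=float)
    if summary == "geometric":
        summ = float(np.exp(np.mean(np.log(ratios))))
    else:
        summ = float(np.mean(ratios))
    return TreatmentRatio(
        gene=gene, ratio=summ, per_pair=tuple(ratios),
        n_pairs=len(ratios), dropped_pairs=dropped,
    )


def ratio_of_ratios(fold_a: float, fold_b: float) -> float:
    """Ratio of two genes' fold-ratios (e.g. nosZII fold over nosZI fold)."""
    if fold_b == 0:
        raise ValueError("denominator fold-ratio is zero")
    return fold_a / fold_b


@dataclass(frozen=True)
class PairedTestResult:
    """Normality-routed paired comparison."""

    test: str  # "paired_t" | "wilcoxon" | "degenerate"
    statistic: float
    pvalue: float
    shapiro_p: float
    n: int
    flags: tuple[str, ...] = ()


def paired_test(values_a, values_b, alpha: float = 0.05) -> PairedTestResult:
    """Paired t-test or Wilcoxon signed-rank, routed by Shapiro–Wilk.

    The Shapiro–Wilk test is applied to the paired differences; p >= alpha
    routes to the paired t-test, otherwise to the Wilcoxon matched-pairs
    signed-rank test.  All-zero differences are degenerate and flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    if np.allclose(diff, 0.0):
        return PairedTestResult(
            test="degenerate", statistic=math.nan, pvalue=math.nan,
            shapiro_p=math.nan, n=int(a.size), flags=("all_differences_zero",),
        )
    sw = stats.shapiro(diff)
    if sw.pvalue >= alpha:
        res = stats.ttest_rel(a, b)
        return PairedTestResult(
            test="paired_t", statistic=float(res.statistic),
            pvalue=float(res.pvalue), shapiro_p=float(sw.pvalue), n=int(a.size),
        )
    res = stats.wilcoxon(a, b)
    return PairedTestResult(
        test="wilcoxon", statistic=float(res.statistic),
        pvalue=float(res.pvalue), shapiro_p=float(sw.pvalue), n=int(a.size),
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values for a family of p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
    return q
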