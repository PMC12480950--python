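"""Survey-scale driver analysis for dissolved N₂ / ΔN₂.

The workflow mirrors a standard environmental-driver chain on a per-site
survey table: Spearman screening of candidate drivers, simple linear
regression, bidirectional stepwise multiple regression optimizing an
information criterion, then validation of the selected model
(multicollinearity via VIF, residual normality and homoscedasticity,
nested-model F-tests) and effect sizing via standardized coefficients.

With only a dozen sites, the default information criterion is the
small-sample corrected AICc (parameter count includes the error
variance); plain AIC and BIC are selectable.  Two nonlinear fits used in
the same survey context are included: an exponential association
``y = a·exp(b·x) + c`` with a one-sided t on ``b``, and a one-phase decay
``y = (Y0 − plateau)·exp(−K·x) + plateau`` with ``K ≥ 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import curve_fit
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "spearman_matrix",
    "simple_lr",
    "SimpleLR",
    "screen_candidates",
    "stepwise_aic_mlr",
    "RegressionReport",
    "standardized_coefficients",
    "compare_nested",
    "exp_association_fit",
    "one_phase_decay_fit",
    "apply_transform_policy",
]


# ---------------------------------------------------------------------------
# Correlation screening
# ---------------------------------------------------------------------------

def spearman_matrix(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p matrices (midrank ties, NaN diagonal p).

    Constant columns yield NaN correlations (flagged by the NaN itself);
    each cell requires at least 4 complete pairs.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    n = len(cols)
    rho = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    pval = pd.DataFrame(np.full((n, n), np.nan), index=cols, columns=cols)
    for i in range(n):
        for j in range(i + 1, n):
            pair = table[[cols[i], cols[j]]].dropna()
            if len(pair) < 4:
                raise ValueError(
                    f"fewer than 4 complete pairs for "
                    f"({cols[i]}, {cols[j]})"
                )
            x, y = pair[cols[i]], pair[cols[j]]
            if x.nunique() < 2 or y.nunique() < 2:
                r, p = math.nan, math.nan
            else:
                r, p = stats.spearmanr(x, y)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    return rho, pval


def screen_candidates(
    table: pd.DataFrame, response: str, candidates: list[str],
    alpha: float = 0.05,
) -> list[str]:
    """Candidates whose Spearman correlation with the response has p < alpha."""
    keep = []
    for c in candidates:
        pair = table[[c, response]].dropna()
        if pair[c].nunique() < 2:
            continue
        _, p = stats.spearmanr(pair[c], pair[response])
        if np.isfinite(p) and p < alpha:
            keep.append(c)
    return keep


# ---------------------------------------------------------------------------
# Simple linear regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimpleLR:
    slope: float
    intercept: float
    r_squared: float
    pvalue: float
    stderr: float
    n: int


def simple_lr(x, y) -> SimpleLR:
    """OLS of y on a single x with two-sided p for the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return SimpleLR(
        slope=res.slope, intercept=res.intercept,
        r_squared=res.rvalue ** 2, pvalue=res.pvalue,
        stderr=res.stderr, n=int(x.size),
    )


# ---------------------------------------------------------------------------
# Stepwise multiple regression
# ---------------------------------------------------------------------------

def _criterion(fit, n: int, kind: str) -> float:
    """Information criterion with k counting coefficients plus sigma^2."""
    k = int(fit.df_model) + 2  # predictors + intercept + error variance
    neg2ll = -2.0 * fit.llf
    if kind == "aic":
        return neg2ll + 2.0 * k
    if kind == "bic":
        return neg2ll + k * math.log(n)
    if kind == "aicc":
        if n - k - 1 <= 0:
            return math.inf
        return neg2ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
    raise ValueError(f"unknown criterion {kind!r}")


def _fit_ols(y: np.ndarray, table: pd.DataFrame, terms: list[str]):
    X = sm.add_constant(table[terms], has_constant="add") if terms else \
        pd.DataFrame({"const": np.ones(len(y))}, index=table.index)
    return sm.OLS(y, X).fit()


def _drop_collinear(
    table: pd.DataFrame, candidates: list[str], log: list[str]
) -> list[str]:
    """Drop candidates that are (near-)perfectly collinear with earlier ones."""
    kept: list[str] = []
    for c in candidates:
        cols = kept + [c]
        X = table[cols].to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        norms = np.linalg.norm(Xc, axis=0)
        if norms[-1] == 0:
            log.append(f"dropped constant candidate {c!r}")
            continue
        rank = np.linalg.matrix_rank(Xc / np.where(norms == 0, 1, norms),
                                     tol=1e-8)
        if rank < len(cols):
            log.append(f"dropped collinear candidate {c!r}")
            continue
        kept.append(c)
    return kept


def standardized_coefficients(fit, table: pd.DataFrame, response: str) -> pd.DataFrame:
    """Betas on z-scored response and predictors, with CI, t, Cohen's d.

    ``beta_std_j = beta_j · sd(x_j)/sd(y)``; confidence intervals transform
    identically; ``Cohen's d = 2t/√df_resid``.
    """
    sd_y = table[response].std(ddof=1)
    if sd_y == 0:
        raise ValueError("response has zero variance")
    ci = fit.conf_int()
    rows = []
    for term in fit.params.index:
        if term == "const":
            continue
        sd_x = table[term].std(ddof=1)
        if sd_x == 0:
            raise ValueError(f"predictor {term!r} has zero variance")
        scale = sd_x / sd_y
        t = float(fit.tvalues[term])
        rows.append({
            "term": term,
            "coef": float(fit.params[term]),
            "stderr": float(fit.bse[term]),
            "t": t,
            "pvalue": float(fit.pvalues[term]),
            "ci_low": float(ci.loc[term, 0]),
            "ci_high": float(ci.loc[term, 1]),
            "std_coef": float(fit.params[term]) * scale,
            "std_ci_low": float(ci.loc[term, 0]) * scale,
            "std_ci_high": float(ci.loc[term, 1]) * scale,
            "cohen_d": 2.0 * t / math.sqrt(fit.df_resid),
        })
    return pd.DataFrame(rows)


def compare_nested(fit_reduced, fit_full) -> dict:
    """Partial F-test between nested OLS fits (reduced ⊂ full)."""
    rss_r, rss_f = fit_reduced.ssr, fit_full.ssr
    df_r, df_f = fit_reduced.df_resid, fit_full.df_resid
    ddf = df_r - df_f
    if ddf <= 0:
        raise ValueError("models are not strictly nested")
    f = ((rss_r - rss_f) / ddf) / (rss_f / df_f)
    p = float(stats.f.sf(f, ddf, df_f))
    return {"F": float(f), "df_num": float(ddf), "df_den": float(df_f), "pvalue": p}


@dataclass
class RegressionReport:
    """Selected model plus its validation diagnostics."""

    response: str
    selected: tuple[str, ...]
    coefficients: pd.DataFrame
    r_squared: float
    adj_r_squared: float
    criterion: str
    criterion_value: float
    aic: float
    vif: dict[str, float]
    residual_shapiro_p: float
    residual_breusch_pagan_p: float
    anova_vs_reduced: dict[str, dict]
    anova_vs_augmented: dict[str, dict]
    n: int
    log: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "selected": list(self.selected),
            "coefficients": self.coefficients.to_dict(orient="records"),
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "criterion": self.criterion,
            "criterion_value": self.criterion_value,
            "aic": self.aic,
            "vif": self.vif,
            "residual_shapiro_p": self.residual_shapiro_p,
            "residual_breusch_pagan_p": self.residual_breusch_pagan_p,
            "anova_vs_reduced": self.anova_vs_reduced,
            "anova_vs_augmented": self.anova_vs_augmented,
            "n": self.n,
            "log": list(self.log),
        }


def stepwise_aic_mlr(
    table: pd.DataFrame,
    response: str,
    candidates: list[str],
    criterion: str = "aicc",
    start: list[str] | None = None,
    vif_threshold: float = 5.0,
) -> RegressionReport:
    """Bidirectional stepwise OLS on an information criterion.

    Starting from ``start`` (default intercept-only), single additions and
    removals are evaluated each round and the best strictly improving move
    is taken; on ties the smaller model wins.  Perfectly collinear
    candidates are dropped with a log entry before stepping.  The final
    model is reported with standardized coefficients, a VIF screen at
    ``vif_threshold``, residual normality (Shapiro–Wilk) and
    homoscedasticity (Breusch–Pagan) checks, and nested F-tests against
    every one-predictor-reduced and one-candidate-augmented model.
    """
    log: list[str] = []
    table = table.reset_index(drop=True)
    work = _drop_collinear(table, list(candidates), log)
    y = table[response].to_numpy(dtype=float)
    n = len(y)
    if n <= len(start or []) + 2:
        raise ValueError("too few rows for the starting model")

    current = list(start or [])
    fit = _fit_ols(y, table, current)
    crit = _criterion(fit, n, criterion)
    tol = 1e-10
    while True:
        moves = []  # (crit, n_terms, terms)
        for c in work:
            if c in current:
                continue
            terms = current + [c]
            if n <= len(terms) + 2:
                continue  # keep n > p + 2 for any visited model
            f = _fit_ols(y, table, terms)
            moves.append((_criterion(f, n, criterion), len(terms), terms))
        for c in current:
            terms = [t for t in current if t != c]
            f = _fit_ols(y, table, terms)
            moves.append((_criterion(f, n, criterion), len(terms), terms))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1]))
        best_crit, best_len, best_terms = moves[0]
        improved = best_crit < crit - tol
        tie_smaller = abs(best_crit - crit) <= tol and best_len < len(current)
        if not (improved or tie_smaller):
            break
        current = best_terms
        fit = _fit_ols(y, table, current)
        crit = best_crit
        log.append(f"stepped to {current} ({criterion}={crit:.3f})")

    # --- validation on the final model -----------------------------------
    if current:
        coeffs = standardized_coefficients(fit, table, response)
        X = sm.add_constant(table[current], has_constant="add")
        vif = {
            c: float(variance_inflation_factor(X.to_numpy(dtype=float), i))
            for i, c in enumerate(X.columns) if c != "const"
        }
        bad_vif = [c for c, v in vif.items() if v >= vif_threshold]
        if bad_vif:
            log.append(f"VIF >= {vif_threshold} for {bad_vif}")
        resid = fit.resid
        shapiro_p = float(stats.shapiro(resid).pvalue)
        try:
            bp_p = float(het_breuschpagan(resid, X.to_numpy(dtype=float))[1])
        except (ValueError, np.linalg.LinAlgError):
            bp_p = math.nan
    else:
        coeffs = pd.DataFrame(columns=[
            "term", "coef", "stderr", "t", "pvalue", "ci_low", "ci_high",
            "std_coef", "std_ci_low", "std_ci_high", "cohen_d",
        ])
        vif = {}
        shapiro_p = math.nan
        bp_p = math.nan

    anova_red = {}
    for c in current:
        reduced = _fit_ols(y, table, [t for t in current if t != c])
        anova_red[c] = compare_nested(reduced, fit)
    anova_aug = {}
    for c in work:
        if c in current or n <= len(current) + 3:
            continue
        full = _fit_ols(y, table, current + [c])
        anova_aug[c] = compare_nested(fit, full)

    return RegressionReport(
        response=response,
        selected=tuple(current),
        coefficients=coeffs,
        r_squared=float(fit.rsquared) if current else 0.0,
        adj_r_squared=float(fit.rsquared_adj) if current else 0.0,
        criterion=criterion,
        criterion_value=float(crit),
        aic=float(_criterion(fit, n, "aic")),
        vif=vif,
        residual_shapiro_p=shapiro_p,
        residual_breusch_pagan_p=bp_p,
        anova_vs_reduced=anova_red,
        anova_vs_augmented=anova_aug,
        n=n,
        log=tuple(log),
    )


def apply_transform_policy(
    table: pd.DataFrame,
    response: str,
    candidates: list[str],
    skew_threshold: float = 1.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """log10-transform positive, right-skewed predictors failing residual checks.

    For each candidate that is strictly positive, has sample skewness above
    ``skew_threshold`` and whose simple-regression residuals fail
    Shapiro–Wilk at ``alpha``, a ``log10_<name>`` column replaces the raw
    candidate.  Returns the augmented table, the updated candidate list and
    a log of transformations.
    """
    out = table.copy()
    new_candidates = []
    log = []
    for c in candidates:
        x = out[c].to_numpy(dtype=float)
        y = out[response].to_numpy(dtype=float)
        transform = False
        if np.all(x > 0) and stats.skew(x, bias=False) > skew_threshold:
            fit = stats.linregress(x, y)
            resid = y - (fit.intercept + fit.slope * x)
            if stats.shapiro(resid).pvalue < alpha:
                transform = True
        if transform:
            name = f"log10_{c}"
            out[name] = np.log10(x)
            new_candidates.append(name)
            log.append(f"log10-transformed {c!r}")
        else:
            new_candidates.append(c)
    return out, new_candidates, log


# ---------------------------------------------------------------------------
# Nonlinear fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpAssociationFit:
    """y = a·exp(b·x) + c with one-sided inference on b > 0."""

    a: float
    b: float
    c: float
    b_stderr: float
    t_b: float
    df: int
    p_one_sided: float
    r_squared: float
    flags: tuple[str, ...] = ()


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan


def _restart_fits(model, x, y, p0, bounds, n_restarts=10, seed=0):
    """curve_fit from p0 plus jittered restarts; best SSR wins."""
    rng = np.random.default_rng(seed)
    best = None
    inits = [np.asarray(p0, dtype=float)]
    scale = np.maximum(np.abs(p0), 1e-3)
    for _ in range(n_restarts):
        inits.append(np.asarray(p0) + rng.normal(0, 0.3, len(p0)) * scale)
    for init in inits:
        lo, hi = bounds
        init = np.clip(init, lo, hi)
        try:
            popt, pcov = curve_fit(
                model, x, y, p0=init, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((y - model(x, *popt)) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    return best


def exp_association_fit(x, y, seed: int = 0) -> ExpAssociationFit:
    """Nonlinear least squares of ``y = a·exp(b·x) + c``.

    Initialization: ``c`` from the flatter endpoint, ``b`` from the
    log-linearized slope, ``a`` from the remaining amplitude; ten jittered
    restarts (fixed seed) before declaring non-convergence.  Reports
    ``t = b̂/SE(b̂)`` with ``df = n − 3`` and a one-sided p for ``b > 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    c0 = float(ys[0]) - 0.05 * float(np.ptp(ys) or 1.0)
    shifted = ys - c0
    pos = shifted > 0
    if pos.sum() >= 2:
        b0 = float(np.polyfit(xs[pos], np.log(shifted[pos]), 1)[0])
    else:
        b0 = 0.0
    b0 = b0 if np.isfinite(b0) and b0 != 0 else 1e-3
    a0 = float(shifted[-1] / math.exp(b0 * xs[-1])) if shifted[-1] > 0 else 1.0

    def model(xx, a, b, c):
        return a * np.exp(b * xx) + c

    bounds = ([-np.inf, -np.inf, -np.inf], [np.inf, np.inf, np.inf])
    best = _restart_fits(model, x, y, (a0, b0, c0), bounds, seed=seed)
    if best is None:
        return ExpAssociationFit(
            a=math.nan, b=math.nan, c=math.nan, b_stderr=math.nan,
            t_b=math.nan, df=int(x.size - 3), p_one_sided=math.nan,
            flags=("fit_failed",), r_squared=math.nan,
        )
    popt, pcov, _ = best
    se_b = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else math.nan
    df = int(x.size - 3)
    t_b = float(popt[1] / se_b) if se_b and np.isfinite(se_b) else math.nan
    p1 = float(stats.t.sf(t_b, df)) if np.isfinite(t_b) else math.nan
    return ExpAssociationFit(
        a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
        b_stderr=se_b, t_b=t_b, df=df, p_one_sided=p1,
        r_squared=_r_squared(y, model(x, *popt)),
    )


@dataclass(frozen=True)
class OnePhaseDecayFit:
    """y = (Y0 − plateau)·exp(−K·x) + plateau with K ≥ 0."""

    y0: float
    plateau: float
    k: float
    k_stderr: float
    r_squared: float
    flags: tuple[str, ...] = ()


def one_phase_decay_fit(x, y, seed: int = 0) -> OnePhaseDecayFit:
    """One-phase exponential decay fit (K constrained nonnegative).

    Flat (plateau-only) data leave K unidentifiable; this is flagged
    (``k_unidentifiable``) rather than reported as a spurious rate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    if np.allclose(y, y[0]):
        return OnePhaseDecayFit(
            y0=float(y[0]), plateau=float(y[0]), k=math.nan,
            k_stderr=math.nan, r_squared=math.nan,
            flags=("k_unidentifiable",),
        )
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    y00 = float(ys[0])
    plat0 = float(ys[-1])
    span = y00 - plat0
    shifted = (ys - plat0) / span if span != 0 else None
    if shifted is not None:
        pos = shifted > 1e-9
        if pos.sum() >= 2:
            k0 = -float(np.polyfit(xs[pos], np.log(shifted[pos]), 1)[0])
        else:
            k0 = 1.0 / (float(xs[-1] - xs[0]) or 1.0)
    else:
        k0 = 1.0
    k0 = max(k0, 1e-6)

    def model(xx, y0, plateau, k):
        return (y0 - plateau) * np.exp(-k * xx) + plateau

    bounds = ([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf])
    best = _restart_fits(model, x, y, (y00, plat0, k0), bounds, seed=seed)
    if best is None:
        return OnePhaseDecayFit(
            y0=math.nan, plateau=math.nan, k=math.nan, k_stderr=math.nan,
            r_squared=math.nan, flags=("fit_failed",),
        )
    popt, pcov, _ = best
    k_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else math.nan
    flags: tuple[str, ...] = ()
    if not np.isfinite(k_se) or (np.isfinite(k_se) and k_se > 1e3 * max(popt[2], 1e-12)):
        flags = ("k_unidentifiable",)
    return OnePhaseDecayFit(
        y0=float(popt[0]), plateau=float(popt[1]), k=float(popt[2]),
        k_stderr=k_se, r_squared=_r_squared(y, model(x, *popt)),
        flags=flags,
    )
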