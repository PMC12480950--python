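# Methods

This note documents the models behind each `sedshuttle` module, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions. It is the package's
account of its own science; all quantitative statements here are
recomputed by the test suite or by `scripts/acceptance.py`.

## Dissolved gases (`gas_chemistry`)

**Headspace equilibrium.** A water sample shaken against an ambient-air
headspace partitions a sparingly soluble gas between the phases. Writing
`Cg` for the post-equilibration headspace concentration, `Cair` for the
ambient-air concentration (both µmol per litre of gas), `Vg/Vl` for the
headspace:water volume ratio, `K₀` for the solubility coefficient
(mol L⁻¹ atm⁻¹) and `R = 0.082` L atm mol⁻¹ K⁻¹, mass conservation gives
the original dissolved concentration

    Cw = Cg (K₀ R T + Vg/Vl) − Cair (Vg/Vl)     [µmol L⁻¹]

`T` is the *equilibration* temperature; equilibrium (saturation)
concentrations use the *in-situ* temperature — the two are separate
inputs because samples are usually shaken at lab temperature. The
inversion is algebraically exact: the round-trip forward-partition →
inversion error is at machine precision (checked over 1000 random
admissible parameter sets). A recovered `Cw` below zero signals
inconsistent inputs and is *flagged, never clamped*, preserving
mass-balance auditability.

**Solubility parameterizations.** N₂O uses the Weiss & Price (1980)
polynomial for K₀ (mol L⁻¹ atm⁻¹); N₂ and Ar use the Hamme & Emerson
(2004) atmospheric-saturation fits (µmol kg⁻¹ at standard dry-air mole
fractions, 1 atm moist total pressure). Sanity anchors: K₀(N₂O, 25 °C,
S = 0) ≈ 0.0248 mol L⁻¹ atm⁻¹; N₂ ≈ 494 and Ar ≈ 12.7 µmol kg⁻¹ at
25 °C fresh water. Standalone re-implementations of both polynomials are
frozen in the tests and must agree to 1 × 10⁻⁶ relative. Valid ranges:
273.15–313.15 K (271.15 K would also be fine for the saturation fits;
the common range is enforced for simplicity) and salinity 0–40; outside
them a domain error names the range. Freshwater density is taken as
1 kg L⁻¹, so µmol kg⁻¹ ≈ µmol L⁻¹ (< 0.3 % error for lake water).
Atmospheric mole fractions (N₂ 0.78084, Ar 0.00934, N₂O 335 ppb) are
configuration values, not constants baked into the functions; outputs
are linear in mole fraction and pressure (Henry's law), so any other
composition is a rescaling. The N₂O equilibrium uses the dry-air mole
fraction against the K₀ form; no separate moist-air correction is
applied beyond what the fits embed.

**N₂:Ar method.** Membrane-inlet mass spectrometry delivers a precise
N₂:Ar ratio; multiplying by the well-constrained equilibrium Ar
concentration converts it to absolute dissolved N₂. Excess gas is
`Δ = measured − equilibrium` with sign preserved (negative =
undersaturation).

**Flux.** `F = k · ΔN₂O`, with the 1 µmol L⁻¹ = 1000 µmol m⁻³
conversion applied inside the function so `k` in m d⁻¹ and Δ in
µmol L⁻¹ give F in µmol m⁻² d⁻¹. `k` is normally a user input; an
optional helper provides the quadratic wind law `k600 = 0.251 u₁₀²`
(cm h⁻¹) scaled by `(Sc/600)^−1/2` with the freshwater N₂O Schmidt
number.

## Isotope pairing (`isotope_pairing`)

In a ¹⁵NO₃⁻-amended anoxic vial, denitrification samples two N atoms
from the nitrate pool (¹⁵N atom fraction `FN`), while anammox pairs one
pool atom with an ambient ¹⁴N atom. The forward model for the labeled
isotopologue production slopes is

    p30 = D FN²,   p29 = 2 D FN (1 − FN) + A FN

and the module inverts it exactly:

    D = p30 / FN²,   A = p29/FN − 2 (1 − FN)/FN² · p30

Assumptions: a single well-mixed nitrate pool of constant `FN` over the
incubation, random pairing, linear accumulation (sacrificial vials,
slopes by OLS with replicates pooled rather than averaged, to preserve
degrees of freedom), and no other ²⁹/³⁰N₂ sources (no N₂O isotopologue
routing, no DNRA). `FN` is a user input; a helper computes it from the
added tracer and ambient nitrate concentrations with a default label
purity of 0.99. Negative anammox estimates arise when the observed p29
is smaller than the denitrification pairing alone would produce; they
are reported raw with a flag, and clamped copies are provided for
summaries. With two time points the slope is returned but SE/p are
flagged unavailable. Per-gram rates use
`slope × V(L) / m(g)`, reported as nmol N₂ g⁻¹ h⁻¹ (×2 for per-N-atom).

## MFC power density (`mfc_power`)

Per sweep point, `I = V/R_ext`, current density `I/A` and power density
`V·I/A` (µW m⁻²), with `A` the anode *projected* area. MPD is the
empirical maximum over the sweep — no interpolation between resistance
steps, matching a plot-based reading; ties break toward the larger
external resistance. For a Thevenin cell `V = Voc R/(R + Rint)` the
peak sits at `R = Rint` with `MPD = Voc²/(4 Rint A)`; this closed form
is the oracle for the generator and the basis of the diagnostic
internal-resistance fit (nonlinear least squares, bounded positive).
Sweeps whose voltage is not monotone in R are flagged.

## qPCR expression (`expression_qpcr`)

Relative expression is `E^(Ct_ref − Ct_target)` against the 16S rRNA
reference, default efficiency `E = 2.0` (perfect doubling); per-gene
efficiencies can be supplied. Treatment effects are per-matched-pair
HS_C/Blank ratios, summarized by the **geometric mean** (ratios are
multiplicative; an arithmetic mean is available behind a flag);
unmatched pairs are dropped and recorded. Group comparisons run
Shapiro–Wilk on the paired differences at α = 0.05 and route to a
paired t-test (normal) or the Wilcoxon matched-pairs signed-rank test;
all-zero differences are degenerate and flagged. Families of p-values
get Benjamini–Hochberg step-up q-values. Under a null simulation
(7 genes, no effect, 1000 replicates) the family rate of any q < 0.05
stays at the nominal 0.05 within Monte Carlo error.

## Driver analysis (`driver_stats`)

The survey workflow is sequential: Spearman screening (midrank ties;
constant columns yield flagged NaNs) keeps candidates with p < 0.05;
an optional transformation policy log10-transforms strictly positive,
right-skewed (sample skewness > 1) predictors whose simple-regression
residuals fail Shapiro–Wilk; bidirectional stepwise OLS then optimizes
an information criterion from an intercept-only start, taking the best
single addition or removal per round, with ties resolved toward the
smaller model and perfectly collinear candidates dropped up front.

**Criterion choice.** The default is AICc with the parameter count
including the error variance. With a dozen sites, the uncorrected AIC
penalty of 2 admits a spurious predictor with probability ≈ 0.16–0.23
per candidate; AICc tightens the implied partial-F threshold to
p ≈ 0.05. This is the standard small-sample recommendation (n/k < 40)
and is the package's default; plain AIC and BIC remain selectable.

**Validation and effects.** The final model is reported with VIF per
predictor (screen at 5), residual normality (Shapiro–Wilk) and
homoscedasticity (Breusch–Pagan), nested partial-F comparisons against
every one-term-reduced and one-candidate-augmented model, and
standardized coefficients `β_std = β · sd(x)/sd(y)` with identically
transformed confidence intervals. For a single-predictor model,
`β_std` equals Pearson's r to 1 × 10⁻¹⁰ (an algebraic identity the
tests enforce). Cohen's d is derived from the coefficient t-statistic
as `d = 2t/√df`; this is one of several conventions in circulation and
is stated here so results are interpretable — it is a reporting choice,
not an inferential one.

**Nonlinear fits.** The exponential association `y = a·e^{bx} + c`
initializes `c` from the flatter endpoint, `b` from a log-linearized
slope and `a` from the residual amplitude, then runs the optimizer from
the heuristic start plus 10 jittered restarts (fixed seed); it reports
`t = b̂/SE(b̂)` with df = n − 3 and a one-sided p for b > 0 (growth is
the directional hypothesis in this context; everything else in the
package is two-sided). The one-phase decay
`y = (Y0 − plateau)·e^{−Kx} + plateau` constrains K ≥ 0 and reports R²
on the original scale; flat data leave K unidentifiable and are
flagged rather than fitted.

## Synthetic data (`synthetic_data`)

Every generator is a pure function of configuration + seed
(numpy `default_rng`), and every generator is exactly inverted by its
analysis stage when noise is zero — the central validation property of
the package.

Default study conditions: 12 sites; HS log-uniform over
9.5–230.1 mg g⁻¹ (field HS spans an order of magnitude, so a
log-uniform draw spreads sites evenly in the regime that matters);
HA fraction normal 0.928 ± 0.094 truncated to (0, 1] by resampling
(truncation pulls the realized mean to ≈ 0.89); MPD = 0.33 µW m⁻² per
mg g⁻¹ of HS plus Gaussian noise calibrated analytically to a target
HS–MPD R² of 0.7355 (`σ = sd(signal)·√((1−R²)/R²)`; the empirical
small-sample mean R² lands a couple of points higher because R² is
upward-biased at n = 12); excess N₂ = 0.5 µmol L⁻¹ per µW m⁻² of MPD
with noise calibrated to R² = 0.7926; excess N₂O weakly *negatively*
coupled to MPD; dissolved concentrations assembled by adding the
excesses to temperature-dependent equilibria; six independent nuisance
columns (DO, pH, water temperature, NO₃⁻, NH₄⁺, NO₂⁻). MPD can dip
slightly below zero at the low end of the range — only the linear
coupling structure matters to the driver analysis, so no truncation is
applied. A companion routine forward-computes the raw gas-measurement
table (headspace concentrations, N₂:Ar ratios) that the gas stage
inverts back to the survey's dissolved gases.

Incubations: D = 0.5 and A = 0.2 µmol L⁻¹ h⁻¹ (a 71.4 % denitrification
share), FN = 0.8, sacrificial vials at 0/6/12/24 h × 3 replicates,
0.05 µmol L⁻¹ Gaussian concentration noise, small nonzero baselines so
noise never clips at zero, between-pair lognormal spread (σ_log 0.15),
and a 2.6× multiplier on D in HS_C vials. qPCR: per-sample biomass
offset (σ = 1 cycle) added to both reference and target Ct — precisely
the nuisance 16S normalization cancels — plus 0.2-cycle read noise;
default fold changes per gene: nirS 6.0, nirK 4.6, nosZI 7.7,
nosZII 31.5, omcB 31.5, omcS 2.0, pilA 3.3, over 8 pairs.

What the generators do *not* emulate: spatial/temporal autocorrelation
among sites, non-Gaussian measurement error, nitrate-pool drift during
incubations, instrument drift and calibration error, biofilm dynamics
in the MFC, amplification-efficiency variation between wells, or any
community-composition structure. Passing tests therefore demonstrate
the correctness and calibration of the *estimators* under the stated
statistical structure, not robustness to every pathology of real field
data.

## Problem sizes and reproducibility

The acceptance script regenerates all headline quantities per run:
1000-draw round-trip checks for the headspace and isotope-pairing
inversions, 50 Thevenin sweeps, 25 × 8 incubation pairs, 300 surveys
for coupling calibration, 200 surveys for selection frequencies,
1000 null qPCR replicates for the FDR check, and 50 tables for fold
recovery — sizes chosen to keep Monte Carlo error small at roughly a
minute of single-core runtime. All sub-seeds derive from the single
`--seed` argument.

## Known limitations

- **Stepwise selection at n = 12 is intrinsically leaky.** Even with
  AICc, each screened spurious candidate enters with probability
  ≈ 0.05, and with ~3 screened candidates per survey plus occasional
  marginal-ordering flips (HS outranking MPD by chance), the frequency
  of recovering MPD as the *sole* predictor plateaus around 80–90 %,
  with MPD carrying the largest standardized coefficient in the full
  screened model in roughly 60–75 % of replicates. These are
  properties of small-sample model selection, not implementation
  defects; the acceptance script reports the measured rates.
- The isotope-pairing partition assumes a constant, well-mixed labeled
  pool; systems with strong DNRA or nitrate drift violate it.
- The headspace inversion treats `K₀RT` as constant during shaking and
  ignores barometric/depth corrections beyond a scalar pressure.
- MPD is a sweep-grid maximum; a coarse resistor ladder biases it low
  (the Thevenin closed form is an upper bound).
- The Cohen's d convention (`2t/√df`) is one of several; compare d
  values across studies only when the convention matches.
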