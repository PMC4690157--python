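# Methods

This note documents the model, the numerical choices and the limits of
what the test suite demonstrates. Notation: `f` is the fraction of initial
sulfite remaining, `j` the fraction of product sulfur residing in
thiosulfate, `α` a fractionation factor in instantaneous-product/reactant
orientation, `ε_r−p = 10³(1/α − 1)` its reactant−product per-mil form, and
`³ˣλ = ln(³ˣα)/ln(³⁴α)` the mass-law exponent for a minor isotope.

## The branched distillation model

The system modelled is a closed vessel in which sulfite is consumed
irreversibly and every removed S atom is committed at the instant of
removal to one of two cumulative pools: reduced S (central S of
trithionate, terminal S of thiosulfate) with branch factor `α_red`, or
sulfonate S with `α_ox`. Three assumptions carry the whole construction:
the branch factors are constant over the run, the molecular split `j` is
constant, and the sulfonate (resp. reduced) moieties of thiosulfate and
trithionate are isotopically identical within each pool. Under these
assumptions the product atom weights are `w_red = j/2 + (1−j)/3`,
`w_ox = 1 − w_red`, the net removal factor is the blend
`α_total = w_red α_red + w_ox α_ox`, the residual reactant follows the
Rayleigh law `R_a = R_a0 f^(α_total−1)`, and each cumulative pool has the
closed form `R_z = (α_z/α_total) R_a0 (1−f^α_total)/(1−f)`.

The per-point inversion is the exact algebraic inverse of these closed
forms. This pairing is deliberate: the forward model is the oracle for
the inversion, and `invert(simulate(θ)) = θ` to better than 1e−8 relative
is enforced across a grid of branch factors, splits and extents. Because
both directions share no code path beyond elementary ratio conversions,
this is a genuine two-sided consistency check, not a tautology.

Rare isotopes are carried in ratio space (rare/³²S) under the standard
approximation that ³²S flux equals total S flux; at natural abundances
the resulting error is < 0.01‰, far below measurement error.

### Numerical choices

* `(1−f^α)/(1−f)` and `ln(R_p/R_a0(f−1)+1)/ln f` are evaluated through
  `expm1`/`log1p`, which keeps full precision as `f → 1` (equivalent to a
  series expansion there, without a switchover threshold). At `f = 1`
  product pools are empty and their ratios are reported as missing, not
  NaN propagated into downstream math.
* `λ` is reported as missing whenever `³⁴α = 1` (the exponent is
  undefined without major-isotope separation).
* Degenerate inputs (no product accumulated, `f ≥ 1`, mass-balance
  argument of the logarithm non-positive) skip the point with a recorded
  reason rather than poisoning the series.

## Early-reaction window and summaries

Branch factors drift once a substantial fraction of sulfite is consumed —
late in a run, reduction of previously formed sulfonate becomes a
plausible second source of reduced S. Summary estimates therefore use
only points with `f ≥ 0.85` (configurable), while the full per-point
table is always produced so the drift diagnostic remains visible. The
`scan_secondary` helper maps the late-window constraint
`R_red = X α_red R_SO3 + (1−X) α_unk R_ox` into a curve `α_unk(X)` over
`X ∈ (0, 1)`; it is reported as a constraint curve because the data do
not identify a unique solution.

Window summaries are inverse-variance-weighted means (a plain mean is
available by flag; with near-equal per-point sigmas the two coincide).
How duplicate experiments are combined is a genuinely open design point;
the default inverts each replicate separately and pools the windowed
summaries, treating replicates as independent because each carries its
own t₀ measurement.

## Error model

Per point and branch the 1σ budget has two analytic pieces:

1. **ε:** power-law propagation through `R_f = R_0 f^(α−1)`:
   `σ_Z/Z = |α−1|·σ_f/f`, combined in quadrature with the relative ratio
   error and converted to ‰. Printed forms of this propagation elsewhere
   sometimes omit the radical and carry a stray sign; it is implemented
   here as standard quadrature. This budget counts the full concentration
   error against every point, which the Monte-Carlo cross-check shows to
   be conservative (by roughly 2× for the reduced branch) — a deliberate
   choice: the reported 2σ should not undercover.
2. **λ:** the analytic error formula in `(δ³⁴S, Δ³³S)` space, with
   partials `∂λ/∂Δ³³S` and `∂λ/∂δ³⁴S` verified against central finite
   differences to 1e−6 relative. The transverse input is the
   capital-delta scatter (default σ(Δ³³S) = 0.008‰, σ(Δ³⁶S) = 0.15‰), not
   the raw minor-isotope delta error (~0.1‰), because correlated
   measurement errors move a point along the reference
   mass-fractionation line (exponents 0.515 and 1.90), to which λ is
   insensitive to first order.

Each per-point σ is split into an independent part (per-point
measurements) and a shared part (the t₀ sulfite measurement common to the
whole series). Window variances average the independent parts down and
carry the shared part as fully correlated; replicate pooling then treats
windows as independent. This decomposition is what makes the analytic
windowed σ_λ agree with the empirical Monte-Carlo spread within ~5–10%
at default settings; ignoring the shared term would understate σ_λ by
~30% for an 8-point window.

Defaults (1σ): σ_f/f = 3% (concentration assays; applied to all three
species, since separate per-assay precisions are not available),
σ_R/R = 0.2‰/1000, σ(δ³⁴S) = 0.2‰, σ(Δ³³S) = 0.008‰, σ(Δ³⁶S) = 0.15‰.
Public reports are 2σ; storage is 1σ. δ³⁶S is carried everywhere δ³³S
is, with no special-casing.

A sensitivity table decomposes the ε variance by source. At the defaults
and a branch ε of ~15‰ the concentration term holds ~84% of the variance
(share `(|α−1|·0.03)² / ((|α−1|·0.03)² + (2·10⁻⁴)²)`); concentration
error dominates for any branch fractionation beyond a few ‰, and the
dominance grows quadratically with |α−1|.

## Synthetic data generator

`synthetic_data.generate` emulates the experiment tables: closed-system
trajectories at constant branch fractionations, constant j = 0.19,
duplicate experiments, 15 mM (alternatively 10 mM) initial sulfite, an f
grid from 0.99 down to 0.60, multiplicative Gaussian concentration noise
(3% CV, truncated at ±3σ to keep concentrations positive), 0.2‰ noise on
each δ³⁴S, and minor-isotope deltas set mass-dependently from the
*perturbed* δ³⁴S plus independent capital-delta scatter. The default
truth is the reference branch parameter set (ε_r−p = +15.3 / −3.2‰,
λ = 0.5150 / 0.495). A `j_drift_per_f` hook deliberately mis-specifies
the constant-split assumption for robustness studies.

What the generator does **not** emulate: chromatographic or
derivatization artifacts, instrument drift, run-to-run calibration
offsets, non-Gaussian outliers, or any real covariance between
concentration assays of different species. Passing tests on synthetic
data therefore demonstrate correctness of the estimator under the stated
noise model, not robustness to every pathology of real measurements; the
mass-balance QC flags (±5% / ±10% recovery bands) are the first line of
defence against the latter.

## Scale-compression correction

Very small CF-IRMS samples show a proportional, size-dependent
compression of the measured ⁵⁰R. The functional basis of the compression
curve is not uniquely established by theory, so the model is a
least-squares polynomial (default quadratic) in log peak area, jointly
fit with each bracketing standard's asymptotic ratio and constrained to
zero correction at the largest calibrated size. Correction is followed by
a linear ⁵⁰R→⁶⁶R transfer (fit from standards carrying both ratios,
identity if none do) and linear V-CDT anchoring through the standards'
accepted δ³⁴S. Validation is by synthetic round trip — data generated
from a known compression law must be recovered to 1e−6 ‰ — because
instrument-specific calibration data are not portable. Residual scatter
of the standards propagates to each sample's σ, inflated outside the
calibrated size range (flagged, not rejected); a counting-statistics
shot-noise curve is provided as the floor such errors should exceed.

## Compilation statistics

Quantile summaries use linear-interpolation (type-7) quantiles, fixed for
reproducibility across tools. The fractionation-rate regression is the
one-phase decay `Y = (Y0 − Plateau)·e^(−KX) + Plateau`, fit by nonlinear
least squares with K initialised over a log-spaced multi-start grid
(realistic decay constants span orders of magnitude, e.g. ~6.4 for
sediment-style volumetric rates vs ~0.054 for rescaled chemostat rates);
95% CIs come from the fit covariance via the t distribution. Constant-y
input degenerates to `Y0 = Plateau = mean` with K flagged unidentifiable.
Rate-unit utilities linearize log₁₀-scale rates and convert
cell-specific to volumetric rates by multiplying out cell density, with
provenance recorded per record.

## Problem sizes used in the checks

Noise-free recovery and oracle-equivalence checks run on 4–8 point grids
(sub-second). Stochastic checks use 200 seeded repetitions of the
duplicate-experiment design for coverage and Monte-Carlo/analytic σ
comparison, 500 repetitions for the ε-bias check, and ~600–1000 points
for generator noise calibration — sizes at which the sampling error of
the checked statistic is several times smaller than the tolerance being
asserted.

## Known limitations

* The model is parameterised on `f`, not time; no kinetic rate law is
  fitted, and the late-reaction drift is reported, not modelled.
* No sulfide branch (none is observed in vitro without the DsrC cycle).
* No covariance is propagated across time points beyond the shared-t₀
  term; points are otherwise treated as independent.
* Absolute V-CDT ratios are community defaults and configurable; every
  ε/λ result depends only on ratios of ratios and is insensitive to
  them.
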