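# Methods

## Cohort model

`recruitmap.core` iterates a closed cohort — no immigration or new
settlement after `t = 0` — in discrete time.  Survival per base step is a
function `λ(u)` of resource use `u = N_t·φ_t`; body size follows the
Ford–Walford recursion `φ_{t+1} = φ_t e^{−K} + φ_∞(1 − e^{−K})`, whose
closed form `φ(t+Δ) = φ_∞ − (φ_∞ − φ_t)e^{−KΔ}` the implementation also
uses for fractional steps (census intervals are rarely whole multiples of
the base step).  Density never increases (λ ≤ 1), size never decreases
and is bounded by φ_∞.

**Logistic sign convention.** Written literally with a negative exponent,
`1/(1 + α'e^{−βu})` *increases* with crowding, contradicting β's role as
a mortality parameter.  The package therefore uses
`λ = 1/(1 + α'e^{+βu})` with `α' = 1/α − 1`, which satisfies `λ(0) = α`
and declines in `u`; the literal variant remains available through
`survival_fraction(..., logistic_literal_sign=True)` for comparison.
With α = 1 the logistic form degenerates to `λ ≡ 1` (α' = 0); the other
two forms still decline.

**Resource budget.** The constraint `A ≥ N·φ` (space cannot be
over-occupied) is reported by `resource_violation` as a diagnostic flag
and excess only.  The recursion is never clipped: clipping would change
the map shapes the model is known for, and transient violations are
informative about parameter regimes rather than errors.

**Settler–recruit maps.** `recruitment_map` iterates a grid of initial
densities (default 400 log-spaced points on [1, 10⁴]) and records density
at requested steps (default 0–500; growth saturates on a `1/K` time
scale, so 500 steps at the default K = 0.01 covers the full size
trajectory).  Curve shape is classified from tolerance-merged interior
local maxima: values within a relative tolerance (default 1e-9 of the
curve maximum; plateaus merge to a single candidate) are treated as
equal.  A curve with no interior maximum is `monotonic_increasing` if
nondecreasing within tolerance, otherwise `unimodal` (a falling curve is
read as the tail of a single hump that peaks at or before the window
edge).  "Points of compensation" are implemented as local maxima of the
curve, which is how the framework uses the term.

## Fitting pipeline

`recruitmap.inference` mirrors how such census data are analysed in
practice:

1. **Interval survival** `S = N_end/N_start`, clipped into
   `[1e-6, 1 − 1e-6]` so the log/logit/reciprocal transforms stay finite.
   Clipped rows are counted and carried in the fit result.  `S > 1`
   (recount error in an intended closed cohort) warns and clips rather
   than dropping the row, keeping the balanced design.  `N_start = 0`
   rows cannot define survival and are excluded (counted).
2. **Time standardization.** Censuses happen at irregular intervals
   (30/90/120 days in the emulated design) while the model works in
   equal steps.  Because survival compounds multiplicatively over
   sub-intervals, standardization is geometric: `S_30 = S^{30/T}`, with
   the exact inverse `λ_T = λ_30^{T/30}` used to map predictions back.
   A 60-day interval and its two 30-day halves carry identical
   information through this transform, and the fit is invariant to that
   split on noiseless data (tested).
3. **Linearized OLS.** Each form's transform makes the model linear in
   the descriptor `X`; ordinary least squares (statsmodels) gives the
   coefficients, which are back-transformed to `(α, β)`.  Estimates
   implying `α ∉ (0, 1]` or `β < 0` are flagged inadmissible but never
   clamped — a wrong-signed slope is a diagnostic, not something to hide.
   No row weights are used; each quadrat × interval is one record.
4. **Goodness of fit** is the adjusted R² on the transformed scale — the
   scale the regression actually minimizes on; a survival-scale R²
   (back-transformed predictions against raw survival) is reported
   alongside for transparency.  Residual diagnostics report Spearman
   correlations of residuals and |residuals| against `X` plus a sign-runs
   count, numbers only, with a floating-point noise floor so numerically
   exact fits report zero trend.
5. **Extended model.** The logistic operculum-cover model optionally gets
   period-specific intercepts (period-varying α) and a dead-shell-cover
   term with its own β.  Fits are always per shore.  With both switches
   off it reduces exactly to the plain logistic/operculum-cover fit.
6. **AIC.** Gaussian-OLS AIC, `n·ln(RSS/n) + 2k`, `k` counting regression
   coefficients plus one for the error variance.  RSS is floored at
   1e-10·TSS so numerically exact fits compare by the penalty rather than
   by log-amplified floating-point dust.  **Selection rule:** among the
   candidates, models within 2 AIC units of the minimum are treated as
   equivalently supported and the most parsimonious is selected
   (`parsimony_margin=2.0`, settable to 0 for strict lowest-AIC).  The
   margin matters: strict lowest-AIC retains a spurious extra parameter
   at the χ² rate (≈ 16% per parameter; the probability that the true
   simpler model beats three extended competitors is only ≈ 0.73),
   whereas the 2-unit convention keeps false structure rare without
   hiding genuinely better models.

Open choices resolved here: adjusted R² is computed on the transformed
scale (the regression's own scale); dead cover enters as the measured
area of shell cover per quadrat; shores are never pooled.

## Synthetic data generator

`recruitmap.synthetic` emulates the motivating field design — two
shores, 52 quadrats of 5×5 cm each, censuses spanning June→July (30 d),
July→October (90 d) and October→February (120 d) — with a fully known
truth.  Defaults, chosen once as a realistic regime for a young barnacle
cohort and kept fixed:

| quantity | default | note |
|---|---|---|
| settlement per quadrat | log-uniform 100–600 | 4–24 settlers/cm², the span a density manipulation covers; log-uniform puts equal effort per decade, median `√(min·max)` |
| operculum growth | K = 0.12 per 30 d, φ_0 = 0.1 mm², φ_∞ = 0.5 mm² | small early-juvenile opercula; density-independent (the non-plastic trait) |
| basal plasticity | `B(N) = B_max/(1 + cN)`, B_max = 5 mm², c = 0.02 | basal area halves at N = 50; the plastic trait |
| survival truth | logistic on operculum cover; per-shore α by period, β_live, β_dead (defaults echo plausible field-scale estimates) | α per 30-day step |
| dead-shell cover | `D += persistence · deaths · B(N)`, persistence = 0.1 | shells mostly removed; D is recorded at interval start and feeds mortality in the truth |
| noise | binomial survival of integer individuals; lognormal σ = 0.05 jitter on recorded trait areas | jitter emulates photograph-based trait estimation (mean of ~20 individuals) |

Randomness uses one sub-stream per (shore, quadrat)
(`SeedSequence(seed, spawn_key=(shore, quadrat))`), so enlarging the
design never perturbs existing quadrats.  A `continuous` mode replaces
the binomial draw by its expectation for exact-recovery oracles.

The settlement/trait scale matters for inference quality: because β is
fixed in units of inverse cover, regimes with large trait areas or very
high settlement drive high-density quadrats to zero counts within an
interval; those rows hit the survival clip and act as gross outliers on
the transformed scale (in coarse scans they biased the dead-cover β by
tens of percent).  The chosen defaults keep most quadrat × interval
records at informative intermediate survival, which is also the regime a
well-designed field manipulation aims for.

**What the generator does not emulate:** within-quadrat spatial
structure (the IBM's job), immigration/late settlement, observation
error on counts (only on traits), temporal autocorrelation beyond the
dead-cover carry-over, and any among-quadrat heterogeneity in α or β.
Passing recovery tests therefore show the pipeline is correct and
well-calibrated for data of this shape and noise family — not that field
data meet those assumptions.

## Individual-based model

`recruitmap.ibm` reconstructs the microscopic mechanism study: settlers
placed as a spatial Poisson process (count Poisson(intensity·side²),
positions uniform) on a **toroidal** square arena — periodic boundaries
remove the edge-density bias of small arenas — growing by the same
Ford–Walford step, with survival driven by *local resource use*: the
summed size of living individuals within a fixed radius, self included
(so local use ≥ own size).  Neighbour queries use a periodic kd-tree and
are tested against an all-pairs distance scan.  Two responses:

* `threshold`: survive with p_high while local use ≤ θ (boundary
  inclusive), else p_low — individual-level threshold phenomena such as
  shell crushing or hummock dislodgement;
* `geometric`: survive with `p_high·e^{−γu}` — the classical smooth
  decline that, paired with Poisson placement, yields the exponential
  macroscopic form (the package tests this correspondence directly:
  one-step survival fraction versus mean crowding across arenas is
  log-linear with slope −γ and intercept ln p_high, transformed-scale
  R² > 0.9).

The neighbourhood metric, threshold quantity and boundary condition are
this package's own reconstructions; only the three core assumptions
(threshold response, growing organisms, Poisson placement) are anchored
in the source framework.  Default parameters (θ = 0.5, p_high = 0.98,
p_low = 0.2, radius = 0.1, K = 0.05, φ_0 = 0.01) come from a coarse
documented search for a regime that exhibits the qualitative shape
transition — they are configuration, not claims.  With them, the mean
settler–recruit curve over a 50–1000 intensity gradient is monotonic at
step 1 and overcompensating (unimodal or multimodal) by steps 5–10;
with the geometric response and growth disabled the late-step curve
never turns multimodal.

Monte-Carlo shape classification needs adequate precision: late-step
arenas can hold few survivors, and replicate noise on a 12-point curve
fakes local maxima at tight tolerances.  The experiment protocol for the
no-growth check therefore uses a 2×2 arena, 12 replicates and a 0.05
relative classification tolerance, sized so that replicate SE stays well
under the merge tolerance.

## Numerical choices

* Survival clip ε = 1e-6; applied to interval survival and re-applied
  after standardization (which can push a clipped value back onto 1).
* Plateau-merge tolerance for maxima counting: 1e-9 relative (exact
  arithmetic on deterministic maps), 0.02–0.05 relative for Monte-Carlo
  IBM curves.
* AIC RSS floor 1e-10·TSS; residual-trend noise floor 1e-10 of the
  fitted-value range.
* Ties in AIC selection (after the parsimony margin) break toward fewer
  coefficients.
* All stochastic components consume `numpy.random.Generator` streams
  derived from explicit seeds; IBM experiment replicates use
  `SeedSequence(seed, spawn_key=(grid_index, replicate))` reduced mod
  2³¹.

## Known limitations

* The cohort model tracks mean body size only; no size distribution or
  among-individual trait variance.
* OLS on the transformed scale treats all records as homoscedastic;
  binomial survival of small counts violates this in the tails (the
  clipping bookkeeping makes affected rows visible, but no weighting or
  robust loss is applied, matching the reference analysis style).
* Repeated measures on the same quadrat are treated as independent
  records; no mixed effects or autocorrelation structure.
* The IBM has no explicit shell mechanics, hummock geometry or
  wave-dislodgement model, and its output is not fitted to data.
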