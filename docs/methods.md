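# Methods

## Model

One subject is observed at strictly increasing positive times
`t(1) < … < t(N)` (missing days are simply absent rows; nothing is imputed).
Counts `y` have means `μ_t = exp(x_tᵀβ + o_t)` under a natural log link,
where the design `x_t` holds an optional intercept plus fractional-polynomial
transforms `t^p` (computed as `exp(p log t)`, so times must be positive), and
`o_t = log Y_t` when exposure totals are present.  Dispersions are log-linear
in their own transforms, `log φ_t = x′_tᵀβ′ (+ o_t)`, inflating the Poisson
variance to `σ_t² = φ_t μ_t`.  With rates `y′ = y/Y` this gives the clean
factorization `σ′² = φ′ μ′` with `μ′ = exp(xᵀβ)` and `φ′ = φ/Y` — the reason
the offset enters the dispersion model by default whenever totals exist
(`offsets_in_dispersion=None` resolves to "totals present").

The covariance of `y` is modeled as `Σ = Diag(σ) R(ρ) Diag(σ)` with working
correlation `R`:

- `ind` — identity (Poisson-process independence);
- `exch` — constant off-diagonals, valid for `ρ ∈ (−1/(N−1), 1)`;
- `ar1` — `ρ^{|t−t′|}`, by actual time distance (spatial, default) or index
  distance.  Negative `ρ` requires integer gaps for `ρ^gap` to be defined.

All validity intervals carry an interior margin of 1e−6; moment estimates
falling outside are clipped to the margin with a warning.

## Estimation

**Standard GEE** — Newton iterations on `g(β) = DᵀΣ⁻¹e` (with
`D = Diag(μ)X`, `H(β) = −DᵀΣ⁻¹D`) at fixed `(φ₀, ρ)`, then the
bias-adjusted Pearson moment update `φ₀ = ΣPe²/(N−J)` and the moment
estimator of ρ from standardized residuals (`ΣΣ stde_i stde_{i′} /
(N(N−1)/2 − J)` for exchangeable; lag-1 products raised to `1/gap` and
divided by `N−1−J` for spatial AR1, using the signed root
`sign(p)|p|^{1/gap}` for negative products, which the plain formula leaves
undefined).  The outer loop `(β → φ₀ → ρ)` stops when all components change
by less than 1e−8 (max 100 rounds).

**Extended GEE** — joint Newton on `(β, β′)` using the dispersion score
`g_j(β′) = stdex′_jᵀ R⁻¹ stde − Σx′_j/2` and the corresponding Hessian-role
blocks; these are *partial* derivatives that hold ρ fixed, and ρ is
refreshed by the moment estimator at every iteration (not only at
convergence).  Steps are halved (≤20 times) when the score norm grows;
singular systems get one diagonal ridge of `1e−8·max|diag|`.

**ELMM** — full Newton maximization of the likelihood-like value over
`θ = (β, β′, ρ)` with the analytic gradient
(`g_j(β) = stdex_jᵀR⁻¹stde − Σx_j/2` with
`stdex_{t,j} = x_{t,j}(y_t+μ_t)/(2σ_t)`;
`g(ρ) = −stdeᵀ ∂R⁻¹/∂ρ stde/2 − tr(R⁻¹∂R/∂ρ)/2`) and Hessian; the
unprinted `∂²R⁻¹/∂ρ²` is assembled as `2R⁻¹R′R⁻¹R′R⁻¹ − R⁻¹R″R⁻¹` by
differentiating `∂R⁻¹/∂ρ = −R⁻¹R′R⁻¹`.  Under independence θ has no ρ
(its derivative is identically zero).  The iteration enforces monotone
ascent by step-halving, shortens any ρ step to stay inside the validity
interval, and — when the optimum sits *on* the boundary (common for
exchangeable structures, whose lower limit `−1/(N−1)` shrinks with N) —
switches to a projected system: the pinned ρ coordinate is dropped and
convergence is judged on the remaining gradient.  "On the boundary" means
within 0.5% of the interval with an outward-pointing gradient: as R
degenerates at the exchangeable lower limit the likelihood-like value has a
log-singular spike, and the optimizer must not chase it (at the cost of
reporting a boundary ρ up to half a percent inside the interval).  Stopping: `max|g| < 1e−6`,
or an accepted step improving the value by `< 1e−7` (early stop), max 200
iterations.  Initialization: the extended-GEE solution when it converges,
else a log-scale least-squares start with the dispersion intercept at the
log Pearson estimate.

The covariance reported for ELMM is the model-based `−H⁻¹`, giving Wald
`z = θ̂/se` with normal p-values.  Because the normal likelihood-like
function is a working model, these SEs are only well calibrated when counts
are large enough to be roughly symmetric: in simulations the nominal 5%
rejection of a null slope holds at mean counts ≈20, but inflates to ≈12% at
mean counts ≈3 and does not vanish with N (a sandwich correction, out of
scope here, would be needed).  For adaptively selected models the z tests
are post-selection quantities and the reports label them as such.

## LCV

`make_folds` assigns each observed time an independent uniform label in
1..k, so fold sizes vary and folds can be empty (empty folds are dropped);
this also means a fixed `(times, k, seed)` triple fully determines the
partition, and two models are comparable only under the same seed.  Each
non-empty fold f is scored as a *difference of joint values on nested
unions*, `log LCV_f = ℓ(T⁺(f); θ_del) − ℓ(T⁺(f−1); θ_del)` with
`ℓ(∅) = 0` — exactly the conditional-density ratio, but through one code
path.  Deleted fits warm-start at the full-data estimate and retry once
cold before the whole score is declared invalid (NaN, model rejected in
searches).  All arithmetic stays in log space; `LCV = exp(Σ_f log LCV_f /N)`.

Two numerical guards matter here.  `ℓ` is computed from a Cholesky
factorization of `R` (quadratic form in standardized residuals plus
`log|R|` from the factor diagonal), never a raw determinant.  And a ρ
estimated on a fold complement can be invalid — or valid but nearly
singular — on a larger union under the exchangeable structure; evaluation
clips ρ so the smallest eigenvalue `1+(m−1)ρ` of the union's R stays ≥0.01,
since evaluating at the exact boundary produces astronomically inflated
quadratic forms.

## Adaptive search

Expansion proposes, for the mean model then the dispersion model, the best
single new transform `t^p`: p is grid-searched over `[−3, 10]` in steps of
0.5 and then hill-climbed at steps 0.1 and 0.01 (hence two-decimal selected
powers), always scored on the shared fold seed, capped at 3 transforms per
submodel, with `p=0` excluded alongside an intercept.  Contraction
repeatedly tries removing each transform and each intercept, re-refines the
surviving powers, and takes the best-scoring removal.

Acceptance is governed by LCV-ratio significance cutoffs rather than flat
tolerances.  Two models whose scores differ by less than
`1 − exp(−χ²₁(0.95)/(2N))` are statistically indistinguishable (the
per-observation geometric-mean analogue of a 1-df likelihood-ratio test),
so contraction removes a transform whenever the drop stays within that
cutoff — parsimony wins ties.  Expansion must clear a stiffer bar: the
candidate it proposes is the *maximum* over ~27 grid points (plus
refinement) on a single CV split, and that maximum is inflated by selection
noise — rescoring selected-on-null models under other fold seeds shows
1–3% phantom gains at N=100.  The expansion cutoff therefore
Bonferroni-adjusts the level for the grid size
(`χ²₁(1−0.05/m)`, ≈4.7% relative at N=100, m=27).  In calibration runs at
N=100 this keeps intercept-only truth at intercept-only selection in 49/50
seeds while recovering a true `t^0.5` trend (power in [0.2, 0.9]) in 46/50.
Both cutoffs are overridable (`tol_expand`, `tol_contract`);
`tol_expand=−inf` accepts every proposal, `tol_contract=0` keeps any
transform whose removal strictly lowers the score.

A residual failure mode is worth knowing: with a zero count at a
high-leverage time (the first or last observation), a near-indicator
transform (large |p|) can drive `μ→0`, `σ→0` there, and the normal
likelihood-like "density" at a zero count diverges like `−log σ` — a true
Poisson log-mass is bounded by 0, but the normal surrogate is not.
Occasionally this wins the search on null data despite the cutoffs; it is a
property of the likelihood-like function itself, not of the optimizer.

Correlation structure is not searched; compare `{ind, exch, ar1}` at a
fixed spec by LCV (see `examples/compare_correlation_structures.py`).

## Synthetic data

The generator draws a latent multivariate normal with correlation `R(ρ)`,
maps it through the standard-normal CDF, and inverts count quantile
functions matched to the model's first two moments: negative binomial with
`size = μ/(φ−1)`, `p = 1/φ` (mean μ, variance φμ exactly) when `φ > 1`,
Poisson when `φ = 1`; `φ < 1` is rejected rather than approximated.
Missing indices are dropped *after* generation, so missingness is a mask
over an underlying complete process.

What this emulates: trending means, time-varying overdispersion,
lag-decaying dependence, gaps, and exposure offsets — the structure of
daily symptom/medication series.  What it does not: the latent-normal ρ is
*attenuated* on the count scale (ρ=0.5 induces ≈0.48 between adjacent
moderate counts, less for very small counts), so recovery checks compare
fitted ρ with the induced count-scale correlation computed independently by
Gauss–Hermite quadrature, not with the latent value; zero-inflation,
day-of-week structure and measurement error in real adherence data are not
modeled, so passing tests demonstrate correctness of the estimators under
the model's own assumptions, not robustness to such features.  The three
`patient_fixtures` series reproduce the shapes of the motivating examples —
33 observed days of 34 with an increasing trend; 92 of 100 with eight
scattered missing days and AR(1) 0.45; 30 subperiods of 3.03 days with 5
scheduled doses/day (totals 15.15) and AR(1) 0.75 — with synthetic draws,
not real patient values.

Known finite-sample behavior measured with this generator: the ELMM
log-dispersion intercept is biased low by ≈0.04–0.06 at N=200 (shrinking
by N=500), the ML-style analogue of the df-loss the bias-adjusted Pearson
estimator divides out; mean-model coefficients are recovered without
detectable bias at the same size.

## Numerical choices

Linear predictors beyond |η| = 700 raise (no silent clipping).  Power
transforms require positive times.  Newton safeguards: ≤20 step-halvings,
one-shot diagonal ridge on singular Hessians, gradient-direction fallback
when the Newton direction is not an ascent direction.  Fits on candidate
specs with overflowing designs fail fast (floating-point errors are raised,
caught, and the candidate is scored NaN).  Problem sizes in the test and
acceptance runs (N ≤ 200 series, ≤100 simulation replicates, 50-seed search
calibrations) were chosen to characterize the estimators at the scale of
the motivating single-patient data while keeping the full suite
desk-runnable.
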