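# Methods

## Response scale and data model

The raw outcome of a novel-object-recognition (NOR) test is the fraction
of exploration time spent at the novel object, `F_nov ∈ (0, 1]`. All
modeling happens on the transformed scale `R = −ln(F_nov)`, which maps
the fraction to a non-negative response that grows with the severity of
the recognition deficit and is closer to Gaussian. A record carries the
subject id, ion species, beam energy (MeV/n), LET (keV/µm), absorbed
dose (Gy), months since exposure, and `F_nov`.

`F_nov = 0` (the rat never explored the novel object) has no finite
transform. The default is to reject such records with a logged reason; a
configuration flag instead clips them up to an epsilon (default 10⁻³,
roughly one time-resolution unit of the assay). Rejection is the
conservative default because a clipped value injects an arbitrary,
extreme response.

LET is binned into four categories. *Exact* mode covers only the LET
values of the emulated design (L = 0.22, M = 13–16, H = 41–50,
VH = 106–181 keV/µm) and raises an error for anything else — silent
nearest-bin assignment would blur the radiation-quality contrast.
*Permissive* mode uses contiguous intervals [0,5), [5,30), [30,80),
[80,∞) so arbitrary simulated LETs are assignable. Sham records (0 Gy)
get their own SHAM category: they identify the baseline in every fit and
belong to no TE/NTE group, and no LET label for an unirradiated animal
needs to be invented.

Time since exposure is ingested and screened (Spearman) but never enters
the dose-response models; its rank correlation with the response is
negligible under both the emulated design and the generative truth.

## The model family

Every variant is a sum of a baseline `B`, an optional NTE term, and
optional TE terms:

```
R(D, cat) = B + kNTE · (1 − exp(−kNTE_r·D)) + Σ_g kTE_g · D^q · 1[cat ∈ g]
```

* `kNTE_r` is fixed at 10³ Gy⁻¹, not estimated: left free it runs to
  enormous values with enormous uncertainty, and the fixed constant keeps
  the saturating rise smooth rather than a step while placing saturation
  below ~0.01 Gy. It is overridable for sensitivity analysis.
* `q` = 1 (linear TE) or 2 (quadratic TE).
* The slope groups `g` partition (a subset of) {L, M, H, VH}; categories
  outside every group have their slope fixed at zero.

The registry enumerates exactly 18 variants: TE-only and NTE-only forms
with and without LET dependence, one NTE variant with per-category
plateaus, and NTE+TE combinations with groupings
{L}{M}{H}{VH}, {LM}{H}{VH} (S1), {LMH}{VH} (S2), {H}{VH} (S3), {VH} (S4)
for both TE powers. No hybrids beyond these are constructed. Because
`kNTE_r` is fixed, every variant is linear in its free parameters; the
design matrix doubles as the exact Jacobian everywhere, so the
"nonlinear" solvers below converge in a handful of steps without
approximation error.

Parameters are unconstrained during optimization (standard nonlinear
regression practice; a negative baseline estimate triggers a warning
rather than a bound, and none of the shipped analyses produce one).

## Robust fitting

The main estimator minimizes `Σ ρ((y_i − f_i(θ))/s)` by iteratively
reweighted least squares: at each iteration the weighted nonlinear
least-squares subproblem is solved by Gauss–Newton with step halving,
the scale `s` is re-estimated as the median absolute residual / 0.6745,
and the weights are updated from the influence function. The default
loss is Huber with tuning constant 1.345 (95% Gaussian efficiency);
Tukey bisquare (4.685) and plain squared error are selectable.
Convergence requires relative parameter change, relative loss change
(both < 10⁻⁸ by default) and a stable scale; non-converged fits are
flagged, never silently returned.

Standard errors use the M-estimation sandwich
`A⁻¹BA⁻¹`, `A = Σ ψ′(u_i) x_i x_iᵀ / s`, `B = Σ ψ(u_i)² x_i x_iᵀ`, with
two-sided normal p-values. Simulation under a true-zero parameter shows
the p-values are uniform (Kolmogorov–Smirnov, see the test suite).

Starting values are deterministic and data-driven: `B₀` = median sham
response, `kNTE₀` = median response at doses ≥ 0.05 Gy (where the NTE
term is fully saturated) minus `B₀`, TE slopes 0. With a convex Huber
loss and a linear-in-parameters model the optimum does not depend on the
start; the heuristic just shortens the iteration.

## Likelihood convention and AICc

Robust losses have no canonical likelihood. For information criteria the
package evaluates the *Gaussian* log-likelihood at the robust estimates
with `σ² = mean squared residual` and counts `k = #regression parameters
+ 1` (for σ). The convention is applied identically to all 18 variants,
so AICc *differences* compare like with like; absolute AICc values (and
hence printed ΔAICc magnitudes from other likelihood conventions) are
not reproduced, and the package's claims rest on the ordering and the
ΔAICc < 6 membership set. `AICc = 2k − 2ℓ + 2k(k+1)/(n−k−1)`; support is
`exp(−ΔAICc/2)`, with ΔAICc > 6 (support < 1/20) read as poor.

Split stability refits the chosen variant on 300 random 50:50 splits and
scores R²/RMSE/MAE on both halves with the training-fit parameters.
Splits are stratified by LET category × dose cell so every slope remains
identifiable in every split; an unstratified mode with
resampling-on-failure exists for comparison. Stratification is this
package's choice — it trades a little randomness for never discarding a
split.

## Quantile regression

The τ-th conditional quantile of the same surface minimizes the check
loss `Σ ρ_τ(r_i)`, `ρ_τ(r) = r(τ − 1[r<0])`. The kink makes generic
smooth optimizers unreliable, so the package minimizes a Huberized
surrogate — quadratic on |r| ≤ h matching value and slope at ±h — with
h annealed through {10⁻¹…10⁻⁴}·scale from the robust-fit start, then
polishes on the exact loss with Nelder–Mead. A multistart simplex oracle
on the exact loss validates the result in the tests. Standard errors are
by case-resampling bootstrap (default 500 replicates, seeded); the
bootstrap refits from the point estimate, and more than 20% replicate
non-convergence marks the SEs unreliable.

Under the generator's symmetric Gaussian noise the median fit coincides
with the mean fit and the quartile fits shift essentially only the
baseline, by ±0.6745σ. On real, right-skewed NOR data the quartile
baselines would not be symmetric about the mean fit — that asymmetry is
a feature of the data, not of the estimator.

## Mixed effects

Most rats are tested twice; their responses share a rat-specific
baseline shift. With the random intercept entering additively on `B`,
each rat's response vector is marginally Gaussian with covariance
`σ_b²·11ᵀ + diag(v_i)` — the marginal likelihood is exact (verified
against 64-node Gauss–Hermite integration to 10⁻⁶), no linearization is
involved. The residual variance function is
`v_i = σ²·λ²_cat·exp(2δ·D_i)` ("combined"; per-LET multipliers with the
reference stratum fixed at 1, times an exponential dose trend), with
by-LET, by-dose and constant structures selectable. The functional form
is this package's choice of the standard stratum-multiplier ×
exponential-trend structure; only the mechanism (variance varying with
dose and LET) is dictated by the analysis design.

Fixed effects are profiled out exactly by GLS inside a Nelder–Mead
search over the log-scale variance parameters; maximum likelihood is the
default (log-likelihoods comparable across fixed-effect structures),
REML by flag. A Wald interval for `σ_b` (log scale, full
finite-difference Hessian) is attached by default; a profile-likelihood
interval — more accurate for small variance components, where the Wald
interval visibly undercovers — is available as `ci_method="profile"`.
Boundary estimates (`σ_b → 0`) are flagged, and an all-singleton design
with constant variance triggers an explicit unidentifiability warning.

Diagnostics operate on conditional residuals (BLUP intercept subtracted,
variance-function standardized): Shapiro–Wilk, skewness, Pearson
kurtosis, residual-vs-dose and residual-vs-time trend tests, lag-1
autocorrelation, and per-LET summaries. Variance homogeneity per factor
uses the Fligner–Killeen test (scipy).

## Feature importance

The feature table holds five predictors — dose, beam energy (0 for
sham), time, LET, and the NTE functional form
`nte_f = 1 − exp(−10³·D)` — plus the response. The screen follows the
shadow-feature wrapper: per round, append an independently permuted copy
of every predictor, fit a random forest (sqrt-mtry feature subsampling),
and count a "hit" when a real predictor's importance exceeds the best
shadow's; a two-sided binomial test at 1% per round confirms or rejects
each predictor (max 100 rounds by default), and the whole screen is
repeated with independent seeds, ranking predictors by the median of
per-repeat median importances.

Importance is *per-tree out-of-bag permutation importance* (each tree
scored on its own OOB samples before and after permuting one column,
averaged over trees). Two implementation points matter and are deliberate:
whole-forest importance computed on training data is spurious for deep
forests (shadows "memorize" too), and whole-forest importance on held-out
data starves whichever of two deterministically related predictors the
trees use less — dose and `nte_f` induce identical sample orderings, so
only the per-tree OOB form, paired with sqrt-mtry randomness, lets them
share credit the way the classical RF importance does. Feature columns
are canonicalized by name internally, making the ranking invariant to
the caller's column order. Tree induction itself is scikit-learn's.

The tuned-forest evaluation grid covers split feature count, leaf size
and split rule; tuning is by RMSE under repeated K-fold cross-validation
on one training half, and the tuned forest is then scored over random
50:50 splits (defaults 3-fold × 30 repeats, 300 splits, 2000 trees;
the shipped analyses and the acceptance script use reduced sizes noted
below).

## Synthetic study conditions

The generator emulates the multi-ion NOR design: sham plus four LET
categories (H 0.22, O 16, Si 44, Fe 181 keV/µm at realistic beam
energies), doses {0.001, 0.005, 0.01, 0.05, 0.1, 0.25, 0.5, 1, 2} Gy,
12 rats per irradiated cell and 30 sham rats, each tested at 3 and 9
months — 924 tests. Generative truth defaults: baseline 0.424, NTE
plateau 0.166, linear TE slopes 0.027 Gy⁻¹ (L/M/H) and 0.127 Gy⁻¹ (VH),
noise SD 0.24 on the response scale (matching the observed residual
RMSE), per-rat baseline SD 0.073, optional gross contamination
(+shift on a random subset). Per-group animal counts are not public for
the emulated study; the cell sizes above are calibrated only to the
~920-sample total.

A noise draw that would push the latent response below zero is
**censored at the boundary** (`F_nov = 1`: the rat spends all its time
at the novel object) and counted. The alternative — resampling the draw
until positive — was rejected after measurement: resampling shifts every
boundary-adjacent group mean upward by the full truncated-tail mean
(≈ +0.021 response units at the default baseline), which breaks the
generator's own mean contracts and biases baseline/plateau recovery;
censoring perturbs the group mean by ≈ +0.004 and mirrors what the assay
records. The residual asymmetry this induces at the default baseline is
a genuine feature of a boundary-limited assay; tests that isolate
*estimator* calibration (SE calibration, random-intercept recovery) use
configurations where the boundary is inactive, and say so.

What the generator does **not** emulate: ion-specific effects beyond
LET, time trends, skewed/heavy-tailed residuals (except via explicit
contamination), dose-dependent variance, and rat-level variation in the
radiation-response parameters themselves. Passing tests therefore
certify the estimators under the stated Gaussian conditions, not the
distributional quirks of any real dataset.

## Problem sizes in the shipped runs

The library defaults keep the published procedure's sizes (300 splits,
500 bootstrap replicates, 100 screen repeats, 2000 trees, 3×30 CV). The
analysis scripts and `scripts/acceptance.py` choose smaller
configurations — e.g. 200 bootstrap replicates, 10 screen repeats of
3 × 6 rounds with 100-tree forests, 30–50 outer forest splits with a
squared-error-only grid — sizes at which every reported quantity is
already stable to well within its own Monte-Carlo spread. The test
suite similarly scales replicate counts (e.g. 60–100 recovery
replicates, 20-run screens) to keep a full run in a few minutes.

## Known limitations

* AICc magnitudes depend on the Gaussian-at-robust-estimates likelihood
  convention; only orderings and membership sets are meaningful.
* The sandwich SEs assume independent observations; with per-rat
  correlation in the data the true sampling SD of slope estimates is
  somewhat larger (the mixed model is the remedy, and the SE-calibration
  tests document the premise).
* The quantile surfaces are fitted per-τ; non-crossing on the observed
  design is checked, not enforced.
* `nte_f` saturates to exactly 1.0 in float64 above ~0.03 Gy; rank-based
  statements about its monotonicity in dose hold on the resolvable range.
* With `kNTE_r` fixed and doses ≥ 0.05 Gy, `kNTE` and any global TE
  intercept-like contrast are near-collinear at very sparse designs;
  the rank check in the fitter names unidentifiable parameters instead
  of returning garbage.
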