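# Methods

## Design construction

A central composite design over k factors combines `2^k` factorial
corners at coded ±1, `2k` axial (star) points at coded ±α, and
`n_center` replicated center runs. The default α is the rotatable value
2^(k/4), which makes the variance of a fitted second-order prediction a
function of distance from the center only; face-centered (α = 1) and
arbitrary numeric α are supported as generalizations. Coded and actual
levels are related by `actual = center + half_range × coded`, with the
sign convention that +1 is the high face; the round trip is exact to
machine precision. The canonical study factors are sucrose
S = 30 ± 17.5 g/dL, yeast protein P = 2 ± 1 g/dL, and duration
D = 5 ± 2 d with six center replicates: 20 runs, α ≈ 1.6818.

Run order is canonical (factorial, axial, center) by default so designs
are reproducible without bookkeeping; a seeded permutation is available
because real studies randomize bench order. Randomization has no effect
on fitting.

## Model fitting and diagnostics

The datapoint is the per-run mean of replicate measurements
(replicate-level fitting is available but not the default; with
near-equal replicate counts the means are close to homoscedastic and OLS on
means matches the standard analysis of this design). The full
second-order basis has p = 1 + 2k + k(k−1)/2 columns (10 for k = 3);
fitting requires more distinct design points than p and a full-rank
basis, otherwise `InsufficientDataError` / `SingularDesignError`.

Diagnostics computed on the hat matrix H = X(XᵀX)⁻¹Xᵀ:

* **Leverage** hᵢᵢ (sums to p over included points).
* **Externally studentized residuals**
  tᵢ = eᵢ / √(MSE₍ᵢ₎ (1 − hᵢᵢ)) with
  MSE₍ᵢ₎ = ((n−p)·MSE − eᵢ²/(1−hᵢᵢ)) / (n−p−1) — algebraically equal to
  the studentized prediction error from a fit excluding point i (tested
  against literal refits). Runs with |ESR| above a configurable
  threshold (default 3, the usual convention) are flagged and can be
  excluded and the model refit; exclusions are recorded on the result.
* **PRESS** via the leave-one-out identity Σ (eᵢ/(1−hᵢᵢ))², giving
  predicted R² = 1 − PRESS/SStot.
* **Adjusted R²** = 1 − (1−R²)(n−1)/(n−p).
* **Adequate precision** = (max ŷ − min ŷ) / √(p·MSE/n), the
  predicted-range signal-to-noise ratio with the conventional > 4 bar.
  (No closed-form reference exists in the primary literature for this
  statistic; this is the definition used by the standard DOE software.)
* **ANOVA**: whole-model F against the intercept-only model; per-term
  partial (type-III) single-df F tests, i.e. the squared coefficient
  t statistics, equivalent to dropping each column from the full basis.

No response transformation and no term reduction are applied — the full
quadratic is always reported. A fit whose residual sum of squares is at
machine-noise level relative to the response scale (SSE ≤ 1e−18·n·mean y²)
is treated as exact: R² statistics are reported as 1, ESR as 0, and
adequate precision as infinite (or 0 if the predictions themselves are
flat). Without this guard, floating-point residuals of order 1e−11
would be studentized into arbitrary values.

## Representation conversion

Actual-unit and coded-unit coefficient sets describe the same
polynomial. Conversion substitutes xᵢ = mᵢ + aᵢuᵢ and collects terms:

* interaction: c_ij = b_ij·aᵢaⱼ
* quadratic:   c_ii = b_ii·aᵢ²
* linear:      c_i  = aᵢ(b_i + 2b_ii·mᵢ + Σ_{j≠i} b_ij·mⱼ)
* intercept:   c₀   = b₀ + Σb_i·mᵢ + Σb_ii·mᵢ² + Σ_{i<j}b_ij·mᵢmⱼ

The reverse direction applies the same algebra with shift −m/a and
scale 1/a. Predictions in the two representations agree to better than
1e−9, and conversion round trips restore coefficients to 1e−9. When the
published 4-decimal actual coefficients of the body-fat model are
converted, the coded interaction and pure-quadratic P²/D² terms agree
with the published coded set at printed precision, while the intercept,
linear and S² terms — each a sum of products of large centers with
rounded coefficients — agree to ≈0.03; the fertility model, published
at 6 decimals, converts to printed precision in every term.

## Desirability integration

Each response is ramped linearly between two anchors and clipped to
[0, 1]; overall desirability is the unweighted geometric mean. The
anchor range defaults to the min/max of the model's predictions over a
dense grid of the coded star-cube [−1.682, 1.682]³ — the integrated
surfaces are functions of the fitted models, so anchoring on model
extremes (rather than observed data extremes) keeps d = 0 and d = 1
attached to the actually attainable surface range. Anchors are user-
overridable. Values outside the anchors clip to {0, 1} rather than
extrapolate, which keeps R in [0, 1]. Only one-sided (maximize /
minimize) goals and equal weights are implemented.

## Optimization

The search domain is the region the design sampled: the coded
star-cube, clipped where −α would imply a negative actual level.
`find_optimum` screens a dense grid (default 50 nodes per factor — for
the published models halving the spacing changes R* by far less than
1e−3) and refines from the best node with bounded Nelder–Mead
(tolerance 1e−6 in R). The result keeps whichever of grid node and
refined point is better, so refinement can never lose to the screen. A
surface that is constant over the grid (range < 1e−12) returns the
domain center flagged `flat`. Confidence bands on surface slices use
the t distribution with the fit's residual df at 95% two-sided.

Two empirical properties of the published surfaces deserve note. First,
with six center replicates the design has near-uniform precision inside
the unit sphere: the mean-prediction band at coded radius ≈1 sits a few
percent *below* the center value before growing steeply toward the
star radius; tests assert the center is within 5% of the minimum and
that edges are ≥1.5× wider, not exact centrality. Second, Scenario-I
desirability at S = 35, P = 3 is not globally monotone in duration —
there is a dip of ≈0.002 near D = 2 — but is strictly non-decreasing
over the treatment window D ≥ 4.

The global Scenario-I optimum under these choices lies at a
protein-starved corner (P ≈ 0.32 g/dL) with R* ≈ 0.857, while the
protein-replete selected condition S35 P3 D6 reaches R ≈ 0.684, i.e.
≈0.80 of R*. The package also provides a sucrose-saturation diagnostic
(relative change of R over S ∈ [35, domain max] at fixed P, D; ≈0.075
for Scenario I at P = 3, D = 6), quantifying that R stops responding
appreciably to sucrose above 35 g/dL — the property that motivates
choosing a moderate-sucrose treatment over the star extreme.

## Synthetic studies

`simulate_measurements` draws each replicate as model prediction +
Gaussian(0, sd); `emulate_study` bundles the 20-run design, both
reference response surfaces, and replicate counts uniform on 4–7 per
run. Noise is homoscedastic per response by default (no transformation
is applied in the standard analysis of such data, implying roughly
constant variance); an option scales sd with the predicted mean for
robustness experiments. Default noise sds — Bf 4 nmol/mg, F 0.6
eggs/female/day — are calibration constants, not measured values: with
them, refits of emulated studies reach mean adjusted R² ≈ 0.97 (Bf) and
≈ 0.99 (F) (`examples/05_noise_calibration.py` reproduces the sweep),
in the range a well-run study of this design reports.

Stochastic draws are clipped at zero because neither response is
physically negative; clipped draws are counted in
`data.attrs["n_clipped"]`. Clipping matters: the fertility surface dips
below zero near the high-duration star run, so at realistic noise the
zero-floor biases that run's mean upward and distorts the D²
coefficient of refits — a deliberate emulation of a real floor effect,
and the reason coefficient-coverage simulations use the body-fat
surface, which stays well above zero (minimum design-point prediction
16.8 at sd 4). Noise-free simulation bypasses the clip so that the
noiseless pipeline identity (recovering the generating coefficients to
1e−6) holds exactly.

What the generator does not emulate: fly survival and attrition,
day-to-day autocorrelation in egg laying, replicate-count dependence of
variance beyond the 4–7 range, and any systematic (non-Gaussian) bench
effects. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated noise model, not robustness to
every artifact of a live experiment.

Simulation study sizes used in the test suite — 500 replications for
coefficient coverage, 200 for significance rates, 20–30 studies for
calibration sweeps — keep Monte Carlo standard errors near 1% on
coverage proportions.

## Assay endpoints

Body fat = mean aliquot TG concentration × buffer volume / body weight
(nmol/mg); aggregation order across aliquots is irrelevant for a mean.
Fertility = eggs / (females × days), with the surviving-fly count as
the intended denominator. Inhibition ratio = treated / control egg
production; hemolymph glucose = glucose mass / body weight (μg/mg).
All are degree-1 homogeneous in the numerator and degree-−1 in the
denominator, which the property tests assert.

## Known limitations

* Anchor choice changes R numerically (not the direction checks);
  observed-data anchors, the common software default, can be supplied
  via `build_scenario(..., anchors=...)` but are not the package
  default.
* Per-term F tests are single-df partial tests; no pure-error /
  lack-of-fit decomposition is offered.
* The zero-floor bias on near-zero fertility runs is inherent to the
  emulation and is reported (clipping counter) rather than corrected.
* The optimizer is a local refinement over a box; it is adequate for
  quadratic-composition surfaces but is not a global optimizer for
  arbitrary user models.
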