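# Methods

## Model

Tuber weight per m² on field *i*, sampling day *j*, year *k* is modelled
as a logistic curve with multiplicative lognormal error:

    y_ijk = exp(a_ik) / (1 + exp(-b_ik (t_ijk − c_ik))) · exp(e_ijk),
    e_ijk ~ N(0, σ²) i.i.d.

Time is measured in days after planting (reset each year) and divided by
its pooled sample standard deviation before fitting; this is purely a
numerical-conditioning step, and `ModelParams.rescale_time` converts
parameters between the day and standardized scales. Field-level curve
parameters combine year fixed effects with three standardized random
effects:

    a_ik = α_0k + σ_α a_i
    b_ik = exp(β_0k + σ_β b_i)          → b_ik > 0, lognormal
    c_ik = γ_0k + exp(σ_γ) c_i

with (a_i, b_i, c_i) multivariate normal, unit variances, correlation
matrix R = [[1, ρ12, ρ13], [ρ12, 1, ρ23], [ρ13, ρ23, 1]]. One set of
scales (σ_α, σ_β, σ_γ) is shared across years (between-year variance
assumed constant). Note that σ_γ is the *pre-exponential* parameter: the
effective scale of the midpoint effect is exp(σ_γ), so σ_γ itself is
unconstrained; σ_α and σ_β are non-negative.

Assumptions worth keeping in mind: the error is multiplicative (constant
coefficient of variation — appropriate while growth is active, and it
makes exact-zero weights uninformative, see below); missingness is
MCAR/MAR, so likelihood-based fitting is valid without a missingness
model; random effects are Gaussian with a single shared correlation
structure.

### Zero weights

A weight recorded as exactly zero (a field destroyed by extreme weather,
after which sampling stops) has zero density under any lognormal error
and carries no curve information. Such rows are excluded from the
likelihood but counted and reported (`Dataset.excluded_zeros`), never
silently dropped. No censoring model is attempted.

### Estimation

All likelihood work happens on the log scale (log y is additive
Gaussian), which is mathematically identical to the multiplicative model
and immune to overflow; reported log-likelihoods include the lognormal
Jacobian, so they are densities of the weights themselves.

The marginal likelihood integrates the 3-dimensional random effect out of
each field's contribution with **adaptive Gauss–Hermite quadrature**: per
field, the posterior mode of (a,b,c) is found by a damped Newton search
(analytic gradient, Gauss–Newton curvature — always positive definite),
and the tensor quadrature grid is recentred at the mode and scaled by the
inverse Cholesky factor of that curvature. One node per dimension is
exactly the Laplace approximation; the default is 5 nodes per dimension
(125 per field). The mode search is vectorized across all fields, and
modes are warm-started between objective evaluations, which makes a full
360-field fit take seconds rather than minutes.

Free parameters are optimized by L-BFGS-B on an unconstrained vector:
σ_α, σ_β and σ on the log scale, σ_γ as is, and the correlation matrix
through the spherical (Cholesky-angle) parameterization, which covers
exactly the positive-definite correlation matrices. Starting values come
from per-year nonlinear least squares of the fixed-effect curve on pooled
data (residual sd from those fits; scales start at 0.3, correlations at
0). The fit runs a Laplace stage to convergence first, then refines at
the requested node count; convergence tolerances are `gtol=1e-5`,
`ftol=1e-8` (relative), at most 500 iterations per stage, and
non-convergence is reported via `FittedModel.converged` and a warning,
never silently.

Empirical-Bayes (EB) random effects are the per-field posterior modes at
the fitted parameters — the same modes the quadrature recentres on. Fit
quality is summarized by the R² of an ordinary least-squares regression
(with intercept) of observed weights on EB-curve predicted weights, both
in g m⁻².

### Numerical edge cases

Degenerate random-effect scales (σ_α = σ_β = 0, σ_γ → −∞) reduce the
marginal to the fixed-effect lognormal density; the quadrature reproduces
this exactly at any node count. Identical weights, fields without
observations, non-PD correlation inputs, zero prediction variance and
single-day time grids all raise explicit errors (or a warning plus skip,
for observation-less fields).

## Mining

After the fit, each field-year is one record; the mining target is one EB
component (a, b or c). Under the model the population of effects is
centred at zero, so a subgroup G is exceptional when its sample pulls
away from zero, measured by t_G = μ̂_G √n / σ̂_G (sample sd, n−1). The
quality is φ = t_G for direction "high" and −t_G for "low".

The search is level-wise beam search over conjunctions of conditions:

- numeric attributes: candidate thresholds are the n_bins − 1
  equal-frequency quantiles of the attribute **within the current
  subgroup** (dynamic discretization; default n_bins = 6), each giving a
  ≤ and a > condition;
- categorical attributes: = and ≠ for every category observed in the
  subgroup;
- records missing the attribute never satisfy a condition, and quantiles
  use non-missing values only.

Descriptions are kept canonical (per attribute only the tightest ≤ and >
survive, conditions sorted), duplicates are removed on (canonical
description, member set), and subgroups with n < 2 or zero spread get
quality −∞ and are never refined. Beam width defaults to 25; `None`
keeps everything (exhaustive over the refinement-generated language,
used by oracle tests). Ties are broken by shorter description, then
lexicographically, so results are fully deterministic.

Search keeps `min_size=2` so the Pareto trade-off can still see small
groups; the minimum-size rule n > 15 is applied at reporting only.

## Pareto filtering and reporting

Each subgroup maps to (directional mean, sd, n); the front keeps those
not dominated (≥, ≤, ≥ with one strict). The directional mean (−μ̂ for
low-direction runs) makes "larger is better" hold in all directions.
Equal triples are mutually non-dominating and both kept. The filtering is
asymmetric: it removes subgroups dominated by *found* subgroups but
cannot certify the survivors globally optimal.

`top_k_report` then drops n ≤ 15, collapses redundant same-direction
thresholds inside a description (already canonical), and when two
survivors' member sets are nested (or identical) under descriptions that
differ only in thresholds on the same attributes, keeps the larger (for
identical sets, the shorter/lexicographically-first description). The
collapse is a presentation step only; the search and the front always
count full candidate sets.

Profiles (year counts, mean yield, irrigation counts, per-year planting
tertiles — earlier tertiles take the remainder, stable sort on date) are
descriptive annotations for confounder inspection; no test is attached,
and no causal reading is implied.

## Synthetic data

The generator draws exactly from the model: correlated standard-normal
effects (Cholesky), curves via the parameter map above, lognormal error,
5–7 jittered sampling days per field in [25, 135] days after planting.
Defaults of `default_farm_config` describe a realistic four-season farm
campaign:

| parameter | default | note |
|---|---|---|
| years × fields/year | 4 × 90 | ≈360 field-years |
| α_0k | 8.6 / 8.1 / 8.5 / 8.2 | asymptotes ≈3300–5400 g m⁻² |
| β_0k (day scale) | −2.25 … −2.40 | steepness ≈0.09–0.11 d⁻¹ |
| γ_0k (day scale) | 72–80 d | midpoint early/mid July |
| σ_α, σ_β, exp(σ_γ) | 0.30, 0.25, 6 d | field-level spread |
| ρ12, ρ13, ρ23 | −0.65, +0.49, −0.73 | case-study estimates (see note) |
| σ (log scale) | 0.15 | ≈15 % CV, puts R² near the mid-0.9s |
| soil descriptors | lognormal, medians at case-study magnitudes | independent of growth |
| yield | year base (63.5/40.1/54.0/38.0 t/ha) + 8·a_i + noise | links yield to the a effect |

On the printed a–c correlation: the case-study table prints −0.49, but
that triple is not a positive-definite correlation matrix (determinant
≈ −0.66) and the accompanying text describes the a–c correlation as
weakly *positive*; the generator therefore uses +0.49 with the printed
magnitude.

`planted_recovery_config` adds one planted effect: fields with
K_soil > 265 kg/ha (≈ upper quarter of the K distribution) get +0.8 on
the a effect — a known answer for end-to-end recovery checks, assessed on
the *reported* top-3 (Pareto front, n > 15), i.e. the pipeline's actual
output.

What the generator does **not** emulate: weather covariates and
year-by-weather interactions beyond the year fixed effects, spatial
correlation between neighbouring fields, descriptor–descriptor
correlation structure, measurement rounding, and destroyed-field zero
sequences. Passing recovery tests therefore show correctness of the
machinery under the model's own assumptions, not robustness to real-data
misspecification; the real-data R² (≈0.92 in the case study) is lower
than the synthetic one (≈0.96) for exactly this reason.

## Problem sizes used in checks

Quadrature-vs-Monte-Carlo uses a 2-field toy with 10⁶ prior draws per
field; the posterior-mode oracle uses a two-stage dense grid (0.08 then
0.005 step on [−4,4]³); parameter recovery fits the 360-field default at
5 quadrature nodes; planted-subgroup recovery runs 10 seeds at the
default size with a Laplace-stage fit (1 node) per seed, which the
Laplace-vs-adaptive agreement check justifies for this purpose.

## Known limitations

- Only the logistic curve family is implemented (no haulm/quadratic
  curves); no censoring model for destroyed fields.
- EB effects are plugged into the mining step without propagating their
  estimation uncertainty; shrinkage makes small-field effects
  conservative.
- The exhaustive oracle and the beam agree on the language generated by
  applying the refinement operator up to depth d; tightening refinements
  may collapse to shorter canonical descriptions.
- Exact reproduction of the original case-study tables additionally
  depends on beam width and discretization choices not restated here;
  the published-table check is therefore an internal-consistency check
  of the quality measure, not a re-listing of those tables.
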