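# egm — Exceptional Growth Mining

Tools for finding *interpretable* subgroups of agricultural fields whose
crop-growth curves deviate systematically from the seasonal average, given
(a) longitudinal in-season growth samples (e.g. potato tuber weight per
m², 5–7 sampling rounds per field) and (b) per-field soil and management
descriptors (nutrient levels, dryness class, previous crop, irrigation,
planting date).

The pipeline has three steps:

1. **Growth curves.** Tuber weight follows a logistic curve with
   multiplicative lognormal error,

   ```
   y_ijk = exp(a_ik) / (1 + exp(-b_ik (t_ijk − c_ik))) · exp(e_ijk),
   e_ijk ~ N(0, σ²)
   ```

   with year-specific fixed effects and three correlated field-level
   random effects:

   ```
   a_ik = α_0k + σ_α a_i            (log maximum weight)
   b_ik = exp(β_0k + σ_β b_i)       (steepness)
   c_ik = γ_0k + exp(σ_γ) c_i       (time of half-maximum)
   (a_i, b_i, c_i) ~ N(0, R),  R a correlation matrix
   ```

   The model is a *nonlinear* mixed model; the marginal likelihood
   integrates the three random effects out per field with adaptive
   Gauss–Hermite quadrature (mode-and-curvature recentred; 1 node =
   Laplace approximation) and is maximized by quasi-Newton optimization.

2. **Mining.** Each field is reduced to its empirical-Bayes random
   effects (â_i, b̂_i, ĉ_i); a beam search over conjunctions of descriptor
   conditions (equal-frequency thresholds for numeric attributes,
   category (in)equalities for categorical ones) scores every subgroup G
   with the one-sample t statistic `t_G = μ̂_G √n / σ̂_G` against mean
   zero, signed by the search direction.

3. **Filtering.** Mined subgroups are reduced to the Pareto front over
   (directional mean, standard deviation, size), then presented as a
   top-k report after a minimum-size filter (n > 15) and collapse of
   redundant or nested threshold descriptions.

A seeded synthetic-data generator reproduces the assumed data-generating
process (including optional *planted* descriptor-linked effects), so the
whole pipeline is testable end to end without any external data.

## Worked example

```python
import egm

cfg = egm.planted_recovery_config(seed=11)   # 4 years x 90 fields; fields with
ds, truth = egm.simulate(cfg)                # K_soil > 265 kg/ha get a +0.8 a-shift
model = egm.fit(ds, egm.FitConfig(n_quadrature=5))
print(f"converged: {model.converged},  R^2 = {egm.r_squared(model, ds):.3f}")
p = model.params
print(f"correlations: rho_ab = {p.rho12:.2f}, rho_ac = {p.rho13:.2f}, rho_bc = {p.rho23:.2f}")

targets = model.eb_frame()["a"]              # mine the log-asymptote effect
bc = egm.BeamConfig(target="a", direction="high", beam_width=25, depth=2)
subgroups = egm.beam_search(ds.fields, targets, bc)
front = egm.pareto_front(subgroups, direction="high")
top, _ = egm.top_k_report(front, k=3, min_size=15)
print(f"{len(subgroups)} subgroups evaluated, {len(front)} on the Pareto front")
for sg in top:
    print("  ", sg)
```

prints

```
converged: True,  R^2 = 0.967
correlations: rho_ab = -0.62, rho_ac = 0.50, rho_bc = -0.70
3464 subgroups evaluated, 126 on the Pareto front
   K_soil > 236.545 ∧ Si_soil ≤ 82.5257  (n=40, mean=0.666, sd=0.970, t=4.34)
   K_soil > 236.545 ∧ Mn_soil ≤ 2430.24  (n=40, mean=0.605, sd=0.896, t=4.27)
   K_soil > 243.474 ∧ S_soil ≤ 15.7669  (n=60, mean=0.550, sd=0.998, t=4.26)
```

Reading: the fit converged and the growth curves explain 96.7 % of the
variance of the observed weights. The fitted random-effect correlations
recover the generator's truth (−0.65, +0.49, −0.73): steeper curves go
with lower maxima and earlier midpoints. All three reported subgroups put
the planted `K_soil` condition first: fields with high potassium have a
log-asymptote effect around +0.6 (i.e. exp(0.6·σ_α) ≈ 20 % higher maximum
tuber weight than the year average), with t ≈ 4.3 on 40–60 fields.

The same pipeline is available from the shell:

```
egm simulate --seed 7 --out-growth G.csv --out-fields F.csv
egm validate --growth G.csv --fields F.csv
egm fit      --growth G.csv --fields F.csv --quad-points 5 --out model.json
egm mine     --model model.json --growth G.csv --fields F.csv \
             --target a --direction high --out subgroups.csv
egm report   --subgroups subgroups.csv --k 5 --min-size 15 --out report.csv
```

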