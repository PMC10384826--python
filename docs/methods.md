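# Methods

## The measurement and its error model

A gel experiment inoculates a desired B16 tumor concentration Ta (cell/mL)
together with OT1 CTLs at concentration E into a 0.1 mL collagen–fibrin gel
and counts surviving tumor cells at time t by a clonogenic assay. The assay
recovers only a fraction 1/α of cells (α ≈ 2.8 fitted, i.e. ~36% recovery),
and count scatter is roughly log-normal, so all fitting happens on the
natural-log scale: the residual SD of the best historical fit is
√(112/431) ≈ 0.51 ln units, and gels occasionally read zero (below the
detection limit of the assay, plausibly 2–10 cell/mL). Zero-count gels
cannot enter a log-scale fit; the package keeps them in storage and resolves
them at analysis time by either exclusion (the default, matching the
historical analysis) or imputation at a user-chosen limit of detection, so
the sensitivity of conclusions to that choice is a re-run, not a new file.
Concentrations are standardized to cell/mL throughout; times are stored in
hours and converted to days only inside model evaluation (factor 24 in one
place, `models.HOURS_PER_DAY`).

## Model family

Every model is a special case of dT/dt = (f_g(E) − f_k(E))T with
T(0) = Ta/α and E constant over the experiment (measured CTL concentrations
remain ~constant for ≥72 h in these gels). The closed-form members are
log-linear in time; their per-capita rates are tabulated in the README. Two
design decisions deserve note:

- **Alt1.** The algebraic-sigmoid growth variant is implemented as
  ln T(t) = ln(Ta/α) + r(√(1+(t−t′)²) − √(1+t′²)), i.e. the integral of a
  per-capita rate r(t−t′)/√(1+(t−t′)²) that switches smoothly from −r to +r
  around t′, re-anchored so that T(0) = Ta/α. This keeps the intended
  decline-then-growth behavior and the three-parameter count (α, r, t′). A
  literal reading without the re-anchoring constant is available via
  `get_model("Alt1", alt1_raw=True)`; it differs only in the meaning of α.
- **SiGMA_ratio.** Ratio-dependent killing f_k = kE/(1+a₁T+a₂E) makes the
  ODE nonlinear in T, so the solution is integrated numerically (LSODA,
  rtol 1e-8) per (Ta, E) condition; with a₁ = a₂ = 0 it reproduces the
  SiGMA closed form to solver tolerance, which is tested.

Parameter constraints are enforced at evaluation time (α > 0; h, g₂, n > 0;
k, d, a₁, a₂ ≥ 0; f_d ∈ [0,1]). For SiGMA the CTL-free growth rate is the
derived quantity r = g₀ + g₁.

## Fitting and model selection

Fits minimize Σ(ln T_obs − ln T_model)² jointly over all conditions with
shared parameters, using a bounded trust-region least-squares solver. The
scale parameters k, h, g₂, a₁, a₂ range over many orders of magnitude and
are optimized on log10 scale. Default bounds: α ∈ [1, 20] (recovery between
5% and 100%), growth rates ∈ [−5, 10]/day (negative values admit declining
high-inoculum conditions in the per-level growth model), scale parameters
∈ [1e−12, 1e12], n ∈ [0.05, 5], t′ ∈ [0, 4] days. Multistart: one fixed
domain-informed start (α = 3, rates ~0.5/day, k = 1e−6, h = 1e6, g₂ = 1e4)
plus Latin-hypercube draws within bounds, 50 starts by default, seeded and
deterministic; estimates pinned at a bound raise a warning flag.

AIC is computed as n ln(SSR/n) + 2(K+1). The additive constant differs
between tools (adding the full Gaussian constant n(ln 2π + 1) reproduces
the absolute values printed by some environments, available via
`compute_aic(..., constant="gaussian")`); all selection rests on AIC
differences and Akaike weights, which are constant-free. Ties in best-model
selection go to the model with fewer parameters.

Confidence intervals are linearized t intervals from the Jacobian at the
optimum (with the chain rule applied so intervals are on the natural
parameter scale); the residual variance estimator is SSR/(n−K). A
residual-resampling bootstrap is available behind a flag for singular or
strongly nonlinear cases. Nested models can be compared both by the F-test
and by a likelihood-ratio χ²; a lack-of-fit F-test decomposes SSR into
pure replicate error (about per-(Ta, E, t) group means, pooled across
datasets) and lack of fit. Residual normality is summarized by the
Shapiro–Wilk test.

## Net-growth and death-rate regression

Per (E, Ta) condition, r_net is the OLS slope of ln T on time in days over
all available time points (for two time points this equals the mean-log
difference over the interval); estimates are averaged over Ta per E. The
death rate attributable to CTLs is K(E) = r₀ − r_net(E) with r₀ the E = 0
rate; its scaling with E is summarized by unweighted OLS of ln K on ln E.
Conditions with K ≤ 0 cannot enter the log regression and are excluded with
a count. Mass-action killing predicts exponent 1; the suppression-in-growth
mechanism produces apparent sublinearity because even low CTL densities
remove the suppressible part of growth.

## Synthetic data generator

The generator evaluates a ground-truth model on a design grid and adds
ln-scale error, either resampled (with replacement, independently per
observation) from a pool of observed residuals about per-(condition, time)
group means, or Gaussian. Built-in designs replicate the five historical
datasets (70, 175, 96, 90, and 7 positive-count gels; grids trimmed
deterministically from full replication to the recorded counts) and the six
hypothetical designs of the power analysis (48 or 40 observations each).
`generate_study_replica` assembles the full 451-gel structure, appending 13
zero-count gels in high-CTL conditions of the killing datasets.

Because the measured residual pool of the original experiments is not
bundled, the default noise is a Gaussian surrogate at the observed scale
(σ = √(112/431) ≈ 0.51), clearly labeled synthetic. What the replica
reproduces: the design grids, the recovery fraction, the noise magnitude,
and therefore the fitted SSRs, the AIC separation between models, parameter
recovery, and interval widths at the real problem size. What it cannot
reproduce: features of the real data that no single generating model
produces — the early non-exponential dip of dense early sampling, mild
density dependence of the CTL-free growth rate, heavy-tailed/non-normal
residuals, and between-experiment variation. Tests passing on the replica
therefore validate the machinery and its calibration, not those historical
idiosyncrasies; analyses of the real measurements require the public data
file converted to the CSV schema.

## Power analysis

For each design, `weight_matrix` simulates n replicates from each of Sat,
Power, and SiGMA (mass action is excluded: it is a boundary case of all
three and never competitive), fits all three models to every replicate, and
tallies the best model by Akaike weight into a column-stochastic 3×3
matrix. Designs are compared by |ΔD|, the absolute difference of the
absolute determinants. Two significance procedures:

- **Null distribution:** pairs of random 3×3 matrices with columns uniform
  on the probability simplex (flat Dirichlet — chosen because it is the
  canonical "columns normalized to unity" null; other constructions change
  the null), default 1e5 draws (configurable upward), smoothed exceedance
  (count+1)/(n+1) so p ∈ (0, 1] and is monotone in the observed value.
- **Permutation:** all C(6,3) = 20 re-assignments of the six observed
  columns into two pseudo-designs; since |det| is invariant to column
  order, weighting each split by the 3!·3! within-matrix orderings (720
  arrangements, the default) and the unordered count give identical
  p-values — both modes are exposed. Exceedance is counted with ≥, and the
  identity split is included, so p ∈ (0, 1].

Replicate seeds are spawned from one master seed, making every matrix and
p-value reproducible bit-for-bit.

## Problem sizes and numerical choices

Default analysis sizes keep a laptop-scale footprint: 50 multistarts for
headline fits (a few seconds for all four models on 431 gels), 100
replicates per generator for recovery matrices, 1e5 null draws; the
bundled design-comparison script scales the D2 comparison to 30 replicates
per generator. Bisection for the control concentration E_c runs on
[0, 1e9] cell/mL with automatic bracket expansion and relative tolerance
1e−6, returning an explicit infeasible verdict when saturated killing
cannot reach the 90% requirement at any density; non-monotone net-rate
configurations raise instead of silently returning one root. The 24 h
"cells killed per day" metric is the difference between the growth-only and
full predictions at 24 h, divided by E afterwards for the per-CTL version.

## Known limitations

Deterministic mean-field dynamics only (no birth–death stochasticity within
gels); no time-varying CTL concentrations; no censored-data likelihood for
below-detection gels (exclusion/imputation only); no mixed-effects
structure across experimental repeats; and the linearized intervals assume
approximately normal ln-scale residuals, which real gel data are known to
violate — the bootstrap flag exists for exactly that case.
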