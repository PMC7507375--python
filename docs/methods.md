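# Methods

## The ICE FALCON procedure

All analyses operate on double-entered twin pairs: each individual
contributes one row as "self" (own outcome, own exposure, own covariates)
with the partner's exposure as `x_cotwin`, and the pair is the cluster.
Three identity-link Gaussian GEE models are fitted per exposure–outcome
pair,

    Model 1:  y_self ~ x_self   + covariates
    Model 2:  y_self ~ x_cotwin + covariates
    Model 3:  y_self ~ x_self + x_cotwin + covariates

with an exchangeable working correlation shared by MZ and DZ clusters (the
pooled analysis is the default; per-zygosity runs are available by
subsetting). Covariates are always the self twin's own values. The
interpretation rule, applied at a common two-sided level α = 0.05 with no
multiplicity adjustment, is a pure function of three component tests:

| β_cotwin_adj significant | δ_cotwin significant | label |
|---|---|---|
| no  | yes (and δ_self not) | consistent_with_causation |
| yes | no                   | consistent_with_familial_confounding |
| yes | yes                  | mixed |
| otherwise                  | inconclusive |

where δ_self = β_self − β_self_adj and δ_cotwin = β_cotwin − β_cotwin_adj.

## GEE estimation conventions

The solver iterates weighted normal equations with the 2×2 exchangeable
block inverse applied in closed form, vectorized over clusters; cluster
sizes 1 and 2 are supported (twin pairs; singletons arise only in generic
clustered designs). The scale uses the moment estimator with denominator
n_obs − p; the working correlation uses the within-cluster residual
cross-products with denominator (number of pairs − p), the geepack
convention. Convergence is max |Δβ| < 1e-8 within 100 iterations,
deterministic and seed-free. Wald inference uses the standard normal
reference (no small-sample t correction). The estimated α is clipped to
[−0.95, 0.95]; a zero residual variance fixes α = 0. Rank deficiency is
detected by pivoted QR and reported with the offending column names.

### What the exchangeable working correlation estimates

Models 1 and 2 are misspecified at the cluster level whenever the outcome
truly depends on the cotwin's exposure (which is the whole point of the
design): E[y₁ | x₁, x₂] ≠ β x₁. The covariate-exogeneity condition for
GEE consistency toward the marginal projection then fails, and the
exchangeable estimand is instead the fixed point

    β(α) = (c_a − α c_b) / (v_x − α r_x),   α = E[e₁e₂] / E[e²],

with (c_a, c_b) the self and cross-twin exposure–outcome covariances (in
that order for Model 1, swapped for Model 2), r_x the cross-twin exposure
covariance. Model 3 contains both exposures, whose design columns swap
under the within-cluster permutation; that symmetry makes its estimand
invariant to α and equal to the least-squares projection. These are not
numerical quirks but the probability limits of the method as practiced;
`expected_coefficients` solves the fixed point (default
`working="exchangeable"`) or returns the projections
(`working="independence"`), and the package's central oracle contract —
population coefficients equal large-n empirical fits — is tested at
n ≈ 90 000 pairs.

Two consequences worth knowing. Under a purely causal model the self
model is correctly specified, so β_self = b exactly for any α, and
β_cotwin_adj = 0 exactly; but β_cotwin itself is already near zero in
Model 2 (not b·r_x, which is the independence-working value), so the
causal signature at realistic sample sizes is "no cross-pair association
at any stage" rather than a significant association that collapses.
Under familial confounding, genetic-pathway confounders attenuate
β_cotwin upon adjustment while shared-environment confounders inflate it;
in between lies a regime where adjustment leaves the cross-pair
coefficient unmoved — the signature reported for real bone–body
composition data, see Calibration below.

### Robust variance

Because the Model-1/2 estimands depend on α, the sampling noise of the
moment α feeds into β̂, and the classical sandwich (α treated as known)
underestimates Var(β̂) — by ~40% for the change statistics in pilot runs.
All robust covariances for exchangeable fits therefore come from the
joint estimating-equation system for (β, α, φ):

    U_β = Σ_c X_c' R(α)^{-1} e_c,
    U_α = Σ_pairs (e₁e₂ − αφ),
    U_φ = Σ_c (e_c'e_c − n_c φ),

sandwiched as A^{-1} (Σ_c U_c U_c') A^{-T} with A the stacked negative
Jacobian, then restricted to the β block. For the change tests the three
models' systems are stacked jointly, so cross-model covariances come from
the score cross-products of shared clusters and
Var(δ) = Var(β̂ᵢ) + Var(β̂ⱼ) − 2 Cov(β̂ᵢ, β̂ⱼ) follows directly. After this
correction the mean model SE tracks the Monte-Carlo SD of every statistic
within a few percent, and the stacked δ SE agrees with the 2000-replicate
pair bootstrap within ~5%. When α is fixed (including independence
working), the classical cluster sandwich is used, which reproduces
cluster-robust OLS exactly. This deliberately differs from geepack's
reported per-coefficient SEs (classical sandwich); the package treats the
joint system as the correct description of its own estimator.

The cluster bootstrap resamples pairs with replacement, refits all three
models per resample, and uses the empirical SD of the deltas
(default n_boot = 1000, explicit seed; fewer than 100 resamples is an
error). A model compared to itself has identically zero change and the
test reports p = 1.

## The synthetic twin generator

Traits are built from additive-genetic (A), shared-environment (C) and
unique-environment (E) standard-normal factor scores:

    X_i = a_x A_xi + c_x C_x + e_x E_xi                (Var X = 1)
    Y_i = b X_i + a_y A_yi + c_y C_y + e_y E_yi        (residual variance 1)

A factors correlate 1 within MZ and 0.5 within DZ pairs (classic twin
assumptions; no dominance or epistasis), C factors correlate 1, E factors
are independent. Familial confounding enters through the cross-trait
factor correlations corr(A_x, A_y) = rho_a and corr(C_x, C_y) = rho_c;
causation through the path b. The implied 4×4 covariance of
(X₁, X₂, Y₁, Y₂) per zygosity is assembled by path algebra and checked
for positive semi-definiteness; the simulator draws the factor scores
directly (shared genetic pair, per-twin unique genetic pairs, shared C
pair, per-twin E, in a fixed documented order), so the implied covariance
is a genuinely independent oracle of the simulation path, verified
element-wise on 6×10⁵ pairs.

Covariates: age is drawn once per pair (mean 50.8, SD 8.1 years) and
height per individual (mean 162.7, SD 6.0 cm; within-pair correlation 0.8
MZ / 0.4 DZ), matching the motivating female cohort's descriptives.
Linear age/height slopes on both traits default to zero so the analytic
oracles stay closed-form; because the generator's covariate effects are
linear-Gaussian and every analysis adjusts for them, nonzero slopes leave
the adjusted estimands unchanged in population.

Default trait structure: exposure A/C/E variance shares 0.78/0.01/0.21,
the unique decomposition of the published body-composition within-pair
correlations r_MZ ≈ 0.79, r_DZ ≈ 0.40; outcome residual heritability
0.78, inside the 0.67–0.88 band reported for bone microarchitecture.
These are calibrations to printed summary statistics, not fitted values.

### Calibration of the confounding scenario

The preset `confounding_balanced` fixes the exposure loadings as above,
outcome A/C/E = 0.4/0.4/0.2, b = 0, and solves for the two cross-trait
correlations such that, under the exchangeable-GEE population fixed point
at the cohort's 98 MZ / 54 DZ mix, (i) the population change δ_cotwin is
exactly zero and (ii) β_cotwin_adj = 0.162, the published adjusted
cross-pair coefficient for the fat-mass → trabecular-number association.
The solution, rho_a = 0.8907 and rho_c = 0.3726, reproduces the published
row essentially in full (β_self = 0.416 vs 0.401 printed;
β_cotwin = β_cotwin_adj = 0.162; both changes null) — evidence that the
"persistent cross-pair association with no change" pattern arises
naturally from mixed genetic/shared-environment confounding under this
estimator. Because the population change is exactly zero under genuine
confounding, the empirical size of the change test in this scenario is a
clean type-I-error check (measured ≈ 0.05 at n = 500 pairs over 2000
replicates). Within this linear family a *purely* genetic confounder
cannot produce a zero change (it always attenuates β_cotwin), so the
balanced mix is the canonical confounding scenario, with
`confounding_weak/strong` (rho_a = 0.3/0.6) covering the attenuating
regime.

## The simulation harness

`run_replicates` simulates a cohort, runs the full three-model procedure,
and records estimates, SEs, p-values and the interpretation label per
replicate; summaries report mean, bias and MSE against the population
fixed-point truths, empirical and mean model SE, and rejection rates.
Replicates are fitted on the generator's own scale (the exposure is
population-standardized by construction), so the analytic estimands are
exact and bias is measured without the O(1/n) distortion per-replicate
z-scoring would add; the pipeline, by contrast, standardizes real data
before analysis, as the reported analyses did. Replicate seeds derive
from the root seed through a splitmix64-style integer mix of (seed,
index), so any replicate is reproducible in isolation and extending the
replicate count preserves the prefix. Replicate fit failures are recorded
and excluded; more than 5% is an error. Problem sizes used by the checked
experiments: 500 replicates × 6 scenarios at n = 1000 pairs (oracle
recovery), 2000 replicates at n = 500 (change-test size), 500 replicates
at the cohort's 98+54 (classification), all preserving the cohort's
0.645 MZ cluster share so pooled estimands are comparable across sizes.

## Other conventions and numerical choices

- **Standardization** uses the pooled analysis sample (both zygosities,
  both twins, n−1 denominator) after complete-pair exclusion; the order
  (exclude, then standardize) is an interpretation the data description
  leaves open.
- **Within-pair correlations** residualize the trait on covariates by OLS
  within each zygosity group (so group mean differences cannot leak in),
  then take the double-entered Pearson correlation over the 2n ordered
  tuples, removing twin-labelling dependence. The Fisher z test uses
  pair counts as effective sample sizes, since pairs are the independent
  units; published per-trait p-values based on other conventions (the
  lean-mass 0.79 vs 0.54 comparison prints 0.003 where the pair-count
  formula gives 0.019) are not chased.
- **Screening** in the pipeline: ICE FALCON runs only for exposure–outcome
  pairs significant in the within-individual stage; the default requires
  both the univariable and the mutually adjusted coefficient at α, with
  `univariable`/`adjusted`/`either` as options.
- **Missing data**: complete-pair deletion per analysis, never imputation.
- **Determinism**: every stochastic entry point takes an explicit seed;
  re-running the pipeline with the same configuration and seed reproduces
  all CSV/JSON outputs byte-identically (the log carries timestamps).

## What passing tests do and do not show

The generator produces exactly multivariate-normal, exchangeable,
complete, linearly related traits with a single exposure–outcome pair per
scenario. Real bone-microarchitecture data deviate in ways the harness
does not emulate: measurement error and device drift, non-normal and
heteroskedastic traits, nonlinear age effects, many mutually correlated
outcomes (and the attendant multiplicity), selection into complete pairs
that may not be MCAR, and zygosity misclassification. Results here
validate the estimator and its inference under the stated model, not
robustness to those features.

Known limitations: power to *positively* identify causation is weak at
cohort scale — under the exchangeable estimands a causal effect mostly
yields a null cross-pair association at every stage, which the rule can
only call inconclusive until n is large; the classification rule
inherits all the usual hazards of accept-the-null logic at fixed α; and
clusters larger than two (non-twin sibships) and non-Gaussian outcomes
are out of scope.
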