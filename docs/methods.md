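# Methods

This note records the models the package implements, the numerical choices
behind the fitters, what the synthetic register does and does not emulate,
and the design decisions taken where the problem left room.

## The hurdle construction

The outcome is a yearly count of psychiatric inpatient hospitalisations.
Because only a minority of individuals in care are hospitalised, the model
is a hurdle: a binary part for whether the count is positive, and a
conditional magnitude part for the positive counts. The two parts are
estimated as independent equations given covariates; their joint sampling
uncertainty is recovered by bootstrapping the whole two-stage procedure.

The binary part is a probit with a Gaussian random intercept for the
individual's municipality of residence. The package parameterises it for
P(hospitalised) by default because that is the sign convention most
reports use; the P(y = 0) direction is a flag (`direction="zero"`) and
differs only by the sign of the fixed effects — variance and likelihood
are identical.

The magnitude part models the natural-log count, standardised to mean 0 and
SD 1. The log base is irrelevant after standardisation; natural logs are
used and the transform parameters are stored for inversion.
Standardisation statistics are computed over the hospitalised subset only,
since that is the only data the magnitude part sees; this is a
documented choice, not a mathematical necessity.

## The multiple-membership random structure

Each individual carries weights w over attended providers — the share of
the individual's total care volume at each provider — and derived weights
ω over provider municipalities, obtained by summing w over co-located
providers. ω is *always* derived from w; there is no independent ω
measurement. "Care volume" may be visits, episodes or days; weights are
invariant to the unit within an individual, and the choice is the user's.
Duplicate (individual, provider) visit rows are summed before weighting so
weights are per unique provider. All provider types (GP, community-based
care, hospital department) share a single variance component: they are
treated as one population of care providers, not separate classifications.

The marginal covariance of the magnitude part is

V = σ²_u2 Z₂Z₂' + σ²_u3 WW' + σ²_v4 ΩΩ' + σ²_e I,

low-rank plus diagonal. The likelihood uses the Woodbury identity on the
q×q capacity matrix (q = municipalities + providers + provider
municipalities): after one sparse precomputation of the cross-products
U'U, U'X, U'z, each likelihood evaluation costs O(q³) independent of n.
Fixed effects are profiled out by GLS at every variance evaluation.

### Identifiability

Every membership block's rows sum to one, so stacking b blocks always
loses b−1 column ranks (a constant can be shifted between levels without
changing the fit). This is inherent to multiple-membership designs and
leaves the variance components identified. Deficiency *beyond* that —
typically a municipality whose single attended provider serves only
single-membership patients, making its Ω column identical to a W column —
leaves σ²_u3 and σ²_v4 only jointly identified locally; the fitter
detects this by an eigenvalue count on U'U and warns rather than failing,
because the components usually remain globally identified through the
rest of the design. On realistic sparse registers this warning is common
and expected.

## Estimation choices

* **Maximum likelihood, not REML**, is the default: structures and
  fixed-effect specifications are compared by likelihood ratios and
  AIC/BIC, which require ML. REML is available as an option.
* Variances are optimised on the log scale (L-BFGS-B, bounds
  log σ² ∈ [−30, 5]) so nonnegativity is automatic. Estimates below 1e-8
  are reported as boundary solutions, never silently zeroed.
* Three starting points by default (equal split of Var(z); mostly-residual;
  a perturbation) guard against local optima. Convergence requires the
  optimiser's success flag or a gradient max-norm below 1e-2; ftol 1e-13.
* Numerically non-positive-definite corners (huge cluster variances with
  vanishing residual) are handled by returning a penalty value, steering
  the optimiser back into the interior.
* The probit integrates its random intercept with adaptive Gauss–Hermite
  quadrature: per-cluster posterior modes by damped Newton, curvature
  scaling, 15 nodes by default (on desk-scale problems 15 vs 41 nodes
  changes the log-likelihood by < 1e-6). A plain prior-centred rule is
  available as a cross-check. Starting values come from a single-level
  probit; complete separation is detected post-fit from diverging scaled
  coefficients.

## Variance partitioning and care profiles

VPCs divide each term of the profile-specific total variance by the total.
A care profile is a hypothetical (w, ω) pair. Two conventions matter for
reproducing published scenario grids:

* profiles printed as "0.33, 0.33, 0.33" are interpreted as exact thirds;
* the dominant-provider profile "0.75, 0.12, 0.12" is used *verbatim*
  (its digits sum to 0.99) via `literal=True`, which relaxes the
  sum-to-one constraint to (0.95, 1] and flags the profile in grid output.

Only this combination reproduces the published scenario percentages, and
both behaviours are explicit options. Explained total variance is
1 − Var_full/Var_vc at a fixed profile and may legitimately be negative
(components can rise after adjustment, reported as an increase).

When transcribing the emulated study's published component table, the
package uses the level assignment that is consistent with *all* of its
worked scenario numbers (individual 0.720, provider 0.075, provider
municipality 0.241, residence municipality 0.032 for the VC model; 0.699 /
0.213 / 0.076 / 0.062 for the adjusted model). The published table's row
labels appear to be permuted relative to its own worked text; eight
independent printed percentages agree with the assignment used here and
none agree with the literal labels.

## The synthetic register

The generator emulates the structure of a national care register: 98
municipalities; providers of three types placed in municipalities with
counts scaled from the full register (2100 GPs, 145 community providers,
42 hospital departments at 64,694 individuals, with small-scale minimums);
individuals with a residence municipality, demographic covariates with
register-like marginal prevalences, and one main diagnosis group.

Attendance starts with a local GP (gatekeeping); each further provider is
drawn from the residence municipality with probability 0.4 and from
anywhere otherwise. The 0.6 out-of-municipality default is a tuning choice
that makes the distinct-HCPM distribution resemble the register's (~41%
of individuals in a single provider municipality); it is not a measured
quantity. The number of distinct providers follows the register's
published count distribution exponentially tilted to a configurable mean
(default 2.23) — the published distribution and published mean disagree
slightly, and the tilt keeps the shape while honouring the mean. Care
weights are Dirichlet(1) over attended providers, emitted as integer visit
counts (≥ 1 per provider) so the membership builder reconstructs the
weights from a realistic visit log.

Outcomes follow the two-part model exactly on the latent scale: the probit
intercept is calibrated numerically so the marginal hospitalisation
probability hits the configured 0.30 target given the drawn covariates and
municipality effects, and the Gaussian part draws z from the four
configured components (defaults 0.032 / 0.075 / 0.241 / 0.720, probit
municipality variance 0.022). Counts are round(exp(1.103 + 1.10·z))
clamped to ≥ 1, calibrated so hospitalised counts have roughly mean 5.8 /
SD 9.4. Randomness is split per component from one seed, so the same seed
reproduces tables byte-for-byte and covariate draws do not shift when the
outcome model changes.

**What the generator does not emulate:** covariates are drawn
independently across and within levels (no cross-level correlation
structure, though the prevalences match), there are no diagnosis-specific
care pathways or calendar time, and the two hurdle parts share no random
effects. Passing recovery tests therefore demonstrate that the estimators
recover the model's parameters under the model's own assumptions at
register-like sparsity — not that the model is correctly specified for any
real register.

**Count discretisation.** The integer round-trip (z → count → standardised
log count) is not invertible: rounding adds noise and the
re-standardisation rescales slightly, which inflates the fitted individual
residual variance by a few percent while leaving the variance *shares*
nearly unchanged. The parameter-recovery study therefore evaluates the
fitters on the model-scale outcome (the generator's latent z), and the
end-to-end examples show the small residual inflation on the count scale.

## Preprocessing rules

Exclusions: individuals with more than 13 distinct providers or more than
7 distinct provider municipalities are dropped (strict inequalities), with
per-rule counts reported. An optional extreme-case rule removes large
outcomes; the phrase "more than 10 hospitalisations on the standardised
scale" is ambiguous between z-units and raw counts, so both
interpretations are implemented (`extreme_scale="z"` with |z| > threshold,
default threshold 10, or `"count"`). Subgroup filters are pure row
selections over precomputed diagnosis-group indicator columns; no ICD
parsing is performed.

## Model battery and comparison

Alternative random structures: the full four-component model; without the
provider-municipality level; a cross-classified comparator that nests each
individual in a single "main" provider — operationalised as the
largest-weight provider with ties broken by smallest provider id, since
visit order is not modelled; providers only; and a single-level regression
(same code path with zero random blocks, equal to OLS). Nested pairs get
likelihood-ratio tests; a single variance component tested on its boundary
uses the 50:50 χ²₀/χ²₁ mixture, larger df use the plain (conservative)
χ². The cross-classified model is not nested in the full model and is
compared by AIC/BIC only. Fits refuse comparison unless their data
fingerprints match.

## Bootstrap

Nonparametric, resampling individuals with replacement (each draw becomes
a distinct pseudo-individual carrying its membership rows and outcome) and
refitting both stages; the SD of replicate estimates is the SE, with
percentile intervals. A municipality-level cluster bootstrap is available;
the resampling unit is a user choice. B defaults to 100, with 1000 the
recommended setting for stable tails; replicate failures are skipped and
counted, and more than 20% failures aborts. No BCa or parametric bootstrap.

## Test problem sizes

The replicated studies in the test suite use sizes chosen to make the
Monte-Carlo bands informative at interactive runtimes: parameter recovery
runs 24 replicates at 5,000 individuals with 3·SE bands (3-sigma keeps the
joint false-alarm rate over five components near 1%), and the structure
battery runs 9 replicates at 4,000 individuals for the majority-AIC check.
Likelihood correctness is established separately against dense oracles on
instances with n ≤ 50, where brute force is exact.

## Known limitations

* No count-scale likelihood (Poisson/negative binomial) and no Bayesian
  estimation; the magnitude part is Gaussian on the standardised log scale.
* The probit part has no multiple-membership structure (by design: only a
  residence-municipality intercept) and no random slopes.
* Agreement with other mixed-model software can be checked only for
  structures they can express; standard packages do not fit weighted
  multiple-membership random effects directly.
* Variance-share scenario grids describe the fitted model's implications;
  they are exact functions of the components, not new estimates, and carry
  the components' sampling uncertainty.
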