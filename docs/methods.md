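# Methods

This note documents the statistical models implemented in `provmeta`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Effect sizes

Each record reports one test of provisioning against an infection outcome
(binary status, prevalence, intensity or seroprevalence).  Reported
statistics are converted to a correlation magnitude:

| reported | conversion | notes |
|---|---|---|
| r | used as-is | |
| χ² (1 df) | r = √(χ²/n) | capped at 1 with a warning if χ² > n |
| F (1, df_e) | r = √(F/(F + df_e)) | valid only for numerator df = 1 |
| odds ratio | r = (OR^¾ − 1)/(OR^¾ + 1) | Digby's approximation; antisymmetric in OR ↔ 1/OR |
| Cohen's d | r = d/√(d² + a), a = (n₁+n₂)²/(n₁n₂) | a = 4 assumed when group sizes are unreported (logged) |
| 2×2 table | Pearson χ² without continuity correction, then χ²→r | identical to the phi coefficient by construction |

The magnitude is signed by the reported direction (decrease → negative)
and transformed to Fisher's *Zr* = atanh(r), sampling variance
v = 1/(n − 3).  Records with n < 4 have no defined variance; they are
read, flagged, and excluded from modelling.  |r| ≥ 1 is clamped to
0.999999 before atanh (a perfect association has infinite *Zr*).
Back-transformed effects are classed trivial (|r| < .1), small-medium
[.1, .3), medium-large [.3, .5], large-very large (> .5); the boundary
handling (.3 and .5 closing the medium-large interval) is our convention
since interval notation leaves it open.

Each annotated record carries a provenance tag naming the formula used,
so choices such as the unadjusted d (no small-sample bias correction —
none of the named conversions applies one) remain auditable.

## Tree processing and the species correlation matrix

Trees are read from Newick, pruned to the study species (names
canonicalized by replacing spaces with underscores; a user-supplied alias
map collapses synonyms at read time), polytomies resolved randomly under
a seed (inserted edges get length 0), and branch lengths assigned by
Grafen's method: node height above the tips proportional to
(descendant tips − 1)^ρ with ρ = 1 (the conventional default), scaled so
the root-to-tip depth is exactly 1.  The species correlation matrix C has
entry (i, j) equal to the depth (measured from the root, 0, towards the
tips, 1) of the most recent common ancestor — the fraction of evolutionary
history shared under Brownian motion.  "Depth" always means
root-to-node distance in this package.  Pagel's λ rescales off-diagonal
entries; λ ∈ [0, 1] keeps C positive semidefinite.

Because the polytomy-resolution order of the original tooling is not
reproducible, resolution is seeded and a sensitivity rerun (different
seed) is the recommended check; zero-length inserted edges mean the
resolution only matters through Grafen's subsequent height assignment.

## Pagel's λ on species means

Within a parasite group, species means are weighted by sample size n
(reading "weighted by sample size" literally; inverse-variance weighting
1/(n−3) is available via `weighting="invvar"` — the two differ only by
the −3 shift and give nearly identical means).  λ is estimated by ML for
y ~ N(μ1, σ²C(λ)): at fixed λ, μ and σ² have closed-form GLS/ML
solutions, so the profile likelihood is a 1-D function of λ, maximized by
a 101-point grid scan plus bounded refinement (guaranteeing the optimum
is no worse than the grid).  Estimation requires ≥ 4 species and
non-constant means (σ² = 0 is degenerate).  Likelihood-ratio statistics
against λ = 0 and λ = 1 are floored at 0 and referred to χ²₁; at a
boundary null this is conservative (the 50:50 mixture would halve the
p-value), which we accept and document rather than adjust.

## The multilevel meta-analytic mixed model

Record-level effect sizes follow

y ~ N(Xβ, V),  V = σ²_obs·I + σ²_study·Z_s Z_sᵀ + σ²_sp·Z_p C Z_pᵀ + diag(v)

with known sampling variances v.  σ²_obs is the residual-heterogeneity
(observation-level) component; σ²_study absorbs clustering of records
within studies; the species component is phylogenetically structured
through C.  Exactly one species term is fitted by default (an optional
non-phylogenetic species component is available behind
`extra_species_iid=True` for users who want the four-component
parameterization).

Estimation maximizes the ML or REML log-likelihood over log-scale
variance parameters with L-BFGS-B, multi-started at
{10⁻⁴, 10⁻², 10⁻¹} × var(y); β is the GLS solution at the optimum and
cov(β) = (XᵀV⁻¹X)⁻¹.  Components below 10⁻¹² (the effective lower bound)
are snapped to 0.  REML is used wherever variance components or H² are
reported; ML only to feed information criteria.  Our REML log-likelihood
omits the constant +½log|XᵀX| that metafor adds; it cancels in every
comparison made here.  No Knapp-Hartung small-sample adjustment is
applied — coefficients are reported with plain z tests.

Phylogenetic heritability is H² = σ²_sp/(σ²_obs + σ²_study + σ²_sp); the
known sampling variances are excluded from the denominator (the
heterogeneity-based definition), and 0/0 is defined as 0.  The omnibus
Q_M statistic is the Wald chi-square βᵀcov(β)⁻¹β over all non-intercept
coefficients.

Design matrices use treatment contrasts with reference levels: dietary
breadth *low* (classes low 1–2, medium 3–4, high 5–6 food categories;
counts 7–8 also map to high), trophic level *herbivore*, provisioning
*unintentional*, *non-migratory*.  Home range enters quarter-root
transformed; pace of life as the phylogenetic PC1 score.  A degenerate
case worth knowing: with one record per species and study and C = I, the
three components are jointly unidentifiable — the fit warns and only
their sum (the classical τ²) is meaningful.

## Phylogenetic PCA of pace of life

Mass, offspring/yr, life span and age at maturity are log-transformed,
body size square-rooted.  With C fixed at its Brownian form (λ = 1 — λ is
not re-estimated inside the PCA), ancestral means are
a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X, the evolutionary covariance is
R = (X−1aᵀ)ᵀC⁻¹(X−1aᵀ)/(n−1), and scores are the centred data projected
on R's eigenvectors.  Covariance mode (untransformed scales) is the
default, matching the common tooling default; a correlation-mode switch
exists.  Loadings are reported as ordinary trait-score correlations.
PC1's sign is fixed so log body mass loads negatively: large, positive
PC1 marks fast-lived (r-selected) species.  With a star tree (C = I) the
procedure reduces exactly to ordinary covariance PCA, which is the oracle
used in tests.  Only PC1 enters downstream models; PC2 is computed and
reported for completeness.

## Candidate models, AICc and pseudo-R²

Candidate sets contain all additive combinations of allowed main effects
with at most 3 distinct covariates, excluding declared collinear pairs,
plus any allowed two-way interactions whose main effects are present (an
interaction respects marginality and consumes no extra covariate slot
beyond its two mains), always including the intercept-only model.
Enumeration is deterministic and deduplicated.  The shipped default
exclusion (dietary breadth with trophic level, both diet-derived) is a
best-effort transcription of constraints not printed in full anywhere and
should be overridden via the config for real analyses.

ML fits feed AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1).  The default parameter
count k includes the 3 variance components alongside the fixed effects
(the information-theoretic convention for mixed models); a display-style
k counting fixed effects only is carried in the same table (`k_fixed`)
and a `k_mode="fixed"` switch makes it the ranking count.  Akaike weights
are exp(−Δᵢ/2)/Σexp(−Δⱼ/2); models within ΔAICc ≤ 2 are flagged
competitive.  A predictor's importance is the summed weight of models
containing it; a main effect counts when it appears only inside an
interaction (the model does contain that predictor), an interaction
counts for itself only.

REML refits of the same formulas provide residual H² and three pseudo-R²
against the intercept-only REML fit: Rv² (proportional reduction in the
summed variance components), Rr² (in σ²_obs alone), and Rp² (adjusted R²,
1 − (1−R²)(n−1)/(n−2), of a 1/v-weighted regression of observed on
predicted *Zr*).  All three are truncated below at 0, so a model whose
components exceed the null's prints 0 rather than a negative value.
Candidates whose design is not of full rank within a stratum (an
unobserved factor level) or whose n cannot support the parameter count
are skipped with a logged reason.

## Synthetic data

The generator emulates: a pure-birth tree (the stopping-time tie between
the last two tips is broken by one extra exponential waiting time, so C
is never singular) scaled to unit depth; Brownian traits driven by a
shared latent pace axis (reproducing the loading pattern: mass, size,
life span and maturity negative, fecundity positive) with log-normal home
ranges; records nested in studies within species; true
zr = xᵀβ + u_species + u_study + u_obs with u_species ~ MVN(0, σ²_sp
C(λ)); observed zr adds N(0, 1/(n−3)) sampling noise; and reported
statistics reconstructed per record in a random format that round-trips
through the conversion routines to machine precision (contingency tables
use real-valued balanced-margin counts, since integer counts cannot hit
an arbitrary zr exactly).  Defaults: 40 species, ~200 records in three
parasite groups at roughly the 42/40/18% split of the record counts,
β = (0, 0.15) on quarter-root home range, components (0.02, 0.02, 0.04),
λ = 1 — i.e. moderate heterogeneity with H² = 0.5.  Sample sizes per
record are uniform on 10–200.

Not emulated: raw infection data (noise is generated directly on the
Fisher-Z scale, consistent with the analysis model, so the generator
cannot probe small-sample failure of the normal approximation),
publication bias, missing statistics, or correlated sampling of traits
and effect sizes.  Passing recovery tests therefore demonstrates that the
estimators invert the assumed data-generating process at realistic sizes,
not that the model is robust to violations of it.

## Recovery study and problem sizes

`provmeta.recovery` fixes the validation design: 60 species × 3 studies ×
3 records (n = 540) with slope 0.3 on quarter-root home range and
components (0.02, 0.02, 0.04); and 100-tip trees for λ under Brownian
versus independent truth.  Medians over 50 seeded replicates are compared
to truth (slope within ±0.05, H² within ±0.1, λ medians ≥ 0.8 / ≤ 0.2).
These sizes keep a full validation run within a few minutes on one CPU
while leaving Monte-Carlo error well inside the stated bands.

## Known limitations

- The λ likelihood can be multimodal; the grid-plus-refine search makes
  the estimate reproducible but a pathological likelihood with basins
  narrower than 0.01 would need a finer grid.
- Dense V (n × n) limits fits to a few thousand records; the compiled
  datasets this package targets are far smaller.
- Boundary LRTs for λ and REML-based H² have no small-sample corrections.
- The CLI `select`/`fit` subcommands rerun shared upstream stages rather
  than caching them; use `run` for the full pipeline.
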