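# Methods

## The question and the three tiers

Reciprocal transplant experiments test for local adaptation by growing
ecotypes (seed origins named after their source region) in common gardens
placed in those same regions. The same dataset can answer three different
questions, and `localadapt` implements all three as separate tiers:

1. **Local vs. foreign (per cell).** Within one garden × species cell, a
   one-way linear model compares ecotype mean biomasses, followed by Tukey
   all-pairwise comparisons. A cell supports *"local is best"* only when
   the local ecotype significantly outperforms **every** nonlocal ecotype;
   it supports *"nonlocal is best"* when **any** nonlocal ecotype
   significantly outperforms the local one. This asymmetry (win all pairs
   to accept, lose one to reject) makes tier 1 deliberately conservative
   for local adaptation and liberal for maladaptation — the package treats
   that asymmetry as a property to measure, not to fix.
2. **Sympatric vs. allopatric, per species.** A linear mixed model of raw
   biomass with garden identity and the sympatry indicator
   (ecotype == garden) as fixed effects and ecotype identity as a random
   intercept. The random ecotype term corrects for the *variance* of
   intrinsic ecotype quality without absorbing its mean — the relevant
   correction when the practical question is which seed material performs
   best, rather than which evolutionary process produced the pattern.
3. **Sympatric vs. allopatric, across species.** Biomass is standardized
   within species (mean 0, SD 1, sample SD with n−1; results at these
   sample sizes are insensitive to the n vs. n−1 choice), then one model is
   fit with garden + sympatry fixed effects and a random intercept per
   ecotype-within-species composite group. No separate species intercept is
   included: standardization removes species means, and the composite
   random term absorbs what remains.

Aboveground dry biomass (grams) is the fitness proxy throughout; any other
nonnegative fitness measure can be substituted in the same CSV schema.

## Mixed-model engine

All mixed models are Gaussian random-intercept LMMs,
`y = Xβ + Zu + ε` with `u ~ N(0, σ²_g I)`, `ε ~ N(0, σ²_e I)`. With a
single grouping factor the (restricted) likelihood profiles analytically
down to one dimension: for each candidate ratio `λ = σ²_g/σ²_e`, β is the
GLS solution and σ²_e the scaled residual quadratic form, both computed per
group via the rank-one Woodbury identity (no n×n matrices). The profiled
criterion is maximized by a 41-point coarse grid on log λ ∈ [−25, 25]
followed by bounded Brent refinement (xatol 1e-10), with the boundary
λ = 0 always evaluated, so `σ²_g ≥ 0` by construction and boundary fits are
exact rather than convergence failures.

REML is the default (standard for variance components); ML is used inside
the resampling procedure, where comparability of fits across subsamples
matters more than unbiasedness. In balanced full-reciprocal designs the
GLS fixed effects are invariant to λ, so ML and REML β coincide there (a
tested property). Fixed factors are dummy-coded against the
first-observed level; `design_info` records levels and references so
prediction grids are encoded identically to the fit.

`loglik_at` exposes the exact objective at arbitrary admissible
parameters; the test suite uses it to verify that the profiled search
attains the maximum found by a generic 2-parameter optimizer on random
problems (tolerance 1e-5), and cross-checks whole fits against
statsmodels `MixedLM` (REML).

## Tukey all-pairwise comparisons

Pairwise ecotype contrasts use the Tukey–Kramer studentized-range
statistic `q = |m_a − m_b| / sqrt(s²/2 (1/n_a + 1/n_b))` referred to the
studentized-range distribution with k groups and the cell's residual df
(the Kramer form handles cells thinned by mortality; with equal n it is
classical Tukey HSD). Tail probabilities are evaluated by a fixed
Gauss–Legendre quadrature of the classical double integral (80 nodes in
the max-order statistic, 50 in the chi scale factor), vectorized over a
batch of q values: agreement with `scipy.stats.studentized_range` is
~2e-12 at ~30× the speed, which is what makes the simulation studies
below affordable. For k = 2 the exact identity `Q = √2·|t_df|` is used,
so two-group Tukey p-values equal pooled two-sided t-test p-values to
machine precision. Degenerate zero-variance cells report p = 0 for
unequal means and p = 1 for equal ones.

## Posterior inference

Uncertainty statements for the sympatry effect come from posterior
simulation under a noninformative prior, seeded by the fitted model:
`σ² ~ σ̂²·df/χ²_df`, then `β|σ² ~ N(β̂, (σ²/σ̂²)·Côv(β̂))`. Variance
components are **not** resampled — they are held at their point estimates,
matching the established sim-from-fit convention; posterior spreads are
therefore slightly anticonservative when σ²_g is poorly determined (few
groups). Marginally, `(β − β̂)/SE` is exactly t with `n − p` df, which the
suite verifies by Kolmogorov distance at 10⁵ draws.

Credible intervals are equal-tailed empirical quantiles with linear
interpolation between order statistics (type-7, numpy's default), fixed so
intervals are bit-reproducible from the seed. Posterior probabilities
count exact zeros half toward each direction, so P(>0) + P(<0) = 1. The
evidence verdict is LOCAL_ADAPTATION iff P(sympatric > allopatric) > 0.95,
MALADAPTATION iff < 0.05, otherwise INCONCLUSIVE.

### Effect sizes

Tier 2 reports `100 · β_symp / B̂` percent, where the allopatric baseline
`B̂` is the model-fitted mean over all allopatric garden × ecotype
combinations — a pure function of the coefficients, propagated draw by
draw (so the percent CI reflects baseline uncertainty too), and invariant
to biomass units. Tier 3 reports β_symp directly in within-species SD
units. Conditional R² is the Nakagawa–Schielzeth plug-in
`(var_f + σ²_g)/(var_f + σ²_g + σ²_e)` with `var_f` the sample variance of
fixed-effect predictions over the fitted rows.

## Resampling power equalization

A cross-species model mechanically has more power than per-species models
fit to subsets of the same data. To check that the tier-3 conclusion is
not a pure sample-size artifact, the standardized dataset is subsampled
without replacement to the size of the largest single-species dataset
(192 measured plants in the benchmark design; configurable, since "the
size of an individual species model" is ambiguous when species sizes
differ, 192 vs 108 here), stratified by species proportionally to their
counts so no species vanishes, and the model is refit by ML. The report
is the exact fraction of permutations with a positive sympatry
coefficient. Note that subsample coefficients are strongly correlated
with the full-data estimate (measured r ≈ 0.98 at 192 of 984 rows), so
for a *single* dataset the proportion is informative about that dataset's
signal, not a binomial(0.5) draw; the null-symmetry test accordingly
averages the proportion over independent null datasets.

## Synthetic data generator

The generator exists so every stage is exercisable with known ground
truth. Per species, log biomass is
`log(mean_s) + G[s,garden] + Q[s,ecotype] + δ·1[ecotype==garden] + ε`,
biomass = exp(·): multiplicative (log-normal) by design so biomass is
strictly positive and δ maps to the percent effect scale
(`100·(e^δ − 1) %`). Garden effects G and ecotype quality effects Q are
drawn once per species (independent across species, the minimal assumption
given per-species tier-2 models) and held fixed across replicates;
residual ε is per plant. Effects, residuals and mortality use three
independent child streams of the seed, with effects drawn in fixed
(species, region) order so changing replicates or mortality never changes
the realized G and Q.

The benchmark configuration reproduces the study design: 4 regions, 6
species (4 with ecotypes from all 4 regions, 2 restricted to 3), 12
replicates — 22 species × garden cells and 984 plants. Defaults where the
design gives no values are package choices: `garden_effect_sd = 0.3`,
`ecotype_quality_sd = 0.2`, `species_sd_log = 0.4` (log scale), species
geometric means 0.6–8 g spanning typical first-season biomass of temperate
grassland perennials, mortality 0.

What the generator does **not** emulate: genotype-by-environment structure
beyond the sympatry indicator, spatial/temporal autocorrelation within
gardens, correlated effects across species, survival/fecundity fitness
components, and block structure. Passing tests therefore demonstrate the
statistical machinery's behavior under a clean factorial world, not the
field messiness of real transplant data.

### The tier-3 estimand

For coverage checks the "true" standardized effect must be defined. The
package uses the infinite-replicate limit of the tier-3 sympatry
coefficient given the realized (G, Q): expected cell biomasses follow from
log-normal moments, are population-standardized within species, and are
projected onto garden + sympatry + ecotype-within-species dummies (the
fixed-effect limit of the random-intercept fit as group sizes grow).
Because the additive analysis model projects a multiplicative mean
surface, this estimand is not exactly 0 at δ = 0 for a fixed draw
(per-draw SD ≈ 0.026 at the default variance components, mean 0 across
draws) — an honest property of applying the standard linear analysis to
multiplicative biology, and the reason coverage is assessed against the
per-draw estimand rather than against δ itself.

## Numerical and design choices

- α = 0.05 for tier 1 (configurable); verdict thresholds 0.95/0.05 fixed.
- Missing biomass (dead plants): retained in the dataset, excluded from
  every model fit (complete case per model); nonpositive values read from
  CSV are flagged missing rather than rejected.
- Default draw/permutation counts are 10,000 each; simulation studies in
  the test suite use 2,000 draws and 150–200 datasets, sized so
  Monte-Carlo error stays inside each test's stated tolerance.
- All pipeline randomness derives from one seed via `SeedSequence.spawn`
  with a fixed stage order (simulate, tier-2 per species, tier-3,
  resample), so outputs are byte-reproducible and adding stages never
  perturbs earlier ones.
- Region identifiers are opaque case-sensitive strings; replicate ids are
  labels only (no block structure is modeled).

## Known limitations

- Single random-intercept grouping only: no crossed random effects, random
  slopes, or non-Gaussian responses (biomass is analyzed on the raw scale,
  as in the tiers it implements, even though the generator is log-normal).
- Posterior simulation ignores variance-component uncertainty (above).
- Tier-1 p-values assume homoscedastic groups within a cell.
- The compact-letter display sometimes drawn on bar charts is not
  implemented; classification works directly from the pairwise table.
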