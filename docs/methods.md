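# Methods

## Model and estimation

Each trait is analysed at the plot level with the linear mixed model
`y = Xt + Z₁g + Z₁l + Z₂c + e`.  Fixed effects are the crossed
year×location factor (year×location×trial for test weight and ergosterol,
which are measured per trial).  Random terms: genomic breeding values
`g ~ N(0, G σ²g)`, iid residual line effects `l ~ N(0, I σ²l)` (omitted
for protein yield, whose model showed no separable line term),
line×(year×location) interactions `c ~ N(0, I σ²c)`, and iid plot
residuals.  All covariances are variance-component multiples of fixed
kernels, so REML reduces to a four- (or three-) parameter problem.

**Exact collapse to cell means.**  Every random term except the residual is
constant within a (line, fixed-level, environment) cell, so the restricted
likelihood factorizes exactly into (i) the cell means, whose residual
variance is σ²e/r for a cell with r plots, and (ii) the within-cell
contrasts, which are iid N(0, σ²e) and enter only through their pooled sum
of squares and degrees of freedom.  REML therefore operates on a dense
matrix of order *n·nₑ* (≈ 620 rows for 309 lines) instead of the plot count,
with no approximation; the unit test `test_loglik_matches_dense_plot_level_oracle`
checks the collapsed criterion against a direct plot-level evaluation to
1e−6 (observed agreement ~1e−14).

**AI-REML.**  Updates are Newton steps using the average-information matrix,
projected onto the parameter space with a floor of 1e−8 × phenotypic
variance per component.  Components pinned at the floor by a negative score
are frozen out of the AI system (active set), which keeps it well
conditioned at boundary solutions.  If a projected AI step (with step
halving) would decrease the restricted likelihood, an EM-REML step — which
cannot decrease it — is taken instead; a component still being driven down
while small is snapped to the floor outright when that costs no likelihood,
avoiding the geometric crawl EM otherwise produces at the boundary.
Convergence requires |Δ log L| < 1e−8 and relative component changes
< 1e−6 (floor-pinned components excluded); non-convergence within 200
iterations raises an error carrying the full trajectory.  The
average-information matrix at the optimum is reported as the curvature
matrix; its inverse supplies the delta-method standard error of h².

**Mixed-model equations.**  GEBVs, line, G×E and fixed effects solve
Henderson's equations on the collapsed cells, with G⁻¹ obtained by Cholesky
(adding ε·I with ε = 1e−6 × mean diagonal, escalating tenfold, when G is
numerically singular — logged).  Breeding values are carried for every line
in G, so lines whose phenotypes are masked from training still receive
GEBVs through the off-diagonals.  When a variance component sits at its
floor the prior block is extremely stiff; solves then fall back from
Cholesky to a symmetric-indefinite factorization.

**Fast cross-validation.**  Removing the phenotypes of a held-out line set
changes the coefficient matrix by a low-rank term, so folds are solved by a
Woodbury downdate of the cached full-system inverse.  This is exact and is
tested against direct re-assembly per fold; it reduces leave-one-out from
*n* dense solves to one inverse plus *n* rank-k corrections.  If removing a
fold would empty a fixed-effect level (leave-set-out does this), the code
falls back to a direct solve with the emptied levels dropped and flagged.

## Heritability scale

With fully inbred lines the VanRaden G has diagonal ≈ 2, so σ²g is variance
*per unit of relationship*; the line-mean heritability formula uses σ²g
directly, matching how the reference variance-component table is printed.
Two published h² values (protein yield 0.26, ergosterol 0.61) do not
reconcile with their printed components through this formula (they give
0.205 and 0.604, presumably component rounding); the tests assert our
computed values and record the discrepancy rather than reproducing the
printed ones.

## Cross-validation conventions

Variance components are estimated once from the full data and held fixed
across folds, matching the reduction experiments' stated protocol and
applied uniformly to all designs.  Corrected phenotypes (per-line means of
y − Xt̂) always use the full-data fixed-effect estimates, so accuracies are
comparable across designs.  LFO defines one family per parent (lines
sharing that parent), keeps families of ≥ 4 lines, and a line held out
under both of its parents contributes the mean of its held-out GEBVs to the
pooled correlation.  Training-set reduction steps shrink by 10% *of the
original size* per step (a compounding mode is available by flag); marker
thinning samples only mapped markers with per-chromosome quotas by largest
remainder and a ≥ 1 cM spacing that is halved whenever a quota is otherwise
infeasible.

## Synthetic breeding program

The generator emulates a two-set spring-barley program: 104 inbred founders
(16 shared between sets), 50 biparental crosses per set, F6 lines by five
generations of single-seed selfing with Poisson crossovers at 1 per 100 cM
(Haldane, no interference), ~3,500 biallelic markers spread near-equally
over 7 chromosomes of 150 cM, founder second-allele frequencies uniform on
[0.1, 0.9], and 1% missing calls injected at random.  Phenotypes follow the
analysis model exactly: fixed year×location means (defaults on the
reference traits' scales), QTL-derived breeding values, iid line, G×E and
plot effects at per-trait variance components defaulting to the reference
table, in 2 locations × 3 replicates of the set's harvest year, with two
ungenotyped check lines in every trial replicate.  Mating-design knobs
(crosses per set, family-size law) are configuration with defaults, since
no source specifies them.

Breeding values are linear in a sampled QTL subset of the markers, rescaled
so that their empirical variance equals σ²g × mean(diag G) — i.e. the
configured σ²g *is* the GBLUP parameter a correctly specified REML should
return.  With a sparse QTL architecture the realized relationship at QTL
deviates from the all-marker G, and REML books that deviation into σ²l;
the parameter-recovery test therefore generates a fully polygenic trait
(every marker a QTL), which is the appropriate design for validating the
estimator against its own model class.  Seed-size fraction weights are
derived as monotone transforms of the latent seed-size trait (fractions
summing to 99 g of a 100 g sample), so the rank-based inverse-normal
pipeline can be exercised end to end; the raw-fraction dialect does not
attempt to emulate instrument noise.

What the generator does **not** emulate: linkage-disequilibrium decay
calibrated to real barley, selection during line development, dominance or
epistasis, genotyping error beyond missingness, or spatial field trends.
Passing tests therefore demonstrate correctness of the estimators and
designs under the assumed model, not robustness to those real-data
features.

## Derived traits

Standardized seed weight applies a rank-based inverse-normal transform
(quantile (r − 0.5)/n, average ranks for ties; Blom's offset by flag) to
the f2.5 and f2.2 fraction weights, pooled across all plots (per-environment
ranking by flag), and averages the two with a sign flip so larger seeds
score higher.  The sign and pooling choices only flip GEBV signs or shift
fixed effects; |accuracy| is invariant, which tests assert.  Protein yield
is (protein%/100) × grain yield.  The < 2.2 mm dust fraction is never used.

## Marker editing

Filter order is fixed and logged: drop monomorphic markers, drop lines with
> 2% missing calls, then recompute frequencies and keep markers with MAF
≥ 5% (inclusive).  An alternative reading of the missingness rule (drop
markers missing in > 2% of lines) is available as `marker_missing_max`.
Residual missing calls are imputed by the marker mean 2p̂−1, which leaves
marker means — and hence the centered Z and G — unchanged.

## Problem sizes in the test suite

The suite validates at reduced but structurally faithful sizes chosen for
quick iteration: oracle equivalence on ≤ 15-line instances, parameter
recovery at 600 lines × 1,200 markers, design ordering on ten 300-line
populations with unrelated breeding sets, and reduction experiments with
6–8 steps × 5–6 replicates.  All stochastic steps take explicit integer
seeds and are bit-reproducible.
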