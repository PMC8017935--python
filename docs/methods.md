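# Methods notes

This note records the models, estimators, numerical choices and known
limitations of the package, in the spirit of a statistical software
vignette. Everything quantitative stated here is computed by the test
suite or the analysis drivers; nothing is asserted that the code does
not check.

## Relatedness from allele-frequency panels

Genomic similarity at a site with allele frequencies p is Σₐ pₐ², the
probability that two individuals drawn **with replacement** are
identical by state; S̄ averages it over core sites, and relatedness is
the F_ST-like contrast r = (S̄_w − S̄_a)/(1 − S̄_a). Two estimator
variants exist:

- **with replacement (default)** — appropriate when frequencies come
  from deep read data, where the sampled pool is effectively infinite
  and self-pairing is negligible;
- **distinct-pair corrected** (`bias_corrected=True`) — per site,
  (n Σp² − 1)/(n − 1) with n the counted sample size (read depth, or
  deme size for simulated panels). This is the estimand that
  population-genetic theory describes; at deme size 10 the
  uncorrected form would inflate within-deme similarity by ~1/N = 0.1,
  so every simulator-versus-theory comparison uses the corrected form.

Core sites are selected by strict prevalence (> threshold, default
0.90): with 10 hosts, presence in exactly 9 does not qualify. Pooling
across hosts is read-depth weighted (mirroring pooling reads across
samples); an unweighted option exists because the convention upstream
tools use is not universally documented. Within-host similarity for a
host uses only the core sites present in that host — this maximizes
data use and every such partial-presence case is visible in the
per-row `n_core_sites` column. Species are dropped — with a logged
reason, never silently — when present in fewer than `min_hosts` hosts
(default 2; the within/across contrast needs at least two), when fewer
than `min_core_sites` core sites remain (default 100; guards against
tiny effective core genomes), or when the pooled core genome is
monomorphic (r is then undefined: division by 1 − S̄_a = 0).

## The Wright–Fisher island model

Haploid demes of size N (one deme per host) evolve at L unlinked
4-state sites: each generation every individual is replaced with
probability m by a migrant drawn from the pooled metapopulation (the
infinite-island approximation), mutates with probability μ to one of
the other three alleles uniformly, and demes are resampled
multinomially. Sites start maximally polymorphic (uniform allele
frequencies) and a burn-in of 10 N generations (configurable) lets
within-deme differentiation reach quasi-equilibrium while global
polymorphism is still high — the classic regime in which the F_ST-type
ratio estimator is informative even as total diversity slowly decays.

The closed-form equilibrium r = (1−m)²/(N − (N−1)(1−m)²) follows from
the identity-by-descent recursion F = (1−m)²(1/N + (1−1/N)F) for an
infinite number of demes. With a finite number of demes two O(1/d)
effects appear (migrants can originate from the focal deme; the pooled
reference includes the focal deme), which partially cancel. At the
validation design used in the tests (N = 10, m = 0.1, d = 20, 500
sites) the residual finite-metapopulation bias is below two Monte-Carlo
standard errors of a single run's across-deme mean, so simulation and
closed form are compared at 3 MC SE. The simulator, not the formula,
is treated as ground truth: a disagreement beyond Monte-Carlo error
fails the build.

## Comparative simulator

Trees are pure-birth (Yule) with the stem edge removed, rescaled to
unit depth. The relatedness trait is Brownian on the logit scale
(unit rate plus an independent N(0, 0.5²) tip deviation) mapped through
the logistic into the requested range — bounded without truncation
artifacts. Genome sizes are log-normal around 3,000 coding sequences
(σ = 0.2), a realistic bacterial scale. Counts are
Pois(exp(β₀ + β_r R + β_n log N + u + ε)) with u multivariate normal on
the scaled tree covariance. Defaults (β₀ = −2, β_r = 0.6, β_n = 0.5,
σ²_p = 0.2, σ²_e = 0.1) give class counts in the tens at that genome
scale.

The annotation-table generator assigns each gene a localization, class
ontology terms (independent per class, so multi-class genes occur), a
background term, and per-species sporulation hits. Genome sizes can be
made log-normally variable (`genome_size_sigma`); the pipeline's
synthetic world uses σ = 0.3 so that log(total CDS − Y) is a genuine
genome-size covariate — with constant genome size that column would be
a deterministic reverse-coding of the response and absorbs the signal,
which is a property of degenerate synthetic worlds, not of real
genomes.

### What the synthetic world does and does not emulate

It emulates island-model population structure per species, a shared
phylogeny, sporulation-driven migration (higher sporulation → higher
migration → lower equilibrium relatedness), and cooperative gene
content scaling log-linearly with true relatedness. It does **not**
emulate read-level noise, sequencing error, linkage, within-host
spatial structure, horizontal gene transfer, or correlated annotation
error across classes. Passing tests therefore demonstrate that the
estimators and samplers recover the truth under the stated generative
models — not that those models capture every property of real
metagenomes.

## Phylogenetic mixed models

Sampler: Metropolis-within-Gibbs. For the Poisson model, each latent
log-rate gets a univariate random-walk Metropolis step (per-site step
sizes adapted toward 44% acceptance during burn-in only, so detailed
balance holds afterwards); (β, u) are updated jointly from their
conditional multivariate normal; variances from their conditional
inverse-gammas (the one-dimensional inverse-Wishart with V = 1,
ν = 0.002). Fixed effects have a diffuse N(0, 1e10) prior. The latent
residual ε in the linear predictor acts as overdispersion — with one
relatedness value per species it is the non-phylogenetic interspecies
variance.

The Gaussian model updates β and each random block (host, species-iid,
species-phylogenetic) sequentially; the three non-residual blocks use
the parameter-expanded prior (working scale α ~ N(0, 1000), ν = 1) by
default, which mixes better when a component is near zero; the
reported component is the effective variance α²σ²_v. Components can be
pinned (`fix_variances`); pinning both Poisson variances to zero
collapses the model to a plain Poisson GLM, sampled by adaptive
random-walk Metropolis on β — this exact limit is validated against
iteratively-reweighted-least-squares fits in the tests.

Conventions: C is scaled to unit diagonal before fitting so σ²_p is
comparable across trees (raw option retained); credible intervals are
equal-tailed (2.5%, 97.5%) quantiles; retained draws per chain are
floor((iterations − burn-in)/thinning); the Gelman–Rubin PSRF is the
classic non-split two-chain form and any parameter above 1.1 triggers
a warning, never a silent pass; a rank-deficient fixed-effect design
triggers a collinearity warning and the unidentified coefficient's
pMCMC sits near 1.

pMCMC is implemented sign-symmetrically, 2·min(P(draw < 0),
P(draw > 0)) capped at one. For positive estimates this equals twice
the posterior probability of being negative — the usual definition,
which presumes a positive estimate — and it behaves correctly for
negative estimates too.

Chain defaults are desk-scale (50,000 iterations, burn-in 5,000, thin
10, two chains); `McmcSettings.paper_scale()` gives the full-length
settings (10⁶ iterations, burn-in 5,000, thin 50). The analysis
drivers use 20,000-iteration chains on 25 species; the test suite uses
6,000–20,000-iteration chains on 30–100 species, sizes at which the
GLM-limit, coverage and variance-partition checks resolve cleanly.

Known mixing caveat: in the Gaussian model the intercept trades off
against the random-block means and is the slowest-mixing parameter;
its PSRF can exceed 1.1 on short chains (the warning fires). Slopes
and variance components are unaffected.

## Cooperation traits

Social-term sets are built from an ontology by case-insensitive
substring match on term **names** per class keyword list, expanded
with all transitive descendants (GO annotation semantics propagate
down; a direct-children-only flag exists) and the direct parents of
matched terms, then curated with include/exclude lists; provenance is
recorded per term. A gene counts once per class if any of its terms is
in the class set, and may count toward several classes. The sporulation
score is the fraction of the 66-gene signature with at least one hit
at e-value ≤ 1e-10 (the boundary value is read inclusively); copy
number is ignored. The shipped curated term list (48/5/11/29/25 per
class, 118 total) and 66-gene signature are synthetic stand-ins with
the real cardinalities, so real-ontology runs are possible but not
required.

## Synthesis

Meta-analysis: between-class variance τ² is estimated by REML
(bounded scalar maximization of the restricted log-likelihood;
DerSimonian–Laird available as an option and cross-checked against
statsmodels); weights are 1/(se² + τ²). When a study supplies only a
95% interval, its SE is recovered as width/3.92 — the symmetric normal
approximation, which is the documented fallback for re-pooling
published per-class estimates.

Wald test: W = bᵀV⁻¹b against chi-square(df) on the posterior
covariance of the six cooperation coefficients from the
reverse-causation model; a covariance with condition number above 1e12
raises an error that reports the condition number (this legitimately
occurs when the species-level design is rank-deficient, e.g. fewer
species than species-level predictors).

Path summary: edges are classified significant (pMCMC < 0.05),
marginal (0.05 ≤ pMCMC < 0.10 — the band used for "marginal effect"
language) or absent, each edge tracing to a named fitted coefficient;
the "similar effect size" check reports the relative change of β_r
between the relatedness-only and ecology-adjusted count models.

## Pipeline

A single global seed fans out to per-stage child seeds by fixed
offsets (seed·101 + stage offset, mod 2³¹−1), so stages rerun in
isolation reproduce the full run. The manifest is plain key=value
text recording the package version, every parameter, and stage
completion status; it contains no timestamps, so identical seeds give
byte-identical outputs. All artifacts are TSV/Newick/text and every
writer has a matching reader.

## Limitations

- No bivariate response models propagating relatedness-estimate
  uncertainty into the count models; the relatedness predictor enters
  as a point estimate.
- Ultrametric input trees are required; no ultrametricization, and no
  alternative trait-evolution models (Ornstein–Uhlenbeck, Pagel's λ).
- No upstream variant calling or read QC: panels are consumed as
  already-filtered frequencies.
- The meta-analysis is univariate; no multivariate pooling across
  classes.
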