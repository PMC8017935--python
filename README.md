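# gutkin

Comparative kin-selection analysis of cooperative gene content in
host-associated microbial communities.

Hamilton's rule (*rb* > *c*) predicts that higher genetic relatedness
among interacting cells favours the evolution of cooperation. Testing
this across a whole microbiota requires (i) measuring relatedness for
every species from strain-level metagenomic data, (ii) measuring each
genome's investment in cooperation, and (iii) comparing the two across
species while controlling for shared phylogenetic history. `gutkin`
implements that entire chain as a tested, reusable pipeline, together
with synthetic-data generators (a Wright–Fisher island model, a
phylogenetic comparative simulator, annotation-table generators) that
provide known ground truth for every step. It is aimed at evolutionary
microbiologists and microbiome researchers who want to run, probe, or
extend this style of comparative analysis.

## The quantities and models

**Relatedness.** For species *s* in host *h*, with S̄ the average
probability that two random haploid individuals are identical by state
at a core-genome site (S̄ = mean over sites of Σₐ pₐ², the complement of
genetic diversity),

    r_{s,h} = (S̄_{s,h} − S̄_s) / (1 − S̄_s),

an F_ST-like contrast of within-host versus pooled across-host
similarity. Core sites are those present in more than 90% of the hosts
carrying the species; species seen in a single host are dropped.

**Cooperation.** Six per-genome counts: secretome size (CDS with
predicted extracellular localization) and five GO-based classes
(biofilm, quorum sensing, secretion systems, siderophores, antibiotic
degradation; a gene counts toward a class if any of its terms is in the
curated social-term set). Ecological covariates: the sporulation score
(fraction of 66 signature genes detected at e-value ≤ 1e-10; a
migration proxy) and mean within-host relative abundance (a group-size
proxy).

**Models.** Bayesian phylogenetic mixed models sampled by
Metropolis-within-Gibbs:

    E[Y_i] = exp(β₀ + β_r R_i + β_n log N_i [+ β_a A_i + β_m S_i] + u_i + ε_i),
    Y_i ~ Pois,   u ~ N(0, σ²_p C),   ε ~ N(0, σ²_e I),

with C the Brownian shared-path covariance of the ultrametric species
tree, and a Gaussian analogue for within-host relatedness with host,
species and phylogenetic variance components. Per-class slopes are
pooled with a REML random-effects meta-analysis; reverse causation
(cooperation → relatedness) is tested per coefficient and jointly with
a Wald test; the infinite-island equilibrium
r = (1−m)²/(N − (N−1)(1−m)²) supplies the theory curve that the island
simulator validates.

## Worked example

The numbered drivers under `analysis/` run a complete desk-scale study
(25 species × 12 hosts, island-model panels, desk-scale chains):

```sh
python analysis/01_simulate.py    # world + island theory-vs-simulation check
python analysis/02_relatedness.py
python analysis/03_traits.py
python analysis/04_fit_models.py
python analysis/05_synthesize.py
```

`01` prints the theory/simulation comparison, e.g. at migration 0.1 the
closed form gives r = 0.2989 and the simulator 0.2952 ± 0.0039 — the
estimates agree within Monte-Carlo error at every grid point. `02`
reports that estimated per-species relatedness tracks the true island
equilibrium (Pearson r = 0.997). `04` prints the per-class slopes, e.g.

```
secretome              beta_r = +1.11 [+0.26, +2.00]  pMCMC = 0.013
...
relatedness ~ sporulation: beta = -0.330, pMCMC = 0.000
```

and `05` prints the synthesis: the pooled relatedness → cooperation
effect is 1.231 (SE 0.312, z 3.95) against a generating coupling of
1.2, migration shapes relatedness negatively, and the reverse-causation
Wald test is null (Chi2 = 4.29, df = 6, p = 0.64) — i.e. the pipeline
recovers the indirect-path scenario it was fed. It also re-pools the
six published per-class slopes, giving a pooled β = 0.773 (SE 0.193,
z = 4.00).

The same study runs from the command line: `gutkin all --outdir run
--seed 20 --n-species 25 --n-hosts 12 --n-sites 300`, with per-stage
subcommands (`simulate`, `relatedness`, `traits`, `fit`, `meta`,
`path`).

## Layout

- `src/gutkin/` — the library: `panels`/`relatedness` (similarity and
  r), `traits` (cooperation counts, ontology term sets, sporulation),
  `trees`/`pmm` (phylogenetic covariance and the MCMC samplers),
  `synthesis` (meta-analysis, Wald, island theory, path summary),
  `simulate` (generators), `pipeline`/`cli` (orchestration).
- `analysis/` — numbered narrative drivers for the desk-scale study.
- `tests/` — unit, property and acceptance tests.
- `docs/methods.md` — modelling and implementation notes.
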