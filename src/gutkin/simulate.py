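"""Synthetic data generators with known ground truth.

Three generative models cover every input the analysis needs:

* a haploid Wright-Fisher island model (demes = hosts) producing
  per-host allele-frequency panels whose equilibrium relatedness is
  known in closed form;
* a phylogenetic comparative model producing an ultrametric tree, a
  bounded Brownian relatedness trait, genome sizes, and Poisson
  cooperative gene counts with configurable phylogenetic and residual
  variance;
* gene-annotation and sporulation-hit tables with configurable
  secretome, social-GO and sporulation-signature content.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy
from dendropy.simulate import treesim
from scipy.special import expit, logit

from .errors import ParameterError, SimulationError
from .panels import AlleleFrequencyPanel
from .trees import covariance_for

__all__ = [
    "IslandModelParams",
    "simulate_island_model",
    "ComparativeSimParams",
    "simulate_comparative_dataset",
    "simulate_pure_birth_tree",
    "simulate_relatedness_observations",
    "GeneTableSimParams",
    "generate_gene_tables",
    "write_annotation_table",
    "write_hit_table",
]

COOPERATION_CLASSES = (
    "biofilm",
    "quorum_sensing",
    "secretion_systems",
    "siderophores",
    "antibiotic_degradation",
)

LOCALIZATIONS = ("extracellular", "cytoplasmic", "membrane", "cellwall", "periplasmic", "unknown")


# ---------------------------------------------------------------------------
# Wright-Fisher island model
# ---------------------------------------------------------------------------

@dataclass
class IslandModelParams:
    """Parameters of the haploid Wright-Fisher island model.

    ``n_demes`` hosts each carry a deme of ``deme_size`` (N) haploid
    individuals evolving at ``n_sites`` unlinked 4-state sites. Each
    generation, every individual is replaced with probability
    ``migration`` (m) by a migrant drawn from the pooled metapopulation
    (the infinite-island approximation), mutates with probability
    ``mutation`` to one of the other three alleles uniformly, and demes
    are resampled multinomially. ``n_generations`` are simulated after a
    burn-in of ``burn_in`` generations (default 10 N, a standard
    drift-equilibration heuristic).
    """

    n_demes: int = 20
    deme_size: int = 10
    migration: float = 0.1
    mutation: float = 1e-4
    n_sites: int = 500
    n_generations: int = 50
    seed: int = 0
    burn_in: int = None
    species: str = "sim_species"

    def __post_init__(self):
        if not (0.0 <= self.migration <= 1.0):
            raise ParameterError(f"migration must be in [0, 1], got {self.migration}")
        if not (0.0 <= self.mutation <= 1.0):
            raise ParameterError(f"mutation must be in [0, 1], got {self.mutation}")
        for name in ("n_demes", "deme_size", "n_sites", "n_generations"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.burn_in is None:
            self.burn_in = 10 * self.deme_size
        if self.burn_in < 0:
            raise ParameterError("burn_in must be >= 0")


def simulate_island_model(params: IslandModelParams) -> AlleleFrequencyPanel:
    """Evolve the island model and return the final allele-frequency panel.

    The panel reports per-deme allele frequencies (summing to one at
    every site), full presence, and depth equal to the deme size, so the
    relatedness stage can apply its finite-sample correction.
    """
    rng = np.random.default_rng(params.seed)
    d, N, L = params.n_demes, params.deme_size, params.n_sites
    m, mu = params.migration, params.mutation
    # polymorphic start: every deme drawn from uniform allele frequencies
    counts = rng.multinomial(N, [0.25] * 4, size=(d, L))
    for _ in range(params.burn_in + params.n_generations):
        freq = counts / N
        pooled = freq.mean(axis=0)
        p = (1.0 - m) * freq + m * pooled[None, :, :]
        if mu > 0:
            p = p * (1.0 - mu) + mu * (1.0 - p) / 3.0
        p = p / p.sum(axis=2, keepdims=True)
        counts = rng.multinomial(N, p)
    freqs = counts / N
    return AlleleFrequencyPanel(
        species=params.species,
        hosts=[f"host{i + 1:03d}" for i in range(d)],
        sites=[f"site{j + 1:05d}" for j in range(L)],
        freqs=freqs,
        presence=np.ones((d, L), dtype=bool),
        depth=np.full((d, L), float(N)),
    )


# ---------------------------------------------------------------------------
# Phylogenetic comparative model
# ---------------------------------------------------------------------------

def simulate_pure_birth_tree(n_species: int, seed: int, depth: float = 1.0) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with tips sp001..spNNN, scaled to
    the requested depth."""
    if n_species < 2:
        raise ParameterError("need at least 2 species")
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=_pyrandom.Random(int(seed)),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:03d}"
    # drop the stem edge above the root, then rescale to the requested depth
    tree.seed_node.edge.length = None
    from .trees import _node_depths

    depths = _node_depths(tree)
    max_depth = max(depths[leaf] for leaf in tree.leaf_node_iter())
    if max_depth <= 0:
        raise SimulationError("degenerate tree with zero depth")
    factor = depth / max_depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


@dataclass
class ComparativeSimParams:
    """Ground-truth parameters of the comparative count model.

    Counts are drawn as ``Y_i ~ Pois(exp(b0 + br * R_i + bn * log(N_i)
    + u_i + e_i))`` with ``u ~ MVN(0, phylo_variance * C)`` on a
    simulated pure-birth tree (C scaled to unit diagonal) and
    ``e_i ~ N(0, residual_variance)``. The relatedness trait R is
    Brownian on the logit scale (unit rate), mapped into
    ``relatedness_range`` through the logistic function so it stays
    bounded without truncation artifacts. Genome sizes are log-normal
    around 3,000 coding sequences, a realistic bacterial scale.
    """

    n_species: int = 100
    true_slope: float = 0.6
    true_intercept: float = -2.0
    genome_size_coef: float = 0.5
    phylo_variance: float = 0.2
    residual_variance: float = 0.1
    relatedness_range: tuple = (0.1, 0.95)
    genome_size_mean: float = 3000.0
    genome_size_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.phylo_variance < 0 or self.residual_variance < 0:
            raise ParameterError("variances must be >= 0")
        lo, hi = self.relatedness_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ParameterError("relatedness_range must be an interval within [0, 1]")
        if self.n_species < 2:
            raise ParameterError("n_species must be >= 2")


def _mvn_phylo(rng, C, variance, size=None):
    try:
        L = np.linalg.cholesky(C + 1e-10 * np.eye(C.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise SimulationError("phylogenetic covariance not positive definite") from exc
    z = rng.standard_normal(C.shape[0])
    return np.sqrt(variance) * (L @ z)


def simulate_comparative_dataset(params: ComparativeSimParams):
    """Simulate (tree, species trait table) under the comparative model.

    The trait table has columns species, relatedness, genome_size,
    count, and the latent components (u_phylo, resid) for diagnostics;
    tip labels of the tree exactly match the species column.
    """
    rng = np.random.default_rng(params.seed)
    tree = simulate_pure_birth_tree(params.n_species, seed=int(rng.integers(2**31 - 1)))
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    C = covariance_for(tree, species, scale_to_unit=True)

    lo, hi = params.relatedness_range
    z = _mvn_phylo(rng, C, 1.0) + rng.standard_normal(len(species)) * 0.5
    R = lo + (hi - lo) * expit(z)

    genome_size = np.round(
        rng.lognormal(np.log(params.genome_size_mean), params.genome_size_sigma, len(species))
    ).astype(int)
    u = _mvn_phylo(rng, C, params.phylo_variance) if params.phylo_variance > 0 else np.zeros(len(species))
    e = rng.normal(0.0, np.sqrt(params.residual_variance), len(species)) if params.residual_variance > 0 else np.zeros(len(species))
    eta = (
        params.true_intercept
        + params.true_slope * R
        + params.genome_size_coef * np.log(genome_size)
        + u
        + e
    )
    counts = rng.poisson(np.exp(eta))
    table = pd.DataFrame(
        {
            "species": species,
            "relatedness": R,
            "genome_size": genome_size,
            "count": counts,
            "u_phylo": u,
            "resid": e,
        }
    )
    return tree, table


def simulate_relatedness_observations(
    n_species: int = 40,
    n_hosts: int = 50,
    occupancy: float = 1.0,
    intercept: float = 0.6,
    beta_abundance: float = 0.0,
    beta_sporulation: float = 0.0,
    host_variance: float = 0.1,
    species_variance: float = 0.05,
    phylo_variance: float = 0.0,
    residual_variance: float = 0.02,
    seed: int = 0,
    tree: dendropy.Tree = None,
):
    """Simulate per-(species, host) relatedness observations.

    The generative model mirrors the Gaussian mixed model of within-host
    relatedness: fixed effects of per-observation relative abundance and
    per-species sporulation score, plus host, species (iid), species
    (phylogenetic) and residual components. Returns ``(tree, DataFrame)``
    with columns species, host, r_obs, abundance, sporulation.
    """
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = simulate_pure_birth_tree(n_species, seed=int(rng.integers(2**31 - 1)))
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    C = covariance_for(tree, species, scale_to_unit=True)
    hosts = [f"host{i + 1:03d}" for i in range(n_hosts)]
    u_h = rng.normal(0, np.sqrt(host_variance), n_hosts)
    u_s = rng.normal(0, np.sqrt(species_variance), len(species))
    u_p = _mvn_phylo(rng, C, phylo_variance) if phylo_variance > 0 else np.zeros(len(species))
    sporulation = rng.beta(2, 2, len(species))
    rows = []
    for si, sp in enumerate(species):
        for hi, host in enumerate(hosts):
            if rng.random() > occupancy:
                continue
            abundance = rng.lognormal(-4.0, 1.0)
            r_obs = (
                intercept
                + beta_abundance * abundance
                + beta_sporulation * sporulation[si]
                + u_h[hi]
                + u_s[si]
                + u_p[si]
                + rng.normal(0, np.sqrt(residual_variance))
            )
            rows.append((sp, host, r_obs, abundance, sporulation[si]))
    df = pd.DataFrame(rows, columns=["species", "host", "r_obs", "abundance", "sporulation"])
    return tree, df


# ---------------------------------------------------------------------------
# Gene annotation tables
# ---------------------------------------------------------------------------

@dataclass
class GeneTableSimParams:
    """Knobs of the annotation-table generator (artifact plumbing).

    ``p_social_per_class`` gives, per cooperation class, the probability
    that a gene carries at least one ontology term of that class; a gene
    can belong to several classes. ``p_sporulation_gene`` is the
    probability that each signature gene is present in a species'
    genome.
    """

    n_genes_per_species: int = 1000
    genome_size_sigma: float = 0.0  # log-normal spread of genome size
    p_extracellular: float = 0.05
    p_social_per_class: tuple = (0.02, 0.004, 0.006, 0.01, 0.008)
    p_sporulation_gene: float = 0.5
    p_background_term: float = 0.3
    seed: int = 0

    def __post_init__(self):
        probs = (self.p_extracellular, self.p_sporulation_gene, self.p_background_term,
                 *self.p_social_per_class)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ParameterError("all probabilities must lie in [0, 1]")
        if self.genome_size_sigma < 0:
            raise ParameterError("genome_size_sigma must be >= 0")
        if len(self.p_social_per_class) != len(COOPERATION_CLASSES):
            raise ParameterError(
                f"p_social_per_class needs {len(COOPERATION_CLASSES)} entries"
            )
        if self.n_genes_per_species < 1:
            raise ParameterError("n_genes_per_species must be >= 1")


_BACKGROUND_TERMS = [f"GO:9{i:06d}" for i in range(1, 41)]


def generate_gene_tables(
    params: GeneTableSimParams,
    species_list,
    per_species_scale=None,
):
    """Generate (annotation table, sporulation hit table) for a species list.

    ``per_species_scale`` optionally maps species -> multiplier applied
    to every social-class probability (and the secretome probability),
    which lets a caller couple cooperative gene content to a known
    relatedness value. Probabilities are clipped to [0, 1].

    The annotation table has one row per gene: species, gene_id,
    localization, go_terms (semicolon-separated, possibly empty), gram.
    The hit table has one row per detected sporulation signature gene:
    species, gene, evalue.
    """
    from .traits import load_social_go_terms, load_sporulation_signature

    if len(species_list) == 0:
        raise ParameterError("species list is empty")
    rng = np.random.default_rng(params.seed)
    term_df = load_social_go_terms()
    class_terms = {
        c: term_df.loc[term_df["class"] == c, "term_id"].tolist()
        for c in COOPERATION_CLASSES
    }
    signature = load_sporulation_signature()
    gene_rows, hit_rows = [], []
    for sp in species_list:
        scale = 1.0
        if per_species_scale is not None:
            scale = float(per_species_scale[sp])
        gram = "positive" if rng.random() < 0.5 else "negative"
        p_ext = min(1.0, params.p_extracellular * scale)
        n_genes = params.n_genes_per_species
        if params.genome_size_sigma > 0:
            n_genes = max(
                1,
                int(round(rng.lognormal(np.log(n_genes), params.genome_size_sigma))),
            )
        for g in range(n_genes):
            gene_id = f"{sp}_g{g + 1:05d}"
            if rng.random() < p_ext:
                loc = "extracellular"
            else:
                loc = LOCALIZATIONS[1:][int(rng.integers(len(LOCALIZATIONS) - 1))]
            terms = []
            for c, p_c in zip(COOPERATION_CLASSES, params.p_social_per_class):
                if rng.random() < min(1.0, p_c * scale):
                    terms.append(class_terms[c][int(rng.integers(len(class_terms[c])))])
            if rng.random() < params.p_background_term:
                terms.append(_BACKGROUND_TERMS[int(rng.integers(len(_BACKGROUND_TERMS)))])
            gene_rows.append((sp, gene_id, loc, ";".join(terms), gram))
        for gene in signature:
            if rng.random() < params.p_sporulation_gene:
                evalue = 10.0 ** (-rng.uniform(12.0, 40.0))
                hit_rows.append((sp, gene, evalue))
    annotation = pd.DataFrame(
        gene_rows, columns=["species", "gene_id", "localization", "go_terms", "gram"]
    )
    hits = pd.DataFrame(hit_rows, columns=["species", "gene", "evalue"])
    return annotation, hits


def write_annotation_table(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)
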