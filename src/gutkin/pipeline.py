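"""End-to-end orchestration: generate/ingest -> relatedness -> traits ->
models -> synthesis.

The pipeline runs either on a self-contained synthetic world (an island
model per species wired so that sporulation ability raises migration and
thereby lowers equilibrium relatedness, and cooperative gene content
scales with relatedness) or on user-supplied tables with the same
schemas. Every stage writes its outputs as TSV into the run directory,
every dropped species is logged with a reason, and a machine-readable
manifest records the seed and all parameter values. A fixed global seed
fans out to per-stage child seeds by fixed offsets, so stages are
individually reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, DataError, GutkinError
from .panels import read_panels, write_panels
from .pmm import McmcSettings, PriorSpec, fit_gaussian_pmm, fit_poisson_pmm
from .relatedness import build_relatedness_table
from .simulate import (
    COOPERATION_CLASSES,
    GeneTableSimParams,
    IslandModelParams,
    generate_gene_tables,
    simulate_island_model,
    simulate_pure_birth_tree,
)
from .synthesis import (
    EffectEstimate,
    island_equilibrium_relatedness,
    meta_analysis,
    path_summary,
)
from .traits import (
    build_cooperation_counts,
    load_sporulation_signature,
    read_annotation_table,
    read_hit_table,
)
from .trees import covariance_for, read_tree, write_tree

logger = logging.getLogger(__name__)

ALL_CLASSES = ("secretome",) + COOPERATION_CLASSES

_STAGE_OFFSETS = {"simulate": 11, "relatedness": 23, "traits": 37, "fit": 53}


class StageError(GutkinError, RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Configuration of a full run; defaults reproduce the documented
    analysis settings (core-site prevalence > 0.90, at least two hosts,
    e-value cutoff 1e-10)."""

    outdir: str = "gutkin_run"
    mode: str = "synthetic"  # or "tables"
    seed: int = 0

    # synthetic world
    n_species: int = 20
    n_hosts: int = 10
    n_sites: int = 200
    deme_size: int = 10
    migration_range: tuple = (0.02, 0.4)
    mutation: float = 1e-4
    n_genes_per_species: int = 800
    world_beta_r: float = 1.0  # relatedness -> cooperation coupling

    # tables mode inputs
    panels_path: str = None
    tree_path: str = None
    annotations_path: str = None
    hits_path: str = None
    abundance_path: str = None

    # filters and scores
    prevalence_threshold: float = 0.90
    min_hosts: int = 2
    min_core_sites: int = 100
    evalue_cutoff: float = 1e-10
    bias_corrected: bool = True

    # models
    mcmc: McmcSettings = field(default_factory=lambda: McmcSettings())

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 101 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


def _manifest_lines(config: PipelineConfig, extra: dict) -> list:
    d = asdict(config)
    d["mcmc"] = (
        f"iters={config.mcmc.n_iterations},burn={config.mcmc.burn_in},"
        f"thin={config.mcmc.thinning},chains={config.mcmc.n_chains},"
        f"seed={config.mcmc.seed}"
    )
    d["version"] = __version__
    d.update(extra)
    return [f"{k}={v}" for k, v in sorted(d.items())]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    """Build the synthetic world and write every pipeline input."""
    rng = np.random.default_rng(config.stage_seed("simulate"))
    tree = simulate_pure_birth_tree(config.n_species, seed=int(rng.integers(2**31 - 1)))
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]

    sporulation_truth = rng.beta(2.0, 2.0, len(species))
    m_lo, m_hi = config.migration_range
    migration = m_lo + (m_hi - m_lo) * sporulation_truth
    true_r = island_equilibrium_relatedness(config.deme_size, migration)

    panels = []
    for sp, m in zip(species, migration):
        params = IslandModelParams(
            n_demes=config.n_hosts,
            deme_size=config.deme_size,
            migration=float(m),
            mutation=config.mutation,
            n_sites=config.n_sites,
            seed=int(rng.integers(2**31 - 1)),
            species=sp,
        )
        panels.append(simulate_island_model(params))
    write_panels(panels, outdir / "panels.tsv")
    write_tree(tree, outdir / "tree.nwk")

    # cooperative gene content scales with true relatedness
    scale = pd.Series(
        np.exp(config.world_beta_r * (true_r - true_r.mean())), index=species
    )
    # genome sizes vary log-normally so log(total CDS - Y) is a genuine
    # genome-size covariate rather than a reverse-coding of the response
    gt_params = GeneTableSimParams(seed=int(rng.integers(2**31 - 1)),
                                   n_genes_per_species=config.n_genes_per_species,
                                   genome_size_sigma=0.3)
    annotation, _ = generate_gene_tables(gt_params, species, per_species_scale=scale)

    # sporulation hits follow each species' latent sporulation ability
    signature = load_sporulation_signature()
    hit_rows = []
    for sp, s_true in zip(species, sporulation_truth):
        for gene in signature:
            if rng.random() < s_true:
                hit_rows.append((sp, gene, 10.0 ** (-rng.uniform(12, 40))))
    hits = pd.DataFrame(hit_rows, columns=["species", "gene", "evalue"])

    abundance_rows = []
    for sp in species:
        base = rng.lognormal(-4.0, 0.8)
        for h in range(config.n_hosts):
            abundance_rows.append((sp, f"host{h + 1:03d}", base * rng.lognormal(0.0, 0.5)))
    abundance = pd.DataFrame(abundance_rows, columns=["species", "host", "abundance"])

    annotation.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    hits.to_csv(outdir / "sporulation_hits.tsv", sep="\t", index=False)
    abundance.to_csv(outdir / "abundance.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "species": species,
            "sporulation_truth": sporulation_truth,
            "migration": migration,
            "true_relatedness": true_r,
        }
    ).to_csv(outdir / "world_truth.tsv", sep="\t", index=False)
    return {
        "panels": panels,
        "tree": tree,
        "annotation": annotation,
        "hits": hits,
        "abundance": abundance,
    }


def stage_relatedness(config: PipelineConfig, outdir: Path, panels) -> dict:
    result = build_relatedness_table(
        panels,
        prevalence_threshold=config.prevalence_threshold,
        min_hosts=config.min_hosts,
        min_core_sites=config.min_core_sites,
        bias_corrected=config.bias_corrected,
    )
    result.write(outdir / "relatedness_by_host.tsv", outdir / "relatedness_summary.tsv")
    pd.DataFrame(result.dropped, columns=["species", "reason"]).to_csv(
        outdir / "relatedness_dropped.tsv", sep="\t", index=False
    )
    for sp, reason in result.dropped:
        logger.info("relatedness stage dropped %s: %s", sp, reason)
    return {"relatedness": result}


def stage_traits(config: PipelineConfig, outdir: Path, annotation, hits, abundance) -> dict:
    counts = build_cooperation_counts(
        annotation, hits, abundance=abundance, evalue_cutoff=config.evalue_cutoff
    )
    counts.to_csv(outdir / "cooperation_counts.tsv", sep="\t", index=False)
    return {"counts": counts}


def _poisson_design(counts: pd.DataFrame, summary: pd.DataFrame, cls: str, ecology: bool):
    df = counts.merge(summary[["species", "mean_r"]], on="species", how="inner")
    y = df[cls].to_numpy()
    non_coop = df["total_cds"].to_numpy() - y
    if np.any(non_coop <= 0):
        raise DataError(f"{cls}: non-cooperative CDS count must be positive")
    X = pd.DataFrame(
        {"relatedness": df["mean_r"].to_numpy(), "log_n": np.log(non_coop)}
    )
    if cls == "secretome":
        X["gram_positive"] = (df["gram"] == "positive").astype(float)
    if ecology:
        # abundance may be absent in tables mode; a constant column would be
        # collinear with the intercept, so fall back to zero contribution
        X["abundance"] = np.nan_to_num(
            df["mean_relative_abundance"].to_numpy(dtype=float), nan=0.0
        )
        X["sporulation"] = df["sporulation_score"].to_numpy()
    return df["species"].tolist(), y, X


def stage_fit(config: PipelineConfig, outdir: Path, counts, relatedness_result, tree) -> dict:
    fit_dir = outdir / "fits"
    fit_dir.mkdir(exist_ok=True)
    summary = relatedness_result.summary
    mcmc = config.mcmc
    seed0 = config.stage_seed("fit")

    cooperation_fits, cooperation_fits_ecology = {}, {}
    for k, cls in enumerate(ALL_CLASSES):
        for ecology in (False, True):
            species, y, X = _poisson_design(counts, summary, cls, ecology)
            C = covariance_for(tree, species, scale_to_unit=True)
            fit = fit_poisson_pmm(
                y,
                X,
                C,
                mcmc=McmcSettings(
                    n_iterations=mcmc.n_iterations,
                    burn_in=mcmc.burn_in,
                    thinning=mcmc.thinning,
                    n_chains=mcmc.n_chains,
                    seed=seed0 + 2 * k + int(ecology),
                ),
            )
            tag = "eco" if ecology else "base"
            fit.write_summary(fit_dir / f"{cls}_{tag}_summary.tsv")
            fit.write_draws(fit_dir / f"{cls}_{tag}_draws.tsv")
            (cooperation_fits_ecology if ecology else cooperation_fits)[cls] = fit

    # Gaussian relatedness models (per-host observations)
    table = relatedness_result.table.merge(
        counts[["species", "sporulation_score"] + list(ALL_CLASSES)],
        on="species",
        how="inner",
    )
    abundance = None
    ab_path = outdir / "abundance.tsv"
    if ab_path.exists():
        abundance = pd.read_csv(ab_path, sep="\t")
        table = table.merge(abundance, on=["species", "host"], how="left")
        table["abundance"] = table["abundance"].fillna(table["abundance"].mean())
    else:
        table["abundance"] = 0.0
    species_levels = sorted(table["species"].unique())
    host_levels = sorted(table["host"].unique())
    C = covariance_for(tree, species_levels, scale_to_unit=True)
    sp_codes = table["species"].map({s: i for i, s in enumerate(species_levels)}).to_numpy()
    host_codes = table["host"].map({h: i for i, h in enumerate(host_levels)}).to_numpy()

    def gaussian(X, seed):
        return fit_gaussian_pmm(
            table["r"].to_numpy(),
            X,
            sp_codes,
            C,
            host_codes=host_codes,
            prior=PriorSpec(parameter_expanded=True),
            mcmc=McmcSettings(
                n_iterations=mcmc.n_iterations,
                burn_in=mcmc.burn_in,
                thinning=mcmc.thinning,
                n_chains=mcmc.n_chains,
                seed=seed,
            ),
        )

    X_rel = pd.DataFrame(
        {
            "abundance": table["abundance"].to_numpy(),
            "sporulation": table["sporulation_score"].to_numpy(),
        }
    )
    relatedness_fit = gaussian(X_rel, seed0 + 100)
    X_rev = X_rel.copy()
    for cls in ALL_CLASSES:
        X_rev[cls] = table[cls].to_numpy(dtype=float)
    relatedness_fit_reverse = gaussian(X_rev, seed0 + 101)
    relatedness_fit.write_summary(fit_dir / "relatedness_model_summary.tsv")
    relatedness_fit_reverse.write_summary(fit_dir / "relatedness_reverse_summary.tsv")
    return {
        "cooperation_fits": cooperation_fits,
        "cooperation_fits_ecology": cooperation_fits_ecology,
        "relatedness_fit": relatedness_fit,
        "relatedness_fit_reverse": relatedness_fit_reverse,
    }


def stage_synthesis(config: PipelineConfig, outdir: Path, fits) -> dict:
    meta = meta_analysis(
        [
            EffectEstimate(
                label=c,
                estimate=float(fits["cooperation_fits"][c].coefficient("relatedness")["mean"]),
                se=float(np.std(fits["cooperation_fits"][c].pooled("relatedness"), ddof=1)),
            )
            for c in ALL_CLASSES
        ]
    )
    summary = path_summary(
        cooperation_fits=fits["cooperation_fits"],
        cooperation_fits_ecology=fits["cooperation_fits_ecology"],
        relatedness_fit=fits["relatedness_fit"],
        relatedness_fit_reverse=fits["relatedness_fit_reverse"],
        meta=meta,
    )
    meta.to_frame().to_csv(outdir / "meta_analysis.tsv", sep="\t", index=False)
    summary.write(outdir / "path_edges.tsv")
    summary.slope_stability.to_csv(outdir / "slope_stability.tsv", sep="\t", index=False)
    (outdir / "path_report.txt").write_text(summary.report() + "\n")
    return {"meta": meta, "path": summary}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _load_tables(config: PipelineConfig) -> dict:
    required = {
        "panels_path": config.panels_path,
        "tree_path": config.tree_path,
        "annotations_path": config.annotations_path,
        "hits_path": config.hits_path,
    }
    missing = [k for k, v in required.items() if not v]
    if missing:
        raise ConfigurationError(f"tables mode requires paths: {missing}")
    data = {
        "panels": read_panels(config.panels_path),
        "tree": read_tree(config.tree_path),
        "annotation": read_annotation_table(config.annotations_path),
        "hits": read_hit_table(config.hits_path),
        "abundance": None,
    }
    if config.abundance_path:
        data["abundance"] = pd.read_csv(config.abundance_path, sep="\t")
    return data


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the run directory.

    Any stage failure raises :class:`StageError` naming the stage; the
    manifest records which stages completed, so partial outputs are
    flagged rather than silently trusted.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed = []

    def run_stage(name, fn, *args):
        try:
            result = fn(config, outdir, *args)
        except GutkinError as exc:
            _write_manifest(failed=name)
            raise StageError(f"stage '{name}' failed: {exc}") from exc
        completed.append(name)
        return result

    def _write_manifest(failed=None):
        extra = {"stages_completed": ",".join(completed)}
        if failed:
            extra["stage_failed"] = failed
            extra["status"] = "partial"
        else:
            extra["status"] = "complete"
        (outdir / "manifest.txt").write_text(
            "\n".join(_manifest_lines(config, extra)) + "\n"
        )

    if config.mode == "synthetic":
        data = run_stage("simulate", stage_simulate)
    elif config.mode == "tables":
        try:
            data = _load_tables(config)
        except GutkinError as exc:
            raise StageError(f"stage 'ingest' failed: {exc}") from exc
        completed.append("ingest")
        if data["abundance"] is not None:
            data["abundance"].to_csv(outdir / "abundance.tsv", sep="\t", index=False)
    else:
        raise ConfigurationError(f"unknown mode {config.mode!r}")

    rel = run_stage("relatedness", stage_relatedness, data["panels"])
    traits = run_stage(
        "traits", stage_traits, data["annotation"], data["hits"], data["abundance"]
    )
    fits = run_stage(
        "fit", stage_fit, traits["counts"], rel["relatedness"], data["tree"]
    )
    run_stage("synthesis", stage_synthesis, fits)
    _write_manifest()
    logger.info("pipeline complete: %s", outdir)
    return outdir
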