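"""Shared configuration for the numbered analysis drivers.

One synthetic study at desk scale: 25 species observed in 12 hosts,
island-model panels of 300 core sites, desk-scale MCMC chains. Every
driver reads and writes under results/.
"""

from pathlib import Path

from gutkin.pipeline import PipelineConfig
from gutkin.pmm import McmcSettings

RESULTS = Path(__file__).resolve().parent.parent / "results"
WORLD = RESULTS / "world"


def study_config() -> PipelineConfig:
    return PipelineConfig(
        outdir=str(WORLD),
        mode="synthetic",
        seed=20,
        n_species=25,
        n_hosts=12,
        n_sites=300,
        deme_size=10,
        migration_range=(0.02, 0.4),
        world_beta_r=1.2,
        mcmc=McmcSettings(
            n_iterations=20_000, burn_in=4_000, thinning=10, n_chains=2, seed=0
        ),
    )
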