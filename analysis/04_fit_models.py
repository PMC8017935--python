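#!/usr/bin/env python
"""Fit the phylogenetic mixed models: six Poisson count models (with and
without ecological covariates) and the Gaussian relatedness model (with
and without the reverse-causation cooperation predictors).

Writes per-model posterior summaries and draws under
results/world/fits/.
"""

import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import WORLD, study_config
from gutkin.pipeline import ALL_CLASSES, stage_fit
from gutkin.relatedness import RelatednessResult, read_relatedness_table
from gutkin.traits import read_cooperation_counts
from gutkin.trees import read_tree


def main():
    config = study_config()
    counts = read_cooperation_counts(WORLD / "cooperation_counts.tsv")
    rel = RelatednessResult(
        table=read_relatedness_table(WORLD / "relatedness_by_host.tsv"),
        summary=pd.read_csv(WORLD / "relatedness_summary.tsv", sep="\t"),
        dropped=[],
    )
    tree = read_tree(WORLD / "tree.nwk")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fits = stage_fit(config, WORLD, counts, rel, tree)
    notes = {str(w.message).split("(")[0] for w in caught}
    for note in sorted(notes):
        print("note:", note.strip())

    print("\nrelatedness slope per cooperation class (base model):")
    for cls in ALL_CLASSES:
        coef = fits["cooperation_fits"][cls].coefficient("relatedness")
        print(
            f"  {cls:22s} beta_r = {coef['mean']:+.2f} "
            f"[{coef['ci_lower']:+.2f}, {coef['ci_upper']:+.2f}]  "
            f"pMCMC = {coef['pmcmc']:.3f}"
        )
    rel_fit = fits["relatedness_fit"]
    for term in ("sporulation", "abundance"):
        coef = rel_fit.coefficient(term)
        print(
            f"relatedness ~ {term}: beta = {coef['mean']:+.3f}, "
            f"pMCMC = {coef['pmcmc']:.3f}"
        )


if __name__ == "__main__":
    main()
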