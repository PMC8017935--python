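#!/usr/bin/env python
"""Quantify cooperative gene content and ecological covariates.

Reads the annotation, sporulation-hit and abundance tables from
results/world/; writes cooperation_counts.tsv there.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import WORLD, study_config
from gutkin.pipeline import stage_traits
from gutkin.traits import read_annotation_table, read_hit_table


def main():
    config = study_config()
    annotation = read_annotation_table(WORLD / "annotations.tsv")
    hits = read_hit_table(WORLD / "sporulation_hits.tsv")
    abundance = pd.read_csv(WORLD / "abundance.tsv", sep="\t")
    counts = stage_traits(config, WORLD, annotation, hits, abundance)["counts"]
    print(counts.round(3).to_string(index=False, max_rows=10))
    class_cols = counts.columns[1:7]
    print("\nmean count per cooperation class:")
    print(counts[class_cols].mean().round(1).to_string())


if __name__ == "__main__":
    main()
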