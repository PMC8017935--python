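import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gutkin.panels import AlleleFrequencyPanel
from gutkin.synthesis import EffectEstimate


@pytest.fixture
def toy_ontology():
    """Small is_a DAG with named terms for keyword-expansion tests.

    root -> {metabolism, social}
    metabolism -> polysaccharide production
    social -> extracellular polysaccharide production -> {eps biosynthesis, eps export}
    social -> quorum sensing
    """
    g = nx.DiGraph()
    nodes = {
        "GO:1": "biological process",
        "GO:2": "metabolism",
        "GO:3": "polysaccharide production",
        "GO:4": "social behaviour",
        "GO:5": "extracellular polysaccharide production",
        "GO:6": "eps biosynthesis",
        "GO:7": "eps export",
        "GO:8": "quorum sensing",
    }
    for tid, name in nodes.items():
        g.add_node(tid, name=name)
    g.add_edges_from(
        [
            ("GO:1", "GO:2"),
            ("GO:1", "GO:4"),
            ("GO:2", "GO:3"),
            ("GO:4", "GO:5"),
            ("GO:5", "GO:6"),
            ("GO:5", "GO:7"),
            ("GO:4", "GO:8"),
        ]
    )
    return g


@pytest.fixture
def toy_annotation():
    rows = [
        ("sp1", "g1", "extracellular", "GO:5;GO:6", "negative"),
        ("sp1", "g2", "cytoplasmic", "GO:8", "negative"),
        ("sp1", "g3", "extracellular", "", "negative"),
        ("sp1", "g4", "membrane", "GO:5;GO:8", "negative"),
        ("sp2", "g1", "unknown", "", "positive"),
    ]
    return pd.DataFrame(
        rows, columns=["species", "gene_id", "localization", "go_terms", "gram"]
    )


@pytest.fixture
def printed_class_slopes():
    """The six per-class slope estimates with their 95% intervals, as
    published for the six cooperation measures; SEs recovered from the
    interval widths."""
    data = [
        ("secretome", 0.59, 0.08, 1.07),
        ("siderophores", 1.56, 0.42, 2.78),
        ("biofilm", 1.06, 0.06, 2.10),
        ("quorum_sensing", 0.39, -1.34, 2.21),
        ("secretion_systems", 0.48, -2.27, 3.08),
        ("antibiotic_degradation", 0.86, -0.26, 2.03),
    ]
    return [
        EffectEstimate(label=l, estimate=e, ci_lower=lo, ci_upper=hi)
        for l, e, lo, hi in data
    ]


def make_panel(freqs, depth=None, presence=None, species="spX"):
    """Build a panel from a (hosts, sites, 4) frequency array."""
    freqs = np.asarray(freqs, dtype=float)
    n_h, n_s, _ = freqs.shape
    if presence is None:
        presence = np.ones((n_h, n_s), dtype=bool)
    if depth is None:
        depth = np.full((n_h, n_s), 10.0)
    return AlleleFrequencyPanel(
        species=species,
        hosts=[f"h{i}" for i in range(n_h)],
        sites=[f"s{j}" for j in range(n_s)],
        freqs=freqs,
        presence=presence,
        depth=depth,
    )


@pytest.fixture
def panel_factory():
    return make_panel
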