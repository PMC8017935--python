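"""Quantifying cooperative gene content per species.

Six measures of a genome's investment in cooperation:

* **secretome size** — number of coding sequences whose product has a
  predicted extracellular final localization (secreted products are
  public goods from the producer's perspective);
* **five ontology-based class counts** — genes annotated with at least
  one term from a curated set of "social" GO terms for biofilm
  formation, quorum sensing, secretion systems, siderophores, and
  antibiotic degradation;

plus two ecological covariates: the **sporulation score** (fraction of
66 signature sporulation genes detected in the genome, a proxy for
migration ability) and mean within-host relative abundance (a proxy for
group size).

The social term sets are built from an ontology graph by
case-insensitive keyword match on term names, expanded to descendants
and direct parents, then manually curated; the curated 118-term list
used downstream ships as a versioned fixture. The shipped fixture files
are synthetic stand-ins with the real per-class term counts
(48/5/11/29/25) and a 66-gene signature, so real-ontology runs are
possible but not required.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError

SOCIAL_CLASSES = (
    "biofilm",
    "quorum_sensing",
    "secretion_systems",
    "siderophores",
    "antibiotic_degradation",
)

COUNTS_COLUMNS = [
    "species",
    "secretome",
    *SOCIAL_CLASSES,
    "total_cds",
    "gram",
    "sporulation_score",
    "mean_relative_abundance",
]

_SOCIAL_FIXTURE = "social_go_terms_118_synthetic.tsv"
_SPORULATION_FIXTURE = "sporulation_signature_66_synthetic.tsv"


def _data_path(name):
    return importlib.resources.files("gutkin.data").joinpath(name)


def load_social_go_terms() -> pd.DataFrame:
    """Curated social GO term list (columns: class, term_id, name).

    Synthetic stand-in fixture with the curated per-class term counts:
    biofilm 48, quorum sensing 5, secretion systems 11, siderophores
    29, antibiotic degradation 25 — 118 terms in total.
    """
    with importlib.resources.as_file(_data_path(_SOCIAL_FIXTURE)) as p:
        return pd.read_csv(p, sep="\t")


def load_sporulation_signature() -> list:
    """The 66 sporulation signature gene identifiers (synthetic stand-in)."""
    with importlib.resources.as_file(_data_path(_SPORULATION_FIXTURE)) as p:
        return pd.read_csv(p, sep="\t")["gene"].tolist()


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def read_annotation_table(path) -> pd.DataFrame:
    """Read a gene annotation TSV (species, gene_id, localization,
    go_terms, gram); go_terms is a semicolon-separated list, possibly
    empty."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"species", "gene_id", "localization", "go_terms", "gram"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"annotation table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["species", "gene_id"])
    if dup.any():
        raise DataError("duplicate gene ids within species")
    return df


def read_hit_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"species", "gene", "evalue"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"hit table missing columns: {sorted(missing)}")
    return df


def _gene_terms(go_field: str) -> set:
    if not go_field or pd.isna(go_field):
        return set()
    return {t for t in str(go_field).split(";") if t}


def count_secretome(table: pd.DataFrame, species: str):
    """Secretome size and gram profile for one species.

    Returns ``(count, gram)``; the gram profile travels with the count
    because the localization predictor differs between Gram-positive
    and Gram-negative organisms and the downstream model needs it as an
    intercept term.
    """
    sub = table[table["species"] == species]
    if sub.empty:
        raise DataError(f"species {species!r} absent from annotation table")
    gram_values = set(sub["gram"].astype(str))
    if gram_values - {"positive", "negative"}:
        raise DataError(
            f"species {species!r}: missing or invalid gram profile {gram_values}"
        )
    if len(gram_values) != 1:
        raise DataError(f"species {species!r}: inconsistent gram profile")
    count = int((sub["localization"] == "extracellular").sum())
    return count, gram_values.pop()


# ---------------------------------------------------------------------------
# Social GO term sets
# ---------------------------------------------------------------------------

@dataclass
class SocialTermSets:
    """Per-class sets of social ontology terms with provenance.

    ``terms`` maps class name -> set of term ids; ``provenance`` maps
    (class, term) -> how the term entered ('keyword', 'descendant',
    'parent', 'curated_in') or left ('curated_out') the set.
    """

    terms: dict
    provenance: dict = field(default_factory=dict)

    @property
    def union(self) -> set:
        out = set()
        for s in self.terms.values():
            out |= s
        return out

    def counts(self) -> dict:
        return {c: len(s) for c, s in self.terms.items()}


def social_term_sets_from_curated(curated: pd.DataFrame = None) -> SocialTermSets:
    """Build term sets directly from a curated list table (class,
    term_id[, name]); defaults to the shipped 118-term fixture."""
    if curated is None:
        curated = load_social_go_terms()
    terms, prov = {}, {}
    for c in SOCIAL_CLASSES:
        ids = set(curated.loc[curated["class"] == c, "term_id"])
        terms[c] = ids
        for t in ids:
            prov[(c, t)] = "curated_in"
    return SocialTermSets(terms=terms, provenance=prov)


def read_ontology(path) -> nx.DiGraph:
    """Read an ontology TSV (term_id, name, parent_ids) into a DiGraph.

    Edges point parent -> child. ``parent_ids`` is a pipe- or
    semicolon-separated list, empty for roots.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"term_id", "name", "parent_ids"}
    if required - set(df.columns):
        raise DataError("ontology table needs columns term_id, name, parent_ids")
    g = nx.DiGraph()
    for _, row in df.iterrows():
        g.add_node(row["term_id"], name=row["name"])
    for _, row in df.iterrows():
        for parent in str(row["parent_ids"]).replace(";", "|").split("|"):
            parent = parent.strip()
            if parent:
                g.add_edge(parent, row["term_id"])
    return g


def build_social_term_sets(
    ontology: nx.DiGraph,
    keywords: dict,
    curation_include: dict = None,
    curation_exclude: dict = None,
    transitive_descendants: bool = True,
) -> SocialTermSets:
    """Keyword-match ontology terms and expand to relatives, per class.

    For each class, terms whose *name* contains any keyword
    (case-insensitive substring) are matched; the set is expanded with
    their descendants (all transitive descendants by default, direct
    children with ``transitive_descendants=False``) and the direct
    parents of matched terms. Curation include/exclude lists are applied
    last, so an exclusion removes a term even if keyword-matched, but
    does not touch independently matched relatives.
    """
    if not nx.is_directed_acyclic_graph(ontology):
        raise DataError("ontology graph is cyclic over is_a edges")
    curation_include = curation_include or {}
    curation_exclude = curation_exclude or {}
    names = {n: str(d.get("name", "")).lower() for n, d in ontology.nodes(data=True)}
    terms, prov = {}, {}
    for cls, kws in keywords.items():
        kws_l = [k.lower() for k in kws]
        matched = {t for t, nm in names.items() if any(k in nm for k in kws_l)}
        selected = {}
        for t in matched:
            selected[t] = "keyword"
        for t in matched:
            if transitive_descendants:
                rel = nx.descendants(ontology, t)
            else:
                rel = set(ontology.successors(t))
            for d in rel:
                selected.setdefault(d, "descendant")
            for p in ontology.predecessors(t):
                selected.setdefault(p, "parent")
        for t in curation_include.get(cls, ()):  # manual additions
            selected.setdefault(t, "curated_in")
        for t in curation_exclude.get(cls, ()):  # manual removals win
            if t in selected:
                del selected[t]
                prov[(cls, t)] = "curated_out"
        terms[cls] = set(selected)
        for t, why in selected.items():
            prov[(cls, t)] = why
    return SocialTermSets(terms=terms, provenance=prov)


def count_cooperative_genes(table: pd.DataFrame, sets: SocialTermSets, species: str) -> dict:
    """Per-class cooperative gene counts for one species.

    A gene counts once toward a class if *at least one* of its terms is
    in that class's set, regardless of how many match; a gene may count
    toward several classes.
    """
    sub = table[table["species"] == species]
    counts = {c: 0 for c in sets.terms}
    for go_field in sub["go_terms"]:
        gene_terms = _gene_terms(go_field)
        if not gene_terms:
            continue
        for c, term_set in sets.terms.items():
            if gene_terms & term_set:
                counts[c] += 1
    return counts


# ---------------------------------------------------------------------------
# Sporulation score
# ---------------------------------------------------------------------------

def sporulation_score(
    hits: pd.DataFrame,
    species: str = None,
    signature=None,
    evalue_cutoff: float = 1e-10,
) -> float:
    """Fraction of signature sporulation genes with a qualifying hit.

    A signature gene is present iff it has at least one hit with
    e-value <= cutoff (the boundary value qualifies); gene copy number
    is ignored — a gene hit twice scores the same as a gene hit once.
    """
    if signature is None:
        signature = load_sporulation_signature()
    signature = list(signature)
    sub = hits if species is None else hits[hits["species"] == species]
    unknown = set(sub["gene"]) - set(signature)
    if unknown:
        raise DataError(f"hits reference unknown signature genes: {sorted(unknown)[:5]}")
    present = set(sub.loc[sub["evalue"].astype(float) <= evalue_cutoff, "gene"])
    return len(present) / len(signature)


# ---------------------------------------------------------------------------
# The full trait table
# ---------------------------------------------------------------------------

def build_cooperation_counts(
    annotation: pd.DataFrame,
    hits: pd.DataFrame,
    sets: SocialTermSets = None,
    abundance: pd.DataFrame = None,
    signature=None,
    evalue_cutoff: float = 1e-10,
) -> pd.DataFrame:
    """Assemble the per-species trait table used by the models.

    Columns: species, secretome, the five class counts, total_cds, gram,
    sporulation_score, mean_relative_abundance. ``abundance`` (optional)
    is a table with columns species, host, abundance; its per-species
    mean fills the last column (NaN when absent).
    """
    if sets is None:
        sets = social_term_sets_from_curated()
    rows = []
    mean_ab = {}
    if abundance is not None:
        mean_ab = abundance.groupby("species")["abundance"].mean().to_dict()
    for species in annotation["species"].unique():
        sec, gram = count_secretome(annotation, species)
        class_counts = count_cooperative_genes(annotation, sets, species)
        total = int((annotation["species"] == species).sum())
        score = sporulation_score(
            hits, species=species, signature=signature, evalue_cutoff=evalue_cutoff
        )
        rows.append(
            (
                species,
                sec,
                *[class_counts[c] for c in SOCIAL_CLASSES],
                total,
                gram,
                score,
                mean_ab.get(species, np.nan),
            )
        )
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


def read_cooperation_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"cooperation counts missing columns: {sorted(missing)}")
    return df
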