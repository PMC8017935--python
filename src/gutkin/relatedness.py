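"""FST-like genetic relatedness from per-host allele-frequency panels.

For a species *s* observed in a set of hosts, relatedness of the
subpopulation in host *h* is

    r_{s,h} = (S_w - S_a) / (1 - S_a),

where ``S_w`` is the average within-host genomic similarity (the
probability that two random haploid individuals from the host carry the
same allele at a random core-genome site) and ``S_a`` the same quantity
for the pooled across-host population. Similarity at a site with allele
frequencies ``p`` is ``sum(p**2)`` — the probability of identity by
state, i.e. one minus the per-site genetic diversity — and ``S`` averages
it over the core genome. Core sites are those present in more than a
prevalence threshold (default 90%) of the hosts carrying the species.

A positive ``r`` means two cells sharing a gut are genetically closer
than two random members of the global population, exactly the statistical
association Hamilton's coefficient of relatedness describes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, UndefinedRelatednessError
from .panels import AlleleFrequencyPanel

logger = logging.getLogger(__name__)

_MONOMORPHIC_TOL = 1e-12

TABLE_COLUMNS = ["species", "host", "s_within", "s_across", "r", "n_core_sites"]
SUMMARY_COLUMNS = ["species", "mean_r", "n_hosts", "n_core_sites"]


def select_core_sites(panel: AlleleFrequencyPanel, prevalence_threshold: float = 0.90) -> np.ndarray:
    """Boolean mask of core sites: present in > threshold of the hosts.

    The inequality is strict, so with 10 hosts a site present in exactly
    9 (prevalence 0.90) is dropped at the default threshold.
    """
    if panel.n_hosts < 1:
        raise DataError(f"{panel.species}: empty panel")
    prevalence = panel.presence.sum(axis=0) / panel.n_hosts
    return prevalence > prevalence_threshold


def genomic_similarity(
    freqs: np.ndarray,
    mask: np.ndarray = None,
    depth: np.ndarray = None,
    bias_corrected: bool = False,
) -> float:
    """Average probability of identity by state over the selected sites.

    Parameters
    ----------
    freqs : ndarray, shape (n_sites, 4)
        Per-site allele frequencies.
    mask : ndarray of bool, optional
        Sites to include; defaults to all.
    depth : ndarray, shape (n_sites,), optional
        Number of haploid individuals behind each frequency vector.
        Required when ``bias_corrected`` is true.
    bias_corrected : bool
        When true, return the distinct-pair (without replacement)
        identity ``(n * sum(p**2) - 1) / (n - 1)`` per site instead of
        the plain ``sum(p**2)``. The uncorrected form matches the
        similarity definition used on read-derived frequencies, where
        the sampled pool is effectively infinite; the corrected form is
        the right estimand when frequencies come from a small counted
        population such as a simulated deme.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 2 or freqs.shape[1] != 4:
        raise DataError("freqs must have shape (n_sites, 4)")
    if mask is None:
        mask = np.ones(freqs.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise DataError("no usable sites for similarity")
    per_site = np.sum(freqs[mask] ** 2, axis=1)
    if bias_corrected:
        if depth is None:
            raise DataError("bias correction requires per-site depth")
        n = np.asarray(depth, dtype=float)[mask]
        if np.any(n < 2):
            raise DataError("bias correction requires depth >= 2 at every site")
        per_site = (n * per_site - 1.0) / (n - 1.0)
    return float(per_site.mean())


def pooled_frequencies(
    panel: AlleleFrequencyPanel,
    mask: np.ndarray = None,
    depth_weighted: bool = True,
):
    """Across-host pooled allele frequencies per site.

    Pools the hosts in which each site is present, weighting each host's
    frequency vector by its read depth (mirroring pooling reads across
    samples); ``depth_weighted=False`` averages hosts equally instead.

    Returns ``(pooled, pooled_depth)`` where ``pooled`` has shape
    (n_selected_sites, 4) and ``pooled_depth`` the summed depth per
    selected site.
    """
    if panel.n_hosts < 2:
        raise DataError(f"{panel.species}: pooling requires at least two hosts")
    if mask is None:
        mask = np.ones(panel.n_sites, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    presence = panel.presence[:, mask]
    freqs = panel.freqs[:, mask, :]
    if depth_weighted:
        w = panel.depth[:, mask] * presence
    else:
        w = presence.astype(float)
    total = w.sum(axis=0)
    if np.any(total <= 0):
        bad = int(np.sum(total <= 0))
        raise DataError(
            f"{panel.species}: {bad} selected site(s) have zero total depth"
        )
    pooled = np.einsum("hs,hsa->sa", w, freqs) / total[:, None]
    pooled_depth = (panel.depth[:, mask] * presence).sum(axis=0)
    return pooled, pooled_depth


def relatedness(s_within: float, s_across: float) -> float:
    """Relatedness r = (S_w - S_a) / (1 - S_a).

    Equals 1 iff the host subpopulation is fully monomorphic at the core
    sites, 0 when the host mirrors the pooled population. Undefined when
    the pooled population is itself monomorphic (S_a = 1).
    """
    if not (0.0 <= s_across <= 1.0) or not (s_within <= 1.0 + 1e-12):
        raise DataError(f"similarities out of range: {s_within}, {s_across}")
    if s_across >= 1.0 - _MONOMORPHIC_TOL:
        raise UndefinedRelatednessError(
            "pooled population monomorphic (S_across = 1); relatedness undefined"
        )
    return (s_within - s_across) / (1.0 - s_across)


@dataclass
class RelatednessResult:
    """Per-(species, host) relatedness plus per-species summary.

    ``table`` has one row per retained (species, host); ``summary`` one
    row per retained species with the unweighted mean of r over hosts;
    ``dropped`` records every excluded species with the reason.
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    dropped: list

    def write(self, table_path, summary_path) -> None:
        self.table.to_csv(table_path, sep="\t", index=False)
        self.summary.to_csv(summary_path, sep="\t", index=False)


def read_relatedness_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "host": str})
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"relatedness table missing columns: {sorted(missing)}")
    return df


def build_relatedness_table(
    panels,
    prevalence_threshold: float = 0.90,
    min_hosts: int = 2,
    min_core_sites: int = 100,
    bias_corrected: bool = False,
    depth_weighted: bool = True,
) -> RelatednessResult:
    """Run the full relatedness stage over a collection of panels.

    Per species: select core sites, drop the species if it is carried by
    fewer than ``min_hosts`` hosts (relatedness needs a within/across
    contrast) or retains fewer than ``min_core_sites`` core sites (very
    small effective core genome), then compute within-host and pooled
    similarity and r per host. Within-host similarity for host h uses
    only the core sites actually present in h. Species whose pooled core
    genome is monomorphic are dropped with a logged reason, never
    silently.
    """
    if not panels:
        raise DataError("no panels supplied")
    rows, summary_rows, dropped = [], [], []
    for panel in panels:
        n_hosts = int(panel.presence.any(axis=1).sum())
        if n_hosts < min_hosts:
            dropped.append((panel.species, f"present in {n_hosts} host(s) < {min_hosts}"))
            logger.info("dropping %s: %s", panel.species, dropped[-1][1])
            continue
        core = select_core_sites(panel, prevalence_threshold)
        n_core = int(core.sum())
        if n_core < min_core_sites:
            dropped.append(
                (panel.species, f"{n_core} core sites < {min_core_sites}")
            )
            logger.info("dropping %s: %s", panel.species, dropped[-1][1])
            continue
        pooled, pooled_depth = pooled_frequencies(panel, core, depth_weighted)
        try:
            s_across = genomic_similarity(
                pooled,
                depth=pooled_depth if bias_corrected else None,
                bias_corrected=bias_corrected,
            )
            # probe for global monomorphism before the per-host loop
            relatedness(0.0, s_across)
        except UndefinedRelatednessError:
            dropped.append((panel.species, "pooled core genome monomorphic"))
            logger.info("dropping %s: %s", panel.species, dropped[-1][1])
            continue
        host_rs = []
        for h, host in enumerate(panel.hosts):
            present_core = core & panel.presence[h]
            if present_core.sum() == 0:
                continue
            s_within = genomic_similarity(
                panel.freqs[h],
                present_core,
                depth=panel.depth[h] if bias_corrected else None,
                bias_corrected=bias_corrected,
            )
            r = relatedness(s_within, s_across)
            rows.append(
                (panel.species, host, s_within, s_across, r, int(present_core.sum()))
            )
            host_rs.append(r)
        if host_rs:
            # unweighted arithmetic mean over hosts
            summary_rows.append(
                (panel.species, float(np.mean(host_rs)), len(host_rs), n_core)
            )
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    summary = pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS)
    return RelatednessResult(table=table, summary=summary, dropped=dropped)
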