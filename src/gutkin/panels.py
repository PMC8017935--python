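"""Per-species allele-frequency panels.

An :class:`AlleleFrequencyPanel` holds, for one bacterial species, the
per-host allele frequencies at every genomic site retained by the upstream
strain profiler: a ``hosts x sites x 4`` array over the A/C/G/T allele
space, together with a presence mask and a read-depth matrix. It is the
substrate from which within-host and across-host genomic similarity, and
hence relatedness, are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

ALLELES = ("A", "C", "G", "T")

#: Columns of the on-disk long-format panel table.
PANEL_COLUMNS = [
    "species",
    "host",
    "site_id",
    "ref_allele",
    "freq_A",
    "freq_C",
    "freq_G",
    "freq_T",
    "depth",
]

_FREQ_TOL = 1e-9


@dataclass
class AlleleFrequencyPanel:
    """Host x site x allele frequency array for one species.

    Attributes
    ----------
    species : str
        Species identifier.
    hosts : list of str
        Host (sample) identifiers, one per row of ``freqs``.
    sites : list of str
        Site identifiers, one per column of ``freqs``.
    freqs : ndarray, shape (n_hosts, n_sites, 4)
        Allele frequencies in A, C, G, T order. Rows for absent
        (host, site) combinations are ignored.
    presence : ndarray of bool, shape (n_hosts, n_sites)
        Whether the site passed coverage requirements in that host.
    depth : ndarray, shape (n_hosts, n_sites)
        Read depth (or haploid sample size) behind each frequency
        estimate; zero where absent.
    """

    species: str
    hosts: list
    sites: list
    freqs: np.ndarray
    presence: np.ndarray
    depth: np.ndarray
    ref_alleles: list = field(default=None)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.presence = np.asarray(self.presence, dtype=bool)
        self.depth = np.asarray(self.depth, dtype=float)
        n_h, n_s = len(self.hosts), len(self.sites)
        if self.freqs.shape != (n_h, n_s, 4):
            raise DataError(
                f"{self.species}: freqs shape {self.freqs.shape} does not "
                f"match ({n_h}, {n_s}, 4)"
            )
        if self.presence.shape != (n_h, n_s) or self.depth.shape != (n_h, n_s):
            raise DataError(f"{self.species}: presence/depth shape mismatch")
        if np.any(self.depth < 0):
            raise DataError(f"{self.species}: negative depth")
        if self.ref_alleles is None:
            self.ref_alleles = ["A"] * n_s
        self.validate_frequencies()

    @property
    def n_hosts(self) -> int:
        return len(self.hosts)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def validate_frequencies(self, tol: float = _FREQ_TOL) -> None:
        """Check that frequencies sum to one at every present (host, site)."""
        if self.presence.any():
            sums = self.freqs.sum(axis=2)[self.presence]
            if np.any(np.abs(sums - 1.0) > tol):
                worst = float(np.max(np.abs(sums - 1.0)))
                raise DataError(
                    f"{self.species}: allele frequencies do not sum to 1 "
                    f"(max deviation {worst:.3g})"
                )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per present (host, site)."""
        rows = []
        h_idx, s_idx = np.nonzero(self.presence)
        for h, s in zip(h_idx, s_idx):
            rows.append(
                (
                    self.species,
                    self.hosts[h],
                    self.sites[s],
                    self.ref_alleles[s],
                    *self.freqs[h, s],
                    self.depth[h, s],
                )
            )
        return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def write_panels(panels, path) -> None:
    """Write one or more panels to a single long-format TSV."""
    frames = [p.to_frame() for p in panels]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_panels(path):
    """Read panels from a long-format TSV; returns a list, one per species.

    Host and site order follow first appearance in the file, so a
    write/read round trip preserves ordering.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "host": str, "site_id": str})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"panel table missing columns: {sorted(missing)}")
    panels = []
    for species, sub in df.groupby("species", sort=False):
        hosts = list(dict.fromkeys(sub["host"]))
        sites = list(dict.fromkeys(sub["site_id"]))
        h_pos = {h: i for i, h in enumerate(hosts)}
        s_pos = {s: i for i, s in enumerate(sites)}
        freqs = np.zeros((len(hosts), len(sites), 4))
        presence = np.zeros((len(hosts), len(sites)), dtype=bool)
        depth = np.zeros((len(hosts), len(sites)))
        refs = [None] * len(sites)
        hi = sub["host"].map(h_pos).to_numpy()
        si = sub["site_id"].map(s_pos).to_numpy()
        freqs[hi, si] = sub[["freq_A", "freq_C", "freq_G", "freq_T"]].to_numpy()
        presence[hi, si] = True
        depth[hi, si] = sub["depth"].to_numpy()
        for s, ref in zip(si, sub["ref_allele"]):
            refs[s] = ref
        panels.append(
            AlleleFrequencyPanel(
                species=str(species),
                hosts=hosts,
                sites=sites,
                freqs=freqs,
                presence=presence,
                depth=depth,
                ref_alleles=refs,
            )
        )
    if not panels:
        raise DataError(f"no panels found in {path}")
    return panels
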