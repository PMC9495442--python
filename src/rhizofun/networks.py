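"""Co-occurrence networks with the robust-correlation edge rule.

For one group's samples, every unordered OTU pair is scored by Pearson
correlation of relative abundances; two-sided p-values come from the exact
t-transform with n-2 degrees of freedom and are Benjamini-Hochberg
adjusted within the network.  Edges require |r| above the r threshold AND
adjusted p below the q threshold.  Summaries report edges, vertices
(OTUs incident to at least one edge) and positive edges, plus how many
pairs survive each criterion separately — with five samples per group the
attainable p-values are coarse, so the two filters must be diagnosable
independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .subcommunities import (
    extract_subcommunity,
    partition_local,
    partition_regional,
    relative_abundance,
)
from .tables import OtuTable, SampleDesign

SUBCOMMUNITY_LEVELS = (
    "whole",
    "locally_abundant",
    "locally_rare",
    "regionally_abundant",
    "regionally_rare",
)


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class NetworkSummary:
    group: str | None
    level: str | None
    edges: pd.DataFrame  # columns otu_i, otu_j, r, p, q (i < j by position)
    n_otus_considered: int
    n_otus_tested: int
    n_pairs_tested: int
    n_pass_r: int
    n_pass_q: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_vertices(self) -> int:
        if self.edges.empty:
            return 0
        return len(set(self.edges["otu_i"]) | set(self.edges["otu_j"]))

    @property
    def n_positive_edges(self) -> int:
        return int((self.edges["r"] > 0).sum())

    def as_graph(self):
        """Edge list as a :mod:`networkx` graph (r and q as attributes)."""
        import networkx as nx

        g = nx.Graph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.otu_i, row.otu_j, r=row.r, q=row.q)
        return g

    def to_row(self) -> dict:
        return {
            "group": self.group,
            "level": self.level,
            "edges": self.n_edges,
            "vertices": self.n_vertices,
            "positive_edges": self.n_positive_edges,
            "pairs_tested": self.n_pairs_tested,
            "pass_r": self.n_pass_r,
            "pass_q": self.n_pass_q,
        }


_EMPTY_EDGES = pd.DataFrame(columns=["otu_i", "otu_j", "r", "p", "q"])


def pearson_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t-transform with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def build_network(
    otu: OtuTable,
    cfg: AnalysisConfig | None = None,
    group: str | None = None,
    level: str | None = None,
) -> NetworkSummary:
    """Score all OTU pairs within one set of samples and keep robust edges."""
    cfg = cfg or AnalysisConfig()
    n_samples = len(otu.sample_ids)
    if n_samples < 3:
        raise ValueError("network construction needs at least 3 samples")
    counts = otu.counts
    n_considered = counts.shape[0]
    occupancy = (counts > 0).sum(axis=1)
    counts = counts.loc[occupancy >= cfg.network_min_occupancy]
    if cfg.network_on_relative:
        totals = otu.counts.sum(axis=0).replace(0, 1)
        mat = counts.div(totals, axis=1)
    else:
        mat = counts.astype(float)
    # correlation is undefined for rows constant across these samples
    mat = mat.loc[mat.std(axis=1) > 0]
    k = mat.shape[0]
    if k < 2:
        return NetworkSummary(group, level, _EMPTY_EDGES.copy(), n_considered, k, 0, 0, 0)
    X = mat.to_numpy()
    C = np.corrcoef(X)
    iu = np.triu_indices(k, 1)
    r = np.clip(C[iu], -1.0, 1.0)
    p = pearson_pvalues(r, n_samples)
    q = fdr_bh(p)
    pass_r = np.abs(r) > cfg.network_r_threshold
    pass_q = q < cfg.network_q_threshold
    keep = pass_r & pass_q
    ids = mat.index.to_numpy()
    edges = pd.DataFrame(
        {
            "otu_i": ids[iu[0][keep]],
            "otu_j": ids[iu[1][keep]],
            "r": r[keep],
            "p": p[keep],
            "q": q[keep],
        }
    )
    return NetworkSummary(
        group=group,
        level=level,
        edges=edges,
        n_otus_considered=n_considered,
        n_otus_tested=k,
        n_pairs_tested=len(r),
        n_pass_r=int(pass_r.sum()),
        n_pass_q=int(pass_q.sum()),
    )


def subcommunity_tables(
    otu: OtuTable, cfg: AnalysisConfig | None = None
) -> dict[str, OtuTable]:
    """The whole table plus its four abundance-class restrictions.

    Partitions are computed on the full sample set; per-group restriction
    happens afterwards so a taxon's class is consistent across groups.
    """
    cfg = cfg or AnalysisConfig()
    rel = relative_abundance(otu)
    local = partition_local(rel, cfg)
    regional = partition_regional(rel, cfg, otu=otu)
    import warnings as _warnings

    out = {"whole": otu}
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # empty subcommunities handled downstream
        out["locally_abundant"] = extract_subcommunity(otu, local, "abundant")
        out["locally_rare"] = extract_subcommunity(otu, local, "rare")
        out["regionally_abundant"] = extract_subcommunity(otu, regional, "abundant")
        out["regionally_rare"] = extract_subcommunity(otu, regional, "rare")
    return out


def network_battery(
    otu: OtuTable,
    design: SampleDesign,
    cfg: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], NetworkSummary]]:
    """Per (subcommunity level x group) network summaries.

    Returns the summary table (one row per level and group, mirroring the
    edges / vertices / positive-edges layout) and the full summaries keyed
    by (level, group).
    """
    cfg = cfg or AnalysisConfig()
    tables = subcommunity_tables(otu, cfg)
    rows = []
    summaries: dict[tuple[str, str], NetworkSummary] = {}
    for level in SUBCOMMUNITY_LEVELS:
        table = tables[level]
        for grp in design.groups:
            samples = design.samples_in_group(grp)
            if table.n_taxa == 0:
                summary = NetworkSummary(
                    grp, level, _EMPTY_EDGES.copy(), 0, 0, 0, 0, 0
                )
            else:
                summary = build_network(
                    table.subset_samples(samples), cfg, group=grp, level=level
                )
            summaries[(level, grp)] = summary
            rows.append(summary.to_row())
    return pd.DataFrame(rows), summaries
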