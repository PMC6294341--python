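"""Compound similarity: pairwise TCS correlation, clustering, MOA networks.

Compounds with the same mechanism of action induce similar transcriptional
responses, so their consensus signatures correlate strongly.  Pairwise
Pearson correlation over the full gene-length score vectors (shared zeros
included), thresholded at r >= 0.7, yields a network whose connected
components group compounds by mechanism; average-linkage hierarchical
clustering on 1 - r gives a complementary flat partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .consensus import ConsensusSignature

__all__ = [
    "CompoundNetwork",
    "pairwise_tcs_correlation",
    "build_network",
    "hierarchical_cluster",
]


@dataclass
class CompoundNetwork:
    """Undirected compound-similarity network at a correlation threshold."""

    graph: nx.Graph
    threshold: float
    components: pd.Series  # node -> component label (smallest member id)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "pearson_r": data["pearson_r"]}
            for u, v, data in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "pearson_r"])
        return df.sort_values(["source", "target"]).reset_index(drop=True)

    def nontrivial_components(self) -> list[set]:
        return [c for c in nx.connected_components(self.graph) if len(c) > 1]


def pairwise_tcs_correlation(tcs_set: list[ConsensusSignature]) -> pd.DataFrame:
    """Pearson correlation of every compound pair's full TCS score vector.

    Correlation is over all genes, zeros included (the TCS is a fixed-length
    vector).  An all-zero (zero-variance) TCS has no defined correlation;
    its row/column is NaN (flagged with a warning), never fabricated.
    """
    if len(tcs_set) < 2:
        raise ValueError("need at least 2 compounds")
    ids = [t.compound_id for t in tcs_set]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids in correlation input")
    genes = tcs_set[0].score.index
    mat = np.stack([t.score.reindex(genes).to_numpy(dtype=float) for t in tcs_set])
    sd = mat.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        bad = [ids[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"zero-variance TCS, correlation undefined for: {bad}", UserWarning, stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(corr, np.where(degenerate, np.nan, 1.0))
    return pd.DataFrame(corr, index=ids, columns=ids)


def build_network(corr: pd.DataFrame, threshold: float = 0.7) -> CompoundNetwork:
    """Threshold a correlation matrix into a mechanism-of-action network.

    An edge joins compounds i, j iff r_ij >= threshold (inclusive).  Isolated
    nodes are retained; components are labeled by their lexicographically
    smallest member, so labels do not depend on input order.
    """
    if corr.shape[0] != corr.shape[1] or list(corr.index) != list(corr.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    g = nx.Graph()
    g.add_nodes_from(corr.index)
    vals = corr.to_numpy(dtype=float)
    ids = list(corr.index)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = vals[i, j]
            if np.isfinite(r) and r >= threshold:
                g.add_edge(ids[i], ids[j], pearson_r=float(r))
    labels = {}
    for comp in nx.connected_components(g):
        rep = min(comp)
        for node in comp:
            labels[node] = rep
    components = pd.Series(labels, name="component").loc[ids]
    return CompoundNetwork(graph=g, threshold=threshold, components=components)


def hierarchical_cluster(
    corr: pd.DataFrame,
    k: int | None = None,
    cut_height: float | None = None,
    linkage: str = "average",
) -> pd.Series:
    """Cluster compounds on the 1 - r distance by agglomerative linkage.

    Exactly one of ``k`` (number of clusters) or ``cut_height`` (dendrogram
    cut on 1 - r) must be given.  NaN correlations (zero-variance TCS) are
    assigned the maximal distance 2 with a warning.  Labels are integers,
    deterministic for a fixed input order.
    """
    if (k is None) == (cut_height is None):
        raise ValueError("specify exactly one of k or cut_height")
    ids = list(corr.index)
    dist = 1.0 - corr.to_numpy(dtype=float)
    if np.isnan(dist).any():
        warnings.warn(
            "missing correlations; treating them as maximal distance 2",
            UserWarning,
            stacklevel=2,
        )
        dist = np.where(np.isnan(dist), 2.0, dist)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices(len(ids), k=1)]
    tree = hierarchy.linkage(condensed, method=linkage)
    if k is not None:
        labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(tree, t=cut_height, criterion="distance")
    return pd.Series(labels, index=ids, name="cluster")
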