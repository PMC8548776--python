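"""Co-occurrence network of core features from thresholded Spearman correlations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats


class NetworkError(ValueError):
    pass


def spearman_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Midrank Spearman correlation between all feature pairs.

    ``values`` is features x samples.  Constant features have undefined
    correlations, recorded as NaN against every partner (diagonal stays 1).
    """
    arr = values.to_numpy(dtype=float)
    if arr.shape[1] < 4 or arr.shape[0] < 2:
        raise NetworkError("need >= 2 features and >= 4 samples")
    ranks = np.apply_along_axis(stats.rankdata, 1, arr)
    constant = np.ptp(arr, axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=values.index, columns=values.index)


def build_network(rho: pd.DataFrame, threshold: float = 0.8,
                  node_attrs: pd.DataFrame | None = None) -> nx.Graph:
    """Undirected graph with an edge wherever |rho| exceeds the threshold.

    The boundary is strict: |rho| must be greater than ``threshold`` (a pair
    at exactly the threshold gets no edge).  Isolated nodes are retained so
    the node set always equals the feature set.  Each edge carries the rho
    value and its sign ("positive"/"negative").
    """
    if not 0 < threshold <= 1:
        raise NetworkError("threshold must lie in (0, 1]")
    mat = rho.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(
            np.nan_to_num(mat), np.nan_to_num(mat.T), atol=1e-10):
        raise NetworkError("correlation matrix must be square and symmetric")
    graph = nx.Graph()
    features = list(rho.index)
    for i, fid in enumerate(features):
        attrs = {}
        if node_attrs is not None and fid in node_attrs.index:
            attrs = node_attrs.loc[fid].to_dict()
        graph.add_node(fid, **attrs)
    iu, ju = np.triu_indices(len(features), k=1)
    for i, j in zip(iu, ju):
        r = mat[i, j]
        if np.isfinite(r) and abs(r) > threshold:
            graph.add_edge(features[i], features[j], rho=float(r),
                           sign="positive" if r > 0 else "negative")
    return graph


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    """Edge list as a DataFrame (feature_a, feature_b, rho, sign)."""
    rows = [(a, b, d["rho"], d["sign"]) for a, b, d in graph.edges(data=True)]
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "rho", "sign"])


def write_network(graph: nx.Graph, edge_path=None, graphml_path=None) -> None:
    if edge_path is not None:
        edge_table(graph).to_csv(edge_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
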