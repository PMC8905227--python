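"""Weighted co-expression network: soft-threshold selection, adjacency
thresholding into an edge list, and hub nomination.

Adjacency is the unsigned WGCNA form |pearson r|^beta.  The soft power is
chosen as the smallest candidate whose connectivity distribution fits a
scale-free law (R² of log10 freq(k) vs log10 k over binned connectivity) at
the requested target, echoing the convention of picking beta where the fit
first exceeds 0.9.  Edges are adjacency >= cutoff (default 0.9); hubs are
lncRNA nodes ranked by (protein-coding) neighbour count.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


def adjacency_matrix(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """|pearson correlation|^beta across features (rows = features)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    variances = expr.var(axis=1)
    kept = expr.loc[variances > 0]
    if len(kept) < len(expr):
        warnings.warn(f"dropped {len(expr) - len(kept)} constant-expression features")
    corr = np.corrcoef(kept.to_numpy(dtype=float))
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=kept.index, columns=kept.index)


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> float:
    """R² of the log-log connectivity histogram (empty bins dropped)."""
    k = adj.to_numpy().sum(axis=1)
    k = k[k > 0]
    if len(k) < 3:
        return 0.0
    counts, edges = np.histogram(k, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = (counts > 0) & (centers > 0)
    if ok.sum() < 3:
        return 0.0
    x, y = np.log10(centers[ok]), np.log10(counts[ok])
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2) if np.isfinite(r) else 0.0


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16),
    r2_target: float = 0.9,
) -> tuple[int, pd.DataFrame]:
    """Smallest power reaching the scale-free R² target; else argmax with warning."""
    if expr.shape[1] < 8:
        raise ValueError("need >= 8 samples for soft-threshold selection")
    rows = []
    for p in candidate_powers:
        r2 = scale_free_fit(adjacency_matrix(expr, p))
        rows.append({"power": p, "scale_free_r2": r2})
    fit = pd.DataFrame(rows)
    reaching = fit.loc[fit.scale_free_r2 >= r2_target, "power"]
    if len(reaching):
        beta = int(reaching.iloc[0])
    else:
        beta = int(fit.loc[fit.scale_free_r2.idxmax(), "power"])
        warnings.warn(f"no candidate power reached R² >= {r2_target}; using argmax beta={beta}")
    return beta, fit


@dataclass
class CoexpressionNetwork:
    graph: nx.Graph
    beta: float
    edge_cutoff: float
    node_kinds: dict = field(default_factory=dict)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(a, b), max(a, b), d["weight"]) for a, b, d in self.graph.edges(data=True)
        )

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": a,
                "target": b,
                "weight": w,
                "source_kind": self.node_kinds.get(a, "PCG"),
                "target_kind": self.node_kinds.get(b, "PCG"),
            }
            for a, b, w in self.edges
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "source_kind", "target_kind"])


def build_network(
    expr: pd.DataFrame,
    beta: float,
    edge_cutoff: float = 0.9,
    node_kinds: dict | None = None,
) -> CoexpressionNetwork:
    """Threshold the adjacency into a weighted undirected graph."""
    if not 0.0 <= edge_cutoff <= 1.0:
        raise ValueError("edge_cutoff must be in [0, 1]")
    adj = adjacency_matrix(expr, beta)
    ids = list(adj.index)
    g = nx.Graph()
    g.add_nodes_from(ids)
    arr = adj.to_numpy()
    ii, jj = np.where(np.triu(arr >= edge_cutoff, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(ids[i], ids[j], weight=float(arr[i, j]))
    return CoexpressionNetwork(
        graph=g, beta=beta, edge_cutoff=edge_cutoff, node_kinds=dict(node_kinds or {})
    )


def find_hubs(
    network: CoexpressionNetwork,
    top_n: int | None = 3,
    min_degree: int | None = None,
    restrict_kind: str = "lncRNA",
    neighbor_kind: str = "PCG",
) -> pd.DataFrame:
    """Rank candidate regulator nodes by neighbour count.

    Only nodes of ``restrict_kind`` are eligible; the reported degree counts
    neighbours of ``neighbor_kind`` (or all neighbours when None).  Ties
    break deterministically by node id.
    """
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    kinds = network.node_kinds
    rows = []
    for node in network.graph.nodes:
        if restrict_kind is not None and kinds.get(node, "PCG") != restrict_kind:
            continue
        neigh = list(network.graph.neighbors(node))
        n_kind = (
            len(neigh)
            if neighbor_kind is None
            else sum(kinds.get(x, "PCG") == neighbor_kind for x in neigh)
        )
        rows.append({"node": node, "degree": len(neigh), "neighbor_count": n_kind})
    hubs = pd.DataFrame(rows, columns=["node", "degree", "neighbor_count"])
    hubs = hubs.sort_values(["neighbor_count", "node"], ascending=[False, True]).reset_index(drop=True)
    if min_degree is not None:
        hubs = hubs[hubs.neighbor_count >= min_degree].reset_index(drop=True)
    elif top_n is not None:
        hubs = hubs.head(top_n)
    return hubs
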