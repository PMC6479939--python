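"""Methanogen–environment co-occurrence networks from MIC association.

Species-level relative abundances and per-sample environmental factors
(acetate, δ13CO2, total C, available K/N/P, ...) are scored pairwise
with the maximal information coefficient; pairs at or above a threshold
become undirected edges.  MIC is unsigned, so each edge carries the
sign of a rank correlation (Spearman by default) computed on the same
pair, and edges among methanogens are classed apart from edges touching
environmental factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .mic import NetworkConfig, mic

__all__ = [
    "NetworkConfig",
    "AbundanceTable",
    "EnvironmentTable",
    "TopologySummary",
    "pairwise_mic",
    "build_network",
    "cooccurrence_network",
    "topology",
    "write_edgelist_tsv",
    "write_graphml",
]


@dataclass(frozen=True)
class AbundanceTable:
    """Species × sample relative-abundance table (rows taxa, cols samples)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.empty:
            raise ValueError("abundance table is empty")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError("abundances must be >= 0")
        if np.all(vals <= 1.0):  # fractional form: closed composition
            sums = vals.sum(axis=0)
            if np.any(sums > 1.0 + 1e-9):
                raise ValueError("per-sample fractional abundances sum above 1")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class EnvironmentTable:
    """Environmental factor × sample table in native units."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.empty:
            raise ValueError("environment table is empty")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValueError("environmental factors must be finite")

    @property
    def factors(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def _stacked(abund: AbundanceTable, env: EnvironmentTable | None) -> pd.DataFrame:
    if env is None:
        return abund.data.astype(float)
    if list(env.data.columns) != list(abund.data.columns):
        raise ValueError(
            "environment samples must match abundance samples in the same order"
        )
    overlap = set(abund.data.index) & set(env.data.index)
    if overlap:
        raise ValueError(f"taxa and factors share labels: {sorted(overlap)}")
    return pd.concat([abund.data, env.data]).astype(float)


def pairwise_mic(
    abund: AbundanceTable,
    env: EnvironmentTable | None = None,
    config: NetworkConfig | None = None,
) -> pd.DataFrame:
    """Symmetric MIC matrix over all species and factors (diagonal 1)."""
    cfg = config or NetworkConfig()
    data = _stacked(abund, env)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 variables for pairwise association")
    names = list(data.index)
    vals = data.to_numpy()
    p = len(names)
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            out[i, j] = out[j, i] = mic(vals[i], vals[j], cfg)
    return pd.DataFrame(out, index=names, columns=names)


def _edge_sign(x: np.ndarray, y: np.ndarray, method: str) -> int:
    if method == "spearman":
        rho = stats.spearmanr(x, y).statistic
    else:
        rho = stats.pearsonr(x, y).statistic
    if not np.isfinite(rho) or rho == 0:
        return 0
    return 1 if rho > 0 else -1


def build_network(
    matrix: pd.DataFrame,
    data: pd.DataFrame,
    taxa: set[str] | list[str],
    config: NetworkConfig | None = None,
) -> nx.Graph:
    """Threshold a MIC matrix into an undirected co-occurrence graph.

    *matrix* is the symmetric association matrix, *data* the variable ×
    sample table the signs are computed from, *taxa* the variable names
    to treat as methanogen species (the rest are factors).  Edges carry
    mic, sign (±1 or 0) and kind ("methanogen" for species–species
    edges, "environment" otherwise).
    """
    cfg = config or NetworkConfig()
    taxa = set(taxa)
    names = list(matrix.index)
    g = nx.Graph()
    for name in names:
        g.add_node(name, kind="taxon" if name in taxa else "factor")
    vals = data.loc[names].to_numpy()
    m = matrix.to_numpy()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            score = float(m[i, j])
            if score < cfg.edge_threshold:
                continue
            kind = (
                "methanogen"
                if names[i] in taxa and names[j] in taxa
                else "environment"
            )
            g.add_edge(
                names[i],
                names[j],
                mic=score,
                sign=_edge_sign(vals[i], vals[j], cfg.sign_method),
                kind=kind,
            )
    return g


def cooccurrence_network(
    abund: AbundanceTable,
    env: EnvironmentTable | None = None,
    config: NetworkConfig | None = None,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Convenience: pairwise MIC then thresholded graph in one call."""
    cfg = config or NetworkConfig()
    matrix = pairwise_mic(abund, env, cfg)
    data = _stacked(abund, env)
    graph = build_network(matrix, data, set(abund.taxa), cfg)
    return matrix, graph


@dataclass(frozen=True)
class TopologySummary:
    n_nodes: int
    n_edges: int
    density: float
    mean_clustering: float
    degrees: Mapping[str, int]


def topology(net: nx.Graph) -> TopologySummary:
    """Degree map, edge count, density 2E/(N(N−1)) and mean local
    clustering coefficient.  An empty network reports zeros."""
    n = net.number_of_nodes()
    if n == 0:
        return TopologySummary(0, 0, 0.0, 0.0, {})
    density = nx.density(net)
    clustering = nx.average_clustering(net) if n > 0 else 0.0
    return TopologySummary(
        n_nodes=n,
        n_edges=net.number_of_edges(),
        density=float(density),
        mean_clustering=float(clustering),
        degrees=dict(net.degree()),
    )


def write_edgelist_tsv(net: nx.Graph, path: str) -> None:
    """Cytoscape-compatible edge list: u, v, mic, sign, kind."""
    rows = [
        {"u": u, "v": v, "mic": d["mic"], "sign": d["sign"], "kind": d["kind"]}
        for u, v, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["u", "v", "mic", "sign", "kind"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(net: nx.Graph, path: str) -> None:
    nx.write_graphml(net, path)
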