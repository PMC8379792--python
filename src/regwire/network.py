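"""Condition-specific network assembly and summaries.

Networks are undirected: edges are significant co-expression associations
carrying the Pearson correlation as weight, nodes are tagged gene or TF.
The high-regulatory-impact table joins per-TF impact scores with the TF's
degree ("frequency of appearance") in each condition network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .pcit import PCITResult
from .types import TFCatalog

__all__ = [
    "ConditionNetwork",
    "build_networks",
    "hri_table",
    "tf_targets",
    "clustering_coefficient",
    "degree_histogram",
    "write_edges_tsv",
    "write_sif",
    "write_graphml",
]


@dataclass
class ConditionNetwork:
    """Undirected co-expression graph for one condition."""

    graph: nx.Graph
    condition: str

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node] if node in self.graph else 0

    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]


def _network_from_pcit(p: PCITResult, tfs: TFCatalog, condition: str) -> ConditionNetwork:
    g = nx.Graph()
    tf_ids = set(tfs.ids)
    for node in p.node_ids:
        g.add_node(node, role="TF" if node in tf_ids else "gene")
    for a, b, w in p.edges():
        g.add_edge(a, b, weight=w)
    return ConditionNetwork(g, condition)


def build_networks(
    p_ref: PCITResult,
    p_alt: PCITResult,
    tfs: TFCatalog,
    labels: tuple[str, str] = ("reference", "alternate"),
) -> tuple[ConditionNetwork, ConditionNetwork]:
    """One network per condition from significant pairs; roles from catalog."""
    if p_ref.node_ids != p_alt.node_ids:
        raise ValueError("per-condition results have mismatched node sets")
    return (
        _network_from_pcit(p_ref, tfs, labels[0]),
        _network_from_pcit(p_alt, tfs, labels[1]),
    )


def hri_table(
    net_ref: ConditionNetwork,
    net_alt: ConditionNetwork,
    rif_table: pd.DataFrame,
    significant_only: bool = True,
) -> pd.DataFrame:
    """High-regulatory-impact TF table.

    Joins each TF's average expression and impact scores with its degree in
    the reference (``freq_ref``) and alternate (``freq_alt``) networks;
    ``freq_diff = freq_ref - freq_alt``. Restricted to significant TFs by
    default; sorted by ``freq_diff`` descending, ties by id.
    """
    rows = rif_table
    if significant_only:
        rows = rif_table[rif_table["sig1"] | rif_table["sig2"]]
    freq_ref = [net_ref.degree(tf) for tf in rows.index]
    freq_alt = [net_alt.degree(tf) for tf in rows.index]
    out = pd.DataFrame(
        {
            "avgexpr": rows["avgexpr"],
            "RIF1": rows["RIF1"],
            "RIF2": rows["RIF2"],
            "freq_ref": freq_ref,
            "freq_alt": freq_alt,
        },
        index=rows.index,
    )
    out["freq_diff"] = out["freq_ref"] - out["freq_alt"]
    out = out.sort_index(kind="mergesort")
    return out.sort_values("freq_diff", ascending=False, kind="mergesort")


def tf_targets(net: ConditionNetwork, tf: str) -> list[str]:
    """Sorted neighbors of a TF in the network."""
    if tf not in net.graph:
        raise KeyError(f"node {tf!r} not in the {net.condition} network")
    return sorted(net.graph.neighbors(tf))


def clustering_coefficient(net: ConditionNetwork) -> float:
    """Mean local clustering coefficient; degree<2 nodes contribute 0."""
    if net.graph.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    return float(nx.average_clustering(net.graph))


def degree_histogram(net: ConditionNetwork) -> dict[int, int]:
    """Map degree -> node count; counts sum to the node count."""
    hist: dict[int, int] = {}
    for _, d in net.graph.degree:
        hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))


def _edge_rows(net: ConditionNetwork) -> list[tuple[str, str, float]]:
    rows = []
    for a, b, data in net.graph.edges(data=True):
        a, b = sorted((a, b))
        rows.append((a, b, data.get("weight", np.nan)))
    return sorted(rows)


def write_edges_tsv(net: ConditionNetwork, path: str | Path) -> None:
    """Edge list TSV: node_a, interaction, node_b, weight, condition."""
    rows = [(a, "cor", b, w, net.condition) for a, b, w in _edge_rows(net)]
    pd.DataFrame(rows, columns=["node_a", "interaction", "node_b", "weight", "condition"]).to_csv(
        path, sep="\t", index=False
    )


def write_sif(net: ConditionNetwork, path: str | Path) -> None:
    """Simple Interaction Format: source, interaction type, target."""
    with open(path, "w") as fh:
        isolated = sorted(n for n in net.graph.nodes if net.graph.degree[n] == 0)
        for a, b, _ in _edge_rows(net):
            fh.write(f"{a}\tcor\t{b}\n")
        for n in isolated:
            fh.write(f"{n}\n")


def write_graphml(net: ConditionNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, path)
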