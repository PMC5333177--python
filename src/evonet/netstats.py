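"""Gene-network container and network-level evolutionary statistics.

Networks have typed nodes (gene / compound / map) and undirected edges, read
from and written to two TSV files (``nodes.tsv``: node_id, type, gene_id,
label; ``edges.tsv``: source, target, interaction).

Statistics over per-gene ages (PAI):

* Gene Set PAI — the arithmetic mean, ``sum(PAI) / N`` over N genes.
* Network PAI — the degree-weighted variant ``sum(PAI * d) / (2N)`` where
  ``d`` is a gene node's degree in the full network (compound wiring counts)
  and N is the number of gene nodes; hubs contribute more to the network age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from evonet.taxonomy import PaiResult, TaxonomyTree, taxon_name_at

NODE_TYPES = {"gene", "compound", "map"}


class GeneNetwork:
    """Undirected network of typed nodes backed by a networkx graph."""

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_node(self, node_id: str, node_type: str, gene_id: str | None = None,
                 label: str | None = None, **attrs) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        if node_type == "gene" and gene_id is None:
            raise ValueError(f"gene node {node_id!r} needs a gene_id")
        self.graph.add_node(node_id, type=node_type, gene_id=gene_id,
                            label=label or node_id, **attrs)

    def add_edge(self, a: str, b: str, interaction: str = "") -> None:
        for n in (a, b):
            if n not in self.graph:
                raise KeyError(f"edge endpoint {n!r} is not a node")
        self.graph.add_edge(a, b, interaction=interaction)

    def gene_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["type"] == "gene"]

    def gene_ids(self) -> list[str]:
        return [self.graph.nodes[n]["gene_id"] for n in self.gene_nodes()]

    def node_of_gene(self, gene_id: str) -> str:
        for n, d in self.graph.nodes(data=True):
            if d["type"] == "gene" and d["gene_id"] == gene_id:
                return n
        raise KeyError(f"no node for gene {gene_id!r}")

    @classmethod
    def read(cls, path: str | Path) -> "GeneNetwork":
        path = Path(path)
        nodes = pd.read_csv(path / "nodes.tsv", sep="\t", comment="#", dtype=str,
                            keep_default_na=False)
        edges = pd.read_csv(path / "edges.tsv", sep="\t", comment="#", dtype=str,
                            keep_default_na=False)
        net = cls()
        for _, row in nodes.iterrows():
            net.add_node(row["node_id"], row["type"],
                         gene_id=row.get("gene_id") or None,
                         label=row.get("label") or row["node_id"])
        for _, row in edges.iterrows():
            net.add_edge(row["source"], row["target"],
                         interaction=row.get("interaction", ""))
        return net

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        nodes = pd.DataFrame(
            [(n, d["type"], d.get("gene_id") or "", d.get("label", n))
             for n, d in self.graph.nodes(data=True)],
            columns=["node_id", "type", "gene_id", "label"],
        )
        edges = pd.DataFrame(
            [(a, b, d.get("interaction", "")) for a, b, d in self.graph.edges(data=True)],
            columns=["source", "target", "interaction"],
        )
        nodes.to_csv(path / "nodes.tsv", sep="\t", index=False)
        edges.to_csv(path / "edges.tsv", sep="\t", index=False)


@dataclass(frozen=True)
class PaiSummary:
    gene_set_pai: float
    network_pai: float
    median_taxon: str
    oldest_taxon: str
    youngest_taxon: str
    total_orthologs: int


def gene_set_pai(pai_values: list[int]) -> float:
    """Mean PAI of a gene set: sum(PAI) / N."""
    if not pai_values:
        raise ValueError("gene_set_pai of an empty set is undefined")
    return sum(pai_values) / len(pai_values)


def network_pai(network: GeneNetwork, pai: dict[str, int]) -> float:
    """Degree-weighted age statistic sum(PAI * d) / (2N).

    d counts every incident edge in the full network (including edges to
    compound or map nodes); N counts gene nodes only. Note the statistic is
    taken literally from its defining formula and is therefore not bounded by
    the maximum PAI on high-degree networks.
    """
    gene_nodes = network.gene_nodes()
    if not gene_nodes:
        raise ValueError("network_pai needs at least one gene node")
    total = sum(pai[n] * network.graph.degree(n) for n in gene_nodes)
    return total / (2 * len(gene_nodes))


def pai_summary(
    network: GeneNetwork,
    pai_results: dict[str, PaiResult],
    tree: TaxonomyTree,
    ref_org: str,
) -> PaiSummary:
    """Summary block: both PAI statistics plus oldest/median/youngest taxa.

    Oldest is the taxon at the minimum PAI, youngest at the maximum; median
    uses the lower middle value for even counts so the result is always an
    attained PAI with a real taxon name.
    """
    gene_nodes = network.gene_nodes()
    values = [pai_results[network.graph.nodes[n]["gene_id"]].pai for n in gene_nodes]
    if not values:
        raise ValueError("no gene with a PAI value")
    svals = sorted(values)
    median_val = svals[(len(svals) - 1) // 2]
    node_pai = {n: pai_results[network.graph.nodes[n]["gene_id"]].pai for n in gene_nodes}
    return PaiSummary(
        gene_set_pai=gene_set_pai(values),
        network_pai=network_pai(network, node_pai),
        median_taxon=taxon_name_at(tree, ref_org, median_val),
        oldest_taxon=taxon_name_at(tree, ref_org, min(values)),
        youngest_taxon=taxon_name_at(tree, ref_org, max(values)),
        total_orthologs=sum(r.n_orthologs for r in pai_results.values()),
    )


def phylogenetic_profile(
    network_genes: list[str],
    ortholog_map: dict[str, set[str]],
    organisms: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Presence/absence matrix of orthologs.

    Columns follow the network gene order; rows are the organisms (sorted by
    org_code) with at least one ortholog of any network gene, so no row is
    all '-'.
    """
    orgs = sorted(set().union(*(ortholog_map.get(g, set()) for g in network_genes))
                  if network_genes else set())
    data = {
        g: ["+" if o in ortholog_map.get(g, set()) else "-" for o in orgs]
        for g in network_genes
    }
    return pd.DataFrame(data, index=orgs, columns=network_genes)


_HEATMAP_ANCHORS = [
    (0.00, (0, 0, 255)),     # blue: oldest
    (0.25, (0, 255, 255)),   # cyan
    (0.50, (0, 255, 0)),     # green
    (0.75, (255, 255, 0)),   # yellow
    (1.00, (255, 0, 0)),     # red: youngest
]
_GRADIENT_ANCHORS = [
    (0.00, (0, 0, 255)),
    (0.50, (255, 255, 255)),
    (1.00, (255, 0, 0)),
]


def _interpolate(anchors: list[tuple[float, tuple[int, int, int]]], t: float) -> tuple[int, int, int]:
    for (t0, c0), (t1, c1) in zip(anchors, anchors[1:]):
        if t <= t1:
            f = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
            return tuple(round(a + f * (b - a)) for a, b in zip(c0, c1))
    return anchors[-1][1]


def color_scale(values: dict[str, float], scheme: str = "heatmap") -> dict[str, tuple[int, int, int]]:
    """Map values to RGB colors, min-max normalized.

    "heatmap" runs blue - cyan - green - yellow - red (old to young);
    "blue_white_red" is the diverging gradient. Constant input maps every
    key to the mid-scale anchor.
    """
    if not values:
        raise ValueError("color_scale needs at least one value")
    if scheme == "heatmap":
        anchors = _HEATMAP_ANCHORS
    elif scheme == "blue_white_red":
        anchors = _GRADIENT_ANCHORS
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    lo, hi = min(values.values()), max(values.values())
    if hi == lo:
        return {k: _interpolate(anchors, 0.5) for k in values}
    return {k: _interpolate(anchors, (v - lo) / (hi - lo)) for k, v in values.items()}


def rgb_hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def layout_rings(
    network: GeneNetwork, pai: dict[str, int], r0: float = 1.0
) -> dict[str, tuple[float, float]]:
    """Concentric ring layout: genes with equal PAI share one circle.

    Distinct PAI values sorted ascending get radii r0*(1+rank); genes on a
    ring are evenly spaced. Non-gene nodes go on separate outermost circles,
    one per node type.
    """
    pos: dict[str, tuple[float, float]] = {}
    gene_nodes = network.gene_nodes()
    distinct = sorted({pai[n] for n in gene_nodes})
    radius_of = {v: r0 * (1 + rank) for rank, v in enumerate(distinct)}
    for v in distinct:
        ring = sorted(n for n in gene_nodes if pai[n] == v)
        r = radius_of[v]
        for i, n in enumerate(ring):
            a = 2 * math.pi * i / len(ring)
            pos[n] = (r * math.cos(a), r * math.sin(a))
    other_types = sorted({d["type"] for _, d in network.graph.nodes(data=True)} - {"gene"})
    base = r0 * (1 + len(distinct))
    for j, t in enumerate(other_types):
        ring = sorted(n for n, d in network.graph.nodes(data=True) if d["type"] == t)
        r = base + r0 * (1 + j)
        for i, n in enumerate(ring):
            a = 2 * math.pi * i / len(ring)
            pos[n] = (r * math.cos(a), r * math.sin(a))
    return pos
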