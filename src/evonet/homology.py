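"""Homology-hit filtering, domain-composition filters and network clustering.

Candidate homologs come from the datastore hit table (pairwise scores and
identities, as a sequence-similarity search service would report them). They
are filtered by minimum score/identity and optionally by domain composition:

* *simple* mode ranks domains by how many candidates carry them and keeps
  candidates containing all of the top ``T`` domains;
* *detailed* mode keeps candidates carrying at least one user-listed domain.

Network genes connected by surviving hits (in either direction) form
homology clusters — connected components of the similarity graph — which can
be collapsed into single merged nodes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import networkx as nx
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from evonet.datastore import DataStore
    from evonet.netstats import GeneNetwork


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds controlling homolog acceptance.

    sw_min and identity_min are inclusive lower bounds. mode selects domain
    filtering: "none", "simple" (top-T ranked domains required) or "detailed"
    (at least one of required_domains). max_dist / whitelist restrict the
    ortholog search taxonomically (see divergence.select_nearest_ortholog).
    """

    sw_min: float = 500.0
    identity_min: float = 0.5
    domain_threshold_T: int = 0
    required_domains: frozenset[str] = frozenset()
    mode: str = "none"
    max_dist: int | None = None
    whitelist: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_min <= 1.0:
            raise ValueError("identity_min must lie in [0, 1]")
        if self.sw_min < 0:
            raise ValueError("sw_min must be non-negative")
        if self.domain_threshold_T < 0:
            raise ValueError("domain_threshold_T must be non-negative")
        if self.mode not in {"none", "simple", "detailed"}:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ClusterAssignment:
    """Partition of network genes into homology clusters."""

    labels: dict[str, str]
    clusters: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.clusters:
            by_label: dict[str, set[str]] = {}
            for gene, lab in self.labels.items():
                by_label.setdefault(lab, set()).add(gene)
            self.clusters = [frozenset(s) for _, s in sorted(by_label.items())]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["gene_id", "cluster_label"]
        )


def filter_hits(hits: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Keep hits with sw_score >= sw_min and identity >= identity_min.

    Both bounds inclusive; row order preserved.
    """
    mask = (hits["sw_score"] >= cfg.sw_min) & (hits["identity"] >= cfg.identity_min)
    return hits.loc[mask]


def rank_domains(candidate_genes: Iterable[str], domains: pd.DataFrame) -> list[str]:
    """Domains ordered by how many candidate genes carry them.

    Descending count, ties broken lexicographically by domain_id so the
    ranking is deterministic.
    """
    candidates = set(candidate_genes)
    sub = domains.loc[domains["gene_id"].isin(candidates)]
    counts = Counter()
    for dom, group in sub.groupby("domain_id"):
        counts[dom] = group["gene_id"].nunique()
    return sorted(counts, key=lambda d: (-counts[d], d))


def domain_filter_simple(
    candidates: Iterable[str], gene_domains: dict[str, frozenset[str]],
    ranking: list[str], T: int,
) -> set[str]:
    """Keep candidates whose domain set contains the first T ranked domains.

    T = 0 keeps everything; T beyond the ranking length requires the whole
    ranking.
    """
    if T < 0:
        raise ValueError("T must be non-negative")
    need = set(ranking[:T])
    return {g for g in candidates if need <= gene_domains.get(g, frozenset())}


def domain_filter_detailed(
    candidates: Iterable[str], gene_domains: dict[str, frozenset[str]],
    required_domains: Iterable[str],
) -> set[str]:
    """Keep candidates carrying at least one required domain.

    An empty requirement keeps everything.
    """
    required = set(required_domains)
    if not required:
        return set(candidates)
    return {g for g in candidates if required & gene_domains.get(g, frozenset())}


def apply_domain_filter(
    candidates: set[str], ds: "DataStore", cfg: FilterConfig
) -> set[str]:
    """Dispatch on cfg.mode; "none" is the identity."""
    if cfg.mode == "none" or not candidates:
        return set(candidates)
    gene_domains = {g: ds.domains_of(g) for g in candidates}
    if cfg.mode == "simple":
        ranking = rank_domains(candidates, ds.domains)
        return domain_filter_simple(candidates, gene_domains, ranking, cfg.domain_threshold_T)
    return domain_filter_detailed(candidates, gene_domains, cfg.required_domains)


def cluster_network_genes(
    network: "GeneNetwork", ds: "DataStore", cfg: FilterConfig
) -> ClusterAssignment:
    """Cluster network genes by filtered homology links.

    An undirected edge joins two network genes when any surviving hit links
    them in either direction; clusters are the connected components, so genes
    with no qualifying link become singletons.
    """
    genes = network.gene_ids()
    known = set(ds.genes["gene_id"])
    for g in genes:
        if g not in known:
            raise KeyError(f"network gene {g!r} not present in datastore")
    gene_set = set(genes)
    kept = filter_hits(ds.hits, cfg)
    candidates = set(kept["query_gene"]) | set(kept["subject_gene"])
    surviving = apply_domain_filter(candidates & gene_set, ds, cfg) | (candidates - gene_set)

    g = nx.Graph()
    g.add_nodes_from(genes)
    for _, row in kept.iterrows():
        a, b = row["query_gene"], row["subject_gene"]
        if a in gene_set and b in gene_set and a in surviving and b in surviving:
            g.add_edge(a, b)

    labels: dict[str, str] = {}
    clusters: list[frozenset[str]] = []
    components = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(components):
        lab = f"C{i:03d}"
        clusters.append(frozenset(comp))
        for gene in comp:
            labels[gene] = lab
    return ClusterAssignment(labels=labels, clusters=clusters)


def collapse_clusters(network: "GeneNetwork", assignment: ClusterAssignment) -> "GeneNetwork":
    """Merge each homology cluster into a single network node.

    Cluster nodes carry the member gene list; edges are re-wired to the
    merged nodes, duplicates merged and intra-cluster self-loops dropped.
    Non-gene nodes pass through unchanged.
    """
    from evonet.netstats import GeneNetwork

    node_map: dict[str, str] = {}
    out = GeneNetwork()
    for node_id, data in network.graph.nodes(data=True):
        if data["type"] != "gene":
            out.add_node(node_id, data["type"], label=data.get("label", node_id))
            node_map[node_id] = node_id
    cluster_of_gene = assignment.labels
    members_by_label: dict[str, list[str]] = {}
    for node_id, data in network.graph.nodes(data=True):
        if data["type"] == "gene":
            lab = cluster_of_gene[data["gene_id"]]
            members_by_label.setdefault(lab, []).append(node_id)
            node_map[node_id] = f"cluster:{lab}"
    for lab, members in sorted(members_by_label.items()):
        out.add_node(
            f"cluster:{lab}", "gene",
            gene_id=f"cluster:{lab}",
            label="+".join(sorted(network.graph.nodes[m].get("label", m) for m in members)),
            members=sorted(members),
        )
    for a, b, data in network.graph.edges(data=True):
        na, nb = node_map[a], node_map[b]
        if na != nb:
            out.add_edge(na, nb, interaction=data.get("interaction", ""))
    return out
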