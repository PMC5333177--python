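"""End-to-end analysis: orthologs, ages, divergence and table outputs.

This module wires the datastore, homology filters, taxonomy and divergence
steps into one call and owns the on-disk result schema (``pai.tsv``,
``di.tsv``, ``clusters.tsv``, ``summary.tsv``, ``profile.tsv``,
``colors.tsv``, ``layout.tsv``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from evonet.datastore import DataStore
from evonet.divergence import DiResult, compute_di
from evonet.homology import (
    ClusterAssignment,
    FilterConfig,
    apply_domain_filter,
    cluster_network_genes,
    filter_hits,
)
from evonet.netstats import (
    GeneNetwork,
    PaiSummary,
    color_scale,
    layout_rings,
    pai_summary,
    phylogenetic_profile,
    rgb_hex,
)
from evonet.taxonomy import PaiResult, TaxonomyTree, compute_pai


def ortholog_genes_of(gene_id: str, ds: DataStore, cfg: FilterConfig) -> set[str]:
    """Candidate homolog genes of one gene after score and domain filtering.

    A candidate is any gene linked to gene_id by a surviving hit in either
    direction. Domain filtering (cfg.mode) is applied to this candidate set,
    with the simple-mode domain ranking computed over the same set.
    """
    kept = filter_hits(ds.hits, cfg)
    cands = set(kept.loc[kept["query_gene"] == gene_id, "subject_gene"])
    cands |= set(kept.loc[kept["subject_gene"] == gene_id, "query_gene"])
    cands.discard(gene_id)
    return apply_domain_filter(cands, ds, cfg)


def ortholog_map(
    network_genes: list[str], ds: DataStore, cfg: FilterConfig, ref_org: str
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Per-gene ortholog organisms and ortholog genes (reference excluded)."""
    org_map: dict[str, set[str]] = {}
    gene_map: dict[str, set[str]] = {}
    for g in network_genes:
        cands = ortholog_genes_of(g, ds, cfg)
        others = {c for c in cands if ds.org_of_gene(c) != ref_org}
        gene_map[g] = others
        org_map[g] = {ds.org_of_gene(c) for c in others}
    return org_map, gene_map


@dataclass
class AnalysisResult:
    """All per-network outputs of one analysis run."""

    network: GeneNetwork
    ref_org: str
    cfg: FilterConfig
    pai_results: dict[str, PaiResult]
    summary: PaiSummary
    clusters: ClusterAssignment
    profile: pd.DataFrame
    di_results: dict[str, DiResult] = field(default_factory=dict)
    name: str = "network"

    def pai_table(self) -> pd.DataFrame:
        rows = [
            (r.gene_id, r.pai, r.taxon_name, r.n_orthologs,
             ";".join(sorted(r.ortholog_orgs)))
            for r in self.pai_results.values()
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "pai", "taxon_name", "n_orthologs", "ortholog_orgs"]
        ).sort_values("gene_id").reset_index(drop=True)

    def di_table(self) -> pd.DataFrame:
        rows = [
            (r.gene_id, r.ortholog_gene_id or "", r.ortholog_org or "",
             _fmt(r.ka), _fmt(r.ks), _fmt(r.di), r.status, r.method)
            for r in self.di_results.values()
        ]
        df = pd.DataFrame(
            rows,
            columns=["gene_id", "ortholog_gene", "ortholog_org", "ka", "ks", "di",
                     "status", "method"],
        )
        # DI descending, undefined values last, stable by gene_id
        df["_key"] = [
            -r.di if r.di is not None else float("inf") for r in self.di_results.values()
        ]
        return (df.sort_values(["_key", "gene_id"]).drop(columns="_key")
                .reset_index(drop=True))

    def summary_table(self) -> pd.DataFrame:
        s = self.summary
        return pd.DataFrame(
            [
                ("gene_set_pai", s.gene_set_pai),
                ("network_pai", s.network_pai),
                ("median_taxon", s.median_taxon),
                ("oldest_taxon", s.oldest_taxon),
                ("youngest_taxon", s.youngest_taxon),
                ("total_orthologs", s.total_orthologs),
            ],
            columns=["statistic", "value"],
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pai_table().to_csv(outdir / "pai.tsv", sep="\t", index=False)
        if self.di_results:
            self.di_table().to_csv(outdir / "di.tsv", sep="\t", index=False)
        self.summary_table().to_csv(outdir / "summary.tsv", sep="\t", index=False)
        self.profile.to_csv(outdir / "profile.tsv", sep="\t", index_label="org_code")
        self.clusters.to_frame().to_csv(outdir / "clusters.tsv", sep="\t", index=False)

        node_pai = {
            n: self.pai_results[self.network.graph.nodes[n]["gene_id"]].pai
            for n in self.network.gene_nodes()
        }
        colors = color_scale({n: float(v) for n, v in node_pai.items()})
        pd.DataFrame(
            [(n, rgb_hex(c)) for n, c in sorted(colors.items())],
            columns=["node_id", "color"],
        ).to_csv(outdir / "colors.tsv", sep="\t", index=False)
        layout = layout_rings(self.network, node_pai)
        pd.DataFrame(
            [(n, f"{x:.6f}", f"{y:.6f}") for n, (x, y) in sorted(layout.items())],
            columns=["node_id", "x", "y"],
        ).to_csv(outdir / "layout.tsv", sep="\t", index=False)


def _fmt(x: float | None) -> str:
    return "" if x is None else f"{x:.6f}"


def analyze_network(
    network: GeneNetwork,
    ds: DataStore,
    tree: TaxonomyTree,
    ref_org: str,
    cfg: FilterConfig = FilterConfig(),
    with_di: bool = True,
    name: str = "network",
) -> AnalysisResult:
    """Run the full evolutionary analysis of one network.

    Computes per-gene PAI from filtered orthologs, summary statistics,
    homology clusters, the phylogenetic profile and (optionally) per-gene
    divergence against the nearest ortholog.
    """
    genes = network.gene_ids()
    org_map, gene_map = ortholog_map(genes, ds, cfg, ref_org)
    pai_results = {
        g: compute_pai(tree, ref_org, org_map[g], gene_id=g, n_orthologs=len(gene_map[g]))
        for g in genes
    }
    summary = pai_summary(network, pai_results, tree, ref_org)
    clusters = cluster_network_genes(network, ds, cfg)
    profile = phylogenetic_profile(genes, org_map)
    di_results: dict[str, DiResult] = {}
    if with_di:
        for g in genes:
            if g in ds.aa_seqs and g in ds.nt_seqs:
                di_results[g] = compute_di(g, ds, tree, cfg)
    return AnalysisResult(
        network=network, ref_org=ref_org, cfg=cfg, pai_results=pai_results,
        summary=summary, clusters=clusters, profile=profile,
        di_results=di_results, name=name,
    )
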