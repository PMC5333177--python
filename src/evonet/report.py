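"""Threshold sweeps and static HTML reports.

A sweep re-runs ortholog detection and the PAI statistics over a grid of
identity thresholds (other filter settings fixed), mirroring the exploratory
use of the tool: as the identity requirement rises, orthologs drop out and
every gene's PAI can only grow. The report is plain static HTML with
relative links — an index page linking one page per analyzed network, each
with a PAI histogram, the sweep curve, the per-gene tables and the summary
block. Every plot has a sibling text file with its data.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, replace
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from evonet.datastore import DataStore
from evonet.homology import FilterConfig
from evonet.netstats import GeneNetwork, gene_set_pai, network_pai
from evonet.pipeline import AnalysisResult, ortholog_map
from evonet.taxonomy import TaxonomyTree, compute_pai


@dataclass
class SweepResult:
    """One row per identity threshold: both PAI statistics + per-gene PAIs."""

    table: pd.DataFrame          # sw_min, identity_min, domain_T, gene_set_pai, network_pai
    per_gene: pd.DataFrame       # index = identity_min, columns = genes, values = PAI


def threshold_sweep(
    network: GeneNetwork,
    ds: DataStore,
    tree: TaxonomyTree,
    ref_org: str,
    identity_grid: list[float],
    cfg: FilterConfig = FilterConfig(),
) -> SweepResult:
    """Recompute orthologs and PAI statistics at each identity threshold."""
    if not identity_grid:
        raise ValueError("identity grid must be non-empty")
    if any(not 0.0 <= t <= 1.0 for t in identity_grid):
        raise ValueError("identity thresholds must lie in [0, 1]")
    genes = network.gene_ids()
    rows = []
    per_gene_rows = []
    for t in identity_grid:
        cfg_t = replace(cfg, identity_min=t)
        org_map, gene_map = ortholog_map(genes, ds, cfg_t, ref_org)
        pai = {g: compute_pai(tree, ref_org, org_map[g], gene_id=g).pai for g in genes}
        node_pai = {
            n: pai[network.graph.nodes[n]["gene_id"]] for n in network.gene_nodes()
        }
        rows.append((cfg.sw_min, t, cfg.domain_threshold_T,
                     gene_set_pai(list(pai.values())), network_pai(network, node_pai)))
        per_gene_rows.append(pai)
    table = pd.DataFrame(
        rows, columns=["sw_min", "identity_min", "domain_T", "gene_set_pai", "network_pai"]
    )
    per_gene = pd.DataFrame(per_gene_rows, index=identity_grid, columns=genes)
    per_gene.index.name = "identity_min"
    return SweepResult(table=table, per_gene=per_gene)


_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 2px 8px; }}
</style></head>
<body>
<h1>{title}</h1>
{body}
<hr><p><small>{footer}</small></p>
</body></html>
"""


def _table_html(df: pd.DataFrame) -> str:
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in df.columns)
    rows = "".join(
        "<tr>" + "".join(f"<td>{html.escape(str(v))}</td>" for v in row) + "</tr>"
        for row in df.itertuples(index=False)
    )
    return f"<table><tr>{head}</tr>{rows}</table>"


def _pai_histogram(result: AnalysisResult, outdir: Path, stem: str) -> str:
    values = [r.pai for r in result.pai_results.values()]
    lo, hi = min(values), max(values)
    bins = range(lo, hi + 2)  # one bin per integer PAI
    counts = {b: values.count(b) for b in range(lo, hi + 1)}
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.hist(values, bins=[b - 0.5 for b in bins], edgecolor="black")
    ax.set_xlabel("PAI")
    ax.set_ylabel("genes")
    fig.tight_layout()
    fig.savefig(outdir / f"{stem}.png", dpi=100)
    plt.close(fig)
    pd.DataFrame(sorted(counts.items()), columns=["pai", "count"]).to_csv(
        outdir / f"{stem}.tsv", sep="\t", index=False
    )
    return stem


def _sweep_plot(sweep: SweepResult, outdir: Path, stem: str) -> str:
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(sweep.table["identity_min"], sweep.table["gene_set_pai"], marker="o",
            label="Gene Set PAI")
    ax.plot(sweep.table["identity_min"], sweep.table["network_pai"], marker="s",
            label="Network PAI")
    ax.set_xlabel("identity threshold")
    ax.set_ylabel("PAI statistic")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / f"{stem}.png", dpi=100)
    plt.close(fig)
    sweep.table.to_csv(outdir / f"{stem}.tsv", sep="\t", index=False)
    return stem


def render_report(
    results: list[AnalysisResult],
    outdir: str | Path,
    sweeps: dict[str, SweepResult] | None = None,
    timestamps: bool = True,
) -> Path:
    """Write the HTML report bundle; returns the index page path.

    One page per network plus a global index with hyperlinks. Set
    ``timestamps=False`` for byte-reproducible output.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"report directory {outdir} is not writable: {exc}") from exc
    sweeps = sweeps or {}
    footer = (
        f"generated {datetime.now(timezone.utc).isoformat(timespec='seconds')}"
        if timestamps else "timestamps suppressed"
    )

    links = []
    for result in results:
        stem = result.name
        page = outdir / f"{stem}.html"
        parts = ["<h2>Summary</h2>", _table_html(result.summary_table())]
        hist = _pai_histogram(result, outdir, f"{stem}_pai_hist")
        parts.append(f'<h2>PAI distribution</h2><img src="{hist}.png" alt="PAI histogram">')
        parts.append(f'<p>data: <a href="{hist}.tsv">{hist}.tsv</a></p>')
        if stem in sweeps:
            curve = _sweep_plot(sweeps[stem], outdir, f"{stem}_sweep")
            parts.append(
                f'<h2>Threshold sweep</h2><img src="{curve}.png" alt="sweep curve">'
            )
            parts.append(f'<p>data: <a href="{curve}.tsv">{curve}.tsv</a></p>')
        parts.append("<h2>Gene ages (PAI)</h2>")
        parts.append(_table_html(result.pai_table()))
        if result.di_results:
            parts.append("<h2>Divergence (sorted by DI, undefined last)</h2>")
            parts.append(_table_html(result.di_table()))
        parts.append('<p><a href="index.html">back to index</a></p>')
        page.write_text(_PAGE.format(title=f"Network {stem}", body="\n".join(parts),
                                     footer=footer))
        links.append(
            f'<li><a href="{stem}.html">{stem}</a> — '
            f"Gene Set PAI = {result.summary.gene_set_pai:.3f}, "
            f"Network PAI = {result.summary.network_pai:.3f}</li>"
        )

    index = outdir / "index.html"
    body = "<h2>Analyzed networks</h2><ul>" + "\n".join(links) + "</ul>"
    index.write_text(_PAGE.format(title="Evolutionary network analysis report",
                                  body=body, footer=footer))
    return index
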