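"""Synthetic datastores, networks and codon pairs with planted ground truth.

The generator makes offline testing possible end to end:

* a taxonomy in which, for every depth ``b`` on the reference lineage, there
  are side organisms whose LCA with the reference sits exactly at ``b``;
* reference genes with planted *birth levels*: a gene born at level ``b``
  has ortholog genes only in organisms inside the clade at depth ``b``, with
  at least one organism exactly at the clade boundary, so its PAI is ``b``
  by construction (at full sampling density);
* codon pairs mutated from a random ancestral CDS with separately planted
  synonymous and nonsynonymous substitution counts (at most one substitution
  per codon, no stop codons ever emitted), so NG86 estimates can be checked
  against known rates.

Ortholog presence is simulated by clade membership, not by sequence
evolution — exact and fast for age-index tests; sequence evolution is used
only for divergence tests. All randomness flows through one seeded
``numpy.random.Generator`` (PCG64), so output is fully deterministic per
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from evonet.datastore import DataStore
from evonet.divergence import CODON_TABLE, syn_site_fraction
from evonet.netstats import GeneNetwork

REF_ORG = "ref"

_SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
_NUCS = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic world.

    lineage_depth is N, the reference terminal depth (14, the human-lineage
    value, by default). branching is the number of side organisms attached at
    each divergence level. target_ka / target_ks are substitutions per
    nonsynonymous / synonymous site for codon pairs.
    """

    seed: int = 0
    lineage_depth: int = 14
    branching: int = 1
    n_genes: int = 20
    birth_levels: tuple[int, ...] | None = None
    ortholog_density: float = 1.0
    codon_length: int = 100
    target_ka: float = 0.05
    target_ks: float = 0.2
    network_density: float = 0.3

    def __post_init__(self) -> None:
        if self.lineage_depth < 1:
            raise ValueError("lineage_depth must be >= 1")
        if self.branching < 1:
            raise ValueError("branching must be >= 1")
        if not 0.0 < self.ortholog_density <= 1.0:
            raise ValueError("ortholog_density must lie in (0, 1]")
        if self.birth_levels is not None:
            if any(not 0 <= b <= self.lineage_depth for b in self.birth_levels):
                raise ValueError("birth levels must lie in [0, lineage_depth]")


@dataclass
class CodonPair:
    """A mutated CDS pair plus its planted substitution counts."""

    nt_a: str
    aa_a: str
    nt_b: str
    aa_b: str
    n_syn: int
    n_nonsyn: int


def reference_lineage(n: int) -> tuple[str, ...]:
    taxa = ["Cellular Organisms"] + [f"Clade{d:02d}" for d in range(1, n)] + ["RefSpecies"]
    return tuple(taxa[: n + 1])


def make_taxonomy(cfg: SimConfig) -> pd.DataFrame:
    """Organisms table: the reference plus side organisms at every level.

    The side organism ``o<b><j>`` diverges from the reference lineage exactly
    at depth b (its LCA with the reference is b).
    """
    n = cfg.lineage_depth
    ref_lin = reference_lineage(n)
    rows = [(REF_ORG, "Reference species", ";".join(ref_lin))]
    for b in range(n):
        for j in range(cfg.branching):
            code = f"o{b:02d}{chr(97 + j)}"
            lineage = list(ref_lin[: b + 1]) + [f"SideClade_{b:02d}_{j}", f"Species_{code}"]
            rows.append((code, f"Side species {code}", ";".join(lineage)))
    df = pd.DataFrame(rows, columns=["org_code", "name", "lineage"])
    return df.assign(lineage=[tuple(s.split(";")) for s in df["lineage"]])


def make_gene_set(
    cfg: SimConfig, organisms: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Genes, hits and domains tables with planted birth levels.

    Returns (genes, hits, domains, birth_level_of_ref_gene). A reference
    gene born at level b gets ortholog genes in side organisms at levels
    b..N-1 — always the one at the boundary level b, the rest sampled at
    ortholog_density — each linked by a hit comfortably above the default
    score thresholds.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.lineage_depth
    if cfg.birth_levels is not None:
        births = list(cfg.birth_levels)
        n_genes = len(births)
    else:
        n_genes = cfg.n_genes
        births = [int(rng.integers(0, n + 1)) for _ in range(n_genes)]

    side_orgs_at = {
        b: [f"o{b:02d}{chr(97 + j)}" for j in range(cfg.branching)] for b in range(n)
    }
    gene_rows, hit_rows, dom_rows = [], [], []
    birth_of: dict[str, int] = {}
    for i, b in enumerate(births):
        gid = f"{REF_ORG}:g{i:03d}"
        birth_of[gid] = b
        gene_rows.append((gid, REF_ORG, f"G{i:03d}", f"EC:1.1.1.{i}"))
        doms = [f"D{i:03d}_{k}" for k in range(1 + i % 2)]
        for d in doms:
            dom_rows.append((gid, d))
        if b >= n:
            continue  # youngest possible: no ortholog outside the reference
        eligible = [o for lvl in range(b, n) for o in side_orgs_at[lvl]]
        boundary = side_orgs_at[b][0]
        chosen = {boundary}
        for o in eligible:
            if o != boundary and rng.random() < cfg.ortholog_density:
                chosen.add(o)
        for o in sorted(chosen):
            oid = f"{o}:g{i:03d}"
            gene_rows.append((oid, o, f"G{i:03d}_{o}", ""))
            sw = float(rng.uniform(600, 1500))
            ident = float(rng.uniform(0.6, 0.95))
            hit_rows.append((gid, oid, round(sw, 1), round(ident, 4)))
            for d in doms:
                dom_rows.append((oid, d))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "org_code", "label", "annotation"])
    hits = pd.DataFrame(hit_rows, columns=["query_gene", "subject_gene", "sw_score", "identity"])
    if hits.empty:
        hits = pd.DataFrame({
            "query_gene": pd.Series(dtype=str), "subject_gene": pd.Series(dtype=str),
            "sw_score": pd.Series(dtype=float), "identity": pd.Series(dtype=float),
        })
    else:
        hits = hits.astype({"sw_score": float, "identity": float})
    domains = pd.DataFrame(dom_rows, columns=["gene_id", "domain_id"]).drop_duplicates()
    return genes, hits, domains, birth_of


def _p_from_rate(d: float) -> float:
    """Invert the Jukes-Cantor correction: expected difference proportion."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(_SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
                   for _ in range(n_codons))


def _substitution_options(codon: str, synonymous: bool) -> list[str]:
    aa = CODON_TABLE[codon]
    opts = []
    for pos in range(3):
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1:]
            if CODON_TABLE[alt] == "*":
                continue
            if (CODON_TABLE[alt] == aa) == synonymous:
                opts.append(alt)
    return opts


def mutate_cds(
    nt: str, rng: np.random.Generator, n_syn: int, n_nonsyn: int
) -> str:
    """Apply the requested substitution counts, at most one per codon.

    One substitution per codon keeps planted counts identifiable: pathway
    averaging in the NG86 counter then classifies every difference exactly
    as planted.
    """
    codons = [nt[i: i + 3] for i in range(0, len(nt), 3)]
    order = list(rng.permutation(len(codons)))
    todo = [True] * n_syn + [False] * n_nonsyn
    rng.shuffle(todo)
    placed = 0
    for want_syn in todo:
        while order:
            idx = order.pop()
            opts = _substitution_options(codons[idx], want_syn)
            if opts:
                codons[idx] = opts[int(rng.integers(len(opts)))]
                placed += 1
                break
        else:
            raise ValueError("not enough codons to place the requested substitutions")
    return "".join(codons)


def translate(nt: str) -> str:
    return "".join(CODON_TABLE[nt[i: i + 3]] for i in range(0, len(nt), 3))


def make_codon_pair(cfg: SimConfig, rng: np.random.Generator | None = None) -> CodonPair:
    """Ancestral CDS + mutated copy with planted syn/nonsyn counts.

    The counts are the target rates converted to expected difference
    proportions (inverse Jukes-Cantor) times the ancestral NG86 site counts,
    rounded. No stop codons appear in either sequence.
    """
    if cfg.codon_length < 30:
        raise ValueError("codon_length must be at least 30 codons")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    nt_a = _random_cds(rng, cfg.codon_length)
    s_sites = sum(syn_site_fraction(nt_a[i: i + 3]) for i in range(0, len(nt_a), 3))
    n_sites = 3 * cfg.codon_length - s_sites
    n_syn = round(_p_from_rate(cfg.target_ks) * s_sites)
    n_nonsyn = round(_p_from_rate(cfg.target_ka) * n_sites)
    nt_b = mutate_cds(nt_a, rng, n_syn, n_nonsyn)
    return CodonPair(
        nt_a=nt_a, aa_a=translate(nt_a), nt_b=nt_b, aa_b=translate(nt_b),
        n_syn=n_syn, n_nonsyn=n_nonsyn,
    )


def simulate_datastore(cfg: SimConfig) -> tuple[DataStore, GeneNetwork, dict[str, int]]:
    """Full synthetic world: datastore + network + planted birth levels.

    Every gene (reference and ortholog) gets coding and protein sequences;
    ortholog sequences are mutated copies of the reference gene's CDS at the
    configured target rates.
    """
    rng = np.random.default_rng(cfg.seed)
    organisms = make_taxonomy(cfg)
    genes, hits, domains, birth_of = make_gene_set(cfg, organisms)

    nt_seqs: dict[str, str] = {}
    aa_seqs: dict[str, str] = {}
    ref_cds: dict[str, str] = {}
    for _, row in genes.iterrows():
        gid = row["gene_id"]
        if row["org_code"] == REF_ORG:
            nt = _random_cds(rng, cfg.codon_length)
            ref_cds[gid] = nt
        else:
            src = f"{REF_ORG}:{gid.split(':')[1]}"
            anc = ref_cds[src]
            s_sites = sum(syn_site_fraction(anc[i: i + 3]) for i in range(0, len(anc), 3))
            n_sites = 3 * cfg.codon_length - s_sites
            nt = mutate_cds(
                anc, rng,
                round(_p_from_rate(cfg.target_ks) * s_sites),
                round(_p_from_rate(cfg.target_ka) * n_sites),
            )
        nt_seqs[gid] = nt
        aa_seqs[gid] = translate(nt)

    ds = DataStore(
        organisms=organisms, genes=genes, hits=hits, domains=domains,
        nt_seqs=nt_seqs, aa_seqs=aa_seqs,
    )

    net = GeneNetwork()
    ref_genes = [g for g in birth_of]
    for g in ref_genes:
        net.add_node(f"n_{g}", "gene", gene_id=g, label=g.split(":")[1])
    n_compounds = max(1, len(ref_genes) // 5)
    for c in range(n_compounds):
        net.add_node(f"cpd{c:02d}", "compound", label=f"C{c:02d}")
    for i, a in enumerate(ref_genes):
        for b in ref_genes[i + 1:]:
            if rng.random() < cfg.network_density:
                net.add_edge(f"n_{a}", f"n_{b}", interaction="reaction")
    for c in range(n_compounds):
        picks = rng.choice(len(ref_genes), size=min(2, len(ref_genes)), replace=False)
        for k in picks:
            net.add_edge(f"cpd{c:02d}", f"n_{ref_genes[int(k)]}", interaction="compound")
    return ds, net, birth_of
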