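"""Divergence index (Ka/Ks) of a gene against its nearest ortholog.

Pipeline: pick the ortholog from the taxonomically closest organism, align
the two proteins globally (Needleman–Wunsch, BLOSUM62, affine gaps), thread
the codons through the protein alignment, then count synonymous and
nonsynonymous sites and differences with the Nei–Gojobori (1986) method and
apply the Jukes–Cantor correction ``d = -(3/4) * ln(1 - (4/3) * p)``.

NG86 conventions used here: a codon's synonymous site count is the fraction
of its nine single-nucleotide neighbors (three per position, each position
weighted 1/3 per alternative) that preserve the amino acid, with changes
producing a stop codon counted as nonsynonymous; site totals are averaged
over the two sequences. For codon pairs differing at two or three positions,
differences are averaged with equal weight over all minimal substitution
pathways, excluding pathways that pass through a stop codon (if every
pathway is blocked, all are used). Alignment columns containing a gap or a
stop codon are excluded entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import TYPE_CHECKING

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from evonet.taxonomy import TaxonomyTree, lca_depth

if TYPE_CHECKING:  # pragma: no cover
    from evonet.datastore import DataStore
    from evonet.homology import FilterConfig

GAP_CODON = "---"
_NUCS = "ACGT"

# codon -> amino acid ('*' for stop), standard nuclear code
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class AlignParams:
    """Global protein alignment parameters.

    A gap run of length L is penalized gap_open + gap_extend * L, terminal
    gaps included.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


@dataclass(frozen=True)
class ProteinAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    @property
    def identity(self) -> float:
        same = sum(1 for x, y in zip(self.aligned_a, self.aligned_b)
                   if x == y and x != "-")
        return same / len(self.aligned_a)


@dataclass(frozen=True)
class CodonAlignment:
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]


@dataclass(frozen=True)
class DiResult:
    gene_id: str
    ortholog_gene_id: str | None
    ortholog_org: str | None
    ka: float | None
    ks: float | None
    di: float | None
    status: str  # ok | undefined_ks_zero | saturated | no_ortholog
    method: str = "NG86"


def select_nearest_ortholog(
    tree: TaxonomyTree,
    ref_org: str,
    ortholog_genes: dict[str, str],
    max_dist: int | None = None,
    whitelist: set[str] | None = None,
) -> str | None:
    """Pick the ortholog gene from the organism closest to the reference.

    ortholog_genes maps gene_id -> org_code. Taxonomic distance is measured
    as N_ref - lca_depth (lineage levels between the reference terminal and
    the divergence node). Candidates outside the whitelist or beyond
    max_dist are dropped; among the rest the maximal LCA depth wins, with
    ties broken by org_code then gene_id. Returns None if nothing survives.
    """
    n_ref = tree.terminal_depth(ref_org)
    best: tuple[int, str, str] | None = None
    for gene_id, org in ortholog_genes.items():
        if org == ref_org:
            continue
        if whitelist is not None and org not in whitelist:
            continue
        depth = lca_depth(tree, ref_org, org)
        if max_dist is not None and (n_ref - depth) > max_dist:
            continue
        key = (-depth, org, gene_id)
        if best is None or key < best:
            best = key
    return best[2] if best else None


_ALIGNER_CACHE: dict[AlignParams, PairwiseAligner] = {}


def _aligner(params: AlignParams) -> PairwiseAligner:
    aligner = _ALIGNER_CACHE.get(params)
    if aligner is None:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load(params.matrix)
        # first gap position charged open+extend, each further one extend:
        # a run of length L costs gap_open + gap_extend * L in total
        aligner.open_gap_score = -(params.gap_open + params.gap_extend)
        aligner.extend_gap_score = -params.gap_extend
        _ALIGNER_CACHE[params] = aligner
    return aligner


def global_align(a: str, b: str, params: AlignParams = AlignParams()) -> ProteinAlignment:
    """Optimal global protein alignment under affine gap scoring.

    Ties between co-optimal alignments are broken by the aligner's canonical
    enumeration order, so the result is deterministic.
    """
    for name, seq in (("a", a), ("b", b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        for i, res in enumerate(seq):
            if res not in STANDARD_RESIDUES:
                raise ValueError(f"sequence {name}: unknown residue {res!r} at position {i}")
    aln = _aligner(params).align(a, b)
    best = aln[0]
    return ProteinAlignment(aligned_a=str(best[0]), aligned_b=str(best[1]), score=aln.score)


def codon_align(pa: ProteinAlignment, nt_a: str, nt_b: str) -> CodonAlignment:
    """Thread the coding sequences through the protein alignment.

    Each residue column is replaced by its codon, each gap by "---". The
    coding sequences must be exactly 3x the ungapped protein lengths and
    every codon must translate (standard code) to its aligned residue.
    """
    out: dict[str, list[str]] = {"a": [], "b": []}
    for key, aligned, nt in (("a", pa.aligned_a, nt_a), ("b", pa.aligned_b, nt_b)):
        ungapped = aligned.replace("-", "")
        if len(nt) != 3 * len(ungapped):
            raise ValueError(
                f"sequence {key}: nt length {len(nt)} != 3 x protein length {len(ungapped)}"
            )
        pos = 0
        for res in aligned:
            if res == "-":
                out[key].append(GAP_CODON)
                continue
            codon = nt[3 * pos: 3 * pos + 3].upper()
            if CODON_TABLE.get(codon) != res:
                raise ValueError(
                    f"sequence {key}: codon {codon!r} at codon index {pos} "
                    f"does not translate to residue {res!r}"
                )
            out[key].append(codon)
            pos += 1
    return CodonAlignment(codons_a=tuple(out["a"]), codons_b=tuple(out["b"]))


def syn_site_fraction(codon: str) -> float:
    """Synonymous site count of one codon (0..3).

    Each position contributes (number of synonymous single-nucleotide
    changes) / 3; changes creating a stop codon are nonsynonymous.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            neighbor = codon[:pos] + nuc + codon[pos + 1:]
            if CODON_TABLE[neighbor] == aa and CODON_TABLE[neighbor] != "*":
                s += 1 / 3
    return s


def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """(syn, nonsyn) differences for one codon pair, pathway-averaged."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    if len(diff_pos) == 1:
        i = diff_pos[0]
        syn = 1.0 if CODON_TABLE[ca] == CODON_TABLE[cb] else 0.0
        return syn, 1.0 - syn
    paths = []
    for order in permutations(diff_pos):
        cur = ca
        sd = nd = 0.0
        blocked = False
        for i in order:
            nxt = cur[:i] + cb[i] + cur[i + 1:]
            if CODON_TABLE[nxt] == "*" and nxt != cb:
                blocked = True
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, sd, nd))
    open_paths = [(sd, nd) for blocked, sd, nd in paths if not blocked]
    if not open_paths:
        open_paths = [(sd, nd) for _, sd, nd in paths]
    sd = sum(p[0] for p in open_paths) / len(open_paths)
    nd = sum(p[1] for p in open_paths) / len(open_paths)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    return -0.75 * math.log(1 - (4 / 3) * p)


def kaks_ng86(ca: CodonAlignment) -> tuple[float | None, float | None, str]:
    """Nei–Gojobori (1986) Ka and Ks with Jukes–Cantor correction.

    Columns containing a gap codon or a stop codon are excluded. Returns
    (ka, ks, status) where status is "ok", "undefined_ks_zero" (no synonymous
    difference observed — the ratio Ka/Ks is undefined) or "saturated"
    (p >= 3/4, the correction diverges).
    """
    pairs = [
        (a, b) for a, b in zip(ca.codons_a, ca.codons_b)
        if a != GAP_CODON and b != GAP_CODON
        and CODON_TABLE[a] != "*" and CODON_TABLE[b] != "*"
    ]
    if not pairs:
        raise ValueError("codon alignment has no countable columns")

    s_sites = sum((syn_site_fraction(a) + syn_site_fraction(b)) / 2 for a, b in pairs)
    n_sites = 3 * len(pairs) - s_sites
    sd = nd = 0.0
    for a, b in pairs:
        ds_, dn_ = _pathway_counts(a, b)
        sd += ds_
        nd += dn_

    p_s = sd / s_sites if s_sites > 0 else 0.0
    p_n = nd / n_sites if n_sites > 0 else 0.0
    if p_s >= 0.75 or p_n >= 0.75:
        return None, None, "saturated"
    ka = _jukes_cantor(p_n) + 0.0  # normalize -0.0
    ks = _jukes_cantor(p_s) + 0.0
    if sd == 0:
        return ka, ks, "undefined_ks_zero"
    return ka, ks, "ok"


def compute_di(
    gene_id: str,
    ds: "DataStore",
    tree: TaxonomyTree,
    cfg: "FilterConfig",
    params: AlignParams = AlignParams(),
) -> DiResult:
    """Full divergence pipeline for one gene.

    Orthologs are the genes linked to gene_id by filtered hits (either
    direction) that pass the configured domain filter and live in another
    organism; the nearest one (by LCA depth, subject to cfg.max_dist and
    cfg.whitelist) is aligned and NG86-counted. DI = Ka/Ks when defined.
    """
    from evonet.pipeline import ortholog_genes_of

    if gene_id not in ds.aa_seqs or gene_id not in ds.nt_seqs:
        raise KeyError(f"gene {gene_id!r} is missing nt or aa sequence")
    ref_org = ds.org_of_gene(gene_id)
    candidates = ortholog_genes_of(gene_id, ds, cfg)
    mapped = {
        g: ds.org_of_gene(g) for g in candidates
        if g in ds.aa_seqs and g in ds.nt_seqs
    }
    chosen = select_nearest_ortholog(
        tree, ref_org, mapped,
        max_dist=cfg.max_dist,
        whitelist=set(cfg.whitelist) if cfg.whitelist is not None else None,
    )
    if chosen is None:
        return DiResult(gene_id, None, None, None, None, None, "no_ortholog")
    pa = global_align(ds.aa_seqs[gene_id], ds.aa_seqs[chosen], params)
    ca = codon_align(pa, ds.nt_seqs[gene_id], ds.nt_seqs[chosen])
    ka, ks, status = kaks_ng86(ca)
    di = ka / ks if status == "ok" else None
    return DiResult(gene_id, chosen, mapped[chosen], ka, ks, di, status)
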