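"""Flat-file datastore of organisms, genes, homology hits, domains and sequences.

The datastore is a directory of TSV tables plus two FASTA files and stands in
for an online annotation resource, so every analysis runs offline:

* ``organisms.tsv`` — org_code, name, lineage (semicolon-joined taxa, root first)
* ``genes.tsv`` — gene_id, org_code, label, annotation
* ``hits.tsv`` — query_gene, subject_gene, sw_score, identity
* ``domains.tsv`` — gene_id, domain_id
* ``nt.fasta`` / ``aa.fasta`` — CDS and protein sequences keyed by gene_id

TSV dialect: UTF-8, tab-separated, one header line, lines starting with ``#``
ignored. A trailing stop codon in a CDS (``len(nt) == 3*len(aa) + 3``) is
trimmed on load so that the codon-length invariant ``len(nt) == 3*len(aa)``
always holds in memory.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ROOT_TAXON = "Cellular Organisms"

ORGANISM_COLS = ["org_code", "name", "lineage"]
GENE_COLS = ["gene_id", "org_code", "label", "annotation"]
HIT_COLS = ["query_gene", "subject_gene", "sw_score", "identity"]
DOMAIN_COLS = ["gene_id", "domain_id"]

_STOPS = {"TAA", "TAG", "TGA"}


class DataStoreError(ValueError):
    """Raised when a datastore directory cannot be loaded."""


@dataclass
class DataStore:
    """In-memory datastore.

    ``organisms.lineage`` holds tuples of taxon names, root first. The hits
    table keeps its on-disk row order; filtering operations preserve it.
    """

    organisms: pd.DataFrame
    genes: pd.DataFrame
    hits: pd.DataFrame
    domains: pd.DataFrame
    nt_seqs: dict[str, str] = field(default_factory=dict)
    aa_seqs: dict[str, str] = field(default_factory=dict)

    def lineage_of(self, org_code: str) -> tuple[str, ...]:
        row = self.organisms.loc[self.organisms["org_code"] == org_code]
        if row.empty:
            raise KeyError(f"unknown organism {org_code!r}")
        return row.iloc[0]["lineage"]

    def org_of_gene(self, gene_id: str) -> str:
        row = self.genes.loc[self.genes["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(f"unknown gene {gene_id!r}")
        return row.iloc[0]["org_code"]

    def domains_of(self, gene_id: str) -> frozenset[str]:
        return frozenset(
            self.domains.loc[self.domains["gene_id"] == gene_id, "domain_id"]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DataStore):
            return NotImplemented
        return (
            self.organisms.reset_index(drop=True).equals(other.organisms.reset_index(drop=True))
            and self.genes.reset_index(drop=True).equals(other.genes.reset_index(drop=True))
            and self.hits.reset_index(drop=True).equals(other.hits.reset_index(drop=True))
            and self.domains.reset_index(drop=True).equals(other.domains.reset_index(drop=True))
            and self.nt_seqs == other.nt_seqs
            and self.aa_seqs == other.aa_seqs
        )


def _read_tsv(path: Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    except pd.errors.ParserError as exc:
        raise DataStoreError(f"{path.name}: malformed TSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataStoreError(f"{path.name}: missing columns {missing}")
    return df[columns]


def _read_fasta(path: Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def load_datastore(path: str | Path) -> DataStore:
    """Load and validate a datastore directory.

    Raises :class:`DataStoreError` naming the offending file or row when a
    mandatory file is missing, a row is malformed, or a cross-reference or
    type invariant is violated.
    """
    path = Path(path)
    mandatory = ["organisms.tsv", "genes.tsv", "hits.tsv", "domains.tsv", "nt.fasta", "aa.fasta"]
    for name in mandatory:
        if not (path / name).exists():
            raise DataStoreError(f"missing mandatory datastore file: {name}")

    organisms = _read_tsv(path / "organisms.tsv", ORGANISM_COLS)
    organisms = organisms.assign(
        lineage=[tuple(t.strip() for t in s.split(";")) for s in organisms["lineage"]]
    )
    genes = _read_tsv(path / "genes.tsv", GENE_COLS)
    hits = _read_tsv(path / "hits.tsv", HIT_COLS)
    if len(hits):
        try:
            hits = hits.assign(
                sw_score=hits["sw_score"].astype(float),
                identity=hits["identity"].astype(float),
            )
        except ValueError as exc:
            raise DataStoreError(f"hits.tsv: non-numeric score column ({exc})") from exc
    else:
        hits = hits.assign(sw_score=pd.Series(dtype=float), identity=pd.Series(dtype=float))
    domains = _read_tsv(path / "domains.tsv", DOMAIN_COLS)

    nt_seqs = _read_fasta(path / "nt.fasta")
    aa_seqs = _read_fasta(path / "aa.fasta")

    # trailing stop codons in CDS entries are conventional; trim them
    for gid, nt in list(nt_seqs.items()):
        aa = aa_seqs.get(gid)
        if aa is not None and len(nt) == 3 * len(aa) + 3 and nt[-3:] in _STOPS:
            nt_seqs[gid] = nt[:-3]

    ds = DataStore(organisms, genes, hits, domains, nt_seqs, aa_seqs)
    violations = validate_datastore(ds)
    if violations:
        raise DataStoreError("invalid datastore:\n" + "\n".join(violations))
    return ds


def validate_datastore(ds: DataStore) -> list[str]:
    """Check every type invariant; return human-readable violations.

    Returns the empty list exactly when the datastore would be accepted by
    :func:`load_datastore`. Never raises.
    """
    v: list[str] = []
    org_codes = set(ds.organisms["org_code"])

    if ds.organisms["org_code"].duplicated().any():
        dups = ds.organisms.loc[ds.organisms["org_code"].duplicated(), "org_code"]
        v.append(f"organisms: duplicated org_code {sorted(set(dups))}")

    roots = set()
    for i, row in ds.organisms.iterrows():
        lin = row["lineage"]
        if not lin or lin == ("",):
            v.append(f"organisms row {i} ({row['org_code']}): empty lineage")
            continue
        roots.add(lin[0])
        if len(set(lin)) != len(lin):
            v.append(f"organisms row {i} ({row['org_code']}): repeated taxon in lineage")
    if len(roots) > 1:
        v.append(f"organisms: lineages disagree on the root taxon: {sorted(roots)}")

    gene_ids = set(ds.genes["gene_id"])
    if ds.genes["gene_id"].duplicated().any():
        dups = ds.genes.loc[ds.genes["gene_id"].duplicated(), "gene_id"]
        v.append(f"genes: duplicated gene_id {sorted(set(dups))}")
    for i, row in ds.genes.iterrows():
        if row["org_code"] not in org_codes:
            v.append(f"genes row {i} ({row['gene_id']}): unknown org_code {row['org_code']!r}")

    for i, row in ds.hits.iterrows():
        if row["query_gene"] not in gene_ids:
            v.append(f"hits row {i}: unknown query_gene {row['query_gene']!r}")
        if row["subject_gene"] not in gene_ids:
            v.append(f"hits row {i}: unknown subject_gene {row['subject_gene']!r}")
        if row["query_gene"] == row["subject_gene"]:
            v.append(f"hits row {i}: self-hit {row['query_gene']!r}")
        if not (float(row["sw_score"]) >= 0):
            v.append(f"hits row {i}: negative sw_score")
        if not (0.0 <= float(row["identity"]) <= 1.0):
            v.append(f"hits row {i}: identity outside [0,1]")

    if ds.domains.duplicated().any():
        v.append("domains: duplicated (gene_id, domain_id) pair")
    for i, row in ds.domains.iterrows():
        if row["gene_id"] not in gene_ids:
            v.append(f"domains row {i}: unknown gene_id {row['gene_id']!r}")

    for gid in ds.nt_seqs:
        if gid not in gene_ids:
            v.append(f"nt.fasta: unknown gene_id {gid!r}")
    for gid in ds.aa_seqs:
        if gid not in gene_ids:
            v.append(f"aa.fasta: unknown gene_id {gid!r}")
    for gid, aa in ds.aa_seqs.items():
        nt = ds.nt_seqs.get(gid)
        if nt is not None and len(nt) != 3 * len(aa):
            v.append(
                f"sequences for {gid}: nt length {len(nt)} is not 3 x aa length {len(aa)}"
            )
    return v


def write_datastore(ds: DataStore, path: str | Path) -> None:
    """Write a datastore directory; inverse of :func:`load_datastore`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    org = ds.organisms.assign(lineage=[";".join(l) for l in ds.organisms["lineage"]])
    org.to_csv(path / "organisms.tsv", sep="\t", index=False)
    ds.genes.to_csv(path / "genes.tsv", sep="\t", index=False)
    ds.hits.to_csv(path / "hits.tsv", sep="\t", index=False)
    ds.domains.to_csv(path / "domains.tsv", sep="\t", index=False)
    _write_fasta(ds.nt_seqs, path / "nt.fasta")
    _write_fasta(ds.aa_seqs, path / "aa.fasta")


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    with io.StringIO() as buf:
        SeqIO.write(records, buf, "fasta")
        path.write_text(buf.getvalue())
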