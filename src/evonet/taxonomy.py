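"""Taxonomy trees from lineage strings and the phylostratigraphic age index.

The tree is the merged prefix tree of all organism lineages (root depth 0,
child depth = parent depth + 1). The phylostratigraphic age index (PAI) of a
gene is the depth, on the reference organism's lineage, of the deepest node
that is still an ancestor of every organism carrying an ortholog of the gene:
0 means the gene traces back to the shared root ("Cellular Organisms"), N —
the reference terminal depth — means no ortholog outside the reference
organism was found. Equivalently, PAI is the minimum over ortholog-bearing
organisms of the LCA depth with the reference, which is how it is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


class TaxonomyError(ValueError):
    """Raised on inconsistent lineages or unknown organisms."""


@dataclass(frozen=True)
class PaiResult:
    """Age call for one gene.

    pai is an integer in [0, N]; taxon_name is the reference lineage entry at
    that depth; ortholog_orgs are the organisms that supported the call.
    """

    gene_id: str
    pai: int
    taxon_name: str
    ortholog_orgs: frozenset[str]
    n_orthologs: int


class TaxonomyTree:
    """Merged prefix tree over organism lineages.

    Taxon names are assumed unique across the tree: a name appearing in two
    lineages must have the same parent in both, otherwise construction fails.
    """

    def __init__(self) -> None:
        self.parent: dict[str, str | None] = {}
        self.depth: dict[str, int] = {}
        self._org_lineage: dict[str, tuple[str, ...]] = {}

    @property
    def organisms(self) -> list[str]:
        return sorted(self._org_lineage)

    def lineage(self, org_code: str) -> tuple[str, ...]:
        try:
            return self._org_lineage[org_code]
        except KeyError:
            raise TaxonomyError(f"organism {org_code!r} is not attached to the tree") from None

    def terminal_depth(self, org_code: str) -> int:
        """N for this organism: depth of its terminal taxon."""
        return len(self.lineage(org_code)) - 1

    def add_lineage(self, org_code: str, lineage: tuple[str, ...]) -> None:
        if not lineage:
            raise TaxonomyError(f"organism {org_code!r}: empty lineage")
        for d, taxon in enumerate(lineage):
            parent = lineage[d - 1] if d > 0 else None
            if taxon in self.parent:
                if self.parent[taxon] != parent:
                    raise TaxonomyError(
                        f"taxon {taxon!r} has conflicting parents "
                        f"{self.parent[taxon]!r} and {parent!r}"
                    )
            else:
                self.parent[taxon] = parent
                self.depth[taxon] = d
        self._org_lineage[org_code] = tuple(lineage)


def build_taxonomy(organisms: pd.DataFrame) -> TaxonomyTree:
    """Build the merged tree from an organisms table (org_code, lineage)."""
    tree = TaxonomyTree()
    for _, row in organisms.iterrows():
        tree.add_lineage(row["org_code"], tuple(row["lineage"]))
    roots = {lin[0] for lin in tree._org_lineage.values()}
    if len(roots) > 1:
        raise TaxonomyError(f"lineages disagree on the root taxon: {sorted(roots)}")
    return tree


def lca_depth(tree: TaxonomyTree, org_a: str, org_b: str) -> int:
    """Depth of the deepest common ancestor of two organisms' terminal taxa."""
    la, lb = tree.lineage(org_a), tree.lineage(org_b)
    d = -1
    for ta, tb in zip(la, lb):
        if ta != tb:
            break
        d += 1
    if d < 0:
        raise TaxonomyError(f"{org_a!r} and {org_b!r} share no ancestor")
    return d


def compute_pai(
    tree: TaxonomyTree,
    ref_org: str,
    ortholog_orgs: set[str],
    gene_id: str = "",
    n_orthologs: int | None = None,
) -> PaiResult:
    """PAI of a reference-organism gene given its ortholog-bearing organisms.

    The reference organism itself is ignored (paralogs do not age a gene);
    with no other organism in the set the gene is as young as the reference
    terminal taxon (PAI = N).
    """
    ref_lineage = tree.lineage(ref_org)
    others = set(ortholog_orgs) - {ref_org}
    if others:
        pai = min(lca_depth(tree, ref_org, o) for o in others)
    else:
        pai = len(ref_lineage) - 1
    return PaiResult(
        gene_id=gene_id,
        pai=pai,
        taxon_name=ref_lineage[pai],
        ortholog_orgs=frozenset(others),
        n_orthologs=len(others) if n_orthologs is None else n_orthologs,
    )


def taxon_name_at(tree: TaxonomyTree, ref_org: str, depth: int) -> str:
    """Taxon name at a given depth on the reference organism's lineage."""
    lineage = tree.lineage(ref_org)
    if not 0 <= depth < len(lineage):
        raise TaxonomyError(
            f"depth {depth} outside [0, {len(lineage) - 1}] for organism {ref_org!r}"
        )
    return lineage[depth]
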