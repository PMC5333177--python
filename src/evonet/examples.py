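"""Small worked-example fixtures.

The taxonomy below encodes the classic human lineage with 15 levels
(depth 0 = "Cellular Organisms" ... depth 14 = "Homo", so N = 14), with a
few companion species attached where they diverge from it: bonobo and
chimpanzee inside Hominidae (LCA depth 13 with human), orangutan at
Hominidae as well, mouse inside Euarchontoglires (depth 9), opossum inside
Mammalia (depth 7), zebrafish inside Vertebrata (depth 5) and fly inside
Metazoa (depth 3). It is the canonical in-memory example for age-index
computations: a human gene whose only ortholog lives in bonobo is young
(PAI 13, "Hominidae"); one with an ortholog as far out as opossum dates
back to Mammalia (PAI 7).
"""

from __future__ import annotations

import pandas as pd

HUMAN_LINEAGE: tuple[str, ...] = (
    "Cellular Organisms",   # 0
    "Eukaryota",            # 1
    "Opisthokonta",         # 2
    "Metazoa",              # 3
    "Chordata",             # 4
    "Vertebrata",           # 5
    "Euteleostomi",         # 6
    "Mammalia",             # 7
    "Eutheria",             # 8
    "Euarchontoglires",     # 9
    "Primates",             # 10
    "Haplorrhini",          # 11
    "Catarrhini",           # 12
    "Hominidae",            # 13
    "Homo",                 # 14
)

# org_code -> (name, depth of divergence from the human lineage, own tail)
_COMPANIONS: dict[str, tuple[str, int, tuple[str, ...]]] = {
    "pps": ("Pan paniscus (bonobo)", 13, ("Pan", "Pan paniscus")),
    "ptr": ("Pan troglodytes (chimpanzee)", 13, ("Pan", "Pan troglodytes")),
    "pon": ("Pongo abelii (orangutan)", 13, ("Pongo", "Pongo abelii")),
    "mmu": ("Mus musculus (mouse)", 9, ("Glires", "Rodentia", "Mus musculus")),
    "mdo": ("Monodelphis domestica (opossum)", 7,
            ("Metatheria", "Didelphimorphia", "Monodelphis domestica")),
    "dre": ("Danio rerio (zebrafish)", 5,
            ("Actinopterygii", "Cypriniformes", "Danio rerio")),
    "dme": ("Drosophila melanogaster (fly)", 3,
            ("Arthropoda", "Insecta", "Drosophila melanogaster")),
}


def human_example_organisms() -> pd.DataFrame:
    """Organisms table for the worked example; loadable by build_taxonomy."""
    rows = [("hsa", "Homo sapiens (human)", HUMAN_LINEAGE)]
    for code, (name, depth, tail) in _COMPANIONS.items():
        rows.append((code, name, HUMAN_LINEAGE[: depth + 1] + tail))
    return pd.DataFrame(rows, columns=["org_code", "name", "lineage"])
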