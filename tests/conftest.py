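import numpy as np
import pandas as pd
import pytest

from evonet.datastore import DataStore
from evonet.examples import human_example_organisms
from evonet.netstats import GeneNetwork
from evonet.taxonomy import build_taxonomy


@pytest.fixture(scope="session")
def human_organisms() -> pd.DataFrame:
    return human_example_organisms()


@pytest.fixture(scope="session")
def human_tree(human_organisms):
    return build_taxonomy(human_organisms)


def make_datastore(
    organisms: pd.DataFrame,
    genes: list[tuple[str, str]],
    hits: list[tuple[str, str, float, float]] = (),
    domains: list[tuple[str, str]] = (),
    nt_seqs: dict[str, str] | None = None,
    aa_seqs: dict[str, str] | None = None,
) -> DataStore:
    """Hand-rolled datastore from terse tuples for unit tests."""
    gene_df = pd.DataFrame(
        [(g, o, g, "") for g, o in genes],
        columns=["gene_id", "org_code", "label", "annotation"],
    )
    hit_df = pd.DataFrame(list(hits), columns=["query_gene", "subject_gene", "sw_score", "identity"])
    if hit_df.empty:
        hit_df = pd.DataFrame({
            "query_gene": pd.Series(dtype=str), "subject_gene": pd.Series(dtype=str),
            "sw_score": pd.Series(dtype=float), "identity": pd.Series(dtype=float),
        })
    dom_df = pd.DataFrame(list(domains), columns=["gene_id", "domain_id"])
    return DataStore(
        organisms=organisms, genes=gene_df, hits=hit_df, domains=dom_df,
        nt_seqs=dict(nt_seqs or {}), aa_seqs=dict(aa_seqs or {}),
    )


def star_network(gene_ids: list[str]) -> GeneNetwork:
    """First gene is the hub, the rest are leaves."""
    net = GeneNetwork()
    for g in gene_ids:
        net.add_node(f"n_{g}", "gene", gene_id=g)
    hub = f"n_{gene_ids[0]}"
    for g in gene_ids[1:]:
        net.add_edge(hub, f"n_{g}")
    return net


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
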