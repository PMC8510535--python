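import io as _io

import dendropy
import numpy as np
import pandas as pd
import pytest

from ecoassembly.io import OtuTable, PhyloTree


def tree_from_newick(newick: str) -> PhyloTree:
    return PhyloTree(dendropy.Tree.get(data=newick, schema="newick"))


@pytest.fixture
def two_tip_tree() -> PhyloTree:
    return tree_from_newick("(A:1,B:1);")


@pytest.fixture
def three_tip_tree() -> PhyloTree:
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def six_taxon_tree() -> PhyloTree:
    return tree_from_newick(
        "(((A:0.5,B:0.7):0.4,(C:0.3,D:0.9):0.6):0.2,(E:1.1,F:0.8):0.5);"
    )


def random_table(
    rng: np.random.Generator, n_samples: int, n_taxa: int, depth: int = 200
) -> OtuTable:
    """Random multinomial count table with lognormal taxon weights."""
    w = rng.lognormal(0, 1, n_taxa)
    counts = np.vstack(
        [rng.multinomial(depth, w / w.sum()) for _ in range(n_samples)]
    )
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{i}" for i in range(n_taxa)],
        )
    )


def random_tree(rng: np.random.Generator, labels) -> PhyloTree:
    """Random coalescent-ish tree over the given tip labels."""
    nodes = [f"{lbl}:{rng.uniform(0.1, 1):.4f}" for lbl in labels]
    while len(nodes) > 1:
        i, j = 0, 1
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 1):.4f}"
        nodes = [merged] + nodes[2:]
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    return tree_from_newick(newick)


def table_from_text(text: str) -> OtuTable:
    return OtuTable(pd.read_csv(_io.StringIO(text), sep=r"\s+", index_col=0))
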