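"""Input/output and depth normalisation for OTU/ASV count tables.

The central object is :class:`OtuTable`, a thin validated wrapper around a
samples x taxa pandas DataFrame of non-negative integer counts.  Trees are
handled through :class:`PhyloTree`, which wraps a rooted dendropy tree and
caches the patristic (branch-length path) distance matrix that the
MNTD-family statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "PhyloTree",
    "read_otu_table",
    "read_tree",
    "read_metadata",
    "read_functions",
    "rarefy",
    "relative_abundance",
]


@dataclass
class OtuTable:
    """Samples x taxa count table.

    Parameters
    ----------
    counts
        DataFrame with sample identifiers as the index and taxon identifiers
        as columns.  Values must be non-negative and finite.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("empty table")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon identifiers: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric cells in count table")
        if not np.isfinite(values).all():
            raise ValueError("non-finite cells in count table")
        if (values < 0).any():
            raise ValueError("negative count in table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        """Counts as a float ndarray (samples x taxa)."""
        return self.counts.to_numpy(dtype=float)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def drop_empty_taxa(self) -> "OtuTable":
        """Remove taxa with zero total abundance."""
        keep = self.counts.sum(axis=0) > 0
        return OtuTable(self.counts.loc[:, keep])

    def subset_taxa(self, taxon_ids) -> "OtuTable":
        return OtuTable(self.counts.loc[:, list(taxon_ids)])

    def to_tsv(self, path, orientation: str = "samples_as_rows") -> None:
        df = self.counts
        if orientation == "taxa_as_rows":
            df = df.T
            df.index.name = "taxon_id"
        else:
            df = df.copy()
            df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


def read_otu_table(path, orientation: str = "samples_as_rows") -> OtuTable:
    """Read a dense TSV count table.

    ``orientation`` must be declared by the caller ("samples_as_rows" or
    "taxa_as_rows"); no auto-detection is attempted, since a silently
    transposed table is a classic source of wrong downstream statistics.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "taxa_as_rows":
        df = df.T
    return OtuTable(df)


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths; source of patristic distances."""

    tree: dendropy.Tree
    _dist_cache: dict = field(default_factory=dict, repr=False)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def patristic_matrix(self, taxon_ids=None) -> pd.DataFrame:
        """Symmetric patristic distance matrix over ``taxon_ids``.

        Raises if any requested taxon is missing from the tree tips.
        """
        labels = self.tip_labels
        if taxon_ids is None:
            taxon_ids = labels
        missing = set(taxon_ids) - set(labels)
        if missing:
            raise ValueError(
                f"tips incomplete: tree is missing {sorted(missing)[:5]}"
                f"{'...' if len(missing) > 5 else ''}"
            )
        key = tuple(taxon_ids)
        if key not in self._dist_cache:
            full = self._full_matrix()
            self._dist_cache[key] = full.loc[list(taxon_ids), list(taxon_ids)]
        return self._dist_cache[key]

    def _full_matrix(self) -> pd.DataFrame:
        if "__full__" in self._dist_cache:
            return self._dist_cache["__full__"]
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = [t for t in self.tree.taxon_namespace if t.label in set(self.tip_labels)]
        labels = [t.label for t in taxa]
        n = len(taxa)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[i], taxa[j])
                mat[i, j] = mat[j, i] = d
        df = pd.DataFrame(mat, index=labels, columns=labels)
        self._dist_cache["__full__"] = df
        return df

    def distance(self, a: str, b: str) -> float:
        return float(self._full_matrix().loc[a, b])

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def read_tree(path, midpoint_root: bool = False) -> PhyloTree:
    """Read a Newick tree with branch lengths.

    By default the file's rooting is trusted; ``midpoint_root=True`` reroots
    at the midpoint instead (use for trees exported unrooted).
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("missing branch lengths in tree")
    if midpoint_root:
        tree.reroot_at_midpoint(update_bipartitions=True)
    return PhyloTree(tree)


def read_metadata(path) -> pd.DataFrame:
    """Per-sample metadata TSV keyed on sample_id; treatment column expected."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValueError("duplicate sample identifiers in metadata")
    return df


def read_functions(path) -> pd.DataFrame:
    """Per-sample ecosystem-function TSV keyed on sample_id; numeric columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.isfinite(values).all():
        raise ValueError("function table must be numeric and finite")
    return df


def rarefy(
    table: OtuTable,
    depth: int | None = None,
    seed: int = 0,
    drop_small: bool = False,
) -> OtuTable:
    """Subsample every sample to a common depth without replacement.

    Each sample is drawn with a multivariate hypergeometric draw from its own
    counts, so the result is a true rarefaction (subsampling of observed
    individuals), not a multinomial resample.  ``depth=None`` uses the
    minimum sample total, mirroring rarefaction "to the minimum sequencing
    depth".  Samples with totals below ``depth`` raise unless
    ``drop_small=True``.
    """
    totals = table.sample_totals
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    small = totals[totals < depth]
    if len(small) > 0:
        if not drop_small:
            raise ValueError(
                f"samples below depth {depth}: {list(small.index)}"
            )
        table = OtuTable(table.counts.loc[totals >= depth])
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy().astype(np.int64)
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(
        pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    )


def relative_abundance(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Row-normalise counts to proportions; rows sum to 1."""
    df = table.counts if isinstance(table, OtuTable) else table
    totals = df.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return df.div(totals, axis=0)
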