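"""Co-occurrence networks, module detection, Zi-Pi, and keystone roles.

Edges connect prevalence-filtered taxa whose relative abundances are
strongly rank-correlated across samples (|rho| above a fixed threshold,
Benjamini-Hochberg adjusted p below a cap).  Topological roles follow the
within-module degree z-score (Zi) and among-module participation
coefficient (Pi): network hubs (Zi > 2.5 and Pi > 0.62), module hubs
(Zi > 2.5 and Pi < 0.62), connectors (Zi < 2.5 and Pi > 0.62); everything
else, including exact threshold hits, is peripheral.  The union of the
three hub/connector roles is the keystone set.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from networkx.algorithms.community import greedy_modularity_communities, modularity
from statsmodels.stats.multitest import multipletests

from .io import OtuTable, relative_abundance

KEYSTONE_ROLES = ("network_hub", "module_hub", "connector")

__all__ = [
    "KEYSTONE_ROLES",
    "build_network",
    "detect_modules",
    "zi_pi",
    "classify_keystones",
    "node_table",
]


def build_network(
    table,
    min_prevalence: float = 0.5,
    method: str = "spearman",
    min_abs_r: float = 0.8,
    max_p: float = 0.05,
    adjust: str | None = "bh",
    node_tags: pd.DataFrame | None = None,
) -> nx.Graph:
    """Correlation network over prevalence-filtered taxa.

    ``table`` is an OtuTable (converted to relative abundance) or an
    already-normalised samples x taxa DataFrame.  ``node_tags`` optionally
    supplies per-taxon attributes (e.g. kingdom, rare/abundant group) to
    attach to nodes.
    """
    if isinstance(table, OtuTable):
        rel = relative_abundance(table)
        presence = table.counts.to_numpy() > 0
    else:
        rel = table
        presence = rel.to_numpy() > 0
    n_samples = rel.shape[0]
    if n_samples < 8:
        raise ValueError("need at least 8 samples for rank correlations")
    prevalence = presence.mean(axis=0)
    keep = prevalence >= min_prevalence
    if keep.sum() < 2:
        raise ValueError("fewer than 2 taxa survive the prevalence filter")
    sub = rel.loc[:, rel.columns[keep]]
    taxa = list(sub.columns)

    if method == "spearman":
        rho, pval = scipy.stats.spearmanr(sub.to_numpy())
    elif method == "pearson":
        arr = sub.to_numpy()
        k = arr.shape[1]
        rho = np.corrcoef(arr, rowvar=False)
        # two-sided t-test p-values for Pearson r
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n_samples - 2) / (1 - rho**2))
        pval = 2 * scipy.stats.t.sf(np.abs(t), df=n_samples - 2)
        np.fill_diagonal(pval, 0.0)
    else:
        raise ValueError(f"unknown method: {method!r}")
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to scalars
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        pval = np.array([[0.0, float(pval)], [float(pval), 0.0]])

    iu, ju = np.triu_indices(len(taxa), k=1)
    p_flat = np.asarray(pval)[iu, ju]
    if adjust == "bh":
        p_flat = multipletests(p_flat, method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment: {adjust!r}")

    g = nx.Graph()
    mean_rel = sub.mean(axis=0)
    for t in taxa:
        attrs = {"mean_relative_abundance": float(mean_rel[t])}
        if node_tags is not None and t in node_tags.index:
            attrs.update(node_tags.loc[t].to_dict())
        g.add_node(t, **attrs)
    r_flat = rho[iu, ju]
    for a, b, r, p in zip(iu, ju, r_flat, p_flat):
        if abs(r) >= min_abs_r and p <= max_p:
            g.add_edge(
                taxa[a],
                taxa[b],
                rho=float(r),
                p_adj=float(p),
                sign="positive" if r > 0 else "negative",
            )
    return g


def detect_modules(net: nx.Graph, seed: int = 0) -> tuple[dict, float]:
    """Greedy modularity maximisation; edges treated unweighted/unsigned.

    Returns (node -> module id, modularity of the partition).  The greedy
    algorithm is deterministic; ``seed`` is accepted for interface
    stability.
    """
    if net.number_of_edges() == 0:
        raise ValueError("empty network: no edges to partition")
    communities = greedy_modularity_communities(net)
    q = modularity(net, communities)
    assignment = {}
    for mid, members in enumerate(communities):
        for node in sorted(members):
            assignment[node] = mid
    return assignment, float(q)


def zi_pi(net: nx.Graph, modules: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardises a node's within-module degree against its module's
    mean and (population) standard deviation; Zi = 0 where the module sd
    is 0.  Pi = 1 - sum_m (k_im / k_i)^2 over modules m.  Isolated nodes
    (degree 0) have undefined Pi and are excluded from the result.
    """
    missing = [n for n in net.nodes if n not in modules]
    if missing:
        raise ValueError(f"module assignment incomplete: {missing[:5]}")
    nodes = [n for n in net.nodes if net.degree(n) > 0]

    within = {
        n: sum(1 for nb in net.neighbors(n) if modules[nb] == modules[n])
        for n in nodes
    }
    by_module: dict[int, list] = {}
    for n in nodes:
        by_module.setdefault(modules[n], []).append(within[n])
    mod_mean = {m: float(np.mean(v)) for m, v in by_module.items()}
    mod_sd = {m: float(np.std(v)) for m, v in by_module.items()}

    rows = []
    for n in nodes:
        k = net.degree(n)
        per_module: dict[int, int] = {}
        for nb in net.neighbors(n):
            per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
        pi = 1.0 - sum((km / k) ** 2 for km in per_module.values())
        sd = mod_sd[modules[n]]
        zi = 0.0 if sd == 0 else (within[n] - mod_mean[modules[n]]) / sd
        rows.append(
            {"node": n, "module": modules[n], "degree": k,
             "within_degree": within[n], "Zi": zi, "Pi": pi}
        )
    return pd.DataFrame(rows).set_index("node")


def classify_keystones(zipi: pd.DataFrame) -> pd.Series:
    """Topological role per node from strict Zi/Pi thresholds."""
    zi = zipi["Zi"].to_numpy(dtype=float)
    pi = zipi["Pi"].to_numpy(dtype=float)
    if not (np.isfinite(zi).all() and np.isfinite(pi).all()):
        raise ValueError("Zi and Pi must be finite")
    role = np.full(len(zipi), "peripheral", dtype=object)
    role[(zi > 2.5) & (pi > 0.62)] = "network_hub"
    role[(zi > 2.5) & (pi < 0.62)] = "module_hub"
    role[(zi < 2.5) & (pi > 0.62)] = "connector"
    return pd.Series(role, index=zipi.index, name="role")


def node_table(net: nx.Graph, modules: dict) -> pd.DataFrame:
    """Full per-node summary: attributes, module, degree, Zi, Pi, role."""
    zipi = zi_pi(net, modules)
    zipi["role"] = classify_keystones(zipi)
    attrs = pd.DataFrame.from_dict(dict(net.nodes(data=True)), orient="index")
    out = zipi.join(attrs, how="left")
    out.index.name = "taxon_id"
    return out
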