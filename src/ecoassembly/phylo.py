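"""Nearest-taxon phylogenetic statistics and their tip-shuffle null models.

Observed statistics
-------------------
MNTD (mean nearest taxon distance) averages, over the taxa present in one
sample, the patristic distance to the closest other taxon in that sample.
betaMNTD is the between-sample analogue: each taxon is matched to its
nearest relative in the *other* sample, and the two directed means are
averaged, giving a symmetric phylogenetic turnover measure.  Both come
abundance-weighted (weights = within-sample relative abundances) or
unweighted (uniform over the taxa present).

Null model and standardised scores
----------------------------------
The null shuffles taxon labels on the patristic distance matrix ("taxa
labels" null): richness and abundances are untouched, only the phylogenetic
identities are randomised.  SES.MNTD and betaNTI are the observed statistic
minus the null mean, in units of the null standard deviation; |betaNTI| > 2
between a pair of communities is the conventional signature of
deterministic selection.  One stream of shuffles is shared by every sample
pair of a table, which keeps the pairwise matrix consistent and allows the
whole null distribution to be computed with vectorised matrix products.

A null standard deviation of zero (e.g. a star phylogeny, or an identical
pair whose betaMNTD is zero under every relabelling) makes the score
undefined; such entries are flagged degenerate rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable, PhyloTree

__all__ = ["PhyloNullMatrices", "mntd", "ses_mntd", "beta_mntd", "beta_nti"]


def _weights(abund: np.ndarray, weighted: bool) -> np.ndarray:
    """Per-taxon weights over the support of one sample (sums to 1)."""
    support = abund > 0
    w = np.zeros_like(abund, dtype=float)
    if weighted:
        w[support] = abund[support] / abund[support].sum()
    else:
        w[support] = 1.0 / support.sum()
    return w


def mntd(abund, dmat, weighted: bool = True) -> float:
    """Mean nearest taxon distance within one sample.

    ``abund`` is the sample's taxon abundance vector aligned with ``dmat``
    (square patristic distances).
    """
    abund = np.asarray(abund, dtype=float)
    d = np.asarray(dmat, dtype=float)
    idx = np.flatnonzero(abund > 0)
    if len(idx) < 2:
        raise ValueError("need at least 2 taxa present in the sample")
    sub = d[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    nn = sub.min(axis=1)
    if weighted:
        w = abund[idx] / abund[idx].sum()
        return float(w @ nn)
    return float(nn.mean())


def beta_mntd(x, y, dmat, weighted: bool = True) -> float:
    """Between-sample mean nearest taxon distance (betaMNTD), symmetric."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.asarray(dmat, dtype=float)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("empty sample")
    ix = np.flatnonzero(x > 0)
    iy = np.flatnonzero(y > 0)
    wx = _weights(x, weighted)[ix]
    wy = _weights(y, weighted)[iy]
    nn_x = d[np.ix_(ix, iy)].min(axis=1)  # each taxon of x to nearest in y
    nn_y = d[np.ix_(iy, ix)].min(axis=1)
    return float(0.5 * (wx @ nn_x + wy @ nn_y))


def _beta_mntd_all_pairs(
    d: np.ndarray, supports: list[np.ndarray], weights: np.ndarray
) -> np.ndarray:
    """betaMNTD for every sample pair via one matrix product.

    ``weights`` is samples x taxa with rows summing to 1 over each support.
    For sample y, ``m_y[i] = min_{j in support(y)} d[i, j]``; then
    betaMNTD(x, y) = 0.5 (w_x . m_y + w_y . m_x).
    """
    n = len(supports)
    m = np.empty((n, d.shape[0]))
    for s in range(n):
        m[s] = d[:, supports[s]].min(axis=1)
    g = weights @ m.T
    return 0.5 * (g + g.T)


def _prepare(table: OtuTable, tree: PhyloTree, weighted: bool):
    d = tree.patristic_matrix(table.taxon_ids).to_numpy(dtype=float)
    counts = table.matrix
    supports = [np.flatnonzero(row > 0) for row in counts]
    for s, supp in zip(table.sample_ids, supports):
        if len(supp) == 0:
            raise ValueError(f"empty sample: {s}")
    weights = np.vstack([_weights(row, weighted) for row in counts])
    return d, supports, weights


@dataclass
class PhyloNullMatrices:
    """Pairwise observed statistic, null moments, and standardised scores."""

    observed: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    score: pd.DataFrame  # betaNTI; NaN where degenerate
    degenerate: pd.DataFrame
    n_null: int
    seed: int

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per unordered sample pair."""
        ids = list(self.observed.index)
        rows = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append(
                    {
                        "sample_i": ids[i],
                        "sample_j": ids[j],
                        "beta_mntd": self.observed.iat[i, j],
                        "beta_nti": self.score.iat[i, j],
                        "degenerate": bool(self.degenerate.iat[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _null_moments(sums, sumsq, n_null):
    mean = sums / n_null
    var = (sumsq - n_null * mean**2) / (n_null - 1)
    var = np.maximum(var, 0.0)
    return mean, np.sqrt(var)


def beta_nti(
    table: OtuTable,
    tree: PhyloTree,
    n_null: int = 999,
    weighted: bool = True,
    seed: int = 0,
) -> PhyloNullMatrices:
    """Pairwise betaNTI under the taxa-labels null.

    Returns the symmetric matrices of observed betaMNTD, null mean/sd, and
    betaNTI = (obs - null mean) / null sd; entries with zero null variance
    are flagged in ``degenerate`` and carry NaN scores.
    """
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    d, supports, weights = _prepare(table, tree, weighted)
    obs = _beta_mntd_all_pairs(d, supports, weights)

    rng = np.random.default_rng(seed)
    n_taxa = d.shape[0]
    sums = np.zeros_like(obs)
    sumsq = np.zeros_like(obs)
    for _ in range(n_null):
        order = rng.permutation(n_taxa)
        dp = d[np.ix_(order, order)]
        bm = _beta_mntd_all_pairs(dp, supports, weights)
        sums += bm
        sumsq += bm**2
    mean, sd = _null_moments(sums, sumsq, n_null)

    degenerate = sd <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(degenerate, np.nan, (obs - mean) / np.where(degenerate, 1, sd))
    np.fill_diagonal(score, np.nan)
    np.fill_diagonal(degenerate, True)

    ids = table.sample_ids
    as_df = lambda a: pd.DataFrame(a, index=ids, columns=ids)
    return PhyloNullMatrices(
        observed=as_df(obs),
        null_mean=as_df(mean),
        null_sd=as_df(sd),
        score=as_df(score),
        degenerate=as_df(degenerate),
        n_null=n_null,
        seed=seed,
    )


def ses_mntd(
    table: OtuTable,
    tree: PhyloTree,
    n_null: int = 999,
    weighted: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample SES.MNTD under the taxa-labels null.

    Negative values indicate phylogenetic clustering (taxa closer together
    on the tree than random relabelling allows).
    """
    d, supports, weights = _prepare(table, tree, weighted)

    def per_sample_mntd(dist):
        vals = np.empty(len(supports))
        for s, supp in enumerate(supports):
            if len(supp) < 2:
                raise ValueError(
                    f"need at least 2 taxa present: {table.sample_ids[s]}"
                )
            sub = dist[np.ix_(supp, supp)].copy()
            np.fill_diagonal(sub, np.inf)
            vals[s] = weights[s, supp] @ sub.min(axis=1)
        return vals

    obs = per_sample_mntd(d)
    rng = np.random.default_rng(seed)
    n_taxa = d.shape[0]
    sums = np.zeros_like(obs)
    sumsq = np.zeros_like(obs)
    for _ in range(n_null):
        order = rng.permutation(n_taxa)
        vals = per_sample_mntd(d[np.ix_(order, order)])
        sums += vals
        sumsq += vals**2
    mean, sd = _null_moments(sums, sumsq, n_null)
    degenerate = sd <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = np.where(degenerate, np.nan, (obs - mean) / np.where(degenerate, 1, sd))
    return pd.DataFrame(
        {
            "mntd_obs": obs,
            "null_mean": mean,
            "null_sd": sd,
            "ses_mntd": ses,
            "degenerate": degenerate,
        },
        index=table.sample_ids,
    )
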