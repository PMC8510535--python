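"""Raup-Crick (Bray-Curtis) null model and the five-way assembly partition.

The taxonomic null model assembles, for each sample, a randomised
community that preserves the sample's observed richness and total count:
taxa are drawn without replacement with probability proportional to their
occupancy across samples (fraction of samples occupied), each drawn taxon
receives one individual, and the remaining individuals are distributed
multinomially with probability proportional to regional relative abundance
restricted to the drawn taxa.  RC_bray compares the observed Bray-Curtis
dissimilarity of a pair with its null distribution and rescales to
[-1, 1]; ties between null and observed count at half weight, which makes
RC unbiased under exchangeability.

Processes are then assigned per pair from (betaNTI, RC_bray):

=====================  =======================================
variable selection      betaNTI > 2
homogeneous selection   betaNTI < -2
dispersal limitation    |betaNTI| < 2 and RC > 0.95
homogenizing dispersal  |betaNTI| < 2 and RC < -0.95
undominated             |betaNTI| < 2 and |RC| < 0.95
=====================  =======================================

The printed rules use strict inequalities on both sides, so exact
threshold hits (|betaNTI| = 2, |RC| = 0.95) fall in no bin and are labelled
``unassigned``, as are degenerate-null pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist

from .commstats import PermTestResult, mantel
from .io import OtuTable

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

__all__ = [
    "PROCESSES",
    "AssemblyResult",
    "raup_crick_bray",
    "partition_processes",
    "process_proportions",
    "bnti_env_association",
]


def null_community_table(
    counts: np.ndarray,
    rng: np.random.Generator,
    occupancy_weighted: bool = True,
    abundance_weighted: bool = True,
) -> np.ndarray:
    """One null realisation of every sample of a counts matrix.

    Each sample keeps its observed richness and total; composition is
    randomised from the regional pool as described in the module docstring.
    """
    n_samples, n_taxa = counts.shape
    occupancy = (counts > 0).mean(axis=0)
    p_occ = occupancy / occupancy.sum() if occupancy_weighted else None
    regional = counts.sum(axis=0).astype(float)
    out = np.zeros_like(counts, dtype=np.int64)
    for s in range(n_samples):
        richness = int(np.count_nonzero(counts[s]))
        total = int(counts[s].sum())
        if richness == 0:
            raise ValueError(f"zero-richness sample at index {s}")
        chosen = rng.choice(n_taxa, size=richness, replace=False, p=p_occ)
        out[s, chosen] = 1
        if total > richness:
            if abundance_weighted:
                p_fill = regional[chosen]
                p_fill = p_fill / p_fill.sum()
            else:
                p_fill = np.full(richness, 1.0 / richness)
            out[s, chosen] += rng.multinomial(total - richness, p_fill)
    return out


def raup_crick_bray(
    table: OtuTable,
    n_null: int = 999,
    seed: int = 0,
    occupancy_weighted: bool = True,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """Pairwise RC_bray matrix in [-1, 1].

    RC = 2 * (#{null BC < observed} + 0.5 #{null BC = observed}) / n_null - 1.
    Values near +1 mean the pair is more dissimilar than the stochastic
    null expects (e.g. dispersal limitation); near -1, more similar
    (homogenizing dispersal).
    """
    counts = table.matrix
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    obs = pdist(counts, metric="braycurtis")
    rng = np.random.default_rng(seed)
    below = np.zeros_like(obs)
    ties = np.zeros_like(obs)
    for _ in range(n_null):
        null = null_community_table(
            counts, rng, occupancy_weighted, abundance_weighted
        )
        bc = pdist(null.astype(float), metric="braycurtis")
        eq = np.isclose(bc, obs, rtol=1e-12, atol=1e-12)
        below += (bc < obs) & ~eq
        ties += eq
    rc = ((below + 0.5 * ties) / n_null) * 2.0 - 1.0
    ids = table.sample_ids
    mat = np.zeros((len(ids), len(ids)))
    iu = np.triu_indices(len(ids), k=1)
    mat[iu] = rc
    mat = mat + mat.T
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class AssemblyResult:
    """Per-pair process labels and the group-level process proportions."""

    pairs: pd.DataFrame  # sample_i, sample_j, beta_nti, rc_bray, process
    proportions: pd.Series  # over the five processes, sums to 1

    @property
    def n_assigned(self) -> int:
        return int((self.pairs["process"] != "unassigned").sum())


def _assign_process(bnti: float, rc: float) -> str:
    if not np.isfinite(bnti):
        return "unassigned"
    if bnti > 2:
        return "variable_selection"
    if bnti < -2:
        return "homogeneous_selection"
    if abs(bnti) < 2:
        if not np.isfinite(rc):
            return "unassigned"
        if rc > 0.95:
            return "dispersal_limitation"
        if rc < -0.95:
            return "homogenizing_dispersal"
        if abs(rc) < 0.95:
            return "undominated"
    return "unassigned"  # exact threshold hits fall in no printed bin


def partition_processes(bnti: pd.DataFrame, rc: pd.DataFrame) -> AssemblyResult:
    """Assign an assembly process to every sample pair."""
    if list(bnti.index) != list(rc.index) or list(bnti.columns) != list(rc.columns):
        raise ValueError("betaNTI and RC matrices must be aligned on the same pairs")
    ids = list(bnti.index)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            b = float(bnti.iat[i, j])
            r = float(rc.iat[i, j])
            rows.append(
                {
                    "sample_i": ids[i],
                    "sample_j": ids[j],
                    "beta_nti": b,
                    "rc_bray": r,
                    "process": _assign_process(b, r),
                }
            )
    pairs = pd.DataFrame(rows)
    if (pairs["process"] != "unassigned").any():
        proportions = process_proportions(pairs)
    else:
        proportions = pd.Series(np.nan, index=list(PROCESSES), name="proportion")
    return AssemblyResult(pairs=pairs, proportions=proportions)


def process_proportions(pairs: pd.DataFrame) -> pd.Series:
    """Fractions of the five processes among assigned pairs (sum to 1)."""
    assigned = pairs[pairs["process"] != "unassigned"]
    if len(assigned) == 0:
        raise ValueError("zero assigned pairs")
    counts = assigned["process"].value_counts()
    return pd.Series(
        {p: counts.get(p, 0) / len(assigned) for p in PROCESSES}, name="proportion"
    )


def bnti_env_association(
    bnti: pd.DataFrame,
    env: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Mantel test and linear regression of betaNTI against |delta env|.

    Pairs with degenerate (NaN) betaNTI are dropped from the regression;
    the Mantel test requires a complete matrix and raises if any score is
    missing.
    """
    ids = list(bnti.index)
    missing = [s for s in ids if s not in env.index]
    if missing:
        raise ValueError(f"env missing for samples: {missing}")
    e = env.loc[ids].to_numpy(dtype=float)
    if np.ptp(e) == 0:
        raise ValueError("constant environmental variable")
    denv = np.abs(e[:, None] - e[None, :])
    b = bnti.to_numpy(dtype=float)

    iu = np.triu_indices(len(ids), k=1)
    bv, ev = b[iu], denv[iu]
    ok = np.isfinite(bv)
    if ok.sum() < 3:
        raise ValueError("too few finite betaNTI pairs")
    ols = scipy.stats.linregress(ev[ok], bv[ok])

    mantel_res: PermTestResult | None = None
    if ok.all():
        bsym = b.copy()
        np.fill_diagonal(bsym, 0.0)
        mantel_res = mantel(
            _SquareMatrix(bsym, ids),
            _SquareMatrix(denv, ids),
            n_perm=n_perm,
            seed=seed,
        )
    return {
        "mantel": mantel_res,
        "slope": float(ols.slope),
        "intercept": float(ols.intercept),
        "r": float(ols.rvalue),
        "p_slope": float(ols.pvalue),
    }


class _SquareMatrix:
    """Minimal distance-matrix-like wrapper (betaNTI can be negative, which
    a strict distance container would reject)."""

    def __init__(self, data: np.ndarray, ids):
        self.data = np.asarray(data, dtype=float)
        self.ids = list(ids)
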