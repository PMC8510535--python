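"""Diversity, dissimilarity, and permutation tests against environment.

Permutation p-values throughout follow the convention
``p = (1 + #{permuted statistic >= observed}) / (n_perm + 1)``,
so the minimum attainable p is ``1/(n_perm + 1)`` and never 0.

The Mantel and environment-fitting tests are implemented with batched
permutations: the test statistic under a label permutation is a linear
functional of the permuted (rank-transformed) vector, so all ``n_perm``
replicates reduce to one matrix product.  This keeps 999-permutation runs
fast enough for the type-I-error calibration studies in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa
from statsmodels.stats.multitest import multipletests

from .io import OtuTable

__all__ = [
    "PermTestResult",
    "shannon",
    "bray_curtis",
    "euclidean_distance",
    "similarity_to_control",
    "mantel",
    "envfit_permutation",
    "spearman_heatmap",
]


@dataclass
class PermTestResult:
    """Observed statistic and its permutation p-value."""

    statistic: float
    p_value: float
    n_perm: int
    seed: int
    method: str

    def __iter__(self):  # allow tuple unpacking (stat, p)
        return iter((self.statistic, self.p_value))


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) of one sample."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    return float(scipy.stats.entropy(arr))


def _as_samples_matrix(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, OtuTable):
        return table.matrix, table.sample_ids
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.index)
    arr = np.asarray(table, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def bray_curtis(table) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity of a samples x taxa table."""
    arr, ids = _as_samples_matrix(table)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    zero_rows = [ids[i] for i in np.flatnonzero(arr.sum(axis=1) == 0)]
    if len(zero_rows) >= 2:
        raise ValueError(
            f"Bray-Curtis undefined for pair of all-zero samples: {zero_rows}"
        )
    return DistanceMatrix(squareform(pdist(arr, metric="braycurtis")), ids=ids)


def euclidean_distance(values) -> DistanceMatrix:
    """Pairwise Euclidean distance of per-sample values.

    ``values`` may be a Series (scalar per sample, e.g. a multifunctionality
    index, giving |v_i - v_j|) or a DataFrame (one row per sample, e.g. the
    full z-scored function matrix).
    """
    if isinstance(values, pd.Series):
        arr = values.to_numpy(dtype=float)[:, None]
        ids = list(values.index)
    else:
        arr, ids = _as_samples_matrix(values)
    return DistanceMatrix(squareform(pdist(arr, metric="euclidean")), ids=ids)


def similarity_to_control(
    dist: DistanceMatrix, meta: pd.DataFrame, control_label: str
) -> pd.DataFrame:
    """Per-treatment mean and dispersion of (1 - dissimilarity) to control.

    Every treatment replicate is paired with every control replicate; a
    greater value means the treatment community stayed closer to the
    control.  Returns a DataFrame indexed by treatment with columns
    ``mean_similarity``, ``sd_similarity``, ``n_pairs``.
    """
    treatments = meta["treatment"]
    if control_label not in set(treatments):
        raise ValueError(f"unknown control label: {control_label!r}")
    ids = list(dist.ids)
    control = [s for s in ids if treatments.get(s) == control_label]
    rows = []
    for treat in sorted(set(treatments) - {control_label}):
        members = [s for s in ids if treatments.get(s) == treat]
        sims = [1.0 - dist[t, c] for t in members for c in control]
        rows.append(
            {
                "treatment": treat,
                "mean_similarity": float(np.mean(sims)),
                "sd_similarity": float(np.std(sims, ddof=1)) if len(sims) > 1 else 0.0,
                "n_pairs": len(sims),
            }
        )
    return pd.DataFrame(rows).set_index("treatment")


def _condensed(dm: DistanceMatrix) -> np.ndarray:
    return squareform(np.asarray(dm.data), checks=False)


def _permutation_matrix(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> PermTestResult:
    """Mantel test of association between two distance matrices.

    The statistic is the (rank) correlation of the n(n-1)/2 upper-triangle
    entries; the null permutes sample labels of the first matrix.  The
    one-sided "greater" alternative is the convention for distance-matrix
    correlation and the default.
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share sample ids and order")
    n = len(d1.ids)
    if n < 4:
        raise ValueError("need at least 4 samples for a Mantel test")
    v1 = _condensed(d1)
    v2 = _condensed(d2)
    if method == "spearman":
        v1 = scipy.stats.rankdata(v1)
        v2 = scipy.stats.rankdata(v2)
    elif method != "pearson":
        raise ValueError(f"unknown method: {method!r}")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("degenerate matrix: constant distance vector")

    v1c = v1 - v1.mean()
    v2c = v2 - v2.mean()
    denom = np.linalg.norm(v1c) * np.linalg.norm(v2c)
    r_obs = float(v1c @ v2c / denom)

    rng = np.random.default_rng(seed)
    perms = _permutation_matrix(rng, n_perm, n)
    sq = squareform(v1, checks=False)  # rank-transformed square matrix
    iu, ju = np.triu_indices(n, k=1)
    # entries of the permuted condensed vector: a permutation of v1's entries,
    # so mean and norm are unchanged and rows need no re-centering
    vp = sq[perms[:, iu], perms[:, ju]]
    r_perm = (vp @ v2c) / denom

    if alternative == "greater":
        exceed = np.count_nonzero(r_perm >= r_obs - 1e-12)
    elif alternative == "two-sided":
        exceed = np.count_nonzero(np.abs(r_perm) >= abs(r_obs) - 1e-12)
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    p = (1 + exceed) / (n_perm + 1)
    return PermTestResult(r_obs, float(p), n_perm, seed, f"mantel_{method}")


def pcoa_coordinates(dist: DistanceMatrix, n_axes: int = 2) -> pd.DataFrame:
    """Principal-coordinate embedding, keeping positive-eigenvalue axes only."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pcoa(dist, method="eigh")
    eig = res.eigvals.to_numpy()
    pos = np.flatnonzero(eig > 1e-10)
    if len(pos) == 0:
        raise ValueError("embedding failure: no positive eigenvalues")
    keep = pos[: min(n_axes, len(pos))]
    coords = res.samples.iloc[:, keep]
    coords.index = list(dist.ids)
    return coords


def envfit_permutation(
    dist: DistanceMatrix,
    env,
    n_axes: int = 2,
    n_perm: int = 999,
    seed: int = 0,
) -> PermTestResult:
    """Monte Carlo permutation test of one environmental variable.

    The community distance matrix is embedded by PCoA on ``n_axes`` axes;
    R^2 is the squared multiple correlation between the variable and its
    least-squares projection onto those axes, and the p-value permutes the
    variable's values across samples.
    """
    env = np.asarray(env, dtype=float)
    if not np.all(np.isfinite(env)):
        raise ValueError("environmental variable must be finite")
    if np.ptp(env) == 0:
        raise ValueError("constant environmental variable")
    n = len(dist.ids)
    if len(env) != n:
        raise ValueError("env length must match number of samples")

    coords = pcoa_coordinates(dist, n_axes=n_axes).to_numpy()
    x = coords - coords.mean(axis=0)
    q, _ = np.linalg.qr(x)
    e = env - env.mean()
    ss_tot = float(e @ e)
    r2_obs = float(np.sum((q.T @ e) ** 2) / ss_tot)

    rng = np.random.default_rng(seed)
    perms = _permutation_matrix(rng, n_perm, n)
    ep = env[perms] - env.mean()  # permuting preserves the mean and norm
    r2_perm = np.sum((ep @ q) ** 2, axis=1) / ss_tot
    exceed = np.count_nonzero(r2_perm >= r2_obs - 1e-12)
    p = (1 + exceed) / (n_perm + 1)
    return PermTestResult(r2_obs, float(p), n_perm, seed, "envfit")


def spearman_heatmap(
    features: pd.DataFrame,
    env: pd.DataFrame,
    adjust: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and two-sided p for every (feature, env variable) pair.

    ``adjust="bh"`` replaces raw p-values with Benjamini-Hochberg adjusted
    values (adjusted within each environmental variable's column).
    """
    common = features.index.intersection(env.index)
    if len(common) < 4:
        raise ValueError("need at least 4 paired observations")
    f = features.loc[common]
    g = env.loc[common]
    rho = pd.DataFrame(index=f.columns, columns=g.columns, dtype=float)
    pval = pd.DataFrame(index=f.columns, columns=g.columns, dtype=float)
    for fc in f.columns:
        for gc in g.columns:
            if np.ptp(f[fc].to_numpy()) == 0 or np.ptp(g[gc].to_numpy()) == 0:
                raise ValueError(f"constant vector in ({fc}, {gc})")
            r, p = scipy.stats.spearmanr(f[fc], g[gc])
            rho.loc[fc, gc] = r
            pval.loc[fc, gc] = p
    if adjust == "bh":
        for gc in pval.columns:
            pval[gc] = multipletests(pval[gc].to_numpy(), method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment: {adjust!r}")
    return rho, pval
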