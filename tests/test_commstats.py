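import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from ecoassembly.commstats import (
    bray_curtis,
    envfit_permutation,
    euclidean_distance,
    mantel,
    pcoa_coordinates,
    shannon,
    similarity_to_control,
    spearman_heatmap,
)
from ecoassembly.io import OtuTable


class TestShannon:
    def test_uniform(self):
        assert shannon([5] * 10) == pytest.approx(np.log(10), abs=1e-12)

    def test_single_taxon(self):
        assert shannon([0, 42, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        expected = -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))
        assert shannon([1, 1, 2]) == pytest.approx(expected, abs=1e-12)
        assert shannon([1, 1, 2]) == pytest.approx(1.0397207708399179, abs=1e-9)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon([0, 0])


def bc_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return np.abs(x - y).sum() / (x + y).sum()


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        df = pd.DataFrame(
            [[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 4]],
            index=list("abc"),
            columns=list("wxyz"),
        )
        dm = bray_curtis(OtuTable(df))
        assert dm["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert dm["a", "c"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_value(self):
        df = pd.DataFrame([[2, 2, 0], [0, 2, 2]], index=["x", "y"], columns=list("abc"))
        assert bray_curtis(OtuTable(df))["x", "y"] == pytest.approx(0.5, abs=1e-12)

    def test_matches_oracle_on_random(self):
        rng = np.random.default_rng(11)
        arr = rng.integers(0, 30, (6, 9)) + (rng.random((6, 9)) < 0.3)
        df = pd.DataFrame(arr.astype(float))
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        dm = bray_curtis(df)
        for i, j in itertools.combinations(range(6), 2):
            assert dm[str(i), str(j)] == pytest.approx(
                bc_oracle(arr[i], arr[j]), abs=1e-10
            )

    def test_proportion_scaling_invariance(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 40, (4, 7)).astype(float)
        rel = counts / counts.sum(axis=1, keepdims=True)
        scaled = counts * np.array([[1], [13], [200], [7]])
        rel2 = scaled / scaled.sum(axis=1, keepdims=True)
        assert np.allclose(
            bray_curtis(rel).condensed_form(), bray_curtis(rel2).condensed_form()
        )

    def test_two_all_zero_samples_rejected(self):
        df = pd.DataFrame(
            [[0, 0], [0, 0], [1, 2]], index=list("abc"), columns=["x", "y"]
        )
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(df)


class TestSimilarityToControl:
    @pytest.fixture
    def meta(self):
        return pd.DataFrame(
            {"treatment": ["control", "control", "T", "T"]},
            index=["c1", "c2", "t1", "t2"],
        )

    def test_toy_mean(self, meta):
        mat = np.zeros((4, 4))
        # pairs (t, c): 0.2, 0.4, 0.6, 0.8 -> mean similarity 0.5
        mat[2, 0] = mat[0, 2] = 0.2
        mat[2, 1] = mat[1, 2] = 0.4
        mat[3, 0] = mat[0, 3] = 0.6
        mat[3, 1] = mat[1, 3] = 0.8
        dm = DistanceMatrix(mat, ids=["c1", "c2", "t1", "t2"])
        out = similarity_to_control(dm, meta, "control")
        assert out.loc["T", "mean_similarity"] == pytest.approx(0.5, abs=1e-12)
        assert out.loc["T", "n_pairs"] == 4

    def test_identical_gives_one(self, meta):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=["c1", "c2", "t1", "t2"])
        out = similarity_to_control(dm, meta, "control")
        assert out.loc["T", "mean_similarity"] == pytest.approx(1.0, abs=1e-12)

    def test_unknown_control_raises(self, meta):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=["c1", "c2", "t1", "t2"])
        with pytest.raises(ValueError, match="unknown control"):
            similarity_to_control(dm, meta, "nope")


def exhaustive_mantel_p(d1: np.ndarray, d2: np.ndarray, method="spearman"):
    """Exact permutation p over all label permutations of d1."""
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    v2 = d2[iu]
    if method == "spearman":
        v2 = scipy.stats.rankdata(v2)

    def corr(perm):
        dp = d1[np.ix_(perm, perm)]
        v1 = dp[iu]
        if method == "spearman":
            v1 = scipy.stats.rankdata(v1)
        return np.corrcoef(v1, v2)[0, 1]

    obs = corr(np.arange(n))
    rs = [corr(np.array(p)) for p in itertools.permutations(range(n))]
    return obs, np.mean([r >= obs - 1e-12 for r in rs])


class TestMantel:
    def _random_dm(self, rng, n):
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return d

    def test_identity(self):
        rng = np.random.default_rng(0)
        d = self._random_dm(rng, 8)
        ids = [f"s{i}" for i in range(8)]
        dm = DistanceMatrix(d, ids=ids)
        res = mantel(dm, dm, n_perm=199, seed=1)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 200)

    def test_minimum_p_convention(self):
        rng = np.random.default_rng(2)
        d = self._random_dm(rng, 10)
        ids = [f"s{i}" for i in range(10)]
        dm = DistanceMatrix(d, ids=ids)
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.p_value >= 1 / 100

    def test_agrees_with_skbio_statistic(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(3)
        ids = [f"s{i}" for i in range(9)]
        d1 = DistanceMatrix(self._random_dm(rng, 9), ids=ids)
        d2 = DistanceMatrix(self._random_dm(rng, 9), ids=ids)
        ours = mantel(d1, d2, method="spearman", n_perm=99, seed=4)
        theirs = skbio_mantel(d1, d2, method="spearman", permutations=0)
        assert ours.statistic == pytest.approx(float(theirs[0]), abs=1e-10)

    def test_montecarlo_close_to_exhaustive(self):
        rng = np.random.default_rng(7)
        d1 = self._random_dm(rng, 5)
        d2 = self._random_dm(rng, 5)
        ids = [f"s{i}" for i in range(5)]
        res = mantel(
            DistanceMatrix(d1, ids=ids), DistanceMatrix(d2, ids=ids),
            n_perm=999, seed=8,
        )
        obs, p_exact = exhaustive_mantel_p(d1, d2)
        assert res.statistic == pytest.approx(obs, abs=1e-10)
        assert abs(res.p_value - p_exact) <= 0.02

    def test_degenerate_raises(self):
        ids = list("abcd")
        flat = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=ids)
        with pytest.raises(ValueError, match="degenerate"):
            mantel(flat, flat)


class TestEnvfit:
    def test_perfect_fit_on_axis(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(10)])
        env = pcoa_coordinates(dm, n_axes=2).iloc[:, 0].to_numpy()
        res = envfit_permutation(dm, env, n_perm=99, seed=2)
        assert res.statistic == pytest.approx(1.0, abs=1e-8)
        assert res.p_value == pytest.approx(1 / 100)

    def test_montecarlo_close_to_exhaustive(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        env = rng.normal(size=6)
        res = envfit_permutation(dm, env, n_perm=999, seed=10)
        # exhaustive p over all 720 orderings of env
        coords = pcoa_coordinates(dm, n_axes=2).to_numpy()
        x = coords - coords.mean(axis=0)
        q, _ = np.linalg.qr(x)
        e0 = env - env.mean()
        ss = e0 @ e0
        r2s = []
        for perm in itertools.permutations(range(6)):
            e = env[list(perm)] - env.mean()
            r2s.append(np.sum((q.T @ e) ** 2) / ss)
        r2s = np.array(r2s)
        obs = np.sum((q.T @ e0) ** 2) / ss
        p_exact = np.mean(r2s >= obs - 1e-12)
        assert res.statistic == pytest.approx(obs, abs=1e-10)
        assert abs(res.p_value - p_exact) <= 0.03

    def test_constant_env_raises(self):
        d = np.abs(np.arange(5)[:, None] - np.arange(5)[None, :]).astype(float)
        dm = DistanceMatrix(d, ids=list("abcde"))
        with pytest.raises(ValueError, match="constant"):
            envfit_permutation(dm, np.ones(5))


def test_pcoa_reproduces_euclidean_distances():
    """Full-rank PCoA of a Euclidean-embeddable 4-point metric is exact."""
    pts = np.array([[0.0, 0], [1, 0], [0, 2], [3, 1]])
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    dm = DistanceMatrix(d, ids=list("abcd"))
    coords = pcoa_coordinates(dm, n_axes=3).to_numpy()
    rec = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
    assert np.allclose(rec, d, atol=1e-8)


class TestSpearmanHeatmap:
    def test_perfect_correlations(self):
        idx = [f"s{i}" for i in range(8)]
        env = pd.DataFrame({"pH": np.arange(8.0)}, index=idx)
        feats = pd.DataFrame(
            {"up": np.arange(8.0) ** 2, "down": -np.arange(8.0)}, index=idx
        )
        rho, p = spearman_heatmap(feats, env)
        assert rho.loc["up", "pH"] == pytest.approx(1.0)
        assert rho.loc["down", "pH"] == pytest.approx(-1.0)

    def test_midrank_oracle_with_ties(self):
        idx = [f"s{i}" for i in range(8)]
        x = np.array([1.0, 2, 2, 3, 3, 3, 4, 5])
        y = np.array([2.0, 1, 4, 4, 6, 5, 8, 7])
        feats = pd.DataFrame({"x": x}, index=idx)
        env = pd.DataFrame({"y": y}, index=idx)
        rho, _ = spearman_heatmap(feats, env)
        rx = scipy.stats.rankdata(x)  # midranks
        ry = scipy.stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["x", "y"] == pytest.approx(expected, abs=1e-12)


def test_euclidean_distance_scalar_is_absolute_difference():
    s = pd.Series([0.0, 1.5, -2.0], index=list("abc"))
    dm = euclidean_distance(s)
    assert dm["a", "b"] == pytest.approx(1.5)
    assert dm["b", "c"] == pytest.approx(3.5)
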