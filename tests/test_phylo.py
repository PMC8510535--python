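import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from ecoassembly.io import OtuTable
from ecoassembly.phylo import beta_mntd, beta_nti, mntd, ses_mntd

from conftest import random_table, random_tree, tree_from_newick


def mntd_oracle(abund, d, weighted):
    """Brute-force double loop over present taxa."""
    idx = [i for i, a in enumerate(abund) if a > 0]
    nn = []
    for i in idx:
        nn.append(min(d[i][j] for j in idx if j != i))
    if weighted:
        w = np.array([abund[i] for i in idx], float)
        w /= w.sum()
        return float(w @ np.array(nn))
    return float(np.mean(nn))


def beta_mntd_oracle(x, y, d, weighted):
    ix = [i for i, a in enumerate(x) if a > 0]
    iy = [j for j, a in enumerate(y) if a > 0]
    wx = np.array([x[i] for i in ix], float)
    wy = np.array([y[j] for j in iy], float)
    wx = wx / wx.sum() if weighted else np.full(len(ix), 1 / len(ix))
    wy = wy / wy.sum() if weighted else np.full(len(iy), 1 / len(iy))
    term_x = sum(w * min(d[i][j] for j in iy) for w, i in zip(wx, ix))
    term_y = sum(w * min(d[j][i] for i in ix) for w, j in zip(wy, iy))
    return 0.5 * (term_x + term_y)


class TestMntd:
    def test_two_tips(self, two_tip_tree):
        d = two_tip_tree.patristic_matrix(["A", "B"]).to_numpy()
        assert mntd([1, 1], d) == pytest.approx(2.0)
        assert mntd([10, 1], d) == pytest.approx(2.0)  # weights moot for a pair

    def test_zero_distance_duplicates_contribute_zero(self):
        tree = tree_from_newick("((A:0,B:0):1,(C:1,D:1):1);")
        d = tree.patristic_matrix(["A", "B", "C", "D"]).to_numpy()
        # A,B are at distance 0; their nearest-neighbour terms vanish
        val = mntd([5, 5, 1, 1], d, weighted=True)
        expected = (1 / 12) * d[2, 3] * 2  # only C and D contribute, weight 1/12 each
        assert val == pytest.approx(expected)

    def test_brute_force_random(self):
        rng = np.random.default_rng(21)
        tree = random_tree(rng, list("ABCD"))
        d = tree.patristic_matrix(list("ABCD")).to_numpy()
        for weighted in (True, False):
            abund = rng.integers(1, 10, 4)
            assert mntd(abund, d, weighted) == pytest.approx(
                mntd_oracle(abund, d, weighted), abs=1e-12
            )

    def test_fewer_than_two_taxa_raises(self, two_tip_tree):
        d = two_tip_tree.patristic_matrix(["A", "B"]).to_numpy()
        with pytest.raises(ValueError, match="at least 2"):
            mntd([1, 0], d)


class TestBetaMntd:
    def test_identical_samples_zero(self, six_taxon_tree):
        labels = list("ABCDEF")
        d = six_taxon_tree.patristic_matrix(labels).to_numpy()
        x = np.array([3, 0, 1, 0, 2, 0], float)
        assert beta_mntd(x, x, d) == pytest.approx(0.0, abs=1e-12)

    def test_two_tip_hand_value(self, two_tip_tree):
        d = two_tip_tree.patristic_matrix(["A", "B"]).to_numpy()
        assert beta_mntd([1, 0], [0, 1], d) == pytest.approx(2.0)

    def test_brute_force_random_fixtures(self):
        rng = np.random.default_rng(33)
        for trial in range(5):
            labels = list("ABCDEF")
            tree = random_tree(rng, labels)
            d = tree.patristic_matrix(labels).to_numpy()
            x = rng.integers(0, 8, 6)
            y = rng.integers(0, 8, 6)
            if x.sum() == 0 or y.sum() == 0:
                continue
            for weighted in (True, False):
                assert beta_mntd(x, y, d, weighted) == pytest.approx(
                    beta_mntd_oracle(x, y, d, weighted), abs=1e-12
                )
                # symmetry
                assert beta_mntd(x, y, d, weighted) == pytest.approx(
                    beta_mntd(y, x, d, weighted), abs=1e-12
                )


class TestBetaNti:
    def test_matrix_symmetric_and_matches_pairwise(self):
        rng = np.random.default_rng(4)
        table = random_table(rng, 5, 8, depth=60)
        tree = random_tree(rng, table.taxon_ids)
        res = beta_nti(table, tree, n_null=49, seed=5)
        s = res.score.to_numpy()
        assert np.allclose(s, s.T, equal_nan=True)
        d = tree.patristic_matrix(table.taxon_ids).to_numpy()
        m = table.matrix
        for i in range(5):
            for j in range(i + 1, 5):
                assert res.observed.iat[i, j] == pytest.approx(
                    beta_mntd(m[i], m[j], d), abs=1e-10
                )

    def test_identical_pair_degenerate(self, six_taxon_tree):
        df = pd.DataFrame(
            [[2, 1, 0, 0, 3, 0]] * 2 + [[0, 0, 1, 2, 0, 4]],
            index=list("xyz"),
            columns=list("ABCDEF"),
        )
        res = beta_nti(OtuTable(df), six_taxon_tree, n_null=49, seed=0)
        assert bool(res.degenerate.loc["x", "y"])
        assert np.isnan(res.score.loc["x", "y"])

    def test_branch_length_scale_invariance(self):
        rng = np.random.default_rng(8)
        table = random_table(rng, 4, 6, depth=50)
        tree = random_tree(rng, table.taxon_ids)
        res1 = beta_nti(table, tree, n_null=99, seed=3)
        scaled = tree_from_newick(tree.to_newick())
        for edge in scaled.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 7.5
        res2 = beta_nti(table, scaled, n_null=99, seed=3)
        a, b = res1.score.to_numpy(), res2.score.to_numpy()
        assert np.allclose(a, b, equal_nan=True, atol=1e-9)

    def test_star_phylogeny_degenerate_null(self):
        tree = tree_from_newick("(A:1,B:1,C:1,D:1);")
        df = pd.DataFrame(
            [[1, 1, 0, 0], [0, 0, 1, 1]], index=["x", "y"], columns=list("ABCD")
        )
        res = beta_nti(OtuTable(df), tree, n_null=49, seed=1)
        assert bool(res.degenerate.loc["x", "y"])


class TestSesMntd:
    def test_star_phylogeny_degenerate(self):
        tree = tree_from_newick("(A:1,B:1,C:1,D:1);")
        df = pd.DataFrame([[1, 2, 3, 0]], index=["s"], columns=list("ABCD"))
        out = ses_mntd(OtuTable(df), tree, n_null=49, seed=0)
        assert bool(out.loc["s", "degenerate"])

    def test_null_consistency_and_clustering_recovery(self):
        """Random draws centre SES near 0; single-clade samples go negative."""
        from ecoassembly.synth import simulate_tree

        rng = np.random.default_rng(12)
        ses_random, ses_clade = [], []
        for rep in range(60):
            tree = simulate_tree(64, seed=1000 + rep)
            labels = tree.tip_labels
            # a genuine clade of 6-12 tips from the topology
            clades = [
                [leaf.taxon.label for leaf in node.leaf_iter()]
                for node in tree.tree.preorder_internal_node_iter()
                if 5 <= len(node.leaf_nodes()) <= 10
            ]
            if not clades:
                continue
            clade = clades[rng.integers(len(clades))]
            pick = rng.choice(64, size=8, replace=False)
            counts = np.zeros((2, 64), int)
            counts[0, pick] = rng.integers(1, 20, 8)
            counts[1, [labels.index(c) for c in clade]] = rng.integers(
                1, 20, len(clade)
            )
            table = OtuTable(
                pd.DataFrame(counts, index=["rand", "clade"], columns=labels)
            )
            out = ses_mntd(table, tree, n_null=199, seed=rep)
            ses_random.append(out.loc["rand", "ses_mntd"])
            ses_clade.append(out.loc["clade", "ses_mntd"])
        assert abs(np.mean(ses_random)) < 0.2
        assert np.mean(np.array(ses_clade) < -1.96) >= 0.9


@pytest.mark.parametrize("weighted", [True])
def test_beta_mntd_matches_picante(tmp_path, weighted):
    """Independent oracle: picante::comdistnt on a small fixture.

    The abundance-weighted statistic is identical across conventions; the
    unweighted one is not checked here because picante averages the pooled
    nearest-neighbour list, whereas this package (following the symmetric
    definition) averages the two per-sample means, and the two differ when
    the samples have unequal richness.
    """
    rng = np.random.default_rng(77)
    table = random_table(rng, 4, 8, depth=100)
    tree = random_tree(rng, table.taxon_ids)
    comm = tmp_path / "comm.csv"
    table.counts.to_csv(comm)
    nwk = tmp_path / "tree.nwk"
    nwk.write_text(tree.to_newick() + "\n")
    out = tmp_path / "out.csv"
    script = textwrap.dedent(
        f"""
        suppressMessages(library(picante))
        comm <- as.matrix(read.csv("{comm}", row.names=1, check.names=FALSE))
        tr <- read.tree("{nwk}")
        d <- cophenetic(tr)
        res <- as.matrix(comdistnt(comm, d, abundance.weighted={'TRUE' if weighted else 'FALSE'}))
        write.csv(res, "{out}")
        """
    )
    r = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert r.returncode == 0, r.stderr
    ref = pd.read_csv(out, index_col=0)
    d = tree.patristic_matrix(table.taxon_ids).to_numpy()
    m = table.matrix
    ids = table.sample_ids
    for i in range(4):
        for j in range(i + 1, 4):
            assert beta_mntd(m[i], m[j], d, weighted) == pytest.approx(
                ref.loc[ids[i], ids[j]], abs=1e-6
            )
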