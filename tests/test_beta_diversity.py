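"""Dissimilarity layers and distance statistics, with independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from traitscape import beta_diversity as bd
from traitscape._flat import FlatTree
from traitscape.exceptions import ValidationError
from traitscape.phylo_io import CommunityTable, parse_newick


def _dm(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(np.asarray(points, float))), ids=ids)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        t = CommunityTable(pd.DataFrame([[1, 2], [1, 2]],
                                        index=["a", "b"], columns=["u", "v"]))
        assert bd.bray_curtis(t)["a", "b"] == 0.0

    def test_disjoint_support_one(self):
        t = CommunityTable(pd.DataFrame([[3, 0], [0, 5]],
                                        index=["a", "b"], columns=["u", "v"]))
        assert bd.bray_curtis(t)["a", "b"] == 1.0

    def test_hand_example(self):
        t = CommunityTable(pd.DataFrame([[9, 1, 5], [0, 2, 8]],
                                        index=["a", "b"],
                                        columns=["u", "v", "w"]))
        assert bd.bray_curtis(t)["a", "b"] == pytest.approx(13 / 25)

    def test_zero_row_rejected(self):
        t = CommunityTable(pd.DataFrame([[1, 1], [0, 0]],
                                        index=["a", "b"], columns=["u", "v"]))
        with pytest.raises(ValidationError):
            bd.bray_curtis(t)


class TestWeightedUnifrac:
    def test_identical_relative_abundances_zero(self):
        tree = parse_newick("((a:1,b:2):1,c:3);")
        t = CommunityTable(pd.DataFrame([[2, 2, 4], [1, 1, 2]],
                                        index=["x", "y"],
                                        columns=["a", "b", "c"]))
        assert bd.weighted_unifrac(t, tree)["x", "y"] == pytest.approx(0.0)

    def test_two_tip_maximal_separation(self):
        tree = parse_newick("(a:1,b:1);")
        t = CommunityTable(pd.DataFrame([[5, 0], [0, 3]],
                                        index=["x", "y"], columns=["a", "b"]))
        assert bd.weighted_unifrac(t, tree)["x", "y"] == pytest.approx(1.0)

    def test_three_tip_branch_sum_oracle(self):
        """Branch-by-branch hand sum on a printed toy."""
        tree = parse_newick("((a:1,b:2):0.5,c:2);")
        counts = pd.DataFrame([[3, 0, 1], [0, 2, 2]], index=["x", "y"],
                              columns=["a", "b", "c"])
        t = CommunityTable(counts)
        A = np.array([3 / 4, 0, 1 / 4])       # tip fractions sample x
        B = np.array([0, 2 / 4, 2 / 4])       # sample y
        raw = (1.0 * abs(A[0] - B[0]) + 2.0 * abs(A[1] - B[1])
               + 2.0 * abs(A[2] - B[2])
               + 0.5 * abs(A[0] + A[1] - B[0] - B[1]))
        denom = (1.0 * (A[0] + B[0]) + 2.0 * (A[1] + B[1])
                 + 2.0 * (A[2] + B[2]) + 0.5 * (A[0] + A[1] + B[0] + B[1]))
        got = bd.weighted_unifrac(t, tree)["x", "y"]
        assert got == pytest.approx(raw / denom, abs=1e-10)
        assert 0 <= got <= 1

    def test_matches_skbio(self):
        """Independent cross-check against scikit-bio's implementation."""
        import skbio
        from skbio.diversity.beta import weighted_unifrac as sk_wu

        rng = np.random.default_rng(2)
        flat = __import__("traitscape").simulate_tree(12, seed=3)
        labels = [flat.labels[i] for i in flat.tip_ids]
        counts = rng.integers(0, 5, size=(4, 12)) + (rng.random((4, 12)) < 0.3)
        counts[:, 0] += 1
        t = CommunityTable(pd.DataFrame(counts.astype(int),
                                        index=[f"s{i}" for i in range(4)],
                                        columns=labels))
        sk_tree = skbio.TreeNode.read([flat.to_newick(fmt="%.17g")])
        ours = bd.weighted_unifrac(t, flat)
        for i in range(4):
            for j in range(i + 1, 4):
                ref = sk_wu(counts[i], counts[j], taxa=labels, tree=sk_tree,
                            normalized=True)
                assert ours.data[i, j] == pytest.approx(ref, abs=1e-10)

    def test_unit_not_in_tree_rejected(self):
        tree = parse_newick("(a:1,b:1);")
        t = CommunityTable(pd.DataFrame([[1, 1]], index=["x"],
                                        columns=["a", "zz"]))
        with pytest.raises(ValidationError):
            bd.weighted_unifrac(t, tree)


class TestMantel:
    def test_self_correlation(self, rng):
        dx = _dm(rng.random((10, 2)))
        res = bd.mantel(dx, dx, n_perm=199, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_power_law_slope(self, rng):
        dx = _dm(rng.random((10, 2)))
        dy = DistanceMatrix(dx.data ** 0.5, ids=dx.ids)
        res = bd.mantel(dx, dy, n_perm=19, seed=1, loglog_slope=True)
        assert res.slope == pytest.approx(0.5, abs=1e-10)
        assert res.slope_ci[0] <= 0.5 <= res.slope_ci[1]

    def test_matches_skbio_statistic(self, rng):
        from skbio.stats.distance import mantel as sk_mantel

        dx = _dm(rng.random((12, 2)))
        dy = _dm(rng.random((12, 3)), ids=list(dx.ids))
        ours = bd.mantel(dx, dy, n_perm=9, seed=0)
        ref_r, _, _ = sk_mantel(dx, dy, permutations=0)
        assert ours.r == pytest.approx(ref_r, abs=1e-12)

    def test_partial_removes_shared_driver(self, rng):
        """dy = dz + tiny noise, dx correlated with dz: partial r collapses."""
        z = rng.random((20, 2))
        dz = _dm(z)
        dx = DistanceMatrix(dz.data + 0.01 * _dm(rng.random((20, 2))).data,
                            ids=dz.ids)
        dy = DistanceMatrix(dz.data + 0.01 * _dm(rng.random((20, 2))).data,
                            ids=dz.ids)
        plain = bd.mantel(dx, dy, n_perm=99, seed=2)
        partial = bd.mantel(dx, dy, n_perm=99, seed=2, conditioning=dz)
        assert plain.r > 0.9
        assert abs(partial.r) < 0.5

    def test_zero_variance_rejected(self):
        ids = list("abcd")
        flat_d = DistanceMatrix(1 - np.eye(4), ids=ids)
        with pytest.raises(ValidationError):
            bd.mantel(flat_d, flat_d, n_perm=9, seed=0)

    def test_type_one_error_calibrated(self):
        """Independent matrices: rejection rate at alpha=.05 is ~5%."""
        rng = np.random.default_rng(77)
        n_rep, n_perm, alpha = 200, 99, 0.05
        rejections = 0
        for _ in range(n_rep):
            dx = _dm(rng.random((10, 2)))
            dy = _dm(rng.random((10, 2)), ids=list(dx.ids))
            res = bd.mantel(dx, dy, n_perm=n_perm,
                            seed=int(rng.integers(2 ** 31)))
            rejections += res.p <= alpha
        rate = rejections / n_rep
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= 3 * se


class TestAnosim:
    def test_perfect_separation(self):
        # all between-pair distances exceed all within-pair distances
        d = np.array([[0, 1, 9, 9],
                      [1, 0, 9, 9],
                      [9, 9, 0, 2],
                      [9, 9, 2, 0]], dtype=float)
        dm = DistanceMatrix(d, ids=list("abcd"))
        res = bd.anosim(dm, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"},
                        n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_hand_ranked_example(self):
        """6 samples, 2 groups; R computed by hand ranking equals ours
        and scikit-bio's."""
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(5)
        d = squareform(rng.random(15))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        res = bd.anosim(dm, groups, n_perm=9, seed=0)
        ranks = pd.Series(squareform(d)).rank()
        within = [i for i, (a, b) in enumerate(
            (a, b) for a in range(6) for b in range(a + 1, 6))
            if groups[f"s{a}"] == groups[f"s{b}"]]
        between = [i for i in range(15) if i not in within]
        expected = (ranks[between].mean() - ranks[within].mean()) / (6 * 5 / 4)
        assert res.R == pytest.approx(expected, abs=1e-12)
        ref = sk_anosim(dm, pd.Series(groups).loc[list(dm.ids)].to_numpy(),
                        permutations=0)
        assert res.R == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(200):
            d = squareform(rng.random(28))
            dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(8)])
            labels = rng.permutation(["g1"] * 4 + ["g2"] * 4)
            groups = dict(zip(dm.ids, labels))
            vals.append(bd.anosim(dm, groups, n_perm=1,
                                  seed=int(rng.integers(2 ** 31))).R)
        assert abs(np.mean(vals)) < 0.05

    def test_singleton_group_rejected(self):
        dm = DistanceMatrix(1 - np.eye(3), ids=list("abc"))
        with pytest.raises(ValidationError):
            bd.anosim(dm, {"a": "g1", "b": "g2", "c": "g2"}, n_perm=9, seed=0)


class TestMrm:
    def test_exact_linear_construction(self, rng):
        p1 = _dm(rng.random((10, 2)))
        p2 = _dm(rng.random((10, 3)), ids=list(p1.ids))
        resp = DistanceMatrix(2 * p1.data + 3 * p2.data, ids=p1.ids)
        res = bd.mrm(resp, {"p1": p1, "p2": p2}, n_perm=49, seed=0)
        assert res.coefficients["p1"] == pytest.approx(2.0, abs=1e-9)
        assert res.coefficients["p2"] == pytest.approx(3.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_collinear_predictors_named(self, rng):
        p1 = _dm(rng.random((8, 2)))
        p2 = DistanceMatrix(2 * p1.data, ids=p1.ids)
        resp = _dm(rng.random((8, 2)), ids=list(p1.ids))
        with pytest.raises(ValidationError, match="p1.*p2|p2.*p1"):
            bd.mrm(resp, {"p1": p1, "p2": p2}, n_perm=9, seed=0)

    def test_signal_vs_noise_selectivity(self):
        """Response tracks p1 only: p(p1) small, p(p2) large, most of the time."""
        rng = np.random.default_rng(8)
        hits_p1, miss_p2 = 0, 0
        n_rep = 40
        for _ in range(n_rep):
            p1 = _dm(rng.random((12, 2)))
            p2 = _dm(rng.random((12, 2)), ids=list(p1.ids))
            noise = _dm(rng.random((12, 2)), ids=list(p1.ids))
            resp = DistanceMatrix(p1.data + 0.15 * noise.data, ids=p1.ids)
            res = bd.mrm(resp, {"p1": p1, "p2": p2}, n_perm=99,
                         seed=int(rng.integers(2 ** 31)))
            hits_p1 += res.p_values["p1"] <= 0.05
            miss_p2 += res.p_values["p2"] > 0.05
        assert hits_p1 >= 0.9 * n_rep
        assert miss_p2 >= 0.8 * n_rep


class TestBioenv:
    def test_planted_subset_recovered(self, rng):
        env = pd.DataFrame(rng.random((15, 4)),
                           index=[f"s{i}" for i in range(15)],
                           columns=["v1", "v2", "v3", "v4"])
        scaled = (env - env.min()) / (env.max() - env.min())
        comm = DistanceMatrix(
            squareform(pdist(scaled[["v1", "v3"]].to_numpy())),
            ids=list(env.index))
        res = bd.bioenv(comm, env)
        assert res.best_subset == ("v1", "v3")
        assert res.correlation == pytest.approx(1.0)

    def test_single_variable(self, rng):
        env = pd.DataFrame(rng.random((10, 1)),
                           index=[f"s{i}" for i in range(10)], columns=["v1"])
        comm = _dm(env.to_numpy(), ids=list(env.index))
        assert bd.bioenv(comm, env).best_subset == ("v1",)

    def test_constant_variable_dropped(self, rng):
        env = pd.DataFrame({"v1": rng.random(10), "flat": np.ones(10)},
                           index=[f"s{i}" for i in range(10)])
        comm = _dm(env[["v1"]].to_numpy(), ids=list(env.index))
        res = bd.bioenv(comm, env)
        assert all("flat" not in s for s in res.table["subset"])


class TestVariablePruning:
    def test_correlated_pair_pruned_keeping_first(self, rng):
        x = rng.random(30)
        env = pd.DataFrame({"clay": x, "sand": -x + 0.01 * rng.random(30),
                            "ph": rng.random(30)})
        kept = bd.prune_correlated_variables(env, r2_threshold=0.7)
        assert list(kept.columns) == ["clay", "ph"]
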