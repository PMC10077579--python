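"""Clustering, ordination, indicator values, Mantel and distance machinery."""

import io
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

import domdiv as dd
from domdiv.community import linkage_to_newick


def _blob_matrix(n_per=5, within=0.01, between=0.9, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    d = np.full((n, n), between)
    d[:n_per, :n_per] = within
    d[n_per:, n_per:] = within
    d = d + rng.uniform(0, 1e-3, (n, n))
    d = np.triu(d, 1)
    d = d + d.T
    return DistanceMatrix(d, [f"s{i}" for i in range(n)])


class TestHierarchicalCluster:
    def test_two_blobs_recovered_perfectly(self):
        result = dd.hierarchical_cluster(_blob_matrix())
        assert result.k == 2
        labels = result.labels
        assert len(set(labels.iloc[:5])) == 1 and len(set(labels.iloc[5:])) == 1
        assert labels.iloc[0] != labels.iloc[-1]
        assert result.mean_silhouette > 0.9

    def test_equal_distances_fall_back_to_smallest_k_with_warning(self):
        n = 6
        d = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix(d, [f"s{i}" for i in range(n)])
        with pytest.warns(UserWarning):
            result = dd.hierarchical_cluster(dm, k_range=range(2, 5))
        assert result.k == 2

    def test_k_range_bounds_enforced(self):
        with pytest.raises(ValueError):
            dd.hierarchical_cluster(_blob_matrix(), k_range=[1, 2])
        with pytest.raises(ValueError):
            dd.hierarchical_cluster(_blob_matrix(n_per=3), k_range=[2, 6])

    def test_deterministic(self):
        a = dd.hierarchical_cluster(_blob_matrix())
        b = dd.hierarchical_cluster(_blob_matrix())
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_newick_export_contains_all_tips(self):
        result = dd.hierarchical_cluster(_blob_matrix())
        newick = linkage_to_newick(result.linkage_matrix, [f"s{i}" for i in range(10)])
        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(newick))
        assert {t.name for t in tree.tips()} == {f"s{i}" for i in range(10)}


class TestNMDS:
    def test_line_embeds_with_near_zero_stress(self):
        x = np.arange(8, dtype=float)
        d = np.abs(x[:, None] - x[None, :]) / 7.0
        dm = DistanceMatrix(d, [f"s{i}" for i in range(8)])
        result = dd.nmds(dm, seed=0)
        assert result.stress < 0.05

    def test_duplicate_samples_nearly_coincide(self):
        d = np.array(
            [
                [0.0, 0.0, 0.8, 0.7],
                [0.0, 0.0, 0.8, 0.7],
                [0.8, 0.8, 0.0, 0.6],
                [0.7, 0.7, 0.6, 0.0],
            ]
        )
        dm = DistanceMatrix(d, list("abcd"))
        coords = dd.nmds(dm, seed=0).coordinates
        spread = np.linalg.norm(coords.max() - coords.min())
        dup = np.linalg.norm(coords.loc["a"] - coords.loc["b"])
        assert dup < 0.05 * spread

    def test_reproducible_given_seed(self):
        dm = _blob_matrix()
        a = dd.nmds(dm, seed=7).coordinates
        b = dd.nmds(dm, seed=7).coordinates
        pd.testing.assert_frame_equal(a, b)


class TestEnvfit:
    def _ordination(self, rng, n=20):
        return pd.DataFrame(
            rng.normal(size=(n, 2)), index=[f"s{i}" for i in range(n)], columns=["NMDS1", "NMDS2"]
        )

    def test_variable_equal_to_axis_gives_perfect_fit(self, rng):
        ord_ = self._ordination(rng)
        env = pd.DataFrame({"v": ord_["NMDS1"]})
        out = dd.envfit(ord_, env, ["v"], n_perm=99, seed=0)
        assert out.loc["v", "r2"] == pytest.approx(1.0)
        assert out.loc["v", "p"] == pytest.approx(1 / 100)

    def test_sign_reversal_flips_direction_not_r2(self, rng):
        ord_ = self._ordination(rng)
        env = pd.DataFrame({"v": ord_["NMDS1"], "w": -ord_["NMDS1"]})
        out = dd.envfit(ord_, env, ["v", "w"], n_perm=49, seed=0)
        assert out.loc["v", "r2"] == pytest.approx(out.loc["w", "r2"])
        assert out.loc["v", "axis1"] == pytest.approx(-out.loc["w", "axis1"])

    def test_constant_variable_rejected(self, rng):
        ord_ = self._ordination(rng)
        env = pd.DataFrame({"v": np.ones(len(ord_))}, index=ord_.index)
        with pytest.raises(ValueError, match="v"):
            dd.envfit(ord_, env, ["v"], n_perm=9, seed=0)


class TestIndval:
    def _matrix(self):
        # formula f1: all of cluster 1, absent in cluster 2; f2 background
        data = {
            "f1": [0.5, 0.3, 0.4, 0.0, 0.0, 0.0],
            "f2": [0.5, 0.7, 0.6, 1.0, 1.0, 1.0],
        }
        return pd.DataFrame(data, index=[f"s{i}" for i in range(6)])

    def _clusters(self):
        return pd.Series([1, 1, 1, 2, 2, 2], index=[f"s{i}" for i in range(6)])

    def test_perfect_indicator_scores_one(self):
        out = dd.indval(self._matrix(), self._clusters(), n_perm=99, seed=0)
        row = out.loc["f1"]
        assert row.A == 1.0 and row.B == 1.0 and row.indval == 1.0
        assert row.best_cluster == 1

    def test_hand_computed_partial_indicator(self):
        # cluster means 3 vs 1 -> A = 0.75; present in half the samples -> B = 0.5
        m = pd.DataFrame(
            {"f": [6.0, 6.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0], "bg": [1.0] * 8},
            index=[f"s{i}" for i in range(8)],
        )
        cl = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=m.index)
        out = dd.indval(m, cl, n_perm=49, seed=0)
        assert out.loc["f", "A"] == pytest.approx(0.75)
        assert out.loc["f", "B"] == pytest.approx(0.5)
        assert out.loc["f", "indval"] == pytest.approx(0.375)

    def test_values_and_pvalues_are_valid(self, rng):
        m = pd.DataFrame(
            rng.random((10, 30)), index=[f"s{i}" for i in range(10)]
        )
        cl = pd.Series([1] * 5 + [2] * 5, index=m.index)
        out = dd.indval(m, cl, n_perm=99, seed=1)
        assert ((out.indval >= 0) & (out.indval <= 1)).all()
        assert (out.p_raw >= 1 / 100).all()
        assert (out.p_adjusted >= out.p_raw - 1e-12).all()

    def test_singleton_cluster_rejected(self):
        m = self._matrix()
        cl = pd.Series([1, 1, 1, 1, 1, 2], index=m.index)
        with pytest.raises(ValueError):
            dd.indval(m, cl, n_perm=9, seed=0)


class TestMantel:
    def _random_dm(self, rng, n=12):
        pts = rng.normal(size=(n, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return DistanceMatrix(d, [f"s{i}" for i in range(n)])

    def test_identity_gives_r_one(self, rng):
        d = self._random_dm(rng)
        result = dd.mantel(d, d, n_perm=99, seed=0)
        assert result.r == pytest.approx(1.0)
        assert result.p == pytest.approx(1 / 100)

    def test_affine_invariance(self, rng):
        d = self._random_dm(rng)
        d2 = DistanceMatrix(3.0 * d.data + 0.5 * (d.data > 0), d.ids)
        assert dd.mantel(d, d2, n_perm=9, seed=0).r == pytest.approx(1.0)

    def test_id_mismatch_rejected(self, rng):
        d1 = self._random_dm(rng)
        d2 = DistanceMatrix(d1.data, [f"x{i}" for i in range(12)])
        with pytest.raises(ValueError):
            dd.mantel(d1, d2)

    def test_statistic_matches_scikit_bio(self, rng):
        d1, d2 = self._random_dm(rng), self._random_dm(rng)
        ours = dd.mantel(d1, d2, n_perm=99, seed=0)
        theirs_r, _, _ = skbio_mantel(d1, d2, permutations=0)
        assert ours.r == pytest.approx(theirs_r, abs=1e-10)


class TestSpatialAndEnvironmentalDistance:
    def test_haversine_reference_values(self):
        env = pd.DataFrame(
            {"latitude": [0.0, 0.0, 0.0], "longitude": [0.0, 1.0, 0.0]},
            index=["a", "b", "c"],
        )
        d = dd.haversine_matrix(env)
        assert d["a", "b"] == pytest.approx(111.195, abs=1e-3)
        assert d["a", "c"] == 0.0
        assert d["a", "b"] == d["b", "a"]

    def test_out_of_range_coordinates_rejected(self):
        env = pd.DataFrame({"latitude": [95.0], "longitude": [0.0]}, index=["a"])
        with pytest.raises(ValueError):
            dd.haversine_matrix(env)

    def test_env_distance_two_samples_single_variable(self):
        env = pd.DataFrame({"pH": [7.0, 8.0]}, index=["a", "b"])
        d = dd.env_distance(env, ["pH"], transforms={})
        # z-scores of two points are +-1/sqrt(2), so the gap is sqrt(2)
        assert d["a", "b"] == pytest.approx(np.sqrt(2.0))

    def test_duplicate_samples_at_zero_distance(self):
        env = pd.DataFrame(
            {"pH": [7.0, 7.0, 8.5], "EC": [1.0, 1.0, 30.0]}, index=["a", "b", "c"]
        )
        d = dd.env_distance(env, ["pH", "EC"])
        assert d["a", "b"] == 0.0

    def test_affine_rescaling_invariance(self, rng):
        env = pd.DataFrame(
            {"pH": rng.uniform(7, 9, 6), "T": rng.uniform(0, 5, 6)},
            index=[f"s{i}" for i in range(6)],
        )
        scaled = env.assign(T=env["T"] * 100 - 7.0)
        d1 = dd.env_distance(env, ["pH", "T"], transforms={})
        d2 = dd.env_distance(scaled, ["pH", "T"], transforms={})
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-9)

    def test_zero_variance_variable_rejected(self):
        env = pd.DataFrame({"pH": [7.0, 7.0, 7.0]}, index=["a", "b", "c"])
        with pytest.raises(ValueError):
            dd.env_distance(env, ["pH"], transforms={})


def test_mantel_and_envfit_statistics_match_vegan(tmp_path, rng):
    """Cross-check r_M and envfit r^2 against the vegan R package."""
    n = 10
    pts = rng.normal(size=(n, 3))
    d1 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    pts2 = rng.normal(size=(n, 3))
    d2 = np.linalg.norm(pts2[:, None] - pts2[None, :], axis=-1)
    ids = [f"s{i}" for i in range(n)]
    ours_mantel = dd.mantel(DistanceMatrix(d1, ids), DistanceMatrix(d2, ids), n_perm=9, seed=0)

    coords = pd.DataFrame(rng.normal(size=(n, 2)), index=ids, columns=["NMDS1", "NMDS2"])
    y = rng.normal(size=n)
    env = pd.DataFrame({"v": y}, index=ids)
    ours_envfit = dd.envfit(coords, env, ["v"], n_perm=9, seed=0)

    np.savetxt(tmp_path / "d1.csv", d1, delimiter=",")
    np.savetxt(tmp_path / "d2.csv", d2, delimiter=",")
    coords.to_csv(tmp_path / "ord.csv", index=False)
    env.to_csv(tmp_path / "env.csv", index=False)
    script = textwrap.dedent(
        """
        suppressMessages(library(vegan))
        d1 <- as.dist(as.matrix(read.csv("d1.csv", header=FALSE)))
        d2 <- as.dist(as.matrix(read.csv("d2.csv", header=FALSE)))
        m <- mantel(d1, d2, permutations=0)
        ord <- as.matrix(read.csv("ord.csv"))
        env <- read.csv("env.csv")
        ef <- envfit(ord, env, permutations=0)
        cat(sprintf("%.12f %.12f\\n", m$statistic, ef$vectors$r[1]))
        """
    )
    (tmp_path / "check.R").write_text(script)
    out = subprocess.run(
        ["Rscript", "check.R"], cwd=tmp_path, capture_output=True, text=True, check=True
    )
    r_vegan, r2_vegan = map(float, out.stdout.split())
    assert ours_mantel.r == pytest.approx(r_vegan, abs=1e-9)
    assert ours_envfit.loc["v", "r2"] == pytest.approx(r2_vegan, abs=1e-9)
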