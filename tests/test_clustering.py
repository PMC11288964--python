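"""Pearson correlation, correlation distance, UPGMA, and tree cutting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from riboratio import (
    RatioMatrix,
    average_linkage,
    cluster_composition,
    correlation_distance,
    cut_tree,
    pearson_correlation,
)


def _frame(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"r{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


def naive_upgma_cophenetic(d: np.ndarray) -> np.ndarray:
    """Brute-force UPGMA oracle: clusters as leaf sets, inter-cluster
    distance recomputed each step as the mean over all cross pairs from the
    original matrix.  Returns the cophenetic distance matrix."""
    n = d.shape[0]
    clusters = [{i} for i in range(n)]
    coph = np.zeros_like(d)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = np.mean(
                [d[i, j] for i in clusters[a] for j in clusters[b]]
            )
            if best is None or dist < best[0] - 1e-15:
                best = (dist, a, b)
        dist, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = dist
        clusters[a] |= clusters[b]
        del clusters[b]
    return coph


class TestPearson:
    def test_self_correlation_is_one(self):
        r = pearson_correlation(_frame([[1, 2], [2, 1], [3, 3]]))
        np.testing.assert_allclose(np.diag(r.r.to_numpy()), 1.0)

    def test_three_point_closed_form(self):
        """Hand-computed Pearson r of (0.2,0.3,0.5) vs (0.5,0.3,0.2):
        covariance -39/900, variances 42/900 each, so r = -39/42."""
        frame = _frame(np.array([[0.2, 0.5], [0.3, 0.3], [0.5, 0.2]]))
        r = pearson_correlation(frame)
        assert r.r.iloc[0, 1] == pytest.approx(-39.0 / 42.0, abs=1e-12)

    def test_alignment_by_id_not_order(self):
        a = pd.Series({"RPL5": 0.5, "RPS3": 0.3, "RPL11": 0.2})
        b = a.reindex(["RPS3", "RPL11", "RPL5"])
        frame = pd.DataFrame({"s1": a, "s2": b})
        r = pearson_correlation(frame)
        assert r.r.loc["s1", "s2"] == pytest.approx(1.0)

    def test_pairwise_complete_and_n_shared(self):
        frame = _frame(
            [[1, 1], [2, np.nan], [3, 3], [4, 2], [5, np.nan]]
        )
        r = pearson_correlation(frame)
        assert r.n_shared.loc["s0", "s1"] == 3

    def test_too_few_shared_is_missing(self, caplog):
        frame = _frame([[1, 1], [2, 2], [3, np.nan], [4, np.nan]])
        with caplog.at_level("WARNING"):
            r = pearson_correlation(frame)
        assert np.isnan(r.r.loc["s0", "s1"])

    def test_symmetry_and_bounds_on_random_fixture(self):
        rng = np.random.default_rng(0)
        frame = _frame(rng.normal(size=(20, 6)))
        r = pearson_correlation(frame).r.to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-15)
        assert (np.abs(r) <= 1 + 1e-12).all()


class TestCorrelationDistance:
    def test_identical_profiles_distance_zero(self):
        frame = _frame([[1, 1], [2, 2], [3, 3]])
        d = correlation_distance(frame)
        assert d.loc["s0", "s1"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        frame = _frame([[1, 3], [2, 2], [3, 1]])
        d = correlation_distance(frame)
        assert d.loc["s0", "s1"] == pytest.approx(2.0)

    def test_definition_one_minus_r(self):
        rng = np.random.default_rng(1)
        frame = _frame(rng.normal(size=(10, 4)))
        d = correlation_distance(frame)
        r = pearson_correlation(frame).r
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(
            d.to_numpy()[off], (1 - r).to_numpy()[off], atol=1e-12
        )

    def test_constant_profile_errors(self):
        frame = _frame([[1, 5], [1, 6], [1, 7]])
        with pytest.raises(ValueError, match="constant"):
            correlation_distance(frame)

    def test_rows_axis(self):
        rng = np.random.default_rng(2)
        frame = _frame(rng.normal(size=(5, 6)))
        d = correlation_distance(frame, axis="rows")
        assert d.shape == (5, 5)


class TestUPGMA:
    def test_two_leaves(self):
        dend = average_linkage(np.array([[0.0, 0.4], [0.4, 0.0]]),
                               labels=["a", "b"])
        assert dend.merges.shape == (1, 4)
        assert dend.merges[0, 2] == pytest.approx(0.4)

    def test_hand_built_four_leaf_tree(self):
        # leaves 0,1 close (0.1); 2,3 close (0.2); the pairs far apart
        d = np.array(
            [
                [0.0, 0.1, 1.0, 1.1],
                [0.1, 0.0, 1.2, 0.9],
                [1.0, 1.2, 0.0, 0.2],
                [1.1, 0.9, 0.2, 0.0],
            ]
        )
        dend = average_linkage(d)
        heights = dend.merges[:, 2]
        np.testing.assert_allclose(heights, [0.1, 0.2, 1.05])

    def test_duplicate_profiles_merge_first_at_zero(self):
        d = np.array(
            [[0.0, 0.0, 0.5], [0.0, 0.0, 0.5], [0.5, 0.5, 0.0]]
        )
        dend = average_linkage(d)
        assert dend.merges[0, 2] == 0.0
        assert set(dend.merges[0, :2]) == {0, 1}

    def test_matches_bruteforce_oracle_small_random(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(3, 7))
            x = rng.random((n, 4))
            d = squareform(squareform(
                np.abs(x[:, None, :] - x[None, :, :]).sum(-1)
            ))
            dend = average_linkage(d)
            coph_mine = squareform(cophenet(dend.to_linkage_matrix()))
            coph_oracle = naive_upgma_cophenetic(d)
            np.testing.assert_allclose(coph_mine, coph_oracle, atol=1e-10)

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            mine = cophenet(average_linkage(d).to_linkage_matrix())
            ref = cophenet(linkage(squareform(d), method="average"))
            np.testing.assert_allclose(mine, ref, atol=1e-10)

    def test_monotone_heights(self):
        rng = np.random.default_rng(5)
        d = rng.random((8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        heights = average_linkage(d).merges[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_asymmetric_input_errors(self):
        with pytest.raises(ValueError, match="symmetric"):
            average_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_newick_round_trips_heights(self):
        d = np.array(
            [[0.0, 0.2, 0.8], [0.2, 0.0, 0.6], [0.8, 0.6, 0.0]]
        )
        dend = average_linkage(d, labels=["a", "b", "c"])
        nwk = dend.to_newick()
        assert nwk.endswith(";") and "a" in nwk and "c" in nwk


class TestCutTree:
    def _dend(self):
        d = np.array(
            [
                [0.0, 0.1, 1.0, 1.1],
                [0.1, 0.0, 1.2, 0.9],
                [1.0, 1.2, 0.0, 0.2],
                [1.1, 0.9, 0.2, 0.0],
            ]
        )
        return average_linkage(d, labels=["a", "b", "c", "d"])

    def test_full_cut_every_leaf_alone(self):
        labels = cut_tree(self._dend(), 4)
        assert labels.nunique() == 4

    def test_single_cluster(self):
        labels = cut_tree(self._dend(), 1)
        assert labels.nunique() == 1

    def test_two_clusters_match_structure(self):
        labels = cut_tree(self._dend(), 2)
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError, match="k must be"):
            cut_tree(self._dend(), 5)

    def test_composition_crosstab(self):
        labels = cut_tree(self._dend(), 2)
        groups = pd.Series(
            {"a": "x", "b": "x", "c": "y", "d": "y"}
        )
        comp = cluster_composition(labels, groups)
        assert comp.to_numpy().sum() == 4
        assert (comp.max(axis=1) == 2).all()
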