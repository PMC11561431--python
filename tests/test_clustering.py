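"""Spearman dissimilarity, UPGMA, cophenetic fit, the k rule, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.cluster.hierarchy import linkage as scipy_linkage

from behavdet import clustering
from behavdet.clustering import (
    ConstantItemError,
    DissimilarityMatrix,
    average_linkage,
    cluster_determinants,
    compactness_separation_curve,
    cophenetic_correlation,
    optimal_k,
    profile_clusters,
    spearman_dissimilarity,
)


def random_dissimilarity(p, seed):
    rng = np.random.default_rng(seed)
    M = rng.random((p, p))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(items=tuple(f"i{j}" for j in range(p)), values=D)


class TestSpearmanDissimilarity:
    def test_duplicate_column_has_zero_dissimilarity(self):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 6, 200)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.integers(1, 6, 200)})
        D = spearman_dissimilarity(df)
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_item_also_maps_to_zero(self):
        # D uses |rho|, so an item and its mirrored copy are maximally similar
        rng = np.random.default_rng(1)
        x = rng.integers(1, 6, 500)
        D = spearman_dissimilarity(pd.DataFrame({"a": x, "rev": 6 - x}))
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_independent_items_near_one(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"a": rng.integers(1, 6, 5000), "b": rng.integers(1, 6, 5000)}
        )
        assert spearman_dissimilarity(df).values[0, 1] > 0.95

    def test_constant_column_raises_naming_item(self):
        df = pd.DataFrame({"a": [1, 2, 3], "flat": [2, 2, 2]})
        with pytest.raises(ConstantItemError, match="flat"):
            spearman_dissimilarity(df)

    def test_matches_rank_then_pearson_oracle_on_ties(self):
        rng = np.random.default_rng(3)
        base = rng.integers(1, 6, 300)
        df = pd.DataFrame(
            {
                "a": base,
                "b": np.clip(base + rng.integers(-1, 2, 300), 1, 5),
                "c": rng.integers(1, 6, 300),
            }
        )
        D = spearman_dissimilarity(df)
        from scipy.stats import rankdata

        ranks = np.column_stack([rankdata(df[c]) for c in df.columns])
        oracle = 1 - np.abs(np.corrcoef(ranks, rowvar=False))
        np.fill_diagonal(oracle, 0.0)
        np.testing.assert_allclose(D.values, oracle, atol=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(400, 3)), columns=list("abc"))
        D1 = spearman_dissimilarity(df)
        D2 = spearman_dissimilarity(np.exp(df * 2) + 7)
        np.testing.assert_allclose(D1.values, D2.values, atol=1e-12)


class TestAverageLinkage:
    def test_three_item_hand_trace(self):
        D = DissimilarityMatrix(
            items=("a", "b", "c"),
            values=np.array([[0.0, 0.1, 0.8], [0.1, 0.0, 0.8], [0.8, 0.8, 0.0]]),
        )
        dend = average_linkage(D)
        np.testing.assert_allclose(dend.heights, [0.1, 0.8])
        assert dend.cut(2) == {"a": 1, "b": 1, "c": 2}
        # average linkage reproduces this ultrametric exactly
        assert cophenetic_correlation(D, dend) == pytest.approx(1.0)

    def test_two_block_last_merge_at_cross_distance(self, two_block_D):
        dend = average_linkage(two_block_D)
        assert dend.heights[-1] == pytest.approx(0.9)
        assert dend.heights[-2] == pytest.approx(0.1)

    def test_all_equal_distances_merge_in_lexicographic_chain(self):
        items = ("b", "a", "c", "d")
        D = DissimilarityMatrix(
            items=items, values=0.5 * (1 - np.eye(4))
        )
        dend = average_linkage(D)
        np.testing.assert_allclose(dend.heights, 0.5)
        # first merge is the lexicographically smallest pair {a, b}
        first = {int(dend.linkage[0, 0]), int(dend.linkage[0, 1])}
        assert first == {items.index("a"), items.index("b")}

    @pytest.mark.parametrize("p", [4, 5, 7])
    def test_matches_scipy_average_linkage(self, p):
        D = random_dissimilarity(p, seed=p)
        dend = average_linkage(D)
        Z = scipy_linkage(D.condensed(), method="average")
        np.testing.assert_allclose(dend.linkage[:, 2], Z[:, 2], atol=1e-12)
        coph_ref = cophenet(Z)
        np.testing.assert_allclose(np.sort(dend.cophenetic), np.sort(coph_ref),
                                   atol=1e-12)

    def test_nested_partitions(self):
        D = random_dissimilarity(9, seed=42)
        dend = average_linkage(D)
        for k in range(2, 9):
            coarse = dend.cut(k)
            fine = dend.cut(k + 1)
            # each fine cluster lies inside exactly one coarse cluster
            mapping = {}
            for item, fid in fine.items():
                cid = coarse[item]
                assert mapping.setdefault(fid, cid) == cid


class TestCophenetic:
    def test_ultrametric_input_gives_ccc_one(self, two_block_D):
        dend = average_linkage(two_block_D)
        assert cophenetic_correlation(two_block_D, dend) == pytest.approx(1.0)

    def test_too_few_items_rejected(self):
        D = DissimilarityMatrix(
            items=("a", "b"), values=np.array([[0.0, 0.4], [0.4, 0.0]])
        )
        with pytest.raises(ValueError):
            cophenetic_correlation(D, average_linkage(D))

    def test_block_structured_synthetic_ccc_high(self):
        from behavdet import synthetic

        cccs = []
        for seed in range(5):
            ds = synthetic.generate(
                synthetic.block_design(3, n_respondents=1000, loading=0.85,
                                       seed=seed)
            )
            D = spearman_dissimilarity(ds.responses, ds.signal_items)
            cccs.append(cophenetic_correlation(D, average_linkage(D)))
        assert min(cccs) >= 0.9


class TestCompactnessSeparation:
    def test_two_block_curve_hand_values(self, two_block_D):
        dend = average_linkage(two_block_D)
        curve = compactness_separation_curve(two_block_D, dend).set_index("k")
        assert curve.loc[2, "compactness"] == pytest.approx(0.1)
        assert curve.loc[2, "separation"] == pytest.approx(0.9)
        # finer cuts split a tight block: separation collapses to 0.1
        assert curve.loc[3, "separation"] == pytest.approx(0.1)
        assert list(curve.index) == [2, 3, 4, 5]  # stops at p-1

    def test_forcing_blocks_together_inflates_compactness(self):
        # three blocks cut at k=2 put two blocks in one cluster
        items = tuple("abcdef")
        D = np.full((6, 6), 0.9)
        for block in ([0, 1], [2, 3], [4, 5]):
            for i in block:
                for j in block:
                    D[i, j] = 0.1 if i != j else 0.0
        np.fill_diagonal(D, 0.0)
        dm = DissimilarityMatrix(items=items, values=D)
        dend = average_linkage(dm)
        curve = compactness_separation_curve(dm, dend).set_index("k")
        assert curve.loc[2, "compactness"] == pytest.approx(0.9)
        assert curve.loc[3, "compactness"] == pytest.approx(0.1)

    def test_optimal_k_picks_the_block_count(self, two_block_D):
        dend = average_linkage(two_block_D)
        curve = compactness_separation_curve(two_block_D, dend)
        assert optimal_k(curve) == 2

    def test_optimal_k_ties_break_small(self):
        curve = pd.DataFrame(
            {"k": [2, 3, 4], "compactness": [0.5, 0.5, 0.5],
             "separation": [0.5, 0.5, 0.5]}
        )
        assert optimal_k(curve) == 2
        with pytest.raises(ValueError):
            optimal_k(curve.iloc[:0])


class TestOracleEquivalence:
    @staticmethod
    def brute_force_upgma(D):
        """Recompute every pairwise average at each step (no Lance-Williams)."""
        p = D.shape[0]
        clusters = {i: [i] for i in range(p)}
        heights = []
        merges = []
        while len(clusters) > 1:
            keys = sorted(clusters)
            best = None
            for i, a in enumerate(keys):
                for b in keys[i + 1:]:
                    avg = np.mean([D[x, y] for x in clusters[a] for y in clusters[b]])
                    cand = (avg, tuple(sorted(clusters[a] + clusters[b])))
                    if best is None or cand < best[:2]:
                        best = (avg, cand[1], a, b)
            avg, _, a, b = best
            heights.append(avg)
            merges.append(frozenset(clusters[a] + clusters[b]))
            clusters[a] = clusters[a] + clusters[b]
            del clusters[b]
        return heights, merges

    @pytest.mark.parametrize("seed", range(6))
    def test_merge_sequence_matches_brute_force(self, seed):
        p = 4 + seed % 4  # p in 4..7
        D = random_dissimilarity(p, seed=100 + seed)
        dend = average_linkage(D)
        ref_heights, ref_merges = self.brute_force_upgma(D.values)
        np.testing.assert_allclose(dend.heights, ref_heights, atol=1e-12)
        # reconstruct merged leaf sets from the linkage matrix
        sets = {i: frozenset([i]) for i in range(p)}
        for t in range(p - 1):
            a, b = int(dend.linkage[t, 0]), int(dend.linkage[t, 1])
            sets[p + t] = sets[a] | sets[b]
            assert sets[p + t] == ref_merges[t]


class TestProfiles:
    def test_singleton_cluster_profile(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.integers(1, 6, 100), "b": rng.integers(1, 6, 100)})
        prof = profile_clusters(df, {"a": 1, "b": 2}).set_index("cluster")
        assert prof.loc[1, "mean_clus"] == pytest.approx(df["a"].mean())
        assert np.isnan(prof.loc[1, "rho_clus"])

    def test_identical_items_profile(self):
        rng = np.random.default_rng(1)
        x = rng.integers(1, 6, 200)
        df = pd.DataFrame({"a": x, "b": x})
        prof = profile_clusters(df, {"a": 1, "b": 1}).set_index("cluster")
        assert prof.loc[1, "rho_clus"] == pytest.approx(1.0)
        assert prof.loc[1, "sd_clus"] == pytest.approx(df["a"].std(ddof=1))

    def test_cluster_mean_matches_construction(self):
        from behavdet import synthetic

        # skewed 3-item block tuned near a mean cluster score of ~2.2-2.4
        ds = synthetic.generate(
            synthetic.SyntheticDesign(
                n_respondents=4000, items_per_cluster=(3,), n_noise_items=0,
                loading=0.8, effect=0.5, seed=8,
            )
        )
        prof = profile_clusters(
            ds.responses.data, {i: 1 for i in ds.signal_items}
        )
        expected = ds.responses.data[ds.signal_items].mean(axis=1).mean()
        assert prof["mean_clus"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert 2.0 < prof["mean_clus"].iloc[0] < 2.8

    def test_missing_item_rejected(self):
        df = pd.DataFrame({"a": [1, 2, 3]})
        with pytest.raises(KeyError):
            profile_clusters(df, {"zz": 1})


def test_cluster_determinants_end_to_end(strong_dataset):
    sol = cluster_determinants(strong_dataset.responses, strong_dataset.signal_items)
    assert sol.k == 3
    assert sol.ccc > 0.9
    truth = strong_dataset.true_assignment
    # planted blocks are recovered exactly (up to label permutation)
    mapping = {}
    for item, cid in sol.assignment.items():
        assert mapping.setdefault(truth[item], cid) == cid


def test_dendrogram_plot_written(two_block_D, tmp_path):
    dend = average_linkage(two_block_D)
    path = clustering.plot_dendrogram(dend, tmp_path / "dend.svg", k=2)
    assert path.stat().st_size > 0
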