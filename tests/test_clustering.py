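"""Ward clustering, flat-cluster cuts, enrichment and spatial ordering."""

import numpy as np
import pandas as pd
import pytest

from tfcatalog import (
    LinkageTree,
    family_enrichment,
    flat_clusters,
    normalize_by_max,
    spatial_zscore_cluster,
    ward_linkage,
    zscore_rows,
)

from oracles import fisher_two_sided, flat_clusters_oracle, naive_ward_heights


def frame(rows, index=None):
    rows = np.asarray(rows, dtype=float)
    index = index or [f"g{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=index,
                        columns=[f"t{j}" for j in range(rows.shape[1])])


class TestNormalizeByMax:
    def test_rows_divided_by_their_max(self):
        out = normalize_by_max(frame([[2, 4, 8]]))
        assert out.iloc[0].tolist() == [0.25, 0.5, 1.0]

    def test_constant_profile_becomes_ones(self):
        out = normalize_by_max(frame([[5, 5, 5]]))
        assert out.iloc[0].tolist() == [1.0, 1.0, 1.0]

    def test_all_zero_profile_dropped(self):
        out = normalize_by_max(frame([[0, 0, 0], [1, 2, 4]]))
        assert list(out.index) == ["g1"]


class TestWardLinkage:
    def test_hand_computed_one_dimensional_merge_heights(self):
        tree = ward_linkage(frame([[0.0], [1.0], [10.0]]))
        assert tree.heights[0] == pytest.approx(1.0)
        assert tree.heights[1] == pytest.approx(np.sqrt(361 / 3))

    def test_identical_rows_merge_first_at_height_zero(self):
        tree = ward_linkage(frame([[1, 2], [5, 9], [1, 2]]))
        assert tree.heights[0] == pytest.approx(0.0)
        assert set(tree.linkage[0, :2].astype(int)) == {0, 2}

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            ward_linkage(np.array([[1.0, np.nan], [0.0, 1.0]]))

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_naive_sum_of_squares_agglomerator(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(3, 9))
        X = rng.normal(size=(n, int(rng.integers(1, 4))))
        tree = ward_linkage(X)
        assert sorted(tree.heights) == pytest.approx(naive_ward_heights(X))


class TestFlatClusters:
    def test_small_gaps_give_single_cluster(self):
        Z = np.array([[0, 1, 2.0, 2], [2, 3, 4.8, 3]])  # all gaps <= 5
        tree = LinkageTree(Z, ["a", "b", "c"])
        assert len(set(flat_clusters(tree, 5.0).values())) == 1

    def test_single_large_gap_cuts_once(self):
        # leaves a,b merge at 1; c joins at 8 -> gap to child c is 8 (> 5)
        Z = np.array([[0, 1, 1.0, 2], [2, 3, 8.0, 3]])
        tree = LinkageTree(Z, ["a", "b", "c"])
        clusters = flat_clusters(tree, 5.0)
        assert clusters["a"] == clusters["b"] != clusters["c"]

    def test_partition_is_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3)) * 5
        tree = ward_linkage(X)
        clusters = flat_clusters(tree, 2.0)
        assert set(clusters) == set(tree.labels)
        assert all(isinstance(c, int) for c in clusters.values())

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_pairwise_path_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 16))
        X = rng.normal(size=(n, 2)) * rng.uniform(0.5, 6)
        threshold = float(rng.uniform(0.5, 5))
        tree = ward_linkage(X)
        mine = flat_clusters(tree, threshold)
        oracle = flat_clusters_oracle(tree.linkage, threshold)
        mine_sets = {}
        for label, cid in mine.items():
            mine_sets.setdefault(cid, set()).add(int(label))
        assert sorted(map(sorted, mine_sets.values())) == \
            sorted(map(sorted, (s for s in oracle)))


class TestFamilyEnrichment:
    def _table(self, a, b, c, d):
        genes, fams, clusters = [], {}, {}
        i = 0
        for count, (in_cl, in_fam) in zip(
                (a, b, c, d), [(1, 1), (1, 0), (0, 1), (0, 0)]):
            for _ in range(count):
                g = f"g{i}"
                clusters[g] = 0 if in_cl else 1
                fams[g] = ["F"] if in_fam else ["G"]
                genes.append(g)
                i += 1
        return family_enrichment(clusters, fams)

    def test_two_sided_p_matches_hypergeometric_enumeration(self):
        out = self._table(3, 1, 1, 3)
        row = out[(out["cluster_id"] == 0) & (out["family"] == "F")].iloc[0]
        assert row["p"] == pytest.approx(34 / 70)
        assert (row["a"], row["b"], row["c"], row["d"]) == (3, 1, 1, 3)

    def test_perfect_separation_p(self):
        out = self._table(4, 0, 0, 4)
        row = out[(out["cluster_id"] == 0) & (out["family"] == "F")].iloc[0]
        assert row["p"] == pytest.approx(2 / 70)

    def test_no_annotated_genes_yields_empty_table(self):
        assert family_enrichment({"g0": 0}, {"g0": []}).empty

    def test_fisher_matches_enumeration_oracle_on_small_margins(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 9, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            _, p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_two_sided(a, b, c, d), rel=1e-8, abs=1e-12)

    def test_bh_rejections_match_step_up_definition(self):
        rng = np.random.default_rng(7)
        genes, fams, clusters = [], {}, {}
        for i in range(60):
            g = f"g{i}"
            clusters[g] = int(rng.integers(4))
            fams[g] = [str(rng.integers(3))]
        out = family_enrichment(clusters, fams, fdr_cutoff=0.1)
        p = out["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        thresh = 0.0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= 0.1 * rank / m:
                thresh = p[idx]
        expected = p <= thresh if thresh > 0 else np.zeros(m, bool)
        assert (out["significant"].to_numpy() == expected).all()
        # q-values are monotone along the p-ordering
        q_sorted = out["fdr"].to_numpy()[order]
        assert (np.diff(q_sorted) >= -1e-12).all()


class TestSpatial:
    def test_zscore_rows_standardized(self):
        z = zscore_rows(frame([[1, 2, 3]]))
        assert z.iloc[0].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        rng = np.random.default_rng(0)
        z = zscore_rows(frame(rng.normal(size=(10, 5))))
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_zero_variance_rows_dropped(self):
        z = zscore_rows(frame([[2, 2, 2], [1, 2, 3]]))
        assert list(z.index) == ["g1"]

    def test_identical_profiles_are_adjacent(self):
        mat = pd.DataFrame(
            [[10, 1, 1, 1, 1], [10, 1, 1, 1, 1], [1, 1, 1, 1, 10]],
            index=["a", "b", "c"], columns=["AC", "DMZ", "LMZ", "VMZ", "VEG"])
        out = spatial_zscore_cluster(mat)
        order = out["leaf_order"]
        assert abs(order.index("a") - order.index("b")) == 1

    def test_leaf_order_follows_animal_vegetal_ratio(self):
        mat = pd.DataFrame(
            [[100, 1, 1, 1, 1], [1, 1, 1, 1, 100], [50, 10, 10, 10, 2]],
            index=["animal", "vegetal", "mid"],
            columns=["AC", "DMZ", "LMZ", "VMZ", "VEG"])
        out = spatial_zscore_cluster(mat)
        order = out["leaf_order"]
        assert order.index("animal") < order.index("vegetal")

    def test_planted_blocks_stay_contiguous(self):
        """Genes planted in 3 regional blocks group contiguously in >= 95%
        of seeds."""
        n_seeds, ok = 20, 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rows, labels, block_of = [], [], {}
            for b, region_idx in enumerate((0, 2, 4)):
                for j in range(6):
                    profile = rng.uniform(0.5, 2.0, 5)
                    profile[region_idx] += 30.0
                    g = f"b{b}_{j}"
                    rows.append(profile)
                    labels.append(g)
                    block_of[g] = b
            mat = pd.DataFrame(rows, index=labels,
                               columns=["AC", "DMZ", "LMZ", "VMZ", "VEG"])
            order = spatial_zscore_cluster(mat)["leaf_order"]
            blocks = [block_of[g] for g in order]
            n_switches = sum(b1 != b2 for b1, b2 in zip(blocks, blocks[1:]))
            ok += n_switches == 2  # three contiguous blocks
        assert ok >= 0.95 * n_seeds
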