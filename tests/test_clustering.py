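"""Distance, UPGMA (vs the scipy oracle), bootstrap support, outlier branches."""

import io

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

import methylomp as M
from methylomp.data_io import DataValidationError
from methylomp.filtering import exclude_subset


def _random_matrix(n_probes, n_samples, seed):
    rng = np.random.default_rng(seed)
    return M.BetaMatrix.from_arrays(
        [f"p{i}" for i in range(n_probes)],
        [f"s{j}" for j in range(n_samples)],
        rng.random((n_probes, n_samples)),
    )


class TestMethylomeDistance:
    def test_duplicate_columns_distance_zero(self):
        vals = np.random.default_rng(0).random((30, 1))
        m = M.BetaMatrix.from_arrays(
            [f"p{i}" for i in range(30)], ["a", "b"], np.hstack([vals, vals])
        )
        d = M.methylome_distance(m)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_anticorrelated_vectors_distance_two(self):
        m = M.BetaMatrix.from_arrays(
            ["p1", "p2"], ["a", "b"], np.array([[0.1, 0.9], [0.9, 0.1]])
        )
        d = M.methylome_distance(m)
        assert d.loc["a", "b"] == pytest.approx(2.0)

    def test_matches_brute_force_pairwise_correlation(self):
        m = _random_matrix(100, 5, seed=1)
        d = M.methylome_distance(m)
        vals = m.values
        for a in range(5):
            for b in range(5):
                r = np.corrcoef(vals[:, a], vals[:, b])[0, 1]
                assert d.iloc[a, b] == pytest.approx(1 - r, abs=1e-12)

    def test_probe_permutation_invariance(self):
        m = _random_matrix(50, 4, seed=2)
        perm = np.random.default_rng(3).permutation(50)
        mp = M.BetaMatrix(m.df.iloc[perm])
        assert np.allclose(M.methylome_distance(m), M.methylome_distance(mp))

    def test_constant_sample_is_error(self):
        vals = np.random.default_rng(0).random((10, 2))
        vals[:, 1] = 0.5
        m = M.BetaMatrix.from_arrays(
            [f"p{i}" for i in range(10)], ["a", "b"], vals
        )
        with pytest.raises(DataValidationError, match="constant"):
            M.methylome_distance(m)

    def test_pairwise_complete_case_with_missing(self):
        vals = np.random.default_rng(4).random((40, 3))
        vals[0, 0] = np.nan
        m = M.BetaMatrix.from_arrays(
            [f"p{i}" for i in range(40)], ["a", "b", "c"], vals
        )
        d = M.methylome_distance(m)
        r = np.corrcoef(vals[1:, 0], vals[1:, 1])[0, 1]
        assert d.loc["a", "b"] == pytest.approx(1 - r)


def _cophenetic(dend):
    """Pairwise cophenetic distances implied by a Dendrogram."""
    sets = dend.leaf_sets()
    n = dend.n_leaves
    coph = {}
    for k, (a, b, h) in enumerate(dend.merges):
        for la in sets[a]:
            for lb in sets[b]:
                coph[frozenset((la, lb))] = h
    return coph


class TestUpgma:
    def test_forced_topology(self):
        import pandas as pd
        d = pd.DataFrame(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        dend = M.hclust_average(d)
        assert dend.merges[0][:2] == (0, 1) and dend.merges[0][2] == pytest.approx(0.1)
        assert dend.merges[1][2] == pytest.approx(0.9)

    def test_two_samples_single_merge(self):
        m = _random_matrix(20, 2, seed=5)
        dend = M.hclust_average(M.methylome_distance(m))
        assert len(dend.merges) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_cophenetic(self, seed):
        """Merge heights agree with the scipy UPGMA reference on 8 samples."""
        m = _random_matrix(60, 8, seed=seed)
        d = M.methylome_distance(m)
        dend = M.hclust_average(d)
        Z = hierarchy.linkage(squareform(d.to_numpy(), checks=False), method="average")
        assert np.allclose(
            sorted(h for _, _, h in dend.merges), sorted(Z[:, 2])
        )
        coph_ref = squareform(hierarchy.cophenet(Z))
        coph_mine = _cophenetic(dend)
        ids = list(d.index)
        for a in range(8):
            for b in range(a + 1, 8):
                assert coph_mine[frozenset((ids[a], ids[b]))] == pytest.approx(
                    coph_ref[a, b]
                )

    def test_heights_nondecreasing_along_merges(self):
        m = _random_matrix(50, 10, seed=6)
        dend = M.hclust_average(M.methylome_distance(m))
        heights = [h for _, _, h in dend.merges]
        # UPGMA on a proper distance is monotone
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_leaves_partition_exactly_once(self):
        m = _random_matrix(30, 6, seed=7)
        dend = M.hclust_average(M.methylome_distance(m))
        root = dend.n_leaves + len(dend.merges) - 1
        assert dend.leaf_sets()[root] == set(m.sample_ids)


class TestBootstrapSupport:
    def test_b1_supports_binary(self):
        m = _random_matrix(30, 5, seed=8)
        dend = M.bootstrap_support(m, B=1, seed=0)
        assert set(dend.support.values()) <= {0.0, 1.0}

    def test_fixed_seed_reproducible(self):
        m = _random_matrix(30, 5, seed=9)
        a = M.bootstrap_support(m, B=20, seed=3)
        b = M.bootstrap_support(m, B=20, seed=3)
        assert a.support == b.support

    def test_well_separated_clusters_high_support(self):
        rng = np.random.default_rng(10)
        base = rng.random(200)
        cols, names = [], []
        for k, offset in enumerate((0.0, 0.35)):
            center = np.clip(base + offset, 0, 1)
            for j in range(4):
                cols.append(np.clip(center + rng.normal(0, 0.01, 200), 0, 1))
                names.append(f"g{k}s{j}")
        m = M.BetaMatrix.from_arrays(
            [f"p{i}" for i in range(200)], names, np.array(cols).T
        )
        dend = M.bootstrap_support(m, B=100, seed=1)
        sets = dend.leaf_sets()
        for group in ({f"g0s{j}" for j in range(4)}, {f"g1s{j}" for j in range(4)}):
            node = next(k for k, s in sets.items() if s == group)
            assert dend.support[node] >= 0.95

    def test_newick_parses_with_biopython(self):
        from Bio import Phylo

        m = _random_matrix(40, 6, seed=11)
        dend = M.bootstrap_support(m, B=10, seed=0)
        tree = Phylo.read(io.StringIO(dend.to_newick()), "newick")
        assert {t.name for t in tree.get_terminals()} == set(m.sample_ids)


class TestOutlierBranches:
    def test_k_zero_empty(self):
        m = _random_matrix(30, 5, seed=12)
        dend = M.hclust_average(M.methylome_distance(m))
        assert M.outlier_branches(dend, 0) == set()

    def test_k_must_be_less_than_leaves(self):
        m = _random_matrix(30, 5, seed=12)
        dend = M.hclust_average(M.methylome_distance(m))
        with pytest.raises(DataValidationError):
            M.outlier_branches(dend, 5)

    def test_planted_cohort_recovery(self, small_cohort):
        cord, ann, sheet, truth = (
            small_cohort["cord"], small_cohort["ann"],
            small_cohort["sheet"], small_cohort["truth"],
        )
        m, _ = exclude_subset(cord, ann.subset("xy_snp"), "xy_snp")
        dend = M.hclust_average(M.methylome_distance(m))
        found = M.outlier_branches(dend, 3)
        assert found == {f"{i}_cb" for i in truth.planted_omp}

    def test_planted_twin_family_not_clade(self, small_cohort):
        """The family containing a planted twin fails to co-cluster; the
        other families form clades."""
        cord, ann, sheet, truth = (
            small_cohort["cord"], small_cohort["ann"],
            small_cohort["sheet"], small_cohort["truth"],
        )
        m, _ = exclude_subset(cord, ann.subset("xy_snp"), "xy_snp")
        dend = M.hclust_average(M.methylome_distance(m))
        fam_samples = {
            fam: [f"{i}_cb" for i in inds]
            for fam, inds in sheet.families().items()
            if len(inds) >= 2
        }
        report = M.family_clade_report(dend, fam_samples)
        planted_fams = {
            fam for fam, inds in sheet.families().items()
            if set(inds) & truth.planted_omp
        }
        for fam, is_clade in report.items():
            assert is_clade == (fam not in planted_fams)
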