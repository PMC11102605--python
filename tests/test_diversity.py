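"""Alpha diversity, weighted UniFrac, PCoA and PERMANOVA."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

import cmuquant as cq
from cmuquant.errors import DesignError, MappingError, UndefinedDiversityError


def tree_from(newick):
    return TreeNode.read(io.StringIO(newick))


TWO_LEAF = tree_from("(A:1,B:1):0;")


def random_profiles(rng, taxa, n):
    return [
        {t: float(v) for t, v in zip(taxa, rng.uniform(0, 10, len(taxa)))}
        for _ in range(n)
    ]


class TestAlpha:
    def test_observed_richness(self):
        assert cq.observed_richness({"a": 10, "b": 0, "c": 5}) == 2
        assert cq.observed_richness({}) == 0
        assert cq.observed_richness({"a": 10, "b": 5}, detection_threshold=7) == 1

    def test_shannon_uniform_and_degenerate(self):
        assert cq.shannon_weaver({c: 2.5 for c in "abcd"}) == pytest.approx(
            math.log(4), abs=1e-12
        )
        assert cq.shannon_weaver({"a": 42.0}) == 0.0

    def test_shannon_two_taxon_value(self):
        # -0.25 ln 0.25 - 0.75 ln 0.75
        h = cq.shannon_weaver({"a": 0.25, "b": 0.75})
        assert h == pytest.approx(0.5623351446188083, abs=1e-12)

    def test_shannon_all_zero_undefined(self):
        with pytest.raises(UndefinedDiversityError):
            cq.shannon_weaver({"a": 0.0, "b": 0.0})

    def test_shannon_bounds(self):
        rng = np.random.default_rng(0)
        for profile in random_profiles(rng, list("abcdefg"), 20):
            h = cq.shannon_weaver(profile)
            assert 0 <= h <= math.log(len(profile)) + 1e-12


class TestWeightedUnifrac:
    def test_identical_profiles_zero(self):
        profile = {"A": 3.0, "B": 7.0}
        assert cq.weighted_unifrac(TWO_LEAF, profile, profile) == pytest.approx(0.0)

    def test_disjoint_two_leaf_raw_and_normalized(self):
        assert cq.weighted_unifrac(
            TWO_LEAF, {"A": 5.0}, {"B": 9.0}, normalized=False
        ) == pytest.approx(2.0)
        assert cq.weighted_unifrac(
            TWO_LEAF, {"A": 5.0}, {"B": 9.0}, normalized=True
        ) == pytest.approx(1.0)

    def test_scale_invariance_of_absolute_input(self):
        tree = cq.simulate_tree(list("ABCD"), seed=3)
        a = {"A": 1.0, "B": 2.0, "C": 0.5}
        b = {"B": 1.0, "C": 4.0, "D": 2.0}
        scaled = {t: 1000 * v for t, v in a.items()}
        assert cq.weighted_unifrac(tree, a, b) == pytest.approx(
            cq.weighted_unifrac(tree, scaled, b)
        )

    def test_symmetry_and_triangle_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        taxa = list("ABCDE")
        tree = cq.simulate_tree(taxa, seed=9)
        profiles = random_profiles(rng, taxa, 6)

        def d(x, y):
            return cq.weighted_unifrac(tree, x, y, normalized=False)

        for i in range(len(profiles)):
            for j in range(i + 1, len(profiles)):
                assert d(profiles[i], profiles[j]) == pytest.approx(
                    d(profiles[j], profiles[i])
                )
                assert d(profiles[i], profiles[j]) >= 0
                for k in range(len(profiles)):
                    if k in (i, j):
                        continue
                    assert d(profiles[i], profiles[j]) <= d(
                        profiles[i], profiles[k]
                    ) + d(profiles[k], profiles[j]) + 1e-9

    @pytest.mark.parametrize("normalized", [False, True])
    def test_matches_skbio_on_integer_counts(self, normalized):
        from skbio.diversity.beta import weighted_unifrac as skbio_wu

        rng = np.random.default_rng(12)
        taxa = [f"t{i}" for i in range(8)]
        tree = cq.simulate_tree(taxa, seed=21)
        for _ in range(5):
            u = rng.integers(0, 50, len(taxa))
            v = rng.integers(0, 50, len(taxa))
            if u.sum() == 0 or v.sum() == 0:
                continue
            ours = cq.weighted_unifrac(
                tree,
                dict(zip(taxa, map(float, u))),
                dict(zip(taxa, map(float, v))),
                normalized=normalized,
            )
            reference = skbio_wu(u, v, taxa=taxa, tree=tree, normalized=normalized)
            assert ours == pytest.approx(float(reference), rel=1e-10)

    def test_missing_taxon_lists_names(self):
        with pytest.raises(MappingError, match="Zeta") as info:
            cq.weighted_unifrac(TWO_LEAF, {"A": 1.0, "Zeta": 2.0}, {"B": 1.0})
        assert "Zeta" in info.value.taxa

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedDiversityError):
            cq.weighted_unifrac(TWO_LEAF, {}, {"B": 0.0})

    def test_distance_matrix_matches_pairwise(self):
        taxa = list("ABCD")
        tree = cq.simulate_tree(taxa, seed=5)
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            rng.uniform(0, 5, (3, 4)), index=["s1", "s2", "s3"], columns=taxa
        )
        dm = cq.unifrac_distance_matrix(tree, table, normalized=True)
        for i, a in enumerate(table.index):
            for j, b in enumerate(table.index):
                expected = (
                    0.0
                    if i == j
                    else cq.weighted_unifrac(
                        tree, table.loc[a].to_dict(), table.loc[b].to_dict()
                    )
                )
                assert dm[a, b] == pytest.approx(expected, abs=1e-12)


class TestPcoa:
    def test_two_samples(self):
        ordination = cq.pcoa([[0.0, 2.0], [2.0, 0.0]])
        coords = ordination.coordinates.to_numpy().ravel()
        assert sorted(coords) == pytest.approx([-1.0, 1.0])
        assert ordination.eigenvalues[0] == pytest.approx(2.0)

    def test_all_zero_distances(self):
        ordination = cq.pcoa(np.zeros((4, 4)))
        assert ordination.coordinates.shape[1] == 0

    def test_three_equidistant_samples(self):
        d = np.ones((3, 3)) - np.eye(3)
        ordination = cq.pcoa(d)
        eig = ordination.eigenvalues
        assert eig[0] == pytest.approx(eig[1], rel=1e-10)
        assert eig[0] > 0

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(4)
        points = rng.normal(size=(8, 3))
        d = squareform(pdist(points))
        ordination = cq.pcoa(d)
        recon = squareform(pdist(ordination.coordinates.to_numpy()))
        assert np.abs(recon - d).max() < 1e-8
        assert ordination.proportion_explained.sum() <= 1 + 1e-12

    def test_matches_skbio_on_euclidean_fixture(self):
        rng = np.random.default_rng(6)
        points = rng.normal(size=(6, 2))
        dm = DistanceMatrix(squareform(pdist(points)))
        ours = cq.pcoa(dm)
        reference = skbio_pcoa(dm, number_of_dimensions=2)
        assert np.asarray(ours.eigenvalues[:2]) == pytest.approx(
            reference.eigvals.to_numpy()[:2], rel=1e-8
        )
        # coordinates agree up to per-axis sign
        ref_coords = reference.samples.to_numpy()[:, :2]
        our_coords = ours.coordinates.to_numpy()[:, :2]
        for axis in range(2):
            assert np.allclose(
                our_coords[:, axis], ref_coords[:, axis], atol=1e-8
            ) or np.allclose(our_coords[:, axis], -ref_coords[:, axis], atol=1e-8)

    def test_asymmetric_rejected_and_k_bounds(self):
        with pytest.raises(ValueError):
            cq.pcoa([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            cq.pcoa(np.zeros((3, 3)), k=3)


class TestPermanova:
    @staticmethod
    def clustered(n_per_group=6, separation=10.0, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(n_per_group, 2))
        b = rng.normal(separation, 1, size=(n_per_group, 2))
        points = np.vstack([a, b])
        labels = ["a"] * n_per_group + ["b"] * n_per_group
        return squareform(pdist(points)), labels

    def test_separated_clusters_minimal_p(self):
        # 10 per group: the chance a random permutation reproduces the
        # observed split (tying the observed F) is negligible
        d, labels = self.clustered(n_per_group=10)
        result = cq.permanova(d, labels, n_perm=999, seed=1)
        assert result.p_value == pytest.approx(1 / 1000)
        assert result.pseudo_f > 10

    def test_relabeling_invariance(self):
        d, labels = self.clustered(seed=3)
        rng = np.random.default_rng(8)
        perm = rng.permutation(len(labels))
        d_perm = d[np.ix_(perm, perm)]
        labels_perm = [labels[i] for i in perm]
        f1 = cq.permanova(d, labels, n_perm=99, seed=0).pseudo_f
        f2 = cq.permanova(d_perm, labels_perm, n_perm=99, seed=0).pseudo_f
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_seed_reproducibility(self):
        d, labels = self.clustered(separation=1.0, seed=5)
        r1 = cq.permanova(d, labels, n_perm=199, seed=42)
        r2 = cq.permanova(d, labels, n_perm=199, seed=42)
        assert r1.p_value == r2.p_value

    def test_pseudo_f_matches_skbio(self):
        d, labels = self.clustered(separation=2.0, seed=7)
        ours = cq.permanova(d, labels, n_perm=99, seed=0)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(len(labels))])
        reference = skbio_permanova(dm, list(labels), permutations=99, seed=0)
        assert ours.pseudo_f == pytest.approx(reference["test statistic"], rel=1e-10)

    def test_design_errors(self):
        d, labels = self.clustered(seed=2)
        with pytest.raises(DesignError):
            cq.permanova(d, ["a"] * len(labels), n_perm=99, seed=0)
        with pytest.raises(DesignError):
            cq.permanova(d, ["a"] + ["b"] * (len(labels) - 1), n_perm=99, seed=0)
        with pytest.raises(ValueError):
            cq.permanova(d, labels, n_perm=10, seed=0)
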