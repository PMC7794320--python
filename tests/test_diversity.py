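"""Diversity, ordination, PERMANOVA and group-test behaviour.

PCoA and PERMANOVA are cross-checked against scikit-bio on small instances;
statistical behaviour (p-value floors, exact small-sample p) is checked
directly.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from mycoconcord import FeatureTable
from mycoconcord.diversity import (
    axis_feature_correlation,
    bray_curtis,
    group_tests,
    pcoa,
    permanova,
    richness,
    shannon,
)


def table(rows, units="counts"):
    arr = np.asarray(rows, dtype=float)
    return FeatureTable(
        pd.DataFrame(arr, index=[f"S{i}" for i in range(arr.shape[0])],
                     columns=[f"F{j}" for j in range(arr.shape[1])]),
        units=units,
    )


class TestAlphaDiversity:
    def test_richness_counts_nonzero_features(self):
        r = richness(table([[0, 0, 5], [1, 2, 3]]))
        assert r.tolist() == [1, 3]

    def test_shannon_uniform_equals_log_k(self):
        h = shannon(table([[1, 1, 1, 1]]))
        assert h.iloc[0] == pytest.approx(np.log(4))

    def test_shannon_single_feature_is_zero(self):
        assert shannon(table([[7, 0, 0]])).iloc[0] == 0.0

    def test_shannon_hand_computed(self):
        h = shannon(table([[0.5, 0.25, 0.25]], units="relative"))
        assert h.iloc[0] == pytest.approx(1.03972, abs=1e-5)

    def test_cohort_richness_median_near_sixty(self, paper_cohort):
        med = richness(paper_cohort.mycobiome).median()
        assert 48 <= med <= 72  # within 20% of the configured median of 60


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(table([[1, 2, 3], [1, 2, 3]]))
        assert d[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(table([[1, 1, 0, 0], [0, 0, 2, 2]]))
        assert d[0, 1] == 1.0

    def test_hand_computed(self):
        d = bray_curtis(table([[1, 1, 0], [0, 1, 1]]))
        assert d[0, 1] == pytest.approx(0.5)

    def test_two_all_zero_samples_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(table([[0, 0], [0, 0], [1, 1]]))

    def test_row_scaling_invariance_after_normalisation(self):
        rng = np.random.default_rng(3)
        x = rng.random((6, 5))
        rel = x / x.sum(axis=1, keepdims=True)
        d1 = bray_curtis(table(rel, units="relative"))
        d2 = bray_curtis(table(rel * 1000, units="intensity"))
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-12)


class TestPcoa:
    def _euclidean_dm(self, n=12, p=4, seed=5):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, p))
        return pts, DistanceMatrix(squareform(pdist(pts)), ids=[f"S{i}" for i in range(n)])

    def test_roundtrip_euclidean_distances(self):
        pts, dm = self._euclidean_dm()
        res = pcoa(dm)
        re_dist = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(re_dist, dm.data, atol=1e-8)

    def test_eigenvalue_sum_matches_centered_trace(self):
        _, dm = self._euclidean_dm(seed=9)
        res = pcoa(dm)
        d2 = dm.data**2
        n = d2.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        trace = np.trace(-0.5 * j @ d2 @ j)
        assert res.eigenvalues.sum() == pytest.approx(trace, abs=1e-8)

    def test_collinear_points_one_axis(self):
        t = np.arange(6.0)[:, None] * np.array([[1.0, 2.0, -1.0]])
        dm = DistanceMatrix(squareform(pdist(t)), ids=[f"S{i}" for i in range(6)])
        res = pcoa(dm)
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_skbio_eigenvalues(self):
        _, dm = self._euclidean_dm(seed=1)
        ours = pcoa(dm)
        ref = skbio_pcoa(dm, number_of_dimensions=4)
        np.testing.assert_allclose(
            ours.eigenvalues[:4], ref.eigvals.to_numpy()[:4], atol=1e-8
        )

    def test_axis_signs_canonical(self):
        _, dm = self._euclidean_dm(seed=2)
        coords = pcoa(dm).coordinates.to_numpy()
        for k in range(coords.shape[1]):
            assert coords[np.argmax(np.abs(coords[:, k])), k] >= 0


class TestPermanova:
    def _dm(self, x):
        return DistanceMatrix(squareform(pdist(x)), ids=[f"S{i}" for i in range(len(x))])

    def test_single_group_errors(self):
        dm = self._dm(np.random.default_rng(0).normal(size=(6, 3)))
        with pytest.raises(ValueError):
            permanova(dm, ["a"] * 6)

    def test_tiny_group_errors(self):
        dm = self._dm(np.random.default_rng(0).normal(size=(6, 3)))
        with pytest.raises(ValueError, match="at least 2"):
            permanova(dm, ["a"] * 5 + ["b"])

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(8)
        dm = self._dm(rng.normal(size=(20, 5)))
        labels = ["a"] * 10 + ["b"] * 10
        ours = permanova(dm, labels, n_permutations=99, seed=1)
        ref = skbio_permanova(dm, grouping=np.array(labels), permutations=0)
        assert ours.statistic == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_separated_clouds_hit_p_floor(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3))])
        res = permanova(self._dm(x), ["a"] * 10 + ["b"] * 10,
                        n_permutations=199, seed=1)
        # a random permutation can reproduce the exact two-group partition
        # (tying the observed F), so allow at most one tie above the floor
        assert res.p_value <= 2 / 200

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(2)
        dm = self._dm(rng.normal(size=(16, 4)))
        labels = ["a", "b"] * 8
        r1 = permanova(dm, labels, n_permutations=99, seed=42)
        r2 = permanova(dm, labels, n_permutations=99, seed=42)
        assert r1.p_value == r2.p_value


class TestAxisCorrelation:
    def test_feature_equal_to_axis_scores(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(15, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"S{i}" for i in range(15)])
        ord_res = pcoa(dm)
        axis1 = ord_res.coordinates.iloc[:, 0]
        data = pd.DataFrame(
            {"same": axis1, "reversed": -axis1, "const": np.ones(15)},
            index=axis1.index,
        )
        t = FeatureTable(data, units="log10")
        out = axis_feature_correlation(t, ord_res, axis_index=0)
        assert out.loc["same", "rho"] == pytest.approx(1.0)
        assert out.loc["reversed", "rho"] == pytest.approx(-1.0)
        assert np.isnan(out.loc["const", "rho"])
        assert np.isnan(out.loc["const", "p_adj"])  # excluded from BH family
        assert (out["p_adj"].dropna() >= out["p"].dropna() - 1e-12).all()


class TestGroupTests:
    def test_two_groups_exact_wilcoxon(self):
        # Fully separated 3 vs 3: the rank-sum is the most extreme of the
        # C(6,3)=20 assignments, so the exact two-sided p is 2/20 = 0.1.
        res = group_tests([1, 2, 3, 10, 11, 12], ["a", "a", "a", "b", "b", "b"])
        assert res.test == "wilcoxon-rank-sum"
        assert res.p_value == pytest.approx(0.1)

    def test_three_groups_kruskal(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=30)
        res = group_tests(vals, ["a", "b", "c"] * 10)
        assert res.test == "kruskal-wallis"
        assert 0 <= res.p_value <= 1

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        res = group_tests(vals, ["a"] * 50 + ["b"] * 50)
        assert res.p_value < 1e-6

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            group_tests([1.0, 2.0], ["a", "a"])


def test_alpha_diversity_correlates_with_first_axis(paper_cohort):
    """Sparse individual-specific communities make diversity the dominant
    gradient: alpha diversity tracks PCoA axis 1 (|rho| > 0.4)."""
    from scipy.stats import spearmanr

    from mycoconcord.processing import log10_transform, normalize_relative

    log10 = log10_transform(normalize_relative(paper_cohort.mycobiome))
    ord_res = pcoa(bray_curtis(log10))
    rich = richness(paper_cohort.mycobiome)
    rho = spearmanr(rich, ord_res.coordinates.iloc[:, 0]).statistic
    assert abs(rho) > 0.4
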