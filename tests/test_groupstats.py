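"""Permutation shape ANOVA, disparity, size tests, Mahalanobis and NJ."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from caprimorph.groupstats import (
    anova_size_twoway,
    fligner_test,
    mahalanobis_group_distances,
    mean_shape,
    morphological_disparity,
    neighbor_joining,
    procrustes_anova,
    procrustes_variance,
    wilcoxon_pairwise,
)


class TestProcrustesANOVA:
    def test_ss_decomposition_adds_up(self):
        rng = np.random.default_rng(40)
        y = rng.normal(size=(40, 10))
        g = np.repeat(["a", "b", "c", "d"], 10)
        tab = procrustes_anova(y, {"group": g}, n_perm=49, seed=0)
        total = ((y - y.mean(axis=0)) ** 2).sum()
        assert tab["SS"].sum() == pytest.approx(total, rel=1e-8)
        assert tab["R2"].sum() == pytest.approx(1.0, rel=1e-8)

    def test_huge_effect_gives_minimal_p(self):
        rng = np.random.default_rng(41)
        y = np.vstack([rng.normal(0, 0.1, (15, 6)), rng.normal(10, 0.1, (15, 6))])
        g = np.repeat(["a", "b"], 15)
        tab = procrustes_anova(y, {"group": g}, n_perm=199, seed=1)
        assert tab.loc[0, "p_perm"] == pytest.approx(1.0 / 200.0)

    def test_r2_one_when_groups_explain_everything(self):
        y = np.vstack([np.tile([1.0, 2.0], (10, 1)), np.tile([5.0, -1.0], (10, 1))])
        g = np.repeat(["a", "b"], 10)
        tab = procrustes_anova(y, {"group": g}, n_perm=19, seed=2)
        assert tab.loc[0, "R2"] == pytest.approx(1.0)

    def test_two_way_with_interaction_terms(self):
        rng = np.random.default_rng(42)
        n = 48
        sp = np.tile(np.repeat(["s", "g"], n // 4), 2)
        co = np.repeat(["m", "a"], n // 2)
        y = rng.normal(size=(n, 8))
        tab = procrustes_anova(
            y, {"species": sp, "cohort": co}, interaction=True, n_perm=49, seed=3
        )
        assert list(tab["term"]) == [
            "species", "cohort", "species:cohort", "Residuals",
        ]
        total = ((y - y.mean(axis=0)) ** 2).sum()
        assert tab["SS"].sum() == pytest.approx(total, rel=1e-8)

    def test_seed_determinism_and_p_range(self):
        rng = np.random.default_rng(43)
        y = rng.normal(size=(30, 4))
        g = np.repeat(["a", "b"], 15)
        t1 = procrustes_anova(y, {"g": g}, n_perm=99, seed=7)
        t2 = procrustes_anova(y, {"g": g}, n_perm=99, seed=7)
        pd.testing.assert_frame_equal(t1, t2)
        p = t1.loc[0, "p_perm"]
        assert 1.0 / 100.0 <= p <= 1.0

    def test_singleton_cell_under_interaction_rejected(self):
        y = np.zeros((5, 4))
        sp = np.array(["s", "s", "g", "g", "g"])
        co = np.array(["m", "a", "m", "m", "m"])
        with pytest.raises(ValueError, match="single specimen"):
            procrustes_anova(y, {"sp": sp, "co": co}, interaction=True, n_perm=9)


class TestDisparity:
    def test_random_split_of_one_group_is_null(self):
        rng = np.random.default_rng(44)
        y = rng.normal(size=(80, 10))
        g = rng.permutation(np.repeat(["a", "b"], 40))
        out = morphological_disparity(y, g, n_perm=199, seed=5)
        assert out["pairwise_distance"].loc["a", "b"] < 0.2 * out["variances"].mean()
        assert out["pairwise_p"].loc["a", "b"] > 0.05

    def test_doubled_noise_recovers_variance_ratio(self):
        rng = np.random.default_rng(45)
        a = rng.normal(0, 1.0, size=(200, 12))
        b = rng.normal(0, 2.0, size=(200, 12))
        y = np.vstack([a, b])
        g = np.repeat(["a", "b"], 200)
        out = morphological_disparity(y, g, n_perm=99, seed=6)
        ratio = out["variances"]["b"] / out["variances"]["a"]
        assert ratio == pytest.approx(4.0, rel=0.10)
        assert out["pairwise_p"].loc["a", "b"] == pytest.approx(1.0 / 100.0)

    def test_variance_invariant_to_order_and_rotation(self):
        rng = np.random.default_rng(46)
        y = rng.normal(size=(30, 5, 2))
        v1 = procrustes_variance(y)
        v2 = procrustes_variance(y[rng.permutation(30)])
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        v3 = procrustes_variance(y @ rot)
        assert v1 == pytest.approx(v2, rel=1e-12)
        assert v1 == pytest.approx(v3, rel=1e-12)

    def test_singleton_group_excluded(self, caplog):
        import logging

        rng = np.random.default_rng(47)
        y = rng.normal(size=(9, 4))
        g = np.array(["a"] * 4 + ["b"] * 4 + ["c"])
        with caplog.at_level(logging.WARNING):
            out = morphological_disparity(y, g, n_perm=19, seed=8)
        assert "c" not in out["variances"].index
        assert "excluding" in caplog.text


def _fligner_by_formula(values, groups):
    """Direct textbook computation: normal scores of ranked |x - median|."""
    v = np.asarray(values, float)
    g = np.asarray(groups)
    labels = list(dict.fromkeys(g))
    centered = np.concatenate([np.abs(v[g == l] - np.median(v[g == l])) for l in labels])
    glab = np.concatenate([g[g == l] for l in labels])
    ranks = scipy.stats.rankdata(centered)
    n = len(v)
    a = scipy.stats.norm.ppf(0.5 + ranks / (2.0 * (n + 1.0)))
    abar = a.mean()
    va = np.sum((a - abar) ** 2) / (n - 1)
    stat = sum(
        (g == l).sum() * (a[glab == l].mean() - abar) ** 2 for l in labels
    ) / va
    return stat


class TestSizeTests:
    def test_fligner_identical_samples_zero(self):
        v = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        g = np.repeat(["a", "b"], 4)
        stat, df, p = fligner_test(v, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_fligner_matches_direct_formula_on_fixed_vector(self):
        values = np.array(
            [2.1, 3.7, 1.4, 5.2, 2.9, 4.4, 0.6, 9.8, 1.1, 7.3, 12.0, 3.3]
        )
        groups = np.repeat(["a", "b"], 6)
        stat, df, p = fligner_test(values, groups)
        assert stat == pytest.approx(_fligner_by_formula(values, groups), rel=1e-10)
        assert df == 1
        assert p == pytest.approx(scipy.stats.chi2.sf(stat, df), rel=1e-10)

    def test_fligner_constant_data(self):
        stat, df, p = fligner_test(np.ones(8), np.repeat(["a", "b"], 4))
        assert (stat, p) == (0.0, 1.0)

    def test_wilcoxon_identical_groups_corrected_to_one(self):
        v = np.tile([1.0, 2, 3, 4, 5], 2)
        g = np.repeat(["a", "b"], 5)
        out = wilcoxon_pairwise(v, g)
        assert out.loc["a", "b"] == 1.0

    def test_wilcoxon_separated_groups_exact_enumeration(self):
        v = np.array([1.0, 2, 3, 4, 5, 11, 12, 13, 14, 15])
        g = np.repeat(["a", "b"], 5)
        out = wilcoxon_pairwise(v, g, correction=None)
        # full separation: two-sided exact p = 2 / C(10, 5)
        assert out.loc["a", "b"] == pytest.approx(2.0 / 252.0, rel=1e-10)

    def test_bonferroni_monotone_and_capped(self):
        rng = np.random.default_rng(48)
        v = rng.normal(size=40)
        g = np.repeat(["a", "b", "c", "d"], 10)
        raw = wilcoxon_pairwise(v, g, correction=None)
        adj = wilcoxon_pairwise(v, g, correction="bonferroni")
        for a in "abcd":
            for b in "abcd":
                if a != b:
                    assert adj.loc[a, b] >= raw.loc[a, b] - 1e-15
                    assert adj.loc[a, b] <= 1.0

    def test_twoway_size_anova_constant_response(self):
        sp = np.repeat(["s", "g"], 20)
        co = np.tile(np.repeat(["m", "a"], 10), 2)
        tab = anova_size_twoway(np.ones(40), sp, co)
        assert (tab.loc[["species", "cohort", "species:cohort"], "F"].fillna(0)
                <= 1e-8).all()

    def test_twoway_size_anova_detects_main_effect(self):
        rng = np.random.default_rng(49)
        sp = np.repeat(["s", "g"], 100)
        co = np.tile(np.repeat(["m", "a"], 50), 2)
        y = rng.normal(size=200)
        y[sp == "s"] += 2.0  # main effect of 2 SD
        tab = anova_size_twoway(y, sp, co)
        assert tab.loc["species", "PR(>F)"] < 1e-3

    def test_twoway_size_anova_empty_cell_rejected(self):
        sp = np.array(["s", "s", "g", "g"])
        co = np.array(["m", "m", "m", "m"])
        with pytest.raises(ValueError, match="empty"):
            anova_size_twoway(np.arange(4.0), sp, co)


class TestMahalanobis:
    def test_equal_means_zero(self):
        rng = np.random.default_rng(50)
        base = rng.normal(size=(30, 3))
        x = np.vstack([base, base])
        g = np.repeat(["a", "b"], 30)
        d = mahalanobis_group_distances(x, g)
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-10)

    def test_identity_covariance_reduces_to_euclidean(self):
        rng = np.random.default_rng(51)
        noise = rng.normal(size=(400, 2))
        noise = (noise - noise.mean(0)) @ np.linalg.inv(
            np.linalg.cholesky(np.cov(noise.T, bias=False)).T
        )  # whiten so pooled covariance is the identity
        x = np.vstack([noise[:200] + [0, 0], noise[200:] + [3, 4]])
        g = np.repeat(["a", "b"], 200)
        d = mahalanobis_group_distances(x, g)
        mean_diff = x[200:].mean(0) - x[:200].mean(0)
        # pooled within-group covariance is identity up to O(1/sqrt(n))
        assert d.loc["a", "b"] == pytest.approx(np.linalg.norm(mean_diff), rel=0.02)

    def test_two_group_worked_example(self):
        # explicit pooled covariance and inverse, computed by hand formulas
        xa = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        xb = xa + np.array([4.0, 1.0])
        x = np.vstack([xa, xb])
        g = np.repeat(["a", "b"], 4)
        # within-group scatter of each block: [[4,0],[0,4]]; pooled over n-2=6
        s_pooled = np.array([[8.0, 0.0], [0.0, 8.0]]) / 6.0
        diff = np.array([4.0, 1.0])
        expected = np.sqrt(diff @ np.linalg.inv(s_pooled) @ diff)
        d = mahalanobis_group_distances(x, g)
        assert d.loc["a", "b"] == pytest.approx(expected, rel=1e-12)

    def test_singular_covariance_advises(self):
        x = np.zeros((10, 3))
        g = np.repeat(["a", "b"], 5)
        with pytest.raises(ValueError, match="singular|components"):
            mahalanobis_group_distances(x, g)


def _patristic(newick):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(taxa)
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                out[i, j] = pdm.patristic_distance(taxa[a], taxa[b])
    return labels, out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d(ab)=3, d(ac)=4, d(bc)=5 -> branches a=1, b=2, c=3
        d = np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0]])
        nwk = neighbor_joining(d, labels=["a", "b", "c"])
        labels, pat = _patristic(nwk)
        np.testing.assert_allclose(pat, d, atol=1e-10)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        d = np.array(
            [
                [0.0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ]
        )
        nwk = neighbor_joining(d, labels=["A", "B", "C", "D"])
        labels, pat = _patristic(nwk)
        assert labels == ["A", "B", "C", "D"]
        np.testing.assert_allclose(pat, d, atol=1e-10)

    def test_equidistant_taxa_star_like(self):
        d = np.ones((4, 4)) - np.eye(4)
        nwk = neighbor_joining(d, labels=list("wxyz"))
        _, pat = _patristic(nwk)
        np.testing.assert_allclose(pat[~np.eye(4, dtype=bool)], 1.0, atol=1e-10)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match=">= 3"):
            neighbor_joining(np.zeros((2, 2)), labels=["a", "b"])

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d, labels=list("abc"))


class TestMeanShape:
    def test_identical_shapes_give_that_shape(self):
        rng = np.random.default_rng(52)
        s = rng.normal(size=(6, 2))
        s -= s.mean(axis=0)
        shapes = np.tile(s, (5, 1, 1))
        out = mean_shape(shapes, np.repeat("a", 5))
        np.testing.assert_allclose(out["a"], s, atol=1e-12)

    def test_two_shapes_midpoint(self):
        a = np.array([[0.0, 0], [2, 0], [1, 2]])
        b = np.array([[0.0, 0], [4, 0], [2, 2]])
        out = mean_shape(np.stack([a, b]))
        mid = (a + b) / 2
        np.testing.assert_allclose(out, mid - mid.mean(axis=0), atol=1e-12)

    def test_size_weighted_grand_mean_equals_consensus(self, aligned_small):
        groups = np.array(
            ["g1"] * 50 + ["g2"] * (aligned_small.n - 50)
        )
        means = mean_shape(aligned_small.shapes, groups)
        counts = pd.Series(groups).value_counts()
        grand = sum(means[g] * counts[g] for g in means) / aligned_small.n
        overall = mean_shape(aligned_small.shapes)
        np.testing.assert_allclose(grand, overall, atol=1e-9)
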