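"""Ordination unit and property tests.

The CAP reference values in ``TestCAPAgainstVegan`` were computed once with
R vegan 2.7-1 (``capscale`` + ``anova.cca(by="terms")``) on the identical
fixture and frozen here as an independent oracle.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scentdiel.ordination import (
    CAP,
    bray_curtis,
    pca_timeseries,
    pcoa,
    permutation_anova,
    wpgma_cluster,
)


class TestBrayCurtis:
    def test_hand_value(self):
        df = pd.DataFrame([[2, 2, 0], [1, 1, 1]])
        d = bray_curtis(df, transform="none")
        assert d.data[0, 1] == pytest.approx(3 / 7)

    def test_identical_rows_zero(self):
        df = pd.DataFrame([[1, 2, 3], [1, 2, 3]])
        assert bray_curtis(df).data[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        df = pd.DataFrame([[1, 0], [0, 1]])
        assert bray_curtis(df, transform="none").data[0, 1] == pytest.approx(1.0)

    def test_all_zero_pair_flagged_zero(self):
        df = pd.DataFrame([[0, 0], [0, 0], [1, 1]])
        d = bray_curtis(df)
        assert d.data[0, 1] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            bray_curtis(pd.DataFrame([[1, -1], [0, 1]]))

    @given(
        st.lists(
            st.lists(st.floats(0, 100), min_size=3, max_size=3),
            min_size=2,
            max_size=5,
        ),
        st.floats(0.1, 50),
    )
    def test_scale_invariance(self, rows, c):
        X = np.array(rows)
        if X.sum() == 0:
            return
        d1 = bray_curtis(pd.DataFrame(X), transform="none").condensed_form()
        d2 = bray_curtis(pd.DataFrame(c * X), transform="none").condensed_form()
        np.testing.assert_allclose(d1, d2, atol=1e-12)


class TestPCoA:
    def test_equilateral_triangle_eigenvalues(self):
        D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(D)
        np.testing.assert_allclose(sorted(res.eigenvalues, reverse=True), [0.5, 0.5])
        assert res.negative_inertia.size == 0

    def test_euclidean_line_reconstruction(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        D = np.abs(x[:, None] - x[None, :])
        res = pcoa(D)
        assert res.eigenvalues.size == 1
        coords = res.coordinates
        recon = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        np.testing.assert_allclose(recon, D, atol=1e-10)

    def test_duplicate_samples_identical_coordinates(self):
        df = pd.DataFrame([[1, 2, 0], [1, 2, 0], [0, 1, 5]], dtype=float)
        res = pcoa(bray_curtis(df))
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-10)

    def test_matches_skbio(self):
        """Cross-check eigenvalues against scikit-bio's implementation."""
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.gamma(2, 1, (7, 4)))
        D = bray_curtis(df)
        ours = pcoa(D)
        theirs = skbio_pcoa(D, number_of_dimensions=0)
        k = ours.eigenvalues.size
        np.testing.assert_allclose(
            ours.eigenvalues, np.asarray(theirs.eigvals)[:k], atol=1e-10
        )


class TestCAP:
    def test_cluster_separation(self, clustered_composition):
        X, design = clustered_composition
        fit = CAP(bray_curtis(X), design, "group", features=X).fit()
        assert fit.constrained_proportion >= 0.9
        score = fit.sample_scores[:, 0]
        a = score[design["group"] == "a"]
        b = score[design["group"] == "b"]
        assert max(a) < min(b) or max(b) < min(a)

    def test_inertia_conservation(self, clustered_composition):
        X, design = clustered_composition
        fit = CAP(bray_curtis(X), design, "group").fit()
        total = fit.eigenvalues.sum() + fit.mds_eigenvalues.sum()
        assert total == pytest.approx(fit.total_inertia, abs=1e-8)

    def test_constant_predictor_rejected(self, clustered_composition):
        X, design = clustered_composition
        design = design.assign(const=1.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            CAP(bray_curtis(X), design, "group + const")

    def test_permuted_labels_explain_less(self, clustered_composition):
        """True labels constrain more inertia than shuffled labels in
        >= 95% of 200 shuffles."""
        X, design = clustered_composition
        D = bray_curtis(X)
        true_ci = CAP(D, design, "group").fit().constrained_inertia
        rng = np.random.default_rng(4)
        worse = 0
        for _ in range(200):
            shuffled = design.assign(group=rng.permutation(design["group"].values))
            ci = CAP(D, shuffled, "group").fit().constrained_inertia
            worse += ci <= true_ci
        assert worse >= 190

    def test_compound_scores_sign_tracks_association(self, clustered_composition):
        X, design = clustered_composition
        fit = CAP(bray_curtis(X), design, "group", features=X).fit()
        scores = fit.compound_score_table()["CAP1"]
        # compounds enriched in opposite clusters load with opposite signs
        assert scores["w"] * scores["y"] < 0
        assert scores["y"] * scores["z"] > 0

    def test_summary_mentions_terms(self, clustered_composition):
        X, design = clustered_composition
        text = CAP(bray_curtis(X), design, "group").fit().summary()
        assert "group" in text and "inertia" in text


@pytest.fixture(scope="module")
def fixture_fit():
    rng = np.random.default_rng(42)
    n = 12
    species = np.repeat(["a", "b"], 6)
    time = np.tile(np.linspace(-1, 2, 6), 2)
    X = rng.gamma(2, 1, (n, 5))
    X[species == "a", 0] += 3
    X[species == "b", 1] += 2
    X[:, 2] += np.concatenate([np.linspace(0, 2, 6)] * 2)
    df = pd.DataFrame(X, columns=[f"c{i}" for i in range(5)])
    design = pd.DataFrame({"species": species, "time": time})
    return CAP(bray_curtis(df), design, "species + time + species:time").fit()


class TestCAPAgainstVegan:
    def test_term_ss_match_vegan(self, fixture_fit):
        np.testing.assert_allclose(
            fixture_fit.ss_terms, [0.073142, 0.022176, 0.006676], atol=5e-6
        )
        assert fixture_fit.ss_residual == pytest.approx(0.060611, abs=5e-6)

    def test_f_match_vegan(self, fixture_fit):
        np.testing.assert_allclose(
            fixture_fit.f_statistics(), [9.6540, 2.9270, 0.8812], atol=5e-4
        )

    def test_constrained_inertia_matches_vegan(self, fixture_fit):
        assert fixture_fit.constrained_inertia == pytest.approx(0.1019939, abs=1e-6)
        np.testing.assert_allclose(
            fixture_fit.eigenvalues[:3],
            [0.07840218, 0.01856524, 0.005026486],
            atol=1e-6,
        )


class TestPermutationAnova:
    def test_reproducible_with_seed(self, clustered_composition):
        X, design = clustered_composition
        fit = CAP(bray_curtis(X), design, "group").fit()
        a = permutation_anova(fit, n_perm=499, seed=9)
        b = permutation_anova(fit, n_perm=499, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_perfect_separation_minimal_p(self, clustered_composition):
        X, design = clustered_composition
        fit = CAP(bray_curtis(X), design, "group").fit()
        out = permutation_anova(fit, n_perm=199, seed=2)
        assert out.loc["group", "p"] == pytest.approx(1 / 200)

    def test_term_order_changes_ss_not_total(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.gamma(2, 1, (10, 4)))
        a = rng.standard_normal(10)
        b = 0.5 * a + rng.standard_normal(10)  # correlated predictors
        d1 = pd.DataFrame({"a": a, "b": b})
        D = bray_curtis(X)
        f1 = CAP(D, d1, "a + b").fit()
        f2 = CAP(D, d1, "b + a").fit()
        assert f1.ss_terms[0] != pytest.approx(f2.ss_terms[1])
        assert f1.ss_terms.sum() == pytest.approx(f2.ss_terms.sum(), abs=1e-10)

    def test_n_perm_validated(self, clustered_composition):
        X, design = clustered_composition
        fit = CAP(bray_curtis(X), design, "group").fit()
        with pytest.raises(ValueError):
            permutation_anova(fit, n_perm=0)


class TestPCATimeseries:
    def test_correlated_ions_single_component(self):
        t = np.linspace(0, 4 * np.pi, 100)
        sig = np.sin(t) + 1.5
        df = pd.DataFrame({"a": sig, "b": 2 * sig})
        out = pca_timeseries(df, threshold=0.001)
        assert out["explained_variance_ratio"][0] == pytest.approx(1.0)

    def test_threshold_excludes_weak_ion(self):
        t = np.linspace(0, 2 * np.pi, 50)
        df = pd.DataFrame(
            {"strong": np.sin(t) * 0.01 + 0.01, "weak": np.full(50, 0.0005),
             "mid": np.cos(t) * 0.01 + 0.01}
        )
        out = pca_timeseries(df, threshold=0.001)
        assert "weak" not in out["ions"]

    def test_orthogonal_sinusoids_equal_eigenvalues(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        df = pd.DataFrame({"a": np.sin(t) + 2, "b": np.cos(t) + 2})
        out = pca_timeseries(df)
        r = out["explained_variance_ratio"]
        assert r[0] == pytest.approx(r[1], abs=1e-8)

    def test_too_few_ions(self):
        df = pd.DataFrame({"only": np.ones(10)})
        with pytest.raises(ValueError, match="fewer than 2"):
            pca_timeseries(df)


class TestWPGMA:
    def test_identical_series_merge_first_at_zero(self):
        t = np.linspace(0, 1, 30)
        df = pd.DataFrame([np.sin(t * 6) + 2, np.sin(t * 6) + 2, np.cos(t * 6) + 2],
                          index=["i1", "i2", "i3"])
        tree = wpgma_cluster(df)
        first = tree.linkage[0]
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_anticorrelated_distance_two(self):
        t = np.linspace(0, 2 * np.pi, 50)
        df = pd.DataFrame([np.sin(t) + 2, -np.sin(t) + 2], index=["p", "q"])
        tree = wpgma_cluster(df)
        assert tree.distances[0, 1] == pytest.approx(2.0)

    def test_two_shape_groups_split_at_top(self):
        t = np.linspace(0, 2 * np.pi, 80)
        g1 = np.sin(t) + 2
        g2 = np.cos(2 * t) + 2
        rng = np.random.default_rng(6)
        rows = [g1 + rng.normal(0, 0.01, t.size) for _ in range(2)]
        rows += [g2 + rng.normal(0, 0.01, t.size) for _ in range(2)]
        df = pd.DataFrame(rows, index=["a1", "a2", "b1", "b2"])
        tree = wpgma_cluster(df)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(tree.linkage, t=2, criterion="maxclust")
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_constant_series_flagged_max_distance(self):
        t = np.linspace(0, 2 * np.pi, 40)
        df = pd.DataFrame([np.sin(t) + 2, np.full(40, 1.0)], index=["s", "flat"])
        tree = wpgma_cluster(df)
        assert tree.flagged_constant == ["flat"]
        assert tree.distances[0, 1] == pytest.approx(2.0)

    def test_matches_scipy_weighted_linkage_heights(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.random((5, 20)) + 0.1,
                          index=[f"i{k}" for k in range(5)])
        tree = wpgma_cluster(df)
        assert np.all(np.diff(tree.linkage[:, 2]) >= -1e-12)

    def test_newick_serialization(self):
        t = np.linspace(0, 2 * np.pi, 30)
        df = pd.DataFrame([np.sin(t) + 2, np.cos(t) + 2, np.sin(t) + 2.1],
                          index=["x", "y", "z"])
        nwk = wpgma_cluster(df).to_newick()
        assert nwk.endswith(";")
        for label in ("x", "y", "z"):
            assert label in nwk
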