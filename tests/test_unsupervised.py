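"""OMP peak selection, bisecting k-means, PCA, PLSA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from msiregio import bisect_kmeans, pca, plsa, select_peaks_omp
from msiregio.preprocess import FeatureMatrix, PeakInterval
from msiregio.unsupervised import plsa_reconstruct

from conftest import merge_truth


def make_fm(values, centers=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    centers = centers or [1000.0 + 10 * j for j in range(p)]
    pt = pd.DataFrame({"pixel_x": np.arange(n) % 100,
                       "pixel_y": np.arange(n) // 100,
                       "section": "s", "group": "g"})
    return FeatureMatrix(values=values,
                         columns=[PeakInterval(c, 0.156) for c in centers],
                         pixel_table=pt)


class TestOmp:
    def test_dominant_column_selected_first(self, rng):
        a = rng.lognormal(0, 1.0, 200)
        vals = np.column_stack([a,
                                0.5 * a + rng.normal(0, 1.0, 200) + 10.0,
                                rng.lognormal(0, 0.3, 200) + 5.0])
        fm = make_fm(vals)
        sel = select_peaks_omp(fm, n_atoms=1)
        assert sel == [0]  # column A explains itself and most of column B

    def test_selecting_all_columns_is_a_permutation(self, rng):
        fm = make_fm(rng.lognormal(0, 0.3, size=(50, 6)))
        sel = select_peaks_omp(fm, n_atoms=6)
        assert sorted(sel) == list(range(6))

    def test_degenerate_identical_columns_stop_early(self, rng, caplog):
        a = rng.lognormal(0, 0.5, 80)
        fm = make_fm(np.column_stack([a, a, a]))
        with caplog.at_level("WARNING"):
            sel = select_peaks_omp(fm, n_atoms=3)
        assert len(sel) == 1

    def test_planted_markers_captured_early(self, default_features,
                                            default_truth):
        """Within the first n_markers + 5 selections on the default batch,
        every planted marker is either selected or already well explained by
        the selected columns (R^2 >= 0.5) — orthogonal pursuit deliberately
        skips columns that are redundant with earlier picks."""
        planted = set(default_truth.treatment_marker_mzs()) | \
            set(default_truth.region_marker_mzs())
        sel = select_peaks_omp(default_features, n_atoms=len(planted) + 5)
        x = default_features.values - default_features.values.mean(axis=0)
        basis, _ = np.linalg.qr(x[:, sel])
        for mz in planted:
            j = default_features.column_index(mz)
            if j in sel:
                continue
            col = x[:, j]
            explained = np.linalg.norm(basis.T @ col) ** 2 / \
                np.linalg.norm(col) ** 2
            assert explained >= 0.5, f"marker {mz:.2f} neither selected nor explained"


class TestBisectKmeans:
    def test_two_well_separated_clouds_recovered(self, rng):
        a = rng.normal(0, 0.2, size=(40, 3)) + 1.0
        b = rng.normal(0, 0.2, size=(40, 3)) + 8.0
        fm = make_fm(np.vstack([a, b]))
        tree = bisect_kmeans(fm, n_segments=2, seed=0, n_atoms=None)
        labels = tree.level_labels(2)
        truth = np.array([0] * 40 + [1] * 40)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_first_split_equals_plain_two_means(self, rng):
        vals = np.abs(rng.normal(2, 1, size=(60, 4)))
        fm = make_fm(vals)
        tree = bisect_kmeans(fm, n_segments=2, seed=5, n_atoms=None)
        z = (fm.values[:, tree.selected_columns] -
             fm.values[:, tree.selected_columns].mean(0)) / \
            fm.values[:, tree.selected_columns].std(0)
        km = KMeans(n_clusters=2, n_init=10, random_state=6).fit_predict(z)
        assert adjusted_rand_score(km, tree.level_labels(2)) == 1.0

    def test_levels_refine_and_runs_reproduce(self, rng):
        vals = np.abs(rng.normal(2, 1, size=(80, 5)))
        fm = make_fm(vals)
        t1 = bisect_kmeans(fm, n_segments=4, seed=3, n_atoms=None)
        t2 = bisect_kmeans(fm, n_segments=4, seed=3, n_atoms=None)
        for k in range(1, 5):
            assert np.array_equal(t1.level_labels(k), t2.level_labels(k))
        # refinement: level k+1 changes labels only inside one level-k segment
        for k in range(1, 4):
            prev, nxt = t1.level_labels(k), t1.level_labels(k + 1)
            changed = prev != nxt
            assert len(np.unique(prev[changed])) <= 1

    def test_too_few_distinct_spectra_rejected(self):
        fm = make_fm(np.ones((5, 3)) * [[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="distinct"):
            bisect_kmeans(fm, n_segments=2, seed=0)

    def test_default_batch_recovers_regions_then_treatment(
            self, default_run, ground_truth_table):
        """Level 2 separates trauma core from adjacent tissue (ARI >= 0.8);
        the level-3 segment lies inside the treated group's tam area."""
        out, _ = default_run
        seg = pd.read_csv(out / "segmentation.csv")
        m = merge_truth(seg, ground_truth_table)
        m = m[m["true_region"] != "off_tissue"]
        ari = adjusted_rand_score(m["true_region"], m["segment_level_2"])
        assert ari >= 0.8
        # one of the level-3 segments is (almost) exclusively treated tam;
        # which child of the split inherits the new label is arbitrary
        fracs = []
        for lab in m["segment_level_3"].unique():
            sub = m[m["segment_level_3"] == lab]
            fracs.append(((sub["true_region"] == "tam") &
                          (sub["true_group"] == "MSC-TX")).mean())
        assert max(fracs) >= 0.8


class TestPca:
    def test_rank_one_data_explained_by_first_component(self, rng):
        u = rng.lognormal(0, 0.5, 30)
        v = np.array([1.0, 2.0, 3.0])
        fm = make_fm(np.outer(u, v))
        dec = pca(fm, n_components=2)
        assert dec.explained[0] == pytest.approx(100.0, abs=1e-8)

    def test_two_factor_variance_ratio(self, rng):
        n = 20000
        f1 = rng.normal(0, 2.0, n)   # variance 4
        f2 = rng.normal(0, 1.0, n)   # variance 1
        vals = np.abs(np.column_stack([5 + f1, 5 + f1, 5 + f2, 5 + f2]))
        dec = pca(make_fm(vals), n_components=4)
        # orthogonal two-factor construction: explained split ~80/20 per pair
        assert dec.explained[0] + dec.explained[1] == pytest.approx(100, abs=1)
        assert dec.explained[0] == pytest.approx(50.0, abs=2.0)

    def test_reconstruction_and_orthonormal_loadings(self, rng):
        vals = np.abs(rng.normal(5, 1, size=(40, 5)))
        fm = make_fm(vals)
        dec = pca(fm, n_components=5)
        np.testing.assert_allclose(dec.loadings @ dec.loadings.T, np.eye(5),
                                   atol=1e-8)
        z = (vals - vals.mean(0)) / vals.std(0)
        np.testing.assert_allclose(dec.scores @ dec.loadings, z, atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        vals = np.abs(rng.normal(5, 1, size=(60, 6)))
        dec = pca(make_fm(vals), n_components=4)
        for row in dec.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_constant_column_dropped_with_warning(self, rng, caplog):
        vals = np.abs(rng.normal(5, 1, size=(30, 4)))
        vals[:, 2] = 7.0
        with caplog.at_level("WARNING"):
            dec = pca(make_fm(vals), n_components=3)
        assert dec.loadings.shape[1] == 3
        assert "constant" in caplog.text

    def test_treatment_component_separates_tam_groups(
            self, default_run, ground_truth_table):
        """Some component's scores split treated-tam from control-tam with
        non-overlapping interquartile ranges on the default batch."""
        out, _ = default_run
        sc = merge_truth(pd.read_csv(out / "pca_scores.csv"),
                         ground_truth_table)
        tt = sc[(sc["true_region"] == "tam") & (sc["true_group"] == "MSC-TX")]
        ct = sc[(sc["true_region"] == "tam") & (sc["true_group"] == "control")]
        found = False
        for c in [f"PC{i}" for i in range(1, 6)]:
            q1a, q3a = np.percentile(tt[c], [25, 75])
            q1b, q3b = np.percentile(ct[c], [25, 75])
            if q1a > q3b or q1b > q3a:
                found = True
        assert found


class TestPlsa:
    def _mixture_counts(self, rng, n=300, p=30):
        """Rows are exact mixtures of two distinct peak distributions."""
        w1 = rng.dirichlet(np.ones(p) * 0.5)
        w2 = rng.dirichlet(np.ones(p) * 0.5)
        # pure rows at both ends (interior pixels of each tissue state) make
        # the extreme factors identifiable; the rest are boundary mixtures
        npure = n // 10
        mix = np.concatenate([np.zeros(npure), np.ones(npure),
                              rng.uniform(0, 1, size=n - 2 * npure)])
        rows = np.outer(mix, w1) + np.outer(1 - mix, w2)
        return rows * 10000.0, rows

    def test_planted_two_factor_recovery(self, rng):
        counts, true_rows = self._mixture_counts(rng)
        dec = plsa(counts, n_components=2, tol=1e-12, max_iter=5000)
        recon = plsa_reconstruct(dec)
        tv = 0.5 * np.abs(recon - true_rows).sum(axis=1)
        assert tv.max() <= 0.01

    def test_log_likelihood_never_decreases(self, rng):
        counts = rng.lognormal(0, 0.4, size=(80, 12)) * 50
        dec = plsa(counts, n_components=3, max_iter=100)
        diffs = np.diff(dec.log_likelihood)
        assert np.all(diffs >= -1e-9 * np.abs(dec.log_likelihood[0]))

    def test_simplex_constraints_hold(self, rng):
        counts = rng.lognormal(0, 0.4, size=(50, 10)) * 20
        dec = plsa(counts, n_components=4, max_iter=60)
        np.testing.assert_allclose(dec.loadings.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(dec.scores.sum(axis=1), 1.0, atol=1e-8)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            plsa(np.array([[1.0, -0.5], [0.2, 0.3]]), n_components=2)

    def test_deterministic_without_seed(self, rng):
        counts = rng.lognormal(0, 0.4, size=(40, 8)) * 30
        d1 = plsa(counts, n_components=3, max_iter=50)
        d2 = plsa(counts, n_components=3, max_iter=50)
        np.testing.assert_array_equal(d1.scores, d2.scores)
        np.testing.assert_array_equal(d1.loadings, d2.loadings)

    def test_components_localize_in_treatment_regions(
            self, default_run, ground_truth_table):
        """One component's top-decile pixels concentrate in treated tam,
        another's in control tam, echoing the component score images of the
        treated-vs-control tissue comparison."""
        out, _ = default_run
        sc = merge_truth(pd.read_csv(out / "plsa_scores.csv"),
                         ground_truth_table)
        lab = np.where((sc["true_region"] == "tam") &
                       (sc["true_group"] == "MSC-TX"), "ttam",
                       np.where((sc["true_region"] == "tam") &
                                (sc["true_group"] == "control"), "ctam",
                                "other"))
        top_fracs = {}
        n_top = len(sc) // 10
        for c in [f"C{i}" for i in range(1, 6)]:
            order = np.argsort(-sc[c].to_numpy())[:n_top]
            top_fracs[c] = {"ttam": (lab[order] == "ttam").mean(),
                            "ctam": (lab[order] == "ctam").mean()}
        assert any(f["ttam"] >= 0.7 for f in top_fracs.values())
        assert any(f["ctam"] >= 0.7 for f in top_fracs.values())
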