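"""Robust scaling, SVD eigenbrains, Horn retention, projection, alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import eigenbrains as eb
from eigenbrains.decomposition import EigenbrainDecomposition, ImageMatrix
from eigenbrains.images import SubjectImage
from eigenbrains.simulate import SimConfig


class TestRobustScale:
    def test_five_point_vector(self):
        out = eb.robust_scale(np.array([1.0, 2, 3, 4, 5]))
        assert np.allclose(out, [-1, -0.5, 0, 0.5, 1])

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="flat"):
            eb.robust_scale(np.full(50, 2.0), subject_id="flatso")

    @settings(derandomize=True, max_examples=50)
    @given(hnp.arrays(np.float64, st.integers(10, 200),
                      elements=st.floats(-1e6, 1e6, allow_nan=False)))
    def test_output_median_zero_iqr_one(self, x):
        q25, q75 = np.percentile(x, [25, 75])
        if q75 - q25 <= 1e-9 * max(1.0, np.abs(x).max()):
            return  # near-flat inputs are rejected by contract
        out = eb.robust_scale(x)
        assert abs(np.median(out)) < 1e-9
        q25o, q75o = np.percentile(out, [25, 75])
        assert abs((q75o - q25o) - 1.0) < 1e-9


class TestBuildMatrix:
    def test_shape_and_row_invariants(self, small_cohort):
        images, _, _, grid = small_cohort
        proc = [eb.normalize_to_reference(im, grid) for im in images[:5]]
        mat = eb.build_matrix(proc, grid)
        assert mat.values.shape == (5, grid.n_voxels)
        assert np.allclose(np.median(mat.values, axis=1), 0, atol=1e-9)
        q25, q75 = np.percentile(mat.values, [25, 75], axis=1)
        assert np.allclose(q75 - q25, 1, atol=1e-9)

    def test_input_order_does_not_matter(self, small_cohort):
        images, _, _, grid = small_cohort
        proc = [eb.normalize_to_reference(im, grid) for im in images[:6]]
        a = eb.build_matrix(proc, grid)
        b = eb.build_matrix(proc[::-1], grid)
        assert a.subject_ids == b.subject_ids
        assert np.array_equal(a.values, b.values)

    def test_duplicate_ids_rejected(self, small_cohort):
        images, _, _, grid = small_cohort
        im = eb.normalize_to_reference(images[0], grid)
        with pytest.raises(ValueError, match="duplicate"):
            eb.build_matrix([im, im], grid)

    def test_unnormalized_rejected(self, small_cohort):
        images, _, _, grid = small_cohort
        with pytest.raises(ValueError, match="normalized"):
            eb.build_matrix(images[:3], grid)


def _matrix_from(values):
    values = np.asarray(values, dtype=float)
    return ImageMatrix(values=values,
                       subject_ids=tuple(f"s{i}" for i in range(len(values))),
                       voxel_index=np.arange(values.shape[1]),
                       scaling_median=np.zeros(len(values)),
                       scaling_iqr=np.ones(len(values)))


class TestSVD:
    def test_diagonal_matrix_singular_values(self):
        dec = eb.svd_decompose(_matrix_from([[2.0, 0.0], [0.0, 1.0]]))
        assert np.allclose(dec.singular_values, [2.0, 1.0])

    def test_reconstruction_and_orthonormality(self, small_decomposition):
        _, mat, dec, _, _ = small_decomposition
        recon = dec.scores @ dec.eigenbrains
        assert np.allclose(recon, mat.values, atol=1e-8)
        gram = dec.eigenbrains @ dec.eigenbrains.T
        assert np.allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_score_columns_orthogonal(self, small_decomposition):
        # the decomposition's guarantee: score columns are orthogonal
        _, _, dec, _, _ = small_decomposition
        gram = dec.scores.T @ dec.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_score_columns_uncorrelated_under_column_centering(self, small_cohort):
        # with the voxel-wise mean removed, orthogonality implies exactly
        # zero sample correlation between score columns
        images, _, _, grid = small_cohort
        proc = [eb.normalize_to_reference(im, grid) for im in images]
        X = np.stack([eb.flatten(im, grid) for im in proc])
        est = EigenbrainDecomposition(retain="all", column_center=True).fit(X)
        scores = est.scores_[:, :10]
        corr = np.corrcoef(scores, rowvar=False)
        assert np.allclose(corr - np.diag(np.diag(corr)), 0, atol=1e-8)

    def test_sign_convention_peak_positive(self, small_decomposition):
        _, _, dec, _, _ = small_decomposition
        peaks = np.argmax(np.abs(dec.eigenbrains), axis=1)
        assert np.all(dec.eigenbrains[np.arange(len(peaks)), peaks] > 0)

    def test_nonfinite_rejected(self):
        bad = np.ones((3, 4))
        bad[1, 2] = np.nan
        with pytest.raises(ValueError):
            eb.svd_decompose(_matrix_from(bad))


class TestPctCovariance:
    def test_squared_share(self):
        assert np.allclose(eb.pct_covariance([2.0, 1.0]), [80.0, 20.0])

    def test_equal_split_and_total(self):
        assert np.allclose(eb.pct_covariance([1.0, 1.0]), [50.0, 50.0])
        rng = np.random.default_rng(0)
        s = rng.uniform(0.1, 5.0, size=12)
        assert abs(eb.pct_covariance(np.sort(s)[::-1]).sum() - 100.0) < 1e-6

    def test_absolute_share_variant(self):
        assert np.allclose(eb.pct_covariance_abs([2.0, 1.0]), [200 / 3, 100 / 3])

    def test_zero_spectrum_errors(self):
        with pytest.raises(ValueError):
            eb.pct_covariance([0.0, 0.0])


class TestHorn:
    def test_percentile_monotonicity(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 200))
        X[:, :5] += 3 * rng.standard_normal((30, 1))
        k95 = eb.horn_parallel(X, n_null=50, percentile=95.0, seed=0).k_retained
        k99 = eb.horn_parallel(X, n_null=50, percentile=99.0, seed=0).k_retained
        assert k99 <= k95

    def test_planted_rank_recovered_small(self, small_decomposition):
        _, mat, _, truth, _ = small_decomposition
        res = eb.horn_parallel(mat, n_null=100, percentile=95.0, seed=2)
        assert res.k_retained == truth.planted_patterns.shape[0]

    def test_invalid_parameters(self):
        X = np.random.default_rng(0).standard_normal((25, 50))
        with pytest.raises(ValueError):
            eb.horn_parallel(X, n_null=5)
        with pytest.raises(ValueError):
            eb.horn_parallel(X, percentile=40.0)


class TestProjection:
    def test_training_image_reproduces_scores(self, small_decomposition):
        proc, mat, dec, _, grid = small_decomposition
        im = next(p for p in proc if p.subject_id == mat.subject_ids[3])
        s = eb.project(im, dec, grid)
        assert np.allclose(s, dec.scores[3], atol=1e-8)

    def test_planted_pattern_projects_to_matched_component(self, small_decomposition):
        _, _, dec, truth, grid = small_decomposition
        matches = eb.align_components(dec.eigenbrains[:3], truth.planted_patterns)
        est_for_truth = {j: (i, r) for i, j, r, _ in matches}
        pat = truth.planted_patterns[0]
        vals = 1.0 + grid.unflatten(5.0 * pat)
        im = eb.normalize_to_reference(SubjectImage("probe", vals), grid)
        s = eb.project(im, dec, grid)
        i, _ = est_for_truth[0]
        assert np.argmax(np.abs(s[:3])) == i

    def test_zero_signal_image_scores_small(self, small_decomposition):
        _, _, dec, _, grid = small_decomposition
        rng = np.random.default_rng(9)
        vals = 1.0 + 1e-4 * rng.standard_normal(grid.dims)
        im = eb.normalize_to_reference(SubjectImage("null", vals), grid)
        s = eb.project(im, dec, grid)
        score_sd = dec.scores[:, :3].std(axis=0)
        assert np.all(np.abs(s[:3]) < 0.1 * score_sd)


class TestAlignment:
    def test_identity_alignment(self, small_decomposition):
        _, _, dec, _, _ = small_decomposition
        matches = eb.align_components(dec.eigenbrains[:3], dec.eigenbrains[:3])
        assert all(i == j for i, j, _, _ in matches)
        assert all(abs(r - 1.0) < 1e-10 for _, _, r, _ in matches)

    def test_sign_flip_recorded(self, small_decomposition):
        _, _, dec, _, _ = small_decomposition
        matches = eb.align_components(dec.eigenbrains[:2], -dec.eigenbrains[:2])
        assert all(abs(r + 1.0) < 1e-10 for _, _, r, _ in matches)
        assert all(flip for _, _, _, flip in matches)

    def test_unrelated_truth_low_correlation(self, small_grid):
        rng = np.random.default_rng(4)
        est = rng.standard_normal((3, small_grid.n_voxels))
        tru = rng.standard_normal((3, small_grid.n_voxels))
        matches = eb.align_components(est, tru)
        assert np.mean([abs(r) for _, _, r, _ in matches]) < 0.2

    def test_empty_truth_errors(self, small_decomposition):
        _, _, dec, _, _ = small_decomposition
        with pytest.raises(ValueError):
            eb.align_components(dec.eigenbrains[:2], np.empty((0, dec.eigenbrains.shape[1])))


class TestGlobalScaleInvariance:
    def test_scores_unchanged_by_global_scale(self, small_cohort):
        images, _, _, grid = small_cohort
        proc = [eb.normalize_to_reference(im, grid) for im in images[:8]]
        mat = eb.build_matrix(proc, grid)
        dec = eb.svd_decompose(mat)
        rng = np.random.default_rng(1)
        scaled = [
            SubjectImage(im.subject_id, rng.uniform(0.5, 2.0) * im.values)
            for im in images[:8]
        ]
        proc2 = [eb.normalize_to_reference(im, grid) for im in scaled]
        mat2 = eb.build_matrix(proc2, grid)
        assert np.allclose(mat.values, mat2.values, atol=1e-8)
        for i, sid in enumerate(mat.subject_ids):
            im = next(p for p in proc2 if p.subject_id == sid)
            assert np.allclose(eb.project(im, dec, grid), dec.scores[i], atol=1e-8)


class TestEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = EigenbrainDecomposition(retain=2, row_scale=False)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()

    def test_fit_transform_matches_scores(self, small_cohort):
        images, _, truth, grid = small_cohort
        proc = [eb.normalize_to_reference(im, grid) for im in images]
        X = np.stack([eb.flatten(im, grid) for im in proc])
        est = EigenbrainDecomposition(retain="horn", n_null=60, random_state=0)
        scores = est.fit_transform(X)
        assert est.n_components_ == truth.planted_patterns.shape[0]
        assert np.allclose(scores, est.transform(X), atol=1e-8)

    def test_column_center_flag(self, small_cohort):
        images, _, _, grid = small_cohort
        proc = [eb.normalize_to_reference(im, grid) for im in images[:10]]
        X = np.stack([eb.flatten(im, grid) for im in proc])
        est = EigenbrainDecomposition(retain=3, column_center=True).fit(X)
        # centring removes the voxel-wise mean, so transformed training data
        # has (near) zero column means after the internal preparation
        assert est.column_mean_.shape == (grid.n_voxels,)
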