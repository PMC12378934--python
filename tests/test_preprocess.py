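import numpy as np
import pytest

from scin.data import ValidationError
from scin.preprocess import (PreprocessConfig, PreprocessPipeline, apply,
                             fit_pca, fit_scale, log1p_transform,
                             normalize_total)

from conftest import make_table
from oracles import pca_axes_eig


class TestNormalizeTotal:
    def test_rows_rescaled_proportionally(self):
        t = make_table([[1, 1, 2]])
        out = normalize_total(t, target_sum=1e4)
        assert np.allclose(out.dense(), [[2500, 2500, 5000]])

    def test_all_zero_row_stays_zero(self):
        t = make_table([[0, 0, 0], [1, 1, 0]])
        out = normalize_total(t, 100)
        assert np.allclose(out.dense()[0], 0)
        assert np.allclose(out.dense()[1].sum(), 100)

    def test_row_sums_hit_target(self, rng):
        t = make_table(rng.poisson(5, size=(20, 30)).astype(float))
        out = normalize_total(t, 1e4)
        sums = out.dense().sum(axis=1)
        assert np.allclose(sums, 1e4, rtol=1e-6)

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            normalize_total(make_table([[1, -1]]), 100)


class TestLog1p:
    def test_closed_form_values(self):
        t = make_table([[0.0, np.e - 1.0]])
        out = log1p_transform(t)
        assert np.allclose(out.dense(), [[0.0, 1.0]])

    def test_monotone(self, rng):
        x = np.sort(rng.uniform(0, 50, size=20))
        out = log1p_transform(make_table(x[None, :])).dense().ravel()
        assert np.all(np.diff(out) > 0)

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            log1p_transform(make_table([[-0.5]]))


class TestScale:
    def test_population_standardization_values(self):
        # column [1,2,3]: mean 2, population sd sqrt(2/3)
        t = make_table([[1.0], [2.0], [3.0]])
        tf = fit_scale(t)
        out = tf.apply(t).dense().ravel()
        assert np.allclose(out, [-1.22474487, 0.0, 1.22474487])

    def test_constant_column_centered_without_nan(self):
        t = make_table([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        out = fit_scale(t).apply(t).dense()
        assert np.all(np.isfinite(out))
        assert np.allclose(out[:, 0], 0.0)

    def test_training_matrix_mean_zero_unit_variance(self, rng):
        t = make_table(rng.normal(3, 2, size=(50, 10)))
        out = fit_scale(t).apply(t).dense()
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(out.var(axis=0), 1.0, atol=1e-6)

    def test_single_cell_cannot_fit(self):
        with pytest.raises(ValidationError):
            fit_scale(make_table([[1.0, 2.0]]))

    def test_apply_uses_frozen_training_statistics(self, rng):
        train = make_table(rng.normal(0, 1, size=(30, 4)))
        shifted = make_table(rng.normal(10, 1, size=(30, 4)))
        tf = fit_scale(train)
        out = tf.apply(shifted).dense()
        # shifted data is far from the training mean, so it must not re-center
        assert out.mean() > 5
        refit = fit_scale(shifted).apply(shifted).dense()
        assert abs(refit.mean()) < 1e-8


class TestPCA:
    def test_axes_match_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(5, 3)) @ np.diag([3.0, 1.0, 0.3])
        t = make_table(X)
        tf = fit_pca(t, 2)
        oracle_axes, _ = pca_axes_eig(X, 2)
        # compare subspaces via principal angles
        _, s, _ = np.linalg.svd(tf.components_ @ oracle_axes.T)
        assert np.allclose(s, 1.0, atol=1e-6)

    def test_components_orthonormal(self, rng):
        t = make_table(rng.normal(size=(20, 8)))
        tf = fit_pca(t, 5)
        gram = tf.components_ @ tf.components_.T
        assert np.allclose(gram, np.eye(5), atol=1e-8)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(10, 4))
        t = make_table(X)
        tf = fit_pca(t, 4)
        proj = tf.apply(t).dense()
        recon = proj @ tf.components_ + tf.mean_
        assert np.allclose(recon, X, atol=1e-6)

    def test_explained_variance_non_increasing(self, rng):
        t = make_table(rng.normal(size=(40, 12)))
        tf = fit_pca(t, 10)
        assert np.all(np.diff(tf.explained_variance_) <= 1e-12)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(15, 6))
        tf = fit_pca(make_table(X), 3)
        for row in tf.components_:
            assert row[np.argmax(np.abs(row))] > 0

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValidationError):
            fit_pca(make_table(rng.normal(size=(3, 5))), 4)

    def test_dimension_mismatch_on_apply(self, rng):
        tf = fit_pca(make_table(rng.normal(size=(10, 5))), 2)
        with pytest.raises(ValidationError):
            apply(tf, make_table(rng.normal(size=(4, 7))))


class TestPipeline:
    def test_chain_records_training_size(self, rng):
        train = make_table(rng.poisson(4, size=(25, 10)).astype(float))
        pipe = PreprocessPipeline(PreprocessConfig(n_pcs=5))
        pipe.fit(train)
        assert pipe.fitted_on == 25
        assert pipe.scale_.fitted_on == 25
        assert pipe.pca_.fitted_on == 25

    def test_transform_single_held_out_cell(self, rng):
        train = make_table(rng.poisson(4, size=(25, 10)).astype(float))
        pipe = PreprocessPipeline(PreprocessConfig(n_pcs=5)).fit(train)
        one = make_table(rng.poisson(4, size=(1, 10)).astype(float))
        out = pipe.transform(one)
        assert out.dense().shape == (1, 5)

    def test_count_steps_skippable(self, rng):
        # continuous (already-normalized) inputs skip normalize/log1p
        train = make_table(rng.normal(size=(20, 6)))
        pipe = PreprocessPipeline(
            PreprocessConfig(normalize=False, log1p=False, n_pcs=3))
        out = pipe.fit_transform(train)
        assert out.dense().shape == (20, 3)

    def test_train_only_statistics_differ_from_pooled(self, rng):
        train = make_table(rng.normal(0, 1, size=(40, 6)))
        test = make_table(rng.normal(4, 1, size=(40, 6)), prefix="t")
        pipe = PreprocessPipeline(
            PreprocessConfig(normalize=False, log1p=False, n_pcs=0))
        pipe.fit(train)
        pooled = make_table(
            np.vstack([train.dense(), test.dense()]), prefix="p")
        pooled_tf = fit_scale(pooled)
        assert not np.allclose(pipe.scale_.mean_, pooled_tf.mean_)
        # the pipeline must carry the train-only statistics
        assert np.allclose(
            pipe.scale_.mean_, train.dense().mean(axis=0))
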