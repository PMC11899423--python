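import numpy as np
import pytest
from scipy.linalg import subspace_angles

from nirclda import clda
from nirclda.clda import (CommonVectorsLDA, between_class_scatter,
                          common_vector, scatter_basis, total_scatter,
                          within_class_scatter)
from nirclda.dataset import SpectralDataset, stratified_split
from nirclda.exceptions import (DegenerateDataError, ParameterError,
                                RegimeError, SchemaError)
from nirclda.synthetic import SyntheticSpec, generate

from conftest import random_small_instance


class TestScatterUtilities:
    def test_within_matches_definition(self):
        rng = np.random.default_rng(0)
        X, y = random_small_instance(rng, d=8, M=12, C=3)
        Sw = within_class_scatter(X, y)
        brute = np.zeros((8, 8))
        for c in np.unique(y):
            mu = X[y == c].mean(axis=0)
            for row in X[y == c]:
                brute += np.outer(row - mu, row - mu)
        np.testing.assert_allclose(Sw, brute, atol=1e-10)

    def test_total_is_within_plus_between(self):
        rng = np.random.default_rng(1)
        X, y = random_small_instance(rng, d=10, M=12, C=3)
        St = total_scatter(X, y)
        np.testing.assert_allclose(
            St, within_class_scatter(X, y) + between_class_scatter(X, y),
            atol=1e-10)


class TestScatterBasis:
    def test_toy_range_space(self, toy_two_class):
        basis = scatter_basis(toy_two_class)
        assert basis.rank == 1
        # range(S_W) is the y-axis
        np.testing.assert_allclose(np.abs(basis.Q.ravel()), [0, 1, 0],
                                   atol=1e-12)

    def test_singleton_classes_give_empty_basis(self):
        ds = SpectralDataset(np.eye(3), axis=[1.0, 2.0, 3.0],
                             labels=["a", "b", "c"])
        basis = scatter_basis(ds)
        assert basis.rank == 0 and basis.Q.shape == (3, 0)

    def test_orthonormal_and_rank_bounded(self, default_dataset):
        train = stratified_split(default_dataset, (2, 1), 0).train
        basis = scatter_basis(train)
        QtQ = basis.Q.T @ basis.Q
        np.testing.assert_allclose(QtQ, np.eye(basis.rank), atol=1e-10)
        assert basis.rank <= train.n_samples - train.n_classes

    def test_gram_trick_matches_direct_eigendecomposition(self):
        """Principal angles between span(Q) from the Gram matrix and the
        non-null eigenvectors of the directly formed S_W are ~0."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            X, y = random_small_instance(rng)
            ds = SpectralDataset(X, axis=np.arange(X.shape[1], dtype=float),
                                 labels=y)
            basis = scatter_basis(ds)
            Sw = within_class_scatter(X, y)
            evals, evecs = np.linalg.eigh(Sw)
            keep = evals > evals[-1] * X.shape[0] * np.finfo(float).eps
            direct = evecs[:, keep]
            assert direct.shape[1] == basis.rank
            angles = subspace_angles(basis.Q, direct)
            assert np.max(angles, initial=0.0) < 1e-8

    def test_regime_guard(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))  # d=5 <= M-C=27
        ds = SpectralDataset(X, axis=np.arange(5.0),
                             labels=np.repeat(["a", "b", "c"], 10))
        with pytest.raises(RegimeError):
            scatter_basis(ds)


class TestCommonVector:
    def test_toy_class_samples_share_common_vector(self, toy_two_class):
        basis = scatter_basis(toy_two_class)
        v1 = common_vector(toy_two_class.X[0], basis)
        v2 = common_vector(toy_two_class.X[1], basis)
        np.testing.assert_allclose(v1, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(v2, [1, 0, 0], atol=1e-12)

    def test_empty_basis_returns_input(self):
        from nirclda.clda import ScatterBasis
        basis = ScatterBasis(Q=np.zeros((4, 0)), rank=0,
                             eigenvalues=np.zeros(0))
        x = np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_array_equal(common_vector(x, basis), x)

    def test_vector_in_range_space_maps_to_zero(self, toy_two_class):
        basis = scatter_basis(toy_two_class)
        np.testing.assert_allclose(
            common_vector(np.array([0.0, 5.0, 0.0]), basis), 0.0, atol=1e-12)

    def test_orthogonality_to_basis(self, default_dataset):
        train = stratified_split(default_dataset, (2, 1), 0).train
        basis = scatter_basis(train)
        v = common_vector(train.X[17], basis)
        assert np.max(np.abs(basis.Q.T @ v)) < 1e-10

    def test_dimension_mismatch(self, toy_two_class):
        basis = scatter_basis(toy_two_class)
        with pytest.raises(SchemaError):
            common_vector(np.zeros(5), basis)


class TestFit:
    def test_toy_hand_computation(self, toy_two_class):
        model = clda.fit(toy_two_class)
        np.testing.assert_allclose(
            model.scalings_.ravel(),
            np.array([1.0, 0.0, -1.0]) / np.sqrt(2), atol=1e-10)
        np.testing.assert_allclose(model.omegas_.ravel(),
                                   [+0.70710678, -0.70710678], atol=1e-6)

    def test_four_class_projection_is_three_dimensional(self, default_dataset):
        train = stratified_split(default_dataset, (2, 1), 0).train
        model = clda.fit(train)
        assert model.scalings_.shape == (228, 3)

    def test_exact_projection_identity(self, default_dataset):
        """Every training sample projects exactly onto its class template."""
        train = stratified_split(default_dataset, (2, 1), 0).train
        model = clda.fit(train)
        Z = model.transform(train.X)
        for i, c in enumerate(model.classes_):
            block = Z[train.y == c]
            assert np.max(np.abs(block - model.omegas_[i])) < 1e-8

    def test_discriminants_lie_in_null_space(self, default_dataset):
        train = stratified_split(default_dataset, (2, 1), 0).train
        model = clda.fit(train)
        assert np.max(np.abs(model.scalings_.T @ model.basis_.Q)) < 1e-8

    def test_orthonormal_scalings(self, default_dataset):
        train = stratified_split(default_dataset, (2, 1), 0).train
        model = clda.fit(train)
        WtW = model.scalings_.T @ model.scalings_
        assert np.max(np.abs(WtW - np.eye(3))) < 1e-10

    def test_representative_choice_is_irrelevant(self, default_dataset):
        """Common vectors are identical for every within-class sample."""
        train = stratified_split(default_dataset, (2, 1), 0).train
        basis = scatter_basis(train)
        for c in train.classes:
            block = train.X[train.y == c]
            coms = block - (block @ basis.Q) @ basis.Q.T
            assert np.max(np.ptp(coms, axis=0)) < 1e-8

    def test_training_set_separability(self, default_dataset):
        train = stratified_split(default_dataset, (2, 1), 0).train
        model = clda.fit(train)
        assert np.all(model.predict(train.X) == train.y)

    def test_single_class_rejected(self):
        ds = SpectralDataset(np.random.default_rng(0).normal(size=(4, 9)),
                             axis=np.arange(9.0), labels=["a"] * 4)
        with pytest.raises(ParameterError):
            clda.fit(ds)

    def test_coinciding_common_vectors_detected(self):
        # classes differing only inside range(S_W): identical common vectors
        X = np.array([
            [0.0, 0.0, 0.0], [0.0, 1.0, 0.0],
            [0.0, 5.0, 0.0], [0.0, 6.0, 0.0],
        ])
        ds = SpectralDataset(X, axis=[1.0, 2.0, 3.0],
                             labels=["a", "a", "b", "b"])
        with pytest.raises(DegenerateDataError, match="coinciding"):
            clda.fit(ds)


class TestProjectAndClassify:
    def test_toy_test_sample(self, toy_two_class):
        model = clda.fit(toy_two_class)
        ds = SpectralDataset(np.array([[1.0, 5.0, 0.0]]),
                             axis=[1.0, 2.0, 3.0], labels=["a"])
        proj = clda.project(model, ds)
        np.testing.assert_allclose(proj, [[0.70710678]], atol=1e-6)
        assert clda.classify_nearest_common_vector(model, ds)[0] == "a"

    def test_zero_vector_projects_to_origin(self, toy_two_class):
        model = clda.fit(toy_two_class)
        np.testing.assert_array_equal(model.transform(np.zeros((1, 3))), 0.0)

    def test_equidistant_tie_takes_lowest_class(self, toy_two_class):
        model = clda.fit(toy_two_class)
        # projection 0 is equidistant from +-0.7071
        mid = SpectralDataset(np.array([[0.5, 0.0, 0.5]]),
                              axis=[1.0, 2.0, 3.0], labels=["a"])
        assert model.predict(mid.X)[0] == "a"

    def test_shape_mismatch(self, toy_two_class):
        model = clda.fit(toy_two_class)
        with pytest.raises(SchemaError):
            model.transform(np.zeros((1, 7)))
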