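"""SVD subspace, generalized eigendecomposition, and the contrast-optimized rotation."""

import numpy as np
import pytest

from contrastnav.basis import (
    AutocorrelationPair,
    autocorrelation,
    build_contrast_basis,
    compute_svd_basis,
    generalized_eigendecomposition,
    gram_schmidt,
    project,
    rayleigh_quotient,
    rotate_basis,
)
from contrastnav.fingerprints import (
    CSF,
    PARENCHYMA,
    FingerprintDictionary,
    TissueParams,
    build_dictionary,
    default_tissue_grid,
)


class TestSvdBasis:
    def test_single_column_normalized(self, rng):
        v = rng.standard_normal(40) + 1j * rng.standard_normal(40)
        basis = compute_svd_basis(v[:, None], rank=1)
        u = basis.U[:, 0]
        # up to global phase
        assert abs(abs(np.vdot(u, v / np.linalg.norm(v))) - 1) < 1e-12

    def test_orthogonal_columns_sorted_by_norm(self):
        S = np.zeros((6, 3))
        S[0, 0], S[1, 1], S[2, 2] = 1.0, 3.0, 2.0
        U = compute_svd_basis(S, rank=3).U
        # expect e1 order: col of norm 3, then 2, then 1
        assert abs(U[1, 0]) > 0.99
        assert abs(U[2, 1]) > 0.99
        assert abs(U[0, 2]) > 0.99

    def test_eckart_young_reconstruction_error(self, rng):
        S = rng.standard_normal((100, 20))
        U = compute_svd_basis(S, rank=3).U
        err = np.linalg.norm(S - U @ (U.conj().T @ S)) ** 2
        sv = np.linalg.svd(S, compute_uv=False)
        assert np.isclose(err, np.sum(sv[3:] ** 2), rtol=1e-10)

    def test_rank_exceeding_dimensions_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_svd_basis(rng.standard_normal((10, 4)), rank=5)


class TestProject:
    def test_basis_column_gives_unit_vector(self, dictionary):
        basis = compute_svd_basis(dictionary, rank=3)
        c = project(basis.U[:, 1], basis)
        assert np.allclose(c.ravel(), [0, 1, 0], atol=1e-12)

    def test_orthogonal_signal_gives_zero(self, rng):
        basis = compute_svd_basis(np.eye(10)[:, :4], rank=2)
        s = np.zeros(10)
        s[7] = 1.0
        assert np.allclose(project(s, basis), 0.0, atol=1e-12)

    def test_bessel_inequality(self, dictionary, rng):
        basis = compute_svd_basis(dictionary, rank=3)
        for _ in range(20):
            s = rng.standard_normal(basis.n_time)
            c = project(s, basis)
            assert np.linalg.norm(c) <= np.linalg.norm(s) + 1e-12


class TestAutocorrelation:
    def test_single_vector_outer_product(self, rng):
        c = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        C = autocorrelation(c)
        assert np.allclose(C, np.outer(c, c.conj()), atol=1e-14)

    def test_identity_columns(self):
        C = autocorrelation(np.eye(3))
        assert np.allclose(C, np.eye(3) / 3)

    def test_always_psd(self, rng):
        C = autocorrelation(rng.standard_normal((3, 50)) + 1j * rng.standard_normal((3, 50)))
        assert np.linalg.eigvalsh(C).min() >= -1e-12


class TestGeneralizedEig:
    def test_equal_matrices_give_unit_eigenvalues(self, rng):
        A = rng.standard_normal((3, 3))
        spd = A @ A.T + 3 * np.eye(3)
        res = generalized_eigendecomposition(AutocorrelationPair(spd, spd))
        assert np.allclose(res.eigenvalues, 1.0, atol=1e-10)

    def test_identity_cf_reduces_to_ordinary_eig(self):
        pair = AutocorrelationPair(np.diag([4.0, 2.0, 1.0]), np.eye(3))
        res = generalized_eigendecomposition(pair)
        assert np.allclose(res.eigenvalues, [4, 2, 1])
        assert np.allclose(np.abs(res.eigenvectors), np.eye(3), atol=1e-12)

    def test_diagonal_ratio(self):
        pair = AutocorrelationPair(np.diag([2.0, 1.0]), np.diag([1.0, 2.0]))
        res = generalized_eigendecomposition(pair)
        assert np.allclose(res.eigenvalues, [2.0, 0.5])
        assert abs(res.eigenvectors[0, 0]) > 0.99
        assert abs(res.eigenvectors[1, 1]) > 0.99

    def test_residual_and_rayleigh_maximality(self, rng):
        A = rng.standard_normal((3, 3))
        B = rng.standard_normal((3, 3))
        Cb = A @ A.T + 0.1 * np.eye(3)
        Cf = B @ B.T + 0.5 * np.eye(3)
        pair = AutocorrelationPair(Cb, Cf)
        res = generalized_eigendecomposition(pair)
        for lam, w in zip(res.eigenvalues, res.eigenvectors.T):
            assert np.linalg.norm(Cb @ w - lam * Cf @ w) <= 1e-10 * np.linalg.norm(Cb)
        # lambda_1 dominates the generalized Rayleigh quotient over random directions
        V = rng.standard_normal((3, 2000))
        V /= np.linalg.norm(V, axis=0)
        quotients = np.einsum("in,ij,jn->n", V, Cb, V) / np.einsum("in,ij,jn->n", V, Cf, V)
        assert res.eigenvalues[0] >= quotients.max() - 1e-9

    def test_singular_cf_raises_with_advice(self):
        pair = AutocorrelationPair(np.eye(3), np.diag([1.0, 1.0, 0.0]))
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            generalized_eigendecomposition(pair)


class TestGramSchmidt:
    def test_textbook_case(self):
        U = np.array([[1.0, 1.0], [0.0, 1.0], [0.0, 0.0]])
        Q = gram_schmidt(U)
        assert np.allclose(Q, np.eye(3)[:, :2], atol=1e-14)

    def test_idempotent_on_orthonormal_input(self, rng):
        Q0, _ = np.linalg.qr(rng.standard_normal((20, 3)))
        assert np.allclose(gram_schmidt(Q0), Q0, atol=1e-12)

    def test_matches_qr_span_and_keeps_first_column(self, rng):
        U = rng.standard_normal((30, 3)) + 1j * rng.standard_normal((30, 3))
        Q = gram_schmidt(U)
        assert np.allclose(Q.conj().T @ Q, np.eye(3), atol=1e-12)
        # first column direction preserved
        u1 = U[:, 0] / np.linalg.norm(U[:, 0])
        assert abs(abs(np.vdot(Q[:, 0], u1)) - 1) < 1e-12
        # span equals the QR span
        Qr, _ = np.linalg.qr(U)
        P = Qr @ Qr.conj().T
        assert np.linalg.norm(Q - P @ Q) < 1e-10

    def test_rank_deficient_rejected(self):
        U = np.ones((5, 2))
        with pytest.raises(np.linalg.LinAlgError):
            gram_schmidt(U)


class TestRotateBasis:
    def test_identity_and_permutation(self, dictionary):
        svd = compute_svd_basis(dictionary, rank=3)
        from contrastnav.basis import GeneralizedEigenResult

        ident = GeneralizedEigenResult(np.ones(3), np.eye(3))
        assert np.allclose(rotate_basis(svd, ident), svd.U)
        perm = np.eye(3)[:, [2, 0, 1]]
        rotated = rotate_basis(svd, GeneralizedEigenResult(np.ones(3), perm))
        assert np.allclose(rotated, svd.U[:, [2, 0, 1]])

    def test_span_preserved_under_random_rotation(self, dictionary, rng):
        svd = compute_svd_basis(dictionary, rank=3)
        from contrastnav.basis import GeneralizedEigenResult

        W = rng.standard_normal((3, 3))
        W /= np.linalg.norm(W, axis=0)
        rotated = rotate_basis(svd, GeneralizedEigenResult(np.ones(3), W))
        P = svd.U @ svd.U.conj().T
        assert np.linalg.norm(rotated - P @ rotated) < 1e-10


class TestContrastBasis:
    def test_orthonormal_and_span_preserved(self, dictionary):
        opt = build_contrast_basis(dictionary, rank=3)
        svd = compute_svd_basis(dictionary, rank=3)
        assert np.allclose(opt.U.conj().T @ opt.U, np.eye(3), atol=1e-12)
        P = svd.U @ svd.U.conj().T
        assert np.linalg.norm(opt.U - P @ opt.U) < 1e-10
        P2 = opt.U @ opt.U.conj().T
        assert np.linalg.norm(svd.U - P2 @ svd.U) < 1e-10

    def test_identical_classes_degenerate_to_unit_eigenvalues(self, short_schedules):
        # same physical atoms labelled as both classes
        grid = [
            TissueParams(1.0, 0.08, label=PARENCHYMA),
            TissueParams(1.3, 0.1, label=PARENCHYMA),
            TissueParams(2.0, 0.3, label=PARENCHYMA),
            TissueParams(1.0, 0.08, label=CSF),
            TissueParams(1.3, 0.1, label=CSF),
            TissueParams(2.0, 0.3, label=CSF),
        ]
        d = build_dictionary(grid, short_schedules[0])
        opt = build_contrast_basis(d, rank=3)
        assert np.allclose(opt.eigenvalues, 1.0, atol=1e-8)

    def test_first_coefficient_beats_every_svd_axis(self, dictionary):
        """The optimized first direction dominates the parenchyma/CSF quotient."""
        svd = compute_svd_basis(dictionary, rank=3)
        cb = project(dictionary.subset(PARENCHYMA), svd)
        cf = project(dictionary.subset(CSF), svd)
        pair = AutocorrelationPair(autocorrelation(cb), autocorrelation(cf))
        opt = build_contrast_basis(dictionary, rank=3)
        w1 = svd.U.conj().T @ opt.U[:, 0]
        q_opt = rayleigh_quotient(w1, pair)
        for axis in np.eye(3):
            assert q_opt >= rayleigh_quotient(axis, pair)

    def test_missing_label_class_rejected(self, short_schedules):
        grid = [TissueParams(1.0, 0.08, label=PARENCHYMA)]
        d = build_dictionary(grid, short_schedules[0])
        with pytest.raises(ValueError):
            build_contrast_basis(d)

    def test_monte_carlo_maximality_in_subspace(self, dictionary, rng):
        svd = compute_svd_basis(dictionary, rank=3)
        cb = project(dictionary.subset(PARENCHYMA), svd)
        cf = project(dictionary.subset(CSF), svd)
        pair = AutocorrelationPair(autocorrelation(cb), autocorrelation(cf))
        opt = build_contrast_basis(dictionary, rank=3)
        w1 = svd.U.conj().T @ opt.U[:, 0]
        q_opt = rayleigh_quotient(w1, pair)
        V = rng.standard_normal((3, 10000))
        V /= np.linalg.norm(V, axis=0)
        quotients = np.einsum("in,ij,jn->n", V, pair.Cb, V) / np.einsum(
            "in,ij,jn->n", V, pair.Cf, V
        )
        assert q_opt >= quotients.max() - 1e-9 * abs(q_opt)
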