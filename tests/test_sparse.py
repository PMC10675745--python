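"""OMP sparse coding, KSVD dictionary learning, max-abs pooling.

scikit-learn's orthogonal_mp serves as an independent cross-check of the
OMP implementation on random instances; recovery oracles plant known
supports/dictionaries and verify they are found.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import orthogonal_mp

from ecgid import (
    FeatureVector,
    SparseCode,
    SparseDictionary,
    encode_matrix,
    ksvd_train,
    max_pool,
    omp,
)
from ecgid.segment import SegmentMatrix


def random_dictionary(d, K, seed):
    rng = np.random.default_rng(seed)
    D = rng.standard_normal((d, K))
    return D / np.linalg.norm(D, axis=0)


class TestOmp:
    def test_orthonormal_dictionary_selects_top_coordinates(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((16, 16)))
        x = rng.standard_normal(16)
        alpha = omp(Q, x, T0=2, tol=0.0)
        proj = Q.T @ x
        expected = np.argsort(np.abs(proj))[-2:]
        assert set(np.flatnonzero(alpha)) == set(expected)
        assert np.allclose(alpha[expected], proj[expected])

    def test_single_atom_signal(self):
        D = random_dictionary(20, 50, seed=2)
        alpha = omp(D, 0.5 * D[:, 7], T0=3, tol=1e-10)
        assert np.flatnonzero(alpha).tolist() == [7]
        assert np.isclose(alpha[7], 0.5)
        assert np.linalg.norm(D @ alpha - 0.5 * D[:, 7]) < 1e-10

    def test_planted_support_recovery(self):
        D = random_dictionary(20, 50, seed=1)
        hits = 0
        for t in range(30):
            r = np.random.default_rng(300 + t)
            sup = r.choice(50, 3, replace=False)
            x = D[:, sup] @ r.standard_normal(3)
            alpha = omp(D, x, T0=3, tol=1e-10)
            if set(np.flatnonzero(alpha)) == set(sup) and np.linalg.norm(D @ alpha - x) < 1e-6:
                hits += 1
        assert hits >= 28

    def test_matches_sklearn_on_random_instances(self):
        D = random_dictionary(30, 60, seed=4)
        r = np.random.default_rng(11)
        for _ in range(10):
            x = r.standard_normal(30)
            mine = omp(D, x, T0=5, tol=0.0)
            ref = orthogonal_mp(D, x, n_nonzero_coefs=5)
            assert set(np.flatnonzero(mine)) == set(np.flatnonzero(ref))
            assert np.allclose(mine, ref, atol=1e-8)

    def test_residual_decreases_with_sparsity_budget(self, rng):
        D = random_dictionary(25, 80, seed=6)
        x = rng.standard_normal(25)
        residuals = [
            np.linalg.norm(x - D @ omp(D, x, T0=t, tol=0.0)) for t in (1, 3, 5, 10, 25)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(residuals, residuals[1:]))
        assert residuals[-1] < 1e-9  # T0 = d: exact representation

    def test_sparsity_bound_and_domain_errors(self, rng):
        D = random_dictionary(10, 30, seed=7)
        with pytest.raises(ValueError):
            omp(D, rng.standard_normal(10), T0=11)
        with pytest.raises(ValueError):
            omp(D, np.zeros(10), T0=2)
        alpha = omp(D, rng.standard_normal(10), T0=4, tol=0.0)
        assert np.count_nonzero(alpha) <= 4


class TestKsvd:
    def test_objective_monotone_and_atoms_unit_norm(self, rng):
        Y = rng.standard_normal((16, 200))
        Y /= np.linalg.norm(Y, axis=0)
        D, code = ksvd_train(Y, K=24, T0=3, iters=15, tol=1e-12, seed=0)
        tr = D.training_meta["objective_trace"]
        assert all(b <= a + 1e-12 for a, b in zip(tr, tr[1:]))
        assert tr[-1] <= tr[0]
        assert np.allclose(np.linalg.norm(D.atoms, axis=0), 1.0, atol=1e-9)

    def test_planted_dictionary_recovery(self):
        planted = random_dictionary(20, 40, seed=8)
        N = 1000
        Y = np.zeros((20, N))
        r = np.random.default_rng(9)
        for i in range(N):
            sup = r.choice(40, 3, replace=False)
            Y[:, i] = planted[:, sup] @ r.standard_normal(3)
        Y /= np.linalg.norm(Y, axis=0)
        learned, _ = ksvd_train(Y, K=40, T0=3, iters=60, tol=1e-12, seed=10)
        C = np.abs(learned.atoms.T @ planted)
        matched = 0
        for _ in range(40):
            i, j = np.unravel_index(np.argmax(C), C.shape)
            if C[i, j] > 0.99:
                matched += 1
            C[i, :] = -1.0
            C[:, j] = -1.0
        assert matched >= 32  # 80% of 40 atoms

    def test_code_sparsity_bound(self, rng):
        Y = rng.standard_normal((12, 80))
        Y /= np.linalg.norm(Y, axis=0)
        _, code = ksvd_train(Y, K=20, T0=4, iters=5, tol=1e-12, seed=1)
        assert all(s.size <= 4 for s in code.supports)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            ksvd_train(np.empty((10, 0)), K=5, T0=2)

    def test_max_coherence_below_duplicate_bound(self, rng):
        Y = rng.standard_normal((16, 300))
        Y /= np.linalg.norm(Y, axis=0)
        D, _ = ksvd_train(Y, K=32, T0=3, iters=10, tol=1e-12, seed=2)
        assert D.max_coherence() < 1.0 - 1e-6


class TestEncode:
    def _dict(self):
        return SparseDictionary(random_dictionary(40, 90, seed=12))

    def _segmat(self, D=40, n=3, seed=13):
        rng = np.random.default_rng(seed)
        cols = rng.standard_normal((D, n))
        cols /= np.linalg.norm(cols, axis=0)
        return SegmentMatrix(cols)

    def test_shape_and_sparsity(self):
        code = encode_matrix(self._dict(), self._segmat(), T0=10)
        assert code.coeffs.shape == (90, 3)
        assert all(np.count_nonzero(code.coeffs[:, j]) <= 10 for j in range(3))

    def test_single_atom_column_codes_to_one_nonzero(self):
        D = self._dict()
        code = encode_matrix(D, D.atoms[:, [5]], T0=10)
        assert np.count_nonzero(code.coeffs) == 1
        assert np.isclose(code.coeffs[5, 0], 1.0)

    def test_deterministic(self):
        a = encode_matrix(self._dict(), self._segmat(), T0=6).coeffs
        b = encode_matrix(self._dict(), self._segmat(), T0=6).coeffs
        assert np.array_equal(a, b)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            encode_matrix(self._dict(), self._segmat(D=30), T0=5)


class TestMaxPool:
    def test_worked_example(self):
        coeffs = np.array([[0.2, -0.7, 0.1], [0.0, 0.0, 0.0], [-1.5, 0.3, 0.9]])
        code = SparseCode(coeffs=coeffs, residuals=np.zeros(3))
        assert np.allclose(max_pool(code).beta, [0.7, 0.0, 1.5])

    def test_single_column_is_absolute_value(self, rng):
        col = rng.standard_normal((8, 1))
        code = SparseCode(coeffs=col, residuals=np.zeros(1))
        assert np.allclose(max_pool(code).beta, np.abs(col[:, 0]))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_column_order_and_sign_flips(self, seed):
        rng = np.random.default_rng(seed)
        coeffs = rng.standard_normal((6, 4))
        base = max_pool(SparseCode(coeffs, np.zeros(4))).beta
        perm = rng.permutation(4)
        signs = rng.choice([-1.0, 1.0], size=(6, 4))
        other = max_pool(SparseCode(coeffs[:, perm] * signs, np.zeros(4))).beta
        assert np.allclose(base, other)

    def test_empty_code_rejected(self):
        with pytest.raises(ValueError):
            max_pool(SparseCode(np.empty((5, 0)), np.empty(0)))

    def test_nonnegativity_enforced(self):
        with pytest.raises(ValueError):
            FeatureVector(beta=np.array([-0.1, 0.2]))
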