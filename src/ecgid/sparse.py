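"""Orthogonal matching pursuit, KSVD dictionary learning and max-abs
pooling.

OMP greedily selects the atom most correlated with the residual and
re-solves the least-squares fit on the selected support each step. KSVD
alternates (i) OMP coding of all training columns with (ii) per-atom
rank-1 SVD updates of the restricted residual; unused atoms are replaced
by the currently worst-represented training column. The identity
signature of a segment group is the per-coordinate maximum absolute
coefficient across its sparse codes (max-abs pooling), a nonnegative
K-vector.

The implementation works in the Gram domain (precomputed ``D^T D`` and
``D^T Y``), so the inner OMP loop touches only K-length vectors and tiny
linear systems regardless of the segment length d.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

DUPLICATE_COHERENCE = 1.0 - 1e-6


@dataclass
class SparseDictionary:
    """Overcomplete d x K matrix of unit-norm atoms."""

    atoms: np.ndarray  # (d, K)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 2:
            raise ValueError("atoms must be a d x K matrix")
        norms = np.linalg.norm(self.atoms, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("every atom must have unit L2 norm")
        if self.K <= self.d:
            warnings.warn(
                f"dictionary is not overcomplete (K={self.K} <= d={self.d})",
                stacklevel=2,
            )

    @property
    def d(self) -> int:
        return self.atoms.shape[0]

    @property
    def K(self) -> int:
        return self.atoms.shape[1]

    def max_coherence(self) -> float:
        """Largest pairwise |<d_i, d_j>| between distinct atoms."""
        g = self.atoms.T @ self.atoms
        np.fill_diagonal(g, 0.0)
        return float(np.abs(g).max()) if self.K > 1 else 0.0

    def save(self, path: str | Path) -> None:
        payload = {
            "d": self.d,
            "K": self.K,
            "training_meta": _jsonable(self.training_meta),
            "atoms": self.atoms.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SparseDictionary":
        payload = json.loads(Path(path).read_text())
        return cls(
            atoms=np.asarray(payload["atoms"], dtype=float),
            training_meta=payload.get("training_meta", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class SparseCode:
    """K x n coefficient matrix with per-column support and residual."""

    coeffs: np.ndarray  # (K, n)
    residuals: np.ndarray  # (n,) final residual L2 norms

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)

    @property
    def supports(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.coeffs[:, j]) for j in range(self.coeffs.shape[1])]

    @property
    def n(self) -> int:
        return self.coeffs.shape[1]


@dataclass
class FeatureVector:
    """Nonnegative length-K identity signature from max-abs pooling."""

    beta: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any(self.beta < 0):
            raise ValueError("pooled features must be nonnegative")


# ---------------------------------------------------------------------------
# OMP


def _omp_column(
    G: np.ndarray, dtx: np.ndarray, norm_x2: float, T0: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gram-domain OMP for one signal.

    Returns (support indices, coefficients on support, residual norm).
    """
    K = G.shape[0]
    support: list[int] = []
    coef = np.empty(0)
    corr = dtx.copy()
    resid2 = norm_x2
    while len(support) < T0 and resid2 > tol * tol:
        masked = np.abs(corr)
        if support:
            masked[support] = -1.0
        k = int(np.argmax(masked))
        if masked[k] < 1e-13:
            break  # residual orthogonal to every remaining atom
        support.append(k)
        Gs = G[np.ix_(support, support)]
        try:
            coef = np.linalg.solve(Gs, dtx[support])
        except np.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(Gs, dtx[support], rcond=None)
        corr = dtx - G[:, support] @ coef
        resid2 = max(norm_x2 - float(dtx[support] @ coef), 0.0)
    return np.asarray(support, dtype=int), coef, float(np.sqrt(resid2))


def omp(
    D: SparseDictionary | np.ndarray,
    x: np.ndarray,
    T0: int = 10,
    tol: float = 1e-6,
) -> np.ndarray:
    """Sparse-code one signal: greedy atom selection by maximal residual
    correlation with per-step least-squares refit. Stops at ``T0`` atoms
    or when the residual norm drops to ``tol``. Returns the length-K
    coefficient vector."""
    A = D.atoms if isinstance(D, SparseDictionary) else np.asarray(D, dtype=float)
    x = np.asarray(x, dtype=float)
    d, K = A.shape
    if not (1 <= T0 <= d):
        raise ValueError(f"sparsity T0 must be in [1, {d}], got {T0}")
    nx = float(x @ x)
    if nx == 0:
        raise ValueError("cannot sparse-code the zero signal")
    G = A.T @ A
    support, coef, _ = _omp_column(G, A.T @ x, nx, T0, tol)
    alpha = np.zeros(K)
    alpha[support] = coef
    return alpha


def batch_omp(
    A: np.ndarray, Y: np.ndarray, T0: int, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """OMP-code every column of ``Y``; returns (K x N coeffs, residual
    norms). Shares the Gram matrix across columns."""
    d, K = A.shape
    if not (1 <= T0 <= d):
        raise ValueError(f"sparsity T0 must be in [1, {d}], got {T0}")
    G = A.T @ A
    DtY = A.T @ Y
    norms2 = np.einsum("ij,ij->j", Y, Y)
    N = Y.shape[1]
    X = np.zeros((K, N))
    res = np.zeros(N)
    for j in range(N):
        if norms2[j] == 0:
            continue
        support, coef, r = _omp_column(G, DtY[:, j], float(norms2[j]), T0, tol)
        X[support, j] = coef
        res[j] = r
    return X, res


# ---------------------------------------------------------------------------
# KSVD


def _fix_sign(d: np.ndarray, xrow: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the rank-1 sign ambiguity: largest-|entry| of the atom is
    positive (makes seeded runs reproducible)."""
    j = int(np.argmax(np.abs(d)))
    if d[j] < 0:
        return -d, -xrow
    return d, xrow


def ksvd_train(
    Y: np.ndarray,
    K: int,
    T0: int = 10,
    iters: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    omp_tol: float | None = None,
) -> tuple[SparseDictionary, SparseCode]:
    """Learn an overcomplete dictionary by KSVD.

    Alternates OMP coding of all columns with per-atom updates: restrict
    to the signals using atom k, form the restricted residual with atom
    k's contribution added back, and take its best rank-1 approximation
    (first singular pair) as the new atom and coefficient row. A column's
    previous code is kept whenever it beats the fresh OMP code, so the
    Frobenius objective ||Y - DX||_F^2 is non-increasing across
    iterations. Unused atoms are replaced by the currently
    worst-represented training column. Stops after ``iters`` iterations
    or when the objective improves by less than ``tol``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] == 0:
        raise ValueError("Y must be a d x N matrix with N >= 1")
    d, N = Y.shape
    if N < K:
        warnings.warn(f"fewer training columns ({N}) than atoms ({K})", stacklevel=2)
    if omp_tol is None:
        omp_tol = tol

    rng = np.random.default_rng(seed)

    # init: K distinct training columns (resampled with noise if N < K)
    if N >= K:
        idx = rng.choice(N, size=K, replace=False)
        D = Y[:, idx].copy()
    else:
        idx = rng.choice(N, size=K, replace=True)
        D = Y[:, idx] + 1e-6 * rng.standard_normal((d, K))
    col_norms = np.linalg.norm(D, axis=0)
    col_norms[col_norms == 0] = 1.0
    D = D / col_norms

    X = np.zeros((K, N))
    R = Y.copy()
    trace: list[float] = []
    prev_obj = np.inf

    for it in range(iters):
        Xnew, _ = batch_omp(D, Y, T0, omp_tol)
        if it > 0:
            # keep the previous code where it fits better (guarantees a
            # monotone objective despite OMP's greediness)
            res_old = np.linalg.norm(R, axis=0)
            res_new = np.linalg.norm(Y - D @ Xnew, axis=0)
            worse = res_new > res_old
            Xnew[:, worse] = X[:, worse]
        X = Xnew
        R = Y - D @ X

        dead: list[int] = []
        for k in range(K):
            omega = np.flatnonzero(X[k])
            if omega.size == 0:
                dead.append(k)
                continue
            Ek = R[:, omega] + np.outer(D[:, k], X[k, omega])
            U, s, Vt = np.linalg.svd(Ek, full_matrices=False)
            d_new, xrow = _fix_sign(U[:, 0], s[0] * Vt[0])
            R[:, omega] = Ek - np.outer(d_new, xrow)
            D[:, k] = d_new
            X[k, omega] = xrow

        if dead:
            # replacing an unused atom leaves the objective untouched
            res_cols = np.linalg.norm(R, axis=0)
            for k in dead:
                j = int(np.argmax(res_cols))
                norm = np.linalg.norm(Y[:, j])
                if norm > 0:
                    D[:, k] = Y[:, j] / norm
                res_cols[j] = -1.0

        obj = float(np.sum(R * R))
        trace.append(obj)
        if prev_obj - obj < tol:
            break
        prev_obj = obj

    _resolve_duplicates(D, X, Y, rng)
    R = Y - D @ X
    final_obj = float(np.sum(R * R))

    dictionary = SparseDictionary(
        atoms=D,
        training_meta={
            "iterations_run": len(trace),
            "objective_trace": trace,
            "final_objective": final_obj,
            "seed": seed,
            "T0": T0,
            "tol": tol,
            "n_training": N,
        },
    )
    code = SparseCode(coeffs=X, residuals=np.linalg.norm(R, axis=0))
    return dictionary, code


def _resolve_duplicates(
    D: np.ndarray, X: np.ndarray, Y: np.ndarray, rng: np.random.Generator
) -> None:
    """Replace near-duplicate atoms (in place). The duplicate's
    coefficient row is transferred to its partner so the representation is
    preserved up to the (tiny) coherence defect."""
    K = D.shape[1]
    G = D.T @ D
    res_cols = np.linalg.norm(Y - D @ X, axis=0)
    for k in range(1, K):
        j = int(np.argmax(np.abs(G[:k, k])))
        if np.abs(G[j, k]) > DUPLICATE_COHERENCE:
            sign = np.sign(G[j, k])
            X[j] += sign * X[k]
            X[k] = 0.0
            jworst = int(np.argmax(res_cols))
            norm = np.linalg.norm(Y[:, jworst])
            if norm > 0:
                D[:, k] = Y[:, jworst] / norm
            else:
                v = rng.standard_normal(D.shape[0])
                D[:, k] = v / np.linalg.norm(v)
            res_cols[jworst] = -1.0
            G = D.T @ D


# ---------------------------------------------------------------------------
# Encoding and pooling


def encode_matrix(
    D: SparseDictionary, S, T0: int = 10, tol: float = 1e-6
) -> SparseCode:
    """Column-wise OMP of a segment matrix against a trained dictionary."""
    cols = S.columns if hasattr(S, "columns") else np.asarray(S, dtype=float)
    if cols.ndim == 1:
        cols = cols[:, None]
    if cols.shape[0] != D.d:
        raise ValueError(
            f"segment length {cols.shape[0]} does not match dictionary d={D.d}"
        )
    X, res = batch_omp(D.atoms, cols, T0, tol)
    return SparseCode(coeffs=X, residuals=res)


def max_pool(code: SparseCode, subject_id: str = "") -> FeatureVector:
    """Per-coordinate maximum absolute coefficient across the code's
    columns (max-abs pooling with modulus): ``beta_k = max_i |alpha_ik|``."""
    if code.coeffs.size == 0 or code.n == 0:
        raise ValueError("cannot pool an empty sparse code")
    beta = np.max(np.abs(code.coeffs), axis=1)
    return FeatureVector(beta=beta, subject_id=subject_id)
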