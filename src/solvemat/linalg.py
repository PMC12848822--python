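"""Projection and truncated-SVD primitives.

Everything downstream is built from three operations: the orthogonal
projector onto a column space, the best rank-r approximation of a matrix
(truncated SVD), and the reparametrization that turns unconstrained kernel
matrices ``(A0, B0, C0)`` into the constrained triple ``(A, B, C)`` with

    col(B) ⊥ col(X),   col(C) ⊥ col(X),   row(C) ⊥ row(Z).

Projectors use a numerical-rank cutoff (singular values below
``max(a, b) * eps * sigma_max`` are treated as zero) so rank-deficient
designs are handled exactly as the Moore–Penrose algebra dictates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProjectorSet",
    "orthogonal_projector",
    "truncated_svd",
    "reparametrize",
    "numerical_rank",
    "svd_flip_signs",
]

#: Relative gap below which the singular values at a truncation boundary
#: are considered tied (the rank-r approximation is then non-unique).
_TIE_RTOL = 1e-12


def _check_finite(M: np.ndarray, name: str = "matrix") -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError(f"{name} contains non-finite entries")
    return M


def numerical_rank(s: np.ndarray, shape: tuple[int, int]) -> int:
    """Numerical rank from singular values ``s`` of a matrix with ``shape``."""
    if s.size == 0:
        return 0
    cutoff = max(shape) * np.finfo(float).eps * s[0]
    return int(np.count_nonzero(s > cutoff))


def svd_flip_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix singular-vector signs: largest-|entry| of each left vector positive.

    The truncated product ``U D Vt`` is invariant; only the factor output is
    made reproducible across LAPACK drivers and platforms.
    """
    if U.shape[1] == 0:
        return U, Vt
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, Vt * signs[:, None]


def orthogonal_projector(M: np.ndarray) -> np.ndarray:
    """Orthogonal projector ``M (MᵀM)⁺ Mᵀ`` onto the column space of ``M``.

    Computed from a rank-revealing SVD as ``U_r U_rᵀ`` so it is exact for
    rank-deficient ``M``.  ``M`` with zero columns yields the zero projector.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be a 2-D array")
    n = M.shape[0]
    if M.shape[1] == 0 or M.size == 0:
        return np.zeros((n, n))
    _check_finite(M, "M")
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    r = numerical_rank(s, M.shape)
    Ur = U[:, :r]
    return Ur @ Ur.T


@dataclass(frozen=True)
class ProjectorSet:
    """The four projectors used by the model.

    ``P_X`` projects onto col(X) (n×n) and ``P_Zt`` onto the row space of Z,
    i.e. col(Zᵀ) (m×m); the ``_perp`` members are their complements.  An
    empty Z (q = 0) yields ``P_Zt = 0`` and ``P_Zt_perp = I``.
    """

    P_X: np.ndarray
    P_X_perp: np.ndarray
    P_Zt: np.ndarray
    P_Zt_perp: np.ndarray

    @classmethod
    def from_designs(cls, X: np.ndarray, Z: np.ndarray | None) -> "ProjectorSet":
        X = _check_finite(X, "X")
        n = X.shape[0]
        P_X = orthogonal_projector(X)
        if Z is None or np.size(Z) == 0:
            # q = 0: no column predictors; the row-space constraint is vacuous.
            m = Z.shape[1] if (Z is not None and Z.ndim == 2) else None
            if m is None:
                raise ValueError("Z must be a q×m array (q may be 0) so m is known")
            P_Zt = np.zeros((m, m))
        else:
            Z = _check_finite(Z, "Z")
            P_Zt = orthogonal_projector(Z.T)
        m = P_Zt.shape[0]
        return cls(
            P_X=P_X,
            P_X_perp=np.eye(n) - P_X,
            P_Zt=P_Zt,
            P_Zt_perp=np.eye(m) - P_Zt,
        )


@dataclass
class TruncatedSVD:
    """Rank-r factor triple with the reconstructed matrix ``S(M; r)``."""

    U: np.ndarray          # a×r left singular vectors
    s: np.ndarray          # r singular values, non-increasing
    Vt: np.ndarray         # r×b right singular vectors (rows)
    matrix: np.ndarray = field(repr=False)  # U @ diag(s) @ Vt


def truncated_svd(M: np.ndarray, r: int) -> TruncatedSVD:
    """Best rank-``r`` Frobenius approximation ``S(M; r)`` of ``M``.

    Keeps the ``r`` largest singular values.  ``r = 0`` returns the zero
    matrix; ``r >= rank(M)`` reproduces ``M`` to machine precision.  A tie
    at the truncation boundary (``σ_r == σ_{r+1}``) makes the approximation
    non-unique; the first ``r`` factors in factorization order are kept and
    a warning is emitted.
    """
    M = _check_finite(M, "M")
    a, b = M.shape
    if not (isinstance(r, (int, np.integer)) and 0 <= r <= min(a, b)):
        raise ValueError(f"rank r={r} must be an integer in [0, min(a, b)={min(a, b)}]")
    if r == 0:
        z = np.zeros((a, b))
        return TruncatedSVD(np.zeros((a, 0)), np.zeros(0), np.zeros((0, b)), z)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if r < s.size and s[r] > 0 and (s[r - 1] - s[r]) <= _TIE_RTOL * s[0]:
        warnings.warn(
            "tied singular values at the truncation boundary: the rank-%d "
            "approximation is not unique" % r,
            RuntimeWarning,
            stacklevel=2,
        )
    U, Vt = svd_flip_signs(U[:, :r], Vt[:r])
    s = s[:r]
    return TruncatedSVD(U, s, Vt, (U * s) @ Vt)


def reparametrize(
    A0: np.ndarray,
    B0: np.ndarray,
    C0: np.ndarray,
    proj: ProjectorSet,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map kernel matrices to the constrained triple.

    ``A = A0``, ``B = P_X⊥ B0``, ``C = P_X⊥ C0 P_Zᵀ⊥``.  The result
    satisfies ``P_X B = 0``, ``P_X C = 0`` and ``C P_Zᵀ = 0`` by
    construction, and ``rank(C) <= rank(C0)``.
    """
    A0 = np.asarray(A0, dtype=float)
    B0 = np.asarray(B0, dtype=float)
    C0 = np.asarray(C0, dtype=float)
    n = proj.P_X.shape[0]
    m = proj.P_Zt.shape[0]
    if C0.shape != (n, m):
        raise ValueError(f"C0 must be {n}×{m}, got {C0.shape}")
    if B0.ndim != 2 or (B0.size and B0.shape[0] != n):
        raise ValueError(f"B0 must have {n} rows, got shape {B0.shape}")
    if A0.ndim != 2 or A0.shape[1] != m:
        raise ValueError(f"A0 must have {m} columns, got shape {A0.shape}")
    B = proj.P_X_perp @ B0 if B0.size else B0.copy()
    C = proj.P_X_perp @ C0 @ proj.P_Zt_perp
    return A0.copy(), B, C
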