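"""Fitting the structured orthogonal latent-variable (SOLVE) model.

The model for an n×m outcome matrix Y with row predictors X (n×p) and
column predictors Z (q×m) is

    g(E[Y]) = X A + B Z + C,
    subject to  P_X B = 0,  P_X C = 0,  C P_Zt = 0,  rank(C) <= r,

where P_X is the projector onto col(X) and P_Zt onto the row space of Z.
The constraints make the decomposition identifiable: C captures only
variation orthogonal to both predictor spaces.

Two solvers are provided.  For squared loss the problem has a global
closed-form optimum (:func:`fit_closed_form`): the latent kernel is the
truncated SVD of the doubly projected outcome, and the coefficient kernels
are pseudoinverse regressions of Y on X and Z.  For general losses with an
L-Lipschitz gradient, :func:`fit_mm` runs a majorization–minimization
scheme: each iteration forms the pseudo-response ``xi = eta - grad l / rho``
and applies the closed-form update to xi, which drives the loss monotonically
downward whenever ``rho >= L``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .linalg import (
    ProjectorSet,
    numerical_rank,
    reparametrize,
    svd_flip_signs,
    truncated_svd,
)
from .losses import LossFamily, get_family, loss_value

__all__ = [
    "DesignData",
    "SolveFit",
    "fit_closed_form",
    "fit_mm",
    "solve_fit",
    "linear_predictor",
    "latent_loadings",
]


def _as_matrix(M, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got ndim={M.ndim}")
    if M.size and not np.all(np.isfinite(M)):
        raise ValueError(f"{name} contains missing or non-finite entries; "
                         "resolve missingness upstream before fitting")
    return M


@dataclass
class DesignData:
    """The observed triple (Y, X, Z) plus preprocessing flags.

    ``Z`` may have zero rows (q = 0), in which case the B-term vanishes and
    the latent constraint reduces to column-space orthogonality only.
    ``intercept_rows`` appends a ones column to X; ``intercept_cols`` a ones
    row to Z.  ``standardize_X`` centers/scales the columns of X and
    ``standardize_Z`` the rows of Z (before intercept augmentation); the
    recorded means and scales allow coefficients to be mapped back to the
    original predictor scale.
    """

    Y: np.ndarray
    X: np.ndarray
    Z: np.ndarray | None = None
    family: str | LossFamily = "gaussian"
    standardize_X: bool = False
    standardize_Z: bool = False
    intercept_rows: bool = False
    intercept_cols: bool = False

    def __post_init__(self) -> None:
        self.Y = _as_matrix(self.Y, "Y")
        self.X = _as_matrix(self.X, "X")
        n, m = self.Y.shape
        if self.Z is None:
            self.Z = np.zeros((0, m))
        self.Z = _as_matrix(self.Z, "Z")
        if self.X.shape[0] != n:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but Y has {n}")
        if self.Z.shape[1] != m:
            raise ValueError(
                f"Z has {self.Z.shape[1]} columns but Y has {m}")
        fam = get_family(self.family)
        fam.validate_Y(self.Y)
        self.family = fam
        self._build_designs()
        if self.n <= self.p or self.m <= self.q:
            raise ValueError(
                f"model requires n > p and m > q after intercept "
                f"augmentation; got n={self.n}, p={self.p}, m={self.m}, "
                f"q={self.q}")

    def _build_designs(self) -> None:
        X = self.X
        self.x_mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
        self.x_scale = np.where(sd > 0, sd, 1.0)
        if self.standardize_X:
            X = (X - self.x_mean) / self.x_scale
        if self.intercept_rows:
            X = np.column_stack([np.ones(X.shape[0]), X])
        self.Xd = X

        Z = self.Z
        self.z_mean = Z.mean(axis=1) if Z.size else np.zeros(Z.shape[0])
        sdz = Z.std(axis=1, ddof=1) if Z.shape[1] > 1 and Z.size else np.ones(Z.shape[0])
        self.z_scale = np.where(sdz > 0, sdz, 1.0)
        if self.standardize_Z and Z.size:
            Z = (Z - self.z_mean[:, None]) / self.z_scale[:, None]
        if self.intercept_cols:
            Z = np.vstack([np.ones(Z.shape[1]), Z])
        self.Zd = Z

    # -- dimensions of the model actually fitted ---------------------------
    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def m(self) -> int:
        return self.Y.shape[1]

    @property
    def p(self) -> int:
        return self.Xd.shape[1]

    @property
    def q(self) -> int:
        return self.Zd.shape[0]

    # Projectors and pseudoinverses are computed once and reused across
    # iterations, the rank grid, and bootstrap refits.
    @cached_property
    def projectors(self) -> ProjectorSet:
        return ProjectorSet.from_designs(self.Xd, self.Zd)

    @cached_property
    def X_pinv(self) -> np.ndarray:
        # (XᵀX)⁺Xᵀ coincides with the Moore–Penrose pseudoinverse of X.
        return np.linalg.pinv(self.Xd)

    @cached_property
    def Z_pinv(self) -> np.ndarray:
        # Zᵀ(ZZᵀ)⁺ is the pseudoinverse of Z (m×q).
        if self.q == 0:
            return np.zeros((self.m, 0))
        return np.linalg.pinv(self.Zd)


@dataclass
class SolveFit:
    """A fitted model: constrained matrices, kernels, and diagnostics."""

    A: np.ndarray            # p×m row-predictor coefficients
    B: np.ndarray            # n×q column-predictor coefficients, P_X B = 0
    C: np.ndarray            # n×m latent component, rank <= r
    A0: np.ndarray
    B0: np.ndarray
    C0: np.ndarray
    eta: np.ndarray          # n×m linear predictor X A + B Z + C
    r: int
    rho: float
    loss_trace: np.ndarray
    n_iter: int
    converged: bool
    projectors: ProjectorSet
    family_id: str

    @property
    def loss(self) -> float:
        return float(self.loss_trace[-1])

    def constraint_residuals(self) -> dict[str, float]:
        """Frobenius norms of P_X B, P_X C and C P_Zt (should all be ~0)."""
        P = self.projectors
        return {
            "PX_B": float(np.linalg.norm(P.P_X @ self.B)) if self.B.size else 0.0,
            "PX_C": float(np.linalg.norm(P.P_X @ self.C)),
            "C_PZt": float(np.linalg.norm(self.C @ P.P_Zt)),
        }


def linear_predictor(
    A0: np.ndarray,
    B0: np.ndarray,
    C0: np.ndarray,
    data: DesignData,
    proj: ProjectorSet | None = None,
) -> np.ndarray:
    """``eta = X A0 + P_X⊥ B0 Z + P_X⊥ C0 P_Zt⊥`` from kernel matrices."""
    proj = proj if proj is not None else data.projectors
    A, B, C = reparametrize(A0, B0, C0, proj)
    eta = data.Xd @ A + C
    if B.size:
        eta = eta + B @ data.Zd
    return eta


def _closed_form_update(
    xi: np.ndarray, data: DesignData, r: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One exact solve of the constrained least-squares problem in xi."""
    P = data.projectors
    A0 = data.X_pinv @ xi
    B0 = xi @ data.Z_pinv
    C0 = truncated_svd(P.P_X_perp @ xi @ P.P_Zt_perp, r).matrix
    return A0, B0, C0


def _assemble(
    A0: np.ndarray,
    B0: np.ndarray,
    C0: np.ndarray,
    data: DesignData,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    P = data.projectors
    A, B, C = reparametrize(A0, B0, C0, P)
    eta = data.Xd @ A + C
    if B.size:
        eta = eta + B @ data.Zd
    return A, B, C, eta


def _check_rank(r: int, data: DesignData) -> int:
    rmax = min(data.n, data.m)
    if not (isinstance(r, (int, np.integer)) and 0 <= r <= rmax):
        raise ValueError(f"rank r={r} must be an integer in [0, {rmax}]")
    return int(r)


def fit_closed_form(data: DesignData, r: int) -> SolveFit:
    """Globally optimal fit under squared loss, in one shot.

    ``C0 = S(P_X⊥ Y P_Zt⊥; r)``, ``A0 = (XᵀX)⁺XᵀY``, ``B0 = Y Zᵀ(ZZᵀ)⁺``;
    the constrained triple follows by reparametrization.  Only valid for the
    gaussian family.
    """
    fam = get_family(data.family)
    if fam.family_id != "gaussian":
        raise ValueError(
            "fit_closed_form requires the gaussian family; use fit_mm for "
            f"family {fam.family_id!r}")
    r = _check_rank(r, data)
    A0, B0, C0 = _closed_form_update(data.Y, data, r)
    A, B, C, eta = _assemble(A0, B0, C0, data)
    lv = loss_value(eta, data.Y, fam)
    return SolveFit(
        A=A, B=B, C=C, A0=A0, B0=B0, C0=C0, eta=eta, r=r, rho=1.0,
        loss_trace=np.array([lv]), n_iter=1, converged=True,
        projectors=data.projectors, family_id=fam.family_id,
    )


def fit_mm(
    data: DesignData,
    r: int,
    rho: float | str = "auto",
    tol: float = 1e-9,
    max_iter: int = 5000,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> SolveFit:
    """Majorization–minimization fit for any Lipschitz-gradient loss.

    Each pass forms the pseudo-response ``xi = eta - grad l(eta) / rho`` and
    solves the constrained least-squares problem in xi exactly.  With
    ``rho >= L`` the loss sequence is non-increasing; with rho below L that
    guarantee is lost (a warning is emitted).  Iteration stops when the
    relative loss decrease ``|l_t - l_{t+1}| / (|l_t| + 1)`` drops below
    ``tol`` or after ``max_iter`` passes (``converged=False`` then, with a
    warning, and the last iterate is still returned).

    ``init`` supplies starting kernels ``(A0, B0, C0)``; the default is all
    zeros.  For the gaussian family with rho = 1 the pseudo-response equals
    Y, so the first pass already lands on the closed-form global optimum.
    """
    fam = get_family(data.family)
    r = _check_rank(r, data)
    if rho == "auto":
        rho = fam.lipschitz_L
    rho = float(rho)
    if rho <= 0:
        raise ValueError("rho must be positive")
    if rho < fam.lipschitz_L:
        warnings.warn(
            f"rho={rho} < L={fam.lipschitz_L}: monotone descent is not "
            "guaranteed", RuntimeWarning, stacklevel=2)
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    n, m = data.n, data.m
    if init is None:
        A0 = np.zeros((data.p, m))
        B0 = np.zeros((n, data.q))
        C0 = np.zeros((n, m))
    else:
        A0, B0, C0 = (np.asarray(M, dtype=float).copy() for M in init)
        if numerical_rank(np.linalg.svd(C0, compute_uv=False), C0.shape) > r:
            raise ValueError("initial C0 has rank exceeding r")

    Y = data.Y
    _, _, _, eta = _assemble(A0, B0, C0, data)
    trace = [loss_value(eta, Y, fam)]
    converged = False
    for t in range(max_iter):
        xi = eta - fam.gradient(eta, Y) / rho
        A0, B0, C0 = _closed_form_update(xi, data, r)
        A, B, C, eta = _assemble(A0, B0, C0, data)
        lv = loss_value(eta, Y, fam)
        prev = trace[-1]
        trace.append(lv)
        if rho >= fam.lipschitz_L and lv > prev + 1e-8 * (abs(prev) + 1.0):
            raise RuntimeError(
                f"loss increased from {prev:.6g} to {lv:.6g} at iteration "
                f"{t + 1} despite rho >= L; this indicates a numerical "
                "problem")
        if abs(prev - lv) < tol * (abs(prev) + 1.0):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MM did not reach tolerance {tol} within {max_iter} iterations; "
            "returning the last iterate (possible slow convergence or "
            "perfect separation under the logistic loss)",
            RuntimeWarning, stacklevel=2)
    return SolveFit(
        A=A, B=B, C=C, A0=A0, B0=B0, C0=C0, eta=eta, r=r, rho=rho,
        loss_trace=np.asarray(trace), n_iter=len(trace) - 1,
        converged=converged, projectors=data.projectors,
        family_id=fam.family_id,
    )


def solve_fit(data: DesignData, r: int, **mm_kwargs) -> SolveFit:
    """Fit at rank r with the appropriate solver for the data's family.

    Gaussian data uses the exact closed form (unless MM options are passed);
    every other family uses the MM iteration.
    """
    if get_family(data.family).family_id == "gaussian" and not mm_kwargs:
        return fit_closed_form(data, r)
    return fit_mm(data, r, **mm_kwargs)


def latent_loadings(fit: SolveFit) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the fitted latent component Ĉ, restricted to its numerical rank.

    Returns ``(U, s, V)``: n×k orthonormal row loadings, k singular values in
    non-increasing order, and m×k orthonormal column loadings, where k is the
    numerical rank of Ĉ.  Row loadings inherit the orthogonality to col(X)
    enforced on C.  An (effectively) zero Ĉ yields empty output with a
    warning.
    """
    U, s, Vt = np.linalg.svd(fit.C, full_matrices=False)
    k = numerical_rank(s, fit.C.shape)
    if k == 0:
        warnings.warn("fitted C is numerically zero; no latent loadings",
                      RuntimeWarning, stacklevel=2)
        n, m = fit.C.shape
        return np.zeros((n, 0)), np.zeros(0), np.zeros((m, 0))
    U, Vt = svd_flip_signs(U[:, :k], Vt[:k])
    return U, s[:k], Vt.T


def coefficients_original_scale(
    fit: SolveFit, data: DesignData
) -> tuple[np.ndarray, np.ndarray]:
    """Map fitted (A, B) back to the raw predictor scale.

    Undoes the column standardization of X and row standardization of Z; any
    intercept row/column absorbs the centering shifts.  With no
    standardization and no intercepts this is the identity.
    """
    A = fit.A.copy()
    B = fit.B.copy()
    off = 1 if data.intercept_rows else 0
    if data.standardize_X:
        A[off:] = A[off:] / data.x_scale[:, None]
        if data.intercept_rows:
            A[0] -= data.x_mean @ A[off:]
    offz = 1 if data.intercept_cols else 0
    if data.standardize_Z and B.size:
        B[:, offz:] = B[:, offz:] / data.z_scale[None, :]
        if data.intercept_cols:
            B[:, 0] -= B[:, offz:] @ data.z_mean
    return A, B
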