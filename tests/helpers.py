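"""Shared test utilities: independent oracles and tiny problem builders.

The oracles here deliberately avoid the code paths they check: projectors
via full SVD bases, best rank-r error via full singular spectra, and the
constrained objective via a generic multi-start quasi-Newton optimizer over
an explicit low-rank factorization.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from solvemat import DesignData, SimulationSpec, generate_dataset
from solvemat.losses import get_family


def projector_oracle(M: np.ndarray) -> np.ndarray:
    """Projector onto col(M) from an orthonormal basis of the column space."""
    if M.size == 0:
        return np.zeros((M.shape[0], M.shape[0]))
    Q, R, = np.linalg.qr(M)
    keep = np.abs(np.diag(R)) > max(M.shape) * np.finfo(float).eps * (
        np.abs(np.diag(R)).max() if np.abs(np.diag(R)).max() > 0 else 1.0)
    Q = Q[:, keep]
    return Q @ Q.T


def tiny_dataset(
    n=8, m=6, p=2, q=1, r=1, *, family="gaussian", sigma2=1.0, seed=0,
    coef_scale=1.0,
):
    """A small simulated dataset and its DesignData, for oracle comparisons."""
    spec = SimulationSpec(n=n, m=m, p=p, q=q, true_rank=r, sigma2=sigma2,
                          family=family, seed=seed, coef_scale=coef_scale,
                          rank_grid=(r,))
    sim = generate_dataset(spec, 0)
    return sim, sim.to_design(family)


def _unpack(theta, n, m, p, q, r):
    i = 0
    A0 = theta[i:i + p * m].reshape(p, m); i += p * m
    B0 = theta[i:i + n * q].reshape(n, q); i += n * q
    L = theta[i:i + n * r].reshape(n, r); i += n * r
    R = theta[i:i + r * m].reshape(r, m)
    return A0, B0, L, R


def brute_force_min(data: DesignData, r: int, n_starts=8, seed=0) -> float:
    """Multi-start L-BFGS minimum of the constrained objective.

    Parametrizes the feasible set explicitly: free kernels (A0, B0) and a
    rank-r factorization C0 = L R, with the orthogonality constraints
    enforced by the same projector reparametrization the model defines.
    Returns the best objective value found.
    """
    fam = get_family(data.family)
    n, m, p, q = data.n, data.m, data.p, data.q
    P = data.projectors
    Y = data.Y

    def objective(theta):
        A0, B0, L, R = _unpack(theta, n, m, p, q, r)
        eta = data.Xd @ A0 + P.P_X_perp @ (L @ R) @ P.P_Zt_perp
        if q:
            eta = eta + (P.P_X_perp @ B0) @ data.Zd
        return fam.value(eta, Y)

    rng = np.random.default_rng(seed)
    dim = p * m + n * q + n * r + r * m
    best = np.inf
    for s in range(n_starts):
        x0 = rng.standard_normal(dim) * (0.0 if s == 0 else 0.5)
        res = minimize(objective, x0, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-14,
                                "gtol": 1e-12})
        best = min(best, res.fun)
    return best
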