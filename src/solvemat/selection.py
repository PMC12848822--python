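"""Rank selection: degrees-of-freedom-penalized AIC over a rank grid,
with the maximum-perpendicular-distance elbow rule.

The latent rank r is the model's single tuning parameter.  For each
candidate rank the model is refit and scored by

    IC(r) = -2 log L + 2 DF(r),      DF(r) = pm + nq + r(n + m - r),

where the deviance term is ``mn log(||Y - eta||_F^2 / nm)`` for gaussian
outcomes (additive constants dropped) and the logistic deviance
``-2 <Y, eta> + 2 sum softplus(eta)`` for binary ones.  Minimizing IC tends
to overfit the rank, so the default selector is the elbow of the IC curve:
both axes are min–max normalized to [0, 1] and the chosen rank maximizes the
perpendicular distance to the chord joining the curve's endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimator import DesignData, SolveFit, fit_closed_form, fit_mm
from .losses import get_family, stable_softplus

__all__ = [
    "RankPath",
    "degrees_of_freedom",
    "deviance",
    "information_criterion",
    "elbow_select",
    "rank_path",
]


def degrees_of_freedom(n: int, m: int, p: int, q: int, r: int) -> int:
    """Effective parameter count ``pm + nq + r(n + m - r)``.

    pm and nq count the entries of A and B; r(n + m - r) is the dimension of
    the rank-r matrix manifold for C.
    """
    for name, v in (("n", n), ("m", m), ("p", p), ("q", q), ("r", r)):
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if r > min(n, m):
        raise ValueError(f"rank r={r} exceeds min(n, m)={min(n, m)}")
    return int(p) * int(m) + int(n) * int(q) + int(r) * (int(n) + int(m) - int(r))


def deviance(fit: SolveFit, data: DesignData) -> float:
    """-2 log-likelihood of the fitted model, up to additive constants.

    Gaussian: ``mn log(RSS / nm)`` with the error variance profiled out; an
    exactly zero RSS returns -inf with a warning.  Bernoulli-logit: the
    model deviance ``-2 sum y eta + 2 sum softplus(eta)``.
    """
    fam = get_family(data.family)
    n, m = data.n, data.m
    if fam.family_id == "gaussian":
        rss = float(np.sum((data.Y - fit.eta) ** 2))
        if rss == 0.0:
            warnings.warn("exact zero residual sum of squares; deviance is "
                          "-inf", RuntimeWarning, stacklevel=2)
            return -np.inf
        return n * m * float(np.log(rss / (n * m)))
    if fam.family_id == "bernoulli_logit":
        return float(2.0 * np.sum(stable_softplus(fit.eta))
                     - 2.0 * np.sum(data.Y * fit.eta))
    raise ValueError(f"no deviance defined for family {fam.family_id!r}")


def information_criterion(fit: SolveFit, data: DesignData) -> float:
    """AIC-type score ``deviance + 2 DF(r)`` balancing fit and complexity."""
    return deviance(fit, data) + 2.0 * degrees_of_freedom(
        data.n, data.m, data.p, data.q, fit.r)


def _elbow_distances(grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Perpendicular distances on the min–max normalized curve."""
    x = grid.astype(float)
    y = values.astype(float)
    x = (x - x[0]) / (x[-1] - x[0])
    rng = y.max() - y.min()
    y = (y - y.min()) / rng if rng > 0 else np.zeros_like(y)
    # distance from (x_i, y_i) to the chord through the first and last points
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    chord = np.hypot(dx, dy)
    return np.abs(dx * (y[0] - y) - (x[0] - x) * dy) / chord


def elbow_select(grid, ic_values) -> int:
    """Rank at the elbow of the IC curve (maximum perpendicular distance).

    Both axes are min–max normalized to [0, 1] before computing each point's
    distance to the straight line joining the first and last points.  Ties
    (including an exactly linear curve, where all distances vanish) resolve
    to the smallest rank.
    """
    grid = np.asarray(list(grid), dtype=int)
    ic = np.asarray(list(ic_values), dtype=float)
    if grid.size != ic.size or grid.size < 1:
        raise ValueError("grid and ic_values must be equal-length, non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if not np.all(np.isfinite(ic)):
        raise ValueError("IC values must be finite for elbow selection")
    if grid.size == 1:
        return int(grid[0])
    if np.ptp(ic) == 0:
        warnings.warn("constant IC curve: returning the smallest rank",
                      RuntimeWarning, stacklevel=2)
        return int(grid[0])
    d = _elbow_distances(grid, ic)
    # ties (within float noise of the maximum) break toward the smallest rank
    dmax = d.max()
    idx = int(np.nonzero(d >= dmax - 1e-12 * max(dmax, 1.0))[0][0])
    return int(grid[idx])


@dataclass
class RankPath:
    """IC trajectory over the candidate rank grid and the selected rank."""

    grid: np.ndarray
    deviance: np.ndarray
    df: np.ndarray
    ic: np.ndarray
    distances: np.ndarray
    selected_rank: int
    fits: list[SolveFit] = field(default_factory=list, repr=False)

    @property
    def selected_fit(self) -> SolveFit:
        idx = int(np.nonzero(self.grid == self.selected_rank)[0][0])
        return self.fits[idx]


def rank_path(
    data: DesignData,
    grid=range(1, 11),
    *,
    method: str = "elbow",
    warm_start: bool = True,
    keep_fits: bool = True,
    **solver_kwargs,
) -> RankPath:
    """Fit the model at every rank in ``grid`` and select one.

    Gaussian data uses the closed-form solver; other families the MM
    iteration, warm-started at each rank from the previous rank's kernels
    (initialization affects speed only, not the descent guarantee; pass
    ``warm_start=False`` for zero initialization at every rank).
    ``method`` is ``"elbow"`` (default) or ``"min"`` — plain IC
    minimization, which tends to overfit the rank.
    """
    grid = np.asarray(list(grid), dtype=int)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a non-empty strictly increasing "
                         "sequence of ranks")
    if method not in ("elbow", "min"):
        raise ValueError("method must be 'elbow' or 'min'")
    fam = get_family(data.family)
    gaussian = fam.family_id == "gaussian" and not solver_kwargs

    fits: list[SolveFit] = []
    dev = np.empty(grid.size)
    dfs = np.empty(grid.size, dtype=int)
    ics = np.empty(grid.size)
    prev: SolveFit | None = None
    for i, r in enumerate(grid):
        if gaussian:
            fit = fit_closed_form(data, int(r))
        else:
            init = (prev.A0, prev.B0, prev.C0) if (warm_start and prev) else None
            fit = fit_mm(data, int(r), init=init, **solver_kwargs)
        dev[i] = deviance(fit, data)
        dfs[i] = degrees_of_freedom(data.n, data.m, data.p, data.q, int(r))
        ics[i] = dev[i] + 2.0 * dfs[i]
        fits.append(fit)
        prev = fit

    if grid.size == 1:
        distances = np.zeros(1)
        selected = int(grid[0])
    elif method == "min":
        distances = _elbow_distances(grid, ics) if np.all(np.isfinite(ics)) else np.full(grid.size, np.nan)
        selected = int(grid[int(np.argmin(ics))])
    else:
        if not np.all(np.isfinite(ics)):
            # a -inf deviance marks an exact fit: the first such rank is the
            # sharpest possible elbow
            selected = int(grid[int(np.nonzero(~np.isfinite(ics))[0][0])])
            distances = np.full(grid.size, np.nan)
        else:
            distances = _elbow_distances(grid, ics)
            selected = elbow_select(grid, ics)
    return RankPath(
        grid=grid, deviance=dev, df=dfs, ic=ics, distances=distances,
        selected_rank=selected, fits=fits if keep_fits else [],
    )
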