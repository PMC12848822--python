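"""Bootstrap inference for the coefficient matrices.

The low-rank constraint on the latent component makes classical asymptotic
standard errors unavailable, so uncertainty is assessed by refitting the
model on resampled outcomes:

* **wild bootstrap** (gaussian outcomes): residuals are flipped by
  independent Rademacher (+/-1) weights, ``Y_b = eta_hat + W_b * E_hat``,
  which is robust to heteroskedastic noise;
* **parametric bootstrap** (binary outcomes): entries of ``Y_b`` are drawn
  Bernoulli with the fitted probabilities ``logistic(eta_hat)``.

Each draw refits the full constrained model on (Y_b, X, Z) at the rank of
the original fit, and the collection of refitted coefficient matrices yields
percentile confidence intervals and two-sided p-values per entry of A (and
B).  Draw b uses the RNG substream keyed by (seed, b), so results do not
depend on execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimator import DesignData, SolveFit, fit_closed_form, fit_mm
from .losses import get_family, inverse_link

__all__ = [
    "BootstrapResult",
    "InferenceSummary",
    "parametric_bootstrap_binary",
    "wild_bootstrap_gaussian",
    "bootstrap",
    "summarize_bootstrap",
]


@dataclass
class BootstrapResult:
    """Per-draw refitted coefficients plus the original point estimates."""

    n_draws: int
    draws_A: np.ndarray      # B_ok × p × m
    draws_B: np.ndarray      # B_ok × n × q
    point_A: np.ndarray
    point_B: np.ndarray
    rank_used: int
    seed: int
    method: str
    n_failed: int = 0
    n_nonconverged: int = 0

    def __post_init__(self) -> None:
        if self.draws_A.size and not np.all(np.isfinite(self.draws_A)):
            raise ValueError("bootstrap draws contain non-finite entries")


def _refit_draws(
    fit: SolveFit,
    data: DesignData,
    make_Y,
    B: int,
    seed: int,
    method: str,
    warm_start: bool,
    mm_kwargs: dict,
) -> BootstrapResult:
    if B < 1:
        raise ValueError("number of bootstrap draws B must be >= 1")
    gaussian = get_family(data.family).family_id == "gaussian"
    init = (fit.A0, fit.B0, fit.C0) if warm_start else None
    draws_A, draws_B = [], []
    n_failed = n_nonconverged = 0
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        Yb = make_Y(rng)
        data_b = DesignData(Y=Yb, X=data.Xd, Z=data.Zd, family=data.family)
        # X and Z are unchanged across draws: reuse the cached projectors
        # and pseudoinverse factors instead of recomputing them per refit.
        data_b.__dict__["projectors"] = data.projectors
        data_b.__dict__["X_pinv"] = data.X_pinv
        data_b.__dict__["Z_pinv"] = data.Z_pinv
        try:
            if gaussian:
                refit = fit_closed_form(data_b, fit.r)
            else:
                with warnings.catch_warnings():
                    # a refit stopped by the iteration budget is still a
                    # valid draw; only solver errors / non-finite results
                    # are excluded
                    warnings.filterwarnings(
                        "ignore", message="MM did not reach tolerance")
                    refit = fit_mm(data_b, fit.r, init=init, **mm_kwargs)
        except (RuntimeError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not (np.all(np.isfinite(refit.A)) and np.all(np.isfinite(refit.B))):
            n_failed += 1
            continue
        if not refit.converged:
            n_nonconverged += 1
        draws_A.append(refit.A)
        draws_B.append(refit.B)
    if n_failed:
        warnings.warn(f"{n_failed} of {B} bootstrap refits failed and were "
                      "excluded", RuntimeWarning, stacklevel=3)
    return BootstrapResult(
        n_draws=B,
        draws_A=np.asarray(draws_A),
        draws_B=np.asarray(draws_B),
        point_A=fit.A.copy(),
        point_B=fit.B.copy(),
        rank_used=fit.r,
        seed=seed,
        method=method,
        n_failed=n_failed,
        n_nonconverged=n_nonconverged,
    )


def parametric_bootstrap_binary(
    fit: SolveFit,
    data: DesignData,
    B: int,
    seed: int = 0,
    *,
    warm_start: bool = True,
    **mm_kwargs,
) -> BootstrapResult:
    """Parametric bootstrap for binary outcomes.

    Draws ``Y_b ~ Bernoulli(logistic(eta_hat))`` entrywise and refits at the
    original rank.  Refits are warm-started at the original kernels by
    default (``warm_start=False`` for zero-start refits); non-converged
    refits are excluded with a count.
    """
    if get_family(data.family).family_id != "bernoulli_logit":
        raise ValueError("parametric_bootstrap_binary requires the "
                         "bernoulli_logit family")
    P = inverse_link(fit.eta, data.family)

    def make_Y(rng: np.random.Generator) -> np.ndarray:
        return (rng.random(P.shape) < P).astype(float)

    return _refit_draws(fit, data, make_Y, B, seed, "parametric_binary",
                        warm_start, mm_kwargs)


def wild_bootstrap_gaussian(
    fit: SolveFit,
    data: DesignData,
    B: int,
    seed: int = 0,
    *,
    warm_start: bool = True,
    **mm_kwargs,
) -> BootstrapResult:
    """Wild (Rademacher) bootstrap for continuous outcomes.

    ``Y_b = eta_hat + W_b ∘ E_hat`` with i.i.d. +/-1 weights W_b and
    residuals ``E_hat = Y - eta_hat``; refits use the exact closed form at
    the original rank.
    """
    if get_family(data.family).family_id != "gaussian":
        raise ValueError("wild_bootstrap_gaussian requires the gaussian "
                         "family")
    resid = data.Y - fit.eta

    def make_Y(rng: np.random.Generator) -> np.ndarray:
        W = rng.integers(0, 2, size=resid.shape) * 2.0 - 1.0
        return fit.eta + W * resid

    return _refit_draws(fit, data, make_Y, B, seed, "wild_gaussian",
                        warm_start, mm_kwargs)


def bootstrap(fit: SolveFit, data: DesignData, B: int, seed: int = 0,
              **kwargs) -> BootstrapResult:
    """Dispatch to the family-appropriate bootstrap scheme."""
    if get_family(data.family).family_id == "gaussian":
        return wild_bootstrap_gaussian(fit, data, B, seed, **kwargs)
    return parametric_bootstrap_binary(fit, data, B, seed, **kwargs)


@dataclass
class InferenceSummary:
    """Entrywise estimates, CIs and p-values for one coefficient block."""

    table: pd.DataFrame
    block: str
    level: float
    p_method: str


def _p_values(draws: np.ndarray, point: np.ndarray, p_method: str) -> np.ndarray:
    B = draws.shape[0]
    if p_method == "normal":
        sd = draws.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = point / sd
        p = 2.0 * norm.sf(np.abs(z))
        degenerate = sd == 0
        if np.any(degenerate):
            warnings.warn("zero bootstrap sd for some entries; their normal "
                          "p-values are degenerate (1 if the estimate is 0, "
                          "else 0)", RuntimeWarning, stacklevel=3)
            p = np.where(degenerate, np.where(point == 0, 1.0, 0.0), p)
        return p
    if p_method == "percentile":
        # sign-flip tail probability with the (count+1)/(B+1) correction
        n_le = np.sum(draws <= 0, axis=0)
        n_ge = np.sum(draws >= 0, axis=0)
        p = 2.0 * np.minimum((n_le + 1) / (B + 1), (n_ge + 1) / (B + 1))
        return np.minimum(p, 1.0)
    raise ValueError("p_method must be 'normal' or 'percentile'")


def summarize_bootstrap(
    result: BootstrapResult,
    level: float = 0.95,
    p_method: str = "normal",
    block: str = "A",
) -> InferenceSummary:
    """Entrywise percentile CIs and two-sided p-values for A (or B).

    The CI is the (alpha/2, 1-alpha/2) percentile interval of the draws.
    ``p_method='normal'`` uses ``z = estimate / sd(draws)`` against a
    standard-normal reference (capable of reporting p-values below the
    empirical-CDF floor of ~2/(B+1)); ``'percentile'`` uses the corrected
    empirical tail probability at zero.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if block not in ("A", "B"):
        raise ValueError("block must be 'A' or 'B'")
    draws = result.draws_A if block == "A" else result.draws_B
    point = result.point_A if block == "A" else result.point_B
    if draws.shape[0] < 2:
        raise ValueError("need at least 2 valid bootstrap draws to summarize")
    alpha = 1.0 - level
    lo = np.quantile(draws, alpha / 2, axis=0)
    hi = np.quantile(draws, 1.0 - alpha / 2, axis=0)
    se = draws.std(axis=0, ddof=1)
    p = _p_values(draws, point, p_method)

    rows, cols = point.shape
    ri, ci = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    table = pd.DataFrame({
        "row": ri.ravel(),
        "col": ci.ravel(),
        "estimate": point.ravel(),
        "se": se.ravel(),
        "ci_lower": lo.ravel(),
        "ci_upper": hi.ravel(),
        "p_value": p.ravel(),
        "p_method": p_method,
    })
    return InferenceSummary(table=table, block=block, level=level,
                            p_method=p_method)
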