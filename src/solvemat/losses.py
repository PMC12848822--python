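"""GLM loss families with Lipschitz-smooth gradients.

Each family packages the loss value, its gradient, the gradient's Lipschitz
constant L, the inverse link, and the cumulant b(.) of the exponential-family
log-partition.  Two families are built in:

* ``gaussian`` — squared Frobenius loss ``||Y - eta||_F^2 / 2``, identity
  link, L = 1.
* ``bernoulli_logit`` — logistic loss ``-<Y, eta> + sum b(eta)`` with
  cumulant ``b(t) = log(1 + e^t)``, logistic inverse link, L = 1/4
  (since ``b''(t) <= 1/4``).

The registry is open: any loss whose gradient is Lipschitz can be added via
:func:`register_family` and used by the MM solver unchanged.  All
exponentials go through the overflow-safe softplus/logistic forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit

__all__ = [
    "LossFamily",
    "get_family",
    "register_family",
    "stable_softplus",
    "loss_value",
    "loss_gradient",
    "pseudo_response",
    "inverse_link",
]


def stable_softplus(z):
    """``log(1 + exp(z))`` as ``max(0, z) + log(1 + exp(-|z|))``; never overflows."""
    z = np.asarray(z, dtype=float)
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


@dataclass(frozen=True)
class LossFamily:
    """A loss with Lipschitz-continuous gradient, in GLM form.

    ``value``/``gradient`` act on the full linear-predictor matrix;
    ``cumulant`` and ``cumulant_prime`` are the componentwise b and b'.
    """

    family_id: str
    lipschitz_L: float
    value: Callable[[np.ndarray, np.ndarray], float]
    gradient: Callable[[np.ndarray, np.ndarray], np.ndarray]
    inv_link: Callable[[np.ndarray], np.ndarray]
    cumulant: Callable[[np.ndarray], np.ndarray]
    cumulant_prime: Callable[[np.ndarray], np.ndarray]
    validate_Y: Callable[[np.ndarray], None]


def _check_eta(eta: np.ndarray) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta contains non-finite entries")
    return eta


def _gaussian_validate(Y: np.ndarray) -> None:
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y contains non-finite entries")


def _bernoulli_validate(Y: np.ndarray) -> None:
    _gaussian_validate(Y)
    if not np.isin(np.asarray(Y), (0.0, 1.0)).all():
        raise ValueError("bernoulli_logit outcomes must lie in {0, 1}")


_REGISTRY: dict[str, LossFamily] = {}


def register_family(family: LossFamily) -> None:
    if family.family_id in _REGISTRY:
        raise ValueError(f"family {family.family_id!r} already registered")
    _REGISTRY[family.family_id] = family


def get_family(family_id) -> LossFamily:
    """Look up a loss family by id (passing a LossFamily through unchanged)."""
    if isinstance(family_id, LossFamily):
        return family_id
    try:
        return _REGISTRY[family_id]
    except KeyError:
        raise KeyError(
            f"unknown loss family {family_id!r}; known: {sorted(_REGISTRY)}"
        ) from None


register_family(
    LossFamily(
        family_id="gaussian",
        lipschitz_L=1.0,
        value=lambda eta, Y: 0.5 * float(np.sum((Y - eta) ** 2)),
        gradient=lambda eta, Y: eta - Y,
        inv_link=lambda eta: np.asarray(eta, dtype=float),
        cumulant=lambda t: 0.5 * np.asarray(t, dtype=float) ** 2,
        cumulant_prime=lambda t: np.asarray(t, dtype=float),
        validate_Y=_gaussian_validate,
    )
)

register_family(
    LossFamily(
        family_id="bernoulli_logit",
        lipschitz_L=0.25,
        value=lambda eta, Y: float(np.sum(stable_softplus(eta)) - np.sum(Y * eta)),
        gradient=lambda eta, Y: expit(eta) - Y,
        inv_link=expit,
        cumulant=stable_softplus,
        cumulant_prime=expit,
        validate_Y=_bernoulli_validate,
    )
)


def loss_value(eta: np.ndarray, Y: np.ndarray, family) -> float:
    """Loss l(eta; Y) for the given family."""
    fam = get_family(family)
    eta = _check_eta(eta)
    fam.validate_Y(Y)
    return fam.value(eta, np.asarray(Y, dtype=float))


def loss_gradient(eta: np.ndarray, Y: np.ndarray, family) -> np.ndarray:
    """Gradient of the loss in eta, ``b'(eta) - Y`` in GLM form."""
    fam = get_family(family)
    eta = _check_eta(eta)
    fam.validate_Y(Y)
    return fam.gradient(eta, np.asarray(Y, dtype=float))


def pseudo_response(eta: np.ndarray, Y: np.ndarray, family, rho: float) -> np.ndarray:
    """Working response ``xi = eta - grad l(eta) / rho`` of the MM surrogate.

    With ``rho >= L`` each surrogate minimization is a constrained least
    squares in xi; for the gaussian family with rho = 1, xi = Y identically.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    fam = get_family(family)
    if rho < fam.lipschitz_L:
        warnings.warn(
            f"rho={rho} is below the gradient Lipschitz constant "
            f"L={fam.lipschitz_L}; monotone descent is no longer guaranteed",
            RuntimeWarning,
            stacklevel=2,
        )
    return _check_eta(eta) - fam.gradient(np.asarray(eta, dtype=float), np.asarray(Y, dtype=float)) / rho


def inverse_link(eta: np.ndarray, family) -> np.ndarray:
    """Map the linear predictor to the mean scale (g^{-1})."""
    fam = get_family(family)
    return fam.inv_link(_check_eta(eta))
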