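"""Distance-decay kernels for catchment weighting.

Within a catchment of radius ``d0`` the interaction between a demand point
and a facility is discounted by a decay weight ``f(d, d0) in [0, 1]``.  Two
kernels are provided:

* a truncated Gaussian — the continuous kernel used by the improved model,
  equal to 1 at ``d = 0`` and falling smoothly to exactly 0 at ``d = d0``;
* a dichotomous (binary) kernel — the classical floating-catchment weight,
  1 inside the catchment and 0 outside, used by the pre-optimization
  baseline variant.

Both kernels use the half-open catchment convention ``[0, d0)``: the weight
at ``d = d0`` is exactly 0, so the two kernels always agree on catchment
membership.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["DecayKind", "DecaySpec", "gaussian_decay", "binary_decay"]

#: e^{-1/2}, the Gaussian kernel's value at d = d0 before truncation.
_E_HALF = math.exp(-0.5)


class DecayKind(str, enum.Enum):
    """Available decay kernels (an extension point for further kernels)."""

    GAUSSIAN = "gaussian"
    BINARY = "binary"


@dataclass(frozen=True)
class DecaySpec:
    """A decay kernel together with its catchment radius.

    Parameters
    ----------
    kind:
        Which kernel to evaluate.
    d0:
        Catchment radius in meters; must be strictly positive.
    """

    kind: DecayKind
    d0: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", DecayKind(self.kind))
        if not (self.d0 > 0 and math.isfinite(self.d0)):
            raise ValueError(f"catchment radius d0 must be positive and finite, got {self.d0}")

    def __call__(self, d):
        """Evaluate the kernel at distance(s) ``d`` (scalar or array)."""
        if self.kind is DecayKind.GAUSSIAN:
            return gaussian_decay(d, self.d0)
        return binary_decay(d, self.d0)


def _check_args(d, d0: float) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if not (d0 > 0 and math.isfinite(d0)):
        raise ValueError(f"catchment radius d0 must be positive and finite, got {d0}")
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValueError("distances must be nonnegative and finite")
    return d


def gaussian_decay(d, d0: float):
    """Truncated Gaussian decay weight.

    For ``d < d0`` returns::

        (exp(-(1/2) (d/d0)^2) - exp(-1/2)) / (1 - exp(-1/2))

    and exactly 0 for ``d >= d0``.  The weight is 1 at ``d = 0``, strictly
    decreasing on ``[0, d0)``, and scale invariant: scaling ``d`` and ``d0``
    by the same factor leaves it unchanged.

    Parameters
    ----------
    d:
        Travel distance(s) in meters, scalar or array-like, ``>= 0``.
    d0:
        Catchment radius in meters, ``> 0``.

    Returns
    -------
    Weight(s) in ``[0, 1]``; scalar if ``d`` is scalar.
    """
    arr = _check_args(d, d0)
    with np.errstate(invalid="ignore"):
        w = (np.exp(-0.5 * (arr / d0) ** 2) - _E_HALF) / (1.0 - _E_HALF)
    w = np.where(arr >= d0, 0.0, w)
    return float(w) if np.isscalar(d) or getattr(d, "ndim", 1) == 0 else w


def binary_decay(d, d0: float):
    """Dichotomous decay weight: 1 for ``d < d0``, 0 for ``d >= d0``."""
    arr = _check_args(d, d0)
    w = np.where(arr < d0, 1.0, 0.0)
    return float(w) if np.isscalar(d) or getattr(d, "ndim", 1) == 0 else w
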