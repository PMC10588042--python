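"""Sigmoid Emax regression function and its parameter gradient.

The four-parameter sigmoid Emax (Hill) model describes a monotone
concentration-response relationship

    eta(x, theta) = E0 + x^h * Emax / (x^h + EC50^h),

where ``E0`` is the response at the placebo concentration ``x = 0``,
``Emax`` the maximal effect (negative for decreasing curves), ``EC50``
the concentration at which half of the maximal effect is reached, and
``h`` the Hill slope.  The design machinery in the rest of the package
only consumes the function/gradient pair, so other response families
could be plugged in, but only the sigmoid Emax model ships.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["EmaxParams", "eval_emax", "grad_emax"]


@dataclass(frozen=True)
class EmaxParams:
    """Parameter vector ``theta = (E0, Emax, EC50, h)`` of one curve.

    ``ec50`` and ``h`` must be strictly positive for evaluation.  A
    vector is *fit-admissible* when it also satisfies the parameter-space
    restriction ``EC50 in [0, 1000]`` and ``h in [0.05, 10]`` used to
    screen fitted curves: an EC50 outside the concentration range is not
    identifiable from data on that range.
    """

    e0: float
    emax: float
    ec50: float
    h: float

    def __post_init__(self) -> None:
        vals = (self.e0, self.emax, self.ec50, self.h)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite Emax parameters: {vals}")
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if self.h <= 0:
            raise ValueError(f"h must be > 0, got {self.h}")

    def as_array(self) -> np.ndarray:
        return np.array([self.e0, self.emax, self.ec50, self.h], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "EmaxParams":
        e0, emax, ec50, h = np.asarray(arr, dtype=float)
        return cls(e0, emax, ec50, h)

    def is_fit_admissible(self, ec50_max: float = 1000.0,
                          h_min: float = 0.05, h_max: float = 10.0) -> bool:
        return (self.ec50 <= ec50_max) and (h_min <= self.h <= h_max)


def _validate_x(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite concentration")
    if np.any(x < 0):
        raise ValueError("concentrations must be >= 0")
    return x


def _fraction(x: np.ndarray, theta: EmaxParams) -> np.ndarray:
    """x^h / (x^h + ec50^h), computed stably as a logistic in log-dose.

    Forming the ratio through ``expit(h * (ln x - ln ec50))`` avoids the
    overflow of x^h for h near 10 and x near 1000 (magnitudes ~1e30) and
    is exact in the limits x -> 0 and x -> inf.
    """
    f = np.zeros_like(x)
    pos = x > 0
    f[pos] = expit(theta.h * (np.log(x[pos]) - np.log(theta.ec50)))
    return f


def eval_emax(x, theta: EmaxParams):
    """Evaluate the sigmoid Emax curve at concentration(s) ``x >= 0``.

    Returns exactly ``E0`` at ``x = 0`` for any ``h > 0`` (explicit
    branch, no 0^h evaluation).
    """
    x = _validate_x(x)
    out = theta.e0 + theta.emax * _fraction(x, theta)
    return out if out.ndim else float(out)


def grad_emax(x, theta: EmaxParams):
    """Gradient of the curve w.r.t. ``(E0, Emax, EC50, h)``.

    With ``f = x^h / (x^h + EC50^h)`` the components are

        (1,  f,  -Emax*h*f*(1-f)/EC50,  Emax*f*(1-f)*ln(x/EC50)).

    At ``x = 0`` the limit ``(1, 0, 0, 0)`` is returned explicitly: every
    term carrying x^h vanishes and dominates the ln(x) singularity.
    Output shape is ``x.shape + (4,)`` (a 4-vector for scalar input).
    """
    x = _validate_x(x)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    f = _fraction(x, theta)
    g = np.empty(x.shape + (4,))
    g[..., 0] = 1.0
    g[..., 1] = f
    f1f = f * (1.0 - f)
    g[..., 2] = -theta.emax * theta.h * f1f / theta.ec50
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.where(x > 0, np.log(x / theta.ec50), 0.0)
    g[..., 3] = theta.emax * f1f * logratio
    # explicit limit at the placebo concentration
    g[x == 0] = np.array([1.0, 0.0, 0.0, 0.0])
    return g[0] if scalar else g
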