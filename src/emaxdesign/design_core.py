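"""Design algebra: approximate designs, information matrices, D-criterion,
D-efficiency and the sensitivity functions of the equivalence theorems.

An *approximate design* is a probability measure on the concentration
range [0, x_max]: support points x_1 < ... < x_n with positive weights
w_i summing to one.  Its information matrix for a curve with parameters
theta is

    M(xi, theta) = sum_i w_i g(x_i) g(x_i)^T,   g = grad_emax(., theta),

a symmetric PSD 4x4 matrix whose inverse governs the asymptotic
covariance of the maximum-likelihood estimator.  D-optimality maximizes
``psi_D = det(M)^(1/4)``; the pointwise sensitivity function

    d(x, xi, theta) = g(x)^T M^{-1} g(x) - 4

is <= 0 everywhere exactly when xi is locally D-optimal (general
equivalence theorem), and its ensemble analogue ``s`` certifies the
simultaneous criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

from .emax_model import EmaxParams, grad_emax

if TYPE_CHECKING:  # pragma: no cover
    from .optimal_design import ParamEnsemble

__all__ = [
    "Design",
    "SingularDesignError",
    "info_matrix",
    "d_criterion",
    "sensitivity_d",
    "d_efficiency",
    "sensitivity_s",
]

#: number of model parameters (E0, Emax, EC50, h)
P_DIM = 4

WEIGHT_SUM_TOL = 1e-10
#: M counts as singular when det(M) <= tol * prod(diag(M)).  The
#: Hadamard bound det <= prod(diag) makes this a relative measure, and
#: both sides scale identically (by c^4) when Emax is scaled by c, so
#: the classification -- and hence D-efficiency -- is invariant to the
#: linear parameters.  An absolute or trace-relative threshold fails
#: across the dynamic range induced by h in [0.05, 10].
SINGULAR_REL_TOL = 1e-12


class SingularDesignError(ValueError):
    """Raised when a sensitivity evaluation needs M^{-1} of a singular M."""


@dataclass(frozen=True)
class Design:
    """An approximate design: support concentrations with probability weights."""

    support: tuple
    weights: tuple
    x_max: float = 1000.0

    def __post_init__(self):
        sup = np.asarray(self.support, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if sup.ndim != 1 or sup.shape != w.shape or sup.size == 0:
            raise ValueError("support and weights must be equal-length 1-d sequences")
        if not (np.all(np.isfinite(sup)) and np.all(np.isfinite(w))):
            raise ValueError("non-finite design entries")
        if np.any(np.diff(sup) <= 0):
            raise ValueError("support must be strictly increasing")
        if sup[0] < 0 or sup[-1] > self.x_max:
            raise ValueError(f"support must lie in [0, {self.x_max}]")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        if abs(w.sum() - 1.0) > WEIGHT_SUM_TOL:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        object.__setattr__(self, "support", tuple(sup))
        object.__setattr__(self, "weights", tuple(w))

    @classmethod
    def create(cls, support, weights, x_max: float = 1000.0) -> "Design":
        """Build a design from raw optimizer output: sorts the points,
        merges points closer than ``1e-6 * x_max`` (adding their weights)
        and renormalizes the weights to sum to one."""
        return _clean(np.asarray(support, float), np.asarray(weights, float),
                      x_max, merge_tol=1e-6 * x_max, prune_tol=0.0)

    @property
    def n_points(self) -> int:
        return len(self.support)

    def support_array(self) -> np.ndarray:
        return np.asarray(self.support)

    def weights_array(self) -> np.ndarray:
        return np.asarray(self.weights)

    def cleaned(self, merge_tol: float | None = None,
                prune_tol: float = 1e-4) -> "Design":
        """Merge near-duplicate support points and drop negligible weights.

        Stochastic optimizers emit near-duplicate points; merging within
        ``merge_tol`` (default 1e-6 * x_max) and pruning weights below
        ``prune_tol`` (renormalizing) yields the clean printed form.
        """
        if merge_tol is None:
            merge_tol = 1e-6 * self.x_max
        return _clean(self.support_array(), self.weights_array(), self.x_max,
                      merge_tol=merge_tol, prune_tol=prune_tol)

    # ---- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"concentration": self.support, "weight": self.weights})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, x_max: float | None = None) -> "Design":
        df = pd.read_csv(path)
        if not {"concentration", "weight"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns 'concentration,weight'")
        w = df["weight"].to_numpy(float)
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError(f"{path}: weights sum to {w.sum()}, not 1")
        sup = df["concentration"].to_numpy(float)
        if x_max is None:
            x_max = max(1000.0, sup.max())
        return cls(tuple(sup), tuple(w / w.sum()), x_max)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"support": list(self.support),
                       "weights": list(self.weights),
                       "x_max": self.x_max}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Design":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(tuple(obj["support"]), tuple(obj["weights"]), obj["x_max"])


def _clean(sup: np.ndarray, w: np.ndarray, x_max: float,
           merge_tol: float, prune_tol: float) -> Design:
    order = np.argsort(sup, kind="stable")
    sup, w = sup[order], w[order]
    merged_x: list[float] = []
    merged_w: list[float] = []
    for xi, wi in zip(sup, w):
        if merged_x and xi - merged_x[-1] <= merge_tol:
            # weight-average the location so merging is symmetric
            tot = merged_w[-1] + wi
            merged_x[-1] = (merged_x[-1] * merged_w[-1] + xi * wi) / tot
            merged_w[-1] = tot
        else:
            merged_x.append(float(xi))
            merged_w.append(float(wi))
    x = np.array(merged_x)
    ww = np.array(merged_w)
    ww = ww / ww.sum()
    if prune_tol > 0:
        keep = ww >= prune_tol
        if not np.any(keep):
            raise ValueError("all weights pruned")
        x, ww = x[keep], ww[keep]
        ww = ww / ww.sum()
    np.clip(x, 0.0, x_max, out=x)
    return Design(tuple(x), tuple(ww), x_max)


# ---- information matrix and criteria -----------------------------------


def info_matrix(xi: Design, theta: EmaxParams) -> np.ndarray:
    """Information matrix ``M(xi, theta) = sum_i w_i g(x_i) g(x_i)^T``."""
    g = grad_emax(xi.support_array(), theta)          # (n, 4)
    m = (g * xi.weights_array()[:, None]).T @ g
    return 0.5 * (m + m.T)                            # exactly symmetric


def _det_psd(m: np.ndarray) -> float:
    """Determinant of a PSD matrix, 0 if singular relative to its scale."""
    det = float(np.linalg.det(m))
    scale = float(np.prod(np.diag(m)))
    if scale <= 0 or det <= SINGULAR_REL_TOL * scale:
        return 0.0
    return det


def d_criterion(xi: Design, theta: EmaxParams) -> float:
    """D-criterion ``psi_D = det(M(xi, theta))^(1/4)`` (0 when singular)."""
    return _det_psd(info_matrix(xi, theta)) ** (1.0 / P_DIM)


def _inverse_or_raise(m: np.ndarray, context: str = "design") -> np.ndarray:
    if _det_psd(m) == 0.0:
        raise SingularDesignError(
            f"information matrix is singular for {context}; "
            "sensitivity is undefined")
    return np.linalg.inv(m)


def sensitivity_d(x, xi: Design, theta: EmaxParams):
    """Equivalence-theorem sensitivity ``d(x, xi, theta) = g^T M^{-1} g - 4``.

    Nonpositive for all x in [0, x_max] iff ``xi`` is locally D-optimal
    for ``theta``; equals 0 at the support of the optimum.  Vectorized
    over x.
    """
    minv = _inverse_or_raise(info_matrix(xi, theta), f"theta={theta}")
    g = grad_emax(x, theta)
    quad = np.einsum("...i,ij,...j->...", g, minv, g)
    out = quad - P_DIM
    return float(out) if np.ndim(out) == 0 else out


def d_efficiency(xi: Design, theta: EmaxParams, xi_local_opt: Design) -> float:
    """D-efficiency ``psi_D(xi) / psi_D(xi*_theta)``, clamped to [0, 1].

    ``xi_local_opt`` must be the locally D-optimal design for ``theta``.
    The ratio is invariant to E0 and Emax (their scaling cancels).
    """
    denom = d_criterion(xi_local_opt, theta)
    if denom <= 0:
        raise ValueError("reference design has zero D-criterion value")
    return float(np.clip(d_criterion(xi, theta) / denom, 0.0, 1.0))


def sensitivity_s(x, xi: Design, ensemble: "ParamEnsemble",
                  local_opts: Mapping[str, Design]):
    """Simultaneous-criterion sensitivity

        s(x, xi, pi) = sum_theta pi(theta) Eff_D(xi, theta) d(x, xi, theta),

    nonpositive for all x iff ``xi`` maximizes the efficiency-averaged
    criterion.  ``local_opts`` maps each member label to its locally
    D-optimal design.  Vectorized over x.
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    total = np.zeros(x_arr.shape)
    for label, theta, pi in ensemble.items():
        if pi == 0.0:
            continue
        eff = d_efficiency(xi, theta, local_opts[label])
        try:
            total += pi * eff * sensitivity_d(x_arr, xi, theta)
        except SingularDesignError as err:
            raise SingularDesignError(
                f"singular information matrix for ensemble member "
                f"'{label}' ({theta})") from err
    return float(total[0]) if np.ndim(x) == 0 else total
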