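"""Benchmark design constructors and efficient rounding to N observations.

The catalog covers the standard comparison designs for concentration-
response experiments on [0, x_max]: the original VPA study design, the
equidistant design, and the log-equidistant design (placebo plus a
geometric progression).  ``efficient_rounding`` converts an approximate
design's weights into integer replication counts summing to the total
sample size N by the Pukelsheim-Rieder apportionment, which maximizes
the smallest realized-to-nominal weight ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design_core import Design

__all__ = [
    "ExactDesign",
    "equidistant_design",
    "log_equidistant_design",
    "original_vpa_design",
    "efficient_rounding",
]


@dataclass(frozen=True)
class ExactDesign:
    """A design realized as integer replication counts ``r_i`` per point."""

    support: tuple
    reps: tuple

    def __post_init__(self):
        sup = np.asarray(self.support, dtype=float)
        reps = np.asarray(self.reps)
        if sup.shape != reps.shape or sup.ndim != 1:
            raise ValueError("support and reps must be equal-length 1-d")
        if np.any(reps < 1) or not np.issubdtype(reps.dtype, np.integer):
            raise ValueError("reps must be positive integers")
        if np.any(np.diff(sup) <= 0):
            raise ValueError("support must be strictly increasing")
        object.__setattr__(self, "support", tuple(sup))
        object.__setattr__(self, "reps", tuple(int(r) for r in reps))

    @property
    def n_total(self) -> int:
        return int(sum(self.reps))

    def empirical_design(self, x_max: float = 1000.0) -> Design:
        """The approximate design with weights ``r_i / N``."""
        reps = np.asarray(self.reps, dtype=float)
        return Design(self.support, tuple(reps / reps.sum()),
                      max(x_max, self.support[-1]))

    def to_csv(self, path) -> None:
        pd.DataFrame({"concentration": self.support,
                      "replicates": self.reps}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ExactDesign":
        df = pd.read_csv(path)
        if not {"concentration", "replicates"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns "
                             "'concentration,replicates'")
        return cls(tuple(df["concentration"].astype(float)),
                   tuple(df["replicates"].astype(int)))


def equidistant_design(n_points: int = 9, x_max: float = 1000.0) -> Design:
    """Equal weights at 0, x_max/(n-1), ..., x_max."""
    if n_points < 2:
        raise ValueError("need at least 2 points")
    support = np.linspace(0.0, x_max, n_points)
    return Design(tuple(support), tuple(np.full(n_points, 1.0 / n_points)),
                  x_max)


def log_equidistant_design(n_points: int = 9, x_max: float = 1000.0,
                           x_min_pos: float = 1.0) -> Design:
    """Placebo 0 plus a geometric progression from x_min_pos to x_max.

    Support is kept at full precision; round for display only.  With the
    defaults the rounded support is (0, 1, 3, 7, 19, 52, 139, 373, 1000).
    """
    if not 0 < x_min_pos < x_max:
        raise ValueError("need 0 < x_min_pos < x_max")
    if n_points < 3:
        raise ValueError("need at least 3 points (placebo plus 2 positive)")
    positive = x_min_pos * (x_max / x_min_pos) ** (
        np.arange(n_points - 1) / (n_points - 2))
    support = np.concatenate([[0.0], positive])
    if np.any(np.diff(support) <= 0):
        raise ValueError("degenerate geometric progression "
                         "(duplicate support points)")
    return Design(tuple(support), tuple(np.full(n_points, 1.0 / n_points)),
                  x_max)


def original_vpa_design() -> Design:
    """The design of the original VPA study: 8 concentrations with the
    placebo weighted twice (2/9 at 0, 1/9 elsewhere)."""
    support = (0.0, 25.0, 150.0, 350.0, 450.0, 550.0, 800.0, 1000.0)
    weights = (2 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9)
    return Design(support, weights, 1000.0)


def efficient_rounding(xi: Design, n_total: int) -> ExactDesign:
    """Pukelsheim-Rieder efficient rounding of weights to N replications.

    Initialize ``r_i = ceil((N - n/2) * w_i)``; while the total differs
    from N, increment the index minimizing ``r_j / w_j`` (total too
    small) or decrement the index maximizing ``(r_j - 1) / w_j`` (total
    too large), ties broken by lowest index.  Every support point keeps
    at least one observation.
    """
    n_pts = xi.n_points
    if n_total < n_pts:
        raise ValueError(
            f"N={n_total} cannot give each of {n_pts} support points one "
            "observation")
    w = xi.weights_array()
    r = np.ceil((n_total - n_pts / 2) * w).astype(int)
    r = np.maximum(r, 1)
    while r.sum() < n_total:
        r[int(np.argmin(r / w))] += 1
    while r.sum() > n_total:
        j = int(np.argmax(np.where(r > 1, (r - 1) / w, -np.inf)))
        r[j] -= 1
    return ExactDesign(xi.support, tuple(int(v) for v in r))
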