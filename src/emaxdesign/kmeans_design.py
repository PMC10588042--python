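"""K-means cluster design built from many locally D-optimal designs.

When one design must serve many curves, the pooled support points of the
individual locally D-optimal designs summarize where observations are
informative.  The cluster design with ``L`` experimental conditions is
built in four steps:

1. Take the common support ``C0`` (points shared by every local design)
   and set ``K = L - |C0|``.
2. Cluster the remaining pooled support points (the union minus ``C0``,
   duplicates kept so frequent points weigh more) into ``K`` groups by
   1-D k-means and record the cluster means.
3. Repeat the clustering ``J`` times with fresh random initializations;
   average the sorted cluster centers position by position for
   robustness.
4. Return the equal-weight design (mass 1/L) on ``C0`` plus the ``K``
   averaged centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .design_core import Design

__all__ = ["KMeansConfig", "common_and_union_support", "build_kmeans_design"]


@dataclass(frozen=True)
class KMeansConfig:
    """Settings for the cluster-design construction.

    ``L`` is the total number of experimental conditions (at least the
    4 model parameters); ``J`` the number of clustering repetitions
    averaged for robustness; ``intersect_tol`` the concentration
    tolerance for membership in the common support (``None`` means
    ``1e-6 * x_max``, exact up to rounding since the shared boundary
    points are exact by construction).
    """

    L: int = 9
    J: int = 100
    seed: int = 0
    intersect_tol: float | None = None

    def __post_init__(self):
        if self.L < 4:
            raise ValueError("L must be >= 4 (the number of model parameters)")
        if self.J < 1:
            raise ValueError("J must be >= 1")


def common_and_union_support(local_designs: list[Design], tol: float = 1e-3,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Split the pooled supports into the common part and the rest.

    Returns ``(C0, C_minus_C0)``: ``C0`` holds the points present
    (within ``tol``) in *every* design's support, sorted; the second
    array pools all remaining support points of all designs with
    duplicates retained, so that clustering sees frequent points more
    often.
    """
    if not local_designs:
        raise ValueError("need at least one design")
    supports = [d.support_array() for d in local_designs]
    c0 = [x for x in supports[0]
          if all(np.min(np.abs(s - x)) <= tol for s in supports[1:])]
    c0 = np.asarray(sorted(c0))
    rest: list[float] = []
    for s in supports:
        for x in s:
            if c0.size == 0 or np.min(np.abs(c0 - x)) > tol:
                rest.append(float(x))
    return c0, np.asarray(rest)


def _cluster_centers(points: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Sorted means of a K-means partition of a 1-D point multiset."""
    km = KMeans(n_clusters=k, init="random", n_init=10,
                random_state=seed).fit(points.reshape(-1, 1))
    return np.sort(km.cluster_centers_.ravel())


def build_kmeans_design(local_designs: list[Design],
                        cfg: KMeansConfig | None = None) -> Design:
    """Equal-weight cluster design with ``cfg.L`` experimental conditions."""
    cfg = cfg or KMeansConfig()
    x_max = max(d.x_max for d in local_designs)
    tol = cfg.intersect_tol if cfg.intersect_tol is not None else 1e-6 * x_max
    c0, pooled = common_and_union_support(local_designs, tol)
    k = cfg.L - c0.size
    if k <= 0:
        raise ValueError(
            f"L={cfg.L} leaves no clusters: common support already has "
            f"{c0.size} points")
    if pooled.size == 0:
        raise ValueError("no support points outside the common support")
    if np.unique(pooled).size < k:
        raise ValueError(
            f"cannot form {k} clusters from {np.unique(pooled).size} "
            "distinct pooled points")
    sub_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.J)
    acc = np.zeros(k)
    for j in range(cfg.J):
        acc += _cluster_centers(pooled, k, int(sub_seeds[j] % 2**31))
    centers = acc / cfg.J
    support = np.sort(np.concatenate([c0, centers]))
    weights = np.full(cfg.L, 1.0 / cfg.L)
    return Design.create(support, weights, x_max)
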