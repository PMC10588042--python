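"""Solvers for locally D-optimal and simultaneous D-optimal designs.

The locally D-optimal design of the sigmoid Emax model on [0, x_max] is
known to have exactly four support points with equal weights 1/4, two of
which are the boundary points 0 and x_max; only the two interior points
depend on (EC50, h).  ``solve_local_d_optimal`` therefore optimizes a
2-dimensional problem and certifies the result with the equivalence
theorem.

For the simultaneous inference of many curves, a design is scored by the
prior-weighted mean of its D-efficiencies over a finite parameter
ensemble,

    Psi(xi, pi) = sum_theta pi(theta) * Eff_D(xi, theta)  in [0, 1],

which is concave in the design measure.  ``solve_simultaneous_d_optimal``
maximizes Psi by particle-swarm search over support points and weights,
followed by a deterministic polish (exact weight optimization by a
multiplicative algorithm, coordinate-wise support refinement, and
sensitivity-guided support addition) until the simultaneous equivalence
theorem certifies optimality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .design_core import (Design, SingularDesignError, d_criterion,
                          d_efficiency, sensitivity_d, sensitivity_s)
from .emax_model import EmaxParams, grad_emax

__all__ = [
    "ParamEnsemble",
    "OptimizerConfig",
    "VerificationReport",
    "NonConvergenceError",
    "theta7_ensemble",
    "solve_local_d_optimal",
    "compute_local_optima",
    "psi_criterion",
    "solve_simultaneous_d_optimal",
    "verify_local",
    "verify_simultaneous",
]

#: equivalence-theorem tolerance on the sensitivity value over the grid
SENSITIVITY_TOL = 1e-3
#: number of uniform grid points used for equivalence checks
VERIFY_GRID = 2001


@dataclass(frozen=True)
class ParamEnsemble:
    """A finite set of curve parameter vectors with a discrete prior."""

    labels: tuple
    thetas: tuple
    prior: tuple

    def __post_init__(self):
        if not (len(self.labels) == len(self.thetas) == len(self.prior)):
            raise ValueError("labels, thetas and prior must have equal length")
        if len(self.labels) == 0:
            raise ValueError("ensemble must be nonempty")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ensemble labels must be unique")
        pi = np.asarray(self.prior, dtype=float)
        if np.any(pi < 0):
            raise ValueError("prior weights must be nonnegative")
        if abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError(f"prior must sum to 1, got {pi.sum()!r}")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "thetas", tuple(self.thetas))
        object.__setattr__(self, "prior", tuple(float(p) for p in pi))

    def __len__(self) -> int:
        return len(self.labels)

    def items(self) -> Iterator[tuple[str, EmaxParams, float]]:
        return iter(zip(self.labels, self.thetas, self.prior))

    @classmethod
    def from_members(cls, members, prior=None) -> "ParamEnsemble":
        """Build from ``[(label, EmaxParams), ...]``; uniform prior if omitted."""
        labels, thetas = zip(*members)
        if prior is None:
            prior = np.full(len(labels), 1.0 / len(labels))
        return cls(tuple(labels), tuple(thetas), tuple(prior))

    @classmethod
    def singleton(cls, theta: EmaxParams, label: str = "theta") -> "ParamEnsemble":
        return cls((label,), (theta,), (1.0,))

    # ---- serialization: CSV "label,e0,emax,ec50,h[,prior]" -------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.labels,
            "e0": [t.e0 for t in self.thetas],
            "emax": [t.emax for t in self.thetas],
            "ec50": [t.ec50 for t in self.thetas],
            "h": [t.h for t in self.thetas],
            "prior": self.prior,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ParamEnsemble":
        df = pd.read_csv(path)
        required = {"label", "e0", "emax", "ec50", "h"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"{path}: expected columns 'label,e0,emax,ec50,h[,prior]'")
        if len(df) == 0:
            raise ValueError(f"{path}: ensemble file is empty")
        thetas = tuple(EmaxParams(r.e0, r.emax, r.ec50, r.h)
                       for r in df.itertuples())
        if "prior" in df.columns:
            pi = df["prior"].to_numpy(float)
            pi = pi / pi.sum()
        else:
            pi = np.full(len(df), 1.0 / len(df))
        return cls(tuple(str(l) for l in df["label"]), thetas, tuple(pi))


#: representative (EC50, h) vectors of the seven high-frequency cells of
#: the VPA gene-expression fits, with their readjusted relative
#: frequencies; linear parameters fixed to E0 = 1, Emax = -1.
THETA7_TABLE = (
    ("theta1", 298.81, 2.53, 0.1192),
    ("theta2", 575.00, 3.77, 0.1633),
    ("theta3", 758.84, 2.72, 0.0897),
    ("theta4", 469.36, 4.00, 0.1225),
    ("theta5", 310.60, 10.00, 0.2009),
    ("theta6", 501.97, 10.00, 0.2172),
    ("theta7", 747.88, 10.00, 0.0872),
)


def theta7_ensemble(e0: float = 1.0, emax: float = -1.0) -> ParamEnsemble:
    """The seven representative VPA parameter vectors with prior pi_7."""
    labels = tuple(row[0] for row in THETA7_TABLE)
    thetas = tuple(EmaxParams(e0, emax, row[1], row[2]) for row in THETA7_TABLE)
    prior = np.array([row[3] for row in THETA7_TABLE])
    return ParamEnsemble(labels, thetas, tuple(prior / prior.sum()))


@dataclass(frozen=True)
class OptimizerConfig:
    """Hyperparameters of the particle-swarm search and its polish."""

    swarm_size: int = 40
    iterations: int = 300
    restarts: int = 5
    seed: int = 0
    max_support: int = 12
    refine: bool = True

    def __post_init__(self):
        for name in ("swarm_size", "iterations", "restarts", "max_support"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class VerificationReport:
    passes: bool
    max_violation: float
    argmax_x: float

    def __iter__(self):  # allow tuple unpacking
        return iter((self.passes, self.max_violation, self.argmax_x))


class NonConvergenceError(RuntimeError):
    """Solver failed the equivalence check after all restarts."""

    def __init__(self, msg: str, best_design: Design, max_violation: float):
        super().__init__(f"{msg} (max sensitivity violation {max_violation:.3e})")
        self.best_design = best_design
        self.max_violation = max_violation


# ---- particle swarm (global-best, Clerc constriction defaults) ---------


def _pso_minimize(fun: Callable[[np.ndarray], float], lower: np.ndarray,
                  upper: np.ndarray, swarm_size: int, iterations: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Minimize ``fun`` over the box [lower, upper] with a seeded PSO."""
    dim = lower.size
    span = upper - lower
    pos = lower + rng.random((swarm_size, dim)) * span
    vel = (rng.random((swarm_size, dim)) - 0.5) * span
    pbest = pos.copy()
    pbest_val = np.array([fun(p) for p in pos])
    gi = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[gi].copy(), float(pbest_val[gi])
    w, c1, c2 = 0.7298, 1.49618, 1.49618
    for _ in range(iterations):
        r1 = rng.random((swarm_size, dim))
        r2 = rng.random((swarm_size, dim))
        vel = w * vel + c1 * r1 * (pbest - pos) + c2 * r2 * (gbest - pos)
        pos = np.clip(pos + vel, lower, upper)
        vals = np.array([fun(p) for p in pos])
        better = vals < pbest_val
        pbest[better] = pos[better]
        pbest_val[better] = vals[better]
        gi = int(np.argmin(pbest_val))
        if pbest_val[gi] < gbest_val:
            gbest, gbest_val = pbest[gi].copy(), float(pbest_val[gi])
    return gbest, gbest_val


# ---- locally D-optimal designs -----------------------------------------


def _local_design(x2: float, x3: float, x_max: float) -> Design:
    return Design.create([0.0, x2, x3, x_max], [0.25] * 4, x_max)


def _local_objective(theta: EmaxParams, x_max: float) -> Callable:
    def negcrit(z: np.ndarray) -> float:
        x2, x3 = float(min(z)), float(max(z))
        if x2 <= 0 or x3 >= x_max or x3 - x2 < 1e-9 * x_max:
            return 0.0
        xs = np.array([0.0, x2, x3, x_max])
        g = grad_emax(xs, theta)
        m = 0.25 * (g.T @ g)
        det = np.linalg.det(m)
        return -det if det > 0 else 0.0
    return negcrit


def solve_local_d_optimal(theta: EmaxParams, x_max: float = 1000.0,
                          cfg: OptimizerConfig | None = None) -> Design:
    """Locally D-optimal design for the sigmoid Emax model on [0, x_max].

    Exploits the proven structure {0, x2, x3, x_max} with equal weights
    1/4 and optimizes only the interior pair (x2, x3); the result is
    certified by the equivalence theorem (``verify_local``).
    """
    if x_max <= 0:
        raise ValueError("x_max must be > 0")
    cfg = cfg or OptimizerConfig()
    negcrit = _local_objective(theta, x_max)
    lower = np.array([1e-6 * x_max, 1e-6 * x_max])
    upper = np.array([(1 - 1e-6) * x_max, (1 - 1e-6) * x_max])
    best: Design | None = None
    best_violation = np.inf
    for r in range(cfg.restarts):
        rng = np.random.default_rng(cfg.seed + r)
        z, _ = _pso_minimize(negcrit, lower, upper, cfg.swarm_size,
                             cfg.iterations, rng)
        if cfg.refine:
            res = minimize(negcrit, z, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14,
                                    "maxiter": 2000})
            if res.fun < negcrit(z):
                z = res.x
        xi = _local_design(min(z), max(z), x_max)
        report = verify_local(xi, theta)
        if report.passes:
            return xi
        if report.max_violation < best_violation:
            best, best_violation = xi, report.max_violation
    raise NonConvergenceError(
        f"locally D-optimal solve failed for {theta}", best, best_violation)


def compute_local_optima(ensemble: ParamEnsemble, x_max: float = 1000.0,
                         cfg: OptimizerConfig | None = None,
                         ) -> dict[str, Design]:
    """Locally D-optimal designs for every ensemble member.

    Results are cached on (ec50, h) rounded to 1e-6: the optimal design
    does not depend on the linear parameters (E0, Emax), so large
    ensembles reuse solves.
    """
    cache: dict[tuple[float, float], Design] = {}
    out: dict[str, Design] = {}
    for label, theta, _ in ensemble.items():
        key = (round(theta.ec50, 6), round(theta.h, 6))
        if key not in cache:
            cache[key] = solve_local_d_optimal(theta, x_max, cfg)
        out[label] = cache[key]
    return out


# ---- simultaneous D-optimality -----------------------------------------


def psi_criterion(xi: Design, ensemble: ParamEnsemble,
                  local_opts: Mapping[str, Design]) -> float:
    """Efficiency-averaged criterion ``Psi = sum pi(theta) Eff_D(xi, theta)``."""
    total = 0.0
    for label, theta, pi in ensemble.items():
        if pi == 0.0:
            continue
        if label not in local_opts:
            raise KeyError(f"no locally optimal design supplied for '{label}'")
        total += pi * d_efficiency(xi, theta, local_opts[label])
    return float(total)


class _PsiEvaluator:
    """Fast Psi evaluation on raw (support, weight) arrays.

    Precomputes the prior/reference-criterion coefficients so a single
    evaluation costs one 4x4 determinant per ensemble member.
    """

    def __init__(self, ensemble: ParamEnsemble,
                 local_opts: Mapping[str, Design]):
        self.thetas = []
        self.coefs = []
        for label, theta, pi in ensemble.items():
            if pi == 0.0:
                continue
            denom = d_criterion(local_opts[label], theta)
            if denom <= 0:
                raise ValueError(
                    f"reference design for '{label}' has zero criterion")
            self.thetas.append(theta)
            self.coefs.append(pi / denom)

    def psi(self, xs: np.ndarray, ws: np.ndarray) -> float:
        total = 0.0
        for theta, c in zip(self.thetas, self.coefs):
            g = grad_emax(xs, theta)
            m = (g * ws[:, None]).T @ g
            det = np.linalg.det(m)
            if det > 0:
                total += c * det ** 0.25
        return float(total)

    def weight_gradient(self, xs: np.ndarray, ws: np.ndarray) -> np.ndarray:
        """dPsi/dw_i; satisfies sum_i w_i * grad_i = Psi."""
        grad = np.zeros_like(ws)
        for theta, c in zip(self.thetas, self.coefs):
            g = grad_emax(xs, theta)
            m = (g * ws[:, None]).T @ g
            det = np.linalg.det(m)
            if det <= 0:
                continue
            minv = np.linalg.inv(m)
            quad = np.einsum("ij,jk,ik->i", g, minv, g)
            grad += c * 0.25 * det ** 0.25 * quad
        return grad


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def _optimize_weights(ev: _PsiEvaluator, xs: np.ndarray, ws: np.ndarray,
                      max_iter: int = 5000, tol: float = 1e-13) -> np.ndarray:
    """Exact weight optimization for fixed support by the multiplicative
    algorithm ``w_i <- w_i * (dPsi/dw_i) / Psi`` (monotone for this
    concave D-type criterion)."""
    ws = ws.copy()
    for _ in range(max_iter):
        grad = ev.weight_gradient(xs, ws)
        psi = float(np.dot(ws, grad))
        if psi <= 0:
            break
        new = ws * grad / psi
        new /= new.sum()
        if np.max(np.abs(new - ws)) < tol:
            ws = new
            break
        ws = new
    return ws


def _refine_supports(ev: _PsiEvaluator, xs: np.ndarray, ws: np.ndarray,
                     x_max: float) -> np.ndarray:
    """One pass of coordinate-wise 1-D maximization of Psi over each
    non-boundary support point (boundary points 0 and x_max stay put)."""
    xs = xs.copy()
    for i in range(xs.size):
        if xs[i] <= 0.0 or xs[i] >= x_max:
            continue
        lo = 0.0 if i == 0 else xs[i - 1]
        hi = x_max if i == xs.size - 1 else xs[i + 1]

        def neg(x: float, i=i) -> float:
            trial = xs.copy()
            trial[i] = x
            return -ev.psi(trial, ws)

        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-7 * x_max})
        if -res.fun > ev.psi(xs, ws):
            xs[i] = float(res.x)
    return xs


def _polish_simultaneous(ev: _PsiEvaluator, xi: Design,
                         ensemble: ParamEnsemble,
                         local_opts: Mapping[str, Design], x_max: float,
                         max_rounds: int = 60) -> Design:
    """Deterministic polish: alternate exact weight optimization and
    coordinate support refinement; add the sensitivity argmax as a new
    support point whenever the equivalence check still fails."""
    xs = xi.support_array()
    ws = xi.weights_array()
    grid = np.linspace(0.0, x_max, VERIFY_GRID)
    for _ in range(max_rounds):
        # consolidate near-duplicate points left behind by the swarm so the
        # weight step does not split one optimal point's mass across two
        merged = Design.create(xs, ws, x_max).cleaned(
            merge_tol=1e-3 * x_max, prune_tol=0.0)
        xs, ws = merged.support_array(), merged.weights_array()
        ws = _optimize_weights(ev, xs, ws)
        # drop negligible mass before refining point locations
        keep = ws > 1e-7
        xs, ws = xs[keep], ws[keep] / ws[keep].sum()
        xs = _refine_supports(ev, xs, ws, x_max)
        order = np.argsort(xs)
        xs, ws = xs[order], ws[order]
        ws = _optimize_weights(ev, xs, ws)
        candidate = Design.create(xs, ws, x_max)
        try:
            s_grid = sensitivity_s(np.unique(np.concatenate([grid, xs])),
                                   candidate, ensemble, local_opts)
        except SingularDesignError:
            break
        j = int(np.argmax(s_grid))
        if s_grid[j] <= 0.5 * SENSITIVITY_TOL:
            return candidate
        x_new = float(np.unique(np.concatenate([grid, xs]))[j])
        if np.min(np.abs(xs - x_new)) < 1e-9 * x_max:
            # argmax already in the support: locations/weights are as
            # converged as the inner loops allow
            return candidate
        xs = np.append(xs, x_new)
        ws = np.append(ws * (1 - 1e-3), 1e-3)
        order = np.argsort(xs)
        xs, ws = xs[order], ws[order]
    return Design.create(xs, ws, x_max)


def solve_simultaneous_d_optimal(ensemble: ParamEnsemble,
                                 x_max: float = 1000.0,
                                 cfg: OptimizerConfig | None = None,
                                 local_opts: Mapping[str, Design] | None = None,
                                 ) -> Design:
    """Design maximizing the efficiency-averaged criterion Psi.

    Particle-swarm search jointly over up to ``cfg.max_support`` support
    points (the boundary points 0 and x_max are always candidates, with
    free weights) and weights parameterized through a softmax; the best
    particle is polished deterministically and the result certified by
    the simultaneous equivalence theorem (``verify_simultaneous``).
    Near-duplicate support points are merged and weights below 1e-4
    pruned before the design is returned.
    """
    cfg = cfg or OptimizerConfig()
    if local_opts is None:
        local_opts = compute_local_optima(ensemble, x_max, cfg)
    ev = _PsiEvaluator(ensemble, local_opts)

    k_free = max(cfg.max_support - 2, 1)

    def unpack(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xs = np.concatenate([[0.0], z[:k_free], [x_max]])
        ws = _softmax(z[k_free:])
        return xs, ws

    def neg(z: np.ndarray) -> float:
        xs, ws = unpack(z)
        return -ev.psi(xs, ws)

    dim = k_free + (k_free + 2)
    lower = np.concatenate([np.zeros(k_free), np.full(k_free + 2, -4.0)])
    upper = np.concatenate([np.full(k_free, x_max), np.full(k_free + 2, 4.0)])

    best_z, best_val = None, np.inf
    for r in range(cfg.restarts):
        rng = np.random.default_rng(cfg.seed + r)
        z, val = _pso_minimize(neg, lower, upper, cfg.swarm_size,
                               cfg.iterations, rng)
        if val < best_val:
            best_z, best_val = z, val

    xs, ws = unpack(best_z)
    xi = Design.create(xs, ws, x_max).cleaned(prune_tol=1e-4)
    if cfg.refine:
        xi = _polish_simultaneous(ev, xi, ensemble, local_opts, x_max)
    xi = xi.cleaned(prune_tol=1e-4)
    report = verify_simultaneous(xi, ensemble, local_opts)
    if not report.passes:
        raise NonConvergenceError(
            "simultaneous D-optimal solve failed the equivalence check",
            xi, report.max_violation)
    return xi


# ---- equivalence-theorem verification ----------------------------------


def _verification_grid(xi: Design) -> np.ndarray:
    grid = np.linspace(0.0, xi.x_max, VERIFY_GRID)
    return np.unique(np.concatenate([grid, xi.support_array()]))


def verify_local(xi: Design, theta: EmaxParams,
                 tol: float = SENSITIVITY_TOL) -> VerificationReport:
    """Grid-scan the local sensitivity d(x, xi, theta); passes iff the
    maximum over [0, x_max] (2001-point grid plus support) is <= tol."""
    grid = _verification_grid(xi)
    vals = sensitivity_d(grid, xi, theta)
    j = int(np.argmax(vals))
    return VerificationReport(bool(vals[j] <= tol), float(vals[j]),
                              float(grid[j]))


def verify_simultaneous(xi: Design, ensemble: ParamEnsemble,
                        local_opts: Mapping[str, Design],
                        tol: float = SENSITIVITY_TOL) -> VerificationReport:
    """Grid-scan of the simultaneous sensitivity s(x, xi, pi).

    A design whose information matrix is singular for some ensemble
    member has zero efficiency there and cannot be optimal, so that
    case reports a failed certificate (infinite violation) rather than
    raising.
    """
    grid = _verification_grid(xi)
    try:
        vals = sensitivity_s(grid, xi, ensemble, local_opts)
    except SingularDesignError:
        return VerificationReport(False, np.inf, np.nan)
    j = int(np.argmax(vals))
    return VerificationReport(bool(vals[j] <= tol), float(vals[j]),
                              float(grid[j]))
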