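"""Fitting parametric chain models to digest data by simulated annealing.

Two model families are fitted to the observed fragment-length distributions:

* H&C — a homogeneous Markov chain over S/U with transition matrix P that
  keeps the overall composition rho stationary (the balance equation
  rhoᵀ P = rhoᵀ), allowing blocks of sulfation but no positional trend;
* N&I — an independent-positions model with a composition profile Gamma
  whose rows 2..n average to rho, allowing positional trends but no blocks.

The fit objective is the sum of squared differences between observed and
predicted cap-pooled bin frequencies over all enzymes; it is zero iff the
model reproduces every bin. The objective is not convex in the parameters,
so it is minimized by simulated annealing with Gaussian perturbations,
Euclidean projection onto the constraint set after every perturbation, and
Metropolis acceptance under geometric cooling; many independent seeded
restarts are run and the best retained. Comparing the best achievable
objectives across model families (together with the nonparametric polytope
feasibility) is the elimination argument: homogeneity and independence can
each be rejected when their best fit stays bounded away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .digest_model import (
    expected_fragment_counts,
    hc_distribution,
    hi_distribution,
    ni_distribution,
)
from .measurements import MeasurementSet

__all__ = [
    "MarkovParams",
    "ProfileParams",
    "FitResult",
    "SAConfig",
    "digest_objective",
    "project_markov",
    "project_gamma",
    "fit_hc",
    "fit_ni",
]


@dataclass(frozen=True)
class MarkovParams:
    """H&C parameters: 2x2 transition matrix over (S, U), rho-stationary."""

    P: np.ndarray
    rho: tuple[float, float]

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (2, 2):
            raise ValueError("P must be 2x2")
        if np.any(P < -1e-8) or np.any(P > 1 + 1e-8):
            raise ValueError("P entries must lie in [0, 1]")
        if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("P rows must sum to 1 within 1e-8")
        rho = np.asarray(self.rho, dtype=float)
        if np.abs(rho @ P - rho).max() > 1e-8:
            raise ValueError("P must satisfy the balance equation rho^T P = rho^T")
        object.__setattr__(self, "P", P)


@dataclass(frozen=True)
class ProfileParams:
    """N&I parameters: n x 2 composition profile, rows 2..n averaging to rho."""

    Gamma: np.ndarray
    rho: tuple[float, float]

    def __post_init__(self) -> None:
        G = np.asarray(self.Gamma, dtype=float)
        if G.ndim != 2 or G.shape[1] != 2 or G.shape[0] < 3:
            raise ValueError("Gamma must be n x 2 with n >= 3")
        if np.any(G < -1e-8) or np.any(G > 1 + 1e-8):
            raise ValueError("Gamma entries must lie in [0, 1]")
        if np.any(np.abs(G.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("Gamma rows must sum to 1 within 1e-8")
        if np.abs(G[1:].mean(axis=0) - np.asarray(self.rho)).max() > 1e-8:
            raise ValueError("mean of Gamma rows 2..n must equal rho within 1e-8")
        object.__setattr__(self, "Gamma", G)

    @property
    def n(self) -> int:
        return self.Gamma.shape[0]


@dataclass(frozen=True)
class FitResult:
    """Best parameters over all restarts, with the per-restart best trace."""

    params: MarkovParams | ProfileParams
    objective: float
    trace: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be nonnegative")


@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing settings.

    ``restarts`` independent runs; each run visits ``n_temps`` temperature
    levels with ``steps_per_temp`` proposals per level, cooling
    geometrically by ``cooling``. The initial temperature is auto-tuned so
    that roughly ``accept_target`` of initial uphill moves are accepted.
    Proposals are additive Gaussian on the free parameters (initial sd
    ``sigma``, rescaled each level toward a moderate acceptance rate),
    projected back onto the constraint set before evaluation.
    """

    restarts: int = 100
    n_temps: int = 300
    steps_per_temp: int = 8
    cooling: float = 0.95
    sigma: float = 0.05
    accept_target: float = 0.8
    seed: int = 0


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------

def digest_objective(
    params: MarkovParams | ProfileParams | str, ms: MeasurementSet, n: int
) -> float:
    """Sum of squared bin differences between observed and model digests.

    ``params`` may be fitted H&C / N&I parameters or the string ``"hi"``
    for the parameter-free homogeneous-independent model. Zero iff the
    model reproduces every cap-pooled bin of every enzyme exactly.
    """
    total = 0.0
    for d in ms.digests:
        if isinstance(params, MarkovParams):
            g = hc_distribution(params.P, ms.table, n, d.enzyme, d.cap).g
        elif isinstance(params, ProfileParams):
            g = ni_distribution(params.Gamma, ms.table, n, d.enzyme, d.cap).g
        elif params == "hi":
            g = hi_distribution(ms.table, n, d.enzyme, d.cap).g
        else:
            raise TypeError(f"unsupported params {params!r}")
        total += float(((d.probs - g) ** 2).sum())
    return total


def _ni_objective_factory(ms: MeasurementSet, n: int):
    """Fast N&I objective over the free vector gamma_S for positions 2..n."""
    specs = []
    for d in ms.digests:
        cS, cU = ms.table.yields_[d.enzyme]
        alpha = (n - 1) * ms.table.mean_yield(d.enzyme)
        specs.append((cS, cU, d.cap, d.probs, alpha))

    def objective(gamma_s: np.ndarray) -> float:
        total = 0.0
        for cS, cU, cap, f, alpha in specs:
            c = cU + (cS - cU) * gamma_s
            q, _ = expected_fragment_counts(c, cap)
            g = q / alpha
            total += float(((f - g) ** 2).sum())
        return total

    return objective


def _hc_objective_factory(ms: MeasurementSet, n: int):
    rho = np.array(ms.table.rho)

    def objective(x: np.ndarray) -> float:
        P = x.reshape(2, 2)
        total = 0.0
        for d in ms.digests:
            g = hc_distribution(P, ms.table, n, d.enzyme, d.cap).g
            total += float(((d.probs - g) ** 2).sum())
        return total

    return objective


# ---------------------------------------------------------------------------
# Projections onto the parameter constraint sets
# ---------------------------------------------------------------------------

def project_markov(
    P_raw: np.ndarray,
    rho: tuple[float, float],
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> MarkovParams:
    """Euclidean projection onto the H&C constraint set.

    Dykstra alternating projections between the affine set {rows sum to 1,
    rhoᵀ P = rhoᵀ} (closed form) and the box [0, 1]^4.
    """
    rS, rU = rho
    M = np.array([
        [1.0, 1.0, 0.0, 0.0],   # row S sums to 1
        [0.0, 0.0, 1.0, 1.0],   # row U sums to 1
        [rS, 0.0, rU, 0.0],     # balance, S component
    ])
    v = np.array([1.0, 1.0, rS])
    MMinv = np.linalg.inv(M @ M.T)

    def proj_affine(y):
        return y - M.T @ (MMinv @ (M @ y - v))

    x = np.asarray(P_raw, dtype=float).ravel().copy()
    inc_a = np.zeros(4)
    inc_b = np.zeros(4)
    for _ in range(max_iter):
        y = proj_affine(x + inc_a)
        inc_a = x + inc_a - y
        x_new = np.clip(y + inc_b, 0.0, 1.0)
        inc_b = y + inc_b - x_new
        if np.abs(x_new - x).max() < tol and np.abs(M @ x_new - v).max() < tol:
            x = x_new
            break
        x = x_new
    else:
        raise RuntimeError("Dykstra projection did not converge")
    # snap residual affine drift (below tol) exactly
    x = np.clip(proj_affine(x), 0.0, 1.0)
    return MarkovParams(P=x.reshape(2, 2), rho=tuple(rho))


def _project_capped_mean(
    y: np.ndarray, target_mean: float, upper: np.ndarray, tol: float = 1e-13
) -> np.ndarray:
    """Euclidean projection of y onto {0 <= x <= upper, mean(x) = target}.

    The projection is x = clip(y - tau, 0, upper) with tau chosen by
    bisection (the mean is continuous and nonincreasing in tau).
    """
    if upper.mean() < target_mean - 1e-12:
        raise ValueError("caps make the mean constraint infeasible")
    lo = float(y.min() - upper.max() - 1.0)
    hi = float(y.max() + 1.0)
    for _ in range(200):
        tau = 0.5 * (lo + hi)
        m = np.clip(y - tau, 0.0, upper).mean()
        if m > target_mean:
            lo = tau
        else:
            hi = tau
        if hi - lo < tol:
            break
    return np.clip(y - 0.5 * (lo + hi), 0.0, upper)


def project_gamma(
    Gamma_raw: np.ndarray,
    rho: tuple[float, float],
    caps: dict[int, float] | None = None,
) -> ProfileParams:
    """Euclidean projection onto the N&I constraint set.

    Rows 2..n are projected onto {row sums to 1, entries in [0, 1], mean of
    S entries = rho(S), optional per-position caps on the S entry}; row 1
    (non-reducing end, unconstrained by data) is only projected onto the
    simplex.
    """
    G = np.asarray(Gamma_raw, dtype=float)
    n = G.shape[0]
    # within each row-sum-1 line, the free coordinate is the S proportion;
    # its closest point to row (a, b) is (a - b + 1)/2
    y = (G[:, 0] - G[:, 1] + 1.0) / 2.0
    upper = np.ones(n - 1)
    if caps:
        for pos, cap in caps.items():
            if not 2 <= pos <= n:
                raise ValueError(f"cap position {pos} outside 2..{n}")
            upper[pos - 2] = min(upper[pos - 2], float(cap))
    gs = np.empty(n)
    gs[0] = np.clip(y[0], 0.0, 1.0)
    gs[1:] = _project_capped_mean(y[1:], rho[0], upper)
    return ProfileParams(Gamma=np.column_stack([gs, 1.0 - gs]), rho=tuple(rho))


# ---------------------------------------------------------------------------
# Simulated-annealing engine
# ---------------------------------------------------------------------------

def _anneal_once(objective, project, x0, config: SAConfig,
                 rng: np.random.Generator):
    """One annealing run; returns (best_x, best_f)."""
    x = project(x0)
    f = objective(x)
    # auto-tune T0 from uphill probe moves around the start
    uphill = []
    for _ in range(32):
        cand = project(x + rng.normal(0.0, config.sigma, size=x.shape))
        df = objective(cand) - f
        if df > 0:
            uphill.append(df)
    T = (np.mean(uphill) / -np.log(config.accept_target)) if uphill else 1e-3
    best_x, best_f = x.copy(), f
    scale = 1.0
    for _ in range(config.n_temps):
        accepted = 0
        for _ in range(config.steps_per_temp):
            cand = project(x + rng.normal(0.0, config.sigma * scale,
                                          size=x.shape))
            fc = objective(cand)
            if fc <= f or rng.random() < np.exp(-(fc - f) / max(T, 1e-300)):
                x, f = cand, fc
                accepted += 1
                if f < best_f:
                    best_x, best_f = x.copy(), f
        # adapt the proposal scale toward a moderate acceptance rate so
        # late, cold levels refine instead of stalling
        rate = accepted / config.steps_per_temp
        if rate > 0.5:
            scale = min(scale * 1.15, 2.0)
        elif rate < 0.3:
            scale = max(scale * 0.85, 1e-4)
        T *= config.cooling
    return best_x, best_f


def fit_hc(ms: MeasurementSet, n: int, sa_config: SAConfig | None = None
           ) -> FitResult:
    """Best H&C transition matrix over seeded annealing restarts."""
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    config = sa_config or SAConfig()
    rho = ms.table.rho
    objective = _hc_objective_factory(ms, n)

    def project(x):
        return project_markov(x.reshape(2, 2), rho).P.ravel()

    trace = np.empty(config.restarts)
    best_x, best_f = None, np.inf
    for k, child in enumerate(np.random.SeedSequence(config.seed).spawn(config.restarts)):
        rng = np.random.default_rng(child)
        x0 = rng.random(4)
        xk, fk = _anneal_once(objective, project, x0, config, rng)
        trace[k] = fk
        if fk < best_f:
            best_x, best_f = xk, fk
    return FitResult(
        params=MarkovParams(P=best_x.reshape(2, 2), rho=rho),
        objective=best_f, trace=trace, seed=config.seed,
    )


def fit_ni(
    ms: MeasurementSet,
    n: int,
    sa_config: SAConfig | None = None,
    caps: dict[int, float] | None = None,
) -> FitResult:
    """Best N&I composition profile over seeded annealing restarts.

    ``caps`` optionally bounds the S proportion at given positions (e.g. a
    reducing-end cap derived from LP bounds), forwarded to the projection.
    """
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    config = sa_config or SAConfig()
    rho = ms.table.rho
    objective = _ni_objective_factory(ms, n)
    upper = np.ones(n - 1)
    if caps:
        for pos, cap in caps.items():
            if not 2 <= pos <= n:
                raise ValueError(f"cap position {pos} outside 2..{n}")
            upper[pos - 2] = min(upper[pos - 2], float(cap))

    def project(x):
        return _project_capped_mean(x, rho[0], upper)

    trace = np.empty(config.restarts)
    best_x, best_f = None, np.inf
    for k, child in enumerate(np.random.SeedSequence(config.seed).spawn(config.restarts)):
        rng = np.random.default_rng(child)
        x0 = rng.random(n - 1)
        xk, fk = _anneal_once(objective, project, x0, config, rng)
        trace[k] = fk
        if fk < best_f:
            best_x, best_f = xk, fk
    gamma_s = np.concatenate([[0.5], best_x])  # NRE row free; report 50/50
    return FitResult(
        params=ProfileParams(
            Gamma=np.column_stack([gamma_s, 1.0 - gamma_s]), rho=rho
        ),
        objective=best_f, trace=trace, seed=config.seed,
    )
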