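"""Feasibility, LP bounds and maximum-entropy estimation over the polytope.

The measurements define the polytope ``{p >= 0 : A p = b}`` of abundance
vectors compatible with all of them. This module answers three questions:

* is the polytope empty? — phase-I linear program with paired nonnegative
  artificial variables per row; the optimum is the L1 distance
  ``min_{p>=0} ||A p - b||_1`` ("infeasibility"), zero up to solver
  tolerance iff the measurements are mutually compatible;
* how much does the data pin down a linear property? — minimize and
  maximize the property over the polytope ("characterization extent");
* which single point to report? — the maximum-entropy vector p*, the
  unique entropy maximizer over the polytope, solved in the dual: with
  multipliers lambda per row, p_s ∝ exp((Aᵀ lambda)_s) and lambda is found
  by damped Newton on the log-partition objective (a geometric program in
  convex form, dimension = number of rows, not number of species).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog
from scipy.special import logsumexp

from .constraint_system import ConstraintSystem, assemble
from .measurements import MeasurementSet
from .species_space import SpeciesSpace, build_space

__all__ = [
    "MaxEntSolution",
    "BoundsProfile",
    "infeasibility",
    "feasibility_scan",
    "lp_extreme",
    "position_bounds",
    "bounds_profile",
    "solve_maxent",
    "marginal_profile",
    "transition_profile",
]

#: Infeasibility at or below this is treated as "numerical precision" (feasible).
FEASIBLE_TOL = 1e-8


class SolverError(RuntimeError):
    """LP or Newton solver failed to converge."""


@dataclass(frozen=True)
class MaxEntSolution:
    """Maximum-entropy abundance vector with its dual certificate."""

    p: np.ndarray
    dual: np.ndarray
    entropy: float
    residual: float


@dataclass(frozen=True)
class BoundsProfile:
    """Per-position [lower, upper] proportion bounds for one category."""

    positions: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    category: str
    alignment: str

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper + 1e-7):
            raise ValueError("lower bounds exceed upper bounds beyond LP tolerance")


def _scaled(cs: ConstraintSystem) -> tuple[sp.csr_matrix, np.ndarray]:
    """Scale rows to unit infinity norm (coefficients span orders of magnitude)."""
    A = cs.A.tocsr()
    norms = np.zeros(A.shape[0])
    for i in range(A.shape[0]):
        row = A.data[A.indptr[i] : A.indptr[i + 1]]
        norms[i] = np.abs(row).max() if row.size else 1.0
    norms[norms == 0] = 1.0
    D = sp.diags(1.0 / norms)
    return (D @ A).tocsr(), cs.b / norms


def infeasibility(cs: ConstraintSystem) -> float:
    """Phase-I optimum: min over p >= 0 of the L1 residual ||A p - b||_1.

    Computed on the row-scaled system via paired artificial variables
    (x+ and x- per row), so the value is an L1 distance in scaled units.
    """
    A, b = _scaled(cs)
    m, n = A.shape
    A_eq = sp.hstack([A, sp.eye(m), -sp.eye(m)], format="csc")
    c = np.concatenate([np.zeros(n), np.ones(2 * m)])
    res = linprog(c, A_eq=A_eq, b_eq=b, bounds=(0, None), method="highs")
    if res.status != 0:
        raise SolverError(f"phase-I LP failed: {res.message}")
    return float(res.fun)


def feasibility_scan(
    ms: MeasurementSet,
    n_range: tuple[int, int],
    parts=("norm", "composition", "digests"),
) -> pd.DataFrame:
    """Infeasibility per chain length n; marks the smallest feasible n.

    Returns a DataFrame with columns ``n``, ``infeasibility``, ``feasible``
    (infeasibility <= FEASIBLE_TOL).
    """
    lo, hi = n_range
    records = []
    for n in range(lo, hi + 1):
        space = build_space([n])
        cs = assemble(ms, space, parts=parts)
        records.append({"n": n, "infeasibility": infeasibility(cs)})
    df = pd.DataFrame.from_records(records)
    df["feasible"] = df["infeasibility"] <= FEASIBLE_TOL
    return df


def lp_extreme(cs: ConstraintSystem, objective: np.ndarray, sense: str) -> float:
    """Optimum of a linear functional of p over the polytope.

    ``sense`` is ``"min"`` or ``"max"``. Rows are unit-scaled before
    solving; only the optimal value is reported (alternative optima are
    irrelevant).
    """
    if sense not in ("min", "max"):
        raise ValueError(f"sense must be 'min' or 'max', got {sense!r}")
    A, b = _scaled(cs)
    c = np.asarray(objective, dtype=float)
    sign = 1.0 if sense == "min" else -1.0
    res = linprog(sign * c, A_eq=A, b_eq=b, bounds=(0, None), method="highs")
    if res.status == 2:
        raise SolverError("polytope is infeasible")
    if res.status != 0:
        raise SolverError(f"LP failed: {res.message}")
    return float(sign * res.fun)


def _indicator(space: SpeciesSpace, position: int, category: str,
               alignment: str) -> np.ndarray:
    """Per-species 0/1 weights: category at an (aligned) position.

    NRE alignment: position i counted from the non-reducing end; species
    shorter than i contribute 0. RE alignment: position j counted from the
    reducing end maps to i = len(s) - j + 1 per species.
    """
    if alignment not in ("nre", "re"):
        raise ValueError(f"alignment must be 'nre' or 're', got {alignment!r}")
    if category not in ("S", "U"):
        raise ValueError(f"unknown category {category!r}")
    ind = np.zeros(space.total)
    for n in space.lengths:
        i = position if alignment == "nre" else n - position + 1
        if not 1 <= i <= n:
            continue
        start, stop = space.block(n)
        bits = space.position_bits(n, i).astype(float)
        ind[start:stop] = bits if category == "S" else 1.0 - bits
    return ind


def position_bounds(
    cs: ConstraintSystem,
    space: SpeciesSpace,
    position: int,
    category: str,
    alignment: str = "nre",
) -> tuple[float, float]:
    """LP [lower, upper] bounds on the proportion of a category at a position.

    The objective is c_s = 1 iff species s has the category at the aligned
    position. For mixture spaces the proportion is conditional on chains
    long enough to have the position; the conditioning mass is fixed by the
    per-length rows (verified by two auxiliary LPs), so the conditional
    bounds are the unconditional optima divided by that mass.
    """
    ind = _indicator(space, position, category, alignment)
    lower = lp_extreme(cs, ind, "min")
    upper = lp_extreme(cs, ind, "max")
    has_pos = np.zeros(space.total)
    missing = False
    for n in space.lengths:
        i = position if alignment == "nre" else n - position + 1
        start, stop = space.block(n)
        if 1 <= i <= n:
            has_pos[start:stop] = 1.0
        else:
            missing = True
    if missing:
        d_lo = lp_extreme(cs, has_pos, "min")
        d_hi = lp_extreme(cs, has_pos, "max")
        if d_hi <= 1e-12:
            return (np.nan, np.nan)
        if d_hi - d_lo > 1e-6:
            raise SolverError(
                "conditioning mass is not pinned by the constraint system; "
                "add per-length rows before asking for aligned bounds"
            )
        lower, upper = lower / d_hi, upper / d_hi
    return (max(lower, 0.0), min(upper, 1.0))


def bounds_profile(
    cs: ConstraintSystem,
    space: SpeciesSpace,
    category: str = "S",
    alignment: str = "nre",
    positions=None,
) -> BoundsProfile:
    """Position-by-position LP bounds (the characterization-extent profile)."""
    if positions is None:
        positions = range(1, max(space.lengths) + 1)
    positions = np.asarray(list(positions))
    lo = np.empty(positions.size)
    hi = np.empty(positions.size)
    for k, i in enumerate(positions):
        lo[k], hi[k] = position_bounds(cs, space, int(i), category, alignment)
    return BoundsProfile(positions=positions, lower=lo, upper=hi,
                         category=category, alignment=alignment)


def solve_maxent(
    cs: ConstraintSystem,
    tol: float = 1e-9,
    max_iter: int = 200,
    lambda0: np.ndarray | None = None,
) -> MaxEntSolution:
    """Maximum-entropy abundance vector over the polytope, via the dual.

    Minimizes F(lambda) = log sum_s exp((Aᵀ lambda)_s) - lambdaᵀ b by damped
    Newton with log-sum-exp stabilization; normalization is built into the
    softmax so the sum-to-one row (if present) simply carries a zero
    gradient. Redundant rows make the Hessian singular; the Newton step is
    taken in the least-squares sense. Fails if the primal residual does not
    reach 1e-7.
    """
    A, b = _scaled(cs)
    m, nsp = A.shape
    lam = np.zeros(m) if lambda0 is None else np.asarray(lambda0, dtype=float)
    At = A.T.tocsr()

    def state(lam):
        eta = At @ lam
        lz = logsumexp(eta)
        p = np.exp(eta - lz)
        return p, float(lz - lam @ b)

    p, f = state(lam)
    for _ in range(max_iter):
        g = A @ p - b
        if np.abs(g).max() <= tol:
            break
        Ap = A @ p
        AW = A.multiply(p).tocsr()  # rows of A weighted by p
        H = (AW @ A.T).toarray() - np.outer(Ap, Ap)
        step = np.linalg.lstsq(H, -g, rcond=1e-12)[0]
        # backtracking line search on the dual objective
        t = 1.0
        while t > 1e-14:
            cand = lam + t * step
            p_c, f_c = state(cand)
            if f_c <= f + 1e-4 * t * (g @ step):
                lam, p, f = cand, p_c, f_c
                break
            t *= 0.5
        else:
            break
    resid = float(np.abs(cs.A @ p - cs.b).max())
    if resid > 1e-7:
        raise SolverError(
            f"maxent dual did not converge: primal residual {resid:.3e}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = float(-np.sum(np.where(p > 0, p * np.log(p), 0.0)))
    return MaxEntSolution(p=p, dual=lam, entropy=ent, residual=resid)


def marginal_profile(
    p: np.ndarray, space: SpeciesSpace, alignment: str = "nre"
) -> pd.DataFrame:
    """Per-position category proportions under an abundance vector.

    For mixtures, proportions at position i are conditioned on chains long
    enough to have that position.
    """
    p = np.asarray(p, dtype=float)
    rows = []
    for j in range(1, max(space.lengths) + 1):
        mass = 0.0
        s_mass = 0.0
        for n in space.lengths:
            i = j if alignment == "nre" else n - j + 1
            if not 1 <= i <= n:
                continue
            start, stop = space.block(n)
            block = p[start:stop]
            mass += block.sum()
            s_mass += float(block @ space.position_bits(n, i))
        rows.append({
            "position": j,
            "S": s_mass / mass if mass > 0 else np.nan,
            "U": 1.0 - s_mass / mass if mass > 0 else np.nan,
        })
    return pd.DataFrame.from_records(rows)


def transition_profile(
    p: np.ndarray, space: SpeciesSpace, alignment: str = "nre"
) -> pd.DataFrame:
    """Per-position transition probabilities P̂_i(a -> b) under p.

    Also reports the independence reference: the marginal at position i+1
    (what the transition would be absent correlation). Undefined entries
    (zero denominator) are NaN, not errors.
    """
    p = np.asarray(p, dtype=float)
    marg = marginal_profile(p, space, alignment)
    rows = []
    for j in range(1, max(space.lengths)):
        joint = np.zeros((2, 2))  # [a, b] with 0 = S, 1 = U
        for n in space.lengths:
            i = j if alignment == "nre" else n - j
            if not (1 <= i <= n - 1):
                continue
            start, stop = space.block(n)
            block = p[start:stop]
            bi = space.position_bits(n, i)
            bj = space.position_bits(n, i + 1)
            for a in (0, 1):
                for bb in (0, 1):
                    sel = (bi == (1 - a)) & (bj == (1 - bb))
                    joint[a, bb] += float(block[sel].sum())
        denom = joint.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = joint / denom[:, None]
        rows.append({
            "position": j,
            "S_to_S": P[0, 0], "S_to_U": P[0, 1],
            "U_to_S": P[1, 0], "U_to_U": P[1, 1],
            "indep_S": marg.loc[marg["position"] == j + 1, "S"].iloc[0]
            if alignment == "nre" else marg.loc[marg["position"] == j, "S"].iloc[0],
        })
    return pd.DataFrame.from_records(rows)
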