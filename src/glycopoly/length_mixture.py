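"""Chain-length distribution models and length-resolved mixture analyses.

Real chain mixtures have a spread of lengths. A :class:`LengthDistribution`
``w`` over lengths ``n- .. n+`` with a fixed mean plugs into the mixture
species space: one normalization row per length (block mass = w(n)) replaces
the single sum-to-one row, composition becomes a linearized ratio row, and
digest rows are built per length and stacked. The analyses here ask whether
the digest data force composition to vary with chain length, and extract
per-length composition summaries from fitted abundance vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .constraint_system import assemble
from .measurements import MeasurementSet
from .polytope_analysis import infeasibility
from .species_space import SpeciesSpace, build_space

__all__ = [
    "LengthDistribution",
    "gaussian_length_distribution",
    "per_length_composition",
    "equal_composition_feasibility",
]


@dataclass(frozen=True)
class LengthDistribution:
    """Probabilities w(n) over lengths with a fixed mean chain length."""

    lengths: tuple[int, ...]
    w: np.ndarray
    mean: float

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.size != len(self.lengths):
            raise ValueError("w and lengths must have equal size")
        if np.any(w < -1e-9):
            raise ValueError("w must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"w sums to {w.sum():.12g}")
        if abs(float(np.dot(self.lengths, w)) - self.mean) > 1e-9:
            raise ValueError("w does not achieve the target mean length")
        object.__setattr__(self, "w", np.clip(w, 0.0, None))


def gaussian_length_distribution(
    mean: float, sigma: float, n_min: int, n_max: int,
    tol: float = 1e-10, max_iter: int = 100_000,
) -> LengthDistribution:
    """Gaussian-binned length distribution projected onto its constraints.

    ``w(n)`` starts as the integral of a Gaussian(mean, sigma) density over
    [n, n+1), then is Euclidean-projected onto
    {w >= 0, sum w = 1, sum n w = mean} by Dykstra alternating projections
    between the affine set (closed form) and the nonnegative orthant.
    ``sigma = 0`` degenerates to a point mass at the mean.
    """
    if not n_min <= mean <= n_max:
        raise ValueError(f"mean {mean} outside [{n_min}, {n_max}]")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    lengths = np.arange(n_min, n_max + 1)
    if sigma == 0:
        w = (lengths == int(round(mean))).astype(float)
        return LengthDistribution(tuple(lengths), w, mean)
    edges = np.concatenate([lengths, [n_max + 1]])
    w0 = np.diff(norm.cdf(edges, loc=mean, scale=sigma))
    M = np.vstack([np.ones_like(lengths, dtype=float), lengths.astype(float)])
    v = np.array([1.0, mean])
    MMinv = np.linalg.inv(M @ M.T)

    def proj_affine(y):
        return y - M.T @ (MMinv @ (M @ y - v))

    x = w0.copy()
    inc = np.zeros_like(x)
    for _ in range(max_iter):
        y = proj_affine(x)
        x_new = np.clip(y + inc, 0.0, None)
        inc = y + inc - x_new
        if (np.abs(x_new - x).max() < tol
                and np.abs(M @ x_new - v).max() < tol):
            x = x_new
            break
        x = x_new
    else:
        raise RuntimeError("length-distribution projection did not converge")
    x = np.clip(x, 0.0, None)
    # snap the affine constraints exactly (drift is below tol)
    x = proj_affine(x)
    x = np.clip(x, 0.0, None)
    x /= x.sum()
    # final exact mean fix along the affine set stays nonneg for small drift
    x = proj_affine(x)
    return LengthDistribution(tuple(lengths), x, mean)


def per_length_composition(p: np.ndarray, space: SpeciesSpace) -> pd.DataFrame:
    """Mean S fraction over positions 2..n per chain length, under p.

    Zero-mass lengths are reported as NaN rather than raising.
    """
    p = np.asarray(p, dtype=float)
    rows = []
    for n in space.lengths:
        start, stop = space.block(n)
        block = p[start:stop]
        mass = block.sum()
        if mass <= 0:
            frac = np.nan
        else:
            frac = float(block @ space.s_counts(n)) / (n - 1) / mass
        rows.append({"n": n, "mass": mass, "S_fraction": frac})
    return pd.DataFrame.from_records(rows)


def equal_composition_feasibility(ms: MeasurementSet, w: LengthDistribution
                                  ) -> float:
    """Infeasibility when every chain length must share the overall rho.

    Builds {length rows, per-length composition rows, digest rows} over the
    mixture space and solves the phase-I LP. A value at numerical precision
    means the digests do not force composition to vary with length.
    """
    space = build_space(w.lengths)
    cs = assemble(
        ms, space,
        parts=("norm", "composition_per_length", "digests"),
        w=w.w,
    )
    return infeasibility(cs)
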