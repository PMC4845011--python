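"""Sparse linear constraint systems A p = b over a species space.

Every supported measurement becomes one or more linear equality rows on the
species-abundance vector ``p``:

* normalization (sum-to-one, or one row per chain length for mixtures),
* overall composition: sum_s r(s, S) p_s = rho(S) (n - 1) for a single
  length; for mixtures the ratio is linearized to the homogeneous row
  sum_s [r(s, S) - rho(S)(len(s) - 1)] p_s = 0,
* digest fragment-length frequencies, linearized per bin l to
  sum_s [q_z(s, l) - f_z(l) Q_z(s)] p_s = 0 (the denominator of the
  frequency — the expected total fragment count — depends on p, and this
  rearrangement restores exact linearity without approximation),
* positional homogeneity: sum_{s: d_i = S} p_s = rho(S) for i = 2..n.

Rows carry provenance labels. Digest rows for one enzyme sum to the zero row
(since sum_l q = Q and sum_l f = 1), a built-in rank deficiency of one per
enzyme that the numerical rank reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .digest_model import expected_fragment_counts_block
from .measurements import CategoryTable, MeasurementSet
from .species_space import SpeciesSpace

__all__ = [
    "ConstraintSystem",
    "composition_constraints",
    "digest_constraints",
    "homogeneity_constraints",
    "length_constraints",
    "sum_to_one_constraints",
    "per_length_composition_constraints",
    "assemble",
    "rank",
]

#: Column batch used when streaming species blocks into rows.
_BATCH = 1 << 16


@dataclass(frozen=True)
class ConstraintSystem:
    """Stacked constraint rows with provenance labels."""

    A: sp.csr_matrix
    b: np.ndarray
    row_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.A.shape[0] != len(self.row_labels) or self.A.shape[0] != self.b.size:
            raise ValueError("row count mismatch between A, b and labels")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("row labels must be unique")
        if not np.all(np.isfinite(self.A.data)) or not np.all(np.isfinite(self.b)):
            raise ValueError("non-finite coefficients")

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    def residual(self, p: np.ndarray) -> np.ndarray:
        return self.A @ p - self.b

    def stack(self, other: "ConstraintSystem") -> "ConstraintSystem":
        return ConstraintSystem(
            A=sp.vstack([self.A, other.A], format="csr"),
            b=np.concatenate([self.b, other.b]),
            row_labels=self.row_labels + other.row_labels,
        )


def _system(rows: list[np.ndarray | sp.spmatrix], b: list[float], labels: list[str],
            ncols: int) -> ConstraintSystem:
    mats = [sp.csr_matrix(r.reshape(1, -1)) if isinstance(r, np.ndarray) else r.tocsr()
            for r in rows]
    A = sp.vstack(mats, format="csr") if mats else sp.csr_matrix((0, ncols))
    return ConstraintSystem(A=A, b=np.asarray(b, dtype=float),
                            row_labels=tuple(labels))


def sum_to_one_constraints(space: SpeciesSpace) -> ConstraintSystem:
    """The normalization row 1ᵀ p = 1."""
    row = np.ones(space.total)
    return _system([row], [1.0], ["norm:sum_to_one"], space.total)


def length_constraints(space: SpeciesSpace, w: np.ndarray) -> ConstraintSystem:
    """One row per chain length: block mass = w(n). Subsumes sum-to-one."""
    w = np.asarray(w, dtype=float)
    if w.size != len(space.lengths):
        raise ValueError("w must be indexed by space.lengths")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"w sums to {w.sum():.12g}, expected 1")
    rows, b, labels = [], [], []
    for wn, n in zip(w, space.lengths):
        start, stop = space.block(n)
        data = np.ones(stop - start)
        rows.append(sp.csr_matrix((data, (np.zeros(stop - start, dtype=np.int64),
                                          np.arange(start, stop))),
                                  shape=(1, space.total)))
        b.append(float(wn))
        labels.append(f"length:n={n}")
    return _system(rows, b, labels, space.total)


def composition_constraints(space: SpeciesSpace, table: CategoryTable
                            ) -> ConstraintSystem:
    """Overall-composition row for category S (the U row is dependent)."""
    rho_S = table.rho[0]
    row = np.empty(space.total)
    single = len(space.lengths) == 1
    for n in space.lengths:
        start, stop = space.block(n)
        counts = space.s_counts(n).astype(float)
        row[start:stop] = counts if single else counts - rho_S * (n - 1)
    b = rho_S * (space.lengths[0] - 1) if single else 0.0
    return _system([row], [b], ["composition:S"], space.total)


def per_length_composition_constraints(space: SpeciesSpace, table: CategoryTable
                                       ) -> ConstraintSystem:
    """Equal overall composition for every chain length (one row per n)."""
    rho_S = table.rho[0]
    rows, b, labels = [], [], []
    for n in space.lengths:
        start, stop = space.block(n)
        data = space.s_counts(n).astype(float) - rho_S * (n - 1)
        rows.append(sp.csr_matrix((data, (np.zeros(stop - start, dtype=np.int64),
                                          np.arange(start, stop))),
                                  shape=(1, space.total)))
        b.append(0.0)
        labels.append(f"composition_per_length:S,n={n}")
    return _system(rows, b, labels, space.total)


def digest_constraints(space: SpeciesSpace, ms: MeasurementSet, enzyme: str
                       ) -> ConstraintSystem:
    """Linearized fragment-frequency rows, one per length bin l = 1..cap."""
    d = ms.digest(enzyme)
    yields = ms.table.yields_[enzyme]
    rows = np.zeros((d.cap, space.total))
    for n in space.lengths:
        start, _ = space.block(n)
        codes = space.codes(n)
        for lo in range(0, codes.size, _BATCH):
            batch = codes[lo : lo + _BATCH]
            q, Q = expected_fragment_counts_block(batch, n, yields, d.cap)
            cols = slice(start + lo, start + lo + batch.size)
            rows[:, cols] = (q - d.probs[None, :] * Q[:, None]).T
    labels = [f"digest:{enzyme},l={l}" for l in range(1, d.cap)]
    labels.append(f"digest:{enzyme},l>={d.cap}")
    A = sp.csr_matrix(rows)
    del rows
    return ConstraintSystem(A=A, b=np.zeros(d.cap), row_labels=tuple(labels))


def homogeneity_constraints(space: SpeciesSpace, table: CategoryTable
                            ) -> ConstraintSystem:
    """Same composition at every position i = 2..n (single-length spaces)."""
    if len(space.lengths) != 1:
        raise ValueError("homogeneity constraints are defined per fixed length")
    n = space.lengths[0]
    rho_S = table.rho[0]
    rows, b, labels = [], [], []
    for i in range(2, n + 1):
        rows.append(space.position_bits(n, i).astype(float))
        b.append(rho_S)
        labels.append(f"homogeneity:S,i={i}")
    return _system(rows, b, labels, space.total)


def assemble(
    ms: MeasurementSet,
    space: SpeciesSpace,
    parts: Sequence[str] = ("norm", "composition", "digests"),
    w: np.ndarray | None = None,
) -> ConstraintSystem:
    """Stack the requested constraint families over ``space``.

    Parts: ``norm`` (sum-to-one, or length rows when ``w`` is given),
    ``composition``, ``digests``, ``homogeneity``,
    ``composition_per_length``.
    """
    known = {"norm", "composition", "digests", "homogeneity",
             "composition_per_length"}
    bad = set(parts) - known
    if bad:
        raise ValueError(f"unknown parts {sorted(bad)}")
    pieces: list[ConstraintSystem] = []
    if "norm" in parts:
        pieces.append(length_constraints(space, w) if w is not None
                      else sum_to_one_constraints(space))
    if "composition" in parts:
        pieces.append(composition_constraints(space, ms.table))
    if "composition_per_length" in parts:
        pieces.append(per_length_composition_constraints(space, ms.table))
    if "homogeneity" in parts:
        pieces.append(homogeneity_constraints(space, ms.table))
    if "digests" in parts:
        for enzyme in ms.enzymes:
            pieces.append(digest_constraints(space, ms, enzyme))
    if not pieces:
        raise ValueError("no parts requested")
    if len(pieces) == 1:
        return pieces[0]
    return ConstraintSystem(
        A=sp.vstack([p.A for p in pieces], format="csr"),
        b=np.concatenate([p.b for p in pieces]),
        row_labels=tuple(lab for p in pieces for lab in p.row_labels),
    )


def rank(cs: ConstraintSystem, rtol: float = 1e-10) -> int:
    """Numerical row rank at relative tolerance ``rtol``.

    Rows are scaled to unit infinity norm first (digest coefficients span
    orders of magnitude), then singular values of the dense row matrix are
    thresholded at ``rtol * sigma_max``.
    """
    A = cs.A.toarray()
    norms = np.abs(A).max(axis=1)
    norms[norms == 0] = 1.0
    sv = scipy.linalg.svd(A / norms[:, None], compute_uv=False)
    if sv.size == 0 or sv[0] == 0:
        return 0
    return int(np.sum(sv > rtol * sv[0]))
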