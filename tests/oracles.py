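"""Independent brute-force reference implementations used only by tests.

Everything here enumerates explicitly — sequences as strings, cut patterns
as subsets — and never calls the package's vectorized code paths, so it can
serve as an oracle for them at small n.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog, minimize


def enumerate_sequences(n: int) -> list[str]:
    """All S/U sequences of length n in bit-code order (U=0, S=1, NRE = MSB)."""
    return ["".join(chars) for chars in itertools.product("US", repeat=n)]


def brute_fragment_counts(seq: str, yields: tuple[float, float], cap: int
                          ) -> tuple[np.ndarray, float]:
    """Expected counted-fragment counts by enumerating all cut patterns.

    Bonds sit on the non-reducing side of positions 2..n and are cut
    independently with probability c(d_i); the fragment containing position
    1 is dropped; lengths >= cap pool into the cap bin.
    """
    n = len(seq)
    c = [yields[0] if ch == "S" else yields[1] for ch in seq[1:]]
    q = np.zeros(cap)
    Q = 0.0
    for pattern in itertools.product([0, 1], repeat=n - 1):
        prob = 1.0
        for bond, cut in enumerate(pattern):
            prob *= c[bond] if cut else 1.0 - c[bond]
        if prob == 0.0:
            continue
        # fragment boundaries: chain start, cut bonds, chain end
        cuts = [i + 2 for i, cut in enumerate(pattern) if cut]  # positions
        boundaries = [1] + cuts + [n + 1]
        for k in range(1, len(boundaries) - 1):  # skip NRE fragment
            length = boundaries[k + 1] - boundaries[k]
            q[min(length, cap) - 1] += prob
            Q += prob
    return q, Q


def brute_digest_distribution(p: dict[str, float], yields, cap: int
                              ) -> np.ndarray:
    """Mixture digest distribution from explicit abundances over sequences."""
    q_tot = np.zeros(cap)
    Q_tot = 0.0
    for seq, ps in p.items():
        q, Q = brute_fragment_counts(seq, yields, cap)
        q_tot += ps * q
        Q_tot += ps * Q
    return q_tot / Q_tot


def brute_constraint_system(ms, n: int, parts=("norm", "composition", "digests")):
    """Dense A, b built from explicit sequence strings (single length)."""
    seqs = enumerate_sequences(n)
    rows, b = [], []
    if "norm" in parts:
        rows.append([1.0] * len(seqs))
        b.append(1.0)
    if "composition" in parts:
        rows.append([float(s.count("S", 1)) for s in seqs])
        b.append(ms.table.rho[0] * (n - 1))
    if "homogeneity" in parts:
        for i in range(2, n + 1):
            rows.append([1.0 if s[i - 1] == "S" else 0.0 for s in seqs])
            b.append(ms.table.rho[0])
    if "digests" in parts:
        for d in ms.digests:
            qs = [brute_fragment_counts(s, ms.table.yields_[d.enzyme], d.cap)
                  for s in seqs]
            for l in range(1, d.cap + 1):
                rows.append([q[l - 1] - d.probs[l - 1] * Q for q, Q in qs])
                b.append(0.0)
    return np.array(rows), np.array(b)


def brute_infeasibility(A: np.ndarray, b: np.ndarray) -> float:
    """min_{p>=0} ||Ap - b||_1 on the dense, row-scaled system."""
    norms = np.abs(A).max(axis=1)
    norms[norms == 0] = 1.0
    A = A / norms[:, None]
    b = b / norms
    m, n = A.shape
    A_eq = np.hstack([A, np.eye(m), -np.eye(m)])
    c = np.r_[np.zeros(n), np.ones(2 * m)]
    res = linprog(c, A_eq=A_eq, b_eq=b, bounds=(0, None), method="highs")
    assert res.status == 0
    return float(res.fun)


def brute_bounds(A, b, objective, ) -> tuple[float, float]:
    outs = []
    for sign in (1.0, -1.0):
        res = linprog(sign * np.asarray(objective), A_eq=A, b_eq=b,
                      bounds=(0, None), method="highs")
        assert res.status == 0
        outs.append(sign * res.fun)
    return outs[0], outs[1]


def brute_maxent(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Primal maximum-entropy solve by SLSQP (tiny spaces only)."""
    m, nsp = A.shape
    x0 = np.full(nsp, 1.0 / nsp)

    def negent(p):
        p = np.clip(p, 1e-300, None)
        return float(np.sum(p * np.log(p)))

    def grad(p):
        return np.log(np.clip(p, 1e-300, None)) + 1.0

    res = minimize(
        negent, x0, jac=grad, method="SLSQP",
        constraints=[{"type": "eq", "fun": lambda p: A @ p - b,
                      "jac": lambda p: A}],
        bounds=[(0.0, 1.0)] * nsp,
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success, res.message
    return res.x
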