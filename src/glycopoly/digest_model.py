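"""Cleavage calculus for enzymatic digests of linear S/U chains.

Cleavage convention
-------------------
For a chain ``d_1 .. d_n`` (position 1 = non-reducing end), an enzyme cuts the
bond on the *non-reducing side* of disaccharide ``d_i`` independently with
probability ``c(d_i)``, for ``i = 2..n``. After cutting, the fragment that
contains position 1 is discarded (it is not counted experimentally); every
other fragment starts at a cut. The expected number of counted fragments of
length ``l`` from sequence ``s`` is

    q(s, l) = sum_{i=2..n-l+1} c_i * prod_{k=i+1..i+l-1} (1 - c_k)
              * (c_{i+l} if i+l <= n else 1)

with ``c_i = c(d_i)``, and the total satisfies the cut-counting identity
``Q(s) = sum_l q(s, l) = sum_{i=2..n} c_i`` (each cut starts exactly one
counted fragment). Lengths >= the cap are pooled into the cap bin, at the
expected-count level, before any normalization.

Closed-form digest distributions are provided for three parametric chain
models — homogeneous independent (H&I), homogeneous Markov (H&C), and
position-dependent independent (N&I) — plus a generic (possibly
nonhomogeneous) Markov route used for N&C ground truths. A seeded
Monte-Carlo simulator serves as the brute-force oracle for all of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .measurements import CategoryTable, MeasurementSet

__all__ = [
    "FragmentLengthDistribution",
    "cut_probs",
    "expected_fragment_counts",
    "expected_fragment_counts_block",
    "hi_distribution",
    "hc_distribution",
    "ni_distribution",
    "markov_digest_distribution",
    "simulate_digest",
    "sample_chains_iid",
    "sample_chains_profile",
    "sample_chains_markov",
    "sample_chains_from_p",
    "log_linear_r2",
]


@dataclass(frozen=True)
class FragmentLengthDistribution:
    """Cap-pooled fragment-length distribution g(l) for one enzyme."""

    enzyme: str
    cap: int
    g: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        if g.size != self.cap:
            raise ValueError(f"g must have length cap={self.cap}")
        if np.any(g < -1e-12):
            raise ValueError("negative probability in fragment distribution")
        if abs(g.sum() - 1.0) > 1e-9:
            raise ValueError(f"fragment distribution sums to {g.sum():.12g}")
        object.__setattr__(self, "g", g)


def _pool(values: np.ndarray, cap: int) -> np.ndarray:
    """Pool entries for lengths >= cap into the cap bin (1-based lengths)."""
    out = np.zeros(cap)
    m = min(cap - 1, values.size)
    out[:m] = values[:m]
    out[cap - 1] = values[cap - 1 :].sum()
    return out


def cut_probs(sequence: str, yields: tuple[float, float]) -> np.ndarray:
    """Vector c_2..c_n of bond-cut probabilities for one sequence."""
    cS, cU = yields
    return np.array([cS if ch == "S" else cU for ch in sequence[1:]])


def expected_fragment_counts(
    c: np.ndarray, cap: int
) -> tuple[np.ndarray, float]:
    """Expected counted-fragment counts (q, Q) from cut probabilities c_2..c_n.

    ``q`` is cap-pooled; ``Q = q.sum() = c.sum()`` exactly.
    """
    if cap < 2:
        raise ValueError(f"cap must be >= 2, got {cap}")
    c = np.asarray(c, dtype=float)
    nb = c.size  # number of cuttable bonds = n - 1
    q = np.zeros(cap)
    for j in range(nb):  # fragment starting at position i = j + 2
        r = c[j]
        l = 1
        while True:
            if j + l <= nb - 1:  # a bond follows the fragment
                q[min(l, cap) - 1] += r * c[j + l]
                r *= 1.0 - c[j + l]
                l += 1
            else:  # fragment runs to the reducing end
                q[min(l, cap) - 1] += r
                break
    return q, float(c.sum())


def expected_fragment_counts_block(
    codes: np.ndarray, n: int, yields: tuple[float, float], cap: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (q, Q) for a batch of bit-coded species of length ``n``.

    Returns ``q`` of shape (len(codes), cap) and ``Q`` of shape (len(codes),).
    Bit convention: S -> 1, position 1 = most significant bit.
    """
    if cap < 2:
        raise ValueError(f"cap must be >= 2, got {cap}")
    cS, cU = yields
    codes = np.asarray(codes)
    nb = n - 1
    # bond matrix: column j is the cut probability at position i = j + 2
    bits = ((codes[:, None] >> np.arange(nb - 1, -1, -1)[None, :]) & 1).astype(float)
    c = cU + (cS - cU) * bits
    q = np.zeros((codes.size, cap))
    for j in range(nb):
        r = c[:, j].copy()
        l = 1
        while True:
            if j + l <= nb - 1:
                q[:, min(l, cap) - 1] += r * c[:, j + l]
                r *= 1.0 - c[:, j + l]
                l += 1
            else:
                q[:, min(l, cap) - 1] += r
                break
    return q, c.sum(axis=1)


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def hi_distribution(
    table: CategoryTable, n: int, enzyme: str, cap: int
) -> FragmentLengthDistribution:
    """Digest distribution under the homogeneous-independent (H&I) model.

    With every position 2..n drawn i.i.d. from rho, cuts are i.i.d.
    Bernoulli(cbar) and the uncapped distribution is

        g(l) = (1 - cbar)^(l-1) * [(n - l - 1) cbar + 1] / (n - 1)

    for 1 <= l <= n-1, then cap-pooled.
    """
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    cbar = table.mean_yield(enzyme)
    ls = np.arange(1, n)
    g = (1.0 - cbar) ** (ls - 1) * ((n - ls - 1) * cbar + 1.0) / (n - 1)
    return FragmentLengthDistribution(enzyme=enzyme, cap=cap, g=_pool(g, cap))


def markov_digest_distribution(
    marginal2: np.ndarray,
    transitions: np.ndarray,
    yields: tuple[float, float],
    n: int,
    enzyme: str,
    cap: int,
) -> FragmentLengthDistribution:
    """Exact digest distribution for a (possibly nonhomogeneous) Markov chain.

    ``marginal2`` is the (S, U) marginal at position 2; ``transitions`` has
    shape (n-2, 2, 2) with ``transitions[k]`` mapping position k+2 to k+3.
    Expected fragment counts are accumulated by propagating 2-vectors through
    diag(c) / diag(1-c) cut events; the result is normalized by the expected
    total count alpha = sum_i mu_i . c.
    """
    mu = np.asarray(marginal2, dtype=float)
    P = np.asarray(transitions, dtype=float)
    if P.shape != (n - 2, 2, 2):
        raise ValueError(f"transitions must have shape {(n - 2, 2, 2)}")
    if np.any(np.abs(P.sum(axis=2) - 1.0) > 1e-8):
        raise ValueError("transition rows must sum to 1 within 1e-8")
    c = np.array(yields, dtype=float)
    # marginals at positions 2..n
    marginals = np.empty((n - 1, 2))
    marginals[0] = mu
    for k in range(n - 2):
        marginals[k + 1] = marginals[k] @ P[k]
    alpha = float((marginals * c).sum())
    q = np.zeros(max(cap, n - 1))
    for j in range(n - 1):  # start position i = j + 2
        v = marginals[j] * c
        l = 1
        while True:
            if j + l <= n - 2:  # bond follows: transition to position i + l
                w = v @ P[j + l - 1]
                q[l - 1] += float(w @ c)
                v = w * (1.0 - c)
                l += 1
            else:
                q[l - 1] += float(v.sum())
                break
    if alpha <= 0:
        raise ValueError("model has zero expected cut count")
    return FragmentLengthDistribution(enzyme=enzyme, cap=cap, g=_pool(q / alpha, cap))


def hc_distribution(
    P: np.ndarray, table: CategoryTable, n: int, enzyme: str, cap: int
) -> FragmentLengthDistribution:
    """Digest distribution under the homogeneous Markov (H&C) model.

    Chains carry the overall composition rho at position 2 and evolve by the
    single transition matrix ``P`` (which should satisfy the balance equation
    so that rho is stationary).
    """
    P = np.asarray(P, dtype=float)
    if P.shape != (2, 2):
        raise ValueError("P must be 2x2")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("P rows must sum to 1 within 1e-8")
    transitions = np.broadcast_to(P, (n - 2, 2, 2))
    return markov_digest_distribution(
        np.array(table.rho), transitions, table.yields_[enzyme], n, enzyme, cap
    )


def ni_distribution(
    gamma: np.ndarray, table: CategoryTable, n: int, enzyme: str, cap: int
) -> FragmentLengthDistribution:
    """Digest distribution under the nonhomogeneous-independent (N&I) model.

    ``gamma`` has shape (n, 2): row i-1 is the (S, U) composition at position
    i. Row 0 (non-reducing end) does not enter the calculation. Positions are
    independent, so the expected counts are the single-species formula
    evaluated at c_i = sum_b c(b) Gamma_i(b), normalized by
    alpha = (n - 1) cbar with cbar from the overall composition.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (n, 2):
        raise ValueError(f"gamma must have shape {(n, 2)}")
    if np.any(np.abs(gamma[1:].sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("gamma rows 2..n must sum to 1 within 1e-8")
    cS, cU = table.yields_[enzyme]
    c = gamma[1:, 0] * cS + gamma[1:, 1] * cU  # c_i for i = 2..n
    q, _ = expected_fragment_counts(c, max(cap, 2))
    if q.size < cap:
        q = np.concatenate([q, np.zeros(cap - q.size)])
    alpha = (n - 1) * table.mean_yield(enzyme)
    return FragmentLengthDistribution(enzyme=enzyme, cap=cap, g=_pool(q / alpha, cap))


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

ChainSampler = Callable[[np.random.Generator, int], np.ndarray]


def sample_chains_iid(n: int, rho_S: float) -> ChainSampler:
    """Sampler of i.i.d. chains: bits (1 = S) for positions 2..n."""

    def sample(rng: np.random.Generator, m: int) -> np.ndarray:
        return (rng.random((m, n - 1)) < rho_S).astype(np.uint8)

    return sample


def sample_chains_profile(gamma_S: np.ndarray) -> ChainSampler:
    """Independent positions with per-position S proportions gamma_S[i-1]."""
    g = np.asarray(gamma_S, dtype=float)[1:]  # positions 2..n

    def sample(rng: np.random.Generator, m: int) -> np.ndarray:
        return (rng.random((m, g.size)) < g[None, :]).astype(np.uint8)

    return sample


def sample_chains_markov(
    marginal2: np.ndarray, transitions: np.ndarray, n: int
) -> ChainSampler:
    """Markov chains over positions 2..n (state 0 = S, 1 = U in bit terms 1/0)."""
    mu = np.asarray(marginal2, dtype=float)
    P = np.asarray(transitions, dtype=float).reshape(n - 2, 2, 2)

    def sample(rng: np.random.Generator, m: int) -> np.ndarray:
        bits = np.empty((m, n - 1), dtype=np.uint8)
        bits[:, 0] = rng.random(m) < mu[0]
        for k in range(n - 2):
            p_s = np.where(bits[:, k] == 1, P[k, 0, 0], P[k, 1, 0])
            bits[:, k + 1] = rng.random(m) < p_s
        return bits

    return sample


def sample_chains_from_p(p: np.ndarray, n: int) -> ChainSampler:
    """Sampler drawing species indices from an explicit abundance vector."""
    p = np.asarray(p, dtype=float)
    if p.size != 1 << n:
        raise ValueError(f"p must have 2**{n} entries")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must be a normalized abundance vector")
    pp = np.clip(p, 0.0, None)
    pp /= pp.sum()
    shifts = np.arange(n - 2, -1, -1)

    def sample(rng: np.random.Generator, m: int) -> np.ndarray:
        idx = rng.choice(p.size, size=m, p=pp)
        return ((idx[:, None] >> shifts[None, :]) & 1).astype(np.uint8)

    return sample


def simulate_digest(
    sample: ChainSampler,
    yields: tuple[float, float],
    n: int,
    cap: int,
    reps: int,
    seed: int,
    enzyme: str = "sim",
    batch: int = 200_000,
) -> FragmentLengthDistribution:
    """Empirical digest distribution by direct simulation (the oracle).

    Draws ``reps`` chains, cuts each bond independently with probability
    c(d_i), discards the fragment containing position 1, and tallies counted
    fragment lengths into cap bins. Reproducible given ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    cS, cU = yields
    counts = np.zeros(cap, dtype=np.int64)
    done = 0
    while done < reps:
        m = min(batch, reps - done)
        bits = sample(rng, m)
        if bits.shape != (m, n - 1):
            raise ValueError("sampler must return (reps, n-1) category bits")
        c = np.where(bits == 1, cS, cU)
        cuts = rng.random((m, n - 1)) < c
        # boundary grid: col 0 = chain start, cols 1..n-1 = bonds, col n = end
        B = np.ones((m, n + 1), dtype=bool)
        B[:, 1:n] = cuts
        idx = np.flatnonzero(B.ravel())
        lengths = np.diff(idx)
        startcol = idx[:-1] % (n + 1)
        keep = (startcol >= 1) & (startcol <= n - 1)
        lengths = np.minimum(lengths[keep], cap)
        counts += np.bincount(lengths, minlength=cap + 1)[1 : cap + 1]
        done += m
    total = counts.sum()
    if total == 0:
        return FragmentLengthDistribution(
            enzyme=enzyme, cap=cap, g=np.r_[1.0, np.zeros(cap - 1)]
        )
    return FragmentLengthDistribution(enzyme=enzyme, cap=cap, g=counts / total)


def mix_over_lengths(
    dists: Sequence[FragmentLengthDistribution],
    alphas: Sequence[float],
    weights: Sequence[float],
) -> FragmentLengthDistribution:
    """Pool per-length digest distributions into a mixture distribution.

    Fragment *counts* (weight x expected count alpha x per-length g) are
    pooled before renormalizing, so long chains contribute proportionally
    to the fragments they shed, not one vote per chain.
    """
    if not dists:
        raise ValueError("need at least one distribution")
    cap = dists[0].cap
    if any(d.cap != cap for d in dists):
        raise ValueError("all distributions must share the cap")
    q = np.zeros(cap)
    for d, a, w in zip(dists, alphas, weights):
        q += w * a * d.g
    return FragmentLengthDistribution(
        enzyme=dists[0].enzyme, cap=cap, g=q / q.sum()
    )


def log_linear_r2(g: np.ndarray) -> float:
    """R^2 of log g(l) against l (used to test near-exponential decay)."""
    g = np.asarray(g, dtype=float)
    y = np.log(g)
    x = np.arange(1, g.size + 1, dtype=float)
    resid = y - np.polyval(np.polyfit(x, y, 1), x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def observed_and_modeled(
    ms: MeasurementSet, model_g: dict[str, FragmentLengthDistribution]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pair observed digest vectors with model predictions per enzyme."""
    return {
        d.enzyme: (d.probs, model_g[d.enzyme].g)
        for d in ms.digests
        if d.enzyme in model_g
    }
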