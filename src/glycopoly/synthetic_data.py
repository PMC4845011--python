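"""Ground-truth chain models and synthetic measurement sets.

A :class:`GroundTruth` fixes a generative chain model — homogeneous
independent (HI), homogeneous Markov (HC), independent with a positional
profile (NI), or a position-dependent Markov chain (NC) — and
:func:`synthesize_measurements` turns it into the same measurement format
the real experiments produce: overall composition, per-enzyme digest
fragment-length distributions with cap bins, and the chain length. With
zero noise the digests are exact model expectations (closed forms; the
generic Markov route covers NC), so the resulting constraint polytope must
contain the truth — the basis for parameter-recovery and feasibility
self-consistency tests. Optional truncated-Gaussian noise perturbs each
reported proportion before renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .digest_model import (
    hi_distribution,
    markov_digest_distribution,
    ni_distribution,
)
from .measurements import CategoryTable, DigestDistribution, MeasurementSet

__all__ = ["GroundTruth", "synthesize_measurements", "true_marginal_profile"]

_KINDS = ("HI", "HC", "NI", "NC")


@dataclass(frozen=True)
class GroundTruth:
    """A fully specified chain model used to generate measurements.

    ``params`` by kind:
      HI: {"rho_S": float}
      HC: {"P": (2,2) transition matrix, "rho_S": stationary S proportion}
      NI: {"gamma_S": length-n vector of per-position S proportions}
      NC: {"marginal2_S": float, "transitions": (n-2, 2, 2) array}
    """

    kind: str
    n: int
    params: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.n < 3:
            raise ValueError("n must be >= 3")


def true_marginal_profile(truth: GroundTruth) -> np.ndarray:
    """Exact S proportion at positions 2..n under the ground-truth model."""
    n = truth.n
    if truth.kind == "HI":
        return np.full(n - 1, float(truth.params["rho_S"]))
    if truth.kind == "NI":
        g = np.asarray(truth.params["gamma_S"], dtype=float)
        if g.size != n:
            raise ValueError("gamma_S must have length n")
        return g[1:].copy()
    if truth.kind == "HC":
        rho_S = float(truth.params["rho_S"])
        mu = np.array([rho_S, 1.0 - rho_S])
        P = np.asarray(truth.params["P"], dtype=float)
        out = np.empty(n - 1)
        for k in range(n - 1):
            out[k] = mu[0]
            mu = mu @ P
        return out
    # NC: propagate the position-2 marginal through per-position transitions
    mu = np.array([float(truth.params["marginal2_S"]), 0.0])
    mu[1] = 1.0 - mu[0]
    P = np.asarray(truth.params["transitions"], dtype=float).reshape(n - 2, 2, 2)
    out = np.empty(n - 1)
    out[0] = mu[0]
    for k in range(n - 2):
        mu = mu @ P[k]
        out[k + 1] = mu[0]
    return out


def _exact_digest(truth: GroundTruth, table: CategoryTable, enzyme: str,
                  cap: int) -> np.ndarray:
    n = truth.n
    if truth.kind == "HI":
        return hi_distribution(table, n, enzyme, cap).g
    if truth.kind == "NI":
        g = np.asarray(truth.params["gamma_S"], dtype=float)
        gamma = np.column_stack([g, 1.0 - g])
        return ni_distribution(gamma, table, n, enzyme, cap).g
    if truth.kind == "HC":
        rho_S = float(truth.params["rho_S"])
        P = np.asarray(truth.params["P"], dtype=float)
        tr = np.broadcast_to(P, (n - 2, 2, 2))
        return markov_digest_distribution(
            np.array([rho_S, 1 - rho_S]), tr, table.yields_[enzyme],
            n, enzyme, cap,
        ).g
    m2 = float(truth.params["marginal2_S"])
    tr = np.asarray(truth.params["transitions"], dtype=float).reshape(n - 2, 2, 2)
    return markov_digest_distribution(
        np.array([m2, 1 - m2]), tr, table.yields_[enzyme], n, enzyme, cap,
    ).g


def synthesize_measurements(
    truth: GroundTruth,
    enzymes: Mapping[str, tuple[float, float]],
    caps: Mapping[str, int],
    noise_sd: float = 0.0,
) -> MeasurementSet:
    """Build a MeasurementSet from a ground-truth model.

    ``enzymes`` maps enzyme name -> (c_S, c_U) yields; ``caps`` gives the
    cap bin per enzyme. The overall composition is the exact model marginal
    averaged over positions 2..n and the digest vectors are exact model
    expectations. ``noise_sd > 0`` adds independent Gaussian noise truncated
    at zero to every reported proportion, then renormalizes (seeded by
    ``truth.seed``).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rho_S = float(true_marginal_profile(truth).mean())
    rng = np.random.default_rng(truth.seed)

    def perturb(vec: np.ndarray) -> np.ndarray:
        if noise_sd == 0:
            return vec
        noisy = np.clip(vec + rng.normal(0.0, noise_sd, size=vec.shape), 0.0, None)
        if noisy.sum() <= 0:
            noisy = vec
        return noisy / noisy.sum()

    rho = perturb(np.array([rho_S, 1.0 - rho_S]))
    table = CategoryTable(rho=(rho[0], rho[1]), yields_=dict(enzymes))
    # exact digests are computed at the *unperturbed* composition
    clean_table = CategoryTable(rho=(rho_S, 1.0 - rho_S), yields_=dict(enzymes))
    digests = []
    for enzyme in enzymes:
        g = _exact_digest(truth, clean_table, enzyme, caps[enzyme])
        digests.append(
            DigestDistribution(enzyme=enzyme, cap=caps[enzyme], probs=perturb(g))
        )
    return MeasurementSet(table=table, digests=tuple(digests),
                          mean_length=truth.n)
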