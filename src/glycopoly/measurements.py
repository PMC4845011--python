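"""Data model and I/O for bulk measurements on mixtures of linear S/U chains.

A :class:`MeasurementSet` bundles everything the downstream analyses consume:

* the overall disaccharide composition ``rho`` over positions 2..n (the
  non-reducing end, position 1, is excluded because it does not contribute
  to any of the supported measurements),
* per-enzyme cleavage yields ``c(d)`` — the probability that the lyase cuts
  the bond on the non-reducing side of a disaccharide of category ``d``,
* per-enzyme fragment-length distributions with a terminal cap bin
  (all fragments of length >= ``cap`` are pooled),
* the mean chain length ``n`` and, optionally, a chain-length range and
  Gaussian spread for mixture-of-length models.

The built-in fixture :func:`builtin_bkhs_table1` carries the published bulk
measurements on bovine kidney heparan sulfate (BKHS): composition, heparinase
I/III yields and digest fragment-length distributions, mean length 16.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "CATEGORIES",
    "CategoryTable",
    "DigestDistribution",
    "MeasurementSet",
    "MeasurementError",
    "builtin_bkhs_table1",
    "load_measurements",
    "write_measurements",
]

#: Disaccharide categories, in fixed order: S = 2-O-sulfated, U = unsulfated.
CATEGORIES = ("S", "U")

#: Drift in a digest vector's sum above which renormalization warns.
RENORM_WARN_DRIFT = 1e-3


class MeasurementError(ValueError):
    """Raised for schema or validation problems in measurement inputs."""


@dataclass(frozen=True)
class CategoryTable:
    """Overall composition and per-enzyme cleavage yields for categories S/U.

    Parameters
    ----------
    rho
        ``(rho_S, rho_U)`` — overall proportions over positions 2..n;
        must sum to 1 within 1e-12.
    yields_
        Mapping enzyme name -> ``(c_S, c_U)`` cleavage probabilities in [0,1].
    """

    rho: tuple[float, float]
    yields_: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.rho[0] + self.rho[1] - 1.0) > 1e-12:
            raise MeasurementError(f"rho must sum to 1, got {self.rho}")
        if min(self.rho) < 0:
            raise MeasurementError(f"rho must be nonnegative, got {self.rho}")
        for enzyme, cy in self.yields_.items():
            if len(cy) != 2 or not all(0.0 <= c <= 1.0 for c in cy):
                raise MeasurementError(
                    f"yields for {enzyme!r} must be two values in [0,1], got {cy}"
                )

    @property
    def categories(self) -> tuple[str, str]:
        return CATEGORIES

    def rho_of(self, category: str) -> float:
        return self.rho[CATEGORIES.index(category)]

    def yield_of(self, enzyme: str, category: str) -> float:
        return self.yields_[enzyme][CATEGORIES.index(category)]

    def mean_yield(self, enzyme: str) -> float:
        """Mixture-average cut probability c̄ = Σ_d c(d) ρ(d)."""
        cS, cU = self.yields_[enzyme]
        return cS * self.rho[0] + cU * self.rho[1]


@dataclass(frozen=True)
class DigestDistribution:
    """Measured fragment-length distribution for one enzyme digest.

    ``probs[l-1]`` is the relative abundance of fragments of length ``l``
    disaccharides for ``l < cap``; ``probs[cap-1]`` aggregates all fragments
    of length >= ``cap``. Fragments containing the non-reducing end are not
    counted. The vector is renormalized on construction; drift larger than
    ``RENORM_WARN_DRIFT`` triggers a warning (printed tables are rounded).
    """

    enzyme: str
    cap: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.cap < 2:
            raise MeasurementError(f"cap must be >= 2, got {self.cap}")
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size != self.cap:
            raise MeasurementError(
                f"probs must have length cap={self.cap}, got shape {p.shape}"
            )
        if np.any(p < 0):
            raise MeasurementError(f"negative proportion in digest {self.enzyme!r}")
        total = p.sum()
        if total <= 0:
            raise MeasurementError(f"digest {self.enzyme!r} sums to zero")
        if abs(total - 1.0) > RENORM_WARN_DRIFT:
            warnings.warn(
                f"digest {self.enzyme!r} sums to {total:.6g}; renormalizing",
                stacklevel=2,
            )
        object.__setattr__(self, "probs", p / total)

    def prob(self, length: int) -> float:
        """f(l) for l < cap, or the pooled f(l >= cap) when length == cap."""
        if not 1 <= length <= self.cap:
            raise IndexError(f"length {length} outside 1..{self.cap}")
        return float(self.probs[length - 1])


@dataclass(frozen=True)
class MeasurementSet:
    """A complete set of bulk measurements on one chain mixture."""

    table: CategoryTable
    digests: tuple[DigestDistribution, ...]
    mean_length: int
    length_range: tuple[int, int] | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.mean_length < 2:
            raise MeasurementError(f"mean_length must be >= 2, got {self.mean_length}")
        if self.length_range is not None:
            lo, hi = self.length_range
            if not lo <= self.mean_length <= hi:
                raise MeasurementError(
                    f"length_range {self.length_range} must bracket mean_length "
                    f"{self.mean_length}"
                )
        object.__setattr__(self, "digests", tuple(self.digests))
        seen = [d.enzyme for d in self.digests]
        if len(set(seen)) != len(seen):
            raise MeasurementError(f"duplicate digest enzymes: {seen}")
        for d in self.digests:
            if d.enzyme not in self.table.yields_:
                raise MeasurementError(f"no yields for digest enzyme {d.enzyme!r}")

    @property
    def enzymes(self) -> tuple[str, ...]:
        return tuple(d.enzyme for d in self.digests)

    def digest(self, enzyme: str) -> DigestDistribution:
        for d in self.digests:
            if d.enzyme == enzyme:
                return d
        raise KeyError(enzyme)


def builtin_bkhs_table1() -> MeasurementSet:
    """The published BKHS measurement set.

    Overall S/U proportions (positions 2..n), heparinase I and III cleavage
    yields, the two digest fragment-length distributions (caps 11 and 6),
    and the NMR-determined mean chain length n = 16.
    """
    table = CategoryTable(
        rho=(0.1358, 0.8642),
        yields_={"hepI": (1.000, 0.030), "hepIII": (0.033, 1.000)},
    )
    hep1 = DigestDistribution(
        enzyme="hepI",
        cap=11,
        probs=np.array(
            [0.4676, 0.0711, 0.0544, 0.0361, 0.0351,
             0.0307, 0.0353, 0.0380, 0.0321, 0.0302, 0.1694]
        ),
    )
    hep3 = DigestDistribution(
        enzyme="hepIII",
        cap=6,
        probs=np.array([0.9211, 0.0545, 0.0164, 0.0058, 0.0018, 0.0004]),
    )
    return MeasurementSet(
        table=table,
        digests=(hep1, hep3),
        mean_length=16,
        length_range=(10, 20),
        sigma=3.5,
    )


# ---------------------------------------------------------------------------
# JSON serialization: one document with sections "composition", "yields",
# "digest:<enzyme>" (cap bin encoded as the last row labeled ">=L"), "length".
# ---------------------------------------------------------------------------

def to_dict(ms: MeasurementSet) -> dict:
    doc: dict = {
        "composition": {c: ms.table.rho[i] for i, c in enumerate(CATEGORIES)},
        "yields": {
            enz: {c: cy[i] for i, c in enumerate(CATEGORIES)}
            for enz, cy in ms.table.yields_.items()
        },
        "length": {"mean": ms.mean_length},
    }
    if ms.length_range is not None:
        doc["length"]["range"] = list(ms.length_range)
    if ms.sigma is not None:
        doc["length"]["sigma"] = ms.sigma
    for d in ms.digests:
        rows = {str(l): float(d.probs[l - 1]) for l in range(1, d.cap)}
        rows[f">={d.cap}"] = float(d.probs[d.cap - 1])
        doc[f"digest:{d.enzyme}"] = rows
    return doc


def from_dict(doc: Mapping) -> MeasurementSet:
    for section in ("composition", "yields", "length"):
        if section not in doc:
            raise MeasurementError(f"missing section {section!r}")
    comp = doc["composition"]
    try:
        rho = tuple(float(comp[c]) for c in CATEGORIES)
    except KeyError as exc:
        raise MeasurementError(f"composition lacks category {exc}") from exc
    yields_ = {
        enz: tuple(float(cy[c]) for c in CATEGORIES)
        for enz, cy in doc["yields"].items()
    }
    digests = []
    for key, rows in doc.items():
        if not key.startswith("digest:"):
            continue
        enzyme = key.split(":", 1)[1]
        cap_labels = [lab for lab in rows if lab.startswith(">=")]
        if len(cap_labels) != 1:
            raise MeasurementError(
                f"digest {enzyme!r} needs exactly one '>=L' cap row"
            )
        cap = int(cap_labels[0][2:])
        if cap < 2:
            raise MeasurementError(f"digest {enzyme!r} cap must be >= 2, got {cap}")
        probs = np.empty(cap)
        for l in range(1, cap):
            if str(l) not in rows:
                raise MeasurementError(f"digest {enzyme!r} missing length {l}")
            probs[l - 1] = float(rows[str(l)])
        probs[cap - 1] = float(rows[cap_labels[0]])
        digests.append(DigestDistribution(enzyme=enzyme, cap=cap, probs=probs))
    length = doc["length"]
    return MeasurementSet(
        table=CategoryTable(rho=rho, yields_=yields_),
        digests=tuple(digests),
        mean_length=int(length["mean"]),
        length_range=tuple(length["range"]) if "range" in length else None,
        sigma=float(length["sigma"]) if "sigma" in length else None,
    )


def write_measurements(ms: MeasurementSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(to_dict(ms), indent=1, sort_keys=True))


def load_measurements(source: str | Path | Mapping) -> MeasurementSet:
    """Load a MeasurementSet from a JSON file or an already-parsed mapping."""
    if isinstance(source, Mapping):
        return from_dict(source)
    return from_dict(json.loads(Path(source).read_text()))
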