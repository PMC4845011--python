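"""Enumeration and indexing of all S/U chain sequences.

A chain of length ``n`` is the sequence ``d_1 .. d_n`` with position 1 at the
non-reducing end (NRE) and position ``n`` at the reducing end (RE). A
:class:`SpeciesSpace` indexes every sequence for one length or a range of
lengths: blocks ordered by length ascending, and within a block by the bit
code that maps S -> 1, U -> 0 with position 1 as the most significant bit.
Position 1 does not contribute to any supported measurement but is part of
the species definition, so each length-``n`` block has ``2**n`` species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .measurements import CATEGORIES

__all__ = [
    "Species",
    "SpeciesSpace",
    "build_space",
    "encode",
    "decode",
    "composition_counts",
]

_BIT = {"S": 1, "U": 0}
_SYM = ("U", "S")  # index by bit


@dataclass(frozen=True)
class Species:
    """One chain sequence; ``sequence`` is a string over {S, U}, NRE first."""

    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError("species length must be >= 2")
        bad = set(self.sequence) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories {bad} in {self.sequence!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def category(self, position: int) -> str:
        """Category at 1-based position from the non-reducing end."""
        return self.sequence[position - 1]


def composition_counts(species: Species, category: str) -> int:
    """r(s, j): occurrences of ``category`` at positions 2..n (NRE excluded)."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return species.sequence.count(category, 1)


@dataclass(frozen=True)
class SpeciesSpace:
    """Index set over all S/U sequences of the given lengths."""

    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        lens = tuple(sorted(set(self.lengths)))
        if not lens:
            raise ValueError("lengths must be nonempty")
        if lens[0] < 2:
            raise ValueError(f"all lengths must be >= 2, got {lens[0]}")
        object.__setattr__(self, "lengths", lens)

    @property
    def offsets(self) -> dict[int, int]:
        """Starting index of each length block."""
        out, acc = {}, 0
        for n in self.lengths:
            out[n] = acc
            acc += 1 << n
        return out

    @property
    def total(self) -> int:
        return sum(1 << n for n in self.lengths)

    def block(self, n: int) -> tuple[int, int]:
        """Index range [start, stop) of the length-``n`` block."""
        start = self.offsets[n]
        return start, start + (1 << n)

    def length_of(self, index: int) -> int:
        if not 0 <= index < self.total:
            raise IndexError(f"index {index} outside space of {self.total}")
        for n in self.lengths:
            start, stop = self.block(n)
            if index < stop:
                return n
        raise AssertionError("unreachable")

    # -- vectorized per-block helpers (builders never materialize Species) --

    def codes(self, n: int) -> np.ndarray:
        """All bit codes 0..2**n-1 of the length-``n`` block, in index order."""
        if n not in self.offsets:
            raise KeyError(f"length {n} not in space")
        return np.arange(1 << n, dtype=np.uint32 if n <= 32 else np.uint64)

    def position_bits(self, n: int, position: int) -> np.ndarray:
        """0/1 vector over the length-``n`` block: 1 where d_position = S."""
        if not 1 <= position <= n:
            raise IndexError(f"position {position} outside 1..{n}")
        return (self.codes(n) >> (n - position)) & 1

    def s_counts(self, n: int) -> np.ndarray:
        """r(s, S) over the length-``n`` block: S count at positions 2..n."""
        mask = (1 << (n - 1)) - 1  # drop the position-1 (most significant) bit
        return np.bitwise_count(self.codes(n) & np.uint32(mask)).astype(np.int64)

    def iter_species(self, batch: int = 4096) -> Iterator[tuple[int, int, np.ndarray]]:
        """Yield (length, start_index, codes_batch) blocks over the space."""
        for n in self.lengths:
            start, stop = self.block(n)
            codes = self.codes(n)
            for lo in range(0, codes.size, batch):
                yield n, start + lo, codes[lo : lo + batch]


def build_space(lengths: Sequence[int]) -> SpeciesSpace:
    """Create a SpeciesSpace; deterministic index order (length, then code)."""
    return SpeciesSpace(lengths=tuple(int(n) for n in lengths))


def encode(space: SpeciesSpace, species: Species) -> int:
    """Global index of ``species`` in ``space``."""
    n = species.length
    if n not in space.offsets:
        raise KeyError(f"length {n} not in space lengths {space.lengths}")
    code = 0
    for ch in species.sequence:
        code = (code << 1) | _BIT[ch]
    return space.offsets[n] + code


def decode(space: SpeciesSpace, index: int) -> Species:
    """Inverse of :func:`encode`."""
    n = space.length_of(index)
    code = index - space.offsets[n]
    seq = "".join(_SYM[(code >> (n - i)) & 1] for i in range(1, n + 1))
    return Species(sequence=seq)
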