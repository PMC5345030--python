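"""Domain types for phosphate traces and secondary structure.

The whole package works on a reduced RNA representation: one 3D point per
nucleotide, the phosphate atom.  Secondary structure is a set of base pairs;
ladders of three or more consecutive pairs form rigid secondary-structure
elements (SSEs), and the pair set decomposes into a nested (bracket-
representable) subset plus the crossing, pseudoknot remainder.

All residue indices are 0-based internally; file readers and writers convert
to and from 1-based numbering at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._geometry import ideal_duplex
from .errors import InvalidStructureError


class BasePair(NamedTuple):
    """A base pair between residues ``i < j`` (0-based)."""

    i: int
    j: int


def _validate_pairs(pairs: Iterable[BasePair], length: int | None = None) -> list[BasePair]:
    out: list[BasePair] = []
    seen: dict[int, BasePair] = {}
    for p in pairs:
        p = BasePair(int(p[0]), int(p[1]))
        if p.i >= p.j:
            raise InvalidStructureError(f"base pair must have i < j, got {p}")
        if p.i < 0 or (length is not None and p.j >= length):
            raise InvalidStructureError(f"base pair {p} out of range for length {length}")
        for r in p:
            if r in seen:
                raise InvalidStructureError(
                    f"residue {r} appears in two base pairs: {seen[r]} and {p}"
                )
            seen[r] = p
        out.append(p)
    return sorted(out)


@dataclass(frozen=True)
class Chain:
    """An ordered phosphate trace: one 3D coordinate per residue.

    Parameters
    ----------
    ids
        One ``(chain_id, residue_number)`` identifier per residue, in chain
        order.  Residue numbers must increase strictly within each chain id.
    coords
        ``(L, 3)`` array of coordinates in angstrom.
    """

    ids: tuple[tuple[str, int], ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InvalidStructureError("coords must have shape (L, 3)")
        if len(self.ids) != coords.shape[0]:
            raise InvalidStructureError("ids and coords lengths differ")
        if coords.shape[0] < 2:
            raise InvalidStructureError("a chain needs at least 2 residues")
        if not np.all(np.isfinite(coords)):
            raise InvalidStructureError("coords must be finite")
        if len(set(self.ids)) != len(self.ids):
            raise InvalidStructureError("residue identifiers must be unique")
        prev: dict[str, int] = {}
        for cid, num in self.ids:
            if cid in prev and num <= prev[cid]:
                raise InvalidStructureError(
                    f"residue numbers not strictly increasing in chain {cid!r}"
                )
            prev[cid] = num

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def length(self) -> int:
        return len(self)

    @classmethod
    def from_coords(cls, coords: np.ndarray, chain_id: str = "A") -> "Chain":
        """Build a chain with residues numbered 1..L in a single chain."""
        coords = np.asarray(coords, dtype=float)
        ids = tuple((chain_id, k + 1) for k in range(coords.shape[0]))
        return cls(ids, coords)

    def with_coords(self, coords: np.ndarray) -> "Chain":
        """Copy of this chain with replaced coordinates (same identifiers)."""
        return Chain(self.ids, np.asarray(coords, dtype=float))

    def distance_matrix(self) -> np.ndarray:
        return squareform(pdist(self.coords))


def pair_distance(chain: Chain, pair: BasePair) -> float:
    """Euclidean distance (angstrom) between the two phosphates of ``pair``."""
    i, j = int(pair[0]), int(pair[1])
    if i >= j:
        raise InvalidStructureError(f"pair must have i < j, got ({i}, {j})")
    if i < 0 or j >= len(chain):
        raise IndexError(f"pair ({i}, {j}) out of range for chain of length {len(chain)}")
    return float(np.linalg.norm(chain.coords[j] - chain.coords[i]))


@dataclass(frozen=True)
class SSE:
    """A secondary-structure element: a ladder of >= 3 consecutive base pairs.

    The ladder is treated as a rigid tubular unit.  ``ideal_distances`` is the
    full intra-element pairwise distance template of an ideal duplex with the
    same number of base pairs; the engine refines the element's internal
    geometry toward this template.
    """

    pair_run: tuple[BasePair, ...]
    members: np.ndarray = field(repr=False)
    ideal_distances: np.ndarray = field(repr=False)

    @classmethod
    def from_run(cls, run: Sequence[BasePair]) -> "SSE":
        run = tuple(run)
        if len(run) < 3:
            raise InvalidStructureError("an SSE needs >= 3 consecutive base pairs")
        for a, b in zip(run, run[1:]):
            if b.i != a.i + 1 or b.j != a.j - 1:
                raise InvalidStructureError(f"pair run not antidiagonally consecutive: {a}, {b}")
        k = len(run)
        # ascending member order maps directly onto ideal_duplex index order:
        # strand 5'->3' then complementary strand 5'->3'
        members = np.array(
            sorted([p.i for p in run] + [p.j for p in run]), dtype=int
        )
        return cls(run, members, _duplex_template(k))

    @property
    def n_bp(self) -> int:
        return len(self.pair_run)


@lru_cache(maxsize=None)
def _duplex_template(n_bp: int) -> np.ndarray:
    return squareform(pdist(ideal_duplex(n_bp)))


def detect_sses(pairs: Iterable[BasePair]) -> list[SSE]:
    """Find maximal ladders of >= 3 antidiagonally consecutive base pairs.

    Returns the elements in 5' order.  Runs shorter than 3 pairs are not
    secondary-structure elements and are excluded.
    """
    plist = _validate_pairs(pairs)
    sses: list[SSE] = []
    run: list[BasePair] = []
    for p in plist:
        if run and p.i == run[-1].i + 1 and p.j == run[-1].j - 1:
            run.append(p)
        else:
            if len(run) >= 3:
                sses.append(SSE.from_run(run))
            run = [p]
    if len(run) >= 3:
        sses.append(SSE.from_run(run))
    return sses


def split_nested(
    pairs: Iterable[BasePair],
) -> tuple[frozenset[BasePair], frozenset[BasePair]]:
    """Split a base-pair set into a maximum nested subset and the crossing rest.

    The nested subset is a maximum-cardinality crossing-free subset, found by
    dynamic programming over sequence intervals (the crossing remainder is the
    pseudoknot part).  Ties between equal-cardinality nested subsets are broken
    by preferring pairs with smaller ``i``.
    """
    plist = _validate_pairs(pairs)
    if not plist:
        return frozenset(), frozenset()
    partner = {}
    for p in plist:
        partner[p.i] = p.j
        partner[p.j] = p.i
    hi_max = max(p.j for p in plist)

    memo: dict[tuple[int, int], tuple[int, bool]] = {}

    def best(lo: int, hi: int) -> int:
        """Max number of mutually nested pairs fully inside [lo, hi]."""
        while lo <= hi and not (lo in partner and lo < partner[lo] <= hi):
            lo += 1
        if lo > hi:
            return 0
        key = (lo, hi)
        if key in memo:
            return memo[key][0]
        p = partner[lo]
        skip = best(lo + 1, hi)
        take = 1 + best(lo + 1, p - 1) + best(p + 1, hi)
        # tie-break: prefer taking the pair with the smaller i
        memo[key] = (take, True) if take >= skip else (skip, False)
        return memo[key][0]

    def collect(lo: int, hi: int, out: list[BasePair]) -> None:
        while lo <= hi and not (lo in partner and lo < partner[lo] <= hi):
            lo += 1
        if lo > hi:
            return
        p = partner[lo]
        if memo[(lo, hi)][1]:
            out.append(BasePair(lo, p))
            collect(lo + 1, p - 1, out)
            collect(p + 1, hi, out)
        else:
            collect(lo + 1, hi, out)

    best(0, hi_max)
    nested: list[BasePair] = []
    collect(0, hi_max, nested)
    nested_set = frozenset(nested)
    crossing = frozenset(p for p in plist if p not in nested_set)
    return nested_set, crossing


@dataclass(frozen=True)
class SecondaryStructure:
    """A base-pair set with its nested / crossing (pseudoknot) decomposition."""

    pairs: frozenset[BasePair]
    nested: frozenset[BasePair]
    crossing: frozenset[BasePair]

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[BasePair], length: int | None = None
    ) -> "SecondaryStructure":
        plist = _validate_pairs(pairs, length)
        nested, crossing = split_nested(plist)
        return cls(frozenset(plist), nested, crossing)

    def __len__(self) -> int:
        return len(self.pairs)
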