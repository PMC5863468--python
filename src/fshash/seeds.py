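"""Spaced-seed model and reuse-plan precomputation.

A spaced seed is a binary pattern such as ``10111011`` in which ``1`` marks a
match position and ``0`` a don't-care position.  Its *shape* Q is the set of
offsets of the 1s, its *weight* W = |Q| the number of 1s, and its *span*
s(Q) = max(Q) + 1 the pattern length.  The *m-vector* assigns to every seed
position k the number of match positions strictly to its left; m(k) fixes the
2-bit field in which the k-th matched nucleotide is stored inside the hash.

The incremental hashing engine rests on the *compatibility sets*

    C_j = { k - j in Q : k in Q  and  m(k - j) = m(k) - m(j) },

the seed positions whose 2-bit encodings, already present in the hash computed
j positions earlier, survive a single uniform right shift and land exactly in
the field the current hash needs.  Everything combinatorial about a seed —
the C_j sets, their maxima ArgBH(s) over lookback windows, and the concrete
bit-level reuse plans (shift amount, keep mask, positions still missing) — is
computed once per seed here and never per sequence position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

__all__ = [
    "SeedError",
    "SpacedSeed",
    "ReusePlan",
    "CompatibilityTable",
    "parse_seed",
    "shift_count_vector",
    "compatibility_sets",
    "best_previous",
]

MAX_WEIGHT = 32  # 2 bits per matched symbol must fit one 64-bit word


class SeedError(ValueError):
    """Invalid spaced-seed pattern."""


@dataclass(frozen=True)
class SpacedSeed:
    """A validated spaced seed.

    Attributes
    ----------
    pattern:
        The binary string, e.g. ``"10111011"``.
    shape:
        Sorted tuple of offsets of the 1s (the shape Q).
    weight:
        Number of match positions, W = |Q|.
    span:
        Pattern length, s(Q) = max(Q) + 1.
    m:
        Tuple of length ``span``; ``m[k]`` counts match positions strictly
        left of k, i.e. the rank of k within the shape when k is a match
        position.
    """

    pattern: str
    shape: tuple[int, ...]
    weight: int
    span: int
    m: tuple[int, ...]

    def __str__(self) -> str:  # pragma: no cover - debugging nicety
        return self.pattern


def parse_seed(pattern: str) -> SpacedSeed:
    """Parse and validate a spaced-seed pattern.

    Raises
    ------
    SeedError
        If the pattern is empty, contains characters outside ``{0,1}``,
        starts or ends with ``0``, or has more than 32 match positions.
    """
    if not pattern:
        raise SeedError("empty spaced-seed pattern")
    bad = set(pattern) - {"0", "1"}
    if bad:
        raise SeedError(
            f"illegal character(s) {sorted(bad)!r} in spaced-seed pattern {pattern!r}"
        )
    if pattern[0] != "1" or pattern[-1] != "1":
        raise SeedError(
            f"spaced-seed pattern must begin and end with '1': {pattern!r}"
        )
    shape = tuple(k for k, c in enumerate(pattern) if c == "1")
    if len(shape) > MAX_WEIGHT:
        raise SeedError(
            f"seed weight {len(shape)} exceeds {MAX_WEIGHT} "
            f"(hash would not fit 64 bits): {pattern!r}"
        )
    span = len(pattern)
    m = _m_vector(shape, span)
    return SpacedSeed(pattern=pattern, shape=shape, weight=len(shape), span=span, m=m)


def _m_vector(shape: tuple[int, ...], span: int) -> tuple[int, ...]:
    shape_set = set(shape)
    m = [0] * span
    for k in range(1, span):
        m[k] = m[k - 1] + (1 if k - 1 in shape_set else 0)
    return tuple(m)


def shift_count_vector(seed: SpacedSeed) -> list[int]:
    """Return m as a list: ``m[k]`` = number of 1s strictly left of position k."""
    return list(seed.m)


@dataclass(frozen=True)
class ReusePlan:
    """Bit-level recipe to build a hash from the hash j positions back.

    ``reused = (prev >> bit_shift) & keep_mask`` carries over the symbols of
    ``kept``; the symbols at seed positions ``missing`` are then encoded and
    OR-ed in at their own rank offsets.
    """

    j: int
    kept: tuple[int, ...]       # C_j, positions of the target seed
    bit_shift: int              # 2 * m[j]
    keep_mask: int              # 2-bit fields at offsets {2*m[k] : k in kept}
    missing: tuple[int, ...]    # shape \ C_j


@dataclass(frozen=True)
class CompatibilityTable:
    """All C_j sets, reuse plans, and the best-previous-hash table of one seed.

    ``best[s]`` for window s in 1..span-1 holds ``(ArgBH(s), |C_ArgBH(s)|)``
    with ties on cardinality broken toward the smallest shift j.
    """

    seed: SpacedSeed
    sets: dict[int, frozenset[int]] = field(repr=False)
    plans: dict[int, ReusePlan] = field(repr=False)
    best: dict[int, tuple[int, int]] = field(repr=False)


def _compatibility_set(seed: SpacedSeed, j: int) -> frozenset[int]:
    q = set(seed.shape)
    m = seed.m
    return frozenset(k - j for k in seed.shape if k - j in q and m[k - j] == m[k] - m[j])


def compatibility_sets(seed: SpacedSeed) -> CompatibilityTable:
    """Precompute C_j, reuse plans and ArgBH for every lookback window.

    O(span^2 * weight) once per seed; a span-1 seed yields an empty table.
    """
    sets: dict[int, frozenset[int]] = {}
    plans: dict[int, ReusePlan] = {}
    best: dict[int, tuple[int, int]] = {}
    m = seed.m
    best_j, best_card = 0, -1
    for j in range(1, seed.span):
        cj = _compatibility_set(seed, j)
        assert len(cj) < seed.weight, "C_j can never retain every symbol"
        sets[j] = cj
        keep_mask = 0
        for k in cj:
            keep_mask |= 0b11 << (2 * m[k])
        plans[j] = ReusePlan(
            j=j,
            kept=tuple(sorted(cj)),
            bit_shift=2 * m[j],
            keep_mask=keep_mask,
            missing=tuple(k for k in seed.shape if k not in cj),
        )
        if len(cj) > best_card:  # strict: ties keep the smallest j
            best_j, best_card = j, len(cj)
        best[j] = (best_j, best_card)
    return CompatibilityTable(seed=seed, sets=sets, plans=plans, best=best)


def best_previous(table: CompatibilityTable, window: int) -> tuple[int, int]:
    """Return ``(j, |C_j|)`` maximizing |C_j| over shifts 1..window (ArgBH).

    Ties are broken toward the smallest j.
    """
    span = table.seed.span
    if not 1 <= window <= span - 1:
        raise ValueError(f"window {window} out of range [1, {span - 1}]")
    return table.best[window]


@lru_cache(maxsize=256)
def _cached_table(pattern: str) -> CompatibilityTable:
    return compatibility_sets(parse_seed(pattern))


def table_for(seed: SpacedSeed) -> CompatibilityTable:
    """Memoized compatibility table for a seed."""
    return _cached_table(seed.pattern)
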