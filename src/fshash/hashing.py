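"""Rabin-Karp spaced-seed hashing: naive oracle and incremental FSH engine.

Each nucleotide is encoded on 2 bits (A=00, C=01, G=10, T=11).  The hash of
the Q-gram at position i packs the encodings of the W matched symbols into one
64-bit word, the r-th matched symbol (rank r within the shape) occupying bit
offsets [2r, 2r+1] — first matched symbol in the least-significant bits:

    h(x[i+Q]) = OR over k in Q of  encode(x[i+k]) << 2*m(k)

No modular reduction is applied; the hash is the exact 2W-bit word.

``naive_hash_all`` evaluates this definition independently at every position
and serves as the reference oracle.  ``fsh_hash_all`` produces bit-identical
output incrementally: at position i it reuses the previously computed hash
that preserves the most symbols (one right shift plus an AND), then encodes
only the missing symbols.  Reads are split into maximal ACGT-only segments;
each segment is hashed independently, so windows overlapping ambiguous bases
(N, IUPAC codes) are simply never emitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .seeds import CompatibilityTable, SpacedSeed, best_previous, table_for

__all__ = [
    "ENCODING",
    "UNENCODABLE",
    "HashVector",
    "encode_symbol",
    "naive_hash_at",
    "naive_hash_all",
    "fsh_hash_all",
    "count_encodings",
    "hash_to_bits",
    "decode_hash",
]

#: 2-bit nucleotide codes, case-insensitive.
ENCODING: dict[str, int] = {
    "A": 0b00, "C": 0b01, "G": 0b10, "T": 0b11,
    "a": 0b00, "c": 0b01, "g": 0b10, "t": 0b11,
}

#: Sentinel returned for symbols outside {A,C,G,T}; consumed by segmentation.
UNENCODABLE: int = -1

_SEGMENT_RE = re.compile(r"[ACGTacgt]+")

# byte-value -> 2-bit code lookup for vectorized encoding; 255 marks unencodable
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _v in ENCODING.items():
    _CODE_LUT[ord(_c)] = _v


def encode_symbol(c: str) -> int:
    """2-bit code of a nucleotide, or ``UNENCODABLE`` for anything else."""
    return ENCODING.get(c, UNENCODABLE)


@dataclass
class HashVector:
    """Hash values of one read under one seed, in position order.

    ``hashes[t]`` is the hash of the Q-gram starting at read coordinate
    ``positions[t]`` (0-based).  Positions whose window overlaps a non-ACGT
    symbol are absent.
    """

    hashes: np.ndarray    # uint64
    positions: np.ndarray  # int64, absolute within the read

    def __len__(self) -> int:
        return len(self.hashes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HashVector):
            return NotImplemented
        return (
            np.array_equal(self.hashes, other.hashes)
            and np.array_equal(self.positions, other.positions)
        )


def _segments(x: str) -> list[tuple[int, str]]:
    """Maximal ACGT-only runs of x as (start, substring) pairs."""
    return [(mo.start(), mo.group(0)) for mo in _SEGMENT_RE.finditer(x)]


def naive_hash_at(x: str, i: int, seed: SpacedSeed) -> int:
    """Hash at one position straight from the definition.

    Raises ``ValueError`` if the window falls outside the sequence or covers
    an unencodable symbol.
    """
    if not 0 <= i <= len(x) - seed.span:
        raise ValueError(
            f"position {i} out of range for sequence of length {len(x)} "
            f"and span {seed.span}"
        )
    h = 0
    for r, k in enumerate(seed.shape):
        code = encode_symbol(x[i + k])
        if code == UNENCODABLE:
            raise ValueError(f"unencodable symbol {x[i + k]!r} at position {i + k}")
        h |= code << (2 * r)
    return h


def _empty_vector() -> HashVector:
    return HashVector(
        hashes=np.empty(0, dtype=np.uint64), positions=np.empty(0, dtype=np.int64)
    )


def naive_hash_all(x: str, seed: SpacedSeed) -> HashVector:
    """Reference oracle: the hash at every valid position, in order.

    Vectorized over positions: one shift-OR pass per match position of the
    seed, within each ACGT segment.
    """
    out_h: list[np.ndarray] = []
    out_p: list[np.ndarray] = []
    span = seed.span
    for start, seg in _segments(x):
        n_pos = len(seg) - span + 1
        if n_pos <= 0:
            continue
        codes = _CODE_LUT[np.frombuffer(seg.encode("ascii"), dtype=np.uint8)]
        codes = codes.astype(np.uint64)
        h = np.zeros(n_pos, dtype=np.uint64)
        for r, k in enumerate(seed.shape):
            h |= codes[k : k + n_pos] << np.uint64(2 * r)
        out_h.append(h)
        out_p.append(np.arange(start, start + n_pos, dtype=np.int64))
    if not out_h:
        return _empty_vector()
    return HashVector(hashes=np.concatenate(out_h), positions=np.concatenate(out_p))


def fsh_hash_all(
    x: str, seed: SpacedSeed, table: CompatibilityTable | None = None
) -> HashVector:
    """Incremental engine; output bit-identical to :func:`naive_hash_all`.

    Within a segment, position 0 is computed naively.  Position i with
    lookback window w = min(i, span-1) reuses the hash at i - j where
    j = ArgBH(w): one right shift by 2*m(j), one AND with the keep mask,
    then one encode-shift-OR per missing symbol.  The lookback never exceeds
    span-1 entries; segments reset the recursion.
    """
    if table is None:
        table = table_for(seed)
    elif table.seed != seed:
        raise ValueError("compatibility table was built for a different seed")
    span = seed.span
    shape = seed.shape
    m = seed.m
    out_h: list[np.ndarray] = []
    out_p: list[np.ndarray] = []
    for start, seg in _segments(x):
        n_pos = len(seg) - span + 1
        if n_pos <= 0:
            continue
        codes = _CODE_LUT[np.frombuffer(seg.encode("ascii"), dtype=np.uint8)]
        h = np.zeros(n_pos, dtype=np.uint64)
        prev: list[int] = [0] * n_pos  # python ints; h filled at the end
        for i in range(n_pos):
            w = min(i, span - 1)
            if w == 0:
                v = 0
                for r, k in enumerate(shape):
                    v |= int(codes[i + k]) << (2 * r)
            else:
                j, _ = best_previous(table, w)
                plan = table.plans[j]
                v = (prev[i - j] >> plan.bit_shift) & plan.keep_mask
                for k in plan.missing:
                    v |= int(codes[i + k]) << (2 * m[k])
            prev[i] = v
        h[:] = prev
        out_h.append(h)
        out_p.append(np.arange(start, start + n_pos, dtype=np.int64))
    if not out_h:
        return _empty_vector()
    return HashVector(hashes=np.concatenate(out_h), positions=np.concatenate(out_p))


def count_encodings(
    x: str, seed: SpacedSeed, mode: str = "fsh"
) -> tuple[int, Fraction]:
    """Count symbols read and encoded while hashing x with the given seed.

    Returns ``(total, per_symbol)``: the total number of symbol encodings over
    all emitted positions, and the average number of encodings per position in
    steady state, i.e. over positions past the transient of the first
    span - 1 hashes of each segment.  ``mode="naive"`` charges the full seed
    weight at every position; ``mode="fsh"`` charges exactly the insertions
    the chosen reuse plans perform.  Positions advance one symbol at a time,
    so per-position insertions equal per-symbol reads in steady state.
    """
    if mode not in ("naive", "fsh"):
        raise ValueError(f"mode must be 'naive' or 'fsh', got {mode!r}")
    seed_table = table_for(seed)
    span, weight = seed.span, seed.weight
    total = 0
    steady_total = 0
    steady_positions = 0
    for _, seg in _segments(x):
        n_pos = len(seg) - span + 1
        if n_pos <= 0:
            continue
        if mode == "naive":
            total += weight * n_pos
            steady = max(0, n_pos - (span - 1))
            steady_total += weight * steady
            steady_positions += steady
            continue
        for i in range(n_pos):
            w = min(i, span - 1)
            if w == 0:
                ins = weight
            else:
                _, kept = best_previous(seed_table, w)
                ins = weight - kept
            total += ins
            if i >= span - 1:
                steady_total += ins
                steady_positions += 1
    per_symbol = (
        Fraction(steady_total, steady_positions) if steady_positions else Fraction(0)
    )
    return total, per_symbol


def hash_to_bits(value: int, seed: SpacedSeed) -> str:
    """Render a hash as a 2W-bit string, most-significant bit first."""
    return format(value, f"0{2 * seed.weight}b")


def decode_hash(value: int, seed: SpacedSeed) -> str:
    """Recover the Q-gram (matched symbols, left to right) from a hash."""
    sym = "ACGT"
    return "".join(sym[(int(value) >> (2 * r)) & 0b11] for r in range(seed.weight))
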