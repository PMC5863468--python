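"""Simultaneous hashing of several equal-span spaced seeds.

When a set S of seeds, all of span L, is hashed over the same read, the hash
of seed y at position i may reuse the hash of *any* seed z at any earlier
position i - j.  The cross-compatibility sets generalize the single-seed C_j:

    C^yz_j = { k - j in Q_y : k in Q_z  and  m_y(k - j) = m_z(k) - m_z(j) }

The rank condition guarantees that after a single uniform right shift of
h_z(i - j) by 2*m_z(j), every kept symbol lands exactly at the 2-bit offset
seed y requires — no per-field remapping is ever needed.  ArgBSH picks, per
target seed and lookback window, the (source seed, shift) pair keeping the
most symbols; ties go to the smallest shift, then the smallest source index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hashing import _CODE_LUT, HashVector, _empty_vector, _segments
from .seeds import SpacedSeed

__all__ = [
    "CrossCompatibilityTable",
    "MultiSeedPlan",
    "cross_compatibility",
    "best_seed_and_shift",
    "build_multi_plan",
    "fsh_hash_multi",
]


@dataclass(frozen=True)
class CrossCompatibilityTable:
    """C^yz_j for every ordered seed pair (y, z) and shift j in 1..L-1."""

    seeds: tuple[SpacedSeed, ...]
    span: int
    # sets[(y, z)][j] with y, z 0-based seed indices
    sets: dict[tuple[int, int], dict[int, frozenset[int]]] = field(repr=False)


@dataclass(frozen=True)
class CrossReusePlan:
    """Recipe for seed y at steady state or window w: reuse seed z at shift j."""

    z: int
    j: int
    kept: tuple[int, ...]
    bit_shift: int            # 2 * m_z[j]
    keep_mask: int            # fields at target offsets {2*m_y[k] : k in kept}
    missing: tuple[int, ...]  # Q_y \ C^yz_j


@dataclass(frozen=True)
class MultiSeedPlan:
    """Per target seed and lookback window, the best cross-seed reuse plan."""

    seeds: tuple[SpacedSeed, ...]
    span: int
    # plans[y][w] for w in 1..span-1
    plans: dict[int, dict[int, CrossReusePlan]] = field(repr=False)
    table: CrossCompatibilityTable = field(repr=False)


def _cross_set(sy: SpacedSeed, sz: SpacedSeed, j: int) -> frozenset[int]:
    qy = set(sy.shape)
    return frozenset(
        k - j for k in sz.shape if k - j in qy and sy.m[k - j] == sz.m[k] - sz.m[j]
    )


def cross_compatibility(seeds: list[SpacedSeed]) -> CrossCompatibilityTable:
    """Compute C^yz_j for all ordered pairs; seeds must share one span."""
    if not seeds:
        raise ValueError("need at least one seed")
    spans = {s.span for s in seeds}
    if len(spans) > 1:
        raise ValueError(
            f"multi-seed hashing requires equal spans, got {sorted(spans)}"
        )
    span = seeds[0].span
    sets: dict[tuple[int, int], dict[int, frozenset[int]]] = {}
    for y, sy in enumerate(seeds):
        for z, sz in enumerate(seeds):
            sets[(y, z)] = {j: _cross_set(sy, sz, j) for j in range(1, span)}
    return CrossCompatibilityTable(seeds=tuple(seeds), span=span, sets=sets)


def best_seed_and_shift(
    table: CrossCompatibilityTable, y: int, window: int
) -> tuple[int, int, int]:
    """ArgBSH: ``(z, j, kept)`` maximizing |C^yz_j| over z and j in 1..window.

    Ties broken by smallest j, then smallest z.
    """
    if not 0 <= y < len(table.seeds):
        raise ValueError(f"seed index {y} out of range")
    if not 1 <= window <= table.span - 1:
        raise ValueError(f"window {window} out of range [1, {table.span - 1}]")
    best = (-1, 0, 0)  # (kept, j, z) — compare kept desc, then j asc, then z asc
    for j in range(1, window + 1):
        for z in range(len(table.seeds)):
            kept = len(table.sets[(y, z)][j])
            if kept > best[0]:
                best = (kept, j, z)
    kept, j, z = best
    return z, j, kept


def build_multi_plan(seeds: list[SpacedSeed]) -> MultiSeedPlan:
    """Precompute the best cross-seed reuse plan per target seed and window."""
    table = cross_compatibility(seeds)
    span = table.span
    plans: dict[int, dict[int, CrossReusePlan]] = {}
    for y, sy in enumerate(table.seeds):
        plans[y] = {}
        for w in range(1, span):
            z, j, _ = best_seed_and_shift(table, y, w)
            cyz = table.sets[(y, z)][j]
            keep_mask = 0
            for k in cyz:
                keep_mask |= 0b11 << (2 * sy.m[k])
            plans[y][w] = CrossReusePlan(
                z=z,
                j=j,
                kept=tuple(sorted(cyz)),
                bit_shift=2 * table.seeds[z].m[j],
                keep_mask=keep_mask,
                missing=tuple(k for k in sy.shape if k not in cyz),
            )
    return MultiSeedPlan(seeds=table.seeds, span=span, plans=plans, table=table)


def fsh_hash_multi(
    x: str, seeds: list[SpacedSeed], plan: MultiSeedPlan | None = None
) -> list[HashVector]:
    """Hash all seeds over x simultaneously; output[y] matches the naive oracle.

    At each position, seeds are processed in input order; every seed may reuse
    the hash of any seed at a strictly earlier position (shift j >= 1).
    """
    if plan is None:
        plan = build_multi_plan(seeds)
    elif plan.seeds != tuple(seeds):
        raise ValueError("plan was built for a different seed set")
    span = plan.span
    n_seeds = len(plan.seeds)
    out_h: list[list[np.ndarray]] = [[] for _ in range(n_seeds)]
    out_p: list[list[np.ndarray]] = [[] for _ in range(n_seeds)]
    for start, seg in _segments(x):
        n_pos = len(seg) - span + 1
        if n_pos <= 0:
            continue
        codes = _CODE_LUT[np.frombuffer(seg.encode("ascii"), dtype=np.uint8)]
        prev: list[list[int]] = [[0] * n_pos for _ in range(n_seeds)]
        for i in range(n_pos):
            w = min(i, span - 1)
            for y, sy in enumerate(plan.seeds):
                if w == 0:
                    v = 0
                    for r, k in enumerate(sy.shape):
                        v |= int(codes[i + k]) << (2 * r)
                else:
                    p = plan.plans[y][w]
                    v = (prev[p.z][i - p.j] >> p.bit_shift) & p.keep_mask
                    for k in p.missing:
                        v |= int(codes[i + k]) << (2 * sy.m[k])
                prev[y][i] = v
        pos = np.arange(start, start + n_pos, dtype=np.int64)
        for y in range(n_seeds):
            out_h[y].append(np.array(prev[y], dtype=np.uint64))
            out_p[y].append(pos)
    result = []
    for y in range(n_seeds):
        if out_h[y]:
            result.append(
                HashVector(
                    hashes=np.concatenate(out_h[y]),
                    positions=np.concatenate(out_p[y]),
                )
            )
        else:
            result.append(_empty_vector())
    return result


def count_insertions_multi(x: str, plan: MultiSeedPlan) -> int:
    """Total symbols encoded when hashing all seeds of the plan over x."""
    span = plan.span
    total = 0
    for _, seg in _segments(x):
        n_pos = len(seg) - span + 1
        if n_pos <= 0:
            continue
        for i in range(n_pos):
            w = min(i, span - 1)
            for y, sy in enumerate(plan.seeds):
                if w == 0:
                    total += sy.weight
                else:
                    total += len(plan.plans[y][w].missing)
    return total
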