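"""Encoding-count benchmarking and theoretical speedup prediction.

Wall-clock time is hardware-dependent, so the portable performance proxy is
the number of symbols read and encoded.  Under the cost model in which shifts
and insertions cost the same, hashing one seed naively encodes W symbols per
position while the incremental engine encodes W - |C_ArgBH(span-1)| in steady
state, so the predicted speedup of a single seed is

    W / (W - |C_ArgBH(span-1)|)

and for a set of seeds hashed simultaneously

    sum_y W_y / sum_y (W_y - kept_y)

with kept_y from ArgBSH at the full window.  The benchmark verifies FSH
output against the naive oracle before timing, then reports measured
encoding counts (which include the transient, so they approach the steady
state as reads grow longer) alongside the predictions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

from .hashing import _segments, count_encodings, fsh_hash_all, naive_hash_all
from .io import read_sequences
from .multiseed import build_multi_plan, count_insertions_multi, fsh_hash_multi
from .seeds import SpacedSeed, best_previous, table_for

__all__ = ["predicted_speedup", "benchmark", "BenchmarkReport", "SeedBenchRow"]


def _steady_kept(seed: SpacedSeed) -> int:
    if seed.span == 1:
        return 0
    _, kept = best_previous(table_for(seed), seed.span - 1)
    return kept


def predicted_speedup(seeds: Sequence[SpacedSeed], mode: str = "independent") -> float:
    """Theoretical steady-state speedup of incremental over naive hashing.

    ``independent``: each seed hashed on its own; for one seed this is
    W / (W - kept).  For several, the aggregate ratio of total naive
    encodings to total incremental encodings.  ``multi``: all seeds hashed
    simultaneously, each reusing the best previous hash of any seed
    (requires equal spans).
    """
    if not seeds:
        raise ValueError("need at least one seed")
    if mode == "independent":
        total_w = sum(s.weight for s in seeds)
        total_ins = sum(s.weight - _steady_kept(s) for s in seeds)
    elif mode == "multi":
        plan = build_multi_plan(list(seeds))
        total_w = sum(s.weight for s in seeds)
        total_ins = sum(
            s.weight - len(plan.plans[y][plan.span - 1].kept)
            for y, s in enumerate(seeds)
        )
    else:
        raise ValueError(f"mode must be 'independent' or 'multi', got {mode!r}")
    return total_w / total_ins


@dataclass
class SeedBenchRow:
    """Per-seed benchmark outcome on one input."""

    pattern: str
    positions: int
    naive_encodings: int
    fsh_encodings: int
    naive_per_symbol: Fraction
    fsh_per_symbol: Fraction
    predicted_speedup: float
    naive_seconds: float  # informational only; never asserted
    fsh_seconds: float    # informational only; never asserted


@dataclass
class BenchmarkReport:
    rows: list[SeedBenchRow]
    mode: str
    n_reads: int
    multi_encodings: int | None = None
    multi_predicted_speedup: float | None = None
    multi_seconds: float | None = None

    def to_text(self) -> str:
        lines = [
            f"# reads: {self.n_reads}   mode: {self.mode}",
            "seed\tpositions\tnaive_enc\tfsh_enc\tnaive_per_sym\tfsh_per_sym"
            "\tpred_speedup\tnaive_s\tfsh_s",
        ]
        for r in self.rows:
            lines.append(
                f"{r.pattern}\t{r.positions}\t{r.naive_encodings}\t{r.fsh_encodings}"
                f"\t{float(r.naive_per_symbol):.3f}\t{float(r.fsh_per_symbol):.3f}"
                f"\t{r.predicted_speedup:.3f}\t{r.naive_seconds:.3f}\t{r.fsh_seconds:.3f}"
            )
        if self.multi_encodings is not None:
            lines.append(
                f"multi\tencodings={self.multi_encodings}"
                f"\tpred_speedup={self.multi_predicted_speedup:.3f}"
                f"\ttime_s={self.multi_seconds:.3f}"
            )
        lines.append("(wall-clock columns are informational only)")
        return "\n".join(lines)


def benchmark(
    input_path: str | Path,
    seeds: Sequence[SpacedSeed],
    mode: str = "independent",
    verify: bool = True,
) -> BenchmarkReport:
    """Count encoded symbols (naive vs incremental) over a read file.

    With ``mode="multi"`` additionally hashes all seeds simultaneously and
    reports the combined insertion count.  FSH output is checked against the
    naive oracle on every read before any timing, unless ``verify=False``.
    """
    if mode not in ("independent", "multi"):
        raise ValueError(f"mode must be 'independent' or 'multi', got {mode!r}")
    records = list(read_sequences(input_path))
    rows = []
    for seed in seeds:
        table = table_for(seed)
        positions = 0
        naive_total = 0
        fsh_total = 0
        t_naive = t_fsh = 0.0
        for rec in records:
            t0 = time.perf_counter()
            ref = naive_hash_all(rec.sequence, seed)
            t1 = time.perf_counter()
            got = fsh_hash_all(rec.sequence, seed, table)
            t2 = time.perf_counter()
            t_naive += t1 - t0
            t_fsh += t2 - t1
            if verify and got != ref:
                raise AssertionError(
                    f"FSH output differs from the naive oracle on read {rec.id!r}"
                )
            positions += len(ref)
            nt, _ = count_encodings(rec.sequence, seed, "naive")
            ft, _ = count_encodings(rec.sequence, seed, "fsh")
            naive_total += nt
            fsh_total += ft
        naive_ps, fsh_ps = _file_per_symbol(records, seed)
        rows.append(
            SeedBenchRow(
                pattern=seed.pattern,
                positions=positions,
                naive_encodings=naive_total,
                fsh_encodings=fsh_total,
                naive_per_symbol=naive_ps,
                fsh_per_symbol=fsh_ps,
                predicted_speedup=predicted_speedup([seed]),
                naive_seconds=t_naive,
                fsh_seconds=t_fsh,
            )
        )
    report = BenchmarkReport(rows=rows, mode=mode, n_reads=len(records))
    if mode == "multi":
        plan = build_multi_plan(list(seeds))
        t0 = time.perf_counter()
        total = 0
        for rec in records:
            if verify:
                got = fsh_hash_multi(rec.sequence, list(seeds), plan)
                for y, seed in enumerate(seeds):
                    if got[y] != naive_hash_all(rec.sequence, seed):
                        raise AssertionError(
                            f"multi-seed FSH differs from oracle on read "
                            f"{rec.id!r}, seed {seed.pattern}"
                        )
            total += count_insertions_multi(rec.sequence, plan)
        report.multi_encodings = total
        report.multi_predicted_speedup = predicted_speedup(seeds, "multi")
        report.multi_seconds = time.perf_counter() - t0
    return report


def _file_per_symbol(records, seed) -> tuple[Fraction, Fraction]:
    """Steady-state per-symbol encoding averages aggregated over all reads."""
    steady_pos = 0
    naive_sum = 0
    fsh_sum = 0
    span, weight = seed.span, seed.weight
    kept_full = _steady_kept(seed)
    for rec in records:
        for _, seg in _segments(rec.sequence):
            n_pos = len(seg) - span + 1
            steady = max(0, n_pos - (span - 1))
            steady_pos += steady
            naive_sum += weight * steady
            fsh_sum += (weight - kept_full) * steady
    if steady_pos == 0:
        return Fraction(0), Fraction(0)
    return Fraction(naive_sum, steady_pos), Fraction(fsh_sum, steady_pos)
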