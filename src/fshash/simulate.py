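"""Synthetic metagenomic-style read simulator.

Emulates the shape of shotgun read sets used to exercise the hashing engine:
a random ACGT genome, reads drawn uniformly from it (typical real sets range
from ~10^5 to ~10^7 reads of ~80 bp Illumina-like to ~700 bp 454-like
length), and uniform substitution errors at ~1% per base.  Indels, quality
modeling and position-dependent error profiles are deliberately omitted:
the hashing engine's behavior depends only on read length and composition.
Output is byte-deterministic for a fixed config and rng seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["SimulationConfig", "simulate_reads"]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated read set.

    error_rate is the per-base substitution probability; an erroneous base is
    replaced by a uniformly chosen different base.
    """

    genome_length: int
    n_reads: int
    read_length: int
    error_rate: float = 0.01
    rng_seed: int = 0
    fmt: str = "fasta"  # "fasta" | "fastq"

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if not 0 < self.read_length <= self.genome_length:
            raise ValueError("read_length must be in [1, genome_length]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.fmt not in ("fasta", "fastq"):
            raise ValueError(f"unknown output format {self.fmt!r}")


def simulate_reads(config: SimulationConfig, out: str | Path) -> Path:
    """Write ``config.n_reads`` simulated reads to ``out``; returns the path."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    genome = rng.integers(0, 4, size=config.genome_length, dtype=np.uint8)
    out = Path(out)
    qual_line = "I" * config.read_length  # constant Q40 placeholder
    with open(out, "w") as fh:
        for i in range(config.n_reads):
            start = int(rng.integers(0, config.genome_length - config.read_length + 1))
            read = genome[start : start + config.read_length].copy()
            if config.error_rate > 0:
                err = rng.random(config.read_length) < config.error_rate
                n_err = int(err.sum())
                if n_err:
                    # add 1..3 mod 4: always a *different* base
                    offset = rng.integers(1, 4, size=n_err, dtype=np.uint8)
                    read[err] = (read[err] + offset) % 4
            seq = _ALPHABET[read].tobytes().decode("ascii")
            name = f"read_{i}_pos{start}"
            if config.fmt == "fasta":
                fh.write(f">{name}\n{seq}\n")
            else:
                fh.write(f"@{name}\n{seq}\n+\n{qual_line}\n")
    return out
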