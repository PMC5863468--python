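"""Sequence and seed file I/O, and the hash TSV writer.

FASTA and FASTQ (optionally gzip-compressed) are parsed with Biopython's
SeqIO; the format is auto-detected from the first non-whitespace byte after
decompression ('>' FASTA, '@' FASTQ).  Seed files are plain text, one binary
pattern per line; '#' comments and blank lines are ignored.  Hashes are
written as a TSV with columns read_id, seed_index, position, hash — rows
ordered by record, then seed, then position, byte-deterministic for a fixed
input.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO

from .hashing import HashVector, hash_to_bits
from .seeds import SeedError, SpacedSeed, parse_seed

__all__ = [
    "SequenceRecord",
    "read_sequences",
    "read_seed_file",
    "write_hashes",
    "published_seed_path",
    "load_published_seeds",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One read: identifier, nucleotide string, and file-of-origin metadata."""

    id: str
    sequence: str
    source: str = ""
    ordinal: int = 0


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _detect_format(handle: IO[str]) -> str | None:
    """Peek the first non-whitespace character: '>' FASTA, '@' FASTQ."""
    pos = handle.tell()
    fmt = None
    while True:
        c = handle.read(1)
        if not c:
            break
        if c.isspace():
            continue
        fmt = {"@": "fastq", ">": "fasta"}.get(c)
        if fmt is None:
            raise ValueError(f"unrecognized sequence file (starts with {c!r})")
        break
    handle.seek(pos)
    return fmt


def read_sequences(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA/FASTQ file, gzip transparent.

    An empty file yields an empty stream.  Malformed records raise a
    ``ValueError`` naming the record ordinal.
    """
    path = Path(path)
    with _open_text(path) as handle:
        fmt = _detect_format(handle)
        if fmt is None:
            return
        parser = SeqIO.parse(handle, fmt)
        ordinal = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}: malformed {fmt} record #{ordinal}: {exc}"
                ) from exc
            yield SequenceRecord(
                id=rec.id, sequence=str(rec.seq), source=str(path), ordinal=ordinal
            )
            ordinal += 1


def read_seed_file(path: str | Path) -> list[SpacedSeed]:
    """Parse a seed file: one pattern per line, '#' comments and blanks skipped."""
    seeds = []
    path = Path(path)
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                seeds.append(parse_seed(line))
            except SeedError as exc:
                raise SeedError(f"{path.name}:{lineno}: {exc}") from exc
    return seeds


def write_hashes(
    results: Iterable[tuple[SequenceRecord, Sequence[HashVector]]],
    out: str | Path,
    seeds: Sequence[SpacedSeed] | None = None,
    bits: bool = False,
) -> None:
    """Write hash vectors as TSV: read_id, seed_index, position, hash.

    ``results`` yields, per record, one HashVector per seed (input seed
    order).  With ``bits=True`` the hash column holds MSB-first bit strings
    (requires ``seeds`` for the word width); otherwise decimal integers.
    """
    if bits and seeds is None:
        raise ValueError("bits=True requires the seed list for the word width")
    with open(out, "w") as fh:
        fh.write("read_id\tseed_index\tposition\thash\n")
        for record, vectors in results:
            for seed_index, vec in enumerate(vectors):
                for pos, h in zip(vec.positions, vec.hashes):
                    if bits:
                        text = hash_to_bits(int(h), seeds[seed_index])
                    else:
                        text = str(int(h))
                    fh.write(f"{record.id}\t{seed_index}\t{int(pos)}\t{text}\n")


def published_seed_path() -> Path:
    """Path of the packaged seed file (Q0–Q10, weight 22 each)."""
    return Path(str(resources.files("fshash").joinpath("data/published_seeds.txt")))


def load_published_seeds(include_special: bool = True) -> list[SpacedSeed]:
    """The packaged published seeds.

    Q1–Q9 are literature seeds (hit-probability-, overlap-complexity- and
    sensitivity-optimized; span 31, weight 22).  With ``include_special`` the
    contiguous 22-mer Q0 and the alternating seed Q10 are appended.
    """
    seeds = read_seed_file(published_seed_path())
    return seeds if include_special else seeds[:9]
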