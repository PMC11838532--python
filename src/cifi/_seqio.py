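"""Small sequence I/O helpers (gzip-transparent) shared across modules."""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Iterator, TextIO


def xopen(path: str | Path, mode: str = "rt") -> TextIO:
    """Open ``path`` transparently handling a ``.gz`` suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, mode.replace("t", "") + "b")) \
            if "r" in mode else io.TextIOWrapper(gzip.open(path, "wb"))
    return open(path, mode)


def read_fastx(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(name, sequence)`` from a FASTA or FASTQ file (optionally gzipped).

    Format is auto-detected from the first character. Only the first
    whitespace-delimited token of the header is kept as the name.
    """
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence


def write_fasta(records, path: str | Path, width: int = 80) -> None:
    with xopen(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records, path: str | Path, qual_char: str = "I") -> None:
    with xopen(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")


def read_chromsizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>size`` file preserving order."""
    sizes: dict[str, int] = {}
    with xopen(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    if not sizes:
        raise ValueError(f"empty chromsizes file: {path}")
    return sizes


def write_chromsizes(sizes: dict[str, int], path: str | Path) -> None:
    with xopen(path, "wt") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
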