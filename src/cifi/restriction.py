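"""Restriction enzymes, genome fragment maps, and in-silico read digestion.

Coordinates are 0-based half-open everywhere in this module; conversion to
1-based happens only at serialization boundaries elsewhere in the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from cifi._seqio import read_fastx, xopen

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC ambiguity codes for the custom-enzyme path. "N" in a motif matches
# any real base but never an N in the sequence.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse-complement an uppercase DNA string (A/C/G/T/N)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction specification: recognition motif plus top-strand cut offset.

    Parameters
    ----------
    name :
        Short display name, e.g. ``"DpnII"``.
    motif :
        Uppercase recognition sequence. Built-ins are plain ACGT; custom
        enzymes may use IUPAC ambiguity codes (expanded at search time).
    cut_offset :
        Cut position within the motif on the top strand, in ``[0, len(motif)]``.
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("enzyme motif must be non-empty")
        motif = self.motif.upper()
        object.__setattr__(self, "motif", motif)
        bad = set(motif) - set(_IUPAC)
        if bad:
            raise ValueError(f"motif {motif!r} contains non-IUPAC characters: {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(motif):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside [0, {len(motif)}] for motif {motif!r}"
            )

    @property
    def is_literal(self) -> bool:
        """True when the motif uses only A/C/G/T (fast exact search)."""
        return set(self.motif) <= set("ACGT")


DPNII = Enzyme("DpnII", "GATC", 0)
HINDIII = Enzyme("HindIII", "AAGCTT", 1)
NLAIII = Enzyme("NlaIII", "CATG", 4)

ENZYMES: dict[str, Enzyme] = {e.name.lower(): e for e in (DPNII, HINDIII, NLAIII)}


def get_enzyme(name: str, motif: str | None = None, cut_offset: int | None = None) -> Enzyme:
    """Look up a built-in enzyme by name, or build a custom one.

    ``name="custom"`` (or any unknown name) requires ``motif`` and
    ``cut_offset``.
    """
    key = name.lower()
    if key in ENZYMES:
        return ENZYMES[key]
    if motif is None or cut_offset is None:
        raise KeyError(
            f"unknown enzyme {name!r}; built-ins are "
            f"{sorted(e.name for e in ENZYMES.values())} "
            "(pass motif and cut_offset for a custom enzyme)"
        )
    return Enzyme(name, motif, cut_offset)


_VALID_SEQ = re.compile(r"^[ACGTN]*$")


def _normalize_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-DNA characters: {bad}")
    return seq


def find_cut_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """Return the ordered 0-based cut positions of ``enzyme`` in ``sequence``.

    A cut is reported at ``p = motif_start + cut_offset`` for every motif
    occurrence, including overlapping occurrences. Cuts falling exactly on
    the sequence boundaries (0 or ``len(sequence)``) are suppressed since
    they do not split anything. Matching is case-insensitive; ``N`` in the
    sequence never matches any motif position.
    """
    seq = _normalize_sequence(sequence)
    motif = enzyme.motif
    cuts: list[int] = []
    if enzyme.is_literal:
        start = seq.find(motif)
        while start != -1:
            cuts.append(start + enzyme.cut_offset)
            start = seq.find(motif, start + 1)  # overlapping occurrences count
    else:
        pattern = re.compile("(?=" + "".join(f"[{_IUPAC[c]}]" for c in motif) + ")")
        cuts = [m.start() + enzyme.cut_offset for m in pattern.finditer(seq)]
    return [p for p in cuts if 0 < p < len(seq)]


@dataclass
class FragmentMap:
    """Genome-wide restriction fragment map.

    Fragments per chromosome tile the chromosome exactly (first start 0,
    last end = chromosome length, adjacent fragments abut). ``offsets``
    give the global index of each chromosome's first fragment so that
    ``fragment_index`` is dense genome-wide.
    """

    enzyme: Enzyme
    chrom_sizes: dict[str, int]
    boundaries: dict[str, np.ndarray]  # per chrom: cut positions incl. 0 and L
    offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        off = 0
        self.offsets = {}
        for chrom in self.chrom_sizes:
            self.offsets[chrom] = off
            off += len(self.boundaries[chrom]) - 1
        self._total = off

    @property
    def n_fragments(self) -> int:
        return self._total

    def fragments(self, chrom: str) -> np.ndarray:
        """``(n, 2)`` array of (start, end) for one chromosome."""
        b = self.boundaries[chrom]
        return np.column_stack([b[:-1], b[1:]])

    def n_fragments_chrom(self, chrom: str) -> int:
        return len(self.boundaries[chrom]) - 1

    def midpoints(self, chrom: str) -> np.ndarray:
        b = self.boundaries[chrom]
        return (b[:-1] + b[1:]) / 2.0

    def fragment_at(self, chrom: str, pos: int) -> int:
        """Global index of the fragment containing ``pos`` (0-based)."""
        b = self.boundaries[chrom]
        if not 0 <= pos < b[-1]:
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        return self.offsets[chrom] + int(np.searchsorted(b, pos, side="right")) - 1

    def nearest_fragment(self, chrom: str, pos: float) -> int:
        """Global index of the fragment whose midpoint is nearest ``pos``."""
        mids = self.midpoints(chrom)
        return self.offsets[chrom] + int(np.argmin(np.abs(mids - pos)))

    def fragment_coords(self, index: int) -> tuple[str, int, int]:
        """Inverse of the global index: ``(chrom, start, end)``."""
        for chrom in self.chrom_sizes:
            off = self.offsets[chrom]
            n = self.n_fragments_chrom(chrom)
            if off <= index < off + n:
                b = self.boundaries[chrom]
                i = index - off
                return chrom, int(b[i]), int(b[i + 1])
        raise IndexError(f"fragment index {index} out of range")

    def to_bed(self, path: str | Path) -> None:
        """Write fragments as BED with the global fragment index in the name column."""
        with xopen(path, "wt") as fh:
            for chrom in self.chrom_sizes:
                b = self.boundaries[chrom]
                off = self.offsets[chrom]
                for i in range(len(b) - 1):
                    fh.write(f"{chrom}\t{b[i]}\t{b[i + 1]}\tfragment_{off + i}\n")


def digest_genome(genome: Mapping[str, str] | str | Path, enzyme: Enzyme) -> FragmentMap:
    """Digest a reference genome into a :class:`FragmentMap`.

    ``genome`` is either a FASTA path or an ordered mapping of name to
    sequence. Fragment count per chromosome equals the number of internal
    cut sites plus one. Deterministic for fixed input.
    """
    if isinstance(genome, (str, Path)):
        records: Iterable[tuple[str, str]] = read_fastx(genome)
    else:
        records = genome.items()

    chrom_sizes: dict[str, int] = {}
    boundaries: dict[str, np.ndarray] = {}
    for name, seq in records:
        if name in chrom_sizes:
            raise ValueError(f"duplicate sequence name in genome: {name!r}")
        if len(seq) == 0:
            raise ValueError(f"zero-length sequence in genome: {name!r}")
        cuts = find_cut_sites(seq, enzyme)
        chrom_sizes[name] = len(seq)
        boundaries[name] = np.asarray([0, *cuts, len(seq)], dtype=np.int64)
    if not chrom_sizes:
        raise ValueError("empty genome: no FASTA records found")
    return FragmentMap(enzyme=enzyme, chrom_sizes=chrom_sizes, boundaries=boundaries)


@dataclass(frozen=True)
class SegmentRecord:
    """One in-silico-digested piece of a concatemer read.

    ``read_start``/``read_end`` are 0-based half-open offsets within the
    read. ``filtered`` marks segments shorter than the digestion length
    floor; they are excluded from downstream pairing but kept so that the
    concatenation of all segments always reconstructs the read.
    """

    read_id: str
    ordinal: int
    read_start: int
    read_end: int
    sequence: str
    filtered: bool = False

    def __len__(self) -> int:
        return self.read_end - self.read_start

    @property
    def name(self) -> str:
        """Aligner-facing segment name: ``{read_id}:{ordinal}:{start}:{end}``."""
        return f"{self.read_id}:{self.ordinal}:{self.read_start}:{self.read_end}"


def digest_read(
    read_id: str,
    sequence: str,
    enzyme: Enzyme,
    min_segment_length: int = 20,
) -> list[SegmentRecord]:
    """Split one concatemer read at every cut site of ``enzyme``.

    Returns all segments in read order; ordinals count every segment,
    filtered or not. An empty sequence yields an empty list.
    """
    if min_segment_length < 1:
        raise ValueError("min_segment_length must be >= 1")
    if not sequence:
        return []
    seq = _normalize_sequence(sequence)
    cuts = find_cut_sites(seq, enzyme)
    edges = [0, *cuts, len(seq)]
    return [
        SegmentRecord(
            read_id=read_id,
            ordinal=i,
            read_start=edges[i],
            read_end=edges[i + 1],
            sequence=seq[edges[i] : edges[i + 1]],
            filtered=(edges[i + 1] - edges[i]) < min_segment_length,
        )
        for i in range(len(edges) - 1)
    ]


def digest_reads(
    reads: Iterable[tuple[str, str]],
    enzyme: Enzyme,
    min_segment_length: int = 20,
) -> Iterator[list[SegmentRecord]]:
    """Digest a stream of ``(read_id, sequence)`` records, one list per read."""
    for read_id, seq in reads:
        yield digest_read(read_id, seq, enzyme, min_segment_length)


def lower_median(values: Sequence[float] | np.ndarray) -> float:
    """Median using the lower-median convention on even counts."""
    arr = np.sort(np.asarray(values))
    if arr.size == 0:
        raise ValueError("lower_median of empty input")
    return float(arr[(arr.size - 1) // 2])


@dataclass
class SegmentStats:
    n_reads: int
    n_segments: int
    median_segments_per_read: float
    median_segment_length: float
    count_hist: tuple[np.ndarray, np.ndarray]  # (edges, counts)
    length_hist: tuple[np.ndarray, np.ndarray]

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_segments": self.n_segments,
            "median_segments_per_read": self.median_segments_per_read,
            "median_segment_length": self.median_segment_length,
        }


def segment_stats(
    segments_per_read: Iterable[Sequence[SegmentRecord]],
    include_filtered: bool = False,
) -> SegmentStats:
    """Summarize digestion output over many reads.

    Medians use the lower-median convention; histograms are returned as
    ``(edges, counts)`` pairs. By default, length-filtered segments are
    excluded from both statistics (they never enter pairing).
    """
    counts: list[int] = []
    lengths: list[int] = []
    for segs in segments_per_read:
        kept = [s for s in segs if include_filtered or not s.filtered]
        counts.append(len(kept))
        lengths.extend(len(s) for s in kept)
    if not counts:
        raise ValueError("segment_stats needs at least one read")

    count_arr = np.asarray(counts)
    length_arr = np.asarray(lengths)
    count_edges = np.arange(0, count_arr.max() + 2)
    count_hist = np.histogram(count_arr, bins=count_edges)[0]
    if length_arr.size:
        length_edges = np.histogram_bin_edges(length_arr, bins=50)
        length_hist = np.histogram(length_arr, bins=length_edges)[0]
        med_len = lower_median(length_arr)
    else:
        length_edges, length_hist, med_len = np.array([0.0, 1.0]), np.array([0]), 0.0

    return SegmentStats(
        n_reads=len(counts),
        n_segments=int(length_arr.size),
        median_segments_per_read=lower_median(count_arr),
        median_segment_length=med_len,
        count_hist=(count_edges, count_hist),
        length_hist=(length_edges, length_hist),
    )


def write_segments(
    segments_per_read: Iterable[Sequence[SegmentRecord]],
    fastq_path: str | Path,
    tsv_path: str | Path,
) -> dict[str, int]:
    """Write segments as FASTQ (aligner-facing) plus a TSV sidecar.

    FASTQ names follow the ``{read_id}:{ordinal}:{read_start}:{read_end}``
    contract; filtered segments appear only in the sidecar. Returns counters.
    """
    n_reads = n_segments = n_filtered = 0
    with xopen(fastq_path, "wt") as fq, xopen(tsv_path, "wt") as tsv:
        tsv.write("read_id\tordinal\tread_start\tread_end\tfiltered\n")
        for segs in segments_per_read:
            n_reads += 1
            for s in segs:
                n_segments += 1
                tsv.write(
                    f"{s.read_id}\t{s.ordinal}\t{s.read_start}\t{s.read_end}"
                    f"\t{int(s.filtered)}\n"
                )
                if s.filtered:
                    n_filtered += 1
                else:
                    fq.write(f"@{s.name}\n{s.sequence}\n+\n{'I' * len(s)}\n")
    return {"reads": n_reads, "segments": n_segments, "segments_filtered": n_filtered}
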