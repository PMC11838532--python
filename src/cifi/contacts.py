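"""Per-segment alignment ingestion and pairwise contact expansion.

One concatemer read with ``n`` mapped monomers contributes all
``n * (n - 1) / 2`` unordered pairwise contacts. Positions are 0-based
internally and shifted to 1-based only in the serialized 4DN ``.pairs``
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import combinations, groupby
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from cifi._seqio import xopen

PAIRS_HEADER = "## pairs format v1.0"
PAIRS_COLUMNS = "#columns: readID chr1 pos1 chr2 pos2 strand1 strand2"

ORACLE_TSV_COLUMNS = ("read_id", "ordinal", "chrom", "start", "end", "strand", "mapq")


@dataclass(frozen=True)
class MonomerAlignment:
    """Selected placement of one read segment on the reference.

    ``start``/``end`` are 0-based half-open reference coordinates. ``mapq``
    follows SAM semantics (0-60). ``fragment_index`` optionally records the
    nearest restriction fragment by midpoint.
    """

    read_id: str
    ordinal: int
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    fragment_index: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"alignment with end <= start: {self}")
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"MAPQ {self.mapq} outside [0, 60]")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class ContactPair:
    """One unordered pairwise interaction between two monomers of a read.

    Mate order is normalized to the upper triangle under (chromosome rank,
    position); ``pos`` is the 5'-most reference coordinate of the monomer
    (0-based here, 1-based when serialized). ``ordinal1 < ordinal2`` always.
    """

    read_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    ordinal1: int
    ordinal2: int
    pair_type: str = "cis"  # "cis" | "trans"
    duplicate: bool = False

    @property
    def distance(self) -> int | None:
        """Reference distance for cis pairs, else None."""
        return abs(self.pos2 - self.pos1) if self.pair_type == "cis" else None


class AlignmentNameError(ValueError):
    """Segment name does not match the ``read:ordinal:start:end`` contract."""


def parse_segment_name(name: str) -> tuple[str, int, int, int]:
    """Split an aligner-facing segment name into its components.

    The contract is ``{read_id}:{ordinal}:{read_start}:{read_end}``; the
    read id itself may contain colons, so splitting is from the right.
    """
    parts = name.rsplit(":", 3)
    if len(parts) != 4:
        raise AlignmentNameError(f"segment name {name!r} does not match read:ordinal:start:end")
    try:
        return parts[0], int(parts[1]), int(parts[2]), int(parts[3])
    except ValueError as exc:
        raise AlignmentNameError(f"segment name {name!r}: {exc}") from exc


@dataclass
class _Candidate:
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    primary: bool


def _iter_bam_candidates(path: str | Path) -> Iterator[tuple[tuple[str, int], _Candidate]]:
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for rec in bam:
            if rec.is_unmapped:
                continue
            read_id, ordinal, _, _ = parse_segment_name(rec.query_name)
            yield (read_id, ordinal), _Candidate(
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                primary=not (rec.is_secondary or rec.is_supplementary),
            )


def _iter_tsv_candidates(path: str | Path) -> Iterator[tuple[tuple[str, int], _Candidate]]:
    with xopen(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[: len(ORACLE_TSV_COLUMNS)]) != ORACLE_TSV_COLUMNS:
            raise ValueError(
                f"oracle TSV {path} must start with columns {ORACLE_TSV_COLUMNS}, got {header}"
            )
        for line in fh:
            f = line.rstrip("\n").split("\t")
            yield (f[0], int(f[1])), _Candidate(
                chrom=f[2], start=int(f[3]), end=int(f[4]),
                strand=f[5], mapq=int(f[6]), primary=True,
            )


def _select(candidates: Sequence[_Candidate]) -> _Candidate:
    # Primary flag wins; then highest MAPQ; then longest span; then smallest
    # (chrom, start) for determinism.
    return min(
        candidates,
        key=lambda c: (not c.primary, -c.mapq, -(c.end - c.start), c.chrom, c.start),
    )


def ingest_alignments(
    source: str | Path | Iterable[tuple[tuple[str, int], _Candidate]],
    mapq_min: int = 1,
    fragment_map=None,
    known_chroms: Iterable[str] | None = None,
) -> tuple[list[MonomerAlignment], dict[str, int]]:
    """Select exactly one placement per (read_id, ordinal) segment.

    ``source`` is a BAM path (segment names must follow the
    ``read:ordinal:start:end`` contract), the simulator's oracle TSV, or an
    iterable of pre-parsed candidates. Secondary/supplementary records are
    never selected over a primary. Segments whose best mapping has
    ``mapq < mapq_min`` are dropped and counted.

    Returns the selected monomers (grouped by read, in read/ordinal order)
    and a counter dict.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        iterator = (
            _iter_bam_candidates(path)
            if path.suffix in {".bam", ".sam", ".cram"}
            else _iter_tsv_candidates(path)
        )
    else:
        iterator = iter(source)

    by_segment: dict[tuple[str, int], list[_Candidate]] = {}
    for key, cand in iterator:
        by_segment.setdefault(key, []).append(cand)

    known = set(known_chroms) if known_chroms is not None else None
    monomers: list[MonomerAlignment] = []
    n_subthreshold = 0
    for (read_id, ordinal) in sorted(by_segment):
        best = _select(by_segment[(read_id, ordinal)])
        if known is not None and best.chrom not in known:
            raise ValueError(
                f"alignment of {read_id}:{ordinal} on unknown reference {best.chrom!r}"
            )
        if best.mapq < mapq_min:
            n_subthreshold += 1
            continue
        frag = (
            fragment_map.nearest_fragment(best.chrom, (best.start + best.end) / 2)
            if fragment_map is not None
            else None
        )
        monomers.append(
            MonomerAlignment(
                read_id=read_id, ordinal=ordinal, chrom=best.chrom,
                start=best.start, end=best.end, strand=best.strand,
                mapq=best.mapq, fragment_index=frag,
            )
        )
    stats = {
        "segments_aligned": len(by_segment),
        "monomers_selected": len(monomers),
        "segments_below_mapq": n_subthreshold,
    }
    return monomers, stats


def _chrom_rank(order: Sequence[str] | Mapping[str, int] | None):
    if order is None:
        return lambda chrom: chrom  # lexicographic fallback
    if isinstance(order, Mapping):
        ranks = dict(order)
    else:
        ranks = {c: i for i, c in enumerate(order)}

    def rank(chrom: str):
        try:
            return ranks[chrom]
        except KeyError:
            raise ValueError(f"chromosome {chrom!r} not in declared chromosome order") from None

    return rank


def expand_pairs(
    monomers: Sequence[MonomerAlignment],
    chrom_order: Sequence[str] | Mapping[str, int] | None = None,
) -> list[ContactPair]:
    """Expand one read's monomers into all unordered pairwise contacts.

    Returns exactly ``C(n, 2)`` pairs. The anchor position of each monomer
    is its 5'-most reference coordinate (alignment start); mates are
    normalized to upper-triangle order under (chromosome rank, position)
    while ordinals keep ``ordinal1 < ordinal2``.
    """
    if len({m.read_id for m in monomers}) > 1:
        raise ValueError("expand_pairs expects monomers of a single read")
    rank = _chrom_rank(chrom_order)
    ordered = sorted(monomers, key=lambda m: m.ordinal)
    pairs: list[ContactPair] = []
    for a, b in combinations(ordered, 2):
        if (rank(b.chrom), b.start) < (rank(a.chrom), a.start):
            a, b = b, a
        pairs.append(
            ContactPair(
                read_id=a.read_id,
                chrom1=a.chrom, pos1=a.start, strand1=a.strand,
                chrom2=b.chrom, pos2=b.start, strand2=b.strand,
                ordinal1=min(a.ordinal, b.ordinal),
                ordinal2=max(a.ordinal, b.ordinal),
                pair_type="cis" if a.chrom == b.chrom else "trans",
            )
        )
    return pairs


def expand_all(
    monomers: Sequence[MonomerAlignment],
    chrom_order: Sequence[str] | Mapping[str, int] | None = None,
) -> list[ContactPair]:
    """Group monomers by read id and expand every read; order preserved."""
    out: list[ContactPair] = []
    keyed = sorted(monomers, key=lambda m: (m.read_id, m.ordinal))
    for _, group in groupby(keyed, key=lambda m: m.read_id):
        out.extend(expand_pairs(list(group), chrom_order))
    return out


def _sort_key(rank):
    def key(p: ContactPair):
        return (rank(p.chrom1), p.pos1, rank(p.chrom2), p.pos2,
                p.strand1, p.strand2, p.read_id, p.ordinal1, p.ordinal2)
    return key


def sort_pairs(
    pairs: Iterable[ContactPair],
    chrom_order: Sequence[str] | Mapping[str, int] | None = None,
) -> list[ContactPair]:
    """Sort pairs by (chrom1, pos1, chrom2, pos2, strands, read) for dedup."""
    return sorted(pairs, key=_sort_key(_chrom_rank(chrom_order)))


def dedup_pairs(
    pairs: Sequence[ContactPair],
    chrom_order: Sequence[str] | Mapping[str, int] | None = None,
) -> list[ContactPair]:
    """Flag coordinate-identical pairs from different reads as duplicates.

    Input must already be sorted by (chrom1, pos1, chrom2, pos2); raises
    otherwise. Among pairs identical on (chrom1, pos1, strand1, chrom2,
    pos2, strand2), every pair whose read id differs from the first one
    seen is flagged; pairs of one read never flag each other.
    """
    rank = _chrom_rank(chrom_order)
    coords = [(rank(p.chrom1), p.pos1, rank(p.chrom2), p.pos2) for p in pairs]
    if any(coords[i] > coords[i + 1] for i in range(len(coords) - 1)):
        raise ValueError("dedup_pairs requires input sorted by (chrom1, pos1, chrom2, pos2)")

    out: list[ContactPair] = []
    keeper_read: dict[tuple, str] = {}
    last_coord = None
    for p, coord in zip(pairs, coords):
        if coord != last_coord:
            keeper_read.clear()
            last_coord = coord
        sig = (p.strand1, p.strand2)
        first = keeper_read.setdefault(sig, p.read_id)
        out.append(replace(p, duplicate=(p.read_id != first)))
    return out


def cis_fraction(pairs: Iterable[ContactPair]) -> float:
    """Fraction of non-duplicate pairs that are intrachromosomal."""
    n_cis = n = 0
    for p in pairs:
        if p.duplicate:
            continue
        n += 1
        n_cis += p.pair_type == "cis"
    if n == 0:
        raise ValueError("cis_fraction needs at least one non-duplicate pair")
    return n_cis / n


def pair_stats(pairs: Sequence[ContactPair]) -> dict:
    """Counters over a pair stream, before and after dedup."""
    n = len(pairs)
    n_dup = sum(p.duplicate for p in pairs)
    n_cis = sum(p.pair_type == "cis" for p in pairs)
    n_cis_nodup = sum(p.pair_type == "cis" and not p.duplicate for p in pairs)
    stats = {
        "pairs_total": n,
        "pairs_duplicate": n_dup,
        "pairs_nodup": n - n_dup,
        "pairs_cis": n_cis,
        "pairs_cis_nodup": n_cis_nodup,
    }
    if n:
        stats["cis_fraction_all"] = n_cis / n
    if n - n_dup:
        stats["cis_fraction_nodup"] = n_cis_nodup / (n - n_dup)
    return stats


def write_pairs(
    pairs: Iterable[ContactPair],
    chrom_sizes: Mapping[str, int],
    path: str | Path,
    include_duplicates: bool = False,
) -> int:
    """Serialize pairs in 4DN ``.pairs`` text format (1-based positions).

    ``chrom_sizes`` must be ordered (genome order) and cover every
    chromosome referenced by a pair. Returns the number of pairs written.
    """
    known = set(chrom_sizes)
    n = 0
    with xopen(path, "wt") as fh:
        fh.write(PAIRS_HEADER + "\n")
        fh.write("#shape: upper triangle\n")
        for chrom, size in chrom_sizes.items():
            fh.write(f"#chromsize: {chrom} {size}\n")
        fh.write(PAIRS_COLUMNS + "\n")
        for p in pairs:
            if p.duplicate and not include_duplicates:
                continue
            if p.chrom1 not in known or p.chrom2 not in known:
                raise ValueError(f"pair on unknown chromosome: {p}")
            fh.write(
                f"{p.read_id}\t{p.chrom1}\t{p.pos1 + 1}\t{p.chrom2}\t{p.pos2 + 1}"
                f"\t{p.strand1}\t{p.strand2}\n"
            )
            n += 1
    return n


def read_pairs(path: str | Path) -> tuple[list[ContactPair], dict[str, int]]:
    """Parse a 4DN ``.pairs`` file back into pairs and ordered chrom sizes."""
    pairs: list[ContactPair] = []
    sizes: dict[str, int] = {}
    with xopen(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != PAIRS_HEADER:
            raise ValueError(f"{path} is not a pairs v1.0 file (header {first!r})")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#chromsize:"):
                _, chrom, size = line.split()
                sizes[chrom] = int(size)
                continue
            if line.startswith("#") or not line:
                continue
            f = line.split("\t")
            chrom1, pos1, chrom2, pos2 = f[1], int(f[2]) - 1, f[3], int(f[4]) - 1
            pairs.append(
                ContactPair(
                    read_id=f[0], chrom1=chrom1, pos1=pos1, strand1=f[5],
                    chrom2=chrom2, pos2=pos2, strand2=f[6],
                    ordinal1=0, ordinal2=1,
                    pair_type="cis" if chrom1 == chrom2 else "trans",
                )
            )
    return pairs, sizes


def write_stats_json(stats: Mapping, path: str | Path) -> None:
    with xopen(path, "wt") as fh:
        json.dump(dict(stats), fh, indent=2, sort_keys=True)
        fh.write("\n")
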