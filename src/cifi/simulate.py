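"""Synthetic genomes and concatemer reads with known contact structure.

Reads are built from restriction fragments of a simulated genome: an
anchor fragment plus partners drawn either in trans (uniform on another
chromosome) or in cis with distance ``s`` sampled proportional to
``s**-alpha`` over fragment midpoints. Fragment cores are joined with the
full recognition motif at every junction, so re-digesting a simulated read
recovers exactly one segment per planted fragment. Truth tables and
perfect "oracle" alignments are emitted for every segment, which makes the
whole downstream pipeline testable without an aligner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from cifi._seqio import write_chromsizes, write_fasta, write_fastq, xopen
from cifi.contacts import ORACLE_TSV_COLUMNS
from cifi.restriction import Enzyme, FragmentMap, digest_genome, get_enzyme, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PlantedDuplication:
    """A source interval copied elsewhere at a stated identity.

    Segments landing in either copy are emitted with MAPQ 0, modelling
    multi-mapping ambiguity.
    """

    chrom: str
    start: int
    end: int
    identity: float = 0.98
    target_chrom: str | None = None  # default: same chromosome
    target_start: int | None = None  # default: mirrored near the far end


@dataclass
class TADBlocks:
    """Planted block structure on one chromosome.

    ``boundaries`` are internal boundary positions in bp; cis partner
    weights are multiplied by ``ratio`` when anchor and partner fall in
    the same block.
    """

    boundaries: Sequence[int]
    ratio: float = 4.0


@dataclass
class SimConfig:
    """Full parameterization of one simulation run."""

    seed: int = 0
    chrom_lengths: Sequence[int] = (1_000_000, 800_000)
    gc: float = 0.5
    enzyme: str = "DpnII"
    n_reads: int = 1000
    segments_median: int = 17
    nb_dispersion: float = 1.5
    alpha: float = 1.0
    trans_fraction: float = 0.1
    duplication_rate: float = 0.0
    min_cis_dist: int = 1000
    min_core: int = 20
    duplication: PlantedDuplication | None = None
    tad_blocks: dict[str, TADBlocks] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("trans_fraction", "duplication_rate", "gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.duplication_rate >= 1.0:
            raise ValueError("duplication_rate must be < 1")
        if self.segments_median < 1:
            raise ValueError("segments_median must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]

    def get_enzyme(self) -> Enzyme:
        return get_enzyme(self.enzyme)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "duplication" in d and isinstance(d["duplication"], dict):
            d["duplication"] = PlantedDuplication(**d["duplication"])
        if "tad_blocks" in d:
            d["tad_blocks"] = {
                chrom: (TADBlocks(**v) if isinstance(v, dict) else v)
                for chrom, v in d["tad_blocks"].items()
            }
        return cls(**d)

    @classmethod
    def from_toml(cls, path: str | Path) -> "SimConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


@dataclass
class SimGenome:
    """A simulated reference: sequences, fragment map, and duplicated intervals."""

    seqs: dict[str, str]
    fragment_map: FragmentMap
    dup_intervals: list[tuple[str, int, int]]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(self.seqs.items(), path)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def simulate_genome(config: SimConfig) -> SimGenome:
    """Generate a random genome, implant the optional duplication, digest it.

    Deterministic for a fixed seed. The duplicated copy carries i.i.d.
    substitutions at rate ``1 - identity``.
    """
    rng = np.random.default_rng([config.seed, 0])
    seqs = {
        name: _random_sequence(rng, length, config.gc)
        for name, length in zip(config.chrom_names, config.chrom_lengths)
    }
    dup_intervals: list[tuple[str, int, int]] = []
    dup = config.duplication
    if dup is not None:
        src = seqs[dup.chrom][dup.start : dup.end]
        if not src:
            raise ValueError("duplication source interval is empty")
        arr = np.frombuffer(src.encode("ascii"), dtype=np.uint8).copy()
        hit = rng.random(len(arr)) < (1.0 - dup.identity)
        shift = rng.integers(1, 4, size=int(hit.sum()))
        base_idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(base_idx + shift) % 4]
        copy = arr.tobytes().decode("ascii")
        tchrom = dup.target_chrom or dup.chrom
        tstart = (
            dup.target_start
            if dup.target_start is not None
            else len(seqs[tchrom]) - 2 * len(copy)
        )
        if tstart < 0 or tstart + len(copy) > len(seqs[tchrom]):
            raise ValueError("duplication target does not fit in the target chromosome")
        s = seqs[tchrom]
        seqs[tchrom] = s[:tstart] + copy + s[tstart + len(copy):]
        dup_intervals = [
            (dup.chrom, dup.start, dup.end),
            (tchrom, tstart, tstart + len(copy)),
        ]
    fragment_map = digest_genome(seqs, config.get_enzyme())
    return SimGenome(seqs=seqs, fragment_map=fragment_map, dup_intervals=dup_intervals)


def _nb_mean_for_median(target_median: int, dispersion: float) -> float:
    """Mean of NB(size=dispersion) whose median equals ``target_median``.

    The segment-count distribution is 1 + NB, so ``target_median`` here is
    the desired read median minus one. Found by bisection on the mean
    (the NB median is monotone in the mean), returning the centre of the
    plateau of means sharing the target median.
    """
    if target_median == 0:
        return 0.35  # median 0 for any small mean; pick a stable value

    def median_of(mu: float) -> int:
        p = dispersion / (dispersion + mu)
        return int(sps.nbinom.median(dispersion, p))

    def smallest_mu_with_median_ge(m: int) -> float:
        lo, hi = 1e-3, 10.0 * m + 10.0
        while median_of(hi) < m:
            hi *= 2
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if median_of(mid) >= m:
                hi = mid
            else:
                lo = mid
        return hi

    lo = smallest_mu_with_median_ge(target_median)
    hi = smallest_mu_with_median_ge(target_median + 1)
    return 0.5 * (lo + hi)


class _ChromFragments:
    """Per-chromosome eligible-fragment arrays for partner sampling."""

    def __init__(self, fm: FragmentMap, chrom: str, enzyme: Enzyme, min_core: int,
                 blocks: TADBlocks | None):
        frags = fm.fragments(chrom)
        n = len(frags)
        lengths = frags[:, 1] - frags[:, 0]
        ok = lengths >= len(enzyme.motif) + min_core
        ok[0] = ok[-1] = False  # chromosome-terminal fragments lack a junction side
        self.local_idx = np.nonzero(ok)[0]
        self.starts = frags[self.local_idx, 0]
        self.ends = frags[self.local_idx, 1]
        self.mids = (self.starts + self.ends) / 2.0
        self.block_id = (
            np.searchsorted(np.asarray(blocks.boundaries), self.mids)
            if blocks is not None
            else None
        )
        self.block_ratio = blocks.ratio if blocks is not None else 1.0

    def __len__(self) -> int:
        return len(self.local_idx)


@dataclass
class SimReadSet:
    """Simulated reads plus their truth table and oracle alignments."""

    reads: list[tuple[str, str]]  # (read_id, sequence)
    truth: pd.DataFrame  # read_id ordinal fragment_index chrom start end strand mapq duplicate_of
    config: SimConfig
    genome: SimGenome

    @property
    def oracle(self) -> pd.DataFrame:
        """Perfect alignment table in the oracle TSV column order."""
        return self.truth[list(ORACLE_TSV_COLUMNS)]

    def write_reads_fastq(self, path: str | Path) -> None:
        write_fastq(self.reads, path)

    def write_truth_tsv(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def write_oracle_tsv(self, path: str | Path) -> None:
        self.oracle.to_csv(path, sep="\t", index=False)


def _has_border(motif: str) -> bool:
    return any(motif[:k] == motif[-k:] for k in range(1, len(motif)))


def simulate_reads(genome: SimGenome, config: SimConfig) -> SimReadSet:
    """Simulate concatemer reads over a digested genome.

    Each read is an anchor fragment plus ``n - 1`` partners; a partner is
    trans with probability ``trans_fraction`` (uniform eligible fragment on
    another chromosome), otherwise cis with midpoint distance ``s`` drawn
    proportional to ``s**-alpha`` (optionally steered by planted blocks).
    Segment counts follow 1 + NB(dispersion, mean matched to
    ``segments_median``). Monomer order within the read and strands are
    random; fragment cores are joined with the recognition motif
    reconstituted once per junction.
    """
    enzyme = config.get_enzyme()
    motif = enzyme.motif
    c = enzyme.cut_offset
    if revcomp(motif) != motif or _has_border(motif):
        raise ValueError(
            "simulate_reads requires a palindromic, non-self-overlapping motif "
            "(all built-in enzymes qualify)"
        )
    fm = genome.fragment_map
    for chrom in fm.chrom_sizes:
        if fm.n_fragments_chrom(chrom) < 10:
            raise ValueError(
                f"chromosome {chrom} digests into fewer than 10 fragments; "
                "cis distance sampling is undefined"
            )

    rng = np.random.default_rng([config.seed, 1])
    chroms = list(fm.chrom_sizes)
    per_chrom = {
        chrom: _ChromFragments(fm, chrom, enzyme, config.min_core,
                               config.tad_blocks.get(chrom))
        for chrom in chroms
    }
    n_eligible = np.array([len(per_chrom[c_]) for c_ in chroms], dtype=float)
    if n_eligible.sum() == 0:
        raise ValueError("no eligible fragments to sample from")

    mu = _nb_mean_for_median(config.segments_median - 1, config.nb_dispersion)
    p_nb = config.nb_dispersion / (config.nb_dispersion + mu) if mu > 0 else 1.0
    seg_counts = 1 + sps.nbinom.rvs(
        config.nb_dispersion, p_nb, size=config.n_reads, random_state=rng
    )

    dup_iv = genome.dup_intervals

    def frag_mapq(chrom: str, start: int, end: int) -> int:
        for dchrom, ds, de in dup_iv:
            if chrom == dchrom and start < de and end > ds:
                return 0
        return 60

    def core_seq(chrom: str, start: int, end: int, strand: str) -> str:
        core = genome.seqs[chrom][start + len(motif) - c : end - c]
        return core if strand == "+" else revcomp(core)

    id_width = max(6, len(str(config.n_reads)))
    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple] = []
    for ridx in range(config.n_reads):
        n = int(seg_counts[ridx])
        read_id = f"read{ridx:0{id_width}d}"

        a_chrom = chroms[int(rng.choice(len(chroms), p=n_eligible / n_eligible.sum()))]
        cf = per_chrom[a_chrom]
        a_local = int(rng.integers(len(cf)))
        monomers = [(a_chrom, a_local)]

        if n > 1:
            is_trans = rng.random(n - 1) < config.trans_fraction
            if len(chroms) == 1:
                is_trans[:] = False
            n_cis = int((~is_trans).sum())
            if n_cis:
                d = np.abs(cf.mids - cf.mids[a_local])
                with np.errstate(divide="ignore"):
                    wgt = np.where(d >= config.min_cis_dist, d, np.nan) ** -config.alpha
                wgt = np.nan_to_num(wgt, nan=0.0)
                if cf.block_id is not None:
                    wgt *= np.where(
                        cf.block_id == cf.block_id[a_local], cf.block_ratio, 1.0
                    )
                total = wgt.sum()
                if total <= 0:
                    wgt = np.ones(len(cf))
                    wgt[a_local] = 0.0
                    total = wgt.sum()
                picks = rng.choice(len(cf), size=n_cis, p=wgt / total)
                monomers.extend((a_chrom, int(k)) for k in picks)
            others = [ch for ch in chroms if ch != a_chrom and len(per_chrom[ch])]
            for _ in range(int(is_trans.sum())):
                if not others:  # nowhere to go in trans; fall back to cis uniform
                    monomers.append((a_chrom, int(rng.integers(len(cf)))))
                    continue
                t_chrom = others[int(rng.integers(len(others)))]
                tcf = per_chrom[t_chrom]
                monomers.append((t_chrom, int(rng.integers(len(tcf)))))

        order = rng.permutation(len(monomers))
        strands = rng.choice(np.array(["+", "-"]), size=len(monomers))
        parts: list[str] = []
        for ordinal, k in enumerate(order):
            chrom, local = monomers[k]
            cfrag = per_chrom[chrom]
            start, end = int(cfrag.starts[local]), int(cfrag.ends[local])
            strand = str(strands[ordinal])
            parts.append(core_seq(chrom, start, end, strand))
            truth_rows.append(
                (
                    read_id,
                    ordinal,
                    fm.offsets[chrom] + int(cfrag.local_idx[local]),
                    chrom,
                    start,
                    end,
                    strand,
                    frag_mapq(chrom, start, end),
                    "",
                )
            )
        reads.append((read_id, motif.join(parts)))

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id", "ordinal", "fragment_index", "chrom",
            "start", "end", "strand", "mapq", "duplicate_of",
        ],
    )
    readset = SimReadSet(reads=reads, truth=truth, config=config, genome=genome)
    if config.duplication_rate > 0:
        readset = inject_duplicates(readset, config.duplication_rate)
    return readset


def inject_duplicates(readset: SimReadSet, rate: float, seed: int | None = None) -> SimReadSet:
    """Append exact copies of ``ceil(rate * n)`` randomly chosen reads.

    Copies get fresh ids (``<id>_dupK``) and are truth-linked via the
    ``duplicate_of`` column.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("duplication rate must be in [0, 1)")
    n = len(readset.reads)
    k = math.ceil(rate * n)
    if k == 0:
        return readset
    rng = np.random.default_rng(
        [readset.config.seed, 2] if seed is None else [seed, 2]
    )
    chosen = rng.choice(n, size=k, replace=False)
    reads = list(readset.reads)
    frames = [readset.truth]
    for j, idx in enumerate(sorted(int(i) for i in chosen)):
        orig_id, seq = readset.reads[idx]
        new_id = f"{orig_id}_dup{j}"
        reads.append((new_id, seq))
        block = readset.truth[readset.truth["read_id"] == orig_id].copy()
        block["read_id"] = new_id
        block["duplicate_of"] = orig_id
        frames.append(block)
    truth = pd.concat(frames, ignore_index=True)
    return replace(readset, reads=reads, truth=truth)


def write_simulation(readset: SimReadSet, outdir: str | Path) -> dict[str, str]:
    """Write all simulator artifacts (text formats only) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = readset.genome
    paths = {
        "genome_fasta": str(outdir / "genome.fa"),
        "chromsizes": str(outdir / "genome.chrom.sizes"),
        "fragments_bed": str(outdir / "fragments.bed"),
        "reads_fastq": str(outdir / "reads.fastq"),
        "truth_tsv": str(outdir / "truth.tsv"),
        "oracle_tsv": str(outdir / "oracle_alignments.tsv"),
    }
    genome.write_fasta(paths["genome_fasta"])
    write_chromsizes(genome.chrom_sizes, paths["chromsizes"])
    genome.fragment_map.to_bed(paths["fragments_bed"])
    readset.write_reads_fastq(paths["reads_fastq"])
    readset.write_truth_tsv(paths["truth_tsv"])
    readset.write_oracle_tsv(paths["oracle_tsv"])
    return paths
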