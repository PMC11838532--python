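"""QC analyses: distance decay, MAPQ stratification by annotation class,
and windowed coverage comparison."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cifi._seqio import xopen
from cifi.contacts import ContactPair, MonomerAlignment

MAPQ_THRESHOLDS = (1, 10, 20, 30, 60)


@dataclass
class DecayProfile:
    """Distance-decay histogram of cis contacts on log10-spaced bins.

    ``freq`` is the per-bin count divided by the bin width in bp, i.e. a
    contact frequency density suitable for log-log slope fitting.
    """

    edges: np.ndarray  # length n_bins + 1, strictly increasing
    counts: np.ndarray  # length n_bins
    freq: np.ndarray
    n_cis: int
    n_below_min: int

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin centers."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    def to_tsv(self, path: str | Path) -> None:
        with xopen(path, "wt") as fh:
            fh.write("dist_lo\tdist_hi\tcount\tfrequency\n")
            for lo, hi, c, f in zip(self.edges[:-1], self.edges[1:], self.counts, self.freq):
                fh.write(f"{lo:.6g}\t{hi:.6g}\t{int(c)}\t{f:.8g}\n")


def decay_profile(
    pairs: Iterable[ContactPair],
    n_bins: int = 60,
    min_dist: int = 100,
    max_dist: float = 3e8,
) -> DecayProfile:
    """Histogram of pairwise cis distances on log10-spaced bins.

    Distance is ``|pos2 - pos1|``; duplicate pairs and cis pairs below
    ``min_dist`` are excluded (the latter counted). Trans pairs are
    ignored; an all-trans input yields an empty profile with a warning.
    """
    if min_dist < 1:
        raise ValueError("min_dist must be >= 1")
    dists = [
        p.distance
        for p in pairs
        if p.pair_type == "cis" and not p.duplicate
    ]
    edges = np.logspace(np.log10(min_dist), np.log10(max_dist), n_bins + 1)
    arr = np.asarray(dists, dtype=float)
    below = int((arr < min_dist).sum())
    kept = arr[arr >= min_dist]
    if kept.size == 0:
        warnings.warn("decay_profile: no cis pairs at or above min_dist", stacklevel=2)
    counts, _ = np.histogram(kept, bins=edges)
    widths = np.diff(edges)
    return DecayProfile(
        edges=edges,
        counts=counts,
        freq=counts / widths,
        n_cis=int(kept.size),
        n_below_min=below,
    )


def fit_decay_slope(
    profile: DecayProfile,
    fit_min: float | None = None,
    fit_max: float | None = None,
) -> float:
    """Log-log least-squares slope of contact frequency vs distance.

    Only bins with nonzero counts inside ``[fit_min, fit_max]`` enter the
    fit. For a power-law decay with exponent alpha the slope is -alpha.
    """
    centers = profile.centers
    ok = profile.counts > 0
    if fit_min is not None:
        ok &= centers >= fit_min
    if fit_max is not None:
        ok &= centers <= fit_max
    if ok.sum() < 3:
        raise ValueError("fewer than 3 nonzero bins in the fit range")
    slope = np.polyfit(np.log10(centers[ok]), np.log10(profile.freq[ok]), 1)[0]
    return float(slope)


@dataclass
class AnnotationClassStats:
    """MAPQ-stratified mapping fractions for one annotation class.

    ``fractions[t]`` = (#segments in class with mapq >= t) / ``n_segments``
    where ``n_segments`` counts class segments with any alignment.
    ``fractions_of_total`` uses all digested segments as denominator when
    that total is supplied (both denominators are reported because the
    choice is ambiguous).
    """

    name: str
    n_segments: int
    fractions: dict[int, float]
    fractions_of_total: dict[int, float] | None = None

    def __post_init__(self) -> None:
        vals = [self.fractions[t] for t in sorted(self.fractions)]
        if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
            raise AssertionError(f"fractions not monotone in threshold for {self.name}")


def read_bed(path: str | Path) -> dict[str, np.ndarray]:
    """Read BED intervals into per-chromosome ``(n, 2)`` arrays."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    with xopen(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            per_chrom.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return {c: np.asarray(sorted(iv), dtype=np.int64) for c, iv in per_chrom.items()}


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if len(iv) == 0:
        return iv
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def _overlaps(intervals: dict[str, np.ndarray], chrom: str, start: int, end: int) -> bool:
    iv = intervals.get(chrom)
    if iv is None or len(iv) == 0:
        return False
    # merged, sorted intervals: candidate is the last one starting before `end`
    k = int(np.searchsorted(iv[:, 0], end, side="left")) - 1
    return k >= 0 and iv[k, 1] > start


def mapq_by_class(
    monomers: Sequence[MonomerAlignment],
    annotations: Mapping[str, dict[str, np.ndarray] | str | Path],
    thresholds: Sequence[int] = MAPQ_THRESHOLDS,
    total_segments: int | None = None,
) -> dict[str, AnnotationClassStats]:
    """MAPQ-stratified mapped fractions per annotation class.

    ``monomers`` must include sub-threshold alignments (ingest with
    ``mapq_min=0``). A segment belongs to a class when its selected
    alignment overlaps any class interval by at least 1 bp; a segment may
    count in several classes. Classes with zero overlapping segments are
    absent from the result.
    """
    beds = {
        name: ({c: _merge_intervals(iv) for c, iv in read_bed(src).items()}
               if isinstance(src, (str, Path))
               else {c: _merge_intervals(np.asarray(iv)) for c, iv in src.items()})
        for name, src in annotations.items()
    }
    out: dict[str, AnnotationClassStats] = {}
    for name, intervals in beds.items():
        mapqs = np.asarray(
            [m.mapq for m in monomers if _overlaps(intervals, m.chrom, m.start, m.end)]
        )
        if mapqs.size == 0:
            continue
        fractions = {int(t): float((mapqs >= t).mean()) for t in thresholds}
        frac_total = (
            {int(t): float((mapqs >= t).sum() / total_segments) for t in thresholds}
            if total_segments
            else None
        )
        out[name] = AnnotationClassStats(
            name=name,
            n_segments=int(mapqs.size),
            fractions=fractions,
            fractions_of_total=frac_total,
        )
    return out


def mapq_table(stats: Mapping[str, AnnotationClassStats]) -> pd.DataFrame:
    """Long-format table (class, threshold, fraction, n_segments)."""
    rows = [
        {"class": s.name, "mapq_min": t, "fraction": f, "n_segments": s.n_segments}
        for s in stats.values()
        for t, f in sorted(s.fractions.items())
    ]
    return pd.DataFrame(rows)


@dataclass
class CoverageTrack:
    """Sliding-window mean depth per chromosome."""

    window: int
    step: int
    starts: dict[str, np.ndarray]
    depth: dict[str, np.ndarray]

    def genome_mean(self) -> float:
        vals = np.concatenate([v for v in self.depth.values()]) if self.depth else np.array([0.0])
        return float(vals.mean())

    def normalized(self) -> "CoverageTrack":
        """Scale so the genome-wide mean depth is 1."""
        mean = self.genome_mean()
        if mean == 0:
            raise ValueError("cannot normalize an all-zero coverage track")
        return CoverageTrack(
            window=self.window,
            step=self.step,
            starts=self.starts,
            depth={c: v / mean for c, v in self.depth.items()},
        )

    def to_bedgraph(self, path: str | Path) -> None:
        with xopen(path, "wt") as fh:
            for chrom, starts in self.starts.items():
                for s, d in zip(starts, self.depth[chrom]):
                    fh.write(f"{chrom}\t{s}\t{s + self.window}\t{d:.6g}\n")


def windowed_coverage(
    monomers: Iterable[MonomerAlignment],
    chrom_sizes: Mapping[str, int],
    window: int = 5000,
    step: int = 4000,
) -> CoverageTrack:
    """Mean per-base alignment depth in sliding windows.

    Defaults follow the 5 kbp window / 1 kbp overlap convention
    (step = window - overlap = 4 kbp). Windows are truncated at chromosome
    ends and the mean uses the truncated length.
    """
    if not (0 < step < window):
        raise ValueError("require window > step > 0 (overlap = window - step)")
    diff = {c: np.zeros(size + 1, dtype=np.int64) for c, size in chrom_sizes.items()}
    for m in monomers:
        d = diff.get(m.chrom)
        if d is None:
            raise ValueError(f"alignment on unknown chromosome {m.chrom!r}")
        d[min(m.start, len(d) - 1)] += 1
        d[min(m.end, len(d) - 1)] -= 1
    starts: dict[str, np.ndarray] = {}
    depth: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        cov = np.cumsum(diff[chrom][:-1])
        csum = np.concatenate([[0], np.cumsum(cov)])
        ws = np.arange(0, size, step)
        we = np.minimum(ws + window, size)
        starts[chrom] = ws
        depth[chrom] = (csum[we] - csum[ws]) / (we - ws)
    return CoverageTrack(window=window, step=step, starts=starts, depth=depth)


def compare_tracks(
    a: CoverageTrack, b: CoverageTrack, smooth_k: int = 25
) -> dict[str, np.ndarray]:
    """Normalized, smoothed difference between two coverage tracks.

    Both tracks are scaled to genome-wide mean 1, smoothed with a centered
    rolling mean of ``smooth_k`` windows (a simple replacement for GAM
    smoothing), and subtracted (a - b) per chromosome.
    """
    if a.window != b.window or a.step != b.step or set(a.starts) != set(b.starts):
        raise ValueError("tracks must share window, step, and chromosomes")
    an, bn = a.normalized(), b.normalized()
    out: dict[str, np.ndarray] = {}
    for chrom in an.starts:
        sa = pd.Series(an.depth[chrom]).rolling(smooth_k, center=True, min_periods=1).mean()
        sb = pd.Series(bn.depth[chrom]).rolling(smooth_k, center=True, min_periods=1).mean()
        out[chrom] = (sa - sb).to_numpy()
    return out
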