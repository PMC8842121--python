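"""TSS tag-cluster calling and the MAD peakedness score.

A tag track holds per-position TSS tag counts on one contig/strand. Clusters
are maximal runs where the rectangular-kernel-smoothed signal exceeds the
genomic background rate; the cluster TSS is the raw-count mode. The MAD
score (mean absolute deviation of tag positions from their median) is
independent of cluster size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class TssError(ValueError):
    pass


@dataclass
class TagTrack:
    contig: str
    strand: str
    counts: np.ndarray
    background_rate: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if (c < 0).any():
            raise TssError("tag counts must be non-negative")
        self.counts = c
        if self.background_rate is None:
            self.background_rate = float(c.sum()) / max(len(c), 1)
        if self.background_rate < 0:
            raise TssError("background rate must be non-negative")


@dataclass
class Annotation:
    """Gene annotation context for cluster association filtering."""

    gene_starts: list[int] = field(default_factory=list)
    utr5_intervals: list[tuple[int, int]] = field(default_factory=list)
    annotated_tss: list[int] = field(default_factory=list)


@dataclass
class TssCluster:
    contig: str
    interval: tuple[int, int]
    n: int
    tss: int
    mad: float
    passes_filters: bool = True
    reasons: list[str] = field(default_factory=list)


def smooth(track: TagTrack, width: int = 41) -> TagTrack:
    """Centered moving average with truncated edge windows."""
    if width < 1 or width % 2 == 0:
        raise TssError("smoothing width must be odd and >= 1")
    kernel = np.ones(width)
    num = np.convolve(track.counts, kernel, mode="same")
    den = np.convolve(np.ones_like(track.counts), kernel, mode="same")
    return TagTrack(track.contig, track.strand, num / den,
                    background_rate=track.background_rate)


def mad_score(positions) -> float:
    """Mean absolute deviation of tag positions from their median."""
    x = np.asarray(list(positions), dtype=float)
    if x.size == 0:
        raise TssError("mad_score of empty position multiset")
    return float(np.abs(x - np.median(x)).mean())


def _tag_positions(counts: np.ndarray, start: int, end: int) -> np.ndarray:
    seg = counts[start:end].astype(int)
    return np.repeat(np.arange(start, end), seg)


def call_clusters(
    track: TagTrack,
    *,
    min_tags: int = 5,
    isolation: int = 150,
    association_window: int = 250,
    annotation: Annotation | None = None,
    require_association: bool = True,
    smooth_width: int = 41,
) -> list[TssCluster]:
    """Call clusters and apply the min-tag, isolation, and association filters.

    Filters are applied in order and rejection reasons are recorded on the
    returned clusters; isolation drops *both* clusters of a too-close pair.
    Association accepts a cluster with a gene start within
    ``association_window`` bp upstream of its TSS, a TSS inside an annotated
    5'UTR, or an annotated TSS anywhere inside the cluster interval.
    """
    if require_association and annotation is None:
        raise TssError("association filtering requested but no annotation supplied")
    sm = smooth(track, smooth_width)
    above = sm.counts > track.background_rate
    clusters: list[TssCluster] = []
    i, n = 0, len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        positions = _tag_positions(track.counts, i, j)
        if positions.size > 0:
            seg = track.counts[i:j]
            tss = i + int(np.argmax(seg))  # leftmost on ties
            clusters.append(
                TssCluster(track.contig, (i, j), int(positions.size), tss,
                           mad_score(positions))
            )
        i = j

    for c in clusters:
        if c.n < min_tags:
            c.passes_filters = False
            c.reasons.append(f"min_tags<{min_tags}")

    # isolation: both members of a close pair are dropped
    live = [c for c in clusters if c.passes_filters]
    for a, b in zip(live, live[1:]):
        if abs(b.tss - a.tss) < isolation:
            for c in (a, b):
                if "isolation" not in c.reasons:
                    c.passes_filters = False
                    c.reasons.append("isolation")

    if require_association:
        for c in clusters:
            if not c.passes_filters:
                continue
            upstream = any(
                c.tss - association_window <= g <= c.tss for g in annotation.gene_starts
            )
            in_utr = any(lo <= c.tss < hi for lo, hi in annotation.utr5_intervals)
            tss_inside = any(c.interval[0] <= t < c.interval[1] for t in annotation.annotated_tss)
            if not (upstream or in_utr or tss_inside):
                c.passes_filters = False
                c.reasons.append("association")
    return clusters


def write_clusters_bed(clusters: list[TssCluster], path: str | Path) -> None:
    """BED6 with mad*1000 in the score column (documented convention)."""
    lines = []
    for c in clusters:
        lines.append(
            f"{c.contig}\t{c.interval[0]}\t{c.interval[1]}\tcluster\t{int(round(c.mad * 1000))}\t+"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_clusters_tsv(clusters: list[TssCluster], path: str | Path) -> None:
    header = "contig\tstart\tend\tn\ttss\tmad\tpasses\treasons"
    rows = [
        f"{c.contig}\t{c.interval[0]}\t{c.interval[1]}\t{c.n}\t{c.tss}\t{c.mad:.6g}"
        f"\t{int(c.passes_filters)}\t{','.join(c.reasons)}"
        for c in clusters
    ]
    Path(path).write_text("\n".join([header, *rows]) + "\n")


def read_bedgraph(path: str | Path, contig: str = "chr", strand: str = "+") -> TagTrack:
    """Load a dense tag track from a bedGraph file (single contig)."""
    entries = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("track", "#")):
            continue
        c, start, end, value = line.split()[:4]
        entries.append((c, int(start), int(end), float(value)))
    if not entries:
        return TagTrack(contig, strand, np.zeros(0))
    length = max(e[2] for e in entries)
    counts = np.zeros(length)
    for c, start, end, value in entries:
        counts[start:end] = value
    return TagTrack(entries[0][0], strand, counts)


def write_bedgraph(track: TagTrack, path: str | Path) -> None:
    lines = []
    for pos, v in enumerate(track.counts):
        if v:
            lines.append(f"{track.contig}\t{pos}\t{pos + 1}\t{v:g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
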