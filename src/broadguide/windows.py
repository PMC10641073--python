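"""Sliding-window hit aggregation and guide scoring.

A window of size k slides along each chromosome in steps; a hit belongs to a
window iff its start position lies in the half-open interval. The window
score W sums per-hit scores (m − n − g)/L, so W is linear in hit count and
mismatches/gaps are penalized uniformly regardless of position. The aggregate
guide score S combines an evenness term with on-target reward and off-target
penalty; with the per-hit mean normalization used here and evenness weight 0
it is bounded in [−1, +1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from bisect import bisect_left
from typing import Sequence

from .genome import Genome, GenomicInterval
from .mapping import Hit, HitTable


@dataclass
class WindowConfig:
    """Window geometry and per-window hit filters.

    ``step`` defaults to size_k // 10 (overlapping windows); ``min_hits``
    drops windows where a guide has too few hits (singleton suppression);
    ``max_hits`` optionally drops windows above a hit ceiling.
    """

    size_k: int
    step: int | None = None
    min_hits: int = 5
    max_hits: int | None = None

    def __post_init__(self) -> None:
        if self.size_k < 1:
            raise ValueError("window size must be positive")
        if self.step is None:
            self.step = max(1, self.size_k // 10)
        if not (0 < self.step <= self.size_k):
            raise ValueError("require 0 < step <= size_k")
        if self.min_hits < 1:
            raise ValueError("min_hits must be >= 1")
        if self.max_hits is not None and self.max_hits < self.min_hits:
            raise ValueError("max_hits must be >= min_hits")


@dataclass
class Window:
    """A guide's hits inside one genomic window."""

    guide_id: str
    interval: GenomicInterval
    hits: list[Hit] = field(default_factory=list)

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def score_W(self) -> float:
        return sum(h.per_hit_score for h in self.hits)


def sliding_windows(
    chrom_len: int, cfg: WindowConfig, chrom: str = "chr"
) -> list[GenomicInterval]:
    """Overlapping windows starting at multiples of step, covering the chromosome.

    Generation stops with the first window whose end reaches the chromosome
    end (clipped there), so the union always covers [0, chrom_len) and no
    redundant trailing fragment is emitted.
    """
    if chrom_len < 1:
        raise ValueError("chromosome length must be positive")
    out: list[GenomicInterval] = []
    s = 0
    while True:
        e = min(s + cfg.size_k, chrom_len)
        out.append(GenomicInterval(chrom, s, e))
        if e >= chrom_len:
            return out
        s += cfg.step


def genome_windows(genome: Genome, cfg: WindowConfig) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    for name, seq in genome:
        if seq:
            out.extend(sliding_windows(len(seq), cfg, chrom=name))
    return out


def region_windows(
    regions: Sequence[GenomicInterval], cfg: WindowConfig
) -> list[GenomicInterval]:
    """Tile each user-supplied region with sliding windows (region-restricted mode)."""
    out: list[GenomicInterval] = []
    for r in regions:
        for w in sliding_windows(r.length, cfg, chrom=r.chrom):
            out.append(GenomicInterval(r.chrom, r.start + w.start, r.start + w.end))
    return out


def assign_hits(
    table: HitTable,
    windows: Sequence[GenomicInterval],
    cfg: WindowConfig,
) -> list[Window]:
    """Assign each guide's hits to windows by hit start; filter by hit count.

    A hit belongs to a window iff window.start <= hit.start < window.end.
    Windows holding fewer than ``min_hits`` (or more than ``max_hits``) hits
    for a guide are dropped; guides retained in no window disappear.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for lst in by_chrom.values():
        lst.sort(key=lambda w: (w.start, w.end))

    out: list[Window] = []
    for gid in table.guide_ids():
        hits = sorted(table.hits_for(gid), key=lambda h: (h.chrom, h.start, h.strand))
        per_chrom: dict[str, list[Hit]] = {}
        for h in hits:
            per_chrom.setdefault(h.chrom, []).append(h)
        for chrom, chrom_hits in per_chrom.items():
            wins = by_chrom.get(chrom)
            if not wins:
                continue
            starts = [h.start for h in chrom_hits]
            for w in wins:
                i = bisect_left(starts, w.start)
                j = bisect_left(starts, w.end)
                n = j - i
                if n < cfg.min_hits:
                    continue
                if cfg.max_hits is not None and n > cfg.max_hits:
                    continue
                out.append(Window(gid, w, chrom_hits[i:j]))
    out.sort(key=lambda w: (w.guide_id, w.interval.chrom, w.interval.start))
    return out


def window_score(window: Window) -> float:
    """Sum of (m − n − g)/L over the window's hits."""
    if not window.hits:
        raise ValueError("window score of an empty window is undefined")
    return window.score_W


def evenness(positions: Sequence[int | float], k: int) -> float:
    """How uniformly hits spread over a window of size k, in [0, 1].

    Positional (population) standard deviation normalized by the standard
    deviation of a uniform distribution over the window, k/sqrt(12), capped
    at 1. A single position (or co-located hits) scores 0; i.i.d.-uniform
    hits approach 1 as their number grows.
    """
    if len(positions) == 0:
        raise ValueError("evenness requires at least one position")
    sd = _pstdev(positions)
    return min(1.0, sd / (k / math.sqrt(12.0)))


def dispersion(positions: Sequence[int | float]) -> float:
    """Population standard deviation of hit positions, in bases (0 if < 2 hits)."""
    if len(positions) < 2:
        return 0.0
    return _pstdev(positions)


def _pstdev(values: Sequence[int | float]) -> float:
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / n)


def aggregate_score(
    t: int,
    h: int,
    o: int,
    W_on: float,
    W_off: float,
    E: float = 0.0,
    evenness_weight: float = 0.0,
) -> float:
    """Aggregate guide score: evenness + on-target reward − off-target penalty.

    S = w·E + (h/t)·(W_on/h) − (o/t)·(W_off/o), with a zero-hit term
    contributing 0. The per-hit means bound S in [−1, +1] when the evenness
    weight is 0, matching the reported score range.
    """
    if t < 1:
        raise ValueError("aggregate score undefined for guides with no hits")
    if t != h + o:
        raise ValueError(f"hit accounting broken: t={t} != h={h} + o={o}")
    on = (h / t) * (W_on / h) if h > 0 else 0.0
    off = (o / t) * (W_off / o) if o > 0 else 0.0
    return evenness_weight * E + on - off
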