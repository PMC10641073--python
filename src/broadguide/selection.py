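"""Target-bin selection, guide ranking, multi-guide pooling and BED regions.

Per guide, the highest-scoring non-overlapping windows (up to the requested
bin count) become its target bins; every hit outside the chosen bins is an
off-target. Guides are ranked by aggregate score. Bins across guides can be
pooled into merged regions for multi-guide targeting of one locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .genome import Genome, GenomicInterval
from .mapping import Hit, HitTable
from .windows import Window, WindowConfig, aggregate_score, dispersion, evenness


@dataclass
class TargetBin:
    interval: GenomicInterval
    n_hits: int
    score_W: float


@dataclass
class TargetPlan:
    """A guide's selected target bins with full on/off-target accounting."""

    guide_id: str
    full_seq: str
    bins: list[TargetBin]
    t: int
    h: int
    o: int
    W_on: float
    W_off: float
    E: float
    dispersion_sd: float
    dispersion_defined: bool
    S: float
    underfilled: bool
    saturated: bool = False
    rank: int | None = None


@dataclass
class PooledRegion:
    interval: GenomicInterval
    guide_ids: tuple[str, ...]
    combined_hits: int


def _hit_in(iv: GenomicInterval, hit: Hit) -> bool:
    return iv.chrom == hit.chrom and iv.start <= hit.start < iv.end


def select_bins(
    guide_windows: Sequence[Window],
    guide_hits: Sequence[Hit],
    cfg: WindowConfig,
    n_bins: int = 1,
    evenness_weight: float = 0.0,
    full_seq: str = "",
    saturated: bool = False,
) -> TargetPlan:
    """Greedy non-overlapping bin selection by window score W.

    Windows are considered in order of descending W (ties: leftmost start,
    then chromosome name); overlapping later windows are skipped. If fewer
    than ``n_bins`` windows qualify, the plan holds fewer bins and is
    flagged. h, o, W_on, W_off, E, dispersion and S are recomputed against
    the union of chosen bins.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not guide_windows:
        raise ValueError("select_bins requires at least one retained window")
    gid = guide_windows[0].guide_id
    ordered = sorted(
        guide_windows,
        key=lambda w: (-w.score_W, w.interval.start, w.interval.chrom),
    )
    chosen: list[Window] = []
    for w in ordered:
        if len(chosen) == n_bins:
            break
        if any(w.interval.overlaps(c.interval) for c in chosen):
            continue
        chosen.append(w)
    top = chosen[0]
    bins = [TargetBin(w.interval, w.n_hits, w.score_W) for w in chosen]
    bins.sort(key=lambda b: (b.interval.chrom, b.interval.start))

    t = len(guide_hits)
    h = o = 0
    W_on = W_off = 0.0
    rel_positions: list[float] = []
    for hit in guide_hits:
        home = next((b for b in bins if _hit_in(b.interval, hit)), None)
        if home is not None:
            h += 1
            W_on += hit.per_hit_score
            rel_positions.append(hit.start - home.interval.start)
        else:
            o += 1
            W_off += hit.per_hit_score
    E = evenness(rel_positions, cfg.size_k) if rel_positions else 0.0
    top_positions = [hit.start for hit in guide_hits if _hit_in(top.interval, hit)]
    disp = dispersion(top_positions)
    S = aggregate_score(t, h, o, W_on, W_off, E, evenness_weight)
    return TargetPlan(
        guide_id=gid,
        full_seq=full_seq,
        bins=bins,
        t=t,
        h=h,
        o=o,
        W_on=W_on,
        W_off=W_off,
        E=E,
        dispersion_sd=disp,
        dispersion_defined=len(top_positions) >= 2,
        S=S,
        underfilled=len(bins) < n_bins,
        saturated=saturated,
    )


def rank_guides(plans: Sequence[TargetPlan]) -> list[TargetPlan]:
    """Descending S; ties broken by higher h, then guide sequence; ranks 1..n."""
    ordered = sorted(plans, key=lambda p: (-p.S, -p.h, p.full_seq, p.guide_id))
    for i, plan in enumerate(ordered, start=1):
        plan.rank = i
    return ordered


def pool_guides(
    plans: Sequence[TargetPlan], region_merge_gap: int = 0
) -> list[PooledRegion]:
    """Merge bins across guides into shared target regions.

    Bins merge when they strictly overlap, or — with a positive gap — when
    separated by at most ``region_merge_gap`` bases. Each pooled region lists
    all contributing guides and the sum of their bin hit counts.
    """
    items = sorted(
        (
            (b.interval.chrom, b.interval.start, b.interval.end, p.guide_id, b.n_hits)
            for p in plans
            for b in p.bins
        ),
    )
    out: list[PooledRegion] = []
    cur: list[tuple[str, int, int, str, int]] = []

    def flush() -> None:
        if not cur:
            return
        chrom = cur[0][0]
        start = min(c[1] for c in cur)
        end = max(c[2] for c in cur)
        gids = tuple(sorted({c[3] for c in cur}))
        out.append(
            PooledRegion(GenomicInterval(chrom, start, end), gids, sum(c[4] for c in cur))
        )

    cur_end = None
    for item in items:
        chrom, start, end = item[0], item[1], item[2]
        if cur and chrom == cur[0][0] and (
            start < cur_end or (region_merge_gap > 0 and start - cur_end <= region_merge_gap)
        ):
            cur.append(item)
            cur_end = max(cur_end, end)
        else:
            flush()
            cur = [item]
            cur_end = end
    flush()
    return out


def read_bed(path: str | Path, genome: Genome | None = None) -> list[GenomicInterval]:
    """Parse BED3/BED6 into intervals; malformed lines are fatal with line number."""
    regions: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"malformed BED line {lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {exc}") from exc
            if not (0 <= start < end):
                raise ValueError(
                    f"malformed BED line {lineno}: invalid interval {start}-{end}"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            if genome is not None:
                if chrom not in genome.chromosomes:
                    raise ValueError(
                        f"BED line {lineno}: unknown chromosome {chrom!r}"
                    )
                if end > len(genome.chromosomes[chrom]):
                    raise ValueError(
                        f"BED line {lineno}: interval exceeds chromosome {chrom!r}"
                    )
            regions.append(GenomicInterval(chrom, start, end, strand))
    if not regions:
        warnings.warn(f"no regions parsed from {path}")
    return regions
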