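"""Staged pipeline orchestration, intermediates, caching and the final report.

The pipeline runs extract → map → window → score → select → pool. Every
stage writes a headered TSV intermediate carrying a schema version and a
parameter hash chained over all upstream stages, so stages can be re-run
independently and an unchanged upstream intermediate is reused instead of
recomputed (mapping is the expensive step). Identical configuration and
genome produce byte-identical outputs regardless of thread count.

Coordinates in intermediates are 0-based half-open; the final report and the
FASTA/BED interfaces use the conventional 1-based inclusive region strings
and BED half-open columns respectively. Floats are fixed at 4 decimals so
byte-identical reproduction is well-defined.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .candidates import (
    CandidateGuide,
    CandidateSet,
    filter_to_regions,
    prefilter_report,
    scan_candidates,
)
from .genome import Genome, GenomicInterval, PamSpec, read_fasta
from .mapping import Hit, HitTable, find_all_hits
from .selection import (
    PooledRegion,
    TargetPlan,
    pool_guides,
    rank_guides,
    read_bed,
    select_bins,
)
from .windows import (
    Window,
    WindowConfig,
    assign_hits,
    evenness,
    genome_windows,
    region_windows,
)

SCHEMA_VERSION = 1
STAGES = ("extract", "map", "window", "score", "select", "pool")


class StageError(RuntimeError):
    """A stage cannot run: missing or stale predecessor intermediate."""


@dataclass
class RunConfig:
    """Full parameter set for one pipeline run (serialized into the run log)."""

    genome: str
    out_prefix: str
    pam_pattern: str = "NGG"
    pam_side: str = "3prime"
    spacer_len: int = 20
    gc_min: float = 0.0
    gc_max: float = 1.0
    max_mismatches: int = 3
    hit_cap: int = 10_000
    window_size: int = 50_000
    step: int | None = None
    min_hits: int = 5
    max_hits: int | None = None
    n_bins: int = 1
    evenness_weight: float = 0.0
    region_merge_gap: int = 0
    regions_bed: str | None = None
    threads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        # Validate everything up front: no stage starts on a bad config.
        self.pam_spec  # noqa: B018 - constructor validates pattern and side
        if self.spacer_len < 10:
            raise ValueError("spacer length must be >= 10")
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise ValueError("require 0 <= gc_min <= gc_max <= 1")
        if not (0 <= self.max_mismatches <= 3):
            raise ValueError("max_mismatches must be in 0..3")
        if self.hit_cap < 1:
            raise ValueError("hit_cap must be >= 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.region_merge_gap < 0:
            raise ValueError("region_merge_gap must be >= 0")
        self.window_config  # noqa: B018 - validates size/step/min/max hits

    @property
    def pam_spec(self) -> PamSpec:
        return PamSpec(self.pam_pattern, self.pam_side)

    @property
    def window_config(self) -> WindowConfig:
        return WindowConfig(self.window_size, self.step, self.min_hits, self.max_hits)

    def to_dict(self) -> dict:
        return asdict(self)

    def path(self, suffix: str) -> Path:
        return Path(f"{self.out_prefix}.{suffix}")


@dataclass
class ReportRow:
    """One final-report line: a ranked guide with full hit accounting."""

    rank: int
    guide_id: str
    guide_sequence: str
    score_S: float
    gc_content: float
    evenness: float
    dispersion_sd: float
    total_hits: int
    on_target_hits: int
    off_target_hits: int
    mm_histogram: list[int]
    saturated: bool
    bins_underfilled: bool
    optimal_window: str
    target_bins: str
    hit_coordinates: str


REPORT_COLUMNS = [
    "rank",
    "guide_id",
    "guide_sequence",
    "score_S",
    "gc_content",
    "evenness",
    "dispersion_sd",
    "total_hits",
    "on_target_hits",
    "off_target_hits",
    "mm_0",
    "mm_1",
    "mm_2",
    "mm_3",
    "saturated",
    "bins_underfilled",
    "optimal_window",
    "target_bins",
    "hit_coordinates",
]


# ---------------------------------------------------------------------------
# parameter hashing (stage cache validity)

def _file_fingerprint(path: str | None) -> list:
    if path is None:
        return [None]
    p = Path(path)
    if not p.exists():
        return [str(p), "missing"]
    st = p.stat()
    return [str(p), st.st_size, st.st_mtime_ns]


def stage_hash(cfg: RunConfig, stage: str) -> str:
    """Chained md5 over the parameters affecting a stage and its ancestors."""
    fields = {
        "extract": [
            _file_fingerprint(cfg.genome),
            cfg.pam_pattern,
            cfg.pam_side,
            cfg.spacer_len,
            cfg.gc_min,
            cfg.gc_max,
            _file_fingerprint(cfg.regions_bed),
        ],
        "map": [cfg.max_mismatches, cfg.hit_cap],
        "window": [cfg.window_size, cfg.step, cfg.min_hits, cfg.max_hits],
        "score": [],
        "select": [cfg.n_bins, cfg.evenness_weight],
        "pool": [cfg.region_merge_gap],
    }
    idx = STAGES.index(stage)
    prev = stage_hash(cfg, STAGES[idx - 1]) if idx else ""
    payload = json.dumps([SCHEMA_VERSION, stage, fields[stage], prev], sort_keys=True)
    return hashlib.md5(payload.encode()).hexdigest()


def _header_line(stage: str, digest: str) -> str:
    return f"#broadguide\tschema={SCHEMA_VERSION}\tstage={stage}\thash={digest}\n"


def _check_header(path: Path, stage: str, digest: str) -> bool:
    if not path.exists():
        return False
    with open(path) as fh:
        first = fh.readline()
    return first == _header_line(stage, digest)


def _require(path: Path, stage: str, digest: str, needed_by: str) -> None:
    if not path.exists():
        raise StageError(
            f"stage {needed_by!r} requires intermediate from stage {stage!r}; "
            f"run it first ({path} missing)"
        )
    if not _check_header(path, stage, digest):
        raise StageError(
            f"intermediate {path} is stale for the current configuration; "
            f"re-run stage {stage!r}"
        )


# ---------------------------------------------------------------------------
# intermediate serialization

def _fmt(x: float) -> str:
    return f"{x:.4f}"


def _write_candidates(cs: CandidateSet, path: Path, digest: str) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line("extract", digest))
        fh.write("#stats\t" + json.dumps(cs.stats, sort_keys=True) + "\n")
        fh.write("guide_id\tfull_seq\tprotospacer\tpam\tgc\torigins\n")
        for g in cs.in_id_order():
            origins = ";".join(
                f"{o.chrom}:{o.start}:{o.end}:{o.strand}" for o in g.origins
            )
            fh.write(
                f"{g.guide_id}\t{g.full_seq}\t{g.protospacer}\t{g.pam}\t"
                f"{_fmt(g.gc)}\t{origins}\n"
            )


def _load_candidates(cfg: RunConfig) -> CandidateSet:
    path = cfg.path("candidates.tsv")
    guides: dict[str, CandidateGuide] = {}
    stats: dict[str, int] = {}
    from .genome import gc_content

    with open(path) as fh:
        for line in fh:
            if line.startswith("#stats\t"):
                stats = json.loads(line.split("\t", 1)[1])
                continue
            if line.startswith(("#", "guide_id\t")):
                continue
            gid, full, proto, pam_seq, _gc, origins_s = line.rstrip("\n").split("\t")
            origins = []
            for part in origins_s.split(";"):
                chrom, s, e, strand = part.rsplit(":", 3)
                origins.append(GenomicInterval(chrom, int(s), int(e), strand))
            guides[full] = CandidateGuide(
                gid, proto, pam_seq, full, gc_content(full), origins
            )
    return CandidateSet(guides, cfg.pam_spec, cfg.spacer_len, stats)


def _write_hits(table: HitTable, path: Path, digest: str) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line("map", digest))
        fh.write("guide_id\tchrom\tstart\tend\tstrand\tm\tn\tg\tsaturated\n")
        for h in table.all_hits():
            sat = 1 if h.guide_id in table.saturated else 0
            fh.write(
                f"{h.guide_id}\t{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t"
                f"{h.matches_m}\t{h.mismatches_n}\t{h.gaps_g}\t{sat}\n"
            )


def _load_hits(cfg: RunConfig) -> HitTable:
    path = cfg.path("hits.tsv")
    full_len = cfg.spacer_len + cfg.pam_spec.length
    grouped: dict[str, list[Hit]] = {}
    saturated: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "guide_id\t")):
                continue
            gid, chrom, s, e, strand, m, n, g, sat = line.rstrip("\n").split("\t")
            grouped.setdefault(gid, []).append(
                Hit(gid, chrom, int(s), int(e), strand, int(m), int(n), int(g), full_len)
            )
            if sat == "1":
                saturated.add(gid)
    table = HitTable()
    for gid in sorted(grouped):
        table.add_guide(gid, grouped[gid], gid in saturated)
    return table


def _write_windows(wins: list[Window], path: Path, digest: str, scored: bool) -> None:
    stage = "score" if scored else "window"
    with open(path, "w") as fh:
        fh.write(_header_line(stage, digest))
        cols = "guide_id\tchrom\tstart\tend\tn_hits"
        if scored:
            cols += "\tscore_W\tevenness"
        fh.write(cols + "\n")
        for w in wins:
            row = (
                f"{w.guide_id}\t{w.interval.chrom}\t{w.interval.start}\t"
                f"{w.interval.end}\t{w.n_hits}"
            )
            if scored:
                E = evenness([h.start - w.interval.start for h in w.hits], w.interval.length)
                row += f"\t{_fmt(w.score_W)}\t{_fmt(E)}"
            fh.write(row + "\n")


def _load_windows(cfg: RunConfig, table: HitTable, scored: bool) -> list[Window]:
    path = cfg.path("scored_windows.tsv" if scored else "windows.tsv")
    out: list[Window] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "guide_id\t")):
                continue
            parts = line.rstrip("\n").split("\t")
            gid, chrom, s, e = parts[0], parts[1], int(parts[2]), int(parts[3])
            iv = GenomicInterval(chrom, s, e)
            hits = [
                h
                for h in table.hits_for(gid)
                if h.chrom == chrom and s <= h.start < e
            ]
            out.append(Window(gid, iv, hits))
    return out


def write_report(rows: list[ReportRow], path: str | Path) -> None:
    """Tab-delimited ranked guide report; floats at 4 decimals."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in rows:
            fields = [
                str(r.rank),
                r.guide_id,
                r.guide_sequence,
                _fmt(r.score_S),
                _fmt(r.gc_content),
                _fmt(r.evenness),
                _fmt(r.dispersion_sd),
                str(r.total_hits),
                str(r.on_target_hits),
                str(r.off_target_hits),
                *[str(c) for c in r.mm_histogram],
                str(int(r.saturated)),
                str(int(r.bins_underfilled)),
                r.optimal_window,
                r.target_bins,
                r.hit_coordinates,
            ]
            fh.write("\t".join(fields) + "\n")


def read_report(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")


def _scaled_score(S: float) -> int:
    return max(0, min(1000, round((S + 1.0) * 500)))


def _write_bins_bed(plans: list[TargetPlan], path: Path) -> None:
    with open(path, "w") as fh:
        for p in plans:
            for b in p.bins:
                fh.write(
                    f"{b.interval.chrom}\t{b.interval.start}\t{b.interval.end}\t"
                    f"{p.guide_id}\t{_scaled_score(p.S)}\t.\n"
                )


def _write_pooled_bed(pools: list[PooledRegion], path: Path) -> None:
    with open(path, "w") as fh:
        for r in pools:
            name = ",".join(r.guide_ids)
            score = min(1000, r.combined_hits)
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{name}\t{score}\t.\n"
            )


def _write_plans(plans: list[TargetPlan], path: Path, digest: str) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line("select", digest))
        fh.write("guide_id\tchrom\tstart\tend\tn_hits\tscore_W\n")
        for p in plans:
            for b in p.bins:
                fh.write(
                    f"{p.guide_id}\t{b.interval.chrom}\t{b.interval.start}\t"
                    f"{b.interval.end}\t{b.n_hits}\t{_fmt(b.score_W)}\n"
                )


def _load_plans_bins(cfg: RunConfig) -> list[TargetPlan]:
    """Minimal plan reconstruction (bins only) for the pooling stage."""
    path = cfg.path("plans.tsv")
    by_gid: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "guide_id\t")):
                continue
            gid, chrom, s, e, n, w = line.rstrip("\n").split("\t")
            by_gid.setdefault(gid, []).append(
                (GenomicInterval(chrom, int(s), int(e)), int(n), float(w))
            )
    from .selection import TargetBin

    plans = []
    for gid in sorted(by_gid):
        bins = [TargetBin(iv, n, w) for iv, n, w in by_gid[gid]]
        plans.append(
            TargetPlan(gid, "", bins, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, False, 0.0, False)
        )
    return plans


# ---------------------------------------------------------------------------
# stages

def stage_extract(cfg: RunConfig, genome: Genome | None = None) -> CandidateSet:
    genome = genome if genome is not None else read_fasta(cfg.genome)
    cs = scan_candidates(
        genome, cfg.pam_spec, cfg.spacer_len, cfg.gc_min, cfg.gc_max
    )
    if cfg.regions_bed:
        regions = read_bed(cfg.regions_bed, genome)
        cs = filter_to_regions(cs, regions)
    _write_candidates(cs, cfg.path("candidates.tsv"), stage_hash(cfg, "extract"))
    return cs


def stage_map(
    cfg: RunConfig,
    genome: Genome | None = None,
    cs: CandidateSet | None = None,
) -> HitTable:
    if cs is None:
        _require(
            cfg.path("candidates.tsv"), "extract", stage_hash(cfg, "extract"), "map"
        )
        cs = _load_candidates(cfg)
    genome = genome if genome is not None else read_fasta(cfg.genome)
    table = find_all_hits(
        genome, cs, cfg.max_mismatches, cfg.hit_cap, threads=cfg.threads
    )
    _write_hits(table, cfg.path("hits.tsv"), stage_hash(cfg, "map"))
    return table


def _target_windows(cfg: RunConfig, genome: Genome) -> list[GenomicInterval]:
    if cfg.regions_bed:
        return region_windows(read_bed(cfg.regions_bed, genome), cfg.window_config)
    return genome_windows(genome, cfg.window_config)


def stage_window(
    cfg: RunConfig,
    genome: Genome | None = None,
    table: HitTable | None = None,
) -> list[Window]:
    if table is None:
        _require(cfg.path("hits.tsv"), "map", stage_hash(cfg, "map"), "window")
        table = _load_hits(cfg)
    genome = genome if genome is not None else read_fasta(cfg.genome)
    wins = assign_hits(table, _target_windows(cfg, genome), cfg.window_config)
    _write_windows(wins, cfg.path("windows.tsv"), stage_hash(cfg, "window"), False)
    return wins


def stage_score(
    cfg: RunConfig,
    wins: list[Window] | None = None,
    table: HitTable | None = None,
) -> list[Window]:
    if wins is None:
        _require(cfg.path("hits.tsv"), "map", stage_hash(cfg, "map"), "score")
        table = table if table is not None else _load_hits(cfg)
        _require(
            cfg.path("windows.tsv"), "window", stage_hash(cfg, "window"), "score"
        )
        wins = _load_windows(cfg, table, scored=False)
    _write_windows(
        wins, cfg.path("scored_windows.tsv"), stage_hash(cfg, "score"), True
    )
    return wins


def stage_select(
    cfg: RunConfig,
    wins: list[Window] | None = None,
    table: HitTable | None = None,
    cs: CandidateSet | None = None,
) -> list[TargetPlan]:
    if table is None:
        _require(cfg.path("hits.tsv"), "map", stage_hash(cfg, "map"), "select")
        table = _load_hits(cfg)
    if wins is None:
        _require(
            cfg.path("scored_windows.tsv"),
            "score",
            stage_hash(cfg, "score"),
            "select",
        )
        wins = _load_windows(cfg, table, scored=True)
    if cs is None:
        _require(
            cfg.path("candidates.tsv"), "extract", stage_hash(cfg, "extract"), "select"
        )
        cs = _load_candidates(cfg)

    by_gid: dict[str, list[Window]] = {}
    for w in wins:
        by_gid.setdefault(w.guide_id, []).append(w)
    by_id = cs.by_id
    plans = []
    for gid in sorted(by_gid):
        plans.append(
            select_bins(
                by_gid[gid],
                table.hits_for(gid),
                cfg.window_config,
                cfg.n_bins,
                cfg.evenness_weight,
                full_seq=by_id[gid].full_seq if gid in by_id else "",
                saturated=gid in table.saturated,
            )
        )
    plans = rank_guides(plans)
    rows = [_plan_to_row(p, table, by_id) for p in plans]
    write_report(rows, cfg.path("report.tsv"))
    _write_bins_bed(plans, cfg.path("bins.bed"))
    _write_plans(plans, cfg.path("plans.tsv"), stage_hash(cfg, "select"))
    return plans


def stage_pool(
    cfg: RunConfig, plans: list[TargetPlan] | None = None
) -> list[PooledRegion]:
    if plans is None:
        _require(cfg.path("plans.tsv"), "select", stage_hash(cfg, "select"), "pool")
        plans = _load_plans_bins(cfg)
    pools = pool_guides(plans, cfg.region_merge_gap)
    _write_pooled_bed(pools, cfg.path("pooled.bed"))
    return pools


def _plan_to_row(plan: TargetPlan, table: HitTable, by_id) -> ReportRow:
    hits = table.hits_for(plan.guide_id)
    coords = ";".join(
        GenomicInterval(h.chrom, h.start, h.end, h.strand).to_region_string()
        for h in hits
    )
    guide = by_id.get(plan.guide_id)
    return ReportRow(
        rank=plan.rank or 0,
        guide_id=plan.guide_id,
        guide_sequence=plan.full_seq,
        score_S=plan.S,
        gc_content=guide.gc if guide else 0.0,
        evenness=plan.E,
        dispersion_sd=plan.dispersion_sd,
        total_hits=plan.t,
        on_target_hits=plan.h,
        off_target_hits=plan.o,
        mm_histogram=table.mismatch_histogram(plan.guide_id),
        saturated=plan.saturated,
        bins_underfilled=plan.underfilled,
        optimal_window=plan.bins[0].interval.to_region_string() if plan.bins else "",
        target_bins=";".join(b.interval.to_region_string() for b in plan.bins),
        hit_coordinates=coords,
    )


# ---------------------------------------------------------------------------
# full run

@dataclass
class PipelineResult:
    config: RunConfig
    candidates: CandidateSet
    hits: HitTable
    plans: list[TargetPlan]
    pooled: list[PooledRegion]
    reused: dict[str, bool] = field(default_factory=dict)

    @property
    def report_path(self) -> Path:
        return self.config.path("report.tsv")


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute all stages, reusing intermediates whose parameter hash matches.

    The run log (JSON) records the verbatim configuration, per-stage hashes,
    reuse flags and summary counts.
    """
    genome = read_fasta(cfg.genome)
    reused: dict[str, bool] = {}

    if _check_header(cfg.path("candidates.tsv"), "extract", stage_hash(cfg, "extract")):
        cs = _load_candidates(cfg)
        reused["extract"] = True
    else:
        cs = stage_extract(cfg, genome)
        reused["extract"] = False

    if _check_header(cfg.path("hits.tsv"), "map", stage_hash(cfg, "map")):
        table = _load_hits(cfg)
        reused["map"] = True
    else:
        table = stage_map(cfg, genome, cs)
        reused["map"] = False

    if _check_header(cfg.path("windows.tsv"), "window", stage_hash(cfg, "window")):
        wins = _load_windows(cfg, table, scored=False)
        reused["window"] = True
    else:
        wins = stage_window(cfg, genome, table)
        reused["window"] = False

    if _check_header(
        cfg.path("scored_windows.tsv"), "score", stage_hash(cfg, "score")
    ):
        reused["score"] = True
    else:
        stage_score(cfg, wins, table)
        reused["score"] = False

    plans = stage_select(cfg, wins, table, cs)
    reused["select"] = False
    pooled = stage_pool(cfg, plans)
    reused["pool"] = False

    log = {
        "tool": "broadguide",
        "version": __version__,
        "config": cfg.to_dict(),
        "stage_hashes": {s: stage_hash(cfg, s) for s in STAGES},
        "stages_reused": reused,
        "summary": {
            "prefilter": prefilter_report(cs).iloc[0].to_dict(),
            "guides_with_hits": len(table.guide_ids()),
            "total_hits": len(table),
            "retained_windows": sum(1 for _ in wins),
            "ranked_guides": len(plans),
            "pooled_regions": len(pooled),
        },
    }
    cfg.path("runlog.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return PipelineResult(cfg, cs, table, plans, pooled, reused)
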