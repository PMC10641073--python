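"""Candidate guide extraction: PAM-anchored protospacer enumeration.

Every genomic position on both strands whose flanking bases realize the PAM
pattern yields one candidate, *including overlapping occurrences*. Candidates
containing N anywhere in protospacer+PAM are discarded (unknown sequence), and
an optional GC window filters on the full guide sequence. Identical sequences
arising at different loci collapse into a single guide with multiple origins —
these multi-origin guides are the multi-targeting candidates of interest.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome import Genome, GenomicInterval, IUPAC_CODES, PamSpec, gc_content, revcomp


@dataclass
class CandidateGuide:
    """A unique protospacer+PAM sequence with all genomic origins."""

    guide_id: str
    protospacer: str
    pam: str
    full_seq: str
    gc: float
    origins: list[GenomicInterval] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.full_seq)

    @property
    def n_origins(self) -> int:
        return len(self.origins)


@dataclass
class CandidateSet:
    """Unique guides keyed by full sequence, plus extraction bookkeeping."""

    guides: dict[str, CandidateGuide]
    pam: PamSpec
    protospacer_len: int
    stats: dict[str, int] = field(default_factory=dict)

    @property
    def total_occurrences(self) -> int:
        return sum(g.n_origins for g in self.guides.values())

    @property
    def n_unique(self) -> int:
        return len(self.guides)

    @property
    def by_id(self) -> dict[str, CandidateGuide]:
        return {g.guide_id: g for g in self.guides.values()}

    def in_id_order(self) -> list[CandidateGuide]:
        return sorted(self.guides.values(), key=lambda g: g.guide_id)


def _pam_regex(pattern: str) -> str:
    # Genomic N never appears in a candidate, so every code expands over ACGT.
    parts = []
    for code in pattern:
        bases = "".join(sorted(IUPAC_CODES[code] - {"N"}))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def scan_candidates(
    genome: Genome,
    pam: PamSpec,
    protospacer_len: int = 20,
    gc_min: float = 0.0,
    gc_max: float = 1.0,
) -> CandidateSet:
    """Enumerate every PAM-anchored candidate guide on both strands.

    Overlapping matches are all reported. The GC filter applies to the full
    protospacer+PAM sequence. Chromosomes shorter than a full guide are
    skipped with a warning.
    """
    if protospacer_len < 1:
        raise ValueError("protospacer length must be positive")
    if not (0.0 <= gc_min <= gc_max <= 1.0):
        raise ValueError("require 0 <= gc_min <= gc_max <= 1")

    p_len, pam_len = protospacer_len, pam.length
    full_len = p_len + pam_len
    pam_re = _pam_regex(pam.pattern)
    if pam.side == "3prime":
        rx = re.compile(rf"(?=([ACGT]{{{p_len}}}{pam_re}))")
    else:
        rx = re.compile(rf"(?=({pam_re}[ACGT]{{{p_len}}}))")

    guides: dict[str, CandidateGuide] = {}
    stats = {"prefilter_occurrences": 0, "gc_pass_occurrences": 0}

    for name, seq in genome:
        if len(seq) < full_len:
            warnings.warn(
                f"chromosome {name!r} shorter than guide length {full_len}; skipped"
            )
            continue
        for strand in "+-":
            scan_seq = seq if strand == "+" else revcomp(seq)
            for m in rx.finditer(scan_seq):
                full = m.group(1)
                stats["prefilter_occurrences"] += 1
                gc = gc_content(full)
                if not (gc_min <= gc <= gc_max):
                    continue
                stats["gc_pass_occurrences"] += 1
                s = m.start()
                if strand == "+":
                    iv = GenomicInterval(name, s, s + full_len, "+")
                else:
                    n0 = len(seq)
                    iv = GenomicInterval(name, n0 - (s + full_len), n0 - s, "-")
                guide = guides.get(full)
                if guide is None:
                    if pam.side == "3prime":
                        proto, pam_seq = full[:p_len], full[p_len:]
                    else:
                        pam_seq, proto = full[:pam_len], full[pam_len:]
                    guide = CandidateGuide("", proto, pam_seq, full, gc)
                    guides[full] = guide
                guide.origins.append(iv)

    width = max(6, len(str(len(guides))))
    for i, guide in enumerate(guides.values()):
        guide.guide_id = f"g{i:0{width}d}"

    return CandidateSet(guides, pam, protospacer_len, stats)


def prefilter_report(cs: CandidateSet) -> pd.DataFrame:
    """One-row summary of extraction: occurrence and unique-sequence tallies."""
    return pd.DataFrame(
        [
            {
                "prefilter_occurrences": cs.stats.get("prefilter_occurrences", 0),
                "gc_pass_occurrences": cs.stats.get("gc_pass_occurrences", 0),
                "total_occurrences": cs.total_occurrences,
                "unique_sequences": cs.n_unique,
            }
        ]
    )


def candidates_to_fasta(cs: CandidateSet, path: str | Path) -> None:
    """Export protospacers (one record per origin) for external aligners.

    Headers are ``guide_id|chrom:start-end:strand`` (1-based inclusive), so
    external SAM alignments remain resolvable to guide ids on import.
    """
    with open(path, "w") as fh:
        for guide in cs.in_id_order():
            for iv in guide.origins:
                fh.write(f">{guide.guide_id}|{iv.to_region_string()}\n")
                fh.write(guide.protospacer + "\n")


def filter_to_regions(cs: CandidateSet, regions: list[GenomicInterval]) -> CandidateSet:
    """Keep only guides with at least one origin fully inside a region.

    Origins outside the regions are dropped from the retained guides; the
    same sequences' outside copies still surface later as genome-wide hits.
    Guide ids are preserved for cross-referencing with the unrestricted set.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    kept: dict[str, CandidateGuide] = {}
    for full, guide in cs.guides.items():
        inside = [
            iv
            for iv in guide.origins
            if any(
                r.start <= iv.start and iv.end <= r.end
                for r in by_chrom.get(iv.chrom, ())
            )
        ]
        if inside:
            kept[full] = CandidateGuide(
                guide.guide_id, guide.protospacer, guide.pam, full, guide.gc, inside
            )
    stats = dict(cs.stats)
    stats["region_restricted"] = 1
    return CandidateSet(kept, cs.pam, cs.protospacer_len, stats)
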