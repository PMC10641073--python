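"""All-occurrence approximate mapping of candidate guides.

The internal mapper is an ungapped Hamming-distance search over both strands:
the protospacer is split into ``max_mismatches + 1`` disjoint exact seed
chunks (pigeonhole: any placement within the mismatch budget contains at
least one exact chunk), candidate placements are gathered from a k-mer index
of the genome, and each placement is verified with vectorized base
comparisons. The PAM is then checked exactly (IUPAC degeneracy only — the
mismatch budget never applies to the PAM), and placements overlapping N are
discarded. Gapped alignments enter only through SAM import from external
aligners.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from .candidates import CandidateGuide, CandidateSet
from .genome import Genome, PamSpec, iupac_match, revcomp

_N_BYTE = ord("N")
_ACGT = frozenset("ACGT")


@dataclass
class Hit:
    """One genomic alignment of a guide (full span: protospacer + PAM).

    ``start``/``end`` delimit the full half-open span on the forward genome;
    ``matches_m``/``mismatches_n``/``gaps_g`` follow the per-hit score
    (m − n − g)/L, with L the full guide length. The PAM, verified exactly,
    counts toward m.
    """

    guide_id: str
    chrom: str
    start: int
    end: int
    strand: str
    matches_m: int
    mismatches_n: int
    gaps_g: int
    length_L: int
    pam_ok: bool = True

    @property
    def per_hit_score(self) -> float:
        return (self.matches_m - self.mismatches_n - self.gaps_g) / self.length_L

    def key(self) -> tuple[str, str, int, str]:
        return (self.guide_id, self.chrom, self.start, self.strand)


class HitTable:
    """Hits grouped per guide, with saturation flags for capped guides."""

    def __init__(self) -> None:
        self._hits: dict[str, list[Hit]] = {}
        self.saturated: set[str] = set()
        self.skipped_records: int = 0

    def add_guide(self, guide_id: str, hits: list[Hit], saturated: bool = False) -> None:
        self._hits[guide_id] = hits
        if saturated:
            self.saturated.add(guide_id)

    def hits_for(self, guide_id: str) -> list[Hit]:
        return self._hits.get(guide_id, [])

    def t(self, guide_id: str) -> int:
        return len(self._hits.get(guide_id, ()))

    def guide_ids(self) -> list[str]:
        return sorted(self._hits)

    def all_hits(self) -> Iterator[Hit]:
        for gid in self.guide_ids():
            yield from self._hits[gid]

    def __len__(self) -> int:
        return sum(len(v) for v in self._hits.values())

    def mismatch_histogram(self, guide_id: str, max_n: int = 3) -> list[int]:
        counts = [0] * (max_n + 1)
        for h in self._hits.get(guide_id, ()):
            if h.mismatches_n <= max_n:
                counts[h.mismatches_n] += 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "guide_id": h.guide_id,
                "chrom": h.chrom,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "matches_m": h.matches_m,
                "mismatches_n": h.mismatches_n,
                "gaps_g": h.gaps_g,
                "per_hit_score": h.per_hit_score,
            }
            for h in self.all_hits()
        ]
        return pd.DataFrame(rows)


def _hit_sort_key(h: Hit) -> tuple[str, int, str]:
    return (h.chrom, h.start, h.strand)


def _pam_geometry(
    side: str, strand: str, s: int, p_len: int, pam_len: int
) -> tuple[int, int, int, int]:
    """PAM slice and full hit span for a protospacer placed at [s, s+P).

    ``s`` is the forward-genome start of the protospacer placement (for minus
    strand hits this is where the reverse complement of the protospacer sits).
    """
    pam_right = (side == "3prime") == (strand == "+")
    if pam_right:
        return s + p_len, s + p_len + pam_len, s, s + p_len + pam_len
    return s - pam_len, s, s - pam_len, s + p_len


def protospacer_span(hit: Hit, pam: PamSpec) -> tuple[int, int]:
    """Recover the protospacer's forward-genome span from a full hit span."""
    pam_right = (pam.side == "3prime") == (hit.strand == "+")
    if pam_right:
        return hit.start, hit.end - pam.length
    return hit.start + pam.length, hit.end


class _GenomeIndex:
    """Exact k-mer index of the forward genome for seed lookup."""

    def __init__(self, genome: Genome, k: int) -> None:
        self.k = k
        self.table: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome:
            limit = len(seq) - k + 1
            table = self.table
            for pos in range(max(0, limit)):
                sub = seq[pos : pos + k]
                if "N" in sub:
                    continue
                table.setdefault(sub, []).append((name, pos))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.table.get(kmer, [])


def find_all_hits(
    genome: Genome,
    cs: CandidateSet,
    max_mismatches: int = 3,
    hit_cap: int = 10_000,
    threads: int = 1,
) -> HitTable:
    """Every end-to-end alignment of every guide within the mismatch budget.

    Hits are emitted only where the adjacent PAM matches the pattern exactly
    and the full span is N-free. Enumeration per guide is truncated at
    ``hit_cap`` (canonical chrom/start/strand order) with a saturation flag.
    Output is canonically ordered and independent of ``threads``.
    """
    if not (0 <= max_mismatches <= 3):
        raise ValueError("max_mismatches must be in 0..3")
    if hit_cap < 1:
        raise ValueError("hit_cap must be >= 1")

    p_len = cs.protospacer_len
    pam = cs.pam
    pam_len = pam.length
    full_len = p_len + pam_len
    chunk = p_len // (max_mismatches + 1)
    index = _GenomeIndex(genome, chunk)
    arrays = {
        name: np.frombuffer(seq.encode(), dtype=np.uint8) for name, seq in genome
    }
    seqs = dict(genome.chromosomes)

    def map_guide(guide: CandidateGuide) -> tuple[str, list[Hit], bool]:
        found: dict[tuple[str, int, str], Hit] = {}
        for strand in "+-":
            search = guide.protospacer if strand == "+" else revcomp(guide.protospacer)
            gbytes = np.frombuffer(search.encode(), dtype=np.uint8)
            starts: dict[str, set[int]] = {}
            for j in range(max_mismatches + 1):
                for name, pos in index.lookup(search[j * chunk : (j + 1) * chunk]):
                    s = pos - j * chunk
                    if s >= 0:
                        starts.setdefault(name, set()).add(s)
            for name, cand in starts.items():
                arr = arrays[name]
                n0 = arr.size
                S = np.fromiter(
                    (s for s in cand if s + p_len <= n0), dtype=np.int64
                )
                if S.size == 0:
                    continue
                mm = np.zeros(S.size, dtype=np.int64)
                has_n = np.zeros(S.size, dtype=bool)
                for j in range(p_len):
                    col = arr[S + j]
                    mm += col != gbytes[j]
                    has_n |= col == _N_BYTE
                keep = (mm <= max_mismatches) & ~has_n
                seq = seqs[name]
                for s, n_mm in zip(S[keep].tolist(), mm[keep].tolist()):
                    ps, pe, span_s, span_e = _pam_geometry(
                        pam.side, strand, s, p_len, pam_len
                    )
                    if ps < 0 or pe > n0 or span_s < 0 or span_e > n0:
                        continue
                    pam_slice = seq[ps:pe]
                    if not _ACGT.issuperset(pam_slice):
                        continue
                    pam_guide = pam_slice if strand == "+" else revcomp(pam_slice)
                    if not iupac_match(pam.pattern, pam_guide):
                        continue
                    found[(name, span_s, strand)] = Hit(
                        guide.guide_id,
                        name,
                        span_s,
                        span_e,
                        strand,
                        matches_m=full_len - n_mm,
                        mismatches_n=n_mm,
                        gaps_g=0,
                        length_L=full_len,
                    )
        hits = sorted(found.values(), key=_hit_sort_key)
        saturated = len(hits) > hit_cap
        if saturated:
            hits = hits[:hit_cap]
        return guide.guide_id, hits, saturated

    guides = cs.in_id_order()
    table = HitTable()
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(map_guide, guides))
    else:
        results = [map_guide(g) for g in guides]
    for gid, hits, saturated in results:
        table.add_guide(gid, hits, saturated)
    return table


def verify_pam_at_locus(genome: Genome, hit: Hit, pam: PamSpec) -> bool:
    """Exact (IUPAC-degenerate) PAM check at a hit locus; False off the edge."""
    qs, qe = protospacer_span(hit, pam)
    pam_right = (pam.side == "3prime") == (hit.strand == "+")
    ps, pe = (qe, qe + pam.length) if pam_right else (qs - pam.length, qs)
    seq = genome.chromosomes.get(hit.chrom)
    if seq is None or ps < 0 or pe > len(seq):
        return False
    pam_slice = seq[ps:pe]
    if not _ACGT.issuperset(pam_slice):
        return False
    pam_guide = pam_slice if hit.strand == "+" else revcomp(pam_slice)
    return iupac_match(pam.pattern, pam_guide)


def export_sam(
    table: HitTable, genome: Genome, cs: CandidateSet, path: str | Path
) -> None:
    """Write internal hits as ungapped SAM records (protospacer alignments)."""
    names = list(genome.chromosomes)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(genome.chromosomes[n])} for n in names],
    }
    ref_id = {n: i for i, n in enumerate(names)}
    by_id = cs.by_id
    p_len = cs.protospacer_len
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for gid in table.guide_ids():
            guide = by_id[gid]
            for k, hit in enumerate(table.hits_for(gid)):
                qs, _ = protospacer_span(hit, cs.pam)
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"{gid}.{k}"
                a.flag = 16 if hit.strand == "-" else 0
                a.reference_id = ref_id[hit.chrom]
                a.reference_start = qs
                a.mapping_quality = 255
                a.cigartuples = [(0, p_len)]
                proto = guide.protospacer
                a.query_sequence = revcomp(proto) if hit.strand == "-" else proto
                a.set_tag("NM", hit.mismatches_n)
                out.write(a)


def import_sam_hits(
    path: str | Path,
    cs: CandidateSet,
    genome: Genome,
    hit_cap: int = 10_000,
) -> HitTable:
    """Build a HitTable from external SAM alignments of exported protospacers.

    Read names are resolved to guide ids by stripping at the first ``.`` or
    ``|``; unresolvable or unmapped records are skipped (counted). Gaps are
    allowed: g = total inserted+deleted bases, n = NM − g, and m = matched
    read bases + PAM length. Every record's PAM is re-verified against the
    genome before acceptance.
    """
    pam = cs.pam
    pam_len = pam.length
    p_len = cs.protospacer_len
    full_len = p_len + pam_len
    by_id = cs.by_id
    found: dict[str, dict[tuple[str, int, str], Hit]] = {}
    skipped = 0

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            gid = rec.query_name.split("|")[0].split(".")[0]
            if gid not in by_id:
                skipped += 1
                continue
            cig = rec.cigartuples or []
            gaps = sum(length for op, length in cig if op in (1, 2))
            aligned = sum(length for op, length in cig if op in (0, 7, 8))
            try:
                nm = int(rec.get_tag("NM"))
            except KeyError:
                nm = 0
            n_mm = max(nm - gaps, 0)
            m = aligned - n_mm + pam_len
            strand = "-" if rec.is_reverse else "+"
            qs, qe = rec.reference_start, rec.reference_end
            pam_right = (pam.side == "3prime") == (strand == "+")
            span = (qs, qe + pam_len) if pam_right else (qs - pam_len, qe)
            hit = Hit(
                gid,
                rec.reference_name,
                span[0],
                span[1],
                strand,
                matches_m=m,
                mismatches_n=n_mm,
                gaps_g=gaps,
                length_L=full_len,
            )
            if span[0] < 0 or span[1] > len(genome.chromosomes[rec.reference_name]):
                continue
            if not verify_pam_at_locus(genome, hit, pam):
                continue
            found.setdefault(gid, {})[(hit.chrom, hit.start, hit.strand)] = hit

    if skipped:
        warnings.warn(f"{skipped} SAM records with unresolvable read names skipped")
    table = HitTable()
    table.skipped_records = skipped
    for gid in sorted(found):
        hits = sorted(found[gid].values(), key=_hit_sort_key)
        saturated = len(hits) > hit_cap
        if saturated:
            hits = hits[:hit_cap]
        table.add_guide(gid, hits, saturated)
    return table
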