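"""Genome containers, coordinate conventions and IUPAC sequence matching.

All coordinates are 0-based half-open internally; user-facing reports use
1-based inclusive coordinates (see :func:`GenomicInterval.to_region_string`).
Sequences are stored uppercase over the alphabet {A, C, G, T, N}.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide codes mapped to the set of genomic bases they accept.
#: Genomic ``N`` (unknown base) is matched by pattern ``N`` only: an unknown
#: base cannot be claimed to satisfy any informative degeneracy code.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# Ambiguity codes degrade to N; anything else is rejected by read_fasta.
_NORMALIZE = str.maketrans(
    {c: ("N" if c not in "ACGT" else c) for c in IUPAC_CODES}
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}; N maps to N."""
    if not _DNA_ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _DNA_ALPHABET)
        raise ValueError(f"invalid characters for reverse complement: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True iff ``seq`` realizes the IUPAC ``pattern`` position by position.

    A genomic ``N`` matches only a pattern ``N``. Raises on length mismatch
    or invalid pattern characters.
    """
    if len(pattern) != len(seq):
        raise ValueError(
            f"pattern/sequence length mismatch: {len(pattern)} vs {len(seq)}"
        )
    try:
        return all(s in IUPAC_CODES[p] for p, s in zip(pattern, seq))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in pattern {pattern!r}: {exc}") from exc


def gc_content(seq: str) -> float:
    """Fraction of G+C over the full sequence length; N counts as neither."""
    if not seq:
        raise ValueError("gc_content of empty sequence is undefined")
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome name is empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def to_region_string(self) -> str:
        """1-based inclusive ``chrom:start-end:strand`` for reports."""
        return f"{self.chrom}:{self.start + 1}-{self.end}:{self.strand}"


@dataclass(frozen=True)
class PamSpec:
    """Protospacer-adjacent motif: IUPAC pattern plus which side it flanks.

    ``side`` is ``3prime`` for Cas9-class PAMs (e.g. NGG downstream of the
    protospacer) or ``5prime`` for Cas12/Cpf1-class PAMs (e.g. TTTV upstream).
    """

    pattern: str
    side: str = "3prime"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        if not self.pattern:
            raise ValueError("PAM pattern is empty")
        bad = sorted(set(self.pattern) - set(IUPAC_CODES))
        if bad:
            raise ValueError(f"invalid IUPAC codes in PAM pattern: {bad}")
        if self.side not in ("3prime", "5prime"):
            raise ValueError(f"PAM side must be 3prime or 5prime, got {self.side!r}")

    @property
    def length(self) -> int:
        return len(self.pattern)


@dataclass
class Genome:
    """Ordered set of named chromosomes over {A,C,G,T,N}."""

    chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not name:
                raise ValueError("empty chromosome name")
            if not _DNA_ALPHABET.issuperset(seq):
                bad = sorted(set(seq) - _DNA_ALPHABET)
                raise ValueError(
                    f"chromosome {name!r} contains non-ACGTN characters: {bad}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end); reverse-complemented when strand is '-'."""
        seq = self.chromosomes[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(f"slice {chrom}:{start}-{end} out of bounds")
        piece = seq[start:end]
        return revcomp(piece) if strand == "-" else piece

    def fetch_interval(self, iv: GenomicInterval) -> str:
        strand = iv.strand if iv.strand in ("+", "-") else "+"
        return self.fetch(iv.chrom, iv.start, iv.end, strand)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.chromosomes.items())


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> Genome:
    """Load a (multi-)FASTA genome, normalizing to uppercase {A,C,G,T,N}.

    IUPAC ambiguity codes are degraded to N; any character outside the IUPAC
    nucleotide alphabet is a fatal error naming the offending record. Gzipped
    input (``.gz``) is handled transparently.
    """
    path = Path(path)
    chroms: dict[str, str] = {}
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if not name:
                raise ValueError(f"FASTA record with empty name in {path}")
            if name in chroms:
                raise ValueError(f"duplicate FASTA record name {name!r} in {path}")
            raw = str(record.seq).upper().replace("U", "T")
            bad = sorted(set(raw) - set(IUPAC_CODES))
            if bad:
                raise ValueError(
                    f"record {name!r} contains non-nucleotide characters: {bad}"
                )
            chroms[name] = raw.translate(_NORMALIZE)
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(chroms)


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    """Write the genome back out as multi-FASTA (round-trips read_fasta)."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def sliding_window_sd(k: int) -> float:
    """Standard deviation of a uniform distribution over a window of size k."""
    return k / math.sqrt(12.0)
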