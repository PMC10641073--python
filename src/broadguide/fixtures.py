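"""Synthetic genomes with planted repeat families, plus a brute-force mapper.

The generator emulates the genomic structure the pipeline exploits: a repeat
family (one protospacer+PAM sequence) planted at known loci — clustered
copies inside a chosen interval (the on-target cluster) and scattered copies
elsewhere (off-targets), each with a prescribed number of protospacer
substitutions. The background is i.i.d. with adjustable GC and is
rejection-checked so no accidental exact copy of any planted protospacer
arises; the manifest of realized coordinates is therefore exact ground truth
for hit counts, mismatch histograms and on/off-target accounting.

:func:`brute_force_hits` is a deliberately naive O(genome × L) scan used as
the independent oracle for the seed-and-verify mapper; it shares no code
path with it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome import Genome, GenomicInterval, IUPAC_CODES, PamSpec, revcomp, write_fasta
from .mapping import Hit, HitTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PlantSpec:
    """One repeat family to embed in a synthetic genome.

    ``mismatch_profile`` lists per-copy protospacer substitution counts for
    all copies, on-target copies first (defaults to all exact). Substitutions
    never touch the PAM. Off-target copies land anywhere outside the cluster
    interval, on any chromosome.
    """

    protospacer: str
    pam_realization: str
    copies_on_target: int
    copies_off_target: int
    cluster: GenomicInterval
    mismatch_profile: list[int] = field(default_factory=list)
    name: str = "plant"

    def __post_init__(self) -> None:
        total = self.copies_on_target + self.copies_off_target
        if not self.mismatch_profile:
            self.mismatch_profile = [0] * total
        if len(self.mismatch_profile) != total:
            raise ValueError("mismatch_profile length must equal total copies")
        if any(not (0 <= k <= 3) for k in self.mismatch_profile):
            raise ValueError("per-copy substitution counts must be in 0..3")

    @property
    def insert(self) -> str:
        return self.protospacer + self.pam_realization


@dataclass
class PlantedCopy:
    plant_name: str
    chrom: str
    start: int
    end: int
    strand: str
    n_substitutions: int
    on_target: bool
    realized_seq: str


@dataclass
class FixtureManifest:
    """Exact ground truth for a generated fixture genome."""

    chrom_sizes: dict[str, int]
    background_gc: float
    seed: int
    plants: list[PlantSpec]
    copies: list[PlantedCopy]

    def copies_for(self, plant_name: str) -> list[PlantedCopy]:
        return [c for c in self.copies if c.plant_name == plant_name]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "chrom_sizes": self.chrom_sizes,
            "background_gc": self.background_gc,
            "seed": self.seed,
            "plants": [
                {**asdict(p), "cluster": asdict(p.cluster)} for p in self.plants
            ],
            "copies": [asdict(c) for c in self.copies],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_background(
    rng: np.random.Generator, length: int, gc: float
) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]
    return rng.choice(_BASES, size=length, p=probs)


def _mutate(rng: np.random.Generator, protospacer: str, k: int) -> str:
    if k == 0:
        return protospacer
    seq = list(protospacer)
    for pos in rng.choice(len(seq), size=k, replace=False):
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def _count_exact(genome: Genome, query: str) -> int:
    total = 0
    rc = revcomp(query)
    for _, seq in genome:
        for probe in {query, rc}:
            start = 0
            while True:
                i = seq.find(probe, start)
                if i < 0:
                    break
                total += 1
                start = i + 1
    return total


def generate_fixture(
    chrom_sizes: dict[str, int],
    plants: list[PlantSpec],
    background_gc: float = 0.36,
    seed: int = 0,
    max_attempts: int = 20,
) -> tuple[Genome, FixtureManifest]:
    """Deterministically build a genome with the requested planted copies.

    Retries with a derived seed if the i.i.d. background happens to contain
    an accidental exact copy of a planted protospacer (so manifests stay
    exact); placement collisions within an attempt are re-drawn up to a
    bounded number of times.
    """
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        try:
            genome, copies = _build(rng, chrom_sizes, plants, background_gc)
        except RuntimeError:
            continue
        expected_exact = {
            p.protospacer: sum(1 for k in p.mismatch_profile if k == 0)
            for p in plants
        }
        # Palindromic or mutually-matching protospacers would double-count;
        # fixtures use distinct non-palindromic families.
        if all(
            _count_exact(genome, proto) == n for proto, n in expected_exact.items()
        ):
            manifest = FixtureManifest(
                dict(chrom_sizes), background_gc, seed, plants, copies
            )
            return genome, manifest
    raise RuntimeError(
        f"could not realize fixture without accidental copies in {max_attempts} attempts"
    )


def _build(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    plants: list[PlantSpec],
    background_gc: float,
) -> tuple[Genome, list[PlantedCopy]]:
    arrays = {
        name: _random_background(rng, size, background_gc)
        for name, size in chrom_sizes.items()
    }
    occupied: list[tuple[str, int, int]] = []
    copies: list[PlantedCopy] = []

    def place(plant: PlantSpec, on_target: bool, n_sub: int) -> PlantedCopy:
        ins_len = len(plant.insert)
        for _ in range(1000):
            if on_target:
                chrom = plant.cluster.chrom
                if chrom not in chrom_sizes:
                    raise ValueError(f"cluster chromosome {chrom!r} not in genome")
                lo = plant.cluster.start
                hi = min(plant.cluster.end, chrom_sizes[chrom]) - ins_len
                if hi < lo:
                    raise ValueError("cluster interval too small for insert")
                start = int(rng.integers(lo, hi + 1))
            else:
                chrom = list(chrom_sizes)[rng.integers(len(chrom_sizes))]
                start = int(rng.integers(0, chrom_sizes[chrom] - ins_len + 1))
                if plant.cluster.chrom == chrom and not (
                    start + ins_len <= plant.cluster.start
                    or start >= plant.cluster.end
                ):
                    continue
            end = start + ins_len
            if any(
                c == chrom and start < e and s < end for c, s, e in occupied
            ):
                continue
            occupied.append((chrom, start, end))
            strand = "+" if rng.integers(2) == 0 else "-"
            proto = _mutate(rng, plant.protospacer, n_sub)
            realized = proto + plant.pam_realization
            written = realized if strand == "+" else revcomp(realized)
            arrays[chrom][start:end] = np.frombuffer(
                written.encode(), dtype=np.uint8
            )
            return PlantedCopy(
                plant.name, chrom, start, end, strand, n_sub, on_target, realized
            )
        raise RuntimeError("placement failed after bounded retries")

    for plant in plants:
        profile = plant.mismatch_profile
        for i in range(plant.copies_on_target):
            copies.append(place(plant, True, profile[i]))
        for i in range(plant.copies_off_target):
            copies.append(place(plant, False, profile[plant.copies_on_target + i]))

    genome = Genome(
        {name: arr.tobytes().decode() for name, arr in arrays.items()}
    )
    return genome, copies


def write_fixture(
    genome: Genome,
    manifest: FixtureManifest,
    fasta_path: str | Path,
    manifest_path: str | Path,
) -> None:
    write_fasta(genome, fasta_path)
    manifest.to_json(manifest_path)


def brute_force_hits(
    genome: Genome,
    protospacer: str,
    pam: PamSpec,
    max_mismatches: int,
    guide_id: str = "query",
) -> HitTable:
    """Naive all-position, both-strand scan; the mapper's independent oracle.

    Direct character comparison at every placement; O(genome × L), intended
    for genomes up to ~1 Mb.
    """
    p_len = len(protospacer)
    pam_len = pam.length
    full_len = p_len + pam_len
    pattern_sets = [IUPAC_CODES[c] for c in pam.pattern]
    found: dict[tuple[str, int, str], Hit] = {}

    for chrom, seq in genome:
        n0 = len(seq)
        for strand in "+-":
            search = protospacer if strand == "+" else revcomp(protospacer)
            for s in range(0, n0 - p_len + 1):
                window = seq[s : s + p_len]
                if "N" in window:
                    continue
                mm = 0
                for a, b in zip(search, window):
                    if a != b:
                        mm += 1
                        if mm > max_mismatches:
                            break
                if mm > max_mismatches:
                    continue
                pam_right = (pam.side == "3prime") == (strand == "+")
                if pam_right:
                    ps, pe = s + p_len, s + p_len + pam_len
                    span = (s, s + p_len + pam_len)
                else:
                    ps, pe = s - pam_len, s
                    span = (s - pam_len, s + p_len)
                if ps < 0 or pe > n0:
                    continue
                pam_slice = seq[ps:pe]
                if "N" in pam_slice:
                    continue
                pam_guide = pam_slice if strand == "+" else revcomp(pam_slice)
                if not all(b in ps_set for ps_set, b in zip(pattern_sets, pam_guide)):
                    continue
                found[(chrom, span[0], strand)] = Hit(
                    guide_id,
                    chrom,
                    span[0],
                    span[1],
                    strand,
                    matches_m=full_len - mm,
                    mismatches_n=mm,
                    gaps_g=0,
                    length_L=full_len,
                )

    table = HitTable()
    table.add_guide(
        guide_id,
        sorted(found.values(), key=lambda h: (h.chrom, h.start, h.strand)),
    )
    return table
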