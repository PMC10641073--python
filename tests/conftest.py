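"""Shared helpers: seeded random DNA, manual candidate sets, fixture builders."""

from __future__ import annotations

import numpy as np
import pytest

from broadguide import (
    CandidateGuide,
    CandidateSet,
    Genome,
    GenomicInterval,
    PamSpec,
    gc_content,
)
from broadguide.fixtures import PlantSpec, generate_fixture


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    at = (1.0 - gc) / 2.0
    bases = rng.choice(list("ACGT"), size=n, p=[at, gc / 2, gc / 2, at])
    return "".join(bases)


def single_guide_set(
    protospacer: str, pam: PamSpec, guide_id: str = "q0", pam_seq: str = ""
) -> CandidateSet:
    """A CandidateSet holding one query guide (origins unused by the mapper)."""
    full = protospacer + pam_seq if pam.side == "3prime" else pam_seq + protospacer
    guide = CandidateGuide(
        guide_id, protospacer, pam_seq, full, gc_content(full), []
    )
    return CandidateSet({full: guide}, pam, len(protospacer))


@pytest.fixture
def ngg() -> PamSpec:
    return PamSpec("NGG")


@pytest.fixture
def clustered_fixture():
    """One family: 6 clustered copies on chr1 plus 2 scattered copies.

    chr1 is exactly the cluster interval, so off-target copies always land
    on chr2 and any window covering chr1 captures all on-target hits.
    """
    plant = PlantSpec(
        protospacer="ACGTGACGTGAACCTTGGCA",
        pam_realization="AGG",
        copies_on_target=6,
        copies_off_target=2,
        cluster=GenomicInterval("chr1", 0, 8000),
        name="fam1",
    )
    genome, manifest = generate_fixture(
        {"chr1": 8000, "chr2": 12000}, [plant], background_gc=0.36, seed=11
    )
    return genome, manifest, plant


def hit_keys(table, gid):
    return [(h.chrom, h.start, h.end, h.strand, h.mismatches_n) for h in table.hits_for(gid)]
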