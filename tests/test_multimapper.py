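"""Seed-and-verify mapper vs brute-force oracle; PAM checks; SAM import."""

import numpy as np
import pytest

from broadguide import (
    Genome,
    GenomicInterval,
    PamSpec,
    export_sam,
    find_all_hits,
    import_sam_hits,
    scan_candidates,
    verify_pam_at_locus,
)
from broadguide.fixtures import PlantSpec, brute_force_hits, generate_fixture
from broadguide.mapping import Hit

from conftest import hit_keys, random_dna, single_guide_set

PROTO = "ACGTGACGTGAACCTTGGCA"


def _fixture(seed, on=5, off=0, profile=None, sizes=None):
    plant = PlantSpec(
        PROTO, "AGG", on, off, GenomicInterval("chr1", 0, 6000),
        mismatch_profile=profile or [], name="fam",
    )
    genome, manifest = generate_fixture(
        sizes or {"chr1": 6000, "chr2": 4000}, [plant], seed=seed
    )
    return genome, manifest


class TestFindAllHits:
    def test_planted_exact_copies(self, ngg):
        genome, manifest = _fixture(seed=21, on=5)
        cs = single_guide_set(PROTO, ngg, pam_seq="AGG")
        table = find_all_hits(genome, cs, max_mismatches=0)
        hits = table.hits_for("q0")
        assert len(hits) == 5
        assert all(h.per_hit_score == 1.0 for h in hits)
        assert sorted(h.start for h in hits) == sorted(c.start for c in manifest.copies)

    def test_divergent_copies_scored_by_mismatch(self, ngg):
        genome, _ = _fixture(seed=22, on=5, off=2, profile=[0, 0, 0, 0, 0, 2, 2])
        cs = single_guide_set(PROTO, ngg, pam_seq="AGG")
        table = find_all_hits(genome, cs, max_mismatches=3)
        hits = table.hits_for("q0")
        assert len(hits) == 7
        scores = sorted(h.per_hit_score for h in hits)
        # (m - n)/L with m = L - n: two hits at n=2 give (21-2)/23 = 19/23
        assert scores[:2] == pytest.approx([19 / 23, 19 / 23])
        assert scores[2:] == [1.0] * 5

    def test_hits_nested_in_mismatch_budget(self, ngg):
        genome, _ = _fixture(seed=23, on=4, off=3, profile=[0, 0, 1, 2, 0, 1, 3])
        cs = single_guide_set(PROTO, ngg, pam_seq="AGG")
        keys = {
            mm: set(map(tuple, hit_keys(find_all_hits(genome, cs, mm), "q0")))
            for mm in range(4)
        }
        for mm in range(3):
            assert {k[:4] for k in keys[mm]} <= {k[:4] for k in keys[mm + 1]}

    @pytest.mark.parametrize("mm", [0, 1, 2, 3])
    def test_agrees_with_brute_force_oracle(self, ngg, mm):
        rng = np.random.default_rng(100 + mm)
        genome = Genome(
            {"c1": random_dna(rng, 3000, gc=0.5), "c2": random_dna(rng, 1500, gc=0.5)}
        )
        # map a guide actually present in the genome plus a random query
        cs_all = scan_candidates(genome, ngg, 20)
        present = cs_all.in_id_order()[0]
        for proto in (present.protospacer, random_dna(rng, 20, gc=0.5)):
            cs = single_guide_set(proto, ngg)
            fast = find_all_hits(genome, cs, max_mismatches=mm)
            slow = brute_force_hits(genome, proto, ngg, mm, guide_id="q0")
            assert hit_keys(fast, "q0") == hit_keys(slow, "q0")

    def test_hit_cap_saturation(self, ngg):
        genome = Genome({"c": ("ACGTGACGTGAACCTTGGCAAGG" + "TTTT") * 30})
        cs = single_guide_set(PROTO, ngg, pam_seq="AGG")
        table = find_all_hits(genome, cs, max_mismatches=0, hit_cap=10)
        assert table.t("q0") == 10
        assert "q0" in table.saturated

    def test_zero_hit_guides_retained(self, ngg):
        genome = Genome({"c": "ATATATAT" * 50})
        cs = single_guide_set(PROTO, ngg, pam_seq="AGG")
        table = find_all_hits(genome, cs, max_mismatches=0)
        assert table.t("q0") == 0
        assert "q0" in table.guide_ids()

    def test_thread_count_does_not_change_output(self, ngg):
        genome, _ = _fixture(seed=24, on=6, off=3, profile=[0, 0, 1, 1, 2, 2, 0, 1, 2])
        cs = scan_candidates(genome, ngg, 20)
        tables = [
            find_all_hits(genome, cs, 2, threads=t).to_dataframe() for t in (1, 4)
        ]
        assert tables[0].equals(tables[1])


class TestVerifyPam:
    def test_pam_present_and_absent(self, ngg):
        genome = Genome({"c": "T" * 10 + PROTO + "AGG" + "T" * 10})
        hit = Hit("q0", "c", 10, 33, "+", 23, 0, 0, 23)
        assert verify_pam_at_locus(genome, hit, ngg)
        genome2 = Genome({"c": "T" * 10 + PROTO + "ATG" + "T" * 10})
        assert not verify_pam_at_locus(genome2, hit, ngg)

    def test_chromosome_edge_lacks_pam_room(self, ngg):
        genome = Genome({"c": "T" * 10 + PROTO + "AG"})  # 1 bp short of a PAM
        hit = Hit("q0", "c", 10, 32, "+", 23, 0, 0, 23)
        assert not verify_pam_at_locus(genome, hit, ngg)

    def test_minus_strand_pam(self, ngg):
        # genome holds revcomp(PROTO + AGG); protospacer span [13, 33)
        from broadguide import revcomp

        genome = Genome({"c": "T" * 10 + revcomp(PROTO + "AGG") + "T" * 10})
        hit = Hit("q0", "c", 10, 33, "-", 23, 0, 0, 23)
        assert verify_pam_at_locus(genome, hit, ngg)


class TestSamImport:
    def test_round_trip_of_internal_hits(self, ngg, tmp_path):
        genome, _ = _fixture(seed=25, on=5, off=2, profile=[0, 0, 1, 1, 2, 0, 2])
        cs = scan_candidates(genome, ngg, 20)
        table = find_all_hits(genome, cs, max_mismatches=2)
        sam = tmp_path / "hits.sam"
        export_sam(table, genome, cs, sam)
        back = import_sam_hits(sam, cs, genome)
        for gid in table.guide_ids():
            if table.t(gid):
                assert hit_keys(back, gid) == hit_keys(table, gid)
                got = {(h.matches_m, h.mismatches_n, h.gaps_g) for h in back.hits_for(gid)}
                want = {(h.matches_m, h.mismatches_n, h.gaps_g) for h in table.hits_for(gid)}
                assert got == want

    def test_one_base_deletion_record(self, ngg, tmp_path):
        # reference carries the protospacer with one extra base (read deletion)
        ref = "T" * 10 + PROTO[:10] + "A" + PROTO[10:] + "AGG" + "T" * 10
        genome = Genome({"c": ref})
        cs = single_guide_set(PROTO, ngg, pam_seq="AGG")
        sam = tmp_path / "del.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            f"@SQ\tSN:c\tLN:{len(ref)}\n"
            f"q0.0\t0\tc\t11\t60\t10M1D10M\t*\t0\t0\t{PROTO}\t*\tNM:i:1\n"
        )
        table = import_sam_hits(sam, cs, genome)
        (hit,) = table.hits_for("q0")
        assert (hit.gaps_g, hit.mismatches_n) == (1, 0)
        # matched read bases (20) + exact PAM (3): score (23 - 0 - 1)/23
        assert hit.matches_m == 23
        assert hit.per_hit_score == pytest.approx(22 / 23)

    def test_unmapped_and_unresolvable_records_skipped(self, ngg, tmp_path):
        genome = Genome({"c": "T" * 10 + PROTO + "AGG" + "T" * 10})
        cs = single_guide_set(PROTO, ngg, pam_seq="AGG")
        sam = tmp_path / "mix.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            f"@SQ\tSN:c\tLN:{len(genome.chromosomes['c'])}\n"
            f"ghost.0\t0\tc\t11\t60\t20M\t*\t0\t0\t{PROTO}\t*\tNM:i:0\n"
            f"q0.0\t4\t*\t0\t0\t*\t*\t0\t0\t{PROTO}\t*\n"
        )
        with pytest.warns(UserWarning, match="unresolvable"):
            table = import_sam_hits(sam, cs, genome)
        assert len(table) == 0
        assert table.skipped_records == 1

    def test_pam_reverified_on_import(self, ngg, tmp_path):
        # alignment is fine but the genomic PAM is broken -> record rejected
        genome = Genome({"c": "T" * 10 + PROTO + "ATT" + "T" * 10})
        cs = single_guide_set(PROTO, ngg, pam_seq="AGG")
        sam = tmp_path / "nopam.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            f"@SQ\tSN:c\tLN:{len(genome.chromosomes['c'])}\n"
            f"q0.0\t0\tc\t11\t60\t20M\t*\t0\t0\t{PROTO}\t*\tNM:i:0\n"
        )
        table = import_sam_hits(sam, cs, genome)
        assert len(table) == 0
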