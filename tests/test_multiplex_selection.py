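"""Bin selection, ranking, pooling and region-restricted mode."""

import pytest

from broadguide import (
    Genome,
    GenomicInterval,
    PamSpec,
    WindowConfig,
    pool_guides,
    rank_guides,
    read_bed,
    select_bins,
)
from broadguide.fixtures import PlantSpec, generate_fixture
from broadguide.mapping import Hit, HitTable
from broadguide.pipeline import RunConfig, run_pipeline
from broadguide.selection import TargetBin, TargetPlan
from broadguide.windows import Window, assign_hits, sliding_windows

L = 23
CFG = WindowConfig(2000, step=200, min_hits=5)


def _hits(gid, chrom, starts):
    return [Hit(gid, chrom, s, s + L, "+", L, 0, 0, L) for s in sorted(starts)]


def _two_cluster_setup():
    """10-hit cluster near 1000, 6-hit cluster near 12000 on one chromosome."""
    big = [1000 + 120 * i for i in range(10)]
    small = [12000 + 150 * i for i in range(6)]
    hits = _hits("g1", "c", big + small)
    table = HitTable()
    table.add_guide("g1", hits)
    wins = sliding_windows(20_000, CFG, chrom="c")
    guide_windows = assign_hits(table, wins, CFG)
    return guide_windows, hits, big, small


class TestSelectBins:
    def test_single_bin_takes_largest_cluster(self):
        guide_windows, hits, big, small = _two_cluster_setup()
        plan = select_bins(guide_windows, hits, CFG, n_bins=1)
        assert plan.h == 10 and plan.o == 6 and plan.t == 16
        assert all(
            plan.bins[0].interval.start <= s < plan.bins[0].interval.end for s in big
        )

    def test_two_bins_capture_both_clusters(self):
        guide_windows, hits, *_ = _two_cluster_setup()
        one = select_bins(guide_windows, hits, CFG, n_bins=1)
        two = select_bins(guide_windows, hits, CFG, n_bins=2)
        assert two.o == 0 and two.h == 16
        assert two.S > one.S
        assert not two.underfilled

    def test_more_bins_than_clusters_flags_plan(self):
        guide_windows, hits, *_ = _two_cluster_setup()
        plan = select_bins(guide_windows, hits, CFG, n_bins=5)
        assert plan.underfilled
        assert plan.o == 0  # both clusters still captured

    def test_bins_pairwise_non_overlapping(self):
        guide_windows, hits, *_ = _two_cluster_setup()
        plan = select_bins(guide_windows, hits, CFG, n_bins=3)
        for i, a in enumerate(plan.bins):
            for b in plan.bins[i + 1 :]:
                assert not a.interval.overlaps(b.interval)

    def test_conservation_and_monotone_trends(self):
        guide_windows, hits, *_ = _two_cluster_setup()
        prev_o, prev_s = None, None
        for n_bins in (1, 2, 3, 4):
            plan = select_bins(guide_windows, hits, CFG, n_bins=n_bins)
            assert plan.h + plan.o == plan.t
            if prev_o is not None:
                assert plan.o <= prev_o
                assert plan.S >= prev_s - 1e-12
            prev_o, prev_s = plan.o, plan.S


class TestRankGuides:
    def _plan(self, gid, seq, S, h):
        bin_ = TargetBin(GenomicInterval("c", 0, 100), h, float(h))
        return TargetPlan(gid, seq, [bin_], h, h, 0, float(h), 0.0, 0.5, 10.0, True, S, False)

    def test_descending_score(self):
        ranked = rank_guides([self._plan("a", "AAA", 0.5, 3), self._plan("b", "CCC", 0.9, 3)])
        assert [p.S for p in ranked] == [0.9, 0.5]
        assert [p.rank for p in ranked] == [1, 2]

    def test_tie_broken_by_on_target_hits_then_sequence(self):
        ranked = rank_guides(
            [
                self._plan("a", "TTT", 0.7, 8),
                self._plan("b", "AAA", 0.7, 12),
                self._plan("c", "CCC", 0.7, 8),
            ]
        )
        assert [p.guide_id for p in ranked] == ["b", "c", "a"]

    def test_ranking_is_a_permutation(self):
        plans = [self._plan(f"g{i}", f"SEQ{i}", 0.1 * i, i + 1) for i in range(7)]
        ranked = rank_guides(plans)
        assert sorted(p.guide_id for p in ranked) == sorted(p.guide_id for p in plans)
        assert sorted(p.rank for p in ranked) == list(range(1, 8))


class TestPoolGuides:
    def _plan_with_bins(self, gid, bins):
        tb = [TargetBin(iv, n, float(n)) for iv, n in bins]
        return TargetPlan(gid, gid, tb, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, False, 0.0, False)

    def test_identical_bins_merge(self):
        iv = GenomicInterval("c", 100, 200)
        pools = pool_guides(
            [self._plan_with_bins("a", [(iv, 5)]), self._plan_with_bins("b", [(iv, 7)])]
        )
        assert len(pools) == 1
        assert pools[0].guide_ids == ("a", "b")
        assert pools[0].combined_hits == 12

    def test_disjoint_bins_stay_separate(self):
        pools = pool_guides(
            [
                self._plan_with_bins("a", [(GenomicInterval("c", 0, 100), 5)]),
                self._plan_with_bins("b", [(GenomicInterval("c", 500, 600), 5)]),
            ],
            region_merge_gap=100,
        )
        assert len(pools) == 2

    def test_gap_merging_and_strict_overlap_default(self):
        a = self._plan_with_bins("a", [(GenomicInterval("c", 0, 100), 5)])
        b = self._plan_with_bins("b", [(GenomicInterval("c", 100, 200), 5)])
        assert len(pool_guides([a, b])) == 2  # touching, strict overlap default
        assert len(pool_guides([a, b], region_merge_gap=10)) == 1

    def test_pooled_union_covers_all_bins(self):
        plans = [
            self._plan_with_bins("a", [(GenomicInterval("c", 0, 150), 5)]),
            self._plan_with_bins("b", [(GenomicInterval("c", 100, 300), 6)]),
            self._plan_with_bins("c", [(GenomicInterval("d", 50, 90), 7)]),
        ]
        pools = pool_guides(plans)
        for p in plans:
            for bin_ in p.bins:
                assert any(
                    r.interval.chrom == bin_.interval.chrom
                    and r.interval.start <= bin_.interval.start
                    and bin_.interval.end <= r.interval.end
                    for r in pools
                )

    def test_three_guides_two_clusters_membership(self):
        shared = GenomicInterval("c", 1000, 3000)
        other = GenomicInterval("c", 9000, 11000)
        plans = [
            self._plan_with_bins("a", [(shared, 6)]),
            self._plan_with_bins("b", [(GenomicInterval("c", 1500, 3500), 5)]),
            self._plan_with_bins("z", [(other, 8)]),
        ]
        pools = sorted(pool_guides(plans), key=lambda r: r.interval.start)
        assert pools[0].guide_ids == ("a", "b")
        assert pools[1].guide_ids == ("z",)


class TestRegionMode:
    PROTO = "ACGTGACGTGAACCTTGGCA"

    def _fixture(self, tmp_path, seed=31):
        from broadguide.fixtures import write_fixture

        plant = PlantSpec(
            self.PROTO, "AGG", 6, 2, GenomicInterval("chr1", 0, 8000), name="fam"
        )
        genome, manifest = generate_fixture(
            {"chr1": 8000, "chr2": 12000}, [plant], seed=seed
        )
        fa = tmp_path / "fix.fa"
        write_fixture(genome, manifest, fa, tmp_path / "fix.json")
        return genome, manifest, fa

    def _cfg(self, fa, out, **kw):
        base = dict(
            genome=str(fa),
            out_prefix=str(out),
            max_mismatches=1,
            window_size=8000,
            step=800,
            min_hits=5,
        )
        base.update(kw)
        return RunConfig(**base)

    def test_whole_chromosome_region_equals_whole_genome_run(self, tmp_path):
        genome, _, fa = self._fixture(tmp_path)
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t0\t8000\n")
        res_full = run_pipeline(self._cfg(fa, tmp_path / "full"))
        res_region = run_pipeline(
            self._cfg(fa, tmp_path / "reg", regions_bed=str(bed))
        )
        full_report = (tmp_path / "full.report.tsv").read_bytes()
        region_report = (tmp_path / "reg.report.tsv").read_bytes()
        assert full_report == region_report
        assert len(res_full.plans) == len(res_region.plans) == 1

    def test_region_without_pam_sites_empty_success(self, tmp_path):
        genome, _ = generate_fixture({"c1": 4000}, [], background_gc=0.0, seed=5)
        from broadguide import write_fasta

        fa = tmp_path / "at.fa"
        write_fasta(genome, fa)
        bed = tmp_path / "r.bed"
        bed.write_text("c1\t0\t4000\n")
        res = run_pipeline(
            self._cfg(fa, tmp_path / "empty", regions_bed=str(bed), window_size=2000, step=200)
        )
        assert res.plans == []
        report = (tmp_path / "empty.report.tsv").read_text().splitlines()
        assert len(report) == 1  # header only

    def test_copies_outside_region_count_as_off_target(self, tmp_path):
        genome, manifest, fa = self._fixture(tmp_path, seed=33)
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t0\t8000\n")
        res = run_pipeline(self._cfg(fa, tmp_path / "off", regions_bed=str(bed)))
        (plan,) = res.plans
        assert plan.h == 6
        assert plan.o == 2  # the chr2 copies fall outside every bin
        assert all(b.interval.chrom == "chr1" for b in plan.bins)


class TestReadBed:
    def test_bed3_and_bed6(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("c1\t0\t100\nc1\t200\t300\tname\t0\t-\n")
        regions = read_bed(p)
        assert [(r.start, r.end, r.strand) for r in regions] == [
            (0, 100, "."),
            (200, 300, "-"),
        ]

    def test_malformed_line_fatal_with_line_number(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("c1\t0\t100\nc1\tx\t300\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(p)

    def test_out_of_bounds_checked_against_genome(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("c1\t0\t5000\n")
        with pytest.raises(ValueError, match="line 1"):
            read_bed(p, Genome({"c1": "ACGT" * 100}))
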