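import numpy as np
import pandas as pd
import pytest

import sibmap as sm
from sibmap.linkmap import GeneticMap, LinkageGroup
from sibmap.simdata import HIT_COLUMNS, RearrangementSpec
from sibmap.synteny import (
    BlockStats,
    assign_anchors,
    block_stats,
    best_unique_hits,
    cluster_placements,
    find_blocks,
    place_features,
    union_coverage_pct,
)


def _hit(q, s, sstart, send, bitscore=200.0, evalue=1e-30):
    return [q, s, 100.0, 150, 0, 0, 1, 150, sstart, send, evalue, bitscore]


def _hits(rows):
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def _gmap(loci_positions):
    return GeneticMap("test", "kosambi", [
        LinkageGroup("LG1", [l for l, _ in loci_positions], [p for _, p in loci_positions])
    ])


class TestAssignAnchors:
    def test_single_good_hit_anchored(self):
        gmap = _gmap([("A", 0.0)])
        anchors = assign_anchors(_hits([_hit("A", "chr1", 100, 249)]), gmap)
        assert len(anchors) == 1
        assert anchors.iloc[0]["chromosome"] == "chr1"

    def test_equal_bitscores_on_two_chromosomes_unanchored(self):
        gmap = _gmap([("A", 0.0)])
        anchors = assign_anchors(
            _hits([_hit("A", "chr1", 100, 249), _hit("A", "chr2", 500, 649)]), gmap)
        assert anchors.empty

    def test_margin_rule_arithmetic(self):
        # 200 vs 150 on another chromosome: margin 0.25 > 0.1 -> best kept
        gmap = _gmap([("A", 0.0)])
        anchors = assign_anchors(
            _hits([_hit("A", "chr1", 100, 249, 200.0),
                   _hit("A", "chr2", 500, 649, 150.0)]), gmap)
        assert len(anchors) == 1
        assert anchors.iloc[0]["chromosome"] == "chr1"

    def test_weak_evalue_rejected(self):
        gmap = _gmap([("A", 0.0)])
        anchors = assign_anchors(
            _hits([_hit("A", "chr1", 100, 249, evalue=1e-3)]), gmap)
        assert anchors.empty

    def test_minus_strand_normalized(self):
        anchors = best_unique_hits(_hits([_hit("A", "chr1", 249, 100)]))
        assert anchors.iloc[0]["strand"] == "-"
        assert anchors.iloc[0]["bp_start"] == 100

    def test_unmapped_loci_ignored(self):
        gmap = _gmap([("A", 0.0)])
        anchors = assign_anchors(_hits([_hit("Z", "chr1", 100, 249)]), gmap)
        assert anchors.empty


class TestFindBlocks:
    def _anchored(self, positions_bp, chrom="chr1"):
        """gmap with loci at 10 cM spacing anchored at the given bp."""
        loci = [(f"L{i}", 10.0 * i) for i in range(len(positions_bp))]
        gmap = _gmap(loci)
        rows = [_hit(f"L{i}", c if isinstance(c, str) else chrom, bp, bp + 149)
                for i, (bp, c) in enumerate(
                    (b if isinstance(b, tuple) else (b, chrom) for b in positions_bp))]
        anchors = assign_anchors(_hits(rows), gmap)
        return gmap, anchors

    def test_collinear_loci_one_block(self):
        gmap, anchors = self._anchored([1000, 2000, 3000, 4000, 5000])
        blocks, _ = find_blocks(gmap, anchors)
        assert len(blocks) == 1
        assert blocks[0].n_loci == 5
        assert blocks[0].orientation == "+"

    def test_interrupting_chromosome_splits(self):
        gmap, anchors = self._anchored(
            [1000, 2000, (9000, "chr2"), 3000, 4000])
        blocks, _ = find_blocks(gmap, anchors)
        assert [b.n_loci for b in blocks] == [2, 2]
        assert all(b.chromosome == "chr1" for b in blocks)

    def test_sub_tolerance_swap_keeps_single_block(self):
        # adjacent pair swapped in bp, 2 cM apart on a 100 cM LG (2% < 5%)
        loci = [(f"L{i}", p) for i, p in enumerate([0.0, 30.0, 60.0, 62.0, 100.0])]
        gmap = _gmap(loci)
        bps = [1000, 2000, 4000, 3000, 5000]  # L2/L3 swapped
        anchors = assign_anchors(
            _hits([_hit(f"L{i}", "chr1", bp, bp + 149) for i, bp in enumerate(bps)]), gmap)
        blocks, excl = find_blocks(gmap, anchors, tolerance_frac=0.05)
        assert len(blocks) == 1
        assert len(excl) == 1
        assert excl.iloc[0]["locus_id"] == "L3"

    def test_above_tolerance_swap_splits(self):
        loci = [(f"L{i}", p) for i, p in enumerate([0.0, 30.0, 60.0, 80.0, 100.0])]
        gmap = _gmap(loci)
        bps = [1000, 2000, 4000, 3000, 5000]
        anchors = assign_anchors(
            _hits([_hit(f"L{i}", "chr1", bp, bp + 149) for i, bp in enumerate(bps)]), gmap)
        blocks, excl = find_blocks(gmap, anchors, tolerance_frac=0.05)
        assert len(blocks) > 1
        assert excl.empty

    def test_reversed_run_minus_orientation(self):
        gmap, anchors = self._anchored([5000, 4000, 3000, 2000, 1000])
        blocks, _ = find_blocks(gmap, anchors)
        assert len(blocks) == 1
        assert blocks[0].orientation == "-"

    def test_exact_recovery_of_simulated_blocks(self):
        tm = sm.simulate_true_map(3, [100.0, 80.0, 90.0], 30, seed=2)
        spec = RearrangementSpec(events=[
            ("inversion", "LG1", (30.0, 60.0)),
            ("translocation", "LG2", (20.0, 40.0), "chr3"),
        ])
        hits, true_blocks = sm.simulate_genome_anchors(tm, spec)
        groups = [LinkageGroup(lg, [l for l, _ in loci], [p for _, p in loci])
                  for lg, _, loci in tm.linkage_groups]
        gmap = GeneticMap("truth", "kosambi", groups)
        anchors = assign_anchors(hits, gmap, "simgenome")
        blocks, _ = find_blocks(gmap, anchors, tolerance_frac=0.0)
        found = {(b.lg, b.chromosome, tuple(b.locus_ids)) for b in blocks}
        truth = {(b.lg, b.chromosome, b.locus_ids) for b in true_blocks}
        assert found == truth  # precision = recall = 1


class TestBlockStats:
    def test_from_totals_reproduces_table_arithmetic(self):
        s = BlockStats.from_totals("flounder", 511, 1900, 287.52, 750.5, 1605.43)
        assert s.avg_loci_per_block == pytest.approx(3.7, abs=0.05)
        assert s.coverage_pct == pytest.approx(46.7, abs=0.05)

    def test_stats_consistency_invariants(self):
        gmap, anchors = TestFindBlocks()._anchored([1000, 2000, 3000, 4000, 5000])
        blocks, _ = find_blocks(gmap, anchors)
        s = block_stats(blocks, gmap)[0]
        assert s.avg_loci_per_block == pytest.approx(s.n_loci / s.n_blocks, abs=0.05)
        assert s.avg_cM == pytest.approx(s.total_cM / s.n_blocks, abs=0.05)
        assert 0 <= s.coverage_pct <= 100

    def test_empty_blocks_zero_stats(self):
        gmap = _gmap([("A", 0.0)])
        assert block_stats([], gmap) == []
        assert union_coverage_pct([], gmap) == 0.0

    def test_coverage_invariant_to_orientation(self):
        g1, a1 = TestFindBlocks()._anchored([1000, 2000, 3000, 4000, 5000])
        g2, a2 = TestFindBlocks()._anchored([5000, 4000, 3000, 2000, 1000])
        s1 = block_stats(find_blocks(g1, a1)[0], g1)[0]
        s2 = block_stats(find_blocks(g2, a2)[0], g2)[0]
        assert s1.coverage_pct == s2.coverage_pct


class TestPlaceFeatures:
    def _setup(self):
        gmap, anchors = TestFindBlocks()._anchored([1000, 2000, 3000, 4000, 5000])
        blocks, _ = find_blocks(gmap, anchors)
        return gmap, anchors, blocks

    def test_midpoint_interpolation(self):
        gmap, anchors, blocks = self._setup()
        # flanks L1 (bp 2075 mid, 10 cM) and L2 (3075, 20 cM); midpoint bp
        mid = (blocks[0].member_bps[1] + blocks[0].member_bps[2]) // 2
        fh = _hits([_hit("F", "chr1", mid, mid)])
        pl, un = place_features(fh, blocks, gmap, anchors)
        assert len(pl) == 1
        assert pl.iloc[0]["position_cM"] == pytest.approx(15.0, abs=0.01)
        assert pl.iloc[0]["flank_left"] == "L1"
        assert pl.iloc[0]["flank_right"] == "L2"

    def test_feature_outside_blocks_unplaced(self):
        gmap, anchors, blocks = self._setup()
        fh = _hits([_hit("F", "chr1", 900000, 900149)])
        pl, un = place_features(fh, blocks, gmap, anchors)
        assert pl.empty
        assert un.iloc[0]["reason"] == "outside_blocks"

    def test_feature_at_member_bp_gets_member_cm(self):
        gmap, anchors, blocks = self._setup()
        bp = blocks[0].member_bps[2]
        fh = _hits([_hit("F", "chr1", bp, bp)])
        pl, _ = place_features(fh, blocks, gmap, anchors)
        assert pl.iloc[0]["position_cM"] == pytest.approx(20.0, abs=1e-6)

    def test_placement_inside_block_cm_span(self):
        gmap, anchors, blocks = self._setup()
        rng = np.random.default_rng(1)
        rows = [_hit(f"F{i}", "chr1", int(bp), int(bp))
                for i, bp in enumerate(rng.integers(1075, 5075, 10))]
        pl, _ = place_features(_hits(rows), blocks, gmap, anchors)
        b = blocks[0]
        lo, hi = min(b.cm_start, b.cm_end), max(b.cm_start, b.cm_end)
        assert ((pl["position_cM"] >= lo - 1e-9) & (pl["position_cM"] <= hi + 1e-9)).all()


class TestClusterPlacements:
    def _pl(self, rows):
        df = pd.DataFrame(rows, columns=["feature_id", "lg", "position_cM"])
        df["primary"] = True
        return df

    def test_identical_positions_one_cluster(self):
        out = cluster_placements(self._pl([("F1", "LG1", 5.0), ("F2", "LG1", 5.0),
                                           ("F3", "LG1", 5.0)]), max_gap_cM=1.0)
        assert out["cluster_id"].nunique() == 1
        assert (out["cluster_size"] == 3).all()

    def test_distant_features_separate_clusters(self):
        out = cluster_placements(self._pl([("F1", "LG1", 0.0), ("F2", "LG1", 50.0)]),
                                 max_gap_cM=1.0)
        assert out["cluster_id"].nunique() == 2

    def test_constructed_cluster_count(self):
        rows = ([(f"A{i}", "LG1", 10.0 + 0.2 * i) for i in range(4)]
                + [(f"B{i}", "LG1", 40.0 + 0.2 * i) for i in range(3)]
                + [("C0", "LG2", 5.0)])
        out = cluster_placements(self._pl(rows), max_gap_cM=1.0)
        assert out["cluster_id"].nunique() == 3
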