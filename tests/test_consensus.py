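import itertools

import numpy as np
import pytest

from sibmap.consensus import (
    ConsensusError,
    ConsensusMapModel,
    detect_conflicts,
    match_linkage_groups,
    merge_linkage_group,
    resolve_conflicts,
)
from sibmap.linkmap import GeneticMap, LinkageGroup


def _map(provenance, *groups):
    return GeneticMap(provenance, "kosambi", [LinkageGroup(*g) for g in groups])


class TestDetectConflicts:
    def test_identical_maps_no_conflicts(self):
        a = _map("A", ("LG1", ["X", "Y", "Z"], [0.0, 5.0, 10.0]))
        b = _map("B", ("LG1", ["X", "Y", "Z"], [0.0, 5.0, 10.0]))
        assert detect_conflicts(a, b) == []

    def test_opposite_order_flags_both(self):
        a = _map("A", ("LG1", ["X", "Y"], [0.0, 5.0]))
        b = _map("B", ("LG1", ["Y", "X"], [0.0, 5.0]))
        conflicts = detect_conflicts(a, b)
        assert sorted(c.locus_id for c in conflicts) == ["X", "Y"]

    def test_cluster_sizes_recorded(self):
        # X co-positioned with 2 mates in A (cluster 3) and 4 mates in B (cluster 5)
        a = _map("A", ("LG1", ["C1", "C2", "X", "Y"], [10.0, 10.0, 10.0, 20.0]))
        b = _map("B", ("LG1", ["Y", "D1", "D2", "D3", "D4", "X"],
                 [5.0, 10.0, 10.0, 10.0, 10.0, 10.0]))
        conflicts = {c.locus_id: c for c in detect_conflicts(a, b)}
        assert conflicts["X"].cluster_size_a == 3
        assert conflicts["X"].cluster_size_b == 5

    def test_ambiguous_lg_correspondence_is_error(self):
        a = _map("A", ("LG1", ["X", "Y"], [0.0, 5.0]))
        b = _map("B", ("LG1", ["X"], [0.0]), ("LG2", ["Y"], [0.0]))
        with pytest.raises(ConsensusError, match="ambiguous"):
            match_linkage_groups(a, b)


class TestResolveConflicts:
    def test_removed_from_larger_cluster(self):
        a = _map("A", ("LG1", ["C1", "C2", "X", "Y"], [10.0, 10.0, 10.0, 20.0]))
        b = _map("B", ("LG1", ["Y", "D1", "D2", "D3", "D4", "X"],
                 [5.0, 10.0, 10.0, 10.0, 10.0, 10.0]))
        a2, b2, log, remaining = resolve_conflicts(a, b)
        # X sits in the size-5 cluster of B -> removed from B, kept in A
        assert "X" in a2.lg("LG1").locus_ids
        assert "X" not in b2.lg("LG1").locus_ids
        row = log.set_index("locus_id").loc["X"]
        assert row["action"] == "removed_from_B"
        assert remaining == []

    def test_clustered_in_one_map_removed_there(self):
        a = _map("A", ("LG1", ["C1", "X", "Y"], [10.0, 10.0, 20.0]))
        b = _map("B", ("LG1", ["Y", "X"], [5.0, 10.0]))
        a2, b2, log, _ = resolve_conflicts(a, b)
        assert "X" not in a2.lg("LG1").locus_ids
        assert "X" in b2.lg("LG1").locus_ids

    def test_no_conflicts_maps_unchanged(self):
        a = _map("A", ("LG1", ["X", "Y"], [0.0, 5.0]))
        b = _map("B", ("LG1", ["X", "Y"], [0.0, 7.0]))
        a2, b2, log, _ = resolve_conflicts(a, b)
        assert a2.lg("LG1").locus_ids == ["X", "Y"]
        assert b2.lg("LG1").locus_ids == ["X", "Y"]
        assert log.empty


class TestMerge:
    def test_identical_maps_mae_zero(self):
        a = _map("A", ("LG1", ["X", "Y", "Z"], [0.0, 5.0, 10.0]))
        b = _map("B", ("LG1", ["X", "Y", "Z"], [0.0, 5.0, 10.0]))
        res = ConsensusMapModel(a, b).fit()
        assert res.mae == pytest.approx(0.0, abs=1e-9)
        cg = res.map.lg("LG1")
        assert cg.locus_ids == ["X", "Y", "Z"]
        assert cg.positions == pytest.approx([0.0, 5.0, 10.0], abs=1e-6)

    def test_partial_overlap_keeps_order_constraints(self):
        a = _map("A", ("LG1", ["A", "B"], [0.0, 10.0]))
        b = _map("B", ("LG1", ["B", "C"], [0.0, 10.0]))
        lg, mae = merge_linkage_group(a.lg("LG1"), b.lg("LG1"))
        assert lg.locus_ids[0] == "A"
        assert lg.locus_ids.index("B") == 1  # B between A and C
        assert lg.locus_ids[-1] == "C"

    def test_mae_matches_bruteforce_on_small_instance(self):
        a = LinkageGroup("LG1", ["A", "B"], [0.0, 10.0])
        b = LinkageGroup("LG1", ["B", "C"], [0.0, 10.0])
        lg, mae = merge_linkage_group(a, b, epsilon=0.01)
        # brute force over a coarse grid, constraints xA < xB < xC
        grid = np.arange(0.0, 20.25, 0.25)
        best = np.inf
        for xa, xb, xc in itertools.product(grid, repeat=3):
            if not (xa < xb < xc):
                continue
            cand = (abs(xa - 0) + abs(xb - 10) + abs(xb - 0) + abs(xc - 10)) / 4
            best = min(best, cand)
        assert mae == pytest.approx(best, abs=0.05)

    def test_consensus_never_contradicts_shared_order(self):
        a = _map("A", ("LG1", ["A", "B", "C", "D"], [0.0, 2.0, 7.0, 9.0]))
        b = _map("B", ("LG1", ["A", "B", "C", "D"], [0.0, 3.0, 5.0, 12.0]))
        res = ConsensusMapModel(a, b).fit()
        cg = res.map.lg("LG1")
        assert cg.locus_ids == ["A", "B", "C", "D"]
        assert all(q >= p for p, q in zip(cg.positions, cg.positions[1:]))

    def test_tie_relaxation_keeps_lp_feasible(self):
        # co-positioned in A, strictly ordered in B: must merge, ordered per B
        a = _map("A", ("LG1", ["X", "Y", "Z"], [0.0, 5.0, 5.0]))
        b = _map("B", ("LG1", ["X", "Z", "Y"], [0.0, 4.0, 6.0]))
        res = ConsensusMapModel(a, b, max_rounds=0).fit()
        cg = res.map.lg("LG1")
        assert cg.locus_ids.index("Z") < cg.locus_ids.index("Y")

    def test_total_loci_is_union_of_components(self):
        a = _map("A", ("LG1", ["C1", "C2", "X", "Y"], [10.0, 10.0, 10.0, 20.0]))
        b = _map("B", ("LG1", ["Y", "D1", "D2", "D3", "D4", "X"],
                 [5.0, 10.0, 10.0, 10.0, 10.0, 10.0]))
        res = ConsensusMapModel(a, b).fit()
        union = {"C1", "C2", "D1", "D2", "D3", "D4", "X", "Y"}
        assert set(res.map.lg("LG1").locus_ids) == union

    def test_deterministic(self):
        a = _map("A", ("LG1", ["A", "B", "C"], [0.0, 4.0, 9.0]))
        b = _map("B", ("LG1", ["A", "C", "B"], [0.0, 5.0, 5.0]))
        r1 = ConsensusMapModel(a, b).fit()
        r2 = ConsensusMapModel(a, b).fit()
        assert r1.map.to_frame().equals(r2.map.to_frame())

    def test_beats_naive_mean_projection(self):
        """LP MAE is no worse than averaging shared positions then projecting
        to a feasible order."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 6
            base = np.sort(rng.uniform(0, 50, n))
            pa = np.maximum.accumulate(base + rng.normal(0, 1.5, n))
            pb = np.maximum.accumulate(base + rng.normal(0, 1.5, n))
            pa -= pa[0]
            pb -= pb[0]
            loci = [f"L{i}" for i in range(n)]
            lg_a = LinkageGroup("LG1", loci, list(pa))
            lg_b = LinkageGroup("LG1", loci, list(pb))
            _, mae = merge_linkage_group(lg_a, lg_b)
            naive = np.sort((pa + pb) / 2)  # feasible projection of the mean
            naive_mae = (np.abs(naive - pa).sum() + np.abs(naive - pb).sum()) / (2 * n)
            assert mae <= naive_mae + 1e-6
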