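import numpy as np
import pytest
from scipy import stats as sstats

import sibmap as sm
from sibmap.linkmap import (
    GeneticMap,
    LinkageGroup,
    LinkageMapModel,
    OrderContext,
    PairStore,
    compute_positions,
    group_loci,
    haldane_cM,
    kosambi_cM,
    order_group,
    order_objective,
)
from sibmap.markerqc import filter_markers
from sibmap.twopoint import TwoPointResult, pairwise_table


def _tp(a, b, rf, lod, n=100):
    return TwoPointResult(a, b, rf, lod, (0, 0), n, 0.0)


class TestMappingFunctions:
    def test_zero_rf_zero_distance(self):
        assert kosambi_cM(0.0) == 0.0
        assert haldane_cM(0.0) == 0.0

    def test_quarter_rf_closed_forms(self):
        assert kosambi_cM(0.25) == pytest.approx(25 * np.log(3))      # ~27.47
        assert haldane_cM(0.25) == pytest.approx(-50 * np.log(0.5))   # ~34.66

    def test_rf_half_raises(self):
        with pytest.raises(ValueError):
            kosambi_cM(0.5)
        with pytest.raises(ValueError):
            haldane_cM(0.5)

    def test_inverse_roundtrip(self):
        from sibmap.linkmap import haldane_rf, kosambi_rf
        for rf in (0.01, 0.1, 0.25, 0.4):
            assert kosambi_rf(kosambi_cM(rf)) == pytest.approx(rf)
            assert haldane_rf(haldane_cM(rf)) == pytest.approx(rf)


class TestGrouping:
    def test_thresholds(self):
        res = {
            ("A", "B"): _tp("A", "B", 0.20, 10.0),   # passes
            ("C", "D"): _tp("C", "D", 0.36, 20.0),   # rf too high
            ("E", "F"): _tp("E", "F", 0.20, 5.0),    # lod too low
        }
        groups = group_loci(res, ["A", "B", "C", "D", "E", "F"])
        assert ["A", "B"] in groups
        assert ["C"] in groups and ["D"] in groups
        assert ["E"] in groups and ["F"] in groups

    def test_transitive_closure(self):
        res = {
            ("A", "B"): _tp("A", "B", 0.1, 10.0),
            ("B", "C"): _tp("B", "C", 0.1, 10.0),
            ("A", "C"): _tp("A", "C", 0.45, 1.0),  # direct link fails
        }
        groups = group_loci(res, ["A", "B", "C"])
        assert groups == [["A", "B", "C"]]

    def test_group_numbering_by_smallest_member(self):
        res = {
            ("Z1", "Z2"): _tp("Z1", "Z2", 0.1, 10.0),
            ("A1", "A2"): _tp("A1", "A2", 0.1, 10.0),
        }
        groups = group_loci(res, ["Z1", "Z2", "A1", "A2"])
        assert groups[0] == ["A1", "A2"]


@pytest.fixture(scope="module")
def three_locus_family():
    tm = sm.simdata.TrueMap([
        ("LG1", 20.0, [("A", 0.0), ("B", 10.0), ("C", 20.0)]),
    ])
    spec = sm.CrossSpec(n_offspring=200, seg_type_mix={sm.SegType.AB_CD: 1.0},
                        error_rate=0.0, missing_rate=0.0, seed=23)
    fam, _ = sm.simulate_family(tm, spec)
    res, _ = pairwise_table(fam)
    return fam, PairStore(res)


class TestOrdering:
    def test_true_order_recovered(self, three_locus_family):
        fam, store = three_locus_family
        order = order_group(["B", "C", "A"], store)
        assert order in (["A", "B", "C"], ["C", "B", "A"])
        # orientation rule: smaller terminal id first
        assert order == ["A", "B", "C"]

    def test_reversal_has_identical_objective(self, three_locus_family):
        fam, store = three_locus_family
        ctx = OrderContext(["A", "B", "C"], store)
        fwd = order_objective(["A", "B", "C"], ctx)
        rev = order_objective(["C", "B", "A"], ctx)
        assert fwd == pytest.approx(rev)

    def test_ripple_keeps_locally_optimal_order(self, three_locus_family):
        from sibmap.linkmap import ripple
        fam, store = three_locus_family
        ctx = OrderContext(["A", "B", "C"], store)
        assert ripple(["A", "B", "C"], ctx, window=3) == ["A", "B", "C"]

    def test_singleton_group_returned_as_is(self, three_locus_family):
        _, store = three_locus_family
        assert order_group(["A"], store) == ["A"]


class TestPositions:
    def test_zero_rf_zero_increment(self):
        store = PairStore({("A", "B"): _tp("A", "B", 0.0, 30.0)})
        lg = compute_positions(["A", "B"], store)
        assert lg.positions == [0.0, 0.0]

    def test_kosambi_increment(self):
        store = PairStore({("A", "B"): _tp("A", "B", 0.25, 10.0)})
        lg = compute_positions(["A", "B"], store, "kosambi")
        assert lg.positions[1] == pytest.approx(27.465, abs=1e-2)

    def test_haldane_increment(self):
        store = PairStore({("A", "B"): _tp("A", "B", 0.25, 10.0)})
        lg = compute_positions(["A", "B"], store, "haldane")
        assert lg.positions[1] == pytest.approx(34.657, abs=1e-2)

    def test_rf_half_signals_ordering_failure(self):
        store = PairStore({("A", "B"): _tp("A", "B", 0.5, 0.0)})
        with pytest.raises(ValueError):
            compute_positions(["A", "B"], store)

    def test_uninformative_adjacency_bridged_by_shortest_path(self):
        # A-B and B-C estimable, A-C not: increment A-C comes through B
        store = PairStore({
            ("A", "B"): _tp("A", "B", 0.1, 20.0),
            ("B", "C"): _tp("B", "C", 0.1, 20.0),
        })
        lg = compute_positions(["A", "C", "B"], store)
        assert np.isfinite(lg.positions).all()


class TestCleanOrder:
    def test_clean_data_nothing_removed(self, clean_family):
        fam, _ = clean_family
        kept, _ = filter_markers(fam)
        res = LinkageMapModel(kept).fit()
        d = res.diagnostics[0]
        assert d.removed_loci == []
        assert d.removed_individuals == []

    def test_double_crossover_call_masked(self):
        # noise-free family, then flip one interior call for one offspring
        tm = sm.simdata.TrueMap([
            ("LG1", 8.0, [("A", 0.0), ("B", 4.0), ("C", 8.0)]),
        ])
        spec = sm.CrossSpec(n_offspring=150, seg_type_mix={sm.SegType.LM_LL: 1.0},
                            error_rate=0.0, missing_rate=0.0, seed=31)
        fam, _ = sm.simulate_family(tm, spec)
        calls = fam["B"].calls
        calls[0] = ("l", "m") if calls[0] == ("l", "l") else ("l", "l")
        res = LinkageMapModel(fam).fit()
        assert sum(d.masked_double_crossovers for d in res.diagnostics) >= 1

    def test_noisy_individual_flagged(self, small_true_map):
        rng = np.random.default_rng(5)
        spec = sm.CrossSpec(n_offspring=100, error_rate=0.0, missing_rate=0.0, seed=33)
        fam, _ = sm.simulate_family(small_true_map, spec)
        # corrupt one individual heavily: random re-draws at 40% of loci
        from sibmap.markers import producible_genotypes
        for m in fam:
            if rng.random() < 0.4:
                poss = producible_genotypes(m.mother, m.father)
                m.calls[7] = poss[int(rng.integers(len(poss)))]
        res = LinkageMapModel(fam).fit()
        flagged = {o for d in res.diagnostics for o in d.removed_individuals}
        assert fam.offspring_ids[7] in flagged


class TestBuildMap:
    def test_groups_recovered(self, small_family):
        fam, _ = small_family
        kept, _ = filter_markers(fam)
        res = LinkageMapModel(kept).fit()
        assert res.map.n_lg == 3
        for g in res.map.linkage_groups:
            true_lgs = {l.split("_")[0] for l in g.locus_ids}
            assert len(true_lgs) == 1  # no group mixes true LGs

    def test_female_scope_uses_maternal_loci_only(self, small_family):
        fam, _ = small_family
        kept, _ = filter_markers(fam)
        res = LinkageMapModel(kept, scope="female").fit()
        for g in res.map.linkage_groups:
            for lid in g.locus_ids:
                assert kept[lid].seg_type.informative_mother

    def test_passenger_reattachment_counts(self, small_true_map):
        # duplicate some loci so co-segregation bins are non-trivial
        fam, _ = sm.simulate_family(
            small_true_map,
            sm.CrossSpec(n_offspring=60, error_rate=0.0, missing_rate=0.0, seed=41),
        )
        from sibmap.markers import FamilyData, MarkerGenotypes
        dup = FamilyData(fam.family_id, fam.offspring_ids)
        for m in fam:
            dup.add(m)
        first = fam[fam.locus_ids[0]]
        dup.add(MarkerGenotypes("zz_twin", "zz", fam.family_id, first.mother,
                                first.father, list(first.calls)))
        res = LinkageMapModel(dup).fit()
        assert res.map.total_loci == len(dup) - len(res.unplaced) - len(res.dropped)
        pax = {p for g in res.map.linkage_groups for p in g.passenger_of}
        assert "zz_twin" in pax
        # passenger sits at its representative's position
        for g in res.map.linkage_groups:
            for p, rep in g.passenger_of.items():
                pi = g.locus_ids.index(p)
                ri = g.locus_ids.index(rep)
                assert g.positions[pi] == g.positions[ri]

    def test_summary_stats_fields(self, small_family):
        fam, _ = small_family
        kept, _ = filter_markers(fam)
        s = LinkageMapModel(kept).fit().summary_stats()
        assert s["total_loci"] > 0
        assert s["mean_loci_per_lg"] == pytest.approx(s["total_loci"] / s["n_lg"], abs=0.1)


class TestGeneticMapRoundtrip:
    def test_frame_roundtrip(self, small_family):
        fam, _ = small_family
        kept, _ = filter_markers(fam)
        gmap = LinkageMapModel(kept).fit().map
        df = gmap.to_frame()
        back = GeneticMap.from_frame(df)
        assert back.total_loci == gmap.total_loci
        assert back.total_length == pytest.approx(gmap.total_length, abs=1e-6)
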