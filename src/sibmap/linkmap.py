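"""Linkage-group construction, marker ordering and genetic maps.

Pipeline per family (and per parental scope for sex-specific maps):
co-segregation binning -> all-pairs two-point estimation -> transitive
grouping at LOD/rf thresholds -> ordering (greedy seeding from loci
informative in both parents, then ripple with a sliding window) -> order
QC (excess crossovers per individual, tight double-crossovers, large
gaps) -> cM positions through a mapping function -> passenger
re-attachment.

The ordering criterion is strictly lexicographic: fewest total crossovers,
then highest likelihood, then shortest map. Total crossovers are the sum
over adjacent pairs of expected recombinant meioses (``n_informative *
rf``); the likelihood term is the sum of adjacent two-point LODs (a
standard two-point surrogate for the multipoint likelihood); length is the
mapping function applied to adjacent rf. All three are invariant under
order reversal, so each group's orientation is fixed by placing the
smaller terminal locus id at 0 cM.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .markerqc import bin_cosegregating
from .markers import FamilyData, SegType
from .twopoint import TwoPointResult, pairwise_table

_BIG_XO = 1e9


# ---------------------------------------------------------------------------
# mapping functions

def kosambi_cM(rf: float) -> float:
    """Kosambi map distance (cM) for a recombination fraction."""
    if rf >= 0.5:
        raise ValueError("rf = 0.5 between adjacent loci: infinite distance (ordering failure)")
    return 25.0 * np.log((1 + 2 * rf) / (1 - 2 * rf))


def haldane_cM(rf: float) -> float:
    """Haldane map distance (cM) for a recombination fraction."""
    if rf >= 0.5:
        raise ValueError("rf = 0.5 between adjacent loci: infinite distance (ordering failure)")
    return -50.0 * np.log(1 - 2 * rf)


def kosambi_rf(d_cM: float) -> float:
    return 0.5 * np.tanh(d_cM / 50.0)


def haldane_rf(d_cM: float) -> float:
    return 0.5 * (1.0 - np.exp(-d_cM / 50.0))


MAPPING_FUNCTIONS = {"kosambi": kosambi_cM, "haldane": haldane_cM}


# ---------------------------------------------------------------------------
# containers

class PairStore:
    """Symmetric access to pairwise two-point results."""

    def __init__(self, results: dict):
        self._r = dict(results)

    def get(self, a: str, b: str) -> Optional[TwoPointResult]:
        r = self._r.get((a, b))
        if r is not None:
            return r
        return self._r.get((b, a))

    def phase_for(self, a: str, b: str) -> tuple:
        """(maternal, paternal) relative phase oriented as a -> b."""
        r = self._r.get((a, b))
        if r is not None:
            return r.phase
        r = self._r.get((b, a))
        return r.phase if r is not None else (None, None)

    def pairs(self):
        return self._r.items()


@dataclass
class LinkageGroup:
    lg_id: str
    locus_ids: list
    positions: list
    passenger_of: dict = field(default_factory=dict)  # passenger -> representative

    def __post_init__(self):
        if len(self.locus_ids) != len(self.positions):
            raise ValueError("loci and positions length mismatch")
        if any(b < a - 1e-9 for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be non-decreasing")

    @property
    def length(self) -> float:
        return float(self.positions[-1]) if self.positions else 0.0

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)


@dataclass
class OrderDiagnostics:
    lg_id: str
    crossovers_per_individual: dict
    masked_double_crossovers: int
    gaps: list  # (left locus, right locus, gap cM) still present after QC
    removed_loci: list
    removed_individuals: list


@dataclass
class GeneticMap:
    """Ordered loci with cM positions on named linkage groups."""

    provenance: str  # e.g. "famA/female", "famA/both", "consensus"
    mapping_function: str
    linkage_groups: list

    @property
    def total_loci(self) -> int:
        return sum(g.n_loci for g in self.linkage_groups)

    @property
    def total_length(self) -> float:
        return float(sum(g.length for g in self.linkage_groups))

    @property
    def n_lg(self) -> int:
        return len(self.linkage_groups)

    def lg(self, lg_id: str) -> LinkageGroup:
        for g in self.linkage_groups:
            if g.lg_id == lg_id:
                return g
        raise KeyError(lg_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.linkage_groups:
            for lid, pos in zip(g.locus_ids, g.positions):
                rows.append((lid, g.lg_id, float(pos), lid in g.passenger_of, self.provenance))
        return pd.DataFrame(
            rows, columns=["locus_id", "lg", "position_cM", "is_passenger", "provenance"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: Optional[str] = None,
                   mapping_function: str = "kosambi") -> "GeneticMap":
        groups = []
        prov = provenance
        for lg_id, sub in df.groupby("lg", sort=True):
            sub = sub.sort_values(["position_cM", "locus_id"], kind="stable")
            if prov is None and "provenance" in sub:
                prov = str(sub["provenance"].iloc[0])
            groups.append(LinkageGroup(str(lg_id), list(sub["locus_id"]),
                                       [float(p) for p in sub["position_cM"]]))
        groups.sort(key=lambda g: g.locus_ids[0])
        return cls(prov or "unknown", mapping_function, groups)

    def summary_stats(self) -> dict:
        """Map summary: totals plus per-LG means/SDs and mean locus interval
        (computed both per mapped interval, length/(loci - LGs), and per
        locus, length/loci)."""
        n_per = np.array([g.n_loci for g in self.linkage_groups], dtype=float)
        sizes = np.array([g.length for g in self.linkage_groups], dtype=float)
        total_loci = int(n_per.sum())
        total_len = float(sizes.sum())
        n_lg = len(self.linkage_groups)
        intervals = total_loci - n_lg
        return {
            "provenance": self.provenance,
            "total_loci": total_loci,
            "n_lg": n_lg,
            "total_length_cM": round(total_len, 2),
            "mean_loci_per_lg": round(float(n_per.mean()), 1) if n_lg else 0.0,
            "sd_loci_per_lg": round(float(n_per.std(ddof=1)), 1) if n_lg > 1 else 0.0,
            "mean_lg_size_cM": round(float(sizes.mean()), 1) if n_lg else 0.0,
            "sd_lg_size_cM": round(float(sizes.std(ddof=1)), 1) if n_lg > 1 else 0.0,
            "mean_interval_cM": round(total_len / intervals, 1) if intervals > 0 else 0.0,
            "mean_interval_per_locus_cM": round(total_len / total_loci, 1) if total_loci else 0.0,
        }


# ---------------------------------------------------------------------------
# grouping

def group_loci(results, loci, min_lod: float = 6.0, max_rf: float = 0.35) -> list:
    """Partition loci into linkage groups by transitive closure of pairs
    passing ``lod >= min_lod`` and ``rf <= max_rf``. Groups are numbered by
    their smallest member locus id."""
    g = nx.Graph()
    g.add_nodes_from(loci)
    items = results.pairs() if isinstance(results, PairStore) else results.items()
    for (a, b), r in items:
        if r is None:
            continue
        if r.lod >= min_lod and r.rf <= max_rf:
            g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return comps


# ---------------------------------------------------------------------------
# ordering

class OrderContext:
    """Adjacency costs for ordering one group.

    Pairs with no shared informative parent (e.g. a maternal-only next to a
    paternal-only locus) carry no direct two-point estimate; their distance
    is completed by the shortest path through estimable pairs, so that such
    adjacencies are priced at the linkage information flowing through
    flanking loci instead of being vetoed outright.
    """

    def __init__(self, loci: list, store: PairStore, mapping: str = "kosambi"):
        from scipy.sparse.csgraph import shortest_path

        self.loci = list(loci)
        self.store = store
        self.mapping = mapping
        fn = MAPPING_FUNCTIONS[mapping]
        self._rf_inv = kosambi_rf if mapping == "kosambi" else haldane_rf
        n = len(self.loci)
        self.idx = {l: i for i, l in enumerate(self.loci)}
        self.xo = np.full((n, n), np.nan)
        self.lod = np.zeros((n, n))
        dist = np.full((n, n), np.inf)
        np.fill_diagonal(dist, 0.0)
        ninfs = []
        for i in range(n):
            for j in range(i + 1, n):
                r = store.get(self.loci[i], self.loci[j])
                if r is None:
                    continue
                d = fn(min(r.rf, 0.4999))
                self.xo[i, j] = self.xo[j, i] = r.n_informative * r.rf
                self.lod[i, j] = self.lod[j, i] = r.lod
                dist[i, j] = dist[j, i] = d
                ninfs.append(r.n_informative)
        self._mean_ninf = float(np.mean(ninfs)) if ninfs else 1.0
        self.dist = shortest_path(dist, method="FW", directed=False) if n > 1 else dist
        big = fn(0.4999)
        self.dist[~np.isfinite(self.dist)] = 2 * big

    def adj_cost(self, a: str, b: str) -> tuple:
        """(expected crossovers, -LOD, length) contribution of adjacency a-b."""
        i, j = self.idx[a], self.idx[b]
        d = self.dist[i, j]
        if not np.isnan(self.xo[i, j]):
            return (self.xo[i, j], -self.lod[i, j], d)
        return (self._mean_ninf * self._rf_inv(min(d, 1e4)), 0.0, d)

    def increment(self, a: str, b: str) -> float:
        """cM increment between adjacent loci (shortest-path completed)."""
        return float(self.dist[self.idx[a], self.idx[b]])


def order_objective(order, ctx: OrderContext) -> tuple:
    """Lexicographic ordering objective (minimized): total expected
    crossovers, negative summed adjacent LOD, map length."""
    xo = lik = length = 0.0
    for a, b in zip(order, order[1:]):
        c = ctx.adj_cost(a, b)
        xo += c[0]
        lik += c[1]
        length += c[2]
    return (xo, lik, length)


def _better(c1: tuple, c2: tuple, eps: float = 1e-9) -> bool:
    """c1 strictly better than c2 lexicographically with tolerance."""
    for x, y in zip(c1, c2):
        if x < y - eps:
            return True
        if x > y + eps:
            return False
    return False


def _greedy_insert(order: list, locus: str, ctx: OrderContext) -> list:
    best_order, best_cost = None, None
    for i in range(len(order) + 1):
        cand = order[:i] + [locus] + order[i:]
        # local delta suffices, but groups are small enough to score fully
        cost = order_objective(cand, ctx)
        if best_cost is None or _better(cost, best_cost):
            best_order, best_cost = cand, cost
    return best_order


def ripple(order: list, ctx: OrderContext, window: int = 4,
           max_passes: int = 20) -> list:
    """Sliding-window local search: permute each window of ``window``
    consecutive loci, accept an alternative only if strictly better on the
    lexicographic criterion; iterate until a full pass accepts nothing."""
    order = list(order)
    n = len(order)
    if n <= 2:
        return order
    w = min(window, n)
    for _ in range(max_passes):
        changed = False
        for start in range(n - w + 1):
            seg = order[start:start + w]
            lo = max(0, start - 1)
            hi = min(n, start + w + 1)
            base = order_objective(order[lo:hi], ctx)
            best_seg, best_cost = None, base
            for perm in itertools.permutations(seg):
                if list(perm) == seg:
                    continue
                cand = order[lo:start] + list(perm) + order[start + w:hi]
                cost = order_objective(cand, ctx)
                if _better(cost, best_cost):
                    best_seg, best_cost = list(perm), cost
            if best_seg is not None:
                order[start:start + w] = best_seg
                changed = True
        if not changed:
            break
    return order


def order_group(group: list, store: PairStore, ripple_window: int = 4,
                mapping: str = "kosambi", seed_loci: Optional[set] = None) -> list:
    """Order one linkage group.

    The seed order is built from the most informative loci (those whose
    segregation is tracked in both parents, phase-confident pairs only) by
    greedy insertion on the lexicographic criterion; remaining loci are then
    inserted one at a time at their best position; finally a ripple with
    the given window size polishes the order. Orientation: the smaller
    terminal locus id comes first.
    """
    group = sorted(group)
    if len(group) <= 1:
        return list(group)
    ctx = OrderContext(group, store, mapping)
    if seed_loci is None:
        seed_loci = set(group)
    seeds = [l for l in group if l in seed_loci]
    if len(seeds) < 2:
        seeds = list(group)
    rest = [l for l in group if l not in seeds]

    # start from the highest-LOD seed pair
    best_pair, best_lod = (seeds[0], seeds[1] if len(seeds) > 1 else seeds[0]), -1.0
    for i, a in enumerate(seeds):
        for b in seeds[i + 1:]:
            r = store.get(a, b)
            if r is not None and r.lod > best_lod:
                best_pair, best_lod = (a, b), r.lod
    order = list(best_pair)
    placed = set(order)

    def insertion_queue(cands):
        # most strongly linked to the growing order first; id tie-break
        out = list(cands)
        while out:
            def link(l):
                lods = [store.get(l, p).lod for p in placed if store.get(l, p) is not None]
                return max(lods) if lods else 0.0
            out.sort(key=lambda l: (-link(l), l))
            yield out.pop(0)

    for locus in insertion_queue([s for s in seeds if s not in placed]):
        order = _greedy_insert(order, locus, ctx)
        placed.add(locus)
    for locus in insertion_queue(rest):
        order = _greedy_insert(order, locus, ctx)
        placed.add(locus)

    order = ripple(order, ctx, ripple_window)
    if order[0] > order[-1]:
        order = order[::-1]
    return order


# ---------------------------------------------------------------------------
# positions

def compute_positions(order: list, store: PairStore, mapping: str = "kosambi",
                      ctx: Optional[OrderContext] = None) -> LinkageGroup:
    """Cumulative cM positions along an ordered group through a mapping
    function: ``cM(i) = cM(i-1) + d(rf_i)``. An adjacent pair with no shared
    informative meioses gets its increment from the shortest path through
    estimable pairs."""
    fn = MAPPING_FUNCTIONS[mapping]
    if len(order) > 1 and any(store.get(a, b) is None for a, b in zip(order, order[1:])):
        if ctx is None:
            ctx = OrderContext(order, store, mapping)
    positions = [0.0]
    for k in range(1, len(order)):
        r = store.get(order[k - 1], order[k])
        if r is not None:
            d = fn(r.rf)  # raises at rf = 0.5 (ordering failure)
        else:
            d = ctx.increment(order[k - 1], order[k])
        positions.append(positions[-1] + d)
    return LinkageGroup("LG?", list(order), positions)


# ---------------------------------------------------------------------------
# order QC

def _chain_phases(order: list, store: PairStore, family: FamilyData) -> tuple:
    """Absolute linkage phase per locus per parent along the order.

    Each parent's chain links that parent's informative loci directly (the
    pairwise table covers all pairs, so one-parent loci of the other sex do
    not break the chain). None marks a genuine break: no phase estimate
    between consecutive informative loci."""
    n = len(order)
    abs_m = [None] * n
    abs_p = [None] * n
    for parent, abs_phase, comp in (
        ("mother", abs_m, 0),
        ("father", abs_p, 1),
    ):
        prev = None
        for k, lid in enumerate(order):
            m = family[lid]
            het = (m.seg_type.informative_mother if parent == "mother"
                   else m.seg_type.informative_father)
            if not het:
                continue
            if prev is None:
                abs_phase[k] = 0
            else:
                rel = store.phase_for(order[prev], lid)[comp]
                if rel is not None and abs_phase[prev] is not None:
                    abs_phase[k] = abs_phase[prev] ^ rel
                else:
                    abs_phase[k] = 0  # chain restart
            prev = k
    return abs_m, abs_p


def _resolved_transmissions(family: FamilyData, order: list, abs_phase, parent: str):
    """Per offspring: list of (order index, grandparental strand) where the
    transmitted allele of ``parent`` is unambiguous."""
    shift = 1 if parent == "mother" else 0
    out = [[] for _ in range(family.n_offspring)]
    for k, lid in enumerate(order):
        if abs_phase[k] is None:
            continue
        m = family[lid]
        het = m.seg_type.informative_mother if parent == "mother" else m.seg_type.informative_father
        if not het:
            continue
        masks = m.masks()
        for o in range(family.n_offspring):
            mk = int(masks[o])
            if mk == 0:
                continue
            idxs = {(b >> shift) & 1 for b in range(4) if (mk >> b) & 1}
            if len(idxs) == 1:
                out[o].append((k, idxs.pop() ^ abs_phase[k]))
    return out


def clean_order(
    order: list,
    family: FamilyData,
    store: PairStore,
    mapping: str = "kosambi",
    gap_cM: float = 20.0,
    xo_z: float = 3.0,
    tight_cM: float = 10.0,
    lg_id: str = "LG?",
    mask_calls: bool = True,
) -> tuple:
    """Order QC: mask calls forming tight double-crossovers, flag/remove
    individuals with excess crossovers (> mean + ``xo_z`` SD), and remove
    loci whose removal closes a > ``gap_cM`` gap.

    Mutates ``family`` (masked calls). Returns
    ``(order, OrderDiagnostics)``; the caller re-estimates and re-orders
    if anything was masked or removed.
    """
    fn = MAPPING_FUNCTIONS[mapping]
    lgp = compute_positions(order, store, mapping)
    pos = lgp.positions
    abs_m, abs_p = _chain_phases(order, store, family)

    masked = 0
    xo_counts = {}
    for parent, abs_phase in (("mother", abs_m), ("father", abs_p)):
        trans = _resolved_transmissions(family, order, abs_phase, parent)
        for o, seq in enumerate(trans):
            oid = family.offspring_ids[o]
            xo = 0
            for (k0, v0), (k1, v1) in zip(seq, seq[1:]):
                if v0 != v1:
                    xo += 1
            xo_counts[oid] = xo_counts.get(oid, 0) + xo
            # tight double-crossovers: single resolved locus disagreeing with
            # agreeing close neighbors
            if mask_calls:
                for (kp, vp), (k, v), (kn, vn) in zip(seq, seq[1:], seq[2:]):
                    if vp == vn != v and (pos[kn] - pos[kp]) <= tight_cM:
                        family.mask_call(order[k], o)
                        masked += 1

    counts = np.array(list(xo_counts.values()), dtype=float)
    removed_individuals = []
    if len(counts) > 1 and counts.std(ddof=1) > 0:
        from scipy import stats as _st

        # z-rule guarded by a Bonferroni Poisson tail so the natural
        # right tail of clean crossover counts is not culled
        thresh = counts.mean() + xo_z * counts.std(ddof=1)
        lam = max(counts.mean(), 1e-9)
        removed_individuals = sorted(
            o for o, c in xo_counts.items()
            if c > thresh and _st.poisson.sf(c - 1, lam) < 0.05 / len(counts)
        )
    for oid in removed_individuals:
        o = family.offspring_ids.index(oid)
        for lid in order:
            family.mask_call(lid, o)

    # large gaps
    order = list(order)
    removed_loci = []
    gaps_left = []
    changed = True
    while changed:
        changed = False
        lgp = compute_positions(order, store, mapping)
        pos = lgp.positions
        for i in range(len(order) - 1):
            gap = pos[i + 1] - pos[i]
            if gap <= gap_cM:
                continue
            drop = _gap_closer(order, i, store, fn, gap_cM)
            if drop is not None:
                removed_loci.append(drop)
                order.remove(drop)
                changed = True
                break
        if not changed:
            lgp = compute_positions(order, store, mapping)
            pos = lgp.positions
            gaps_left = [
                (order[i], order[i + 1], round(pos[i + 1] - pos[i], 3))
                for i in range(len(order) - 1)
                if pos[i + 1] - pos[i] > gap_cM
            ]
    diag = OrderDiagnostics(lg_id, xo_counts, masked, gaps_left, removed_loci, removed_individuals)
    return order, diag


def _merge_diag(a: OrderDiagnostics, b: OrderDiagnostics) -> OrderDiagnostics:
    return OrderDiagnostics(
        b.lg_id,
        b.crossovers_per_individual or a.crossovers_per_individual,
        a.masked_double_crossovers + b.masked_double_crossovers,
        b.gaps,
        a.removed_loci + b.removed_loci,
        sorted(set(a.removed_individuals) | set(b.removed_individuals)),
    )


def _gap_closer(order, i, store, fn, gap_cM):
    """Which flank of the gap between order[i] and order[i+1], if removed,
    closes it? Terminal flanks close trivially."""
    if i == 0:
        return order[0]
    if i + 1 == len(order) - 1:
        return order[-1]

    def dist(a, b):
        r = store.get(a, b)
        return fn(min(r.rf, 0.4999)) if r is not None else np.inf

    close_left = dist(order[i - 1], order[i + 1])  # if order[i] removed
    close_right = dist(order[i], order[i + 2])  # if order[i+1] removed
    best = min(close_left, close_right)
    if best > gap_cM:
        return None
    return order[i] if close_left <= close_right else order[i + 1]


# ---------------------------------------------------------------------------
# map building: model / results

class LinkageMapModel:
    """Builds a genetic map for one full-sib family.

    Parameters
    ----------
    family:
        QC-filtered genotypes (see :func:`sibmap.markerqc.filter_markers`).
    scope:
        ``"both"`` for the family map, ``"female"``/``"male"`` for
        sex-specific maps (only that parent's meioses carry linkage
        information).
    min_lod, max_rf:
        Grouping thresholds (defaults LOD 6, rf 0.35).
    mapping_function:
        ``"kosambi"`` (default) or ``"haldane"``.
    """

    def __init__(
        self,
        family: FamilyData,
        scope: str = "both",
        min_lod: float = 6.0,
        max_rf: float = 0.35,
        ripple_window: int = 4,
        mapping_function: str = "kosambi",
        gap_cM: float = 20.0,
        xo_z: float = 3.0,
        run_clean: bool = True,
    ):
        if scope not in ("both", "female", "male"):
            raise ValueError(f"unknown scope {scope!r}")
        if mapping_function not in MAPPING_FUNCTIONS:
            raise ValueError(f"unknown mapping function {mapping_function!r}")
        self.family = family
        self.scope = scope
        self.min_lod = min_lod
        self.max_rf = max_rf
        self.ripple_window = ripple_window
        self.mapping_function = mapping_function
        self.gap_cM = gap_cM
        self.xo_z = xo_z
        self.run_clean = run_clean

    def _scope_loci(self) -> list:
        keep = []
        for m in self.family:
            if self.scope == "female" and not m.seg_type.informative_mother:
                continue
            if self.scope == "male" and not m.seg_type.informative_father:
                continue
            if m.seg_type is SegType.UNINFORMATIVE:
                continue
            keep.append(m.locus_id)
        return keep

    def fit(self) -> "LinkageMapResults":
        fam = self.family.subset_loci(self._scope_loci())
        bins = bin_cosegregating(fam)
        passenger_of = {
            member: b.representative
            for b in bins
            for member in b.members
            if member != b.representative
        }
        reps = [b.representative for b in bins]
        rep_fam = fam.subset_loci(reps)

        results, _ = pairwise_table(rep_fam, scope=self.scope)
        store = PairStore(results)
        groups = group_loci(store, reps, self.min_lod, self.max_rf)

                # most informative loci seed the order: segregation tracked in both parents
        seed_loci = {lid for lid in reps if rep_fam[lid].seg_type.fully_informative}
        lgs, diags, dropped = [], [], []
        mapped_groups = [g for g in groups if len(g) >= 2]
        for group in mapped_groups:
            order = order_group(group, store, self.ripple_window, self.mapping_function, seed_loci)
            store_for_pos = store
            diag = OrderDiagnostics("pending", {}, 0, [], [], [])
            if self.run_clean and len(order) > 2:
                # QC / re-estimate / re-order, then reassess once more
                for qc_pass in range(2):
                    order, d = clean_order(
                        order, rep_fam, store_for_pos, self.mapping_function,
                        self.gap_cM, self.xo_z, lg_id="pending",
                        mask_calls=(qc_pass == 0),
                    )
                    diag = _merge_diag(diag, d)
                    if not (d.masked_double_crossovers or d.removed_individuals
                            or d.removed_loci):
                        break
                    sub_res, _ = pairwise_table(rep_fam, order, scope=self.scope)
                    store_for_pos = PairStore(sub_res)
                    order = order_group(order, store_for_pos, self.ripple_window,
                                        self.mapping_function, seed_loci)
                diag.gaps = d.gaps
            lg = compute_positions(order, store_for_pos, self.mapping_function)
            lgs.append((lg, diag))
            dropped.extend(diag.removed_loci)

        # number groups by smallest member id, attach passengers
        lgs.sort(key=lambda t: min(t[0].locus_ids))
        final_groups = []
        for i, (lg, diag) in enumerate(lgs, start=1):
            lg_id = f"LG{i}"
            diag.lg_id = lg_id
            pos_of = dict(zip(lg.locus_ids, lg.positions))
            loci, positions, pax = [], [], {}
            for lid, p in zip(lg.locus_ids, lg.positions):
                loci.append(lid)
                positions.append(p)
                for member, rep in passenger_of.items():
                    if rep == lid:
                        loci.append(member)
                        positions.append(p)
                        pax[member] = rep
            final_groups.append(LinkageGroup(lg_id, loci, positions, pax))
        prov = f"{self.family.family_id}/{self.scope}"
        gmap = GeneticMap(prov, self.mapping_function, final_groups)
        unplaced = [g[0] for g in groups if len(g) < 2]
        return LinkageMapResults(
            self, gmap, [d for _, d in lgs], store, bins, unplaced, dropped
        )


class LinkageMapResults:
    """Fitted genetic map with diagnostics.

    Attributes
    ----------
    map : GeneticMap
    diagnostics : list of OrderDiagnostics (one per LG)
    pair_store : PairStore of the representative-locus two-point results
    bins : co-segregation bins used
    unplaced : singleton loci not linked to any group
    dropped : loci removed during order QC
    """

    def __init__(self, model, gmap, diagnostics, pair_store, bins, unplaced, dropped):
        self.model = model
        self.map = gmap
        self.diagnostics = diagnostics
        self.pair_store = pair_store
        self.bins = bins
        self.unplaced = unplaced
        self.dropped = dropped

    def summary_stats(self) -> dict:
        return self.map.summary_stats()

    def summary(self) -> str:
        s = self.map.summary_stats()
        lines = [
            f"Genetic map [{s['provenance']}] ({self.model.mapping_function} mapping function)",
            "=" * 64,
            f"Linkage groups:        {s['n_lg']}",
            f"Total loci:            {s['total_loci']}",
            f"Total length (cM):     {s['total_length_cM']}",
            f"Loci per LG:           {s['mean_loci_per_lg']} +/- {s['sd_loci_per_lg']}",
            f"LG size (cM):          {s['mean_lg_size_cM']} +/- {s['sd_lg_size_cM']}",
            f"Mean locus interval:   {s['mean_interval_cM']} cM "
            f"({s['mean_interval_per_locus_cM']} per locus)",
            f"Unlinked loci:         {len(self.unplaced)}",
            f"Loci dropped in QC:    {len(self.dropped)}",
            "-" * 64,
        ]
        for g in self.map.linkage_groups:
            lines.append(f"{g.lg_id:>6}: {g.n_loci:4d} loci, {g.length:7.2f} cM")
        return "\n".join(lines)
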