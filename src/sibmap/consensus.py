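"""Consensus map: conflict resolution between family maps and LP merging.

Two family maps of the same cross design rarely agree perfectly; loci
whose relative order is inverted between the maps virtually always sit in
a cluster of loci with zero observed recombination (identical cM position)
in at least one map. Conflict resolution iteratively removes each such
locus from the map with the larger zero-recombination cluster (a locus not
in any cluster counts as cluster size 1; ties are removed from map B,
logged), re-deriving conflicts each round, for at most ``max_rounds``
rounds. Because removed loci are co-positioned with their cluster mates,
removal leaves the order and adjacent recombination fractions of the
remaining loci unchanged, so maps are re-anchored (first position 0) and
carried forward directly.

Merging then solves, per linkage group, a linear program over consensus
positions for the union of loci: order constraints from each component map
(strict order separated by ``epsilon`` cM; co-positioned loci equal unless
the other map strictly orders them, in which case the tie is relaxed to a
non-strict constraint in that map's direction), minimizing the mean
absolute error between consensus and component positions. Loci that lost
both family-map positions during resolution are restored into the
consensus at their zero-recombination cluster representative's position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .linkmap import GeneticMap, LinkageGroup

_TIE_TOL = 1e-9


class ConsensusError(ValueError):
    pass


@dataclass
class Conflict:
    locus_id: str
    lg_a: str
    lg_b: str
    cluster_size_a: int
    cluster_size_b: int
    n_opposite_pairs: int


# ---------------------------------------------------------------------------
# helpers

def _positions(gmap: GeneticMap) -> dict:
    return {
        lid: (g.lg_id, p)
        for g in gmap.linkage_groups
        for lid, p in zip(g.locus_ids, g.positions)
    }


def match_linkage_groups(map_a: GeneticMap, map_b: GeneticMap) -> dict:
    """Correspond LGs across maps by maximal shared-locus overlap.

    Returns {lg_a: lg_b}. A tie in the maximal overlap is an error naming
    the LGs involved rather than a guess.
    """
    pos_b = _positions(map_b)
    out = {}
    for ga in map_a.linkage_groups:
        counts: dict = {}
        for lid in ga.locus_ids:
            if lid in pos_b:
                lgb = pos_b[lid][0]
                counts[lgb] = counts.get(lgb, 0) + 1
        if not counts:
            continue
        best = max(counts.values())
        winners = sorted(k for k, v in counts.items() if v == best)
        if len(winners) > 1:
            raise ConsensusError(
                f"ambiguous LG correspondence for {ga.lg_id}: "
                f"{winners} each share {best} loci"
            )
        out[ga.lg_id] = winners[0]
    return out


def zero_recombination_clusters(lg: LinkageGroup) -> dict:
    """locus -> sorted list of co-positioned loci (its cluster, incl. itself)."""
    by_pos: dict = {}
    for lid, p in zip(lg.locus_ids, lg.positions):
        by_pos.setdefault(round(p, 6), []).append(lid)
    return {lid: sorted(v) for v in by_pos.values() for lid in v}


# ---------------------------------------------------------------------------
# conflict detection / resolution

def detect_conflicts(map_a: GeneticMap, map_b: GeneticMap) -> list[Conflict]:
    """Shared loci whose relative order against at least one other shared
    locus is opposite between the two maps, annotated with their
    zero-recombination cluster sizes in each map."""
    conflicts, _ = _detect_with_pairs(map_a, map_b)
    return conflicts


def _detect_with_pairs(map_a: GeneticMap, map_b: GeneticMap):
    lg_match = match_linkage_groups(map_a, map_b)
    pos_a = _positions(map_a)
    pos_b = _positions(map_b)
    conflicts = []
    pairs = []
    for lg_a_id, lg_b_id in lg_match.items():
        ga = map_a.lg(lg_a_id)
        gb = map_b.lg(lg_b_id)
        shared = [l for l in ga.locus_ids if l in pos_b and pos_b[l][0] == lg_b_id]
        if len(shared) < 2:
            continue
        pa = np.array([pos_a[l][1] for l in shared])
        pb = np.array([pos_b[l][1] for l in shared])
        da = pa[:, None] - pa[None, :]
        db = pb[:, None] - pb[None, :]
        opp = (da * db) < -_TIE_TOL
        n_opp = opp.sum(axis=1)
        if not n_opp.any():
            continue
        clus_a = zero_recombination_clusters(ga)
        clus_b = zero_recombination_clusters(gb)
        for i, lid in enumerate(shared):
            if n_opp[i]:
                conflicts.append(Conflict(
                    lid, lg_a_id, lg_b_id,
                    len(clus_a.get(lid, [lid])), len(clus_b.get(lid, [lid])),
                    int(n_opp[i]),
                ))
        ii, jj = np.nonzero(np.triu(opp))
        pairs.extend((shared[i], shared[j]) for i, j in zip(ii, jj))
    conflicts.sort(key=lambda c: c.locus_id)
    return conflicts, pairs


def _map_without(gmap: GeneticMap, drop: set) -> GeneticMap:
    groups = []
    for g in gmap.linkage_groups:
        loci, pos = [], []
        for lid, p in zip(g.locus_ids, g.positions):
            if lid not in drop:
                loci.append(lid)
                pos.append(p)
        if not loci:
            continue
        base = pos[0]
        pax = {k: v for k, v in g.passenger_of.items() if k in loci and v in loci}
        groups.append(LinkageGroup(g.lg_id, loci, [p - base for p in pos], pax))
    return GeneticMap(gmap.provenance, gmap.mapping_function, groups)


def resolve_conflicts(
    map_a: GeneticMap,
    map_b: GeneticMap,
    max_rounds: int = 3,
) -> tuple[GeneticMap, GeneticMap, pd.DataFrame, list]:
    """Iteratively remove conflicting loci from the map with the larger
    zero-recombination cluster (tie: map B). Returns the two pruned maps,
    a removal log (locus, round, cluster sizes, action) and any conflicts
    still present after ``max_rounds`` rounds (reported, never silently
    dropped)."""
    log = []
    a, b = map_a, map_b
    remaining: list = []
    for rnd in range(1, max_rounds + 1):
        conflicts, pairs = _detect_with_pairs(a, b)
        if not conflicts:
            remaining = []
            break
        # greedy cover: remove the most-conflicted loci first, only until
        # every opposite-ordered pair involves a removed locus
        uncovered = set(pairs)
        drop_a, drop_b = set(), set()
        for c in sorted(conflicts, key=lambda c: (-c.n_opposite_pairs, c.locus_id)):
            if not any(c.locus_id in p for p in uncovered):
                continue
            if c.cluster_size_a > c.cluster_size_b:
                drop_a.add(c.locus_id)
                action = "removed_from_A"
            elif c.cluster_size_b > c.cluster_size_a:
                drop_b.add(c.locus_id)
                action = "removed_from_B"
            else:
                drop_b.add(c.locus_id)
                action = "removed_from_B_tie"
            log.append((c.locus_id, rnd, c.cluster_size_a, c.cluster_size_b, action))
            uncovered = {p for p in uncovered if c.locus_id not in p}
        a = _map_without(a, drop_a)
        b = _map_without(b, drop_b)
        remaining = detect_conflicts(a, b)
        if not remaining:
            break
    log_df = pd.DataFrame(
        log, columns=["locus_id", "round", "cluster_size_a", "cluster_size_b", "action"]
    )
    return a, b, log_df, remaining


# ---------------------------------------------------------------------------
# LP merge

def _order_constraints(lg: LinkageGroup, other_pos: dict, epsilon: float):
    """Yield (i_locus, j_locus, kind) with kind in {'strict', 'weak', 'equal'}
    meaning x_j - x_i >= epsilon / >= 0 / == 0, for one component map's LG.
    Ties are chained in the other map's order so the two maps' constraint
    systems cannot contradict each other."""
    items = list(zip(lg.locus_ids, lg.positions))

    def key(t):
        lid, p = t
        op = other_pos.get(lid, (None, np.inf))[1]
        return (p, op, lid)

    items.sort(key=key)
    for (li, pi), (lj, pj) in zip(items, items[1:]):
        if pj - pi > _TIE_TOL:
            yield li, lj, "strict"
        else:
            oi = other_pos.get(li)
            oj = other_pos.get(lj)
            if oi is not None and oj is not None and oi[0] == oj[0] and abs(oi[1] - oj[1]) > _TIE_TOL:
                yield li, lj, "weak"  # other map strictly orders the tie
            else:
                yield li, lj, "equal"


def merge_linkage_group(
    lg_a: Optional[LinkageGroup],
    lg_b: Optional[LinkageGroup],
    epsilon: float = 0.01,
    lg_id: Optional[str] = None,
) -> tuple[LinkageGroup, float]:
    """LP merge of one pair of corresponding LGs.

    Decision variables are consensus positions for the union of loci plus
    one absolute-deviation variable per (locus, map) incidence; the
    objective is the mean absolute error between consensus and component
    positions, subject to each component map's order constraints.
    Returns (consensus LG, achieved MAE).
    """
    comps = [g for g in (lg_a, lg_b) if g is not None]
    if not comps:
        raise ValueError("need at least one LG")
    union = sorted({l for g in comps for l in g.locus_ids})
    n = len(union)
    idx = {l: i for i, l in enumerate(union)}
    incidences = [
        (idx[l], p) for g in comps for l, p in zip(g.locus_ids, g.positions)
    ]
    m = len(incidences)

    n_var = n + m
    c = np.zeros(n_var)
    c[n:] = 1.0 / m
    rows_ub, rhs_ub = [], []
    rows_eq, rhs_eq = [], []

    for k, (i, p) in enumerate(incidences):
        row = np.zeros(n_var)
        row[i] = 1.0
        row[n + k] = -1.0
        rows_ub.append(row)  # x_i - e_k <= p
        rhs_ub.append(p)
        row = np.zeros(n_var)
        row[i] = -1.0
        row[n + k] = -1.0
        rows_ub.append(row)  # -x_i - e_k <= -p
        rhs_ub.append(-p)

    pos_maps = [_single_map_positions(g) for g in comps]
    for gi, g in enumerate(comps):
        other = pos_maps[1 - gi] if len(comps) == 2 else {}
        for li, lj, kind in _order_constraints(g, other, epsilon):
            row = np.zeros(n_var)
            row[idx[li]] = 1.0
            row[idx[lj]] = -1.0
            if kind == "equal":
                rows_eq.append(row)
                rhs_eq.append(0.0)
            else:
                rows_ub.append(row)  # x_i - x_j <= -eps (or 0)
                rhs_ub.append(-epsilon if kind == "strict" else 0.0)

    res = linprog(
        c,
        A_ub=np.array(rows_ub) if rows_ub else None,
        b_ub=np.array(rhs_ub) if rhs_ub else None,
        A_eq=np.array(rows_eq) if rows_eq else None,
        b_eq=np.array(rhs_eq) if rhs_eq else None,
        bounds=[(0, None)] * n + [(0, None)] * m,
        method="highs",
    )
    if not res.success:
        raise ConsensusError(
            f"infeasible consensus LP for {lg_id or (comps[0].lg_id)}: {res.message}"
        )
    x = res.x[:n]
    order = sorted(union, key=lambda l: (x[idx[l]], l))
    base = x[idx[order[0]]]
    positions = [float(x[idx[l]] - base) for l in order]
    positions = np.maximum.accumulate(np.round(positions, 6)).tolist()
    return LinkageGroup(lg_id or comps[0].lg_id, order, positions), float(res.fun)


def _single_map_positions(g: LinkageGroup) -> dict:
    return {l: (g.lg_id, p) for l, p in zip(g.locus_ids, g.positions)}


# ---------------------------------------------------------------------------
# model / results

class ConsensusMapModel:
    """Merges two family maps into a consensus map.

    ``fit()`` runs conflict resolution (``max_rounds`` rounds, default 3)
    followed by the per-LG LP merge, and restores loci that lost both
    family-map positions at their cluster representative's consensus
    position.
    """

    def __init__(self, map_a: GeneticMap, map_b: GeneticMap,
                 max_rounds: int = 3, epsilon: float = 0.01):
        self.map_a = map_a
        self.map_b = map_b
        self.max_rounds = max_rounds
        self.epsilon = epsilon

    def fit(self) -> "ConsensusMapResults":
        a0, b0 = self.map_a, self.map_b
        a, b, log, remaining = resolve_conflicts(a0, b0, self.max_rounds)

        lg_match = match_linkage_groups(a, b)
        matched_b = set(lg_match.values())
        groups, maes = [], {}
        for ga in a.linkage_groups:
            gb = b.lg(lg_match[ga.lg_id]) if ga.lg_id in lg_match else None
            lg, mae = merge_linkage_group(ga, gb, self.epsilon, lg_id=ga.lg_id)
            groups.append(lg)
            maes[ga.lg_id] = mae
        for gb in b.linkage_groups:
            if gb.lg_id not in matched_b:
                lg, mae = merge_linkage_group(gb, None, self.epsilon,
                                              lg_id=f"B:{gb.lg_id}")
                groups.append(lg)
                maes[lg.lg_id] = mae

        restored = self._restore_dropped(groups, log)
        groups.sort(key=lambda g: g.locus_ids[0])
        cmap = GeneticMap("consensus", self.map_a.mapping_function, groups)
        return ConsensusMapResults(self, cmap, maes, log, remaining, restored)

    def _restore_dropped(self, groups: list, log: pd.DataFrame) -> list:
        """Loci removed from *both* family maps during resolution are
        restored at a surviving zero-recombination cluster mate's consensus
        position (they are never removed from the final consensus)."""
        placed = {l for g in groups for l in g.locus_ids}
        removed = set(log["locus_id"]) - placed if len(log) else set()
        restored = []
        if not removed:
            return restored
        clusters: dict = {}
        for gmap in (self.map_a, self.map_b):
            for g in gmap.linkage_groups:
                cl = zero_recombination_clusters(g)
                for lid in removed:
                    if lid in cl:
                        clusters.setdefault(lid, []).extend(cl[lid])
        for lid in sorted(removed):
            mates = [m for m in clusters.get(lid, []) if m in placed]
            if not mates:
                continue
            rep = sorted(mates)[0]
            for g in groups:
                if rep in g.locus_ids:
                    k = g.locus_ids.index(rep)
                    g.locus_ids.insert(k + 1, lid)
                    g.positions.insert(k + 1, g.positions[k])
                    g.passenger_of[lid] = rep
                    restored.append((lid, rep, g.lg_id))
                    break
        return restored


class ConsensusMapResults:
    """Consensus map with achieved MAE and the conflict-resolution log."""

    def __init__(self, model, cmap, mae_per_lg, resolution_log, remaining_conflicts, restored):
        self.model = model
        self.map = cmap
        self.mae_per_lg = mae_per_lg
        self.resolution_log = resolution_log
        self.remaining_conflicts = remaining_conflicts
        self.restored = restored

    @property
    def mae(self) -> float:
        vals = list(self.mae_per_lg.values())
        return float(np.mean(vals)) if vals else 0.0

    def summary_stats(self) -> dict:
        s = self.map.summary_stats()
        s["mean_absolute_error_cM"] = round(self.mae, 4)
        s["loci_removed_in_resolution"] = int(len(self.resolution_log))
        s["conflicts_remaining"] = len(self.remaining_conflicts)
        return s

    def summary(self) -> str:
        s = self.summary_stats()
        lines = [
            "Consensus map",
            "=" * 64,
            f"Linkage groups:         {s['n_lg']}",
            f"Total loci:             {s['total_loci']}",
            f"Total length (cM):      {s['total_length_cM']}",
            f"Loci per LG:            {s['mean_loci_per_lg']} +/- {s['sd_loci_per_lg']}",
            f"LG size (cM):           {s['mean_lg_size_cM']} +/- {s['sd_lg_size_cM']}",
            f"Mean locus interval:    {s['mean_interval_cM']} cM",
            f"Achieved MAE (cM):      {s['mean_absolute_error_cM']}",
            f"Removed in resolution:  {s['loci_removed_in_resolution']} "
            f"(restored into consensus: {len(self.restored)})",
            f"Conflicts remaining:    {s['conflicts_remaining']}",
        ]
        return "\n".join(lines)
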