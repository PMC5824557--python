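"""Synteny blocks between a genetic map and comparison genome assemblies,
and placement of external sequences onto the map via flanking loci.

Mapped-locus sequences (and external feature sequences) arrive as tabular
similarity hits (the standard 12-column dialect). Each locus gets at most
one anchor per genome: the best hit by bitscore, provided its e-value
passes and the best bitscore exceeds the best hit on any *other*
chromosome by a margin fraction (ambiguous loci stay unanchored).

A syntenic block is a maximal run of anchored loci, in map order, on a
single chromosome with monotone bp positions (either direction),
uninterrupted by any other locus anchored to that genome. An
order-breaking locus closer than ``tolerance_frac`` of the LG length to
the neighbor it conflicts with is treated as a local rearrangement or
ordering error: it is skipped (and logged) rather than splitting the run.

External features falling strictly inside a block's bp span are placed at
the bp-fraction linear interpolation between the two flanking mapped loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .linkmap import GeneticMap

ANCHOR_COLUMNS = [
    "locus_id", "genome_id", "chromosome", "bp_start", "bp_end", "bp_mid",
    "strand", "evalue", "bitscore",
]


@dataclass
class SyntenyBlock:
    block_id: str
    lg: str
    genome_id: str
    chromosome: str
    locus_ids: list  # map order
    member_bps: list  # anchor bp (midpoint), parallel to locus_ids
    cm_start: float
    cm_end: float
    bp_min: int
    bp_max: int
    orientation: str  # "+" | "-"

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def cm_span(self) -> float:
        return self.cm_end - self.cm_start

    @property
    def bp_span(self) -> int:
        return self.bp_max - self.bp_min + 1


@dataclass
class BlockStats:
    """Per-genome block summary (the per-genome row of a block table)."""

    genome_id: str
    n_blocks: int
    n_loci: int
    avg_loci_per_block: float
    total_mb: float
    avg_mb: float
    total_cM: float
    avg_cM: float
    coverage_pct: float

    @classmethod
    def from_totals(cls, genome_id: str, n_blocks: int, n_loci: int,
                    total_mb: float, total_cM: float, map_length_cM: float) -> "BlockStats":
        """Recompute the derived columns (averages, proportion of map
        covered) from a table's printed totals."""
        return cls(
            genome_id, n_blocks, n_loci,
            avg_loci_per_block=round(n_loci / n_blocks, 1) if n_blocks else 0.0,
            total_mb=total_mb,
            avg_mb=round(total_mb / n_blocks, 2) if n_blocks else 0.0,
            total_cM=total_cM,
            avg_cM=round(total_cM / n_blocks, 1) if n_blocks else 0.0,
            coverage_pct=round(100.0 * total_cM / map_length_cM, 1) if map_length_cM else 0.0,
        )


# ---------------------------------------------------------------------------
# anchor assignment

def _normalize_hits(hits: pd.DataFrame) -> pd.DataFrame:
    h = hits.copy()
    s, e = h["sstart"].to_numpy(), h["send"].to_numpy()
    h["strand"] = np.where(s <= e, "+", "-")
    h["bp_start"] = np.minimum(s, e)
    h["bp_end"] = np.maximum(s, e)
    h["bp_mid"] = (h["bp_start"] + h["bp_end"]) // 2
    return h


def best_unique_hits(
    hits: pd.DataFrame,
    genome_id: str = "genome",
    min_evalue: float = 1e-10,
    min_bitscore_margin: float = 0.1,
) -> pd.DataFrame:
    """Best-hit filter: per query keep the top-bitscore hit when its e-value
    passes and it beats the best hit on any other chromosome by more than
    the margin fraction of its own bitscore."""
    if hits.empty:
        return pd.DataFrame(columns=ANCHOR_COLUMNS)
    h = _normalize_hits(hits)
    out = []
    for qid, sub in h.groupby("qseqid", sort=True):
        sub = sub.sort_values(["bitscore", "evalue", "sseqid", "sstart"],
                              ascending=[False, True, True, True], kind="stable")
        best = sub.iloc[0]
        if best["evalue"] > min_evalue:
            continue
        others = sub[sub["sseqid"] != best["sseqid"]]
        if len(others):
            margin = (best["bitscore"] - others["bitscore"].max()) / best["bitscore"]
            if not margin > min_bitscore_margin:
                continue  # ambiguous across chromosomes
        out.append((
            qid, genome_id, best["sseqid"], int(best["bp_start"]), int(best["bp_end"]),
            int(best["bp_mid"]), best["strand"], float(best["evalue"]), float(best["bitscore"]),
        ))
    return pd.DataFrame(out, columns=ANCHOR_COLUMNS)


def assign_anchors(
    hits: pd.DataFrame,
    gmap: GeneticMap,
    genome_id: str = "genome",
    min_evalue: float = 1e-10,
    min_bitscore_margin: float = 0.1,
) -> pd.DataFrame:
    """Anchor mapped loci on one comparison genome (hits of loci not on the
    map are ignored)."""
    mapped = {l for g in gmap.linkage_groups for l in g.locus_ids}
    anchors = best_unique_hits(hits, genome_id, min_evalue, min_bitscore_margin)
    return anchors[anchors["locus_id"].isin(mapped)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# block detection

def find_blocks(
    gmap: GeneticMap,
    anchors: pd.DataFrame,
    tolerance_frac: float = 0.05,
    min_block: int = 2,
) -> tuple[list, pd.DataFrame]:
    """Detect syntenic blocks per (LG, genome).

    Returns ``(blocks, exclusion_log)`` where the log records loci skipped
    under the order-mismatch tolerance (columns: locus_id, lg, genome_id,
    neighbor, cM_separation, lg_length).
    """
    blocks: list[SyntenyBlock] = []
    exclusions = []
    if anchors.empty:
        return blocks, pd.DataFrame(
            columns=["locus_id", "lg", "genome_id", "neighbor", "cM_separation", "lg_length"]
        )
    for genome_id in sorted(anchors["genome_id"].unique()):
        ga = anchors[anchors["genome_id"] == genome_id].set_index("locus_id")
        for g in gmap.linkage_groups:
            seq = [
                (lid, pos, ga.loc[lid, "chromosome"], int(ga.loc[lid, "bp_mid"]))
                for lid, pos in zip(g.locus_ids, g.positions)
                if lid in ga.index
            ]
            if len(seq) < min_block:
                continue
            tol_cM = tolerance_frac * g.length
            runs = _scan_runs(seq, tol_cM, exclusions, g.lg_id, genome_id, g.length)
            for run in runs:
                if len(run) < min_block:
                    continue
                bps = [bp for _, _, _, bp in run]
                orient = "-" if bps[-1] < bps[0] else "+"
                k = len(blocks)
                blocks.append(SyntenyBlock(
                    block_id=f"{genome_id}:{g.lg_id}:{k}",
                    lg=g.lg_id,
                    genome_id=genome_id,
                    chromosome=run[0][2],
                    locus_ids=[l for l, _, _, _ in run],
                    member_bps=list(bps),
                    cm_start=float(run[0][1]),
                    cm_end=float(run[-1][1]),
                    bp_min=int(min(bps)),
                    bp_max=int(max(bps)),
                    orientation=orient,
                ))
    log = pd.DataFrame(
        exclusions,
        columns=["locus_id", "lg", "genome_id", "neighbor", "cM_separation", "lg_length"],
    )
    return blocks, log


def _scan_runs(seq, tol_cM, exclusions, lg_id, genome_id, lg_length):
    runs = []
    cur = [seq[0]]
    direction = 0
    for x in seq[1:]:
        lid, cm, chrom, bp = x
        last = cur[-1]
        if chrom != last[2]:
            runs.append(cur)
            cur, direction = [x], 0
            continue
        step = np.sign(bp - last[3])
        if direction == 0 or step == 0 or step == direction:
            cur.append(x)
            if direction == 0 and step != 0:
                direction = int(step)
        else:
            sep = cm - last[1]
            if sep < tol_cM:
                exclusions.append((lid, lg_id, genome_id, last[0], round(sep, 4), lg_length))
            else:
                runs.append(cur)
                # boundary attribution: the last member of the closing run
                # joins the new run when it sits nearer (in bp) to the
                # incoming locus than to its own predecessor — e.g. the
                # first locus of an inverted segment, which still extends
                # the preceding run's direction
                if len(cur) >= 2 and abs(bp - last[3]) < abs(cur[-2][3] - last[3]):
                    runs[-1] = cur[:-1]
                    cur, direction = [last, x], int(np.sign(bp - last[3]))
                else:
                    cur, direction = [x], 0
    runs.append(cur)
    return runs


# ---------------------------------------------------------------------------
# block statistics

def block_stats(blocks: list, gmap: GeneticMap) -> list[BlockStats]:
    """Per-genome totals/averages and the proportion of the linkage map
    covered (overlapping block cM intervals merged within each LG before
    summation)."""
    by_genome: dict = {}
    for b in blocks:
        by_genome.setdefault(b.genome_id, []).append(b)
    map_len = gmap.total_length
    out = []
    for genome_id in sorted(by_genome):
        bs = by_genome[genome_id]
        n_blocks = len(bs)
        n_loci = sum(b.n_loci for b in bs)
        total_mb = sum(b.bp_span for b in bs) / 1e6
        total_cm = sum(b.cm_span for b in bs)
        covered = _merged_cm(bs)
        out.append(BlockStats(
            genome_id, n_blocks, n_loci,
            avg_loci_per_block=round(n_loci / n_blocks, 1) if n_blocks else 0.0,
            total_mb=round(total_mb, 2),
            avg_mb=round(total_mb / n_blocks, 2) if n_blocks else 0.0,
            total_cM=round(total_cm, 1),
            avg_cM=round(total_cm / n_blocks, 1) if n_blocks else 0.0,
            coverage_pct=round(100.0 * covered / map_len, 1) if map_len else 0.0,
        ))
    return out


def union_coverage_pct(blocks: list, gmap: GeneticMap) -> float:
    """Proportion of the map covered by blocks of *any* genome (cM
    intervals merged per LG across genomes)."""
    covered = _merged_cm(blocks)
    return round(100.0 * covered / gmap.total_length, 1) if gmap.total_length else 0.0


def _merged_cm(blocks: list) -> float:
    by_lg: dict = {}
    for b in blocks:
        by_lg.setdefault(b.lg, []).append((b.cm_start, b.cm_end))
    total = 0.0
    for ivs in by_lg.values():
        ivs.sort()
        cur_lo, cur_hi = ivs[0]
        for lo, hi in ivs[1:]:
            if lo <= cur_hi:
                cur_hi = max(cur_hi, hi)
            else:
                total += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
        total += cur_hi - cur_lo
    return total


# ---------------------------------------------------------------------------
# feature placement

def place_features(
    feature_hits: pd.DataFrame,
    blocks: list,
    gmap: GeneticMap,
    anchors: pd.DataFrame,
    min_evalue: float = 1e-10,
    min_bitscore_margin: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Localize external feature sequences on the map.

    Each feature is anchored per genome by the best-unique-hit rule; if its
    bp position falls within a block of that genome, the feature is placed
    at the linear bp interpolation between the flanking mapped loci (a
    feature at a member locus's exact bp gets that locus's cM). Returns
    ``(placements, unplaced)``; features supported by several genomes
    report every placement, with the smallest-evalue one marked primary.
    """
    del anchors  # flank bp positions are carried on the blocks themselves
    pos_of = {
        lid: (g.lg_id, p)
        for g in gmap.linkage_groups
        for lid, p in zip(g.locus_ids, g.positions)
    }
    placements, unplaced = [], []
    if feature_hits.empty:
        return (
            pd.DataFrame(columns=["feature_id", "genome_id", "block_id", "lg",
                                  "flank_left", "flank_right", "position_cM",
                                  "evalue", "primary"]),
            pd.DataFrame(columns=["feature_id", "genome_id", "reason"]),
        )
    genomes = sorted({b.genome_id for b in blocks}) or ["genome"]
    for genome_id in genomes:
        fa = best_unique_hits(feature_hits, genome_id, min_evalue, min_bitscore_margin)
        gblocks = [b for b in blocks if b.genome_id == genome_id]
        for _, row in fa.iterrows():
            placed = _place_one(row, gblocks, pos_of)
            if placed is None:
                unplaced.append((row["locus_id"], genome_id, "outside_blocks"))
            else:
                placements.append(placed)
    pl = pd.DataFrame(
        placements,
        columns=["feature_id", "genome_id", "block_id", "lg", "flank_left",
                 "flank_right", "position_cM", "evalue"],
    )
    pl["primary"] = False
    if len(pl):
        idx = pl.groupby("feature_id")["evalue"].idxmin()
        pl.loc[idx, "primary"] = True
    un = pd.DataFrame(unplaced, columns=["feature_id", "genome_id", "reason"])
    # a feature is only reported unplaced if no genome placed it
    if len(pl):
        un = un[~un["feature_id"].isin(set(pl["feature_id"]))].reset_index(drop=True)
    return pl, un


def _place_one(row, gblocks, pos_of) -> Optional[tuple]:
    bp = int(row["bp_mid"])
    chrom = row["chromosome"]
    for b in gblocks:
        if b.chromosome != chrom or not (b.bp_min <= bp <= b.bp_max):
            continue
        members = [(l, pos_of[l][1], mb) for l, mb in zip(b.locus_ids, b.member_bps)]
        members.sort(key=lambda t: t[2])
        for (l1, c1, b1), (l2, c2, b2) in zip(members, members[1:]):
            if b1 <= bp <= b2:
                if bp == b1:
                    cm = c1
                elif bp == b2:
                    cm = c2
                else:
                    cm = c1 + (bp - b1) / (b2 - b1) * (c2 - c1)
                left, right = (l1, l2) if c1 <= c2 else (l2, l1)
                return (row["locus_id"], b.genome_id, b.block_id, b.lg,
                        left, right, float(round(cm, 6)), float(row["evalue"]))
    return None


def cluster_placements(placements: pd.DataFrame, max_gap_cM: float = 1.0) -> pd.DataFrame:
    """Single-linkage clustering of primary placements along each LG: two
    features join a cluster when separated by at most ``max_gap_cM``.
    Returns placements annotated with cluster_id and cluster_size."""
    if placements.empty:
        return placements.assign(cluster_id=pd.Series(dtype=str),
                                 cluster_size=pd.Series(dtype=int))
    prim = placements[placements["primary"]].copy() if "primary" in placements else placements.copy()
    prim = prim.sort_values(["lg", "position_cM", "feature_id"], kind="stable")
    ids, sizes = [], {}
    for lg, sub in prim.groupby("lg", sort=True):
        k = 0
        prev = None
        for i, (_, row) in enumerate(sub.iterrows()):
            if prev is not None and row["position_cM"] - prev > max_gap_cM:
                k += 1
            cid = f"{lg}:c{k}"
            ids.append(cid)
            sizes[cid] = sizes.get(cid, 0) + 1
            prev = row["position_cM"]
    prim["cluster_id"] = ids
    prim["cluster_size"] = prim["cluster_id"].map(sizes)
    return prim.reset_index(drop=True)
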